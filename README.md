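# evotherm

Analysis toolkit for long-term thermal selection experiments in clonal
microbial populations. It covers the full computational arc of such a
study:

- **`evotherm.simulate`** — synthetic data with known truth for every
  input the pipeline consumes: pooled-sequencing VCFs (clonal ancestor
  whose only standing variation is heterozygosity at frequency 0.5,
  evolved pools with planted heterozygosity-loss and de-novo fixations,
  reads drawn binomially at Poisson depth with a symmetric per-read error
  rate), thermal-response and light-response rate tables, and logistic
  growth series. Identical configs give byte-identical outputs.
- **`evotherm.growth`** — specific growth rates from paired counts,
  logistic growth fits, and weekly trajectory binning with Tukey whiskers.
- **`evotherm.tpc`** — a Boltzmann-rise / high-temperature-inactivation
  thermal performance model with closed-form optimum temperature,
  bounded multi-start least-squares fitting, and AICc model comparison
  with weight-based averaging.
- **`evotherm.metabolism`** — photoinhibition light-response fitting,
  gross photosynthesis, O2-to-carbon unit conversion via the C:N-derived
  assimilation quotient M = n/(n+2), carbon-use efficiency (1 − R/P), and
  PSII quantum-yield light decay.
- **`evotherm.variants`** — VCF parsing (DP/AD per sample, INFO IDV),
  quality/depth/indel-proximity filtering, exact binomial
  allele-frequency intervals, fixation calling for de-novo and
  heterozygosity-loss events with per-criterion audit booleans, a minimal
  single-CDS coding-effect annotator, and frequency-matrix assembly.
- **`evotherm.stats`** — squared-Euclidean distance matrices,
  hierarchical AMOVA with permutation significance, PERMANOVA,
  homogeneity-of-dispersion tests with Tukey HSD contrasts, PCA with
  top-loading treatment association, and score-weighted KS enrichment.

## Command line

Every analysis is exposed through one entry point:

```sh
# generate a synthetic experiment
evotherm simulate poolseq --seed 11 --out-dir sim/
evotherm simulate tpc --seed 2 --out tpc.tsv

# variant pipeline
evotherm variants filter sim/anc.vcf
evotherm variants call sim/*.vcf --out calls.tsv
evotherm variants matrix sim/*.vcf --calls calls.tsv --fixed-only --out fm.tsv

# divergence statistics
evotherm stats amova fm.tsv sim/samples.tsv --n-perm 999 --seed 1
evotherm stats permanova fm.tsv sim/samples.tsv
evotherm stats pca fm.tsv sim/samples.tsv --scores-out scores.tsv --loadings-out loadings.tsv

# physiology
evotherm tpc fit tpc.tsv --tc 18
evotherm metab fit-pi pi.tsv --out pifits.tsv
evotherm metab cue pifits.tsv
evotherm growth fit growth.tsv
evotherm growth bin rates.tsv --bin-width 7
```

Filter and caller thresholds are configurable
(`--min-qual 35 --min-dp 5 --min-idv 2 --snp-gap 10 --anc-depth 10
--evo-depth 5 --het-window 0.2` are the defaults).

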