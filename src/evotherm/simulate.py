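"""Synthetic data with known truth for every pipeline input.

Generates pooled-sequencing VCFs (a clonal ancestor whose only standing
variation is heterozygosity at frequency 0.5, plus evolved pools with
planted heterozygosity-loss and de-novo fixations), thermal-response and
light-response rate tables, and logistic growth series. All randomness
derives from a single named seed; identical configs produce byte-identical
outputs.

The read model at each site and sample draws depth D ~ Poisson(lambda)
(floored at 1) and observed alt count A ~ Binomial(D, f(1-e) + (1-f)e)
where f is the true allele frequency and e the symmetric per-read
substitution error rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .growth import logistic
from .metabolism import PhotoinhibitionParams, np_at_irradiance
from .tpc import SharpeSchoolfieldParams, celsius_to_kelvin, ss_log_rate
from .variants import VariantRecord

__all__ = [
    "SimulationConfig",
    "DEFAULT_TREATMENTS",
    "simulate_pool_seq",
    "simulate_tpc_data",
    "simulate_pi_curves",
    "simulate_growth_series",
    "sample_manifest",
    "write_vcf",
    "config_to_yaml",
    "config_from_yaml",
]

DEFAULT_TREATMENTS = ("22C", "26C", "32C", "FS")

# assay grids: temperatures 4..45 degC in 3 degC steps; irradiance steps of
# 50 up to 300, 100 up to 1000, then 200 up to 2000 umol quanta m^-2 s^-1
TPC_TEMP_GRID_C = tuple(float(t) for t in range(4, 46, 3))
PI_IRRADIANCE_GRID = tuple(
    float(i)
    for i in list(range(0, 301, 50)) + list(range(400, 1001, 100)) + list(range(1200, 2001, 200))
)

_DEFAULT_TPC_TRUTH = SharpeSchoolfieldParams(
    ln_b_tc=-0.5, ea=1.0, eh=3.5, th=303.15
)
_DEFAULT_PI_TRUTH = PhotoinhibitionParams(np_max=10.0, alpha=0.1, i_opt=400.0, r=2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Seeds, depths, error rates, planted truth and curve parameters.

    ``n_het_sites`` ancestral sites are heterozygous (frequency 0.5); each
    evolved population receives ``n_hetfix_per_population`` planted
    heterozygosity-loss fixations and ``n_denovo_per_population`` de-novo
    fixations. ``n_indel_sites`` places indel records (no generative indel
    model) to exercise the indel-proximity filter.
    """

    seed: int = 0
    n_treatments: int = 4
    n_replicates_per_treatment: int = 6
    n_sites: int = 200
    mean_depth: float = 25.0
    error_rate: float = 0.001
    n_het_sites: int = 100
    n_denovo_per_population: int = 2
    n_hetfix_per_population: int = 10
    n_indel_sites: int = 0
    depth_distribution: str = "poisson"  # or "fixed"; library depths unreported
    qual_floor: float = 35.0
    treatments: tuple[str, ...] | None = None
    tpc_truth: dict[str, SharpeSchoolfieldParams] = field(default_factory=dict)
    rate_noise_sd: float = 0.1
    n_tpc_replicates: int = 6
    pi_truth: PhotoinhibitionParams = _DEFAULT_PI_TRUTH
    pi_noise_sd: float = 0.0
    growth_truth: tuple[float, float, float] = (1e6, 0.8, 100.0)  # (K, r, N0)
    growth_noise_cv: float = 0.0
    time_grid: tuple[float, ...] = tuple(float(t) for t in range(15))

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must satisfy 0 <= e < 0.5")
        if self.mean_depth <= 0:
            raise ValueError("mean depth (Poisson rate) must be positive")
        if self.n_het_sites + self.n_indel_sites > self.n_sites:
            raise ValueError("het + indel sites exceed n_sites")
        if self.n_hetfix_per_population > self.n_het_sites:
            raise ValueError("cannot plant more het-fixations than het sites")
        n_plain = self.n_sites - self.n_het_sites - self.n_indel_sites
        if self.n_denovo_per_population > n_plain:
            raise ValueError("cannot plant more de-novo fixations than free sites")
        if self.n_hetfix_per_population + self.n_denovo_per_population > self.n_sites:
            raise ValueError("planted fixations exceed n_sites")
        if self.depth_distribution not in ("poisson", "fixed"):
            raise ValueError("depth_distribution must be 'poisson' or 'fixed'")
        if self.n_treatments < 1 or self.n_replicates_per_treatment < 1:
            raise ValueError("need at least one treatment and one replicate")
        if self.treatments is not None and len(self.treatments) != self.n_treatments:
            raise ValueError("treatments length must equal n_treatments")

    @property
    def treatment_labels(self) -> tuple[str, ...]:
        if self.treatments is not None:
            return tuple(self.treatments)
        if self.n_treatments <= len(DEFAULT_TREATMENTS):
            return DEFAULT_TREATMENTS[: self.n_treatments]
        return tuple(f"T{i + 1}" for i in range(self.n_treatments))

    def tpc_truth_for(self, treatment: str) -> SharpeSchoolfieldParams:
        return self.tpc_truth.get(treatment, _DEFAULT_TPC_TRUTH)


def sample_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Sample table: the ancestor plus one row per evolved population."""
    rows = [{"sample": "anc", "treatment": "ancestor", "replicate": "0"}]
    for t in config.treatment_labels:
        for r in range(1, config.n_replicates_per_treatment + 1):
            rows.append({"sample": f"{t}_r{r}", "treatment": t, "replicate": str(r)})
    return pd.DataFrame(rows)


def _site_layout(config: SimulationConfig, rng: np.random.Generator):
    """Positions, alleles and per-population truth frequencies."""
    bases = np.array(list("ACGT"))
    n = config.n_sites
    positions = 100 * (np.arange(n) + 1)  # spaced to stay clear of SnpGap
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = bases[ref_idx]
    alts = bases[(ref_idx + alt_shift) % 4]

    order = rng.permutation(n)
    het_sites = np.sort(order[: config.n_het_sites])
    indel_sites = np.sort(order[config.n_het_sites: config.n_het_sites + config.n_indel_sites])
    free_sites = np.sort(order[config.n_het_sites + config.n_indel_sites:])
    # place indel records 5 bp downstream of the preceding SNV slot so the
    # indel-proximity filter has something to catch
    positions = positions.copy()
    positions[indel_sites] -= 95
    return positions, refs, alts, het_sites, indel_sites, free_sites


def simulate_pool_seq(
    config: SimulationConfig, out_dir=None
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame, dict[str, str] | None]:
    """Simulate pooled-seq read counts for the ancestor and evolved pools.

    Returns per-sample record lists, the truth table (one row per site and
    population with the true ancestral/evolved frequencies and planted
    category), and, if ``out_dir`` is given, the paths of one VCF written
    per sample.
    """
    rng = np.random.default_rng(config.seed)
    positions, refs, alts, het_sites, indel_sites, free_sites = _site_layout(config, rng)
    n = config.n_sites
    manifest = sample_manifest(config)
    evolved = [s for s in manifest["sample"] if s != "anc"]

    f_anc = np.zeros(n)
    f_anc[het_sites] = 0.5

    # plant per-population fixations
    f_evo = {}
    categories = {}
    for pop in evolved:
        f = f_anc.copy()
        cat = np.where(f_anc == 0.5, "unchanged_het", "absent").astype(object)
        hetfix = rng.choice(het_sites, size=config.n_hetfix_per_population, replace=False)
        denovo = rng.choice(free_sites, size=config.n_denovo_per_population, replace=False)
        f[hetfix] = 1.0
        f[denovo] = 1.0
        cat[hetfix] = "het_origin_fixed"
        cat[denovo] = "de_novo_fixed"
        cat[indel_sites] = "indel"
        f_evo[pop] = f
        categories[pop] = cat

    # draw reads per sample
    def draw(freqs):
        if config.depth_distribution == "fixed":
            depth = np.full(n, max(int(round(config.mean_depth)), 1))
        else:
            depth = np.maximum(rng.poisson(config.mean_depth, size=n), 1)
        p = freqs * (1.0 - config.error_rate) + (1.0 - freqs) * config.error_rate
        alt_count = rng.binomial(depth, p)
        return depth, alt_count

    per_sample: dict[str, list[VariantRecord]] = {}
    is_indel = np.zeros(n, dtype=bool)
    is_indel[indel_sites] = True

    def records_for(sample, freqs):
        depth, alt_count = draw(freqs)
        recs = []
        for i in range(n):
            ref = refs[i] + "T" if is_indel[i] else refs[i]
            alt = refs[i] if is_indel[i] else alts[i]
            recs.append(
                VariantRecord(
                    chrom="chr1",
                    pos=int(positions[i]),
                    ref=ref,
                    alt=alt,
                    qual=float(config.qual_floor + depth[i]),
                    is_indel=bool(is_indel[i]),
                    depths={sample: int(depth[i])},
                    alt_depths={sample: int(alt_count[i])},
                    idv=int(alt_count[i]) if is_indel[i] else None,
                )
            )
        return recs

    per_sample["anc"] = records_for("anc", f_anc)
    for pop in evolved:
        per_sample[pop] = records_for(pop, f_evo[pop])

    truth_rows = []
    for pop in evolved:
        for i in range(n):
            truth_rows.append(
                {
                    "site": f"chr1:{positions[i]}",
                    "locus_id": per_sample[pop][i].locus_id,
                    "population": pop,
                    "f_anc": f_anc[i],
                    "f_evo": f_evo[pop][i],
                    "category": categories[pop][i],
                }
            )
    truth = pd.DataFrame(truth_rows)

    paths = None
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for sample in ["anc"] + evolved:
            path = os.path.join(str(out_dir), f"{sample}.vcf")
            write_vcf(per_sample[sample], sample, path)
            paths[sample] = path
    return per_sample, truth, paths


def write_vcf(records, sample: str, path) -> None:
    """Write single-sample records as VCF v4.2 with DP/AD and INFO IDV."""
    max_pos = max((r.pos for r in records), default=1)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={max_pos + 1000}>",
        '##INFO=<ID=IDV,Number=1,Type=Integer,Description="Maximum number of raw reads supporting an indel">',
        '##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indicates that the variant is an INDEL">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        d = r.depths[sample]
        a = r.alt_depths[sample]
        info_parts = []
        if r.is_indel:
            info_parts.append("INDEL")
        if r.idv is not None:
            info_parts.append(f"IDV={r.idv}")
        info = ";".join(info_parts) or "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.1f}\t.\t{info}"
            f"\tDP:AD\t{d}:{d - a},{a}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def simulate_tpc_data(config: SimulationConfig) -> pd.DataFrame:
    """Thermal-response rate table over the 4-45 degC assay grid.

    Rates are the model curve exp(ln b(T)) under each treatment's truth
    parameters, multiplied by lognormal noise with log-sd
    ``rate_noise_sd``, replicated per biological replicate.
    """
    rng = np.random.default_rng(config.seed + 1)
    temps = np.array(TPC_TEMP_GRID_C)
    t_k = celsius_to_kelvin(temps)
    rows = []
    for treatment in config.treatment_labels:
        truth = config.tpc_truth_for(treatment)
        curve = np.exp(ss_log_rate(t_k, truth))
        for rep in range(1, config.n_tpc_replicates + 1):
            noise = (
                np.exp(rng.normal(0.0, config.rate_noise_sd, size=len(temps)))
                if config.rate_noise_sd > 0
                else np.ones(len(temps))
            )
            for t_c, rate in zip(temps, curve * noise):
                rows.append(
                    {
                        "temp_c": t_c,
                        "rate": rate,
                        "flux": "growth",
                        "replicate": f"r{rep}",
                        "treatment": treatment,
                    }
                )
    return pd.DataFrame(rows)


def simulate_pi_curves(config: SimulationConfig) -> pd.DataFrame:
    """Light-response table over the stepped irradiance grid.

    Observations are the photoinhibition model at ``pi_truth`` plus
    additive Gaussian noise with sd ``pi_noise_sd`` (zero noise returns
    the exact curve; at I=0 the observation is -R).
    """
    rng = np.random.default_rng(config.seed + 2)
    grid = np.array(PI_IRRADIANCE_GRID)
    curve = np_at_irradiance(grid, config.pi_truth)
    rows = []
    for treatment in config.treatment_labels:
        for rep in range(1, config.n_replicates_per_treatment + 1):
            noise = (
                rng.normal(0.0, config.pi_noise_sd, size=len(grid))
                if config.pi_noise_sd > 0
                else np.zeros(len(grid))
            )
            for i, y in zip(grid, curve + noise):
                rows.append(
                    {
                        "irradiance": i,
                        "net_o2_flux": y,
                        "replicate": f"r{rep}",
                        "treatment": treatment,
                    }
                )
    return pd.DataFrame(rows)


def simulate_growth_series(config: SimulationConfig) -> pd.DataFrame:
    """Logistic cell-count time series with multiplicative lognormal noise.

    ``growth_noise_cv`` is the coefficient of variation of the counts;
    zero noise returns the exact logistic curve, which plateaus at K.
    """
    rng = np.random.default_rng(config.seed + 3)
    k, r, n0 = config.growth_truth
    t = np.array(config.time_grid, dtype=float)
    curve = logistic(t, k, r, n0)
    sd = np.sqrt(np.log1p(config.growth_noise_cv**2))
    rows = []
    for treatment in config.treatment_labels:
        for rep in range(1, config.n_replicates_per_treatment + 1):
            noise = np.exp(rng.normal(0.0, sd, size=len(t))) if sd > 0 else np.ones(len(t))
            for ti, ni in zip(t, curve * noise):
                rows.append(
                    {
                        "time_days": ti,
                        "cells_per_ml": ni,
                        "replicate": f"r{rep}",
                        "treatment": treatment,
                    }
                )
    return pd.DataFrame(rows)


# --- config serialization --------------------------------------------------


def config_to_yaml(config: SimulationConfig, path) -> None:
    """Write the config as a flat YAML mapping."""
    d = dataclasses.asdict(config)
    d["pi_truth"] = dataclasses.asdict(config.pi_truth)
    d["tpc_truth"] = {
        k: dataclasses.asdict(v) for k, v in config.tpc_truth.items()
    }
    d["growth_truth"] = list(config.growth_truth)
    d["time_grid"] = list(config.time_grid)
    if config.treatments is not None:
        d["treatments"] = list(config.treatments)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["pi_truth"] = PhotoinhibitionParams(**d["pi_truth"])
    d["tpc_truth"] = {
        k: SharpeSchoolfieldParams(**v) for k, v in d.get("tpc_truth", {}).items()
    }
    d["growth_truth"] = tuple(d["growth_truth"])
    d["time_grid"] = tuple(d["time_grid"])
    if d.get("treatments") is not None:
        d["treatments"] = tuple(d["treatments"])
    return SimulationConfig(**d)
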