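"""Pooled-sequencing variant handling: VCF parsing and filtering, binomial
allele-frequency estimation, fixation calling for evolved populations,
a minimal coding-effect annotator, and frequency-matrix assembly.

Coordinates are 1-based inclusive at VCF boundaries and converted to
0-based offsets only inside the coding-effect annotator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta, norm

logger = logging.getLogger(__name__)

SNV_BASES = frozenset("ACGT")

__all__ = [
    "VariantRecord",
    "AlleleFrequencyEstimate",
    "FixationCall",
    "FrequencyMatrix",
    "GeneModel",
    "read_vcf",
    "merge_records",
    "filter_variants",
    "estimate_allele_frequency",
    "prob_missed_het",
    "prob_false_fixation",
    "call_fixation",
    "call_fixations_table",
    "annotate_coding_effect",
    "read_gene_models",
    "read_genome",
    "build_frequency_matrix",
]


@dataclass
class VariantRecord:
    """One VCF site with per-sample read counts.

    ``depths`` and ``alt_depths`` map sample id to total aligned depth D
    and alt-supporting read count A (0 <= A <= D). ``idv`` is the
    indel-supporting read count where defined (indel records only).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    is_indel: bool
    depths: dict[str, int] = field(default_factory=dict)
    alt_depths: dict[str, int] = field(default_factory=dict)
    idv: int | None = None

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def counts(self, sample: str) -> tuple[int, int]:
        """(A, D) for one sample; raises KeyError for unknown samples."""
        return self.alt_depths[sample], self.depths[sample]


@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    f_hat: float
    a: int
    d: int
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


@dataclass(frozen=True)
class FixationCall:
    """Fixation classification of one site in one evolved population.

    ``criteria`` records the five audit booleans:
    i   ancestral depth >= anc_min_depth,
    ii  ancestral alt count == 0 (de novo) / ancestral frequency in the
        heterozygous window (het origin),
    iii evolved depth >= evo_min_depth,
    iv  evolved alt fraction == 1,
    v   site passed the record filter in at least one population.
    """

    locus_id: str
    population: str
    category: str  # de_novo_fixed | het_origin_fixed | not_fixed | not_assessable
    criteria: dict[str, bool]


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Read an uncompressed VCF (v4.2, FORMAT DP/AD, INFO IDV) via cyvcf2.

    Multi-allelic records are split into one record per alt allele.
    Records with malformed AD are skipped with a warning. Returns the
    records and the sample names.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        dp = v.format("DP")
        ad = v.format("AD")
        if dp is None or ad is None:
            logger.warning("skipping %s:%s: missing DP/AD", v.CHROM, v.POS)
            continue
        for alt_i, alt in enumerate(v.ALT):
            depths, alt_depths = {}, {}
            ok = True
            for s_i, s in enumerate(samples):
                d = int(dp[s_i][0])
                try:
                    a = int(ad[s_i][alt_i + 1])
                except (IndexError, ValueError):
                    ok = False
                    break
                if a < 0 or d < 0 or a > d:
                    ok = False
                    break
                depths[s] = d
                alt_depths[s] = a
            if not ok:
                logger.warning("skipping %s:%s: malformed AD", v.CHROM, v.POS)
                continue
            idv = v.INFO.get("IDV")
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    qual=float(v.QUAL) if v.QUAL is not None else float("nan"),
                    is_indel=bool(v.is_indel),
                    depths=depths,
                    alt_depths=alt_depths,
                    idv=int(idv) if idv is not None else None,
                )
            )
    return records, samples


def merge_records(per_sample: dict[str, list[VariantRecord]]) -> list[VariantRecord]:
    """Merge per-sample record lists into multi-sample records keyed by
    (chrom, pos, ref, alt). QUAL is the maximum across samples carrying
    the site; samples without the site get depth 0.
    """
    merged: dict[tuple, VariantRecord] = {}
    for sample, records in per_sample.items():
        for r in records:
            key = (r.chrom, r.pos, r.ref, r.alt)
            m = merged.get(key)
            if m is None:
                m = VariantRecord(
                    chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                    qual=r.qual, is_indel=r.is_indel, idv=r.idv,
                )
                merged[key] = m
            m.qual = max(m.qual, r.qual)
            if r.idv is not None:
                m.idv = r.idv if m.idv is None else max(m.idv, r.idv)
            m.depths[sample] = r.depths[sample]
            m.alt_depths[sample] = r.alt_depths[sample]
    out = sorted(merged.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    all_samples = list(per_sample)
    for r in out:
        for s in all_samples:
            r.depths.setdefault(s, 0)
            r.alt_depths.setdefault(s, 0)
    return out


def _check_sorted(records):
    last = None
    for r in records:
        key = (r.chrom, r.pos)
        if last is not None and key < last:
            raise ValueError("records must be sorted by (chrom, pos)")
        last = key


def filter_variants(
    records,
    *,
    min_qual: float = 35.0,
    min_dp: int = 5,
    min_idv: int = 2,
    snp_gap: int = 10,
) -> list[VariantRecord]:
    """Retain SNVs passing quality, depth, indel-support and indel-proximity
    rules.

    A record is kept iff it is a single-base A/C/G/T substitution, QUAL >=
    ``min_qual`` (boundary inclusive), min per-sample depth >= ``min_dp``,
    IDV >= ``min_idv`` where IDV is defined (missing IDV passes: the tag is
    indel-specific), and no indel record lies within ``snp_gap`` bp on the
    same chromosome. Indel proximity is assessed against all indel records
    in the input, including ones that fail other filters. Idempotent.
    """
    records = list(records)
    _check_sorted(records)
    indel_pos: dict[str, list[int]] = {}
    for r in records:
        if r.is_indel:
            indel_pos.setdefault(r.chrom, []).append(r.pos)

    kept = []
    for r in records:
        if r.is_indel:
            continue
        if len(r.ref) != 1 or len(r.alt) != 1:
            continue
        if r.ref not in SNV_BASES or r.alt not in SNV_BASES:
            continue
        if not (r.qual >= min_qual):
            continue
        if r.depths and min(r.depths.values()) < min_dp:
            continue
        if r.idv is not None and r.idv < min_idv:
            continue
        if any(abs(r.pos - p) <= snp_gap for p in indel_pos.get(r.chrom, ())):
            continue
        kept.append(r)
    return kept


def estimate_allele_frequency(
    a: int, d: int, ci_level: float = 0.95, method: str = "clopper-pearson"
) -> AlleleFrequencyEstimate:
    """Binomial allele-frequency estimate f_hat = A/D with a central CI.

    The default Clopper-Pearson (exact) interval reproduces the familiar
    half-widths for f_hat = 0.5: +/-0.31 at depth 10, +/-0.14 at 50 and
    +/-0.10 at 100 (to 2 d.p.); ``method="normal"`` selects the Wald
    approximation, which matches at the same precision.
    """
    a, d = int(a), int(d)
    if d < 1:
        raise ValueError("depth must be >= 1 (depth 0 is not assessable)")
    if not 0 <= a <= d:
        raise ValueError("alt count must satisfy 0 <= A <= D")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    f = a / d
    alpha = 1.0 - ci_level
    if method == "clopper-pearson":
        lo = 0.0 if a == 0 else float(beta.ppf(alpha / 2, a, d - a + 1))
        hi = 1.0 if a == d else float(beta.ppf(1 - alpha / 2, a + 1, d - a))
    elif method == "normal":
        z = float(norm.ppf(1 - alpha / 2))
        half = z * math.sqrt(f * (1 - f) / d)
        lo, hi = max(0.0, f - half), min(1.0, f + half)
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return AlleleFrequencyEstimate(f, a, d, lo, hi, ci_level)


def prob_missed_het(d: int) -> float:
    """Probability that a frequency-0.5 allele is absent from d reads: 0.5^d."""
    d = int(d)
    if d < 0:
        raise ValueError("depth must be non-negative")
    return 0.5**d


def prob_false_fixation(d: int, err: float) -> float:
    """Probability that d reads all show an absent allele by error: err^d."""
    d = int(d)
    err = float(err)
    if d < 0:
        raise ValueError("depth must be non-negative")
    if not 0 <= err <= 1:
        raise ValueError("error rate must be in [0, 1]")
    return err**d


def call_fixation(
    record: VariantRecord,
    ancestor: str,
    populations,
    *,
    anc_min_depth: int = 10,
    evo_min_depth: int = 5,
    het_window: float = 0.2,
    passed_filter: bool = True,
) -> list[FixationCall]:
    """Classify one site as fixed or not in each evolved population.

    De-novo fixation requires ancestral depth >= ``anc_min_depth`` with
    zero ancestral alt reads and an evolved alt fraction of exactly 1 at
    depth >= ``evo_min_depth``. Heterozygosity-loss fixation instead
    requires the ancestral frequency estimate to lie in the inclusive
    window 0.5 +/- ``het_window``. Depth failures yield ``not_assessable``.
    """
    if ancestor not in record.depths:
        raise KeyError(f"unknown ancestor sample {ancestor!r}")
    a0, d0 = record.counts(ancestor)
    calls = []
    for pop in populations:
        if pop not in record.depths:
            raise KeyError(f"unknown population sample {pop!r}")
        ap, dp_ = record.counts(pop)
        c1 = d0 >= anc_min_depth
        c2_denovo = c1 and a0 == 0
        f0 = a0 / d0 if d0 > 0 else float("nan")
        c2_het = c1 and (0.5 - het_window) <= f0 <= (0.5 + het_window)
        c3 = dp_ >= evo_min_depth
        c4 = dp_ > 0 and ap == dp_
        c5 = bool(passed_filter)
        if not (c1 and c3):
            category = "not_assessable"
        elif c4 and c5 and c2_denovo:
            category = "de_novo_fixed"
        elif c4 and c5 and c2_het:
            category = "het_origin_fixed"
        else:
            category = "not_fixed"
        calls.append(
            FixationCall(
                locus_id=record.locus_id,
                population=pop,
                category=category,
                criteria={
                    "i_anc_depth": c1,
                    "ii_anc_state": c2_denovo or c2_het,
                    "iii_evo_depth": c3,
                    "iv_evo_fixed": c4,
                    "v_passed_filter": c5,
                },
            )
        )
    return calls


def call_fixations_table(
    per_sample: dict[str, list[VariantRecord]],
    ancestor: str,
    populations,
    *,
    filter_kwargs: dict | None = None,
    **call_kwargs,
) -> pd.DataFrame:
    """Run the full calling pipeline over per-sample record lists.

    Each evolved sample's records are filtered independently; a site is
    assessed only if it passes the filter in at least one evolved
    population (criterion v). Returns one row per (site, population) with
    the category and the five criteria booleans.
    """
    filter_kwargs = filter_kwargs or {}
    passing: set[tuple] = set()
    for sample in populations:
        for r in filter_variants(per_sample[sample], **filter_kwargs):
            passing.add((r.chrom, r.pos, r.ref, r.alt))
    merged = merge_records(per_sample)
    rows = []
    for rec in merged:
        if rec.is_indel:
            continue
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        if key not in passing:
            continue
        for call in call_fixation(rec, ancestor, populations, **call_kwargs):
            row = {
                "locus_id": call.locus_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "population": call.population,
                "category": call.category,
            }
            row.update(call.criteria)
            rows.append(row)
    return pd.DataFrame(rows)


# --- minimal coding-effect annotation -------------------------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS gene model: ordered 1-based inclusive CDS intervals."""

    name: str
    chrom: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for start, end in self.cds:
            if start > end or start < 1:
                raise ValueError(f"invalid CDS interval ({start}, {end})")


def read_genome(fasta_path) -> dict[str, str]:
    """Load a FASTA genome into a dict of uppercase sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Read single-CDS gene models from a GFF3 file (CDS features grouped
    by their Parent, or ID when parentless)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", cds.attributes.get("ID", [cds.id]))[0]
        grouped.setdefault(parent, []).append(cds)
    models = []
    for name, feats in sorted(grouped.items()):
        feats.sort(key=lambda f: f.start)
        models.append(
            GeneModel(
                name=name,
                chrom=feats[0].seqid,
                strand=feats[0].strand,
                cds=tuple((f.start, f.end) for f in feats),
            )
        )
    return models


def annotate_coding_effect(
    chrom: str, pos: int, ref: str, alt: str,
    gene_models, genome: dict[str, str],
) -> str:
    """Classify a substitution as synonymous/missense/stop_gained/non_coding.

    The codon containing the site is translated before and after the
    substitution, reverse-complementing on minus-strand genes. A CDS whose
    length is not divisible by 3 is a model error.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("annotator handles single-base substitutions only")
    for gm in gene_models:
        if gm.chrom != chrom:
            continue
        if not any(start <= pos <= end for start, end in gm.cds):
            continue
        seq = genome[chrom]
        for start, end in gm.cds:
            if end > len(seq):
                raise ValueError(f"gene model {gm.name} exceeds genome bounds")
        cds_positions = [p for start, end in gm.cds for p in range(start, end + 1)]
        cds_seq = "".join(seq[p - 1] for p in cds_positions)
        if seq[pos - 1] != ref:
            logger.warning(
                "reference mismatch at %s:%d (genome %s, record %s)",
                chrom, pos, seq[pos - 1], ref,
            )
        offset = cds_positions.index(pos)  # 0-based within forward CDS
        mutated = cds_seq[:offset] + alt + cds_seq[offset + 1:]
        if gm.strand == "-":
            cds_seq = cds_seq[::-1].translate(_COMPLEMENT)
            mutated = mutated[::-1].translate(_COMPLEMENT)
            offset = len(cds_seq) - 1 - offset
        if len(cds_seq) % 3 != 0:
            raise ValueError(f"CDS length of {gm.name} not divisible by 3")
        ci = offset // 3
        codon_ref = cds_seq[3 * ci: 3 * ci + 3]
        codon_alt = mutated[3 * ci: 3 * ci + 3]
        aa_ref = CODON_TABLE[codon_ref]
        aa_alt = CODON_TABLE[codon_alt]
        if aa_ref == aa_alt:
            return "synonymous"
        if aa_alt == "*":
            return "stop_gained"
        return "missense"
    return "non_coding"


# --- frequency matrix ------------------------------------------------------

NON_SILENT = {"missense", "stop_gained"}


@dataclass
class FrequencyMatrix:
    """Loci x samples allele-frequency matrix with a missingness mask.

    ``values`` is indexed by locus id with one column per sample; ``mask``
    is True where the frequency is missing (zero depth). ``metadata`` holds
    per-locus chrom/pos/gene/effect annotations when available.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def complete_cases(self) -> pd.DataFrame:
        """Drop loci with any masked cell (locus-wise complete-case)."""
        keep = ~self.mask.any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d loci with missing cells", dropped)
        return self.values.loc[keep]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out[self.mask] = np.nan
        out.to_csv(path, sep="\t", index_label="locus_id", na_rep="NA")


def build_frequency_matrix(
    records,
    samples,
    *,
    fixed_only: bool = False,
    calls: pd.DataFrame | None = None,
    effect_filter: str = "all",
    effects: dict[str, str] | None = None,
) -> FrequencyMatrix:
    """Assemble the loci x samples frequency matrix from merged records.

    With ``fixed_only`` a locus is retained only if ``calls`` (a fixation
    table) reports a fixation in at least one population; with
    ``effect_filter="non-silent"`` only missense/stop_gained loci (per
    ``effects``) are kept. Cells with zero depth are masked, not zero.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in manifest")
    if fixed_only:
        if calls is None:
            raise ValueError("fixed_only requires a fixation-call table")
        fixed_loci = set(
            calls.loc[
                calls["category"].isin(["de_novo_fixed", "het_origin_fixed"]),
                "locus_id",
            ]
        )
    if effect_filter not in ("all", "non-silent"):
        raise ValueError("effect_filter must be 'all' or 'non-silent'")
    if effect_filter == "non-silent" and effects is None:
        raise ValueError("effect_filter='non-silent' requires effects")

    rows, mask_rows, meta = [], [], []
    for rec in records:
        lid = rec.locus_id
        if fixed_only and lid not in fixed_loci:
            continue
        if effect_filter == "non-silent" and effects.get(lid) not in NON_SILENT:
            continue
        freqs, miss = [], []
        for s in samples:
            a, d = rec.alt_depths.get(s, 0), rec.depths.get(s, 0)
            if d == 0:
                freqs.append(np.nan)
                miss.append(True)
            else:
                freqs.append(a / d)
                miss.append(False)
        rows.append(pd.Series(freqs, index=samples, name=lid))
        mask_rows.append(pd.Series(miss, index=samples, name=lid))
        meta.append(
            {
                "locus_id": lid,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "effect": (effects or {}).get(lid, ""),
            }
        )
    if not rows:
        logger.warning("no loci retained; returning empty matrix")
        empty = pd.DataFrame(columns=samples)
        return FrequencyMatrix(empty, empty.astype(bool), pd.DataFrame(meta))
    values = pd.DataFrame(rows)
    mask = pd.DataFrame(mask_rows)
    return FrequencyMatrix(values, mask, pd.DataFrame(meta).set_index("locus_id"))
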