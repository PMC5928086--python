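"""Divergence statistics on allele-frequency matrices: squared-Euclidean
distances, hierarchical AMOVA with permutation significance, PERMANOVA,
homogeneity of dispersion with Tukey HSD contrasts, PCA with top-loading
treatment association, and score-weighted KS enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "AMOVAResult",
    "PermanovaResult",
    "DispersionResult",
    "PCAResult",
    "LoadingAssociation",
    "EnrichmentResult",
    "distance_matrix",
    "amova",
    "permanova",
    "dispersion_test",
    "pca",
    "top_loading_associations",
    "weighted_ks_enrichment",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise (squared) Euclidean distances among samples."""

    values: np.ndarray
    ids: tuple[str, ...]
    squared: bool = True

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids must match matrix dimension")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    @property
    def d2(self) -> np.ndarray:
        """Squared distances regardless of storage convention."""
        return self.values if self.squared else self.values**2

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(fm, *, squared: bool = True) -> DistanceMatrix:
    """Pairwise (squared) Euclidean distances among sample columns.

    ``fm`` is a loci x samples DataFrame or a FrequencyMatrix (in which
    case loci with masked cells are dropped, complete-case)."""
    if hasattr(fm, "complete_cases"):
        df = fm.complete_cases()
    else:
        df = fm
    x = df.to_numpy(dtype=float).T  # samples x loci
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("masked cells present; drop incomplete loci first")
    metric = "sqeuclidean" if squared else "euclidean"
    return DistanceMatrix(squareform(pdist(x, metric=metric)), tuple(df.columns), squared)


# --- AMOVA -----------------------------------------------------------------


@dataclass(frozen=True)
class AMOVAResult:
    """Variance components per hierarchical level with permutation p-values.

    ``components`` has one row per level (plus Total) with columns sigma2,
    pct and p_value; negative component estimates are reported as-is but
    truncated to 0 when computing percentages (logged). Percentages sum
    to 100.
    """

    components: pd.DataFrame
    n_permutations: int
    seed: int | None


def _ss_within_groups(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss


def _perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    return (np.sum(permuted >= observed - 1e-12) + 1) / (len(permuted) + 1)


def _two_level_components(d2, groups):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = _ss_within_groups(d2, groups)
    ss_among = ss_total - ss_within
    uniq, counts = np.unique(groups, return_counts=True)
    g = uniq.size
    df_among, df_within = g - 1, n - g
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n - (counts**2).sum() / n) / df_among
    ms_among = ss_among / df_among
    sigma_a = (ms_among - ms_within) / n0
    return sigma_a, ms_within, ss_among, ss_within, df_among, df_within


def amova(
    dm: DistanceMatrix,
    treatments,
    populations=None,
    *,
    n_perm: int = 999,
    seed: int | None = None,
) -> AMOVAResult:
    """Hierarchical AMOVA from a squared-Euclidean distance matrix.

    With only ``treatments`` given, a two-level analysis partitions the
    variance into within- and among-treatment components. Supplying
    ``populations`` (nested in treatments, each with >= 2 samples) enables
    the three-level analysis with components for within populations,
    among populations within treatments, and between treatments.

    Significance: the between-treatment component is tested by
    unrestricted permutation of samples across treatments; the
    among-population component by permuting samples among populations
    within each treatment. p = (#permuted >= observed + 1) / (n_perm + 1).
    """
    d2 = dm.d2
    n = dm.n
    treatments = np.asarray(treatments)
    if treatments.shape != (n,):
        raise ValueError("treatments must give one label per sample")
    if np.unique(treatments).size < 2:
        raise ValueError("degenerate design: need >= 2 treatments")
    rng = np.random.default_rng(seed)

    total_pairs = d2[np.triu_indices(n, 1)].sum() / n
    if total_pairs == 0:
        logger.warning("all samples identical: variance components are 0")

    if populations is None:
        sigma_a, sigma_w, *_ = _two_level_components(d2, treatments)
        perm = np.empty(n_perm)
        for i in range(n_perm):
            perm[i] = _two_level_components(d2, rng.permutation(treatments))[0]
        p_a = _perm_pvalue(sigma_a, perm)
        comp = pd.DataFrame(
            {
                "sigma2": [sigma_w, sigma_a],
                "p_value": [np.nan, p_a],
            },
            index=["within_treatment", "between_treatments"],
        )
    else:
        populations = np.asarray(populations)
        if populations.shape != (n,):
            raise ValueError("populations must give one label per sample")
        # nesting and size checks
        pop_treat = {}
        for t, p in zip(treatments, populations):
            if pop_treat.setdefault(p, t) != t:
                raise ValueError(f"population {p!r} spans multiple treatments")
        uniq_p, counts_p = np.unique(populations, return_counts=True)
        if np.any(counts_p < 2):
            raise ValueError(
                "three-level AMOVA needs >= 2 samples per population "
                "(level: population)"
            )
        comp_obs = _three_level_components(d2, treatments, populations)
        sigma_wp, sigma_ap, sigma_bt = comp_obs
        perm_bt = np.empty(n_perm)
        perm_ap = np.empty(n_perm)
        idx = np.arange(n)
        for i in range(n_perm):
            # between treatments: permute samples freely
            order = rng.permutation(idx)
            perm_bt[i] = _three_level_components(
                d2, treatments[order], populations[order]
            )[2]
            # among populations: shuffle population labels within treatments
            pops_shuffled = populations.copy()
            for t in np.unique(treatments):
                sel = np.flatnonzero(treatments == t)
                pops_shuffled[sel] = pops_shuffled[sel][rng.permutation(sel.size)]
            perm_ap[i] = _three_level_components(d2, treatments, pops_shuffled)[1]
        comp = pd.DataFrame(
            {
                "sigma2": [sigma_wp, sigma_ap, sigma_bt],
                "p_value": [
                    np.nan,
                    _perm_pvalue(sigma_ap, perm_ap),
                    _perm_pvalue(sigma_bt, perm_bt),
                ],
            },
            index=[
                "within_population",
                "among_populations_within_treatments",
                "between_treatments",
            ],
        )

    clipped = comp["sigma2"].clip(lower=0.0)
    if (comp["sigma2"] < 0).any():
        logger.info("negative variance component truncated to 0 for percentages")
    total = clipped.sum()
    comp["pct"] = 100.0 * clipped / total if total > 0 else np.nan
    total_row = pd.DataFrame(
        {"sigma2": [comp["sigma2"].sum()], "p_value": [np.nan],
         "pct": [100.0 if total > 0 else np.nan]},
        index=["total"],
    )
    comp = pd.concat([comp, total_row])
    return AMOVAResult(comp[["sigma2", "pct", "p_value"]], n_perm, seed)


def _three_level_components(d2, treatments, populations):
    """Nested variance components (within pop, among pops in treatments,
    between treatments) from squared distances, unequal group sizes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_wp = _ss_within_groups(d2, populations)
    ss_wt = _ss_within_groups(d2, treatments)
    ss_ap = ss_wt - ss_wp
    ss_bt = ss_total - ss_wt

    uniq_t = np.unique(treatments)
    uniq_p = np.unique(populations)
    t_count = {t: np.sum(treatments == t) for t in uniq_t}
    p_count = {p: np.sum(populations == p) for p in uniq_p}
    p_of_t: dict = {}
    for t, p in zip(treatments, populations):
        p_of_t.setdefault(t, set()).add(p)

    n_t, n_p = len(uniq_t), len(uniq_p)
    df_bt, df_ap, df_wp = n_t - 1, n_p - n_t, n - n_p
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    ms_ap = ss_ap / df_ap if df_ap else 0.0
    ms_bt = ss_bt / df_bt if df_bt else 0.0

    sum_p2_over_t = sum(
        sum(p_count[p] ** 2 for p in p_of_t[t]) / t_count[t] for t in uniq_t
    )
    sum_p2 = sum(c**2 for c in p_count.values())
    sum_t2 = sum(c**2 for c in t_count.values())
    n_coef = (n - sum_p2_over_t) / df_ap if df_ap else 0.0
    n_prime = (sum_p2_over_t - sum_p2 / n) / df_bt
    n_dprime = (n - sum_t2 / n) / df_bt

    sigma_wp = ms_wp
    sigma_ap = (ms_ap - ms_wp) / n_coef if n_coef else 0.0
    sigma_bt = (ms_bt - ms_wp - n_prime * sigma_ap) / n_dprime
    return sigma_wp, sigma_ap, sigma_bt


# --- PERMANOVA and dispersion ---------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int


def _pseudo_f(d2, groups):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = _ss_within_groups(d2, groups)
    g = np.unique(groups).size
    df_among, df_within = g - 1, n - g
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0, ss_among, ss_within, df_among, df_within
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_among, ss_within, df_among, df_within


def permanova(
    dm: DistanceMatrix, groups, *, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """One-way PERMANOVA pseudo-F with permutation p-value.

    Operates on the squared distances of ``dm``; group labels are permuted
    unrestrictedly. Requires >= 2 groups with >= 2 samples each.
    """
    groups = np.asarray(groups)
    d2 = dm.d2
    if groups.shape != (dm.n,):
        raise ValueError("groups must give one label per sample")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    f_obs, ss_a, ss_w, df_a, df_w = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = _pseudo_f(d2, rng.permutation(groups))[0]
    return PermanovaResult(
        f_obs, _perm_pvalue(f_obs, perm), n_perm, seed, ss_a, ss_w, df_a, df_w
    )


@dataclass(frozen=True)
class DispersionResult:
    dispersions: pd.Series  # per-sample distance to its group centroid
    group_means: pd.Series
    f_stat: float
    p_value: float
    tukey: pd.DataFrame
    n_permutations: int
    seed: int | None
    undefined_groups: tuple[str, ...] = ()


def _pcoa_coords(dm: DistanceMatrix) -> np.ndarray:
    """Principal-coordinate embedding of the distance matrix."""
    d2 = dm.d2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(g)
    w = np.clip(w, 0.0, None)[::-1]
    v = v[:, ::-1]
    return v * np.sqrt(w)


def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    grand = values.mean()
    uniq = np.unique(groups)
    ss_between = sum(
        np.sum(groups == g) * (values[groups == g].mean() - grand) ** 2 for g in uniq
    )
    ss_within = sum(
        np.sum((values[groups == g] - values[groups == g].mean()) ** 2) for g in uniq
    )
    df_b, df_w = uniq.size - 1, len(values) - uniq.size
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def dispersion_test(
    dm: DistanceMatrix, groups, *, n_perm: int = 999, seed: int | None = None
) -> DispersionResult:
    """Homogeneity-of-dispersion test with Tukey HSD pairwise contrasts.

    Dispersion of a sample is its Euclidean distance to its group centroid
    in principal-coordinate space. The F statistic on the dispersion
    values is assessed by permuting group labels; pairwise group contrasts
    use Tukey's HSD on the same values. Groups of size 1 have undefined
    dispersion and are excluded (flagged).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = np.asarray(groups, dtype=object)
    if groups.shape != (dm.n,):
        raise ValueError("groups must give one label per sample")
    uniq, counts = np.unique(groups, return_counts=True)
    undefined = tuple(str(g) for g, c in zip(uniq, counts) if c < 2)
    keep = ~np.isin(groups, list(undefined))
    if undefined:
        logger.warning("dispersion undefined for singleton groups: %s", undefined)
    coords = _pcoa_coords(dm)[keep]
    sub_groups = groups[keep]
    if np.unique(sub_groups).size < 2:
        raise ValueError("need >= 2 groups of size >= 2")

    disp = np.empty(len(sub_groups))
    for g in np.unique(sub_groups):
        sel = sub_groups == g
        centroid = coords[sel].mean(axis=0)
        disp[sel] = np.linalg.norm(coords[sel] - centroid, axis=1)

    f_obs = _anova_f(disp, sub_groups)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(sub_groups)
        perm_disp = np.empty_like(disp)
        for g in np.unique(shuffled):
            sel = shuffled == g
            centroid = coords[sel].mean(axis=0)
            perm_disp[sel] = np.linalg.norm(coords[sel] - centroid, axis=1)
        perm[i] = _anova_f(perm_disp, shuffled)
    p = _perm_pvalue(f_obs, perm)

    ids = [s for s, k in zip(dm.ids, keep) if k]
    disp_s = pd.Series(disp, index=ids, name="dispersion")
    means = disp_s.groupby(sub_groups).mean()
    tk = pairwise_tukeyhsd(disp, sub_groups.astype(str))
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return DispersionResult(disp_s, means, f_obs, p, tukey, n_perm, seed, undefined)


# --- PCA and loadings ------------------------------------------------------


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the locus-centered frequency matrix.

    ``scores`` (samples x components) reproduce pairwise Euclidean sample
    distances; ``loadings`` (loci x components) are orthonormal;
    ``explained`` gives non-increasing variance fractions summing to <= 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    centered: pd.DataFrame = field(repr=False, default=None)


def pca(fm) -> PCAResult:
    """PCA of the loci x samples matrix (samples as observations)."""
    df = fm.complete_cases() if hasattr(fm, "complete_cases") else fm
    x = df.to_numpy(dtype=float).T  # samples x loci
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 loci")
    xc = x - x.mean(axis=0, keepdims=True)
    if np.allclose(xc, 0):
        logger.warning("constant matrix: zero total variance")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(x.shape[0] - 1, x.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    total = (s**2).sum()
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=df.columns, columns=comps)
    loadings = pd.DataFrame(vt.T, index=df.index, columns=comps)
    centered = pd.DataFrame(xc.T, index=df.index, columns=df.columns)
    return PCAResult(scores, loadings, explained, centered)


@dataclass(frozen=True)
class LoadingAssociation:
    locus_id: str
    component: int  # 1-based
    loading_score: float  # absolute loading weight
    treatment: str


def top_loading_associations(
    pca_result: PCAResult,
    treatments,
    *,
    n_top: int = 100,
    components: int = 2,
) -> list[LoadingAssociation]:
    """Associate the strongest-loading loci with a treatment.

    For each of the first ``components`` axes, the ``n_top`` loci by
    absolute loading are assigned to the treatment whose group-mean
    centered frequency at that locus has the largest absolute value; ties
    break by locus order (logged).
    """
    treatments = np.asarray(treatments)
    centered = pca_result.centered
    if treatments.shape != (centered.shape[1],):
        raise ValueError("treatments must give one label per sample")
    n_loci = centered.shape[0]
    if n_top > n_loci:
        logger.warning("n_top=%d exceeds %d loci; truncating", n_top, n_loci)
        n_top = n_loci
    uniq = list(dict.fromkeys(treatments))
    group_means = pd.DataFrame(
        {t: centered.loc[:, treatments == t].mean(axis=1) for t in uniq}
    )
    out = []
    for ci in range(min(components, pca_result.loadings.shape[1])):
        col = pca_result.loadings.iloc[:, ci]
        order = np.argsort(-np.abs(col.to_numpy()), kind="stable")[:n_top]
        for li in order:
            locus = col.index[li]
            gm = group_means.loc[locus].abs()
            best = gm.max()
            winners = gm.index[gm == best]
            if len(winners) > 1:
                logger.info("tie at locus %s; keeping first treatment", locus)
            out.append(
                LoadingAssociation(
                    locus_id=str(locus),
                    component=ci + 1,
                    loading_score=float(abs(col.iloc[li])),
                    treatment=str(winners[0]),
                )
            )
    return out


# --- enrichment ------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    ann: int  # genes annotated to the term in the universe
    sig: int  # of those, genes in the significant set
    exp: float  # ann * |significant| / |universe|
    ks_p: float
    ks_stat: float


def weighted_ks_enrichment(
    gene_scores: dict[str, float],
    annotation: dict[str, set],
    universe: set,
    *,
    significant: set | None = None,
) -> list[EnrichmentResult]:
    """Score-weighted KS enrichment of annotation terms.

    Each term's member genes are compared to the remaining universe via a
    two-sample KS test on gene scores (genes without a score contribute
    0). ``significant`` defaults to the scored gene set; Exp = Ann x
    |significant| / |universe|. Terms with no annotated genes in the
    universe are skipped. Results are sorted by KS p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    extra = set(gene_scores) - universe
    if extra:
        raise ValueError(f"scored genes outside universe: {sorted(extra)[:5]}")
    significant = set(gene_scores) if significant is None else set(significant)
    scores = {g: float(gene_scores.get(g, 0.0)) for g in universe}

    results = []
    for term, genes in annotation.items():
        members = set(genes) & universe
        if not members:
            continue
        rest = universe - members
        in_scores = np.array([scores[g] for g in sorted(members)])
        if not rest:
            results.append(
                EnrichmentResult(term, len(members), len(members & significant),
                                 len(members) * len(significant) / len(universe),
                                 1.0, 0.0)
            )
            continue
        out_scores = np.array([scores[g] for g in sorted(rest)])
        ks = ks_2samp(in_scores, out_scores, method="auto")
        results.append(
            EnrichmentResult(
                term=term,
                ann=len(members),
                sig=len(members & significant),
                exp=len(members) * len(significant) / len(universe),
                ks_p=float(ks.pvalue),
                ks_stat=float(ks.statistic),
            )
        )
    results.sort(key=lambda r: (r.ks_p, r.term))
    return results
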