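"""Gene-level inference on DMP counts.

A differentially methylated gene (DMG) is a gene whose per-sample DMP
counts over the extended genic region (body ±1 kb) pass a density filter
(>= 2.5 DMPs per kb), differ between groups under a count GLM with log
link (Poisson when the pooled mean/variance ratio is high enough,
negative-binomial otherwise), with |log2 fold-change| of the group means
> 1 and Benjamini-Hochberg adjusted p < 0.05.

Also here: the transgenerational heritability set logic (intersection
and recurrence counts of per-generation DMG lists), the null recurrence
simulation that calibrates how much list overlap pure chance produces,
and TE-proximity enrichment of a gene set (Fisher exact on the 2x2 of
proximal/non-proximal by in-set/out-of-set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from memsig.bsio import GenomicAnnotation

__all__ = [
    "GeneCountMatrix",
    "DMGResult",
    "RecurrenceSimResult",
    "count_dmps_per_region",
    "density_filter",
    "glm_count_test",
    "bh_adjust",
    "heritable_set",
    "recurrence_simulation",
    "recurrence_closed_form",
    "te_proximity_enrichment",
]


@dataclass
class GeneCountMatrix:
    """Genes x samples DMP counts plus region lengths (bp)."""

    counts: pd.DataFrame  # index gene_id, columns sample ids
    region_kb: pd.Series  # extended-region length in kb per gene

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative DMP counts")
        if (self.region_kb <= 0).any():
            raise ValueError("non-positive region length")


@dataclass
class RecurrenceSimResult:
    reps: int
    fraction_in_ge_k: dict[int, float]  # k -> mean fraction of first-list genes
    count_in_all: float  # mean count of first-list genes present in every list
    chi2_p: float | None = None
    expected_hist: np.ndarray | None = None  # mean counts of first-list genes by k = 1..L


def count_dmps_per_region(
    dmps: pd.DataFrame, annotation: GenomicAnnotation, sample_ids: list[str] | None = None,
    region: str = "extended",
) -> GeneCountMatrix:
    """Per-gene per-sample DMP counts within the gene region.

    ``region``: "extended" (body ±1 kb, the default) or "body". DMPs are
    instance rows (one per site per carrier sample).
    """
    from intervaltree import IntervalTree

    genes = annotation.genes()
    if region == "extended":
        starts, ends = genes["extended_start"], genes["extended_end"]
    elif region == "body":
        starts, ends = genes["start"], genes["end"]
    else:
        raise ValueError(f"unknown region {region!r}")
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, gid in zip(genes["chrom"], starts, ends, genes["feature_id"]):
        trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e) + 1, gid)

    if sample_ids is None:
        sample_ids = sorted(dmps["sample_id"].unique())
    counts = pd.DataFrame(0, index=list(genes["feature_id"]), columns=sample_ids, dtype=int)
    for row in dmps.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.at(int(row.pos)):
            if row.sample_id in counts.columns:
                counts.loc[iv.data, row.sample_id] += 1
    region_kb = pd.Series(
        (ends.to_numpy() - starts.to_numpy() + 1) / 1000.0, index=list(genes["feature_id"])
    )
    return GeneCountMatrix(counts, region_kb)


def gene_count_matrix_from_result(
    result, annotation: GenomicAnnotation, sample_ids: list[str], region: str = "extended"
) -> GeneCountMatrix:
    """Gene count matrix from a DMP-calling result: treatment DMP instances
    plus control spontaneous-DMP instances, one column per sample."""
    instances = pd.concat([result.dmps, result.spontaneous], ignore_index=True)
    return count_dmps_per_region(instances, annotation, sample_ids=sample_ids, region=region)


def density_filter(
    matrix: GeneCountMatrix,
    min_density: float = 2.5,
    scope: str = "treatment_each",
    treatment_samples: list[str] | None = None,
) -> list[str]:
    """Genes with at least ``min_density`` DMPs per kb (boundary included).

    Scopes: ``treatment_each`` (default; every treatment sample must
    reach the density — the group carrying the signal), ``each_sample``
    (every sample in the matrix), ``any_sample``, ``group_mean`` (mean
    density over the treatment samples, or over all samples if no
    treatment list is given).
    """
    density = matrix.counts.div(matrix.region_kb, axis=0)
    if scope in ("treatment_each", "group_mean") and treatment_samples is not None:
        density_scope = density[treatment_samples]
    else:
        density_scope = density
    if scope in ("treatment_each", "each_sample"):
        keep = (density_scope >= min_density).all(axis=1)
    elif scope == "any_sample":
        keep = (density_scope >= min_density).any(axis=1)
    elif scope == "group_mean":
        keep = density_scope.mean(axis=1) >= min_density
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return list(density.index[keep])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DMGResult:
    gene_id: str
    mean_control: float
    mean_treatment: float
    log2fc: float
    model_used: str  # poisson / quasipoisson / negbinomial / exact_poisson
    p: float
    padj: float = np.nan
    is_dmg: bool = False


def _fit_gene(y: np.ndarray, is_treat: np.ndarray, mv_rate: float,
              use_quasipoisson: bool) -> tuple[float, str]:
    """Wald p for the group effect on one gene's counts under a log link."""
    import statsmodels.api as sm

    means = np.array([y[~is_treat].mean(), y[is_treat].mean()])
    if min(y[~is_treat].sum(), y[is_treat].sum()) == 0:
        # perfect separation: exact conditional two-sample Poisson test
        total = int(y.sum())
        n_t = int(is_treat.sum())
        p0 = n_t / len(y)
        p = stats.binomtest(int(y[is_treat].sum()), total, p0).pvalue if total else 1.0
        return float(p), "exact_poisson"
    variances = np.array([y[~is_treat].var(ddof=1), y[is_treat].var(ddof=1)])
    pooled_mean = means.mean()
    pooled_var = variances.mean()
    X = sm.add_constant(is_treat.astype(float))
    if pooled_var <= 0 or pooled_mean / pooled_var >= mv_rate:
        fam = sm.families.Poisson()
        name = "poisson"
    elif use_quasipoisson:
        fam = sm.families.Poisson()
        name = "quasipoisson"
    else:
        alpha = max((pooled_var - pooled_mean) / pooled_mean**2, 1e-8)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        name = "negbinomial"
    model = sm.GLM(y, X, family=fam)
    if name == "quasipoisson":
        res = model.fit(scale="X2")
    else:
        res = model.fit()
    return float(res.pvalues[1]), name


def glm_count_test(
    matrix: GeneCountMatrix,
    groups: dict[str, str],
    mv_rate: float = 0.95,
    log2fc_min: float = 1.0,
    padj_max: float = 0.05,
    min_density: float = 2.5,
    scope: str = "treatment_each",
    use_quasipoisson: bool = False,
) -> pd.DataFrame:
    """Count-GLM DMG test over a gene count matrix.

    Per gene, the model is chosen by the pooled mean/variance ratio:
    Poisson when mean/variance >= ``mv_rate``, else negative-binomial
    (quasi-Poisson by flag). The group effect is Wald-tested under a log
    link; a perfectly separated gene (one group all zero) falls back to
    the exact conditional Poisson test. log2 fold-change of group means
    uses a +0.5 continuity guard on both means when either is zero.
    p-values are BH-adjusted across tested genes; a DMG needs
    |log2fc| > log2fc_min, padj < padj_max and the density filter.
    """
    samples = list(matrix.counts.columns)
    is_treat = np.array([groups[s] == "treatment" for s in samples])
    if is_treat.sum() < 2 or (~is_treat).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    treatment_samples = [s for s in samples if groups[s] == "treatment"]
    retained = set(density_filter(matrix, min_density, scope, treatment_samples))

    results: list[DMGResult] = []
    for gene_id, row in matrix.counts.iterrows():
        if gene_id not in retained:
            continue
        y = row.to_numpy(float)
        if y.sum() == 0:
            continue
        mean_c = y[~is_treat].mean()
        mean_t = y[is_treat].mean()
        if mean_c == 0 or mean_t == 0:
            log2fc = float(np.log2((mean_t + 0.5) / (mean_c + 0.5)))
        else:
            log2fc = float(np.log2(mean_t / mean_c))
        p, model_used = _fit_gene(y, is_treat, mv_rate, use_quasipoisson)
        results.append(DMGResult(gene_id, mean_c, mean_t, log2fc, model_used, p))
    if not results:
        return pd.DataFrame(columns=["gene_id", "mean_control", "mean_treatment", "log2fc",
                                     "model_used", "p", "padj", "is_dmg"])
    padj = bh_adjust([r.p for r in results])
    for r, a in zip(results, padj):
        r.padj = float(a)
        r.is_dmg = bool(abs(r.log2fc) > log2fc_min and r.padj < padj_max)
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Heritability and recurrence
# ---------------------------------------------------------------------------


def heritable_set(dmg_lists: list[set[str]]) -> tuple[set[str], pd.Series]:
    """Intersection of per-generation DMG lists plus per-gene recurrence
    counts (in how many lists each union gene appears)."""
    if len(dmg_lists) < 2:
        raise ValueError("need >= 2 gene lists")
    sets = [set(s) for s in dmg_lists]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    rec = pd.Series({g: sum(g in s for s in sets) for g in sorted(union)}, dtype=int)
    return inter, rec


def recurrence_closed_form(universe_n: int, list_sizes: list[int]) -> dict[int, float]:
    """Poisson-binomial expectation for list recurrence.

    A first-list gene appears in each other list j independently with
    probability p_j = n_j / universe_n; returns P(total membership >= k)
    for k = 2..L, computed by exact convolution.
    """
    probs = [n / universe_n for n in list_sizes[1:]]
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    tail = np.cumsum(pmf[::-1])[::-1]  # tail[j] = P(extra memberships >= j)
    return {k: float(tail[k - 1]) if k - 1 < len(tail) else 0.0
            for k in range(2, len(list_sizes) + 1)}


def recurrence_simulation(
    universe_n: int,
    list_sizes: list[int],
    reps: int = 200,
    seed: int = 0,
    observed_hist: np.ndarray | None = None,
) -> RecurrenceSimResult:
    """Null recurrence of random gene lists.

    Per replicate, each list is drawn uniformly without replacement from
    the universe; for every gene of the first list its membership count
    across all lists (including the first) is tallied. Reported are the
    mean fractions of first-list genes with membership >= k and the mean
    count present in all lists. If an observed histogram of first-list
    gene membership counts (k = 1..L) is given, it is compared to the
    simulated expectation with Pearson's chi-squared test.
    """
    sizes = list(list_sizes)
    if any(n > universe_n for n in sizes):
        raise ValueError("list size exceeds universe")
    L = len(sizes)
    rng = np.random.default_rng(seed)
    frac_acc = {k: 0.0 for k in range(2, L + 1)}
    all_acc = 0.0
    hist_acc = np.zeros(L)
    for _ in range(reps):
        member = np.zeros(universe_n, dtype=np.int8)
        first = rng.choice(universe_n, size=sizes[0], replace=False)
        member[first] = 1
        for n in sizes[1:]:
            idx = rng.choice(universe_n, size=n, replace=False)
            member[idx] += 1
        counts = member[first]
        for k in range(2, L + 1):
            frac_acc[k] += float((counts >= k).mean())
        all_acc += float((counts == L).sum())
        hist_acc += np.bincount(counts, minlength=L + 1)[1:L + 1]
    fractions = {k: v / reps for k, v in frac_acc.items()}
    expected = hist_acc / reps
    chi2_p = None
    if observed_hist is not None:
        obs = np.asarray(observed_hist, dtype=float)
        exp = expected * obs.sum() / expected.sum()
        keep = exp > 0
        chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
        chi2_p = float(stats.chi2.sf(chi2, df=int(keep.sum()) - 1))
    return RecurrenceSimResult(
        reps=reps, fraction_in_ge_k=fractions, count_in_all=all_acc / reps,
        chi2_p=chi2_p, expected_hist=expected,
    )


def te_proximity_enrichment(
    gene_set: set[str],
    annotation: GenomicAnnotation,
    universe: set[str] | None = None,
    dist: int = 1000,
) -> tuple[np.ndarray, float, float]:
    """Fisher enrichment of TE proximity in a gene set.

    A gene is TE-proximal iff the gap between its body and the nearest
    TE-related feature is <= ``dist`` (overlap counts as gap 0). Returns
    the 2x2 table [[set proximal, set distal], [rest proximal, rest
    distal]], the odds ratio and the two-sided Fisher p.
    """
    from intervaltree import IntervalTree

    genes = annotation.genes()
    if universe is None:
        universe = set(genes["feature_id"])
    gene_set = set(gene_set)
    if not gene_set or not universe:
        raise ValueError("empty gene set or universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    tes = annotation.by_class("TE_related")
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in zip(tes["chrom"], tes["start"], tes["end"]):
        trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e) + 1)
    proximal: set[str] = set()
    for row in genes.itertuples():
        if row.feature_id not in universe:
            continue
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(int(row.start) - dist, int(row.end) + dist + 1):
            proximal.add(row.feature_id)
    a = len(gene_set & proximal)
    b = len(gene_set) - a
    rest = universe - gene_set
    c = len(rest & proximal)
    d = len(rest) - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table)
    return table, float(odds), float(p)
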