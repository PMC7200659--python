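"""Synthetic bisulfite methylomes with known truth.

Emulates the transgenerational design the pipeline targets: a wild-type
control group, a "memory" treatment group carrying induced methylation
repatterning (CHH hypermethylation in promoters, CG hypomethylation in
gene bodies of chosen target genes), and a first-generation "nonmemory"
sibling group sharing only part of the induced repatterning. Induced
sites are retained across generations with a per-generation retention
probability, so truth sets are nested.

Noise model: per-site baseline levels from context-specific mixtures,
beta-binomial inter-individual variation (spontaneous epigenomic
fluctuation is non-negligible, which is why the divergence-based caller
exists), negative-binomial sequencing coverage, and rare spontaneous
single-individual level shifts.

Every stochastic operation derives a child generator from
(config.seed, operation-name), so each stage is independently
reproducible under one global seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from memsig.bsio import CytosineCountTable, GenomicAnnotation, SampleManifest

__all__ = [
    "SyntheticConfig",
    "EffectConfig",
    "SyntheticTruth",
    "GenerationalStudy",
    "build_toy_genome",
    "genome_sites",
    "simulate_counts",
    "simulate_generations",
    "simulate_expression",
]


@dataclass
class EffectConfig:
    """Treatment-induced methylation repatterning.

    CHH promoter sites of target genes shift up by ``delta_chh_promoter``;
    CG gene-body sites shift down by ``delta_cg_body`` (≤ 0). A fraction
    ``affected_site_frac`` of the eligible sites per target gene is
    induced; sites where clipping to (0.01, 0.99) would leave less than
    ``min_realized_shift`` of the intended shift are ineligible, so every
    truth site carries a recoverable effect.
    """

    target_gene_count: int = 5
    delta_chh_promoter: float = 0.4
    delta_cg_body: float = -0.4
    affected_site_frac: float = 0.7
    min_realized_shift: float = 0.25

    def __post_init__(self) -> None:
        if self.delta_chh_promoter < 0:
            raise ValueError("delta_chh_promoter must be >= 0")
        if self.delta_cg_body > 0:
            raise ValueError("delta_cg_body must be <= 0")


@dataclass
class SyntheticConfig:
    """Toy-genome and noise parameters; defaults give a ~50-kb genome,
    five plants per group and six generations, mirroring the design the
    pipeline is meant for."""

    # genome layout
    n_chrom: int = 1
    chrom_len: int = 50_000
    n_genes: int = 8
    n_tes: int = 6
    n_other: int = 3
    te_near_gene_frac: float = 0.5
    gene_len: int = 1500
    te_len: int = 300
    other_len: int = 150
    site_density: float = 0.06  # cytosines per bp carried into the tables
    # context frequencies among simulated sites
    context_probs: tuple[float, float, float] = (0.25, 0.25, 0.50)  # CG, CHG, CHH
    # baseline methylation mixtures
    cg_body_high_level: float = 0.85
    cg_body_high_frac: float = 0.3
    cg_low_level: float = 0.08
    chg_level: float = 0.10
    chh_level: float = 0.05
    te_levels: tuple[float, float, float] = (0.80, 0.50, 0.30)  # CG, CHG, CHH in TEs
    # noise
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0  # negative-binomial size; larger = tighter
    rho: float = 0.05  # beta-binomial intra-class correlation
    spontaneous_dmp_rate: float = 0.002  # per site per individual
    spontaneous_shift: tuple[float, float] = (0.2, 0.5)
    # design
    effect: EffectConfig = field(default_factory=EffectConfig)
    retention_rate: float = 0.8
    nonmemory_shared_frac: float = 0.3
    n_generations: int = 6
    n_control: int = 5
    n_treatment: int = 5
    n_nonmemory: int = 5
    # expression coupling
    expression_coupling: float = -2.0
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("te_near_gene_frac", "site_density", "rho", "spontaneous_dmp_rate",
                     "retention_rate", "nonmemory_shared_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.context_probs) - 1.0) > 1e-9:
            raise ValueError("context_probs must sum to 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")

    def rng(self, op_name: str) -> np.random.Generator:
        """Child generator for one named stochastic operation."""
        return np.random.default_rng([self.seed, zlib.crc32(op_name.encode())])


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator.

    ``induced_sites``: one row per induced site (chrom, pos, strand,
    context, gene_id, region, direction, delta = realized mean shift after
    clipping). ``retained``: generation -> boolean mask over
    ``induced_sites`` rows (nested across generations).
    ``nonmemory_mask``: induced sites shared by the nonmemory group.
    """

    induced_sites: pd.DataFrame
    target_genes: list[str]
    gene_ids: list[str]
    retained: dict[int, np.ndarray] = field(default_factory=dict)
    nonmemory_mask: np.ndarray | None = None

    def retained_sites(self, generation: int) -> pd.DataFrame:
        return self.induced_sites[self.retained[generation]]

    def site_keys(self, generation: int | None = None) -> set[tuple[str, int, str]]:
        df = self.induced_sites if generation is None else self.retained_sites(generation)
        return set(zip(df["chrom"], df["pos"], df["strand"]))


@dataclass
class GenerationalStudy:
    """All simulated samples across generations plus the truth."""

    tables: dict[str, CytosineCountTable]
    samples: pd.DataFrame  # sample_id, phenotype (WT/MM/NM), generation
    truth: SyntheticTruth

    def comparison(self, generation: int, ref: str = "WT", alt: str = "MM"
                   ) -> tuple[SampleManifest, dict[str, CytosineCountTable]]:
        """Control/treatment manifest and tables for one group contrast."""
        sel = self.samples[
            (self.samples["generation"] == generation)
            & (self.samples["phenotype"].isin([ref, alt]))
        ].copy()
        sel["group"] = np.where(sel["phenotype"] == ref, "control", "treatment")
        manifest = SampleManifest(sel[["sample_id", "group", "generation", "phenotype"]])
        return manifest, {s: self.tables[s] for s in sel["sample_id"]}


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

# Inter-feature spacing. > 1 kb keeps far TEs non-proximal; > 2 kb keeps each
# gene's extended region (body ±1 kb) disjoint from every other gene's body,
# promoter and induced sites, so gene-level truth labels are unambiguous.
_GAP = 2200


def build_toy_genome(config: SyntheticConfig) -> GenomicAnnotation:
    """Deterministic (given seed) toy annotation: genes, TEs (a configured
    fraction placed within 1 kb downstream of distinct genes) and small
    "other" features, non-overlapping, with >1 kb spacing otherwise."""
    rng = config.rng("genome")
    n_near = int(round(config.te_near_gene_frac * config.n_genes))
    if n_near > config.n_tes:
        raise ValueError(
            f"te_near_gene_frac requires {n_near} gene-proximal TEs but n_tes={config.n_tes}"
        )
    near_genes = set(rng.choice(config.n_genes, size=n_near, replace=False).tolist())

    chroms = [f"Chr{i + 1}" for i in range(config.n_chrom)]
    cursors = {c: _GAP for c in chroms}
    rows: list[tuple] = []
    te_idx = 0

    def place(chrom: str, length: int, fid: str, subtype: str, fclass: str,
              strand: str) -> tuple[int, int]:
        start = cursors[chrom]
        end = start + length - 1
        if end > config.chrom_len - _GAP:
            raise ValueError(
                "toy genome does not fit: increase chrom_len or reduce feature counts"
            )
        rows.append((chrom, start, end, strand, fid, fclass, subtype))
        cursors[chrom] = end + _GAP
        return start, end

    for g in range(config.n_genes):
        chrom = chroms[g % config.n_chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        _, gene_end = place(chrom, config.gene_len, f"gene{g + 1:03d}", "gene", "genic", strand)
        if g in near_genes:
            gap = int(rng.integers(50, 900))
            te_start = gene_end + gap
            te_end = te_start + config.te_len - 1
            rows.append((chrom, te_start, te_end, "+", f"te{te_idx + 1:03d}",
                         "TE_related", "transposable_element"))
            te_idx += 1
            cursors[chrom] = te_end + _GAP
    for _ in range(te_idx, config.n_tes):
        chrom = chroms[int(rng.integers(config.n_chrom))]
        place(chrom, config.te_len, f"te{te_idx + 1:03d}", "transposable_element", "TE_related", "+")
        te_idx += 1
    for o in range(config.n_other):
        chrom = chroms[int(rng.integers(config.n_chrom))]
        place(chrom, config.other_len, f"other{o + 1:03d}", "ncRNA", "other", "+")

    feats = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_id", "feature_class", "subtype"]
    )
    sizes = {c: config.chrom_len for c in chroms}
    return GenomicAnnotation(feats.sort_values(["chrom", "start"]).reset_index(drop=True), sizes)


def genome_sites(annotation: GenomicAnnotation, config: SyntheticConfig) -> pd.DataFrame:
    """Cytosine site layout for a toy genome: positions, strand, context,
    region tag (promoter/body/te/other/intergenic with its feature id) and
    baseline methylation level. Deterministic given config.seed."""
    rng = config.rng("sites")
    frames = []
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        n_sites = int(round(size * config.site_density))
        pos = np.sort(rng.choice(np.arange(1, size + 1), size=n_sites, replace=False))
        strand = np.where(rng.random(n_sites) < 0.5, "+", "-")
        context = rng.choice(np.array(["CG", "CHG", "CHH"]), size=n_sites,
                             p=np.asarray(config.context_probs))
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": strand, "context": context}))
    sites = pd.concat(frames, ignore_index=True)

    region = np.full(len(sites), "intergenic", dtype=object)
    gene_id = np.full(len(sites), "", dtype=object)
    feats = annotation.features
    for _, f in feats.iterrows():
        on = sites["chrom"].to_numpy() == f["chrom"]
        p = sites["pos"].to_numpy()
        if f["feature_class"] == "genic":
            body = on & (p >= f["start"]) & (p <= f["end"])
            if f["strand"] == "+":
                prom = on & (p >= f["start"] - 1000) & (p < f["start"])
            else:
                prom = on & (p > f["end"]) & (p <= f["end"] + 1000)
            region[body] = "body"
            gene_id[body] = f["feature_id"]
            # promoters do not overwrite another gene's body
            prom &= region == "intergenic"
            region[prom] = "promoter"
            gene_id[prom] = f["feature_id"]
        elif f["feature_class"] == "TE_related":
            te = on & (p >= f["start"]) & (p <= f["end"])
            region[te] = "te"
            gene_id[te] = f["feature_id"]
        else:
            oth = on & (p >= f["start"]) & (p <= f["end"])
            region[oth] = "other"
            gene_id[oth] = f["feature_id"]
    sites["region"] = region
    sites["feature_id"] = gene_id

    # Baseline levels: CG bimodal in gene bodies, low elsewhere; CHG/CHH low;
    # TE sites elevated in all contexts.
    level = np.empty(len(sites))
    ctx = sites["context"].to_numpy()
    level[ctx == "CG"] = config.cg_low_level
    level[ctx == "CHG"] = config.chg_level
    level[ctx == "CHH"] = config.chh_level
    cg_body = (ctx == "CG") & (region == "body")
    high = cg_body & (rng.random(len(sites)) < config.cg_body_high_frac)
    level[high] = config.cg_body_high_level
    in_te = region == "te"
    for c, lv in zip(("CG", "CHG", "CHH"), config.te_levels):
        level[in_te & (ctx == c)] = lv
    sites["base_level"] = level
    return sites


# ---------------------------------------------------------------------------
# Effects and counts
# ---------------------------------------------------------------------------


def _choose_induced(sites: pd.DataFrame, config: SyntheticConfig) -> SyntheticTruth:
    """Pick target genes and the induced site set with realized deltas."""
    rng = config.rng("effects")
    eff = config.effect
    gene_ids = sorted(sites.loc[sites["region"].isin(["body", "promoter"]), "feature_id"].unique())
    k = min(eff.target_gene_count, len(gene_ids))
    targets = sorted(rng.choice(gene_ids, size=k, replace=False).tolist()) if k else []

    in_target = sites["feature_id"].isin(targets)
    cand_hyper = in_target & (sites["region"] == "promoter") & (sites["context"] == "CHH")
    cand_hypo = in_target & (sites["region"] == "body") & (sites["context"] == "CG")
    rows = []
    for cand, delta, direction in (
        (cand_hyper, eff.delta_chh_promoter, "hyper"),
        (cand_hypo, eff.delta_cg_body, "hypo"),
    ):
        if delta == 0:
            continue
        sub = sites[cand]
        realized = np.clip(sub["base_level"] + delta, 0.01, 0.99) - sub["base_level"]
        eligible = sub[np.abs(realized) >= eff.min_realized_shift]
        take = rng.random(len(eligible)) < eff.affected_site_frac
        chosen = eligible[take]
        r = np.clip(chosen["base_level"] + delta, 0.01, 0.99) - chosen["base_level"]
        for (_, s), d in zip(chosen.iterrows(), r):
            rows.append((s["chrom"], s["pos"], s["strand"], s["context"],
                         s["feature_id"], s["region"], direction, float(d)))
    induced = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "gene_id", "region", "direction", "delta"],
    )
    return SyntheticTruth(induced_sites=induced, target_genes=targets, gene_ids=gene_ids)


def _sample_counts(
    sites: pd.DataFrame,
    mean_level: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One individual's count table rows given per-site mean levels."""
    n = len(sites)
    m, k = config.coverage_mean, config.coverage_dispersion
    cov = rng.negative_binomial(k, k / (k + m), size=n)
    p = mean_level.copy()
    # spontaneous single-individual level shifts
    eps = config.spontaneous_dmp_rate
    if eps > 0:
        hit = rng.random(n) < eps
        lo, hi = config.spontaneous_shift
        shift = rng.uniform(lo, hi, size=n) * np.where(rng.random(n) < 0.5, 1.0, -1.0)
        p = np.where(hit, np.clip(p + shift, 0.01, 0.99), p)
    if config.rho > 0:
        c = 1.0 / config.rho - 1.0
        level = rng.beta(np.maximum(p * c, 1e-6), np.maximum((1 - p) * c, 1e-6))
    else:
        level = p
    n_meth = rng.binomial(cov, level)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "context": sites["context"].to_numpy(),
            "n_meth": n_meth,
            "n_unmeth": cov - n_meth,
        }
    )
    return out[cov > 0].reset_index(drop=True)


def _shifted_levels(sites: pd.DataFrame, truth: SyntheticTruth,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Baseline levels with the induced deltas applied (optionally only
    the masked subset of induced sites)."""
    levels = sites["base_level"].to_numpy().copy()
    ind = truth.induced_sites if mask is None else truth.induced_sites[mask]
    if len(ind) == 0:
        return levels
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos", "strand"]])
    ind_key = pd.MultiIndex.from_frame(ind[["chrom", "pos", "strand"]])
    loc = key.get_indexer(ind_key)
    levels[loc] = np.clip(sites["base_level"].to_numpy()[loc] + ind["delta"].to_numpy(), 0.01, 0.99)
    return levels


def simulate_counts(
    annotation: GenomicAnnotation,
    config: SyntheticConfig,
    design: SampleManifest,
) -> tuple[dict[str, CytosineCountTable], SyntheticTruth]:
    """Replicate count tables for one control/treatment contrast.

    Treatment individuals carry the induced effects of
    ``config.effect``; controls carry baseline levels. Both share the
    noise model. Bit-identical under a fixed config.seed.
    """
    sites = genome_sites(annotation, config)
    truth = _choose_induced(sites, config)
    truth.retained[1] = np.ones(len(truth.induced_sites), dtype=bool)
    treat_levels = _shifted_levels(sites, truth)
    base_levels = sites["base_level"].to_numpy()
    rng = config.rng("counts")
    tables: dict[str, CytosineCountTable] = {}
    for _, row in design.entries.iterrows():
        levels = treat_levels if row["group"] == "treatment" else base_levels
        tables[row["sample_id"]] = CytosineCountTable(
            row["sample_id"], _sample_counts(sites, levels, config, rng)
        )
    return tables, truth


def simulate_generations(
    annotation: GenomicAnnotation, config: SyntheticConfig
) -> GenerationalStudy:
    """Full transgenerational study.

    Generation 1 holds wild-type (WT), memory (MM) and nonmemory (NM)
    groups; NM shares a random ``nonmemory_shared_frac`` of the induced
    sites. Generations 2..G hold WT and MM, each induced site surviving
    independently with probability ``retention_rate`` per generation
    transition (truth sets nested by construction).
    """
    sites = genome_sites(annotation, config)
    truth = _choose_induced(sites, config)
    n_ind = len(truth.induced_sites)
    r_rng = config.rng("retention")
    retained = np.ones(n_ind, dtype=bool)
    truth.retained[1] = retained.copy()
    for g in range(2, config.n_generations + 1):
        retained = retained & (r_rng.random(n_ind) < config.retention_rate)
        truth.retained[g] = retained.copy()
    truth.nonmemory_mask = r_rng.random(n_ind) < config.nonmemory_shared_frac

    rng = config.rng("counts")
    base = sites["base_level"].to_numpy()
    tables: dict[str, CytosineCountTable] = {}
    rows = []

    def emit(sample_id: str, phenotype: str, generation: int, levels: np.ndarray) -> None:
        tables[sample_id] = CytosineCountTable(
            sample_id, _sample_counts(sites, levels, config, rng)
        )
        rows.append((sample_id, phenotype, generation))

    for g in range(1, config.n_generations + 1):
        mm_levels = _shifted_levels(sites, truth, truth.retained[g])
        for i in range(config.n_control):
            emit(f"WT_g{g}_{i + 1}", "WT", g, base)
        for i in range(config.n_treatment):
            emit(f"MM_g{g}_{i + 1}", "MM", g, mm_levels)
        if g == 1:
            nm_levels = _shifted_levels(sites, truth, truth.nonmemory_mask)
            for i in range(config.n_nonmemory):
                emit(f"NM_g1_{i + 1}", "NM", 1, nm_levels)

    samples = pd.DataFrame(rows, columns=["sample_id", "phenotype", "generation"])
    return GenerationalStudy(tables=tables, samples=samples, truth=truth)


def simulate_expression(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Matched expression results: target genes get log2 fold-changes with
    sign opposite to their mean methylation shift (times
    ``expression_coupling``, which is negative, i.e. promoter CHH gain or
    body CG loss in methylation couples to expression with the configured
    sign), plus Gaussian noise; non-targets are noise only. ``padj`` is a
    BH-adjusted two-sided normal p against the noise null."""
    from statsmodels.stats.multitest import multipletests
    from scipy import stats

    rng = config.rng("expression")
    genes = truth.gene_ids
    shift = pd.Series(0.0, index=genes)
    if len(truth.induced_sites):
        per_gene = truth.induced_sites.groupby("gene_id")["delta"].mean()
        shift.loc[per_gene.index] = per_gene
    sd = config.expression_noise_sd
    noise = rng.normal(0.0, sd, size=len(genes)) if sd > 0 else np.zeros(len(genes))
    log2fc = config.expression_coupling * shift.to_numpy() + noise
    if sd > 0:
        p = 2 * stats.norm.sf(np.abs(log2fc) / sd)
    else:
        p = np.where(log2fc == 0, 1.0, 0.0)
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else p
    return pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "padj": padj})
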