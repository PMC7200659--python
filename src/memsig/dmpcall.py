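"""Signal-detection DMP calling.

The caller treats methylation divergence as a noisy signal: most
per-site Hellinger divergences reflect spontaneous inter-individual
variation, and true treatment effects live in the upper tail. The
procedure is:

1. per sample, fit a two-parameter gamma to the positive HD values and
   take its (1 - alpha) quantile as that individual's critical value;
2. keep potential DMPs (pDMPs): sites with |TV| strictly above ``tv_min``
   (default 20% level difference) and HD at or above the critical value;
3. estimate a single HD cutoff over the pooled pDMPs by maximizing the
   Youden index J = sensitivity + specificity - 1 for discriminating
   treatment-carried from control-carried pDMPs;
4. final DMPs are treatment pDMPs with HD >= cutoff; control pDMPs
   passing the same rule are kept separately as spontaneous DMPs.

Direction is hyper when TV > 0, hypo when TV < 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from memsig.bsio import CytosineCountTable, GenomicAnnotation, SampleManifest, filter_coverage
from memsig.divergence import divergence_table, pool_reference

logger = logging.getLogger(__name__)

__all__ = [
    "GammaModel",
    "CutpointResult",
    "fit_hd_model",
    "select_pdmp",
    "estimate_cutpoint",
    "call_dmps",
    "classify_direction",
    "assign_features",
    "dmp_frequency_table",
    "call_dmp_pipeline",
    "DMPCallResult",
]


@dataclass
class GammaModel:
    """Fitted null model for one sample's HD distribution."""

    dist_name: str  # "gamma" or "weibull"
    shape: float
    scale: float
    n_fit: int
    aic: float
    ks_stat: float
    alpha: float
    hd_crit: float

    def quantile(self, q: float) -> float:
        dist = stats.gamma if self.dist_name == "gamma" else stats.weibull_min
        return float(dist.ppf(q, self.shape, scale=self.scale))


@dataclass
class CutpointResult:
    """Youden-index optimal HD cutoff over pooled pDMPs."""

    cutoff_hd: float
    youden_j: float
    sensitivity: float
    specificity: float


def _fit_one(dist, values: np.ndarray) -> tuple[float, float, float, float]:
    shape, _, scale = dist.fit(values, floc=0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise RuntimeError("distribution fit did not converge; try the alternate model")
    ll = float(np.sum(dist.logpdf(values, shape, scale=scale)))
    aic = 2 * 2 - 2 * ll
    ks = float(stats.kstest(values, lambda x: dist.cdf(x, shape, scale=scale)).statistic)
    return shape, scale, aic, ks


def fit_hd_model(
    hd_values, alpha: float = 0.05, model: str = "gamma2p", min_n: int = 100
) -> GammaModel:
    """Fit the per-sample HD null model and derive the critical value.

    Zeros are excluded (the point mass at identity breaks continuous
    MLE). ``model``: "gamma2p" (default), "weibull2p", or "auto" which
    fits both and keeps the lower-AIC fit. The critical value is the
    (1 - alpha) quantile of the fitted distribution.
    """
    values = np.asarray(hd_values, dtype=float)
    values = values[values > 0]
    if len(values) < min_n:
        raise ValueError(f"need >= {min_n} positive HD values, got {len(values)}")
    if np.var(values) == 0:
        raise RuntimeError("constant HD input: fit cannot converge; check upstream filtering")
    candidates = {"gamma2p": [("gamma", stats.gamma)],
                  "weibull2p": [("weibull", stats.weibull_min)],
                  "auto": [("gamma", stats.gamma), ("weibull", stats.weibull_min)]}
    if model not in candidates:
        raise ValueError(f"unknown model {model!r}")
    best: GammaModel | None = None
    for name, dist in candidates[model]:
        shape, scale, aic, ks = _fit_one(dist, values)
        m = GammaModel(
            dist_name=name, shape=shape, scale=scale, n_fit=len(values), aic=aic,
            ks_stat=ks, alpha=alpha,
            hd_crit=float(dist.ppf(1 - alpha, shape, scale=scale)),
        )
        if best is None or m.aic < best.aic:
            best = m
    assert best is not None
    return best


def select_pdmp(div_table: pd.DataFrame, model: GammaModel, tv_min: float = 0.2) -> pd.DataFrame:
    """Potential DMPs: |TV| strictly greater than ``tv_min`` and HD at or
    above the sample's critical value."""
    keep = (div_table["tv"].abs() > tv_min) & (div_table["hd"] >= model.hd_crit)
    return div_table[keep].reset_index(drop=True)


def estimate_cutpoint(control_hd, treatment_hd) -> CutpointResult:
    """Youden-optimal HD threshold separating treatment from control pDMPs.

    Candidates are the sorted unique observed HD values (both groups); a
    pDMP is classified treatment iff HD >= cutoff. Sensitivity is the
    treatment fraction at or above the cutoff, specificity the control
    fraction below it. Ties in J break toward the smallest cutoff.
    """
    ctrl = np.sort(np.asarray(control_hd, dtype=float))
    treat = np.sort(np.asarray(treatment_hd, dtype=float))
    if len(ctrl) == 0 or len(treat) == 0:
        raise ValueError("cutpoint estimation needs pDMPs in both groups")
    candidates = np.unique(np.concatenate([ctrl, treat]))
    sens = 1.0 - np.searchsorted(treat, candidates, side="left") / len(treat)
    spec = np.searchsorted(ctrl, candidates, side="left") / len(ctrl)
    j = sens + spec - 1.0
    i = int(np.argmax(j))  # argmax returns the first (smallest-cutoff) maximum
    return CutpointResult(
        cutoff_hd=float(candidates[i]), youden_j=float(j[i]),
        sensitivity=float(sens[i]), specificity=float(spec[i]),
    )


def classify_direction(tv) -> np.ndarray:
    """hyper iff TV > 0, hypo iff TV < 0; TV == 0 cannot reach a DMP set
    (the tv_min filter is strict) and is rejected."""
    tv = np.atleast_1d(np.asarray(tv, dtype=float))
    if np.any(tv == 0):
        raise ValueError("tv == 0 cannot be a DMP")
    return np.where(tv > 0, "hyper", "hypo")


def call_dmps(
    pdmps: pd.DataFrame, cutpoint: CutpointResult, groups: pd.Series | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Final DMPs from pooled pDMPs given a cutpoint.

    Returns (treatment DMPs, spontaneous control DMPs); both apply
    HD >= cutoff (boundary included). ``groups`` maps sample_id to
    control/treatment.
    """
    g = pdmps["sample_id"].map(groups)
    passing = pdmps[pdmps["hd"] >= cutpoint.cutoff_hd].copy()
    passing["direction"] = classify_direction(passing["tv"]) if len(passing) else \
        pd.Series(dtype=str)
    gp = g[passing.index]
    treat = passing[gp == "treatment"].reset_index(drop=True)
    spont = passing[gp == "control"].reset_index(drop=True)
    return treat, spont


# ---------------------------------------------------------------------------
# Feature assignment
# ---------------------------------------------------------------------------

_CLASS_PRIORITY = ("TE_related", "genic", "other")


def _class_trees(annotation: GenomicAnnotation):
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], "IntervalTree"] = {}
    for _, f in annotation.features.iterrows():
        if f["feature_class"] == "genic":
            start, end = int(f["extended_start"]), int(f["extended_end"])
        else:
            start, end = int(f["start"]), int(f["end"])
        key = (f["chrom"], f["feature_class"])
        trees.setdefault(key, IntervalTree()).addi(start, end + 1, f["feature_id"])
    return trees


def assign_features(positions: pd.DataFrame, annotation: GenomicAnnotation) -> pd.Series:
    """Feature class per position with priority TE_related > genic
    (extended, body ±1 kb) > other > intergenic."""
    trees = _class_trees(annotation)
    out = np.full(len(positions), "intergenic", dtype=object)
    chroms = positions["chrom"].to_numpy()
    pos = positions["pos"].to_numpy()
    for i in range(len(positions)):
        for fclass in _CLASS_PRIORITY:
            tree = trees.get((chroms[i], fclass))
            if tree is not None and tree.overlaps_point(int(pos[i])):
                out[i] = fclass
                break
    return pd.Series(out, index=positions.index, name="feature_class")


def dmp_frequency_table(
    dmps: pd.DataFrame, annotation: GenomicAnnotation, all_sites: pd.DataFrame
) -> pd.DataFrame:
    """Relative DMP frequency per genomic feature class: DMP count divided
    by the total number of genomic cytosine positions of that context in
    that class, per sample and context. ``all_sites`` lists every assayed
    cytosine (chrom, pos, context)."""
    sites = all_sites.drop_duplicates(["chrom", "pos"]).copy()
    sites["feature_class"] = assign_features(sites, annotation)
    totals = sites.groupby(["feature_class", "context"]).size()
    d = dmps.copy()
    if "feature_class" not in d.columns:
        d["feature_class"] = assign_features(d, annotation)
    counts = d.groupby(["sample_id", "context", "feature_class"]).size()
    rows = []
    for (sample_id, context, fclass), n in counts.items():
        denom = totals.get((fclass, context), 0)
        rows.append((sample_id, context, fclass, int(n), int(denom),
                     n / denom if denom else np.nan))
    return pd.DataFrame(
        rows, columns=["sample_id", "context", "feature_class", "n_dmps", "n_cytosines",
                       "frequency"],
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class DMPCallResult:
    """Everything the signal-detection caller produced for one contrast."""

    dmps: pd.DataFrame  # treatment DMPs: site key, context, sample_id, hd, tv, direction
    spontaneous: pd.DataFrame  # control DMPs passing the same rule
    pdmps: pd.DataFrame
    models: dict[str, GammaModel]
    cutpoint: CutpointResult | None
    centroid: pd.DataFrame
    divergences: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def dmp_sites(self) -> pd.DataFrame:
        """Unique called sites (union over treatment samples)."""
        return self.dmps.drop_duplicates(["chrom", "pos", "strand"])[
            ["chrom", "pos", "strand", "context"]
        ].reset_index(drop=True)

    def consensus_sites(
        self, min_samples: int = 2, exclude_control_overlap: bool = True
    ) -> pd.DataFrame:
        """Treatment-specific site-level calls.

        A site must be called in at least ``min_samples`` treatment
        individuals (replication separates induced repatterning from
        single-individual fluctuation), and by default is discarded if any
        control individual shows pDMP evidence there — the same
        "treatment-specific, distinct from spontaneous variation" logic
        the gene-level analysis applies when subtracting control-overlap
        calls.
        """
        if len(self.dmps) == 0:
            return self.dmp_sites()
        mult = self.dmps.groupby(["chrom", "pos", "strand"], as_index=False).agg(
            context=("context", "first"), n_samples_called=("sample_id", "nunique")
        )
        keep = mult[mult["n_samples_called"] >= min_samples]
        if exclude_control_overlap and len(self.pdmps):
            ctrl_ids = {s for s, g in self.groups.items() if g == "control"}
            ctrl = self.pdmps[self.pdmps["sample_id"].isin(ctrl_ids)]
            ctrl_sites = set(zip(ctrl["chrom"], ctrl["pos"], ctrl["strand"]))
            mask = [
                (c, p, s) not in ctrl_sites
                for c, p, s in zip(keep["chrom"], keep["pos"], keep["strand"])
            ]
            keep = keep[mask]
        return keep.reset_index(drop=True)


def call_dmp_pipeline(
    tables: dict[str, CytosineCountTable],
    manifest: SampleManifest,
    annotation: GenomicAnnotation | None = None,
    alpha: float = 0.05,
    tv_min: float = 0.2,
    model: str = "gamma2p",
    min_cov: int = 4,
    max_cov: int = 500,
    min_fit_n: int = 100,
) -> DMPCallResult:
    """Run the whole signal-detection procedure for one contrast.

    Coverage-filters every sample, pools the control group into the
    reference centroid, computes per-sample divergences, fits the HD null
    per individual, selects pDMPs, estimates the Youden cutoff
    (control vs treatment pDMPs) and calls final plus spontaneous DMPs.
    If the control group yields no pDMPs the cutoff step is skipped with
    a warning and every treatment pDMP is accepted.
    """
    controls = manifest.samples("control")
    treatments = manifest.samples("treatment")
    if len(controls) < 2 or len(treatments) < 1:
        raise ValueError("need >= 2 control and >= 1 treatment samples")
    filtered = {s: filter_coverage(tables[s], max_cov=max_cov, min_cov=min_cov)
                for s in controls + treatments}
    centroid = pool_reference([filtered[s] for s in controls])
    divergences = {s: divergence_table(filtered[s], centroid) for s in controls + treatments}
    models = {s: fit_hd_model(divergences[s]["hd"], alpha=alpha, model=model, min_n=min_fit_n)
              for s in divergences}
    pdmp_frames = [select_pdmp(divergences[s], models[s], tv_min=tv_min) for s in divergences]
    pdmps = pd.concat(pdmp_frames, ignore_index=True)
    groups = {s: manifest.group_of(s) for s in divergences}
    grp = pdmps["sample_id"].map(groups)
    ctrl_hd = pdmps.loc[grp == "control", "hd"]
    treat_hd = pdmps.loc[grp == "treatment", "hd"]
    if len(ctrl_hd) and len(treat_hd):
        cutpoint = estimate_cutpoint(ctrl_hd, treat_hd)
    else:
        logger.warning("no pDMPs in one group: skipping cutoff, accepting all treatment pDMPs")
        cutpoint = CutpointResult(cutoff_hd=0.0, youden_j=float("nan"),
                                  sensitivity=float("nan"), specificity=float("nan"))
    dmps, spont = call_dmps(pdmps, cutpoint, groups)
    if annotation is not None:
        if len(dmps):
            dmps["feature_class"] = assign_features(dmps, annotation)
        if len(spont):
            spont["feature_class"] = assign_features(spont, annotation)
    return DMPCallResult(
        dmps=dmps, spontaneous=spont, pdmps=pdmps, models=models, cutpoint=cutpoint,
        centroid=centroid, divergences=divergences, groups=groups,
    )
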