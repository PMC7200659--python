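"""Benchmark of four DMP-calling strategies scored by discrimination power.

The callers mirror the families used across the methylation literature:
a pooled Fisher exact test, a replicate-aware Wald test on levels, a
root-mean-square goodness-of-fit test with a Monte-Carlo null, and the
signal-detection caller from :mod:`memsig.dmpcall`. All share the same
thresholds (level difference > 0.25, p < 0.05 where applicable).

Scoring: a DMP set is only as good as its power to discriminate the
groups. At every called site, each sample contributes a feature row
(HD, |TV|, log2 coverage, context indicators) labeled by its group; a
regularized logistic classifier is trained on a stratified 60% split and
scored on the held-out 40%, with 999 bootstrap resamples of the test set
for 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from memsig.bsio import CytosineCountTable, SampleManifest
from memsig.dmpcall import DMPCallResult, call_dmp_pipeline

__all__ = [
    "ClassifierReport",
    "pooled_counts",
    "fisher_caller",
    "wald_caller",
    "rms_caller",
    "sd_caller",
    "site_feature_frame",
    "validate_dmps",
    "benchmark_compare",
    "run_benchmark",
]

SITE_KEY = ["chrom", "pos", "strand"]


@dataclass
class ClassifierReport:
    method: str
    accuracy: float
    sensitivity: float
    specificity: float
    fdr: float
    n_dmps: int
    n_boot: int = 999
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def pooled_counts(
    tables: dict[str, CytosineCountTable], manifest: SampleManifest
) -> pd.DataFrame:
    """Per-site pooled (mC, uC) for each group, inner-joined on sites
    covered in both pools."""
    out = {}
    for group in ("control", "treatment"):
        ids = manifest.samples(group)
        stacked = pd.concat([tables[s].data for s in ids], ignore_index=True)
        pooled = stacked.groupby(SITE_KEY + ["context"], as_index=False)[
            ["n_meth", "n_unmeth"]
        ].sum()
        out[group] = pooled.rename(
            columns={"n_meth": f"m_{group[0]}", "n_unmeth": f"u_{group[0]}"}
        )
    merged = out["control"].merge(out["treatment"], on=SITE_KEY + ["context"], how="inner")
    cov_c = merged["m_c"] + merged["u_c"]
    cov_t = merged["m_t"] + merged["u_t"]
    keep = (cov_c > 0) & (cov_t > 0)
    merged = merged[keep].reset_index(drop=True)
    merged["diff"] = merged["m_t"] / (merged["m_t"] + merged["u_t"]) - merged["m_c"] / (
        merged["m_c"] + merged["u_c"]
    )
    return merged


def fisher_caller(
    pooled: pd.DataFrame, diff_min: float = 0.25, p_max: float = 0.05
) -> pd.DataFrame:
    """Two-sided Fisher exact test on the pooled 2x2 per site, called when
    p < p_max and |level difference| > diff_min."""
    cand = pooled[pooled["diff"].abs() > diff_min]
    pvals = np.array([
        stats.fisher_exact([[r.m_c, r.u_c], [r.m_t, r.u_t]])[1]
        for r in cand.itertuples()
    ]) if len(cand) else np.array([])
    called = cand[pvals < p_max].copy() if len(cand) else cand.copy()
    if len(cand):
        called["p"] = pvals[pvals < p_max]
    return called.reset_index(drop=True)


def wald_caller(
    tables: dict[str, CytosineCountTable],
    manifest: SampleManifest,
    diff_min: float = 0.25,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Replicate-level Wald test on methylation proportions.

    Per group the variance of the mean is max(empirical across-replicate
    variance of levels, binomial floor pbar(1-pbar)/sum n) / n_reps; the
    floor keeps z finite when replicates agree exactly. This is a
    moment-estimator stand-in for the dispersion-shrinkage tests of that
    family, faithful in spirit and documented as an approximation.
    """
    stats_by_group = {}
    for group in ("control", "treatment"):
        ids = manifest.samples(group)
        if len(ids) < 2:
            raise ValueError("wald_caller needs >= 2 replicates per group")
        frames = []
        for s in ids:
            d = tables[s].data
            cov = d["n_meth"] + d["n_unmeth"]
            frames.append(pd.DataFrame({
                "chrom": d["chrom"], "pos": d["pos"], "strand": d["strand"],
                "context": d["context"], "level": d["n_meth"] / cov, "cov": cov,
                "sample": s,
            }))
        long = pd.concat(frames, ignore_index=True)
        g = long.groupby(SITE_KEY + ["context"])
        agg = g.agg(mean=("level", "mean"), var=("level", "var"), n_reps=("level", "size"),
                    total_cov=("cov", "sum")).reset_index()
        agg = agg[agg["n_reps"] >= 2]
        floor = agg["mean"] * (1 - agg["mean"]) / agg["total_cov"]
        agg["se2"] = np.maximum(agg["var"].fillna(0.0), floor) / agg["n_reps"]
        stats_by_group[group] = agg
    m = stats_by_group["control"].merge(
        stats_by_group["treatment"], on=SITE_KEY + ["context"], suffixes=("_c", "_t")
    )
    m["diff"] = m["mean_t"] - m["mean_c"]
    se = np.sqrt(m["se2_c"] + m["se2_t"])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, m["diff"] / se, 0.0)
    m["p"] = 2 * stats.norm.sf(np.abs(z))
    called = m[(m["p"] < p_max) & (m["diff"].abs() > diff_min)]
    return called[SITE_KEY + ["context", "diff", "p"]].reset_index(drop=True)


def rms_statistic(table: np.ndarray) -> float:
    """Root-mean-square distance of a 2x2 table's joint proportions from
    the independence table implied by its margins."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0:
        return 0.0
    pi = t / n
    indep = np.outer(pi.sum(axis=1), pi.sum(axis=0))
    return float(np.sqrt(0.25 * np.sum((pi - indep) ** 2)))


def rms_caller(
    pooled: pd.DataFrame,
    n_mc: int = 1000,
    diff_min: float = 0.25,
    p_max: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """RMS goodness-of-fit caller with an add-one Monte-Carlo null: null
    tables are multinomial draws under independence with the observed
    margins and total; p = (1 + #{sim >= obs}) / (1 + n_mc)."""
    rng = np.random.default_rng(seed)
    cand = pooled[pooled["diff"].abs() > diff_min]
    pvals = []
    for r in cand.itertuples():
        obs = np.array([[r.m_c, r.u_c], [r.m_t, r.u_t]], dtype=float)
        n = int(obs.sum())
        stat_obs = rms_statistic(obs)
        pi = obs / n
        indep = np.outer(pi.sum(axis=1), pi.sum(axis=0)).ravel()
        sims = rng.multinomial(n, indep, size=n_mc).reshape(n_mc, 2, 2)
        p_sim = sims / n
        margins_r = p_sim.sum(axis=2, keepdims=True)
        margins_c = p_sim.sum(axis=1, keepdims=True)
        stat_sim = np.sqrt(0.25 * ((p_sim - margins_r * margins_c) ** 2).sum(axis=(1, 2)))
        pvals.append((1 + int((stat_sim >= stat_obs).sum())) / (1 + n_mc))
    pvals = np.array(pvals)
    called = cand[pvals < p_max].copy() if len(cand) else cand.copy()
    if len(cand):
        called["p"] = pvals[pvals < p_max]
    return called.reset_index(drop=True)


def sd_caller(
    tables: dict[str, CytosineCountTable],
    manifest: SampleManifest,
    diff_min: float = 0.25,
    **pipeline_kwargs,
) -> tuple[pd.DataFrame, DMPCallResult]:
    """Signal-detection caller at benchmark parity (tv_min = diff_min).
    Returns the caller's consensus site set plus the full pipeline result."""
    result = call_dmp_pipeline(tables, manifest, tv_min=diff_min, **pipeline_kwargs)
    return result.consensus_sites(), result


# ---------------------------------------------------------------------------
# Classifier validation
# ---------------------------------------------------------------------------


def site_feature_frame(
    sites: pd.DataFrame,
    divergences: dict[str, pd.DataFrame],
    manifest: SampleManifest,
) -> pd.DataFrame:
    """One labeled feature row per (called site, sample): hd, |tv|,
    log2 coverage and context indicators, labeled by the sample's group."""
    key = sites[["chrom", "pos", "strand"]].drop_duplicates()
    frames = []
    for sample_id, div in divergences.items():
        sub = div.merge(key, on=SITE_KEY)
        if len(sub) == 0:
            continue
        frames.append(pd.DataFrame({
            "hd": sub["hd"],
            "abs_tv": sub["tv"].abs(),
            "log2_cov": np.log2(sub["n_sample"].astype(float)),
            "is_cg": (sub["context"] == "CG").astype(float),
            "is_chg": (sub["context"] == "CHG").astype(float),
            "group": manifest.group_of(sample_id),
            "sample_id": sample_id,
        }))
    if not frames:
        return pd.DataFrame(columns=["hd", "abs_tv", "log2_cov", "is_cg", "is_chg",
                                     "group", "sample_id"])
    return pd.concat(frames, ignore_index=True)


_FEATURES = ["hd", "abs_tv", "log2_cov", "is_cg", "is_chg"]


def validate_dmps(
    feature_frame: pd.DataFrame,
    method: str = "dmps",
    split: float = 0.6,
    n_boot: int = 999,
    seed: int = 0,
    classifier: str = "logistic",
) -> ClassifierReport:
    """Held-out classifier validation of a DMP set.

    Trains on a stratified ``split`` fraction, reports accuracy,
    sensitivity (treatment recall), specificity and FDR = FP/(TP+FP) on
    the held-out rows, with percentile bootstrap 95% CIs from ``n_boot``
    resamples of the test set. Treatment is the positive class.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    df = feature_frame
    y = (df["group"] == "treatment").to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires rows from both groups")
    X = df[_FEATURES].to_numpy(float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed
    )
    if classifier == "logistic":
        clf = make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=1000))
    elif classifier == "lda":
        clf = make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)

    def metrics(yt: np.ndarray, yp: np.ndarray) -> dict[str, float]:
        tp = int(((yt == 1) & (yp == 1)).sum())
        tn = int(((yt == 0) & (yp == 0)).sum())
        fp = int(((yt == 0) & (yp == 1)).sum())
        fn = int(((yt == 1) & (yp == 0)).sum())
        return {
            "accuracy": (tp + tn) / max(len(yt), 1),
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "fdr": fp / (tp + fp) if tp + fp else 0.0,
        }

    point = metrics(y_te, pred)
    rng = np.random.default_rng(seed)
    boot = {k: [] for k in point}
    n = len(y_te)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = metrics(y_te[idx], pred[idx])
        for k, v in m.items():
            boot[k].append(v)
    ci = {
        k: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
        for k, v in boot.items()
    }
    n_dmps = len(df)  # instance rows; run_benchmark overrides with unique site counts
    return ClassifierReport(
        method=method, accuracy=point["accuracy"], sensitivity=point["sensitivity"],
        specificity=point["specificity"], fdr=point["fdr"], n_dmps=n_dmps,
        n_boot=n_boot, ci=ci,
    )


def benchmark_compare(reports: list[ClassifierReport]) -> pd.DataFrame:
    """Ranking table ordered by accuracy (stable, so equal-accuracy
    reports keep their input order)."""
    if not reports:
        raise ValueError("no reports to compare")
    df = pd.DataFrame([
        {"method": r.method, "accuracy": r.accuracy, "sensitivity": r.sensitivity,
         "specificity": r.specificity, "fdr": r.fdr, "n_dmps": r.n_dmps,
         "accuracy_ci_low": r.ci.get("accuracy", (np.nan, np.nan))[0],
         "accuracy_ci_high": r.ci.get("accuracy", (np.nan, np.nan))[1]}
        for r in reports
    ])
    return df.sort_values("accuracy", ascending=False, kind="mergesort").reset_index(drop=True)


def run_benchmark(
    tables: dict[str, CytosineCountTable],
    manifest: SampleManifest,
    diff_min: float = 0.25,
    p_max: float = 0.05,
    n_mc: int = 1000,
    n_boot: int = 999,
    seed: int = 0,
    **pipeline_kwargs,
) -> tuple[pd.DataFrame, dict[str, ClassifierReport]]:
    """Run all four callers on one contrast and rank them by held-out
    classifier accuracy. Feature rows for every caller come from the same
    per-sample divergence tables, so only the site sets differ."""
    sd_sites, sd_result = sd_caller(tables, manifest, diff_min=diff_min, **pipeline_kwargs)
    pooled = pooled_counts(tables, manifest)
    site_sets = {
        "signal_detection": sd_sites,
        "fisher": fisher_caller(pooled, diff_min, p_max),
        "wald": wald_caller(tables, manifest, diff_min, p_max),
        "rms": rms_caller(pooled, n_mc, diff_min, p_max, seed=seed),
    }
    reports: dict[str, ClassifierReport] = {}
    for name, sites in site_sets.items():
        if len(sites) == 0:
            reports[name] = ClassifierReport(
                method=name, accuracy=np.nan, sensitivity=np.nan, specificity=np.nan,
                fdr=np.nan, n_dmps=0, n_boot=n_boot,
            )
            continue
        frame = site_feature_frame(sites, sd_result.divergences, manifest)
        report = validate_dmps(frame, method=name, n_boot=n_boot, seed=seed)
        report.n_dmps = sites.drop_duplicates(["chrom", "pos", "strand"]).shape[0]
        reports[name] = report
    ranking = benchmark_compare([r for r in reports.values() if not np.isnan(r.accuracy)])
    return ranking, reports
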