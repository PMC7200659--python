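"""Methylation levels, level differences and Hellinger divergence.

Each sample is compared site-by-site against a reference centroid — the
element-wise pool of the control-group counts. Two statistics are kept
per site: the signed level difference TV = p - q (individual level minus
centroid level, later defining hyper/hypo) and the coverage-weighted
Hellinger divergence

    HD = 2 w [ (sqrt(p) - sqrt(q))^2 + (sqrt(1-p) - sqrt(1-q))^2 ],
    w  = n1 n2 / (n1 + n2),

where n1 is the sample coverage and n2 the pooled reference coverage.
HD is zero iff p = q, symmetric in the two (level, coverage) pairs, and
scales linearly in w, so well-covered discrepancies rank above poorly
covered ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from memsig.bsio import CytosineCountTable

__all__ = [
    "methylation_level",
    "tv_difference",
    "hellinger_divergence",
    "pool_reference",
    "divergence_table",
    "context_summary",
    "bin_matrix",
]

SITE_KEY = ["chrom", "pos", "strand"]


def methylation_level(n_meth, n_unmeth):
    """ML level estimate mC / (mC + uC). Zero-coverage input is an error
    (such sites are filtered upstream)."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    if np.any(cov < 1):
        raise ValueError("zero-coverage site: level undefined")
    out = n_meth / cov
    return float(out) if out.ndim == 0 else out


def tv_difference(p_hat, q_hat):
    """Signed level difference p - q; > 0 will be hyper, < 0 hypo."""
    p_hat = np.asarray(p_hat, dtype=float)
    q_hat = np.asarray(q_hat, dtype=float)
    out = p_hat - q_hat
    return float(out) if out.ndim == 0 else out


def hellinger_divergence(p_hat, n_sample, q_hat, n_ref):
    """Coverage-weighted Hellinger divergence between two proportions."""
    p = np.asarray(p_hat, dtype=float)
    q = np.asarray(q_hat, dtype=float)
    n1 = np.asarray(n_sample, dtype=float)
    n2 = np.asarray(n_ref, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((q < 0) | (q > 1)):
        raise ValueError("levels must lie in [0, 1]")
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("coverages must be >= 1")
    w = n1 * n2 / (n1 + n2)
    hd = 2.0 * w * ((np.sqrt(p) - np.sqrt(q)) ** 2 + (np.sqrt(1 - p) - np.sqrt(1 - q)) ** 2)
    return float(hd) if hd.ndim == 0 else hd


def pool_reference(tables: list[CytosineCountTable]) -> pd.DataFrame:
    """Element-wise pooled counts over the reference samples.

    Returns a frame with chrom, pos, strand, context, n_meth, n_unmeth and
    the centroid level. A site contributes wherever it is covered in at
    least one reference sample; fewer than two samples is an error (a
    single individual is not a population reference).
    """
    if len(tables) < 2:
        raise ValueError("a reference centroid needs at least 2 samples")
    stacked = pd.concat([t.data for t in tables], ignore_index=True)
    pooled = (
        stacked.groupby(SITE_KEY + ["context"], sort=True, as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
    )
    pooled["level"] = pooled["n_meth"] / (pooled["n_meth"] + pooled["n_unmeth"])
    return pooled


def divergence_table(sample: CytosineCountTable, centroid: pd.DataFrame) -> pd.DataFrame:
    """Per-site divergence of one sample against the pooled centroid.

    Sites missing from either side are dropped (no imputation). Columns:
    site key, context, p_hat, q_hat, tv, hd, n_sample, n_ref.
    """
    merged = sample.data.merge(
        centroid.rename(columns={"n_meth": "ref_meth", "n_unmeth": "ref_unmeth"}),
        on=SITE_KEY + ["context"],
        how="inner",
    )
    n1 = (merged["n_meth"] + merged["n_unmeth"]).to_numpy(float)
    n2 = (merged["ref_meth"] + merged["ref_unmeth"]).to_numpy(float)
    p = merged["n_meth"].to_numpy(float) / n1
    q = merged["ref_meth"].to_numpy(float) / n2
    out = merged[SITE_KEY + ["context"]].copy()
    out["p_hat"] = p
    out["q_hat"] = q
    out["tv"] = p - q
    out["hd"] = hellinger_divergence(p, n1, q, n2)
    out["n_sample"] = n1.astype(int)
    out["n_ref"] = n2.astype(int)
    out["sample_id"] = sample.sample_id
    return out


def context_summary(tables: list[CytosineCountTable]) -> pd.DataFrame:
    """Genome-wide weighted methylation level per context per sample:
    sum(mC) / sum(mC + uC). Contexts with no covered sites are reported
    as missing (NaN), not zero."""
    if not tables:
        raise ValueError("no tables given")
    rows = []
    for t in tables:
        g = t.data.groupby("context")[["n_meth", "n_unmeth"]].sum()
        for ctx in ("CG", "CHG", "CHH"):
            if ctx in g.index:
                tot = g.loc[ctx].sum()
                level = g.loc[ctx, "n_meth"] / tot if tot else np.nan
            else:
                level = np.nan
            rows.append((t.sample_id, ctx, level))
    return pd.DataFrame(rows, columns=["sample_id", "context", "level"])


def bin_matrix(
    div_tables: list[pd.DataFrame],
    chrom_sizes: dict[str, int],
    positions: pd.DataFrame | None = None,
    width: int = 2000,
    statistic: str = "mean_hd_at_dmps",
) -> pd.DataFrame:
    """Sample-by-bin matrix over a complete genome tiling.

    Bins are half-open [k*width+1, (k+1)*width] in 1-based coordinates and
    tile every chromosome in ``chrom_sizes``. Statistics:

    - ``mean_hd_at_dmps``: mean HD over the supplied DMP positions per
      bin (requires ``positions`` with chrom/pos columns); 0 where a bin
      holds none. This is the vector used for hierarchical clustering.
    - ``sum_abs_level_diff``: sum of |tv| over the rows of each
      divergence table (pass DMP-restricted tables for the heatmap
      matrix of differential sites).
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if statistic not in ("mean_hd_at_dmps", "sum_abs_level_diff"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "mean_hd_at_dmps" and positions is None:
        raise ValueError("mean_hd_at_dmps requires a DMP position set")

    bin_index: list[str] = []
    offsets: dict[str, int] = {}
    for chrom in sorted(chrom_sizes):
        n_bins = int(np.ceil(chrom_sizes[chrom] / width))
        offsets[chrom] = len(bin_index)
        bin_index += [f"{chrom}:{k * width + 1}-{(k + 1) * width}" for k in range(n_bins)]

    def bin_of(df: pd.DataFrame) -> np.ndarray:
        return (
            df["chrom"].map(offsets).to_numpy() + (df["pos"].to_numpy() - 1) // width
        ).astype(int)

    mat = np.zeros((len(div_tables), len(bin_index)))
    sample_ids = []
    for i, dt in enumerate(div_tables):
        sample_ids.append(dt["sample_id"].iloc[0] if "sample_id" in dt and len(dt) else f"s{i}")
        if statistic == "sum_abs_level_diff":
            use = dt
            values = use["tv"].abs().to_numpy()
        else:
            keyed = dt.merge(positions[["chrom", "pos"]].drop_duplicates(), on=["chrom", "pos"])
            use = keyed
            values = keyed["hd"].to_numpy()
        if len(use) == 0:
            continue
        b = bin_of(use)
        sums = np.bincount(b, weights=values, minlength=len(bin_index))
        if statistic == "mean_hd_at_dmps":
            counts = np.bincount(b, minlength=len(bin_index))
            with np.errstate(invalid="ignore"):
                mat[i] = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        else:
            mat[i] = sums
    return pd.DataFrame(mat, index=sample_ids, columns=bin_index)
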