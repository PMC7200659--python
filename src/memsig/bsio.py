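"""I/O for per-cytosine count tables, annotations, manifests and QC rules.

Coordinates are 1-based inclusive throughout (the Bismark coverage
convention); BED inputs are shifted on read. Strand is retained but never
merged: all site identity is (chrom, pos, strand).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: Default mapping from GFF3/BED feature types to the three feature classes.
#: TE-related covers transposable elements, TE genes, TE fragments and
#: pseudogenes; "other" covers the small structural-RNA types.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "gene": "genic",
    "protein_coding_gene": "genic",
    "mRNA": "genic",
    "transposable_element": "TE_related",
    "transposable_element_gene": "TE_related",
    "transposon_fragment": "TE_related",
    "pseudogene": "TE_related",
    "tRNA": "other",
    "rRNA": "other",
    "snRNA": "other",
    "snoRNA": "other",
    "miRNA": "other",
    "ncRNA": "other",
    "lnc_RNA": "other",
}

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


@dataclass
class CytosineCountTable:
    """Per-site methylated/unmethylated read counts for one sample.

    ``data`` columns: chrom, pos (1-based), strand, context, n_meth,
    n_unmeth. Records are unique per (chrom, pos, strand) and sorted by
    (chrom, pos).
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValueError("negative read counts")
        bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown contexts: {sorted(bad_ctx)}")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) records")
        self.data = (
            df[SITE_COLUMNS]
            .sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def coverage(self) -> pd.Series:
        return self.data["n_meth"] + self.data["n_unmeth"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SampleManifest:
    """Sample design: id, group (control/treatment), generation, phenotype."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "generation", "phenotype"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.entries["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in manifest")

    def samples(self, group: str | None = None) -> list[str]:
        df = self.entries
        if group is not None:
            df = df[df["group"] == group]
        return list(df["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.entries[self.entries["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]


@dataclass
class GenomicAnnotation:
    """Genome features with a three-way class and ±1 kb extended gene regions.

    ``features`` columns: chrom, start, end (1-based inclusive), strand,
    feature_id, feature_class in {genic, TE_related, other}, subtype, and
    for genic features extended_start/extended_end (body ±1 kb, clipped at
    chromosome bounds when known).
    """

    features: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.features
        required = ["chrom", "start", "end", "strand", "feature_id", "feature_class"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if (f["start"] > f["end"]).any():
            bad = f.loc[f["start"] > f["end"], "feature_id"].iloc[0]
            raise ValueError(f"feature {bad!r} has start > end")
        if "subtype" not in f.columns:
            f = f.assign(subtype=f["feature_class"])
        if "extended_start" not in f.columns:
            f = add_extended_regions(f, self.chrom_sizes)
        self.features = f.reset_index(drop=True)

    def genes(self) -> pd.DataFrame:
        return self.features[self.features["feature_class"] == "genic"]

    def by_class(self, feature_class: str) -> pd.DataFrame:
        return self.features[self.features["feature_class"] == feature_class]


def add_extended_regions(
    features: pd.DataFrame, chrom_sizes: dict[str, int], flank: int = 1000
) -> pd.DataFrame:
    """Attach [start-flank, end+flank] regions to genic features, clipped
    at position 1 and at the chromosome length when known."""
    f = features.copy()
    genic = f["feature_class"] == "genic"
    f["extended_start"] = np.where(genic, (f["start"] - flank).clip(lower=1), f["start"])
    upper = f["chrom"].map(chrom_sizes).astype("float64")
    ext_end = np.where(genic, f["end"] + flank, f["end"]).astype("float64")
    f["extended_end"] = np.where(np.isnan(upper), ext_end, np.minimum(ext_end, upper)).astype(
        "int64"
    )
    f["extended_start"] = f["extended_start"].astype("int64")
    return f


# ---------------------------------------------------------------------------
# Bismark coverage / cytosine-report files
# ---------------------------------------------------------------------------


def read_cov(
    path: str | Path,
    sample_id: str | None = None,
    context_track: pd.DataFrame | None = None,
) -> CytosineCountTable:
    """Read a Bismark coverage (6 columns) or cytosine-report (7 columns) file.

    The coverage dialect is chrom, start, end, methylation %, n_meth,
    n_unmeth; the report dialect is chrom, pos, strand, n_meth, n_unmeth,
    context, trinucleotide. The dialect is auto-detected from the column
    count; the percentage column is ignored and levels are always
    recomputed from counts.

    Plain coverage files carry no context: ``context_track`` (columns
    chrom, pos, strand, context) supplies it, and records without a context
    are dropped with a warning.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem.removesuffix(".cov")
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty file, returning empty table", path)
        return CytosineCountTable(sample_id, _empty_site_frame())

    ncol = raw.shape[1]
    if ncol == 6:
        df = pd.DataFrame(
            {
                "chrom": raw[0],
                "pos": _to_int(raw[1], path, "position"),
                "strand": ".",
                "context": pd.NA,
                "n_meth": _to_int(raw[4], path, "n_meth"),
                "n_unmeth": _to_int(raw[5], path, "n_unmeth"),
            }
        )
        if context_track is not None:
            key = ["chrom", "pos"]
            track = context_track.drop_duplicates(["chrom", "pos"])[key + ["context"]]
            df = df.drop(columns="context").merge(track, on=key, how="left")
            n_missing = int(df["context"].isna().sum())
            if n_missing:
                logger.warning(
                    "%s: dropping %d records with no context in the track", path, n_missing
                )
                df = df.dropna(subset=["context"])
    elif ncol == 7:
        df = pd.DataFrame(
            {
                "chrom": raw[0],
                "pos": _to_int(raw[1], path, "position"),
                "strand": raw[2],
                "context": raw[5],
                "n_meth": _to_int(raw[3], path, "n_meth"),
                "n_unmeth": _to_int(raw[4], path, "n_unmeth"),
            }
        )
    else:
        raise ParseError(f"{path}: expected 6 or 7 tab-separated columns, found {ncol}")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        line = int((df["n_meth"] < 0).idxmax() if (df["n_meth"] < 0).any() else (df["n_unmeth"] < 0).idxmax()) + 1
        raise ParseError(f"{path}: negative count at line {line}")
    if df["context"].isna().any():
        logger.warning("%s: %d records lack context and are dropped", path, int(df["context"].isna().sum()))
        df = df.dropna(subset=["context"])
    return CytosineCountTable(sample_id, df.reset_index(drop=True))


def _to_int(col: pd.Series, path: Path, what: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    if out.isna().any():
        line = int(out.isna().idxmax()) + 1
        raise ParseError(f"{path}: malformed {what} at line {line}: {col.iloc[line - 1]!r}")
    return out.astype("int64")


def write_cov(table: CytosineCountTable, path: str | Path, dialect: str = "report") -> None:
    """Write a count table as a cytosine report (default, keeps context)
    or plain coverage file."""
    df = table.data
    cov = df["n_meth"] + df["n_unmeth"]
    if dialect == "report":
        out = pd.DataFrame(
            {
                0: df["chrom"],
                1: df["pos"],
                2: df["strand"],
                3: df["n_meth"],
                4: df["n_unmeth"],
                5: df["context"],
                6: df["context"],
            }
        )
    elif dialect == "coverage":
        with np.errstate(invalid="ignore"):
            pct = np.where(cov > 0, 100.0 * df["n_meth"] / cov, 0.0)
        out = pd.DataFrame(
            {0: df["chrom"], 1: df["pos"], 2: df["pos"], 3: pct, 4: df["n_meth"], 5: df["n_unmeth"]}
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


def _empty_site_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype="int64"),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype="int64"),
            "n_unmeth": pd.Series(dtype="int64"),
        }
    )


# ---------------------------------------------------------------------------
# QC rules
# ---------------------------------------------------------------------------


def conversion_rate(
    table: CytosineCountTable, chloroplast_chrom: str = "ChrC", threshold: float = 0.99
) -> tuple[float, bool]:
    """Bisulfite conversion rate from the (unmethylated) chloroplast genome.

    rate = sum(n_unmeth) / sum(coverage) over chloroplast records; the QC
    passes when the rate exceeds ``threshold`` (default 99%).
    """
    chl = table.data[table.data["chrom"] == chloroplast_chrom]
    total = int((chl["n_meth"] + chl["n_unmeth"]).sum())
    if total == 0:
        raise ValueError(
            f"cannot compute conversion rate: no covered records on {chloroplast_chrom!r}"
        )
    rate = float(chl["n_unmeth"].sum()) / total
    return rate, rate > threshold


def filter_coverage(
    table: CytosineCountTable, max_cov: int = 500, min_cov: int = 4
) -> CytosineCountTable:
    """Drop sites with coverage above ``max_cov`` (PCR-bias control; strictly
    greater than) or below ``min_cov``. Idempotent and order-preserving."""
    if max_cov < min_cov:
        raise ValueError(f"max_cov ({max_cov}) < min_cov ({min_cov})")
    cov = table.coverage
    keep = (cov <= max_cov) & (cov >= min_cov)
    n_high = int((cov > max_cov).sum())
    n_low = int((cov < min_cov).sum())
    if n_high or n_low:
        logger.info(
            "%s: removed %d sites with coverage > %d and %d with coverage < %d",
            table.sample_id, n_high, max_cov, n_low, min_cov,
        )
    return CytosineCountTable(table.sample_id, table.data[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Annotations, manifests, expression tables
# ---------------------------------------------------------------------------

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_annotation(
    path: str | Path,
    class_map: dict[str, str] | None = None,
    feature_types: set[str] | None = None,
) -> GenomicAnnotation:
    """Read a GFF3 or BED6 file into a classed annotation.

    ``class_map`` maps source feature types (GFF3 column 3 / BED name
    prefix before the first ``:``) to {genic, TE_related, other}; unmapped
    types are logged and dropped. BED intervals are converted to 1-based
    inclusive coordinates. Genic features get ±1 kb extended regions.
    """
    path = Path(path)
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(path, sep="\t", header=None)
        types = bed[3].astype(str).str.split(":").str[0]
        feats = pd.DataFrame(
            {
                "chrom": bed[0],
                "start": bed[1].astype("int64") + 1,
                "end": bed[2].astype("int64"),
                "strand": bed[5] if bed.shape[1] > 5 else "+",
                "feature_id": bed[3].astype(str),
                "subtype": types,
            }
        )
        chrom_sizes: dict[str, int] = {}
    else:
        chrom_sizes = {}
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        chrom_sizes[parts[1]] = int(parts[3])
                    continue
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ParseError(f"{path}: malformed GFF3 line {i}")
                m = _GFF_ID_RE.search(cols[8])
                fid = m.group(1) if m else f"{cols[2]}:{cols[0]}:{cols[3]}-{cols[4]}"
                rows.append((cols[0], int(cols[3]), int(cols[4]), cols[6], fid, cols[2]))
        feats = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "feature_id", "subtype"]
        )
    if feature_types is not None:
        feats = feats[feats["subtype"].isin(feature_types)]
    feats["feature_class"] = feats["subtype"].map(class_map)
    unmapped = feats.loc[feats["feature_class"].isna(), "subtype"].unique()
    if len(unmapped):
        logger.info("%s: dropping unmapped feature types %s", path, sorted(unmapped))
        feats = feats.dropna(subset=["feature_class"])
    bad = feats["start"] > feats["end"]
    if bad.any():
        raise ParseError(f"{path}: feature {feats.loc[bad, 'feature_id'].iloc[0]!r} has start > end")
    return GenomicAnnotation(feats.reset_index(drop=True), chrom_sizes)


def read_manifest(path: str | Path) -> SampleManifest:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return SampleManifest(pd.read_csv(path, sep=sep))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene expression results table (gene_id, log2fc, padj)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = ["gene_id", "log2fc", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    return df[required]
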