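"""Genome-level methylation summaries from per-CpG call tables.

Aggregation of bisulphite calls into feature-class methylation, CGI /
non-CGI decomposition, CGI methylation binning, hierarchical sample
clustering and pairwise per-CpG comparison.  Calls are 1-based internally;
feature intervals follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "meth_count", "total_count"]


# ---------------------------------------------------------------------------
# IO


def read_calls(path, dialect: str = "cpg_report") -> pd.DataFrame:
    """Read a per-CpG call table.

    ``cpg_report``  headerless TSV (chrom, pos, strand, meth_count,
                    total_count), positions 1-based.
    ``bedgraph``    headerless TSV (chrom, start, end, meth_count,
                    total_count), 0-based half-open; positions are
                    normalized to 1-based (pos = start + 1), strand '.'.

    Rows with meth_count > total_count or unparseable fields are rejected
    and counted in the log.
    """
    if dialect == "cpg_report":
        raw = pd.read_csv(
            path, sep="\t", header=None,
            names=CALL_COLUMNS, dtype=str, comment="#",
        )
    elif dialect == "bedgraph":
        raw = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "meth_count", "total_count"],
            dtype=str, comment="#",
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    skipped = 0
    for tup in raw.itertuples(index=False):
        try:
            if dialect == "cpg_report":
                pos = int(tup.pos)
                strand = str(tup.strand)
            else:
                pos = int(tup.start) + 1
                strand = "."
            meth = int(tup.meth_count)
            total = int(tup.total_count)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if meth > total or meth < 0:
            skipped += 1
            continue
        rows.append((str(tup.chrom), pos, strand, meth, total))
    if skipped:
        logger.warning("read_calls: skipped %d malformed/invalid rows", skipped)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(calls: pd.DataFrame, path, dialect: str = "cpg_report") -> Path:
    path = Path(path)
    if dialect == "cpg_report":
        calls[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    elif dialect == "bedgraph":
        out = calls.copy()
        out["start"] = out["pos"] - 1
        out["end"] = out["pos"]
        out[["chrom", "start", "end", "meth_count", "total_count"]].to_csv(
            path, sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_bed(path) -> pd.DataFrame:
    """BED intervals (chrom, start, end[, name]); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"feature_{i}" for i in range(len(df))]
    return df


def pool_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Pool the two strands of each CpG dyad into one record.

    The - strand call at pos p+1 is folded onto the + strand C at p;
    pooled records carry strand '.'.
    """
    df = calls.copy()
    dyad_pos = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"])
    df["pos"] = dyad_pos
    pooled = (
        df.groupby(["chrom", "pos"], as_index=False)[["meth_count", "total_count"]]
        .sum()
    )
    pooled["strand"] = "."
    return pooled[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# Aggregation


def feature_methylation(
    calls: pd.DataFrame, features: pd.DataFrame, min_depth: int = 1
) -> pd.DataFrame:
    """Count-weighted methylation per feature.

    A 1-based call at pos p belongs to the BED feature [start, end) iff
    start + 1 <= p <= end.  Per feature: sum(meth)/sum(total) over calls
    with total_count >= min_depth; features without a qualifying CpG get
    NaN (never zero).
    """
    out_rows = []
    for tup in features.itertuples(index=False):
        sel = calls[
            (calls["chrom"] == tup.chrom)
            & (calls["pos"] >= tup.start + 1)
            & (calls["pos"] <= tup.end)
            & (calls["total_count"] >= min_depth)
        ]
        total = int(sel["total_count"].sum())
        meth = int(sel["meth_count"].sum())
        out_rows.append(
            dict(
                feature_id=getattr(tup, "name", None)
                or getattr(tup, "feature_id", None),
                chrom=tup.chrom,
                start=tup.start,
                end=tup.end,
                n_cpg=len(sel),
                methylation=(meth / total) if total > 0 else np.nan,
            )
        )
    return pd.DataFrame(out_rows)


def split_cgi_noncgi(calls: pd.DataFrame, cgi_intervals: pd.DataFrame):
    """Partition calls into (CGI, non-CGI) by containment.

    A call at 1-based pos p is inside the CGI [start, end) iff
    start <= p - 1 < end.  Every call lands in exactly one output.
    """
    inside = np.zeros(len(calls), dtype=bool)
    pos0 = calls["pos"].to_numpy() - 1
    chroms = calls["chrom"].to_numpy()
    for tup in cgi_intervals.itertuples(index=False):
        inside |= (chroms == tup.chrom) & (pos0 >= tup.start) & (pos0 < tup.end)
    return (
        calls.loc[inside].reset_index(drop=True),
        calls.loc[~inside].reset_index(drop=True),
    )


def split_features_cgi_noncgi(features: pd.DataFrame, cgi_intervals: pd.DataFrame):
    """Partition features by any-overlap with a CGI interval."""
    overlap = np.zeros(len(features), dtype=bool)
    for i, tup in enumerate(features.itertuples(index=False)):
        for cgi in cgi_intervals.itertuples(index=False):
            if (
                tup.chrom == cgi.chrom
                and tup.start < cgi.end
                and cgi.start < tup.end
            ):
                overlap[i] = True
                break
    return (
        features.loc[overlap].reset_index(drop=True),
        features.loc[~overlap].reset_index(drop=True),
    )


def classify_cgis(methylation: pd.Series | dict) -> pd.DataFrame:
    """Bin per-CGI methylation: high [0.75, 1], moderate [0.50, 0.75),
    low otherwise; retained_flag iff methylation > 0.25.

    Bin boundaries are closed at the lower edge.
    """
    if isinstance(methylation, dict):
        methylation = pd.Series(methylation)
    rows = []
    for cgi_id, value in methylation.items():
        if np.isnan(value):
            continue
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{cgi_id}: methylation {value} outside [0, 1]")
        if value >= 0.75:
            bin_label = "high"
        elif value >= 0.50:
            bin_label = "moderate"
        else:
            bin_label = "low"
        rows.append(
            dict(
                cgi_id=cgi_id,
                mean_methylation=float(value),
                bin=bin_label,
                retained_flag=bool(value > 0.25),
            )
        )
    return pd.DataFrame(rows, columns=["cgi_id", "mean_methylation", "bin", "retained_flag"])


def bin_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = {"high": 0, "moderate": 0, "low": 0}
    for b in classified["bin"]:
        counts[b] += 1
    counts["retained"] = int(classified["retained_flag"].sum())
    return counts


# ---------------------------------------------------------------------------
# Clustering and comparison


def _pairwise_euclidean_nan(matrix: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances with pairwise NaN dropping."""
    n = matrix.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(matrix[i]) | np.isnan(matrix[j]))
            if not ok.any():
                raise ValueError(
                    f"samples {i} and {j} share no non-missing features"
                )
            diff = matrix[i, ok] - matrix[j, ok]
            dm[i, j] = dm[j, i] = float(np.sqrt(np.sum(diff**2)))
    return squareform(dm, checks=False)


def cluster_samples(
    matrix: pd.DataFrame, method: str = "average", metric: str = "euclidean"
):
    """Hierarchical clustering of samples (rows) over feature methylation.

    Missing values are dropped pairwise when computing distances.  Returns
    (scipy linkage matrix, Newick string with the sample index order of
    ``matrix``).
    """
    if metric != "euclidean":
        raise ValueError("only euclidean distance is supported")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = _pairwise_euclidean_nan(matrix.to_numpy(dtype=float))
    Z = _scipy_linkage(condensed, method=method)
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(matrix.index.astype(str)))
    newick = str(tree).strip()
    return Z, newick


def pairwise_cpg_compare(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    min_depth: int = 1,
    unchanged_band: float = 0.1,
):
    """Per-CpG methylation differences (b - a) and a change summary.

    Only CpGs with depth >= min_depth in both samples contribute.  A CpG
    is "unchanged" when |delta| <= unchanged_band, else counted as
    decreasing/increasing by the sign of delta.
    """
    key = ["chrom", "pos", "strand"]
    merged = sample_a.merge(sample_b, on=key, suffixes=("_a", "_b"))
    merged = merged[
        (merged["total_count_a"] >= min_depth)
        & (merged["total_count_b"] >= min_depth)
    ]
    if len(merged) == 0:
        raise ValueError("no shared CpGs at the requested depth")
    merged = merged.copy()
    merged["meth_a"] = merged["meth_count_a"] / merged["total_count_a"]
    merged["meth_b"] = merged["meth_count_b"] / merged["total_count_b"]
    merged["delta"] = merged["meth_b"] - merged["meth_a"]
    delta = merged["delta"].to_numpy()
    n = len(delta)
    summary = dict(
        n_cpg=n,
        frac_decreasing=float(np.sum(delta < -unchanged_band) / n),
        frac_increasing=float(np.sum(delta > unchanged_band) / n),
        frac_unchanged=float(np.sum(np.abs(delta) <= unchanged_band) / n),
        mean_delta=float(delta.mean()),
    )
    return merged[key + ["meth_a", "meth_b", "delta"]], summary
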