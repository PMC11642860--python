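"""Gene assignment, count normalisation, expression profiles and DEG calling.

Sites are assigned to the single nearest gene by |site midpoint - TSS| on the
same chromosome, within a maximum distance (1 Mb for genome-wide association,
2.5 kb for the enhancer screen).  Raw count matrices are normalised with
median-of-ratios size factors: the per-gene reference is the geometric mean
across samples (genes with any zero are excluded from the reference), and each
sample's factor is the median of its count/reference ratios.

Differential expression uses a deliberately transparent engine: a Welch
two-sample test on log2(normalised + 0.5) with Benjamini-Hochberg adjustment;
genes pass with |log2FC| strictly above the fold-change threshold and adjusted
p strictly below alpha.  The small wet-lab formulas (2^(-dCt) relative
expression, colony-based reprogramming efficiency, pooled-variance t test)
live here as well.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet

__all__ = [
    "read_gene_annotation",
    "read_gtf_tss",
    "nearest_gene",
    "distance_bins",
    "size_factors",
    "normalize_counts",
    "median_profile",
    "call_degs",
    "qpcr_relative",
    "reprogramming_efficiency",
    "unpaired_t_test",
    "two_tailed_p",
    "DEFAULT_DISTANCE_EDGES",
]

DEFAULT_DISTANCE_EDGES = (0, 5_000, 50_000, 500_000, 1_000_000)
DEG_LFC_THRESHOLD = 0.58
DEG_ALPHA = 0.05
PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Gene annotation

_ANNOT_COLS = ["gene_id", "chrom", "tss", "strand"]


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a 4-column TSV gene annotation: gene_id, chrom, tss, strand.

    ``tss`` is a 0-based position.  A header line is detected and skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (gene_id, chrom, tss, strand)")
    df = df.iloc[:, :4]
    df.columns = _ANNOT_COLS
    if df.iloc[0]["gene_id"].lower() in ("gene_id", "gene"):
        df = df.iloc[1:].reset_index(drop=True)
    df["tss"] = df["tss"].astype(int)
    _check_annotation(df)
    return df


def read_gtf_tss(path) -> pd.DataFrame:
    """Derive per-gene TSSs from GTF transcript records.

    TSS is the transcript start for + strand genes and end - 1 for - strand
    (converted from the 1-based inclusive GTF convention to 0-based).  For
    genes with several transcripts the 5'-most TSS is kept.
    """
    best: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("transcript", "gene"):
                continue
            chrom, start, end, strand, attrs = parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8]
            gene_id = _gtf_attr(attrs, "gene_id") or _gtf_attr(attrs, "gene_name")
            if gene_id is None:
                continue
            tss = start - 1 if strand == "+" else end - 1
            prev = best.get(gene_id)
            if prev is None:
                best[gene_id] = (chrom, tss, strand)
            else:
                _, ptss, pstrand = prev
                upstream = tss < ptss if strand == "+" else tss > ptss
                if upstream:
                    best[gene_id] = (chrom, tss, strand)
    rows = [
        {"gene_id": g, "chrom": c, "tss": t, "strand": s}
        for g, (c, t, s) in sorted(best.items())
    ]
    df = pd.DataFrame(rows, columns=_ANNOT_COLS)
    _check_annotation(df)
    return df


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def _check_annotation(df: pd.DataFrame) -> None:
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in annotation: {dup}")
    if (df["tss"] < 0).any():
        raise ValueError("negative TSS position in annotation")


# ---------------------------------------------------------------------------
# Site-to-gene assignment

def nearest_gene(
    sites: IntervalSet, genes: pd.DataFrame, max_distance_bp: int = 1_000_000
) -> pd.DataFrame:
    """Assign each site to the gene minimising |site midpoint - TSS|.

    Only genes on the site's chromosome are considered; the assignment is
    dropped to ``gene_id = None`` when the minimum distance exceeds
    ``max_distance_bp``.  Ties break to the lexicographically smallest
    gene_id.  Returns one row per site, in site order.
    """
    if len(genes) == 0:
        raise ValueError("nearest_gene requires a non-empty gene annotation")
    per_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values(["tss", "gene_id"])
        per_chrom[chrom] = (sub["tss"].to_numpy(dtype=np.int64), list(sub["gene_id"]))
    rows = []
    for iv in sites:
        mid = iv.midpoint
        gene_id, dist = None, None
        entry = per_chrom.get(iv.chrom)
        if entry is not None:
            tss, ids = entry
            k = int(np.searchsorted(tss, mid))
            best = None
            for i in (k - 1, k):
                if 0 <= i < len(ids):
                    d = abs(int(tss[i]) - mid)
                    if best is None or d < best[0]:
                        best = (d, i)
            if best is not None and best[0] <= max_distance_bp:
                dist = best[0]
                # equidistant candidates lie at mid-dist and mid+dist; take the
                # lexicographically smallest gene_id among them
                lo = int(np.searchsorted(tss, mid - dist, side="left"))
                hi = int(np.searchsorted(tss, mid + dist, side="right"))
                tied = [ids[i] for i in range(lo, hi) if abs(int(tss[i]) - mid) == dist]
                gene_id = min(tied)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "site_name": iv.name,
                "gene_id": gene_id,
                "distance_bp": dist,
            }
        )
    return pd.DataFrame(rows)


def distance_bins(
    assignments: pd.DataFrame, edges: Sequence[int] = DEFAULT_DISTANCE_EDGES
) -> pd.Series:
    """Histogram of assigned site-to-TSS distances over half-open bins.

    Bins are ``[edge_i, edge_{i+1})`` with the final bin closed on the right
    (numpy convention), so every assigned distance within the edge span is
    counted exactly once.
    """
    assigned = assignments.dropna(subset=["gene_id"])
    dists = assigned["distance_bp"].to_numpy(dtype=float)
    counts, _ = np.histogram(dists, bins=np.asarray(edges, dtype=float))
    labels = [f"[{edges[i]},{edges[i+1]})" for i in range(len(edges) - 1)]
    return pd.Series(counts, index=labels, name="n_sites")


# ---------------------------------------------------------------------------
# Count normalisation (median-of-ratios)

def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors per sample.

    Reference = per-gene geometric mean over samples, genes with any zero
    excluded; factor_s = median over reference genes of count/reference.
    """
    mat = raw.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("size factors undefined: no gene has nonzero counts in all samples")
    kept = mat[nonzero]
    reference = np.exp(np.log(kept).mean(axis=1))  # per-gene geometric mean
    factors = np.median(kept / reference[:, None], axis=0)
    return pd.Series(factors, index=raw.columns, name="size_factor")


def normalize_counts(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Raw counts divided per sample by the median-of-ratios size factor."""
    factors = size_factors(raw)
    return raw / factors, factors


def _sample_timepoint(label: str) -> str:
    """Time-point prefix of a ``<timepoint>_<replicate>`` sample label."""
    return label.rsplit("_", 1)[0]


def median_profile(
    gene_set: Iterable[str],
    normalized: pd.DataFrame,
    timepoints: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Median per-stage expression profile of a gene set.

    Replicates are averaged (arithmetic mean of normalised counts) per stage
    per gene, then the median across genes is taken.  Genes with zero
    normalised counts at every stage are excluded first; if that excludes all
    genes the profile is undefined.
    """
    gene_set = [g for g in gene_set if g in normalized.index]
    if not gene_set:
        raise ValueError("median_profile: no genes from the set are in the matrix")
    sub = normalized.loc[gene_set]
    by_tp = sub.T.groupby(_sample_timepoint).mean().T
    if timepoints is not None:
        by_tp = by_tp[list(timepoints)]
    expressed = by_tp[(by_tp != 0).any(axis=1)]
    if expressed.empty:
        raise ValueError("median_profile: all genes have zero counts at every stage")
    return expressed.median(axis=0)


# ---------------------------------------------------------------------------
# Differential expression

def call_degs(
    raw: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = DEG_LFC_THRESHOLD,
    alpha: float = DEG_ALPHA,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene differential expression of group_b relative to group_a.

    Counts are normalised (median-of-ratios over the union of the two
    groups), log2 fold change is ``log2((mean_b + c0)/(mean_a + c0))`` and
    the p-value comes from a Welch test on ``log2(normalised + c0)``,
    BH-adjusted across all tested genes.  Direction is ``up`` iff
    ``log2fc > lfc_threshold`` and ``padj < alpha`` (both strict), ``down``
    symmetrically, else ``none``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("call_degs requires >= 2 samples per group")
    norm, _ = normalize_counts(raw[group_a + group_b])
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    log2fc = np.log2(b.mean(axis=1) + pseudocount) - np.log2(a.mean(axis=1) + pseudocount)
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    # degenerate genes (zero variance in both groups) get p = 1
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (log2fc > lfc_threshold) & (padj < alpha),
        "up",
        np.where((log2fc < -lfc_threshold) & (padj < alpha), "down", "none"),
    )
    return pd.DataFrame(
        {
            "gene_id": raw.index,
            "log2fc": log2fc,
            "pvalue": p,
            "padj": padj,
            "direction": direction,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Wet-lab formulas

def qpcr_relative(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the 2^(-dCt) method against a reference gene."""
    return float(2.0 ** (-(ct_target - ct_reference)))


def reprogramming_efficiency(n_colonies: int, n_seeded: int) -> float:
    """Percent of seeded cells yielding AP-positive iPSC colonies."""
    if n_seeded <= 0:
        raise ValueError("n_seeded must be positive")
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    return 100.0 * n_colonies / n_seeded


def two_tailed_p(t: float, df: float) -> float:
    """Two-tailed p-value of a t statistic from the t-distribution survival function."""
    return float(2.0 * stats.t.sf(abs(t), df))


def unpaired_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test: (t, df, two-tailed p).

    df = n_a + n_b - 2.  Zero pooled variance with equal means yields
    (t=0, p=1); with unequal means the difference is infinitely significant
    relative to zero noise and p -> 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired_t_test requires >= 2 values per group")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return (0.0, df, 1.0) if diff == 0 else (float("inf"), df, 0.0)
    t = diff / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    return float(t), int(df), two_tailed_p(t, df)
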