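"""The unbiased Reprogramming-Inducible Enhancer (RIE) filter chain.

Starting from the de-novo early-bound ESC sites (bound by OSKM from day 1 but
not KM-pre-bound in MEFs), three sequential filters retain candidate
enhancers:

1. *proximal*: the site's nearest TSS lies within 2.5 kb of the site midpoint
   (unassigned sites are dropped);
2. *upregulated*: the assigned gene is up-regulated between MEFs and ESCs with
   log2FC > 2 and adjusted p < 0.05 (both strict);
3. *peak density*: the total number of individual O/S/K/M peaks (per factor,
   per reprogramming stage) overlapping the site exceeds 10 — sites with <= 10
   binding events are removed.

Survivors are putative RIEs; adjacent survivors are additionally grouped into
co-bound regions by gap-merging (the grouping radius is a configurable
default, not part of the published chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .expression import nearest_gene
from .integration import Factor, Timepoint
from .intervals import GenomicInterval, IntervalSet, count_overlaps, merge_within_gap, sort_intervals

__all__ = [
    "RIEConfig",
    "RIECandidate",
    "RIEScreenResult",
    "proximal_filter",
    "upregulated_filter",
    "peak_density_filter",
    "run_rie_screen",
]

#: Stages whose individual factor peaks count towards binding density
#: ("peaks in reprogramming": the induced stages, excluding the MEF state).
DENSITY_TIMEPOINTS: tuple[Timepoint, ...] = (
    Timepoint.D1,
    Timepoint.D3,
    Timepoint.D6,
    Timepoint.ESC,
)


@dataclass(frozen=True)
class RIEConfig:
    max_distance_bp: int = 2_500
    lfc_min: float = 2.0
    padj_alpha: float = 0.05
    min_total_peaks: int = 10          # candidates with total <= this fail
    timepoints_for_density: tuple[Timepoint, ...] = DENSITY_TIMEPOINTS
    adjacency_gap_bp: int = 1_000


@dataclass
class RIECandidate:
    """One screened site with its per-filter verdicts."""

    site: GenomicInterval
    gene_id: Optional[str]
    distance_bp: Optional[int]
    peak_counts: dict[str, int] = field(default_factory=dict)
    total_peaks: int = 0
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return bool(self.filter_trace) and all(v for _, v in self.filter_trace)


def proximal_filter(
    denovo_early: IntervalSet,
    genes: pd.DataFrame,
    max_distance_bp: int = 2_500,
) -> pd.DataFrame:
    """Site-gene pairs whose nearest TSS is within ``max_distance_bp`` (midpoint).

    Unassigned sites (nearest TSS farther than the bound, strict) are dropped.
    Returns one row per retained site with its site index, gene and distance.
    """
    assigned = nearest_gene(denovo_early, genes, max_distance_bp)
    assigned.insert(0, "site_index", range(len(assigned)))
    return assigned.dropna(subset=["gene_id"]).reset_index(drop=True)


def upregulated_filter(
    pairs: pd.DataFrame,
    degs: pd.DataFrame,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep pairs whose gene is up-regulated: log2fc > lfc_min and padj < alpha.

    ``degs`` is the MEF-vs-ESC differential table indexed by gene_id; genes
    absent from it fail the filter.
    """
    def gene_up(g: str) -> bool:
        if g not in degs.index:
            return False
        row = degs.loc[g]
        return bool(row["log2fc"] > lfc_min and row["padj"] < alpha)

    mask = pairs["gene_id"].map(gene_up).astype(bool)
    return pairs[mask].reset_index(drop=True)


def peak_density_filter(
    pairs: pd.DataFrame,
    sites: IntervalSet,
    factor_peaks: Mapping[tuple[Factor, Timepoint], IntervalSet],
    min_total_exclusive: int = 10,
) -> list[RIECandidate]:
    """Score each pair's site by total individual O/S/K/M peak overlaps.

    ``total_peaks`` sums, over every supplied (factor, stage) peak set, the
    number of peaks overlapping the site; candidates with
    ``total_peaks <= min_total_exclusive`` are marked failed.
    """
    site_list = list(sites)
    sub = IntervalSet([site_list[i] for i in pairs["site_index"]])
    per_key = {
        key: count_overlaps(sub, peaks) for key, peaks in factor_peaks.items()
    }
    candidates = []
    for row_i, row in pairs.reset_index(drop=True).iterrows():
        counts: dict[str, int] = {}
        for (factor, tp), arr in per_key.items():
            label = f"{factor.value}_{tp.value}"
            counts[label] = int(arr[row_i])
        total = sum(counts.values())
        cand = RIECandidate(
            site=sub[row_i],
            gene_id=row["gene_id"],
            distance_bp=int(row["distance_bp"]),
            peak_counts=counts,
            total_peaks=total,
        )
        cand.filter_trace.append(("proximal", True))
        cand.filter_trace.append(("upregulated", True))
        cand.filter_trace.append(("peak_density", total > min_total_exclusive))
        candidates.append(cand)
    return candidates


@dataclass
class RIEScreenResult:
    candidates: list[RIECandidate]
    survivors: list[RIECandidate]
    stage_counts: dict[str, int]
    rie_regions: IntervalSet

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "chrom": c.site.chrom,
                    "start": c.site.start,
                    "end": c.site.end,
                    "gene_id": c.gene_id,
                    "distance_bp": c.distance_bp,
                    "total_peaks": c.total_peaks,
                    "passed": c.passed,
                    "filter_trace": ";".join(f"{n}={'pass' if v else 'fail'}" for n, v in c.filter_trace),
                }
            )
        return pd.DataFrame(rows)

    def provenance(self) -> str:
        lines = ["RIE screen filter chain"]
        for stage, n in self.stage_counts.items():
            lines.append(f"  {stage}: {n}")
        return "\n".join(lines)


def run_rie_screen(
    denovo_early: IntervalSet,
    genes: pd.DataFrame,
    degs: pd.DataFrame,
    factor_peaks: Mapping[tuple[Factor, Timepoint], IntervalSet],
    config: RIEConfig = RIEConfig(),
) -> RIEScreenResult:
    """Execute proximal -> up-regulated -> peak-density sequentially.

    Every input site appears in ``candidates`` with its filter trace; sites
    failing a stage carry that stage's failing verdict and are not evaluated
    further.  Survivors are sorted by total_peaks descending, ties by
    (chrom, start); ``rie_regions`` gap-merges the survivors into co-bound
    regions.
    """
    if len(denovo_early) == 0:
        raise ValueError("RIE screen requires a non-empty de novo early site set")
    if genes is None or len(genes) == 0:
        raise ValueError("RIE screen missing the gene annotation stage input")
    if degs is None:
        raise ValueError("RIE screen missing the MEF-vs-ESC differential table")

    assigned = nearest_gene(denovo_early, genes, config.max_distance_bp)
    assigned.insert(0, "site_index", range(len(assigned)))
    proximal = assigned.dropna(subset=["gene_id"]).reset_index(drop=True)
    upreg = upregulated_filter(proximal, degs, config.lfc_min, config.padj_alpha)
    peaks_supplied = {
        key: s for key, s in factor_peaks.items() if key[1] in config.timepoints_for_density
    }
    scored = peak_density_filter(upreg, denovo_early, peaks_supplied, config.min_total_peaks)

    candidates: list[RIECandidate] = []
    upreg_idx = set(upreg["site_index"])
    proximal_idx = set(proximal["site_index"])
    scored_by_idx = {int(i): c for i, c in zip(upreg["site_index"], scored)}
    for i, row in assigned.iterrows():
        idx = int(row["site_index"])
        if idx in scored_by_idx:
            candidates.append(scored_by_idx[idx])
            continue
        cand = RIECandidate(
            site=denovo_early[idx],
            gene_id=row["gene_id"] if idx in proximal_idx else None,
            distance_bp=int(row["distance_bp"]) if idx in proximal_idx else None,
        )
        cand.filter_trace.append(("proximal", idx in proximal_idx))
        if idx in proximal_idx:
            cand.filter_trace.append(("upregulated", idx in upreg_idx))
        candidates.append(cand)

    survivors = sorted(
        (c for c in candidates if c.passed),
        key=lambda c: (-c.total_peaks, c.site.chrom, c.site.start),
    )
    regions = merge_within_gap(
        sort_intervals(IntervalSet([c.site for c in survivors])), config.adjacency_gap_bp
    )
    stage_counts = {
        "input": len(denovo_early),
        "proximal": len(proximal),
        "upregulated": len(upreg),
        "peak_density": len(survivors),
    }
    return RIEScreenResult(candidates, survivors, stage_counts, regions)
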