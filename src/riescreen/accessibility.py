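"""Open-chromatin (ATAC) overlay for classified binding sites.

A site is counted as accessible at a stage when it overlaps any called ATAC
peak of that stage by at least one base.  Per class and stage the fraction of
accessible sites is reported with an OPEN_MAJOR/CLOSED_MAJOR flag at the 30%
threshold (strictly greater than 0.30 is OPEN_MAJOR; exactly 30% is
CLOSED_MAJOR).  MEF-vs-ESC Venn counts partition the open-in-either sites,
and arbitrary feature sets (super-enhancers, MTLs) can be overlap-annotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .integration import Timepoint
from .intervals import IntervalSet, count_overlaps

__all__ = [
    "OPEN_FRACTION_THRESHOLD",
    "fraction_open",
    "open_fraction_table",
    "open_venn",
    "VennCounts",
    "annotate_feature_overlap",
]

OPEN_FRACTION_THRESHOLD = 0.30


def fraction_open(
    sites: IntervalSet,
    atac: Mapping[Timepoint, IntervalSet],
    threshold: float = OPEN_FRACTION_THRESHOLD,
) -> pd.DataFrame:
    """Per stage: number and fraction of sites overlapping an ATAC peak.

    The flag is OPEN_MAJOR when fraction > ``threshold`` (strict), else
    CLOSED_MAJOR.  Empty ``sites`` is an error (the fraction is undefined).
    """
    if len(sites) == 0:
        raise ValueError("fraction_open is undefined for an empty site set")
    rows = []
    for tp, peaks in atac.items():
        n_open = int((count_overlaps(sites, peaks) > 0).sum())
        frac = n_open / len(sites)
        rows.append(
            {
                "timepoint": tp.value,
                "n_sites": len(sites),
                "n_open": n_open,
                "fraction_open": frac,
                "flag": "OPEN_MAJOR" if frac > threshold else "CLOSED_MAJOR",
            }
        )
    return pd.DataFrame(rows)


def open_fraction_table(
    class_sets: Mapping[str, IntervalSet],
    atac: Mapping[Timepoint, IntervalSet],
    threshold: float = OPEN_FRACTION_THRESHOLD,
) -> pd.DataFrame:
    """Stacked open-fraction table over several site classes (skips empty ones)."""
    frames = []
    for label, sites in class_sets.items():
        if len(sites) == 0:
            continue
        df = fraction_open(sites, atac, threshold)
        df.insert(0, "site_class", label)
        frames.append(df)
    if not frames:
        raise ValueError("no non-empty site classes to tabulate")
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class VennCounts:
    mef_only: int
    shared: int
    esc_only: int

    @property
    def total_open(self) -> int:
        return self.mef_only + self.shared + self.esc_only


def open_venn(
    sites: IntervalSet, atac_mef: IntervalSet, atac_esc: IntervalSet
) -> VennCounts:
    """Partition the sites open in MEFs and/or ESCs by where they are open."""
    open_mef = count_overlaps(sites, atac_mef) > 0
    open_esc = count_overlaps(sites, atac_esc) > 0
    return VennCounts(
        mef_only=int((open_mef & ~open_esc).sum()),
        shared=int((open_mef & open_esc).sum()),
        esc_only=int((~open_mef & open_esc).sum()),
    )


def annotate_feature_overlap(
    sites: IntervalSet, features: IntervalSet
) -> tuple[np.ndarray, dict]:
    """Per-site overlap counts against a feature set plus a coverage summary.

    Returns the per-record counts (order matches ``sites``) and a summary with
    the number and fraction of sites hitting >= 1 feature.
    """
    counts = count_overlaps(sites, features)
    n_hit = int((counts > 0).sum())
    summary = {
        "n_sites": len(sites),
        "n_overlapping": n_hit,
        "fraction_overlapping": (n_hit / len(sites)) if len(sites) else float("nan"),
    }
    return counts, summary
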