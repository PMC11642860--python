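"""Pairwise co-binding, between-stage retention and mobility statistics.

Co-binding is reported as row-conditional percentages: cell (r, c) is the
percentage of factor-r sites overlapped by at least one factor-c site, so the
matrix is not symmetric when the factors bind different numbers of sites.
Retention between consecutive stages (D1->D3, D3->D6, D6->ESC) counts the
fraction of a factor's sites preserved at the next stage; mobility counts the
new sites gained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .integration import Factor, OSKM_FACTORS, Timepoint
from .intervals import IntervalSet, intersect_any, subtract_nonoverlapping

__all__ = [
    "RetentionRecord",
    "cobinding_matrix",
    "retention_between",
    "mobility_series",
    "TRANSITIONS",
]

#: Ordered stage transitions used for retention and mobility reports.
TRANSITIONS: tuple[tuple[Timepoint, Timepoint], ...] = (
    (Timepoint.D1, Timepoint.D3),
    (Timepoint.D3, Timepoint.D6),
    (Timepoint.D6, Timepoint.ESC),
)


def cobinding_matrix(
    sets: Mapping[Factor, IntervalSet], tp: Optional[Timepoint] = None
) -> pd.DataFrame:
    """Row-conditional co-binding percentages between the four O/S/K/M sets.

    cell(r, c) = 100 * |records of set_r overlapping set_c| / |set_r|.
    The diagonal is exactly 100.  An empty row set yields a NaN row (undefined,
    not zero).  Oct4 is expected to be pre-downsampled where applicable.
    """
    missing = [f.value for f in OSKM_FACTORS if f not in sets]
    if missing:
        raise ValueError(f"co-binding matrix needs all four factor sets; missing {missing}")
    labels = [f.value for f in OSKM_FACTORS]
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for fr in OSKM_FACTORS:
        row = sets[fr]
        if len(row) == 0:
            continue
        for fc in OSKM_FACTORS:
            n_common = len(intersect_any(row, sets[fc]))
            mat.loc[fr.value, fc.value] = 100.0 * n_common / len(row)
    mat.attrs["timepoint"] = tp.value if tp is not None else None
    return mat


@dataclass(frozen=True)
class RetentionRecord:
    """Preserved/new site bookkeeping for one factor across one transition."""

    factor: Factor
    from_tp: Timepoint
    to_tp: Timepoint
    n_from: int
    n_preserved: int
    n_new: int

    @property
    def percent_preserved(self) -> float:
        return 100.0 * self.n_preserved / self.n_from


def retention_between(
    factor: Factor,
    set_t1: IntervalSet,
    set_t2: IntervalSet,
    from_tp: Timepoint,
    to_tp: Timepoint,
) -> RetentionRecord:
    """Fraction of a factor's sites at one stage still bound at the next stage.

    ``n_preserved`` counts records of ``set_t1`` overlapping ``set_t2``;
    ``n_new`` counts records of ``set_t2`` with no overlap back to ``set_t1``.
    """
    if len(set_t1) == 0:
        raise ValueError(f"retention undefined: empty {factor.value} set at {from_tp.value}")
    n_preserved = len(intersect_any(set_t1, set_t2))
    n_new = len(subtract_nonoverlapping(set_t2, set_t1))
    return RetentionRecord(factor, from_tp, to_tp, len(set_t1), n_preserved, n_new)


def mobility_series(
    factor: Factor, sets_by_tp: Mapping[Timepoint, IntervalSet]
) -> pd.DataFrame:
    """New-site gains per consecutive transition for one factor.

    For each transition t1 -> t2 present in ``sets_by_tp``:
    ``n_new = |set_t2 \\ set_t1|`` (records of t2 with no overlap to t1), also
    reported relative to ``|set_t2|``.  Both the absolute and the normalised
    count are emitted because either reading of a "relative number of new
    sites" is defensible.
    """
    tps = [tp for tp in Timepoint if tp in sets_by_tp]
    if len(tps) < 2:
        raise ValueError("mobility_series requires sets at >= 2 time-points")
    rows = []
    for t1, t2 in zip(tps, tps[1:]):
        s1, s2 = sets_by_tp[t1], sets_by_tp[t2]
        n_new = len(subtract_nonoverlapping(s2, s1))
        rows.append(
            {
                "factor": factor.value,
                "transition": f"{t1.value}->{t2.value}",
                "n_to": len(s2),
                "n_new": n_new,
                "fraction_new": (n_new / len(s2)) if len(s2) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def retention_table(
    sets: Mapping[Factor, Mapping[Timepoint, IntervalSet]]
) -> pd.DataFrame:
    """Long-format retention table over all factors and standard transitions."""
    rows = []
    for factor, by_tp in sets.items():
        for t1, t2 in TRANSITIONS:
            if t1 not in by_tp or t2 not in by_tp or len(by_tp[t1]) == 0:
                continue
            rec = retention_between(factor, by_tp[t1], by_tp[t2], t1, t2)
            rows.append(
                {
                    "factor": factor.value,
                    "transition": f"{t1.value}->{t2.value}",
                    "n_from": rec.n_from,
                    "n_preserved": rec.n_preserved,
                    "n_new": rec.n_new,
                    "percent_preserved": round(rec.percent_preserved, 2),
                }
            )
    return pd.DataFrame(rows)
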