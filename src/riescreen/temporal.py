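"""Temporal occupancy classification of pooled OSKM binding sites.

Sites bound by the OSKM group across the reprogramming course are partitioned
by successive record-level intersections into:

* early-bound ESC sites (bound in ESCs and already on day 1), subdivided into
  stable (D1+D3+D6+ESC) and the three dynamic subcategories missing D6, D3, or
  both; early sites further split into MEF pre-bound (overlap KM MEF peaks)
  versus de novo;
* late-bound ESC sites (bound in ESCs but not on day 1);
* transient sites (bound at >= 1 intermediate stage, in neither MEFs nor ESCs);
* MEF-lost sites (KM-bound in MEFs, absent in ESCs).

Classification keeps/drops original records by overlap, exactly mirroring
``bedtools intersect -wa -u / -v`` chains; it does not precompute an occupancy
matrix.  The two views coincide when site footprints correspond one-to-one
across stages, which the synthetic generator guarantees and the test suite
audits against an exhaustive occupancy truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import pandas as pd

from .integration import Timepoint
from .intervals import (
    GenomicInterval,
    IntervalSet,
    assert_mutually_disjoint,
    intersect_any,
    merge_within_gap,
    sort_intervals,
    subtract_nonoverlapping,
)

__all__ = [
    "SiteClass",
    "Origin",
    "classify_esc_sites",
    "subclassify_early",
    "split_prebound_denovo",
    "transient_sites",
    "mef_lost_sites",
    "classify_all",
    "audit_partition",
    "ClassifiedSites",
    "AuditReport",
]


class SiteClass(str, Enum):
    EARLY_STABLE = "EARLY_STABLE"          # D1, D3, D6 and ESC
    EARLY_NO_D6 = "EARLY_NO_D6"            # D1, D3, ESC; absent D6
    EARLY_NO_D3 = "EARLY_NO_D3"            # D1, D6, ESC; absent D3
    EARLY_D1_ONLY = "EARLY_D1_ONLY"        # D1 and ESC only
    LATE_ESC = "LATE_ESC"                  # ESC, not D1
    TRANSIENT = "TRANSIENT"                # >=1 intermediate, neither MEF nor ESC
    MEF_LOST = "MEF_LOST"                  # KM in MEFs, absent in ESC


class Origin(str, Enum):
    PREBOUND_MEF = "PREBOUND_MEF"
    DE_NOVO = "DE_NOVO"
    NA = "NA"


EARLY_SUBCLASSES = (
    SiteClass.EARLY_STABLE,
    SiteClass.EARLY_NO_D6,
    SiteClass.EARLY_NO_D3,
    SiteClass.EARLY_D1_ONLY,
)


def classify_esc_sites(
    esc: IntervalSet, d1: IntervalSet
) -> tuple[IntervalSet, IntervalSet]:
    """Split ESC sites into early (overlap day-1 sites) and late (no overlap).

    The two outputs partition the ESC records.
    """
    early = intersect_any(esc, d1).with_metadata(site_class="EARLY")
    late = subtract_nonoverlapping(esc, d1).with_metadata(site_class=SiteClass.LATE_ESC.value)
    return early, late


def subclassify_early(
    early: IntervalSet, d3: IntervalSet, d6: IntervalSet
) -> dict[SiteClass, IntervalSet]:
    """Partition early ESC sites by day-3/day-6 persistence (stable vs dynamic)."""
    with_d3 = intersect_any(early, d3)
    no_d3 = subtract_nonoverlapping(early, d3)
    out = {
        SiteClass.EARLY_STABLE: intersect_any(with_d3, d6),
        SiteClass.EARLY_NO_D6: subtract_nonoverlapping(with_d3, d6),
        SiteClass.EARLY_NO_D3: intersect_any(no_d3, d6),
        SiteClass.EARLY_D1_ONLY: subtract_nonoverlapping(no_d3, d6),
    }
    return {
        cls: s.with_metadata(site_class=cls.value) for cls, s in out.items()
    }


def split_prebound_denovo(
    early: IntervalSet, mef_km: IntervalSet
) -> tuple[IntervalSet, IntervalSet]:
    """Split early sites into MEF pre-bound (overlap KM MEF peaks) and de novo."""
    prebound = intersect_any(early, mef_km).with_metadata(origin=Origin.PREBOUND_MEF.value)
    denovo = subtract_nonoverlapping(early, mef_km).with_metadata(origin=Origin.DE_NOVO.value)
    return prebound, denovo


def _merge_union(*sets: IntervalSet) -> IntervalSet:
    pooled = IntervalSet([iv for s in sets for iv in s])
    return merge_within_gap(sort_intervals(pooled), 0)


def _pair_category(
    a: IntervalSet, b: IntervalSet, remaining: IntervalSet, esc: IntervalSet
) -> IntervalSet:
    # keep the original records of BOTH intersected files, merged (default gap),
    # then strip the remaining intermediate stage and ESC.
    kept = _merge_union(intersect_any(a, b), intersect_any(b, a))
    kept = subtract_nonoverlapping(kept, remaining)
    return subtract_nonoverlapping(kept, esc)


def _transient_categories(
    d1: IntervalSet, d3: IntervalSet, d6: IntervalSet, esc: IntervalSet
) -> list[IntervalSet]:
    """The seven intermediate-occupancy categories, ESC-filtered, MEF-unfiltered.

    Single-stage categories follow the narrative order: remove ESC overlaps
    first, then the other two intermediate stages.  Two-stage categories keep
    and merge the original records of both files, then remove the remaining
    stage and ESC.  The three-stage category intersects stepwise, keeping and
    merging originals at each step, then removes ESC.
    """
    cats: list[IntervalSet] = []
    # single-stage
    for own, others in ((d1, (d3, d6)), (d3, (d1, d6)), (d6, (d1, d3))):
        cur = subtract_nonoverlapping(own, esc)
        for other in others:
            cur = subtract_nonoverlapping(cur, other)
        cats.append(cur)
    # two-stage
    cats.append(_pair_category(d1, d3, d6, esc))
    cats.append(_pair_category(d1, d6, d3, esc))
    cats.append(_pair_category(d3, d6, d1, esc))
    # three-stage: stepwise, keeping originals of all intersected files
    step12 = _merge_union(intersect_any(d1, d3), intersect_any(d3, d1))
    step123 = _merge_union(intersect_any(step12, d6), intersect_any(d6, step12))
    cats.append(subtract_nonoverlapping(step123, esc))
    return cats


def transient_sites(
    d1: IntervalSet,
    d3: IntervalSet,
    d6: IntervalSet,
    esc: IntervalSet,
    mef_km: IntervalSet,
) -> IntervalSet:
    """Sites bound at >= 1 intermediate stage but in neither MEFs nor ESCs."""
    cats = _transient_categories(d1, d3, d6, esc)
    filtered = [subtract_nonoverlapping(c, mef_km) for c in cats]
    return _merge_union(*filtered).with_metadata(site_class=SiteClass.TRANSIENT.value)


def mef_lost_sites(
    mef_km: IntervalSet,
    d1: IntervalSet,
    d3: IntervalSet,
    d6: IntervalSet,
    esc: IntervalSet,
) -> IntervalSet:
    """KM MEF sites absent in ESCs: MEF-only plus MEF sites lost progressively.

    MEF records overlapping ESC sites are excluded up front (the class is
    defined by absence in ESCs); the progressive branch intersects the
    remaining MEF records with the transient union taken *before* its MEF
    filtering step.
    """
    mef_not_esc = subtract_nonoverlapping(mef_km, esc)
    mef_only = mef_not_esc
    for stage in (d1, d3, d6):
        mef_only = subtract_nonoverlapping(mef_only, stage)
    pre_mef_transient = _merge_union(*_transient_categories(d1, d3, d6, esc))
    lost_progressively = intersect_any(mef_not_esc, pre_mef_transient)
    return _merge_union(mef_only, lost_progressively).with_metadata(
        site_class=SiteClass.MEF_LOST.value
    )


@dataclass
class ClassifiedSites:
    """All class outputs of one classification run."""

    early: IntervalSet
    late: IntervalSet
    early_subclasses: dict[SiteClass, IntervalSet]
    prebound: IntervalSet
    denovo: IntervalSet
    transient: IntervalSet
    mef_lost: IntervalSet

    def class_sets(self) -> dict[SiteClass, IntervalSet]:
        """The seven mutually disjoint class sets."""
        out = dict(self.early_subclasses)
        out[SiteClass.LATE_ESC] = self.late
        out[SiteClass.TRANSIENT] = self.transient
        out[SiteClass.MEF_LOST] = self.mef_lost
        return out

    def counts(self) -> pd.DataFrame:
        rows = [
            {"site_class": cls.value, "n_sites": len(s)}
            for cls, s in self.class_sets().items()
        ]
        rows.append({"site_class": "EARLY_PREBOUND_MEF", "n_sites": len(self.prebound)})
        rows.append({"site_class": "EARLY_DE_NOVO", "n_sites": len(self.denovo)})
        return pd.DataFrame(rows)


def classify_all(group_sets: Mapping[Timepoint, IntervalSet]) -> ClassifiedSites:
    """Run the full successive-intersection classification.

    ``group_sets`` maps each stage to the pooled OSKM group set; the D0 entry
    is the KM MEF peak set.
    """
    missing = [tp.value for tp in Timepoint if tp not in group_sets]
    if missing:
        raise ValueError(f"classification needs all five stages; missing {missing}")
    mef = group_sets[Timepoint.D0]
    d1 = group_sets[Timepoint.D1]
    d3 = group_sets[Timepoint.D3]
    d6 = group_sets[Timepoint.D6]
    esc = group_sets[Timepoint.ESC]
    if len(esc) == 0:
        raise ValueError("empty ESC site set; nothing to classify")
    early, late = classify_esc_sites(esc, d1)
    subclasses = subclassify_early(early, d3, d6)
    prebound, denovo = split_prebound_denovo(early, mef)
    transient = transient_sites(d1, d3, d6, esc, mef)
    mef_lost = mef_lost_sites(mef, d1, d3, d6, esc)
    return ClassifiedSites(early, late, subclasses, prebound, denovo, transient, mef_lost)


@dataclass
class AuditReport:
    ok: bool
    counts: pd.DataFrame
    violation: Optional[tuple[str, str, GenomicInterval]] = None


def audit_partition(classified: ClassifiedSites) -> AuditReport:
    """Verify that the seven class sets share no bases; report class counts.

    Raises ``ValueError`` with the witness interval on any overlap, matching
    the hard-failure contract of the published multi-intersection audit.
    """
    class_sets = classified.class_sets()
    labels = [cls.value for cls in class_sets]
    ok, violation = assert_mutually_disjoint(list(class_sets.values()))
    report = AuditReport(ok, classified.counts())
    if not ok:
        i, j, witness = violation
        report.violation = (labels[i], labels[j], witness)
        raise ValueError(
            f"site classes {labels[i]} and {labels[j]} share bases at "
            f"{witness.chrom}:{witness.start}-{witness.end}"
        )
    return report
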