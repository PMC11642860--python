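"""Composite per-factor per-time-point peak universes from multiple datasets.

Public ChIP-seq peak sets for the same factor come from several studies whose
time labels differ (18 h vs day 1, day 5 vs day 6, SSEA1+/Thy1+ sorted
fractions of the same day).  This module canonicalises those labels onto the
five-stage axis D0(MEF) -> D1 -> D3 -> D6 -> ESC, concatenates the per-dataset
BED records and merges them with a 300 bp gap, producing one composite peak
set per factor and time-point, plus the pooled OSKM group set used for the
temporal classification.

Oct4 datasets are systematically larger than the others; for co-binding
statistics the Oct4 peaks at D1/D3/D6 are randomly downsampled to the mean of
the Sox2 and Klf4 peak counts at the same time-point (ESC Oct4 is never
downsampled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet, merge_within_gap, sort_intervals

__all__ = [
    "Factor",
    "Timepoint",
    "SourcePeakFile",
    "canonicalize_timepoint",
    "combine_datasets",
    "merge_factor_group",
    "downsample_peaks",
    "oct4_downsample_target",
    "DEFAULT_MERGE_GAP",
]

DEFAULT_MERGE_GAP = 300  # bp, the "-d 300" dataset-merge convention


class Factor(str, Enum):
    """The reprogramming factors; OSKM_GROUP denotes the pooled O+S+K+M set."""

    OCT4 = "Oct4"
    SOX2 = "Sox2"
    KLF4 = "Klf4"
    MYC = "Myc"
    NANOG = "Nanog"
    OSKM_GROUP = "OSKM"


#: The four factors pooled into the OSKM group.
OSKM_FACTORS: tuple[Factor, ...] = (Factor.OCT4, Factor.SOX2, Factor.KLF4, Factor.MYC)


class Timepoint(str, Enum):
    """Canonical reprogramming stages; D0 is the MEF starting state."""

    D0 = "D0"
    D1 = "D1"
    D3 = "D3"
    D6 = "D6"
    ESC = "ESC"

    @property
    def order(self) -> int:
        return list(Timepoint).index(self)


# Raw labels seen across source datasets -> canonical stage.  18h is folded
# into D1 and day5 into D6; SSEA1+/Thy1+ efficiency-sorted fractions map to
# their nominal day (the bulk population is what is being modelled).
_ALIASES: dict[str, Timepoint] = {
    "d0": Timepoint.D0,
    "day0": Timepoint.D0,
    "mef": Timepoint.D0,
    "mefs": Timepoint.D0,
    "18h": Timepoint.D1,
    "d1": Timepoint.D1,
    "day1": Timepoint.D1,
    "d3": Timepoint.D3,
    "day3": Timepoint.D3,
    "d5": Timepoint.D6,
    "day5": Timepoint.D6,
    "d6": Timepoint.D6,
    "day6": Timepoint.D6,
    "es": Timepoint.ESC,
    "esc": Timepoint.ESC,
    "escs": Timepoint.ESC,
}

_FRACTION_TOKENS = frozenset({"ssea1+", "ssea1", "thy1+", "thy1", "high", "low"})


def canonicalize_timepoint(raw: str) -> Timepoint:
    """Map a raw dataset time label onto the canonical five-stage axis.

    ``"18h" -> D1``, ``"day5" -> D6``, ``"MEF" -> D0``, ``"ES" -> ESC``;
    sorted-fraction suffixes (``SSEA1+``, ``Thy1+``) are ignored, e.g.
    ``"day3_SSEA1+" -> D3``.  Unknown labels raise ``ValueError``.
    """
    key = raw.strip().lower().replace(" ", "_").replace("-", "_")
    tokens = [t for t in key.split("_") if t and t not in _FRACTION_TOKENS]
    key = "".join(tokens)
    if key in _ALIASES:
        return _ALIASES[key]
    accepted = sorted(set(_ALIASES))
    raise ValueError(
        f"unknown time-point label {raw!r}; accepted aliases: {', '.join(accepted)}"
    )


@dataclass
class SourcePeakFile:
    """One published peak file: dataset id, factor, raw time label, intervals."""

    dataset_id: str
    factor: Factor
    raw_timepoint: str
    intervals: IntervalSet

    @property
    def timepoint(self) -> Timepoint:
        return canonicalize_timepoint(self.raw_timepoint)


def combine_datasets(
    files: Sequence[SourcePeakFile],
    factor: Factor,
    tp: Timepoint,
    gap_bp: int = DEFAULT_MERGE_GAP,
) -> IntervalSet:
    """Concatenate, sort and gap-merge all source peak files for one factor/stage.

    All files must match ``factor`` and canonicalise to ``tp``.  The output
    metadata records the contributing dataset ids.  An empty file list yields
    an empty set with a warning.
    """
    if not files:
        warnings.warn(f"no source files for {factor.value}/{tp.value}; empty peak set")
        return IntervalSet(metadata={"factor": factor.value, "timepoint": tp.value, "datasets": []})
    for f in files:
        if f.factor != factor:
            raise ValueError(
                f"dataset {f.dataset_id} is {f.factor.value}, expected {factor.value}"
            )
        if f.timepoint != tp:
            raise ValueError(
                f"dataset {f.dataset_id} label {f.raw_timepoint!r} maps to "
                f"{f.timepoint.value}, expected {tp.value}"
            )
    pooled = IntervalSet([iv for f in files for iv in f.intervals])
    merged = merge_within_gap(sort_intervals(pooled), gap_bp)
    return merged.with_metadata(
        factor=factor.value,
        timepoint=tp.value,
        datasets=sorted({f.dataset_id for f in files}),
        merge_gap_bp=gap_bp,
    )


def merge_factor_group(
    per_factor: Mapping[Factor, IntervalSet],
    tp: Timepoint,
    gap_bp: int = DEFAULT_MERGE_GAP,
) -> IntervalSet:
    """Pool the four O/S/K/M composite sets at one stage into the OSKM group set."""
    for f in per_factor:
        if f not in OSKM_FACTORS:
            raise ValueError(f"merge_factor_group accepts only O/S/K/M inputs, got {f.value}")
    missing = [f.value for f in OSKM_FACTORS if f not in per_factor]
    if missing:
        raise ValueError(f"missing factor sets for OSKM group merge: {', '.join(missing)}")
    pooled = IntervalSet(
        [iv for f in OSKM_FACTORS for iv in per_factor[f]]
    )
    merged = merge_within_gap(sort_intervals(pooled), gap_bp)
    return merged.with_metadata(
        factor=Factor.OSKM_GROUP.value, timepoint=tp.value, merge_gap_bp=gap_bp
    )


def downsample_peaks(s: IntervalSet, target_n: int, seed: int) -> IntervalSet:
    """Uniform sample without replacement of ``target_n`` records, seeded.

    The result is a subset of the input records in input order; deterministic
    for a given seed.
    """
    if target_n < 0 or target_n > len(s):
        raise ValueError(f"target_n={target_n} outside [0, {len(s)}]")
    if target_n == len(s):
        return s
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(s), size=target_n, replace=False))
    md = dict(s.metadata)
    md.update(downsample_seed=seed, downsample_from=len(s))
    return IntervalSet([s[i] for i in keep], s.sorted_flag, md)


def oct4_downsample_target(n_sox2: int, n_klf4: int) -> int:
    """Downsampling target for Oct4: mean of |Sox2| and |Klf4|, rounded half-up."""
    return (n_sox2 + n_klf4 + 1) // 2
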