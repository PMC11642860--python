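"""Synthetic miniature reprogramming studies with planted ground truth.

The generator emulates the input side of the real analysis: several source
ChIP-seq datasets per factor whose peak boundaries jitter around shared true
binding sites, per-stage ATAC peak sets realising a per-class accessibility
schedule, a TSV gene annotation whose planted enhancer genes sit within the
proximal screening window, and negative-binomial count matrices with planted
MEF->ESC fold changes.  Every emitted record traces back to a truth table of
site classes, per-factor occupancy flags and per-gene true fold changes, so
each pipeline stage can be scored for exact recovery.

Sites are placed on a regular grid whose spacing dominates peak width plus
jitter; this guarantees that record-filtering classification and the boolean
occupancy truth table coincide, and that gap-300 dataset merging never
bridges neighbouring sites.

What the generator does *not* emulate: read-level noise, peak-calling
artefacts, copy-number or mappability biases, overlapping/fragmented peak
footprints, and the genome-scale correlation structure of real chromatin.
Exact recovery on this synthetic study validates the bookkeeping of the
pipeline, not its behaviour on messy real peak sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .integration import Factor, OSKM_FACTORS, SourcePeakFile, Timepoint
from .intervals import GenomicInterval, IntervalSet, write_bed
from .temporal import Origin, SiteClass

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "simulate_study",
    "simulate_null_counts",
    "enumerate_occupancy_patterns",
    "clean_config",
    "score_site_classes",
]

#: Stages of the expression time-course (8 stages, matching the RNA design).
EXPRESSION_TIMEPOINTS = ("D0", "D1", "D2", "D3", "D4", "D6", "D8", "ESC")

#: Which stages each class's sites are accessible at (the planted schedule).
OPEN_SCHEDULES: dict[SiteClass, tuple[Timepoint, ...]] = {
    SiteClass.EARLY_STABLE: (Timepoint.D0, Timepoint.D1, Timepoint.D3, Timepoint.D6, Timepoint.ESC),
    SiteClass.EARLY_NO_D6: (Timepoint.D1, Timepoint.D3, Timepoint.ESC),
    SiteClass.EARLY_NO_D3: (Timepoint.D1, Timepoint.D6, Timepoint.ESC),
    SiteClass.EARLY_D1_ONLY: (Timepoint.D1, Timepoint.ESC),
    SiteClass.LATE_ESC: (Timepoint.ESC,),
    SiteClass.TRANSIENT: (Timepoint.D1, Timepoint.D3, Timepoint.D6),
    SiteClass.MEF_LOST: (Timepoint.D0, Timepoint.D1),
}

_DEFAULT_N_SITES: dict[SiteClass, int] = {
    SiteClass.EARLY_STABLE: 160,
    SiteClass.EARLY_NO_D6: 80,
    SiteClass.EARLY_NO_D3: 80,
    SiteClass.EARLY_D1_ONLY: 80,
    SiteClass.LATE_ESC: 200,
    SiteClass.TRANSIENT: 300,
    SiteClass.MEF_LOST: 100,
}

# Raw time labels each synthetic dataset uses, cycling; exercises aliasing.
_RAW_LABELS = (
    {Timepoint.D0: "day0", Timepoint.D1: "day1", Timepoint.D3: "day3", Timepoint.D6: "day6", Timepoint.ESC: "ESC"},
    {Timepoint.D0: "MEF", Timepoint.D1: "18h", Timepoint.D3: "day3", Timepoint.D6: "day5", Timepoint.ESC: "ES"},
    {Timepoint.D0: "day0", Timepoint.D1: "day1_SSEA1+", Timepoint.D3: "day3_Thy1+", Timepoint.D6: "day6", Timepoint.ESC: "ESCs"},
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults model a miniature version of the integrated study: a few
    chromosomes, ~1,000 sites over all temporal classes, 2-3 source datasets
    per factor with <= 50 bp boundary jitter, 300 genes with a handful of
    planted enhancer-adjacent up-regulated genes, and NB counts with
    dispersion 0.1 over 8 stages with 3 replicates.
    """

    seed: int = 0
    n_chroms: int = 3
    n_sites: dict[SiteClass, int] = field(default_factory=lambda: dict(_DEFAULT_N_SITES))
    prebound_fraction: float = 0.4
    n_datasets_per_factor: int = 2
    boundary_jitter_bp: int = 50
    peak_width_range: tuple[int, int] = (200, 600)
    site_width_bp: int = 400
    site_spacing_bp: int = 6_000
    factor_bind_prob: float = 0.7
    atac_peak_width_bp: int = 500
    n_genes: int = 300
    n_planted_ries: int = 5
    n_planted_up: int = 10
    n_planted_down: int = 10
    planted_lfc: float = 3.0
    nb_dispersion: float = 0.1
    count_mean_range: tuple[float, float] = (50.0, 500.0)
    replicates: int = 3

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be non-negative")
        if self.planted_lfc <= 2.0:
            raise ValueError("planted_lfc must exceed 2 (the screen's up-regulation bound)")
        min_clearance = self.site_spacing_bp - self.peak_width_range[1] - 2 * self.boundary_jitter_bp
        if min_clearance <= 300:
            raise ValueError(
                "site spacing too small for peak width + jitter: neighbouring "
                "sites would merge at the 300 bp dataset-merge gap"
            )
        denovo_stable = round(self.n_sites.get(SiteClass.EARLY_STABLE, 0) * (1 - self.prebound_fraction))
        if self.n_planted_ries > denovo_stable:
            raise ValueError("not enough de novo early-stable sites to host the planted RIEs")


def clean_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A zero-noise study: no boundary jitter, Poisson counts, strong effects.

    These are the conditions under which planted-structure recovery is exact
    by construction; the defaults elsewhere retain jitter and NB noise.
    """
    kwargs = dict(
        seed=seed,
        boundary_jitter_bp=0,
        nb_dispersion=0.0,
        count_mean_range=(500.0, 2000.0),
        planted_lfc=4.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-site classes/occupancy and per-gene effects."""

    sites: pd.DataFrame      # site_id, chrom, start, end, site_class, origin, bound_<tp>
    factor_bound: pd.DataFrame  # site_id, factor, timepoint (one row per bound flag)
    genes: pd.DataFrame      # gene_id, chrom, tss, strand, true_lfc, is_rie_gene, rie_site_id
    rie_site_ids: list[str]

    def sites_of_class(self, cls: SiteClass, origin: Optional[Origin] = None) -> pd.DataFrame:
        sub = self.sites[self.sites["site_class"] == cls.value]
        if origin is not None:
            sub = sub[sub["origin"] == origin.value]
        return sub


@dataclass
class SyntheticStudy:
    """In-memory bundle of everything one pipeline run consumes."""

    config: SimulationConfig
    source_files: list[SourcePeakFile]
    atac: dict[Timepoint, IntervalSet]
    features: IntervalSet             # synthetic super-enhancer-like regions
    genes: pd.DataFrame
    counts: pd.DataFrame
    truth: SyntheticTruth

    def factor_files(self, factor: Factor, tp: Timepoint) -> list[SourcePeakFile]:
        return [f for f in self.source_files if f.factor == factor and f.timepoint == tp]

    def write(self, outdir) -> Path:
        """Emit the bundle as the plain-text formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        peaks_dir = outdir / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for f in self.source_files:
            safe_tp = f.raw_timepoint.replace("+", "pos").replace(" ", "")
            name = f"{f.dataset_id}_{f.factor.value}_{safe_tp}.bed"
            write_bed(f.intervals, peaks_dir / name)
            manifest_rows.append(
                f"{f.dataset_id}\t{f.factor.value}\t{f.raw_timepoint}\t{Path('peaks') / name}"
            )
        (outdir / "manifest.tsv").write_text(
            "\n".join(["dataset_id\tfactor\traw_timepoint\tpath"] + manifest_rows) + "\n"
        )
        atac_dir = outdir / "atac"
        atac_dir.mkdir(exist_ok=True)
        for tp, peaks in self.atac.items():
            write_bed(peaks, atac_dir / f"atac_{tp.value}.bed")
        write_bed(self.features, outdir / "features_se.bed")
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["n_sites"] = {k.value: v for k, v in self.config.n_sites.items()}
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str) + "\n")
        return outdir


_GROUP_FLAGS: dict[SiteClass, dict[Timepoint, bool]] = {
    SiteClass.EARLY_STABLE: {Timepoint.D1: True, Timepoint.D3: True, Timepoint.D6: True, Timepoint.ESC: True},
    SiteClass.EARLY_NO_D6: {Timepoint.D1: True, Timepoint.D3: True, Timepoint.D6: False, Timepoint.ESC: True},
    SiteClass.EARLY_NO_D3: {Timepoint.D1: True, Timepoint.D3: False, Timepoint.D6: True, Timepoint.ESC: True},
    SiteClass.EARLY_D1_ONLY: {Timepoint.D1: False, Timepoint.D3: False, Timepoint.D6: False, Timepoint.ESC: True},
}
# note: EARLY_D1_ONLY overrides D1 below; the dict above stores D3/D6/ESC.
_GROUP_FLAGS[SiteClass.EARLY_D1_ONLY][Timepoint.D1] = True

_INTERMEDIATES = (Timepoint.D1, Timepoint.D3, Timepoint.D6)


def _occupancy_for(cls: SiteClass, origin: Origin, rng: np.random.Generator) -> dict[Timepoint, bool]:
    flags = {tp: False for tp in Timepoint}
    if cls in _GROUP_FLAGS:
        flags.update(_GROUP_FLAGS[cls])
        flags[Timepoint.D0] = origin == Origin.PREBOUND_MEF
    elif cls is SiteClass.LATE_ESC:
        flags[Timepoint.ESC] = True
        # late sites arrive at D3 and/or D6 (or only in ESCs); never at D1
        pattern = rng.integers(0, 4)  # 0: ESC only, 1: +D6, 2: +D3, 3: +D3+D6
        flags[Timepoint.D3] = pattern in (2, 3)
        flags[Timepoint.D6] = pattern in (1, 3)
    elif cls is SiteClass.TRANSIENT:
        while True:
            sub = rng.random(3) < 0.5
            if sub.any():
                break
        for tp, on in zip(_INTERMEDIATES, sub):
            flags[tp] = bool(on)
    elif cls is SiteClass.MEF_LOST:
        flags[Timepoint.D0] = True
        sub = rng.random(3) < 0.5  # any intermediate pattern, incl. none
        for tp, on in zip(_INTERMEDIATES, sub):
            flags[tp] = bool(on)
    return flags


def _factors_at(
    tp: Timepoint, rng: np.random.Generator, p: float, force_all: bool
) -> tuple[Factor, ...]:
    if tp is Timepoint.D0:
        pool = (Factor.KLF4, Factor.MYC)   # only KM are present in MEFs
    else:
        pool = OSKM_FACTORS
    if force_all:
        return pool
    while True:
        chosen = tuple(f for f in pool if rng.random() < p)
        if chosen:
            return chosen


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate a full miniature study; deterministic for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    half_w = cfg.site_width_bp // 2

    # ---- site placement on a grid, classes shuffled over slots
    class_list: list[SiteClass] = []
    for cls, n in cfg.n_sites.items():
        class_list.extend([cls] * n)
    n_total = len(class_list)
    if n_total == 0:
        raise ValueError("no sites requested")
    order = rng.permutation(n_total)
    class_list = [class_list[i] for i in order]

    per_chrom = int(np.ceil(n_total / cfg.n_chroms))
    margin = cfg.site_spacing_bp
    site_rows = []
    for i, cls in enumerate(class_list):
        chrom = f"chr{i % cfg.n_chroms + 1}"
        slot = i // cfg.n_chroms
        center = margin + slot * cfg.site_spacing_bp
        if cls in (SiteClass.EARLY_STABLE, SiteClass.EARLY_NO_D6, SiteClass.EARLY_NO_D3, SiteClass.EARLY_D1_ONLY):
            origin = Origin.PREBOUND_MEF if rng.random() < cfg.prebound_fraction else Origin.DE_NOVO
        else:
            origin = Origin.NA
        site_rows.append(
            {
                "site_id": f"site_{i:05d}",
                "chrom": chrom,
                "start": center - half_w,
                "end": center + half_w,
                "site_class": cls.value,
                "origin": origin.value,
            }
        )
    sites = pd.DataFrame(site_rows)

    # ---- planted RIE hosts: de novo early-stable sites, forced dense binding
    stable_denovo = sites[
        (sites["site_class"] == SiteClass.EARLY_STABLE.value)
        & (sites["origin"] == Origin.DE_NOVO.value)
    ]
    if len(stable_denovo) < cfg.n_planted_ries:
        # prebound draw was unlucky; flip enough early-stable sites to de novo
        need = cfg.n_planted_ries - len(stable_denovo)
        flip = sites[
            (sites["site_class"] == SiteClass.EARLY_STABLE.value)
            & (sites["origin"] == Origin.PREBOUND_MEF.value)
        ].index[:need]
        sites.loc[flip, "origin"] = Origin.DE_NOVO.value
        stable_denovo = sites[
            (sites["site_class"] == SiteClass.EARLY_STABLE.value)
            & (sites["origin"] == Origin.DE_NOVO.value)
        ]
    rie_idx = list(stable_denovo.index[: cfg.n_planted_ries])
    rie_site_ids = list(sites.loc[rie_idx, "site_id"])

    # ---- occupancy truth: group flags per stage, then per-factor flags
    occ_rows = []
    factor_rows = []
    for idx, row in sites.iterrows():
        cls = SiteClass(row["site_class"])
        origin = Origin(row["origin"])
        flags = _occupancy_for(cls, origin, rng)
        occ_rows.append({f"bound_{tp.value}": flags[tp] for tp in Timepoint})
        force_all = row["site_id"] in rie_site_ids
        for tp in Timepoint:
            if not flags[tp]:
                continue
            for factor in _factors_at(tp, rng, cfg.factor_bind_prob, force_all):
                factor_rows.append(
                    {"site_id": row["site_id"], "factor": factor.value, "timepoint": tp.value}
                )
    sites = pd.concat([sites, pd.DataFrame(occ_rows, index=sites.index)], axis=1)
    factor_bound = pd.DataFrame(factor_rows)

    # ---- per-dataset jittered peak files
    bound_lookup: dict[tuple[str, str], list[int]] = {}
    for r in factor_rows:
        bound_lookup.setdefault((r["factor"], r["timepoint"]), []).append(
            int(r["site_id"].split("_")[1])
        )
    centers = ((sites["start"] + sites["end"]) // 2).to_numpy()
    chroms = sites["chrom"].to_numpy()

    source_files: list[SourcePeakFile] = []
    for ds in range(cfg.n_datasets_per_factor):
        labels = _RAW_LABELS[ds % len(_RAW_LABELS)]
        dataset_id = f"SYN{ds:03d}"
        for factor in OSKM_FACTORS:
            for tp in Timepoint:
                if tp is Timepoint.D0 and factor in (Factor.OCT4, Factor.SOX2):
                    continue  # OS are not expressed in MEFs
                idxs = bound_lookup.get((factor.value, tp.value), [])
                ivs = []
                for i in sorted(idxs):
                    c = int(centers[i])
                    if cfg.boundary_jitter_bp > 0:
                        c += int(rng.integers(-cfg.boundary_jitter_bp, cfg.boundary_jitter_bp + 1))
                    w = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
                    ivs.append(GenomicInterval(chroms[i], max(0, c - w // 2), c - w // 2 + w))
                source_files.append(
                    SourcePeakFile(
                        dataset_id=dataset_id,
                        factor=factor,
                        raw_timepoint=labels[tp],
                        intervals=IntervalSet(ivs, metadata={"dataset": dataset_id}),
                    )
                )

    # ---- ATAC peaks realising each class's open schedule
    atac: dict[Timepoint, IntervalSet] = {}
    for tp in Timepoint:
        ivs = []
        for idx, row in sites.iterrows():
            cls = SiteClass(row["site_class"])
            if tp not in OPEN_SCHEDULES[cls]:
                continue
            c = int(centers[idx])
            if cfg.boundary_jitter_bp > 0:
                c += int(rng.integers(-cfg.boundary_jitter_bp, cfg.boundary_jitter_bp + 1))
            w = cfg.atac_peak_width_bp
            ivs.append(GenomicInterval(row["chrom"], max(0, c - w // 2), c - w // 2 + w))
        atac[tp] = IntervalSet(sorted(ivs), True, {"timepoint": tp.value})

    # ---- synthetic super-enhancer-like features over some early-stable sites
    stable_idx = sites.index[sites["site_class"] == SiteClass.EARLY_STABLE.value]
    se_idx = stable_idx[: max(1, len(stable_idx) // 4)]
    features = IntervalSet(
        sorted(
            GenomicInterval(chroms[i], max(0, int(centers[i]) - 2_000), int(centers[i]) + 2_000, f"SE_{k}")
            for k, i in enumerate(se_idx)
        ),
        True,
        {"feature": "synthetic_SE"},
    )

    # ---- gene annotation: RIE genes proximal to their sites, rest on chrG
    gene_rows = []
    for k, i in enumerate(rie_idx):
        gene_rows.append(
            {
                "gene_id": f"gene_{k:04d}",
                "chrom": chroms[i],
                "tss": int(centers[i]) + 1_200,
                "strand": "+",
                "true_lfc": cfg.planted_lfc,
                "is_rie_gene": True,
                "rie_site_id": sites.at[i, "site_id"],
            }
        )
    n_rest = cfg.n_genes - len(gene_rows)
    up_left, down_left = cfg.n_planted_up, cfg.n_planted_down
    for k in range(n_rest):
        gid = f"gene_{k + len(gene_rows):04d}"
        if up_left > 0:
            lfc, up_left = cfg.planted_lfc, up_left - 1
        elif down_left > 0:
            lfc, down_left = -cfg.planted_lfc, down_left - 1
        else:
            lfc = 0.0
        gene_rows.append(
            {
                "gene_id": gid,
                "chrom": "chrG",
                "tss": 50_000 + k * 20_000,
                "strand": "+" if k % 2 == 0 else "-",
                "true_lfc": lfc,
                "is_rie_gene": False,
                "rie_site_id": None,
            }
        )
    genes_truth = pd.DataFrame(gene_rows)
    genes = genes_truth[["gene_id", "chrom", "tss", "strand"]].copy()

    # ---- counts: NB around stage means interpolating D0 -> ESC on log2 scale
    counts = _simulate_counts(genes_truth, cfg, rng)

    truth = SyntheticTruth(
        sites=sites, factor_bound=factor_bound, genes=genes_truth, rie_site_ids=rie_site_ids
    )
    return SyntheticStudy(cfg, source_files, atac, features, genes, counts, truth)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _simulate_counts(
    genes_truth: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    tps = EXPRESSION_TIMEPOINTS
    n_genes = len(genes_truth)
    lo, hi = cfg.count_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    lfc = genes_truth["true_lfc"].to_numpy(dtype=float)
    cols = {}
    for j, tp in enumerate(tps):
        frac = j / (len(tps) - 1)  # linear log2 trajectory D0 -> ESC
        mean = base * np.exp2(lfc * frac)
        for rep in range(1, cfg.replicates + 1):
            cols[f"{tp}_{rep}"] = _nb_draw(rng, mean, cfg.nb_dispersion)
    return pd.DataFrame(cols, index=pd.Index(genes_truth["gene_id"], name="gene_id"))


def simulate_null_counts(
    cfg: SimulationConfig, n_genes: Optional[int] = None
) -> pd.DataFrame:
    """Count matrix with identical means in two conditions (A/B), no effects."""
    rng = np.random.default_rng(cfg.seed)
    n = n_genes if n_genes is not None else cfg.n_genes
    lo, hi = cfg.count_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    cols = {}
    for cond in ("A", "B"):
        for rep in range(1, cfg.replicates + 1):
            cols[f"{cond}_{rep}"] = _nb_draw(rng, base, cfg.nb_dispersion)
    idx = pd.Index([f"gene_{i:04d}" for i in range(n)], name="gene_id")
    return pd.DataFrame(cols, index=idx)


def enumerate_occupancy_patterns(
    site_width: int = 400, spacing: int = 6_000
) -> list[tuple[tuple[int, int, int, int, int], dict[Timepoint, IntervalSet]]]:
    """All 31 non-empty (MEF, D1, D3, D6, ESC) occupancy patterns as mini-studies.

    Each pattern gets a single site at its own genomic position; the returned
    stage sets contain that site's footprint wherever the pattern is bound.
    Useful for exhaustive truth-table audits of the temporal classifier.
    """
    patterns = []
    half = site_width // 2
    stage_ivs: dict[Timepoint, list[GenomicInterval]] = {tp: [] for tp in Timepoint}
    singles = []
    k = 0
    for bits in range(1, 32):
        pattern = tuple((bits >> s) & 1 for s in range(5))
        center = spacing * (k + 1)
        iv = GenomicInterval("chrP", center - half, center + half, name=str(pattern))
        for tp, bit in zip(Timepoint, pattern):
            if bit:
                stage_ivs[tp].append(iv)
        singles.append((pattern, iv))
        k += 1
    sets = {tp: IntervalSet(ivs, True) for tp, ivs in stage_ivs.items()}
    for pattern, iv in singles:
        patterns.append((pattern, sets))
    return patterns


def score_site_classes(
    truth: SyntheticTruth, class_sets, site_width_margin: int = 0
) -> pd.DataFrame:
    """Recall/precision of recovered class sets against the planted truth.

    A recovered record is matched to the true site it overlaps (grid spacing
    guarantees at most one).  Per class: recall = matched true sites /
    planted sites; precision = matched records / recovered records.
    """
    from .intervals import count_overlaps  # local to avoid cycle at import time

    truth_sites = truth.sites
    rows = []
    for label, recovered in class_sets.items():
        cls_value = label.value if isinstance(label, SiteClass) else str(label)
        planted = truth_sites[truth_sites["site_class"] == cls_value]
        planted_ivs = IntervalSet(
            [
                GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
                for _, r in planted.iterrows()
            ]
        )
        hits = count_overlaps(planted_ivs, recovered) > 0
        n_matched_records = int((count_overlaps(recovered, planted_ivs) > 0).sum())
        rows.append(
            {
                "site_class": cls_value,
                "n_planted": len(planted),
                "n_recovered": len(recovered),
                "recall": float(hits.mean()) if len(planted) else np.nan,
                "precision": (n_matched_records / len(recovered)) if len(recovered) else np.nan,
            }
        )
    return pd.DataFrame(rows)
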