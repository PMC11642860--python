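"""End-to-end orchestration: integrate -> cobind -> classify -> accessibility
-> genes/DEG -> RIE screen, with a reproducibility manifest.

A run is driven by a single declarative config (YAML/JSON mapping); every
threshold applied comes from that config or a documented module default and
is logged.  All randomness flows from one root seed recorded in the manifest,
and every output file is listed there with its SHA-256 checksum, so two runs
with identical config and inputs produce identical primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .accessibility import annotate_feature_overlap, open_fraction_table, open_venn
from .cobinding import cobinding_matrix, mobility_series, retention_table
from .expression import call_degs, distance_bins, nearest_gene, normalize_counts, read_gene_annotation
from .integration import (
    DEFAULT_MERGE_GAP,
    Factor,
    OSKM_FACTORS,
    SourcePeakFile,
    Timepoint,
    combine_datasets,
    downsample_peaks,
    merge_factor_group,
    oct4_downsample_target,
)
from .intervals import IntervalSet, read_bed, write_bed
from .rie import RIEConfig, run_rie_screen
from .temporal import SiteClass, audit_partition, classify_all

log = logging.getLogger("riescreen")

ALL_STAGES = ("integrate", "cobind", "classify", "accessibility", "genes", "deg", "rie")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_manifest(path, base_dir: Optional[Path] = None) -> list[SourcePeakFile]:
    """Read the source-peak manifest TSV: dataset_id, factor, raw_timepoint, path."""
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    df = pd.read_csv(path, sep="\t")
    required = {"dataset_id", "factor", "raw_timepoint", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(required)}")
    files = []
    for _, row in df.iterrows():
        bed = base / row["path"]
        if not bed.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {bed}")
        files.append(
            SourcePeakFile(
                dataset_id=str(row["dataset_id"]),
                factor=Factor(row["factor"]),
                raw_timepoint=str(row["raw_timepoint"]),
                intervals=read_bed(bed, {"dataset": row["dataset_id"]}),
            )
        )
    return files


class PipelineRun:
    """Holds intermediate artefacts so stages can be run selectively."""

    def __init__(self, config: Mapping, outdir, seed: int = 42):
        self.config = dict(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed)
        self.base_dir = Path(self.config.get("base_dir", "."))
        self.params = dict(self.config.get("params", {}))
        self.inputs = dict(self.config.get("inputs", {}))
        self.counts_by_stage: dict[str, dict] = {}
        self.outputs: list[Path] = []
        # populated by stages
        self.source_files: list[SourcePeakFile] = []
        self.factor_sets: dict[tuple[Factor, Timepoint], IntervalSet] = {}
        self.group_sets: dict[Timepoint, IntervalSet] = {}
        self.classified = None
        self.genes: Optional[pd.DataFrame] = None
        self.degs: Optional[pd.DataFrame] = None

    # -- helpers ------------------------------------------------------------
    def _write_bed(self, s: IntervalSet, name: str) -> Path:
        path = self.outdir / name
        write_bed(s, path)
        self.outputs.append(path)
        return path

    def _write_tsv(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=index)
        self.outputs.append(path)
        return path

    def _input_path(self, key_path: Sequence[str]) -> Optional[Path]:
        node = self.inputs
        for key in key_path:
            if not isinstance(node, dict) or key not in node:
                return None
            node = node[key]
        return self.base_dir / node

    # -- stages -------------------------------------------------------------
    def integrate(self) -> None:
        manifest = self._input_path(["manifest"])
        if manifest is None:
            raise FileNotFoundError("config inputs.manifest is required for integration")
        gap = int(self.params.get("merge_gap_bp", DEFAULT_MERGE_GAP))
        log.info("integrate: merge gap %d bp", gap)
        self.source_files = read_manifest(manifest, self.base_dir / Path(self.inputs["manifest"]).parent)
        for factor in OSKM_FACTORS:
            for tp in Timepoint:
                files = [
                    f for f in self.source_files if f.factor == factor and f.timepoint == tp
                ]
                if not files:
                    continue
                combined = combine_datasets(files, factor, tp, gap)
                self.factor_sets[(factor, tp)] = combined
                self._write_bed(combined, f"peaks_{factor.value}_{tp.value}.bed")
        for tp in Timepoint:
            if tp is Timepoint.D0:
                # MEF stage: pool whatever is bound in MEFs (KM)
                present = {
                    f: self.factor_sets.get((f, tp), IntervalSet()) for f in OSKM_FACTORS
                }
                self.group_sets[tp] = merge_factor_group(present, tp, gap)
            else:
                per_factor = {
                    f: self.factor_sets.get((f, tp), IntervalSet()) for f in OSKM_FACTORS
                }
                self.group_sets[tp] = merge_factor_group(per_factor, tp, gap)
            self._write_bed(self.group_sets[tp], f"peaks_OSKM_{tp.value}.bed")
        self.counts_by_stage["integrate"] = {
            f"{f.value}_{tp.value}": len(s) for (f, tp), s in self.factor_sets.items()
        } | {f"OSKM_{tp.value}": len(s) for tp, s in self.group_sets.items()}

    def cobind(self) -> None:
        self._need("integrate", self.factor_sets)
        downsample = bool(self.params.get("downsample_oct4", True))
        sets_for_stats: dict[Factor, dict[Timepoint, IntervalSet]] = {
            f: {} for f in OSKM_FACTORS
        }
        for (factor, tp), s in self.factor_sets.items():
            sets_for_stats[factor][tp] = s
        if downsample:
            for tp in (Timepoint.D1, Timepoint.D3, Timepoint.D6):
                oct4 = sets_for_stats[Factor.OCT4].get(tp)
                sox2 = sets_for_stats[Factor.SOX2].get(tp)
                klf4 = sets_for_stats[Factor.KLF4].get(tp)
                if oct4 is None or sox2 is None or klf4 is None:
                    continue
                target = oct4_downsample_target(len(sox2), len(klf4))
                if target < len(oct4):
                    log.info("cobind: downsampling Oct4 %s %d -> %d", tp.value, len(oct4), target)
                    sets_for_stats[Factor.OCT4][tp] = downsample_peaks(oct4, target, self.seed)
        matrices = []
        for tp in (Timepoint.D1, Timepoint.D3, Timepoint.D6, Timepoint.ESC):
            per_factor = {f: sets_for_stats[f].get(tp) for f in OSKM_FACTORS}
            if any(s is None for s in per_factor.values()):
                continue
            mat = cobinding_matrix(per_factor, tp)
            mat.insert(0, "timepoint", tp.value)
            matrices.append(mat)
        if matrices:
            self._write_tsv(pd.concat(matrices), "cobinding_matrices.tsv", index=True)
        self._write_tsv(retention_table(sets_for_stats), "retention.tsv")
        mobility = []
        for f in OSKM_FACTORS:
            by_tp = {tp: s for tp, s in sets_for_stats[f].items() if tp is not Timepoint.D0}
            if len(by_tp) >= 2:
                mobility.append(mobility_series(f, by_tp))
        if mobility:
            self._write_tsv(pd.concat(mobility, ignore_index=True), "mobility.tsv")
        self.counts_by_stage["cobind"] = {"n_matrices": len(matrices)}

    def classify(self) -> None:
        self._need("integrate", self.group_sets)
        self.classified = classify_all(self.group_sets)
        report = audit_partition(self.classified)
        for cls, s in self.classified.class_sets().items():
            named = IntervalSet(
                [iv.__class__(iv.chrom, iv.start, iv.end, cls.value) for iv in s],
                s.sorted_flag,
                s.metadata,
            )
            self._write_bed(named, f"class_{cls.value}.bed")
        self._write_bed(self.classified.prebound, "class_EARLY_PREBOUND_MEF.bed")
        self._write_bed(self.classified.denovo, "class_EARLY_DE_NOVO.bed")
        self._write_tsv(report.counts, "class_counts.tsv")
        self.counts_by_stage["classify"] = {
            row["site_class"]: int(row["n_sites"]) for _, row in report.counts.iterrows()
        }

    def accessibility(self) -> None:
        atac_cfg = self.inputs.get("atac")
        if not atac_cfg:
            log.info("accessibility: no ATAC inputs configured; stage skipped")
            self.counts_by_stage["accessibility"] = {"skipped": "no ATAC inputs"}
            return
        self._need("classify", self.classified)
        atac = {
            Timepoint(tp): read_bed(self.base_dir / path)
            for tp, path in atac_cfg.items()
        }
        class_sets = {cls.value: s for cls, s in self.classified.class_sets().items()}
        table = open_fraction_table({k: v for k, v in class_sets.items() if len(v)}, atac)
        self._write_tsv(table, "open_fractions.tsv")
        if Timepoint.D0 in atac and Timepoint.ESC in atac:
            rows = []
            for label, s in class_sets.items():
                if len(s) == 0:
                    continue
                venn = open_venn(s, atac[Timepoint.D0], atac[Timepoint.ESC])
                rows.append(
                    {
                        "site_class": label,
                        "mef_only": venn.mef_only,
                        "shared": venn.shared,
                        "esc_only": venn.esc_only,
                    }
                )
            self._write_tsv(pd.DataFrame(rows), "open_venn.tsv")
        features_path = self._input_path(["features"])
        if features_path is not None:
            features = read_bed(features_path)
            rows = []
            for label, s in class_sets.items():
                if len(s) == 0:
                    continue
                _, summary = annotate_feature_overlap(s, features)
                rows.append({"site_class": label, **summary})
            self._write_tsv(pd.DataFrame(rows), "feature_overlap.tsv")
        self.counts_by_stage["accessibility"] = {"n_atac_stages": len(atac)}

    def genes_stage(self) -> None:
        genes_path = self._input_path(["genes"])
        if genes_path is None:
            log.info("genes: no annotation configured; stage skipped")
            self.counts_by_stage["genes"] = {"skipped": "no gene annotation"}
            return
        self._need("classify", self.classified)
        self.genes = read_gene_annotation(genes_path)
        max_dist = int(self.params.get("nearest_gene_max_bp", 1_000_000))
        esc_sites = IntervalSet(
            list(self.classified.early) + list(self.classified.late)
        )
        assignments = nearest_gene(esc_sites, self.genes, max_dist)
        self._write_tsv(assignments, "gene_assignments.tsv")
        bins = distance_bins(assignments)
        self._write_tsv(bins.rename_axis("distance_bin").reset_index(), "distance_bins.tsv")
        self.counts_by_stage["genes"] = {
            "n_assigned": int(assignments["gene_id"].notna().sum())
        }

    def deg(self) -> None:
        counts_path = self._input_path(["counts"])
        if counts_path is None:
            log.info("deg: no count matrix configured; stage skipped")
            self.counts_by_stage["deg"] = {"skipped": "no count matrix"}
            return
        raw = pd.read_csv(counts_path, sep="\t", index_col=0)
        deg_params = dict(self.params.get("deg", {}))
        group_a = deg_params.get("group_a") or [c for c in raw.columns if c.startswith("D0_")]
        group_b = deg_params.get("group_b") or [c for c in raw.columns if c.startswith("ESC_")]
        lfc = float(deg_params.get("lfc_threshold", 0.58))
        alpha = float(deg_params.get("alpha", 0.05))
        log.info("deg: %s vs %s, |log2FC| > %g, padj < %g", group_a, group_b, lfc, alpha)
        norm, factors = normalize_counts(raw)
        self._write_tsv(norm, "normalized_counts.tsv", index=True)
        self._write_tsv(factors.rename_axis("sample").reset_index(), "size_factors.tsv")
        self.degs = call_degs(raw, group_a, group_b, lfc, alpha)
        self._write_tsv(self.degs.reset_index(), "degs.tsv")
        n_up = int((self.degs["direction"] == "up").sum())
        n_down = int((self.degs["direction"] == "down").sum())
        self.counts_by_stage["deg"] = {"n_up": n_up, "n_down": n_down}

    def rie(self) -> None:
        self._need("classify", self.classified)
        if self.genes is None or self.degs is None:
            raise RuntimeError(
                "RIE stage requires the genes and deg stages (gene annotation and "
                "MEF-vs-ESC differential table)"
            )
        rp = dict(self.params.get("rie", {}))
        config = RIEConfig(
            max_distance_bp=int(rp.get("max_distance_bp", 2_500)),
            lfc_min=float(rp.get("lfc_min", 2.0)),
            padj_alpha=float(rp.get("padj_alpha", 0.05)),
            min_total_peaks=int(rp.get("min_total_peaks", 10)),
            adjacency_gap_bp=int(rp.get("adjacency_gap_bp", 1_000)),
        )
        result = run_rie_screen(
            self.classified.denovo, self.genes, self.degs, self.factor_sets, config
        )
        self._write_tsv(result.table(), "rie_candidates.tsv")
        survivors = IntervalSet(
            [c.site.__class__(c.site.chrom, c.site.start, c.site.end, c.gene_id, float(c.total_peaks)) for c in result.survivors]
        )
        self._write_bed(survivors, "rie_sites.bed")
        self._write_bed(result.rie_regions, "rie_regions.bed")
        (self.outdir / "rie_provenance.txt").write_text(result.provenance() + "\n")
        self.outputs.append(self.outdir / "rie_provenance.txt")
        self.counts_by_stage["rie"] = dict(result.stage_counts)

    def _need(self, stage: str, artefact) -> None:
        if artefact is None or (hasattr(artefact, "__len__") and len(artefact) == 0):
            raise RuntimeError(f"stage requires '{stage}' to have run first")

    # -- driver -------------------------------------------------------------
    def run(self, stages: Sequence[str] = ALL_STAGES) -> dict:
        dispatch = {
            "integrate": self.integrate,
            "cobind": self.cobind,
            "classify": self.classify,
            "accessibility": self.accessibility,
            "genes": self.genes_stage,
            "deg": self.deg,
            "rie": self.rie,
        }
        unknown = [s for s in stages if s not in dispatch]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            log.info("stage: %s", stage)
            try:
                dispatch[stage]()
            except Exception:
                log.error("stage %s failed", stage)
                raise
        manifest = self.write_manifest()
        return manifest

    def write_manifest(self) -> dict:
        manifest = {
            "tool": "riescreen",
            "version": __version__,
            "seed": self.seed,
            "config": _jsonable(self.config),
            "stage_counts": self.counts_by_stage,
            "outputs": {
                str(p.relative_to(self.outdir)): _sha256(p) for p in sorted(set(self.outputs))
            },
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        path = self.outdir / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_full(config: Mapping, outdir, seed: int = 42, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the configured stages in order and write the run manifest."""
    return PipelineRun(config, outdir, seed).run(stages)


def report(manifest_path) -> str:
    """Human-readable markdown summary of a finished run."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    outdir = manifest_path.parent
    lines = [
        "# riescreen run report",
        "",
        f"- tool: {manifest['tool']} {manifest['version']}",
        f"- seed: {manifest['seed']}",
        "",
        "## Stage record counts",
        "",
    ]
    for stage, counts in manifest.get("stage_counts", {}).items():
        lines.append(f"### {stage}")
        for key, val in counts.items():
            lines.append(f"- {key}: {val}")
        lines.append("")
    cand_path = outdir / "rie_candidates.tsv"
    if cand_path.exists():
        table = pd.read_csv(cand_path, sep="\t")
        survivors = table[table["passed"] == True]  # noqa: E712
        lines.append("## Putative RIE survivors")
        lines.append("")
        if survivors.empty:
            lines.append("(none)")
        else:
            for _, row in survivors.iterrows():
                lines.append(
                    f"- {row['chrom']}:{row['start']}-{row['end']} -> {row['gene_id']} "
                    f"({row['total_peaks']} peaks)"
                )
        lines.append("")
    return "\n".join(lines)
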