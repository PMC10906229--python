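"""Pipeline orchestration: read inputs, QC, normalize, detect markers,
filter and classify EV proteins, trace, and write reports.

Group analyses are independent: for each requested group the pipeline
subsets that group's post-QC cells, recomputes markers and the gene
universe on them, applies that group's protein filters and mean areas, and
traces. A ``both`` run is therefore exactly the two single-group runs into
sibling output directories, plus the IRI-vs-sham differential table.

Outputs carry no wall-clock timestamps, so identical inputs and config
produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, sc_preprocess, ev_proteomics, ev_tracing, synthetic_data
from .errors import EvtraceError, PipelineError, ValidationError

log = logging.getLogger("evtrace")

STAGES = ("qc", "markers", "trace")


def setup_logging(level=logging.INFO) -> None:
    """Timestamped, stage-tagged logging to stderr."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and options for one pipeline run."""

    matrix: str
    genes: str
    barcodes: str
    cell_meta: str
    labels: str
    protein_quant: str
    design: str
    output_dir: str
    mapping: str | None = None
    qc: sc_preprocess.QCThresholds = dataclasses.field(
        default_factory=sc_preprocess.QCThresholds
    )
    mito_prefix: str = "mt-"
    markers: sc_preprocess.MarkerParams = dataclasses.field(
        default_factory=sc_preprocess.MarkerParams
    )
    expression_mode: str = "normalized"   # normalized | raw
    protein_scope: str = "all"            # all | markers_only
    group: str = "both"                   # sham | IRI | both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expression_mode not in ("normalized", "raw"):
            raise ValidationError("expression_mode must be 'normalized' or 'raw'")
        if self.protein_scope not in ("all", "markers_only"):
            raise ValidationError("protein_scope must be 'all' or 'markers_only'")
        if self.group not in ("sham", "IRI", "both"):
            raise ValidationError("group must be 'sham', 'IRI' or 'both'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        qc_raw = dict(raw.get("qc", {}))
        mito_prefix = qc_raw.pop("mito_prefix", "mt-")
        tracing = raw.get("tracing", {})
        return cls(
            matrix=inputs["matrix"],
            genes=inputs["genes"],
            barcodes=inputs["barcodes"],
            cell_meta=inputs["cell_meta"],
            labels=inputs["labels"],
            protein_quant=inputs["protein_quant"],
            design=inputs["design"],
            mapping=inputs.get("mapping"),
            output_dir=raw["output_dir"],
            qc=sc_preprocess.QCThresholds(**qc_raw),
            mito_prefix=mito_prefix,
            markers=sc_preprocess.MarkerParams(**raw.get("markers", {})),
            expression_mode=tracing.get("expression_mode", "normalized"),
            protein_scope=tracing.get("protein_scope", "all"),
            group=tracing.get("group", "both"),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "matrix": self.matrix,
                "genes": self.genes,
                "barcodes": self.barcodes,
                "cell_meta": self.cell_meta,
                "labels": self.labels,
                "protein_quant": self.protein_quant,
                "design": self.design,
                "mapping": self.mapping,
            },
            "qc": {**dataclasses.asdict(self.qc), "mito_prefix": self.mito_prefix},
            "markers": dataclasses.asdict(self.markers),
            "tracing": {
                "expression_mode": self.expression_mode,
                "protein_scope": self.protein_scope,
                "group": self.group,
            },
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def analysis_dict(self) -> dict:
        """The per-group analysis parameters (no file paths, no group
        selection), used for the config hash: a ``both`` run's group
        directories hash identically to the corresponding single-group
        runs."""
        d = self.to_dict()
        d.pop("inputs")
        d.pop("output_dir")
        d["tracing"] = {k: v for k, v in d["tracing"].items() if k != "group"}
        return d

    def input_paths(self) -> dict:
        paths = {
            "matrix": self.matrix, "genes": self.genes,
            "barcodes": self.barcodes, "cell_meta": self.cell_meta,
            "labels": self.labels, "protein_quant": self.protein_quant,
            "design": self.design,
        }
        if self.mapping:
            paths["mapping"] = self.mapping
        return paths


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class _EventLog:
    def __init__(self) -> None:
        self.events: list[dict] = []

    def emit(self, stage: str, **fields) -> None:
        event = {"stage": stage, **fields}
        self.events.append(event)
        log.info("[%s] %s", stage, json.dumps(fields, default=str))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event, sort_keys=True, default=str) + "\n")


def run_trace_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Execute the pipeline and write reports under ``config.output_dir``.

    ``stop_after`` truncates the run after ``"qc"`` or ``"markers"`` for the
    stage subcommands. Returns a summary dict (per-stage counts and per-group
    results). Raises :class:`PipelineError` naming the failing stage.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(f"stop_after must be one of {STAGES}")
    events = _EventLog()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for name, path in config.input_paths().items():
        if not Path(path).exists():
            raise PipelineError(f"[io] input {name!r} does not exist: {path}")

    cfg_hash = io_formats.config_hash(config.analysis_dict())
    summary: dict = {"config_hash": cfg_hash, "seed": config.seed}

    # -- io ----------------------------------------------------------------
    try:
        matrix = io_formats.read_count_matrix(
            config.matrix, config.genes, config.barcodes, config.cell_meta
        )
        table = io_formats.read_protein_quant(config.protein_quant, config.design)
        labels_all = io_formats.read_cluster_labels(config.labels, matrix.cell_ids)
        mapping = (
            io_formats.read_protein_gene_mapping(config.mapping)
            if config.mapping else None
        )
    except EvtraceError as exc:
        raise PipelineError(f"[io] {exc}") from exc
    events.emit("io", n_cells=matrix.n_cells, n_genes=matrix.n_genes,
                n_proteins=table.n_proteins)

    # -- qc ------------------------------------------------------------------
    try:
        metrics = sc_preprocess.compute_qc_metrics(matrix, config.mito_prefix)
        qc_matrix, qc_report = sc_preprocess.filter_cells(matrix, metrics, config.qc)
    except EvtraceError as exc:
        raise PipelineError(f"[qc] {exc}") from exc
    labels_qc = labels_all[qc_report.kept_mask]
    events.emit("qc", **qc_report.as_dict())
    summary["qc"] = qc_report.as_dict()
    metrics.reset_index(names="cell_id").to_csv(
        out_dir / "qc_metrics.tsv", sep="\t", index=False
    )
    if stop_after == "qc":
        _finish(events, out_dir, summary, config, cfg_hash)
        return summary

    groups = ["sham", "IRI"] if config.group == "both" else [config.group]
    summary["groups"] = {}
    for group in groups:
        try:
            summary["groups"][group] = _run_group(
                group, config, qc_matrix, labels_qc, table, mapping,
                out_dir / group, events, stop_after,
            )
        except EvtraceError as exc:
            raise PipelineError(f"[{group}] {exc}") from exc

    # -- differential (plumbing for the volcano plot) ------------------------
    if config.group == "both" and stop_after is None:
        n_sham = len(table.replicate_columns("sham"))
        n_iri = len(table.replicate_columns("IRI"))
        if n_sham >= 2 and n_iri >= 2:
            diff = ev_proteomics.differential_abundance(table)
            diff.to_csv(out_dir / "differential.tsv", sep="\t", index=False)
            counts = diff["status"].value_counts().to_dict()
            events.emit("differential", **{str(k): int(v) for k, v in counts.items()})
        else:
            log.warning("differential skipped: fewer than 2 replicates per group")

    _finish(events, out_dir, summary, config, cfg_hash)
    return summary


def _run_group(group, config, qc_matrix, labels_qc, table, mapping,
               group_dir, events, stop_after) -> dict:
    """One group's marker detection, protein filtering and tracing."""
    group_mask = (qc_matrix.cell_meta["group"] == group).to_numpy()
    if not group_mask.any():
        raise ValidationError(f"no post-QC cells in group {group}")
    sub = qc_matrix.subset_cells(group_mask)
    labels = labels_qc[group_mask]
    group_dir.mkdir(parents=True, exist_ok=True)

    normalized = sc_preprocess.normalize_cp10k_log(sub)
    markers = sc_preprocess.find_all_markers(
        normalized, sub.gene_ids, labels, config.markers
    )
    markers.to_csv(group_dir / "markers.tsv", sep="\t", index=False)
    n_marker_rows = int(markers["is_marker"].sum()) if len(markers) else 0
    events.emit("markers", group=group, n_cells=sub.n_cells,
                n_tested=len(markers), n_markers=n_marker_rows)
    if stop_after == "markers":
        return {"n_cells": sub.n_cells, "n_markers": n_marker_rows}

    universe = ev_proteomics.gene_universe_from_matrix(sub)
    filtered, drop_report = ev_proteomics.build_filtered_protein_set(
        table, group, universe, mapping
    )
    drop_report.to_csv(group_dir / "drop_report.tsv", sep="\t", index=False)

    # classification covers the group-detected proteins (pre-transcriptome
    # filter), so the "not detected" class is populated
    detected_ids = ev_proteomics.filter_detected_in_all_replicates(table, group)
    detected_set = set(detected_ids)
    det_mask = np.asarray([p in detected_set for p in table.protein_ids])
    symbols = table.gene_symbols.copy()
    if mapping:
        symbols = np.asarray(
            [mapping.get(p, s) for p, s in zip(table.protein_ids, symbols)],
            dtype=object,
        )
    classification = ev_tracing.classify_ev_proteins(
        table.protein_ids[det_mask], symbols[det_mask], markers, universe
    )
    classification.to_csv(group_dir / "classification.tsv", sep="\t", index=False)

    traced_set = filtered
    if config.protein_scope == "markers_only":
        marker_ids = set(
            classification.loc[
                classification["ev_class"] == ev_tracing.CLASS_CLUSTER_MARKER,
                "protein_id",
            ]
        )
        keep = np.asarray([p in marker_ids for p in filtered.protein_ids])
        traced_set = ev_proteomics.FilteredProteinSet(
            group=group,
            protein_ids=filtered.protein_ids[keep],
            genes=filtered.genes[keep],
            areas=filtered.areas[keep],
        )

    expression = (
        normalized if config.expression_mode == "normalized"
        else sub.counts.astype(float)
    )
    trace_input = ev_tracing.build_trace_input(
        traced_set, expression, sub.gene_ids, labels, cell_ids=sub.cell_ids
    )
    result = ev_tracing.trace(trace_input)

    manifest = {
        "group": group,
        "config_hash": io_formats.config_hash(config.analysis_dict()),
        "seed": config.seed,
        "n_cells_group": sub.n_cells,
        "n_proteins_input": table.n_proteins,
        "n_proteins_detected": int(det_mask.sum()),
        "n_proteins_retained": len(filtered),
        "n_proteins_traced": len(traced_set),
        "n_dropped_detection": int(
            (drop_report["rule"] == ev_proteomics.RULE_DETECTION).sum()
        ),
        "n_dropped_transcriptome": int(
            (drop_report["rule"] == ev_proteomics.RULE_TRANSCRIPTOME).sum()
        ),
        "n_markers": n_marker_rows,
    }
    io_formats.write_trace_report(result, group_dir, manifest)
    events.emit("trace", group=group, n_proteins_used=result.n_proteins_used,
                sev_total=float(result.sev.sum()))
    return {
        "n_cells": sub.n_cells,
        "n_markers": n_marker_rows,
        "n_proteins_detected": int(det_mask.sum()),
        "n_proteins_retained": len(filtered),
        "n_proteins_traced": len(traced_set),
        "tev": result.tev.to_dict(),
        "cell_pct": result.cell_pct.to_dict(),
    }


def _finish(events, out_dir, summary, config, cfg_hash) -> None:
    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        **{f"qc_{k}": v for k, v in summary.get("qc", {}).items()},
    }
    lines = [f"{k}\t{manifest[k]}" for k in sorted(manifest)]
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
    events.write(out_dir / "events.jsonl")


# ---------------------------------------------------------------------------
# Simulation entry points
# ---------------------------------------------------------------------------

def simulate_to_dir(config: synthetic_data.SyntheticConfig, out_dir, seed=None) -> dict:
    """Generate a synthetic dataset and write it in the pipeline's on-disk
    conventions. Returns the written paths plus the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    expr, truth = synthetic_data.generate_expression(config, seed=seed)
    table, mapping = synthetic_data.generate_ev_quant(
        expr, truth, config, seed=seed + 1
    )

    paths = io_formats.write_count_matrix(expr, out_dir)
    io_formats.write_cluster_labels(expr.cell_ids, truth.labels,
                                    out_dir / "labels.tsv")
    io_formats.write_protein_quant(table, out_dir / "protein_quant.tsv",
                                   out_dir / "design.tsv")
    mapping.to_csv(out_dir / "mapping.tsv", sep="\t", index=False)
    truth_json = {
        "true_tev_fractions": truth.true_tev_fractions.to_dict(),
        "realized_tev_fractions": {
            g: s.to_dict() for g, s in (truth.realized_tev_fractions or {}).items()
        },
        "marker_genes": {c: list(v) for c, v in truth.marker_genes.items()},
        "protein_source_cluster": list(truth.protein_source_cluster),
        "seed": seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    paths.update({
        "labels": out_dir / "labels.tsv",
        "protein_quant": out_dir / "protein_quant.tsv",
        "design": out_dir / "design.tsv",
        "mapping": out_dir / "mapping.tsv",
        "truth": out_dir / "truth.json",
    })
    return {"paths": paths, "truth": truth}


def demo_pipeline_config(sim_dir, run_dir, seed: int = 0) -> PipelineConfig:
    """Pipeline config for the bundled synthetic demo.

    QC bounds are scaled to the synthetic library sizes (a few hundred
    detected genes per cell), keeping the same strict boundary semantics.
    """
    sim_dir = Path(sim_dir)
    return PipelineConfig(
        matrix=str(sim_dir / "matrix.mtx"),
        genes=str(sim_dir / "genes.tsv"),
        barcodes=str(sim_dir / "barcodes.tsv"),
        cell_meta=str(sim_dir / "cell_meta.tsv"),
        labels=str(sim_dir / "labels.tsv"),
        protein_quant=str(sim_dir / "protein_quant.tsv"),
        design=str(sim_dir / "design.tsv"),
        mapping=str(sim_dir / "mapping.tsv"),
        output_dir=str(run_dir),
        qc=sc_preprocess.QCThresholds(min_genes=50, max_genes=6000,
                                      max_mito_fraction=0.25),
        group="both",
        seed=seed,
    )


def run_demo(out_dir, seed: int = 0,
             sim_config: synthetic_data.SyntheticConfig | None = None) -> dict:
    """Simulate the default study conditions and run the full pipeline.

    Writes the dataset under ``out_dir/sim``, the pipeline outputs under
    ``out_dir/run`` and the resolved config as ``out_dir/config.yaml``.
    """
    out_dir = Path(out_dir)
    sim_config = sim_config or synthetic_data.SyntheticConfig(seed=seed)
    sim = simulate_to_dir(sim_config, out_dir / "sim", seed=seed)
    config = demo_pipeline_config(out_dir / "sim", out_dir / "run", seed=seed)
    config.to_yaml(out_dir / "config.yaml")
    summary = run_trace_pipeline(config)
    summary["truth"] = sim["truth"]
    summary["config"] = config
    return summary
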