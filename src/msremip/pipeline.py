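"""End-to-end pipeline: configuration, staged execution, fixture generator.

Stages run in order demux/count -> qc -> normalize -> train -> predict; each
stage writes its artifact independently so any stage's output can be
consumed on its own, and a machine-readable manifest records the seed,
thresholds and per-stage tallies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import classify, qc, readproc
from .matrix import CountMatrix
from .panel import Panel
from .simulate import (
    ReadSet,
    SampleSpec,
    SimConfig,
    default_sample_sheet,
    make_panel,
    simulate_reads,
)

ALL_STAGES = ("count", "qc", "normalize", "train", "predict")


def _version() -> str:
    try:
        return _pkg_version("msremip")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Paths, thresholds and switches for a full pipeline run.

    Threshold defaults are the assay's: 5% non-digestion, 5000 counts per
    sample, cvAUC 0.8, 1000 cumulative undigested counts, 5 folds,
    pair quality > 15, 5-bp position margin, 5-nt UMI per side.
    """

    panel_tsv: str
    panel_fasta: str
    r1: str
    r2: str
    i1: str
    i2: str
    sample_sheet: str
    out_dir: str
    seed: int = 0
    digestion_threshold_pct: float = 5.0
    min_counts: int = 5000
    min_cvauc: float = 0.8
    min_cum_undigested: int = 1000
    n_folds: int = 5
    min_quality: int = 15
    margin: int = 5
    umi_len_per_side: int = 5
    scale: str = "normalized"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_sample_sheet(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample sheet TSV -> (sample metadata, barcode table)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta = df[["tissue", "condition", "digested"]].copy()
    meta["digested"] = meta["digested"].astype(bool)
    barcodes = df[["barcode1", "barcode2"]].copy()
    return meta, barcodes


def write_sample_sheet(samples: list[SampleSpec], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.id for s in samples],
            "tissue": [s.tissue for s in samples],
            "condition": [s.condition for s in samples],
            "digested": [s.digested for s in samples],
            "barcode1": [s.barcode1 for s in samples],
            "barcode2": [s.barcode2 for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Any stage failure raises :class:`StageError`; partial outputs stay on
    disk next to a ``FAILED`` marker naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version(),
        "seed": config.seed,
        "thresholds": {
            "digestion_threshold_pct": config.digestion_threshold_pct,
            "min_counts": config.min_counts,
            "min_cvauc": config.min_cvauc,
            "min_cum_undigested": config.min_cum_undigested,
            "n_folds": config.n_folds,
            "min_quality": config.min_quality,
            "margin": config.margin,
        },
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(stage, exc)

    panel = Panel.from_files(config.panel_tsv, config.panel_fasta)
    sample_meta, barcode_table = read_sample_sheet(config.sample_sheet)

    counts: CountMatrix | None = None
    if "count" in config.stages:
        try:
            reads = ReadSet.read(config.r1, config.r2, config.i1, config.i2)
            result = readproc.process_reads(
                reads,
                panel,
                barcode_table,
                sample_meta,
                umi_len_per_side=config.umi_len_per_side,
                min_quality=config.min_quality,
                margin=config.margin,
            )
            counts = result.counts
            counts.to_tsv(out / "counts.tsv", out / "samples_meta.tsv")
            result.tally_frame().to_csv(out / "read_tally.tsv", sep="\t")
            manifest["stages"]["count"] = {
                "read_pairs": result.n_read_pairs,
                "counted_unique": result.n_counted,
                "discards": result.discard_tally,
            }
        except Exception as exc:  # noqa: BLE001 - stage boundary
            fail("count", exc)
    else:
        counts = CountMatrix.from_tsv(
            out / "counts.tsv", out / "samples_meta.tsv", panel.smmip_meta()
        )

    if "qc" in config.stages:
        try:
            counts, report = qc.apply_sample_qc(
                counts,
                threshold_pct=config.digestion_threshold_pct,
                min_counts=config.min_counts,
            )
            counts, dropped = qc.drop_dead_smmips(counts)
            report.dropped_smmips = dropped
            report.to_tsv(out / "qc_report.tsv")
            (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))
            counts.to_tsv(out / "counts_qc.tsv", out / "samples_meta_qc.tsv")
            manifest["stages"]["qc"] = {
                "samples_in": int(report.per_sample.shape[0]),
                "samples_removed": report.removed_samples,
                "smmips_dropped": int((dropped["reason"] == "no counts in any sample").sum())
                if len(dropped)
                else 0,
            }
        except Exception as exc:  # noqa: BLE001
            fail("qc", exc)

    if "normalize" in config.stages:
        try:
            norm = classify.normalize(counts)
            norm.values.T.rename_axis("smmip_id").to_csv(out / "normalized.tsv", sep="\t")
            manifest["stages"]["normalize"] = {"reference_smmips": len(norm.reference_ids)}
        except Exception as exc:  # noqa: BLE001
            fail("normalize", exc)

    model: classify.TrainedModel | None = None
    if "train" in config.stages:
        try:
            tumor = (counts.sample_meta["condition"] == "tumor") & counts.sample_meta[
                "digested"
            ].astype(bool)
            if not tumor.any() or tumor.all():
                raise ValueError("training set is empty or single-class after QC")
            model = classify.train_ensemble(
                counts,
                scale=config.scale,
                n_folds=config.n_folds,
                min_cvauc=config.min_cvauc,
                min_cum_undigested=config.min_cum_undigested,
                seed=config.seed,
            )
            model.to_json(out / "model.json")
            metrics = pd.DataFrame([model.classifier.training_metrics_], index=["training"])
            metrics.rename_axis("split").to_csv(out / "metrics.tsv", sep="\t")
            manifest["stages"]["train"] = {
                "included_smmips": len(model.classifier.included_smmips_),
                "vote_threshold": int(model.classifier.vote_threshold_),
                "training_metrics": model.classifier.training_metrics_,
            }
        except Exception as exc:  # noqa: BLE001
            fail("train", exc)

    if "predict" in config.stages and model is not None:
        try:
            digested = counts.subset(samples=counts.digested_samples)
            preds = model.predict(digested)
            preds.rename_axis("sample_id").to_csv(out / "predictions.tsv", sep="\t")
            manifest["stages"]["predict"] = {
                "samples_scored": int(preds.shape[0]),
                "tumor_calls": int((preds["prediction"] == "tumor").sum()),
            }
        except Exception as exc:  # noqa: BLE001
            fail("predict", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Fixture generator


def make_fixtures(seed: int, out_dir: str | Path) -> RunConfig:
    """Small on-disk dataset exercising the whole pipeline.

    Panel of 40 CpG + 20 reference + 8 lambda smMIPs; 12 samples (4 tumor,
    4 normal, 2 blood, 2 undigested controls) with a deliberately large
    tumor/normal methylation separation so the end-to-end run classifies
    perfectly.  Depth-related thresholds in the emitted config are scaled
    to the fixture's simulated depth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = make_panel(seed)
    samples = default_sample_sheet(
        seed, n_tumor=4, n_normal=4, n_blood=2, n_undigested=2
    )
    config = SimConfig(
        seed=seed,
        samples=samples,
        n_molecules_per_target=200,
        capture_efficiency=0.5,
        non_digestion_rate=0.013,
        pcr_duplication_mean=1.5,
        read_error_rate=0.0,
        methylation_betas={
            "tumor": (20.0, 5.0),
            "normal": (2.0, 18.0),
            "blood": (1.0, 19.0),
        },
    )
    reads, counts, truth = simulate_reads(panel, config)

    panel.to_tsv(out / "panel.tsv")
    panel.to_fasta(out / "panel.fasta")
    panel.to_bed(out / "targets.bed")
    write_sample_sheet(samples, out / "samples.tsv")
    truth.to_tsv(out / "truth.tsv")
    counts.to_tsv(out / "expected_counts.tsv")
    paths = reads.write(out)

    run_config = RunConfig(
        panel_tsv=str(out / "panel.tsv"),
        panel_fasta=str(out / "panel.fasta"),
        r1=str(paths["R1"]),
        r2=str(paths["R2"]),
        i1=str(paths["I1"]),
        i2=str(paths["I2"]),
        sample_sheet=str(out / "samples.tsv"),
        out_dir=str(out / "run"),
        seed=seed,
        min_counts=1000,  # scaled to the fixture's simulated depth
        min_cum_undigested=100,
    )
    run_config.to_yaml(out / "config.yaml")
    return run_config
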