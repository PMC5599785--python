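"""End-to-end orchestration: manifest of recordings -> metric and stats tables.

Per subject and band the pipeline produces epoch-level connectivity
matrices, their epoch average, spanning trees (one per epoch by default)
and an averaged metric record; at study level it produces the group
comparison table over all bands and metrics and, within the smoker group,
the metric-vs-covariate correlation table for one band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, connectivity, io, mst, preprocess, stats
from .preprocess import DEFAULT_BANDS, BandDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "run_pipeline",
    "run_preprocess_stage",
    "run_connectivity_stage",
    "run_mst_stage",
    "run_stats_stage",
]

#: Alpha-band metrics correlated against smoking covariates.
CORRELATION_METRICS = ("eccentricity", "diameter", "leaf_fraction", "kappa")

AGGREGATION_MODES = ("per_epoch_trees", "averaged_matrix_tree")


@dataclass
class PipelineConfig:
    """Tunable settings; every default mirrors the reference protocol."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    epoch_seconds: float = 8.0
    n_epochs_keep: int = 10
    ptp_threshold_uv: float = 100.0
    reference_labels: tuple[str, ...] = ("TP9", "TP10")
    aggregation_mode: str = "per_epoch_trees"
    correlation_band: str = "alpha"
    broadband: BandDefinition | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregation_mode not in AGGREGATION_MODES:
            raise ValueError(
                f"aggregation_mode must be one of {AGGREGATION_MODES}, "
                f"got {self.aggregation_mode!r}"
            )
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if self.n_epochs_keep < 1:
            raise ValueError("n_epochs_keep must be >= 1")


def _format_bands(bands: tuple[BandDefinition, ...]) -> str:
    return ",".join(f"{b.name}:{b.low:g}:{b.high:g}" for b in bands)


def _parse_bands(text: str) -> tuple[BandDefinition, ...]:
    out = []
    for part in text.split(","):
        name, low, high = part.split(":")
        out.append(BandDefinition(name.strip(), float(low), float(high)))
    return tuple(out)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a flat key = value config document."""
    bb = "none" if cfg.broadband is None else (
        f"{cfg.broadband.low:g}:{cfg.broadband.high:g}"
    )
    lines = [
        f"bands = {_format_bands(cfg.bands)}",
        f"epoch_seconds = {cfg.epoch_seconds:g}",
        f"n_epochs_keep = {cfg.n_epochs_keep}",
        f"ptp_threshold_uv = {cfg.ptp_threshold_uv:g}",
        f"reference_labels = {','.join(cfg.reference_labels)}",
        f"aggregation_mode = {cfg.aggregation_mode}",
        f"correlation_band = {cfg.correlation_band}",
        f"broadband = {bb}",
        f"seed = {cfg.seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key = value config; unknown keys are rejected."""
    cfg = PipelineConfig()
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "bands":
            cfg = replace(cfg, bands=_parse_bands(value))
        elif key == "epoch_seconds":
            cfg = replace(cfg, epoch_seconds=float(value))
        elif key == "n_epochs_keep":
            cfg = replace(cfg, n_epochs_keep=int(value))
        elif key == "ptp_threshold_uv":
            cfg = replace(cfg, ptp_threshold_uv=float(value))
        elif key == "reference_labels":
            labels = tuple(s for s in (p.strip() for p in value.split(",")) if s)
            cfg = replace(cfg, reference_labels=labels)
        elif key == "aggregation_mode":
            cfg = replace(cfg, aggregation_mode=value)
        elif key == "correlation_band":
            cfg = replace(cfg, correlation_band=value)
        elif key == "broadband":
            if value.lower() == "none":
                cfg = replace(cfg, broadband=None)
            else:
                low, high = value.split(":")
                cfg = replace(
                    cfg,
                    broadband=BandDefinition(
                        "broadband", float(low), float(high)
                    ),
                )
        elif key == "seed":
            cfg = replace(cfg, seed=int(value))
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return cfg


def _process_subject(
    rec: preprocess.Recording,
    cfg: PipelineConfig,
    subject_dir: Path,
) -> tuple[dict[tuple[str, str], float], dict[str, int]]:
    """One subject through all bands; returns metrics and epoch counts."""
    if cfg.reference_labels:
        rec = preprocess.rereference(rec, list(cfg.reference_labels))
    if cfg.broadband is not None:
        rec = preprocess.bandpass(rec, cfg.broadband)
    metrics: dict[tuple[str, str], float] = {}
    kept: dict[str, int] = {}
    for band in cfg.bands:
        band_dir = subject_dir / band.name
        band_dir.mkdir(parents=True, exist_ok=True)
        filtered = preprocess.bandpass(rec, band)
        es = preprocess.epoch(filtered, cfg.epoch_seconds, band)
        es = preprocess.reject_artifacts(
            es, cfg.ptp_threshold_uv, cfg.n_epochs_keep
        )
        kept[band.name] = es.n_epochs
        mats = []
        for k in range(es.n_epochs):
            pe = connectivity.instantaneous_phase(
                es.epochs[k], es.fs, labels=es.channel_labels
            )
            mat = connectivity.pli_matrix(pe)
            mats.append(mat)
            io.write_connectivity(mat, band_dir / f"pli_epoch{k:02d}.tsv")
        avg = connectivity.average_pli(mats)
        io.write_connectivity(avg, band_dir / "pli_mean.tsv")
        if cfg.aggregation_mode == "per_epoch_trees":
            trees = [mst.build_tree(m) for m in mats]
            for k, t in enumerate(trees):
                io.write_tree(t, band_dir / f"tree_epoch{k:02d}.tsv")
        else:
            trees = [mst.build_tree(avg)]
            io.write_tree(trees[0], band_dir / "tree_mean.tsv")
        record = mst.metric_record(trees, connectivity.mean_pli(avg))
        for name, value in record.as_dict().items():
            metrics[(band.name, name)] = value
    return metrics, kept


def run_pipeline(
    manifest_path: str | Path,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> Path:
    """Run every stage for every manifest subject; returns the output dir.

    Study-level comparison and correlation tables are produced only when
    both groups have at least two subjects; per-subject artifacts are
    written regardless (partial-output contract).
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(manifest_path)
    manifest_dir = Path(manifest_path).parent

    log_lines: list[str] = [
        f"plitree {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"manifest: {manifest_path} ({len(manifest)} subjects)",
        f"seed: {cfg.seed}",
        f"config: bands={_format_bands(cfg.bands)} "
        f"epoch_seconds={cfg.epoch_seconds:g} "
        f"n_epochs_keep={cfg.n_epochs_keep} "
        f"ptp_threshold_uv={cfg.ptp_threshold_uv:g} "
        f"reference_labels={','.join(cfg.reference_labels) or '(none)'} "
        f"aggregation_mode={cfg.aggregation_mode}",
    ]

    subjects: list[stats.SubjectRecord] = []
    metric_rows: list[dict] = []
    n_channels_seen: int | None = None
    for _, row in manifest.iterrows():
        subject = io.manifest_subject(row)
        rec_path = Path(row["path"])
        if not rec_path.is_absolute():
            rec_path = manifest_dir / rec_path
        rec = io.read_recording(rec_path, fs=float(row["fs_hz"]))
        if n_channels_seen is None:
            n_channels_seen = rec.n_channels
        elif rec.n_channels != n_channels_seen:
            raise ValueError(
                f"channel-count mismatch: {rec_path} has {rec.n_channels} "
                f"channels, previous subjects had {n_channels_seen}"
            )
        subject_dir = outdir / "subjects" / subject.subject_id
        metrics, kept = _process_subject(rec, cfg, subject_dir)
        subject.metrics = metrics
        subjects.append(subject)
        kept_str = ", ".join(f"{b}={k}" for b, k in kept.items())
        log_lines.append(
            f"subject {subject.subject_id} ({subject.group}): "
            f"epochs kept {kept_str}"
        )
        for (band_name, metric_name), value in metrics.items():
            metric_rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "band": band_name,
                    "metric": metric_name,
                    "value": value,
                }
            )

    metrics_df = pd.DataFrame(metric_rows)
    io.write_metrics(metrics_df, outdir / "metrics.tsv")

    _write_study_tables(subjects, cfg, outdir, log_lines)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir


def _write_study_tables(
    subjects: list[stats.SubjectRecord],
    cfg: PipelineConfig,
    outdir: Path,
    log_lines: list[str],
) -> None:
    n_smoker = sum(s.group == stats.GROUP_SMOKER for s in subjects)
    n_nonsmoker = sum(s.group == stats.GROUP_NONSMOKER for s in subjects)
    if n_smoker < 2 or n_nonsmoker < 2:
        msg = (
            f"group comparison refused: need >= 2 subjects per group, got "
            f"smoker={n_smoker}, nonsmoker={n_nonsmoker}"
        )
        logger.warning(msg)
        log_lines.append(msg)
        return
    band_names = [b.name for b in cfg.bands]
    rows = stats.comparison_table(subjects, band_names, list(mst.METRIC_NAMES))
    stats.comparison_frame(rows).to_csv(
        outdir / "comparison.tsv", sep="\t", index=False, float_format="%.10g"
    )
    log_lines.append(f"comparison table: {len(rows)} rows")

    smokers = [s for s in subjects if s.group == stats.GROUP_SMOKER]
    with_cov = [s for s in smokers if s.covariates]
    if len(with_cov) >= 3 and cfg.correlation_band in band_names:
        corr_rows = stats.correlation_table(
            with_cov,
            cfg.correlation_band,
            list(CORRELATION_METRICS),
            list(io.COVARIATE_COLUMNS),
        )
        stats.correlation_frame(corr_rows).to_csv(
            outdir / "correlation.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
        log_lines.append(f"correlation table: {len(corr_rows)} rows")
    else:
        log_lines.append(
            "correlation table skipped: need >= 3 smokers with covariates"
        )


# ---------------------------------------------------------------------------
# Stage-wise entry points: each stage reads the previous stage's on-disk
# outputs, enabling partial reruns from any point in the chain.


def run_preprocess_stage(
    manifest_path: str | Path, outdir: str | Path, cfg: PipelineConfig | None = None
) -> Path:
    """Re-reference, filter, epoch and screen; write one file per epoch.

    Produces ``<outdir>/epochs/<subject>/<band>/epoch<k>.tsv`` plus an
    ``index.tsv`` consumed by the connectivity stage.
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    epochs_root = outdir / "epochs"
    manifest = io.read_manifest(manifest_path)
    manifest_dir = Path(manifest_path).parent
    index_rows = []
    for _, row in manifest.iterrows():
        rec_path = Path(row["path"])
        if not rec_path.is_absolute():
            rec_path = manifest_dir / rec_path
        rec = io.read_recording(rec_path, fs=float(row["fs_hz"]))
        if cfg.reference_labels:
            rec = preprocess.rereference(rec, list(cfg.reference_labels))
        if cfg.broadband is not None:
            rec = preprocess.bandpass(rec, cfg.broadband)
        for band in cfg.bands:
            filtered = preprocess.bandpass(rec, band)
            es = preprocess.epoch(filtered, cfg.epoch_seconds, band)
            es = preprocess.reject_artifacts(
                es, cfg.ptp_threshold_uv, cfg.n_epochs_keep
            )
            band_dir = epochs_root / str(row["subject_id"]) / band.name
            band_dir.mkdir(parents=True, exist_ok=True)
            for k in range(es.n_epochs):
                path = band_dir / f"epoch{k:02d}.tsv"
                epoch_rec = preprocess.Recording(
                    es.channel_labels, es.fs, es.epochs[k]
                )
                io.write_recording(epoch_rec, path)
                index_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "group": row["group"],
                        "band": band.name,
                        "epoch": k,
                        "path": str(path.relative_to(epochs_root)),
                        "fs_hz": es.fs,
                    }
                )
    pd.DataFrame(index_rows).to_csv(
        epochs_root / "index.tsv", sep="\t", index=False
    )
    return epochs_root


def run_connectivity_stage(epochs_root: str | Path, outdir: str | Path) -> Path:
    """Per-epoch PLI matrices (plus the epoch mean) from stored epochs."""
    epochs_root = Path(epochs_root)
    pli_root = Path(outdir) / "pli"
    index = pd.read_csv(epochs_root / "index.tsv", sep="\t")
    index_rows = []
    for (sid, group, band), part in index.groupby(
        ["subject_id", "group", "band"], sort=False
    ):
        band_dir = pli_root / str(sid) / str(band)
        band_dir.mkdir(parents=True, exist_ok=True)
        mats = []
        for _, row in part.sort_values("epoch").iterrows():
            rec = io.read_recording(
                epochs_root / row["path"], fs=float(row["fs_hz"])
            )
            pe = connectivity.instantaneous_phase(
                rec.data, rec.fs, labels=rec.channel_labels
            )
            mat = connectivity.pli_matrix(pe)
            mats.append(mat)
            path = band_dir / f"pli_epoch{int(row['epoch']):02d}.tsv"
            io.write_connectivity(mat, path)
            index_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "band": band,
                    "epoch": int(row["epoch"]),
                    "path": str(path.relative_to(pli_root)),
                }
            )
        avg = connectivity.average_pli(mats)
        mean_path = band_dir / "pli_mean.tsv"
        io.write_connectivity(avg, mean_path)
        index_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "band": band,
                "epoch": -1,
                "path": str(mean_path.relative_to(pli_root)),
            }
        )
    pd.DataFrame(index_rows).to_csv(pli_root / "index.tsv", sep="\t", index=False)
    return pli_root


def run_mst_stage(
    pli_root: str | Path,
    outdir: str | Path,
    aggregation_mode: str = "per_epoch_trees",
) -> Path:
    """Spanning trees and the tidy metric table from stored PLI matrices."""
    if aggregation_mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation_mode {aggregation_mode!r}")
    pli_root = Path(pli_root)
    outdir = Path(outdir)
    index = pd.read_csv(pli_root / "index.tsv", sep="\t")
    metric_rows = []
    for (sid, group, band), part in index.groupby(
        ["subject_id", "group", "band"], sort=False
    ):
        band_dir = outdir / "trees" / str(sid) / str(band)
        band_dir.mkdir(parents=True, exist_ok=True)
        epoch_mats = [
            io.read_connectivity(pli_root / row["path"])
            for _, row in part[part["epoch"] >= 0].sort_values("epoch").iterrows()
        ]
        mean_rows = part[part["epoch"] < 0]
        avg = (
            io.read_connectivity(pli_root / mean_rows.iloc[0]["path"])
            if len(mean_rows)
            else connectivity.average_pli(epoch_mats)
        )
        if aggregation_mode == "per_epoch_trees":
            trees = [mst.build_tree(m) for m in epoch_mats]
            for k, t in enumerate(trees):
                io.write_tree(t, band_dir / f"tree_epoch{k:02d}.tsv")
        else:
            trees = [mst.build_tree(avg)]
            io.write_tree(trees[0], band_dir / "tree_mean.tsv")
        record = mst.metric_record(trees, connectivity.mean_pli(avg))
        for name, value in record.as_dict().items():
            metric_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "band": band,
                    "metric": name,
                    "value": value,
                }
            )
    metrics_df = pd.DataFrame(metric_rows)
    io.write_metrics(metrics_df, outdir / "metrics.tsv")
    return outdir / "metrics.tsv"


def run_stats_stage(
    metrics_path: str | Path,
    manifest_path: str | Path,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> Path:
    """Comparison and correlation tables from a tidy metric table."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics_df = io.read_metrics(metrics_path)
    manifest = io.read_manifest(manifest_path)
    subjects = []
    for _, row in manifest.iterrows():
        subject = io.manifest_subject(row)
        part = metrics_df[metrics_df["subject_id"] == row["subject_id"]]
        subject.metrics = {
            (r["band"], r["metric"]): float(r["value"])
            for _, r in part.iterrows()
        }
        subjects.append(subject)
    log_lines: list[str] = []
    _write_study_tables(subjects, cfg, outdir, log_lines)
    (outdir / "stats_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir
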