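"""Plain-text readers and writers for every pipeline artifact.

Recordings are whitespace-separated numeric matrices, one channel per row,
with an optional ``# channels: a,b,c`` header line carrying labels. The
manifest is a tab-separated table (subject_id, group, path, fs_hz, plus
covariate columns). Connectivity matrices, tree edge lists and metric
tables are all tab-separated text so that every artifact survives a
text-only round trip.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .mst import SpanningTree
from .preprocess import Recording
from .stats import SubjectRecord

__all__ = [
    "COVARIATE_COLUMNS",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "read_connectivity",
    "write_connectivity",
    "read_tree",
    "write_tree",
    "read_metrics",
    "write_metrics",
    "read_edf",
]

COVARIATE_COLUMNS = ("ftnd", "cigarettes_per_day", "pack_years", "onset_age")

_FLOAT_FMT = "%.10g"


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as one whitespace-separated row per channel."""
    header = "channels: " + ",".join(rec.channel_labels)
    np.savetxt(path, rec.data, fmt=_FLOAT_FMT, header=header)


def read_recording(
    path: str | os.PathLike, fs: float, channel_labels: list[str] | None = None
) -> Recording:
    """Read a plain-text matrix recording.

    Labels come from the ``# channels:`` header when present, then the
    ``channel_labels`` argument, then generated ``ch00 ...`` names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    header_labels = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "channels:" in first:
        header_labels = [
            s.strip() for s in first.split("channels:", 1)[1].split(",")
        ]
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"cannot parse recording {path}: {exc}") from exc
    labels = header_labels or channel_labels
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(data.shape[0])]
    return Recording(labels, fs, data)


def write_manifest(
    records: list[SubjectRecord],
    paths: list[str],
    fs: float,
    out_path: str | os.PathLike,
) -> None:
    """Write the subject manifest TSV next to a set of recording files."""
    rows = []
    for rec, p in zip(records, paths, strict=True):
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "path": p,
            "fs_hz": fs,
        }
        for cov in COVARIATE_COLUMNS:
            row[cov] = rec.covariates.get(cov, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False, na_rep="NA")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate the subject manifest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"subject_id", "group", "path", "fs_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"manifest {path} missing column(s): {', '.join(sorted(missing))}"
        )
    if df["group"].isna().any():
        bad = df.index[df["group"].isna()].tolist()
        raise ValueError(f"manifest {path}: absent group label at row(s) {bad}")
    return df


def manifest_subject(row: pd.Series) -> SubjectRecord:
    """Build a SubjectRecord (metrics empty) from one manifest row."""
    covariates = {
        c: float(row[c])
        for c in COVARIATE_COLUMNS
        if c in row.index and pd.notna(row[c])
    }
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        covariates=covariates,
    )


def write_connectivity(m: ConnectivityMatrix, path: str | os.PathLike) -> None:
    """Dense TSV with a header row of channel labels."""
    df = pd.DataFrame(m.weights, columns=m.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_connectivity(path: str | os.PathLike) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_tree(t: SpanningTree, path: str | os.PathLike) -> None:
    """Three-column TSV edge list: label_i, label_j, weight."""
    with open(path, "w") as fh:
        fh.write("label_i\tlabel_j\tweight\n")
        for i, j, w in t.edges:
            fh.write(f"{t.labels[i]}\t{t.labels[j]}\t{w:.10g}\n")


def read_tree(path: str | os.PathLike) -> SpanningTree:
    df = pd.read_csv(path, sep="\t")
    labels: list[str] = []
    for col in ("label_i", "label_j"):
        for lab in df[col]:
            if lab not in labels:
                labels.append(lab)
    labels = sorted(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    edges = [
        (index[a], index[b], float(w))
        for a, b, w in df.itertuples(index=False)
    ]
    return SpanningTree(len(labels), edges, labels)


def write_metrics(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Tidy metric table: subject_id, group, band, metric, value."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_metrics(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_edf(path: str | os.PathLike) -> Recording:
    """Read a European Data Format recording (requires ``mne``).

    EDF support is optional; the core pipeline operates on plain-text
    matrices.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires the optional dependency 'mne' "
            "(pip install mne)"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(list(raw.ch_names), float(raw.info["sfreq"]), data)
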