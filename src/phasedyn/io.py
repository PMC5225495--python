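"""Plain-text readers and writers with lossless numeric round-trips.

Formats:

* panel: one TSV per subject (rows = timepoints, columns = ``node_1..N``)
  plus a sidecar JSON with ``tr_seconds``, ``subject_id`` and ``group``;
* phase panel: ``*_phase.tsv`` and ``*_envelope.tsv`` with the sidecar;
* cohort: CSV with columns subject_id, group, age, sex, headcoil, motion;
* edge matrices: CSV with ``subject_id`` index and ``edge_0001..`` columns,
  plus a pair-map CSV (edge, node_i, node_j);
* results: JSON.

Numbers are written with 17 significant digits, which round-trips IEEE
doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import PhasePanel, TimeSeriesPanel, default_node_labels
from .simulate import CohortSpec
from .static_fc import edge_columns, edge_pairs, n_edges

__all__ = [
    "write_panel",
    "read_panel",
    "write_phase_panel",
    "read_phase_panel",
    "write_cohort",
    "read_cohort",
    "write_edge_matrix",
    "read_edge_matrix",
    "write_json",
    "read_json",
]

FLOAT_FMT = "%.17g"


def _write_matrix_tsv(path: Path, values: np.ndarray, labels: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, values.T, fmt=FLOAT_FMT, delimiter="\t")


def _read_matrix_tsv(path: Path, what: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = list(df.columns)
    expected = default_node_labels(len(labels))
    if labels != expected:
        raise ValueError(
            f"{path}: malformed header; expected {expected[:2]}..., got {labels[:2]}..."
        )
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0])
        raise ValueError(f"{path}: NaN cell in {what} at line {row + 2}")
    return df.to_numpy(dtype=float).T, labels


def write_panel(panel: TimeSeriesPanel, directory) -> Path:
    """Write ``<subject_id>.tsv`` + ``<subject_id>.json``; returns the TSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{panel.subject_id}.tsv"
    _write_matrix_tsv(tsv, panel.values, panel.node_labels)
    sidecar = {
        "tr_seconds": panel.tr_seconds,
        "subject_id": panel.subject_id,
        "group": panel.group,
    }
    (directory / f"{panel.subject_id}.json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )
    return tsv


def read_panel(tsv_path) -> TimeSeriesPanel:
    tsv_path = Path(tsv_path)
    values, labels = _read_matrix_tsv(tsv_path, "panel")
    sidecar_path = tsv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar JSON for {tsv_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("tr_seconds", "subject_id"):
        if key not in meta:
            raise ValueError(f"{sidecar_path}: sidecar missing key {key!r}")
    return TimeSeriesPanel(
        values=values,
        tr_seconds=float(meta["tr_seconds"]),
        subject_id=str(meta["subject_id"]),
        group=meta.get("group"),
        node_labels=labels,
    )


def write_phase_panel(pp: PhasePanel, directory) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p_phase = directory / f"{pp.subject_id}_phase.tsv"
    p_env = directory / f"{pp.subject_id}_envelope.tsv"
    _write_matrix_tsv(p_phase, pp.phase, pp.node_labels)
    _write_matrix_tsv(p_env, pp.envelope, pp.node_labels)
    sidecar = {
        "tr_seconds": pp.tr_seconds,
        "subject_id": pp.subject_id,
        "group": pp.group,
        "trim": pp.trim,
    }
    (directory / f"{pp.subject_id}_phase.json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )
    return p_phase, p_env


def read_phase_panel(phase_tsv) -> PhasePanel:
    phase_tsv = Path(phase_tsv)
    phase, labels = _read_matrix_tsv(phase_tsv, "phase")
    env_path = Path(str(phase_tsv).replace("_phase.tsv", "_envelope.tsv"))
    envelope, _ = _read_matrix_tsv(env_path, "envelope")
    meta = json.loads(phase_tsv.with_suffix(".json").read_text())
    return PhasePanel(
        phase=phase,
        envelope=envelope,
        tr_seconds=float(meta["tr_seconds"]),
        trim=int(meta["trim"]),
        subject_id=str(meta["subject_id"]),
        group=meta.get("group"),
        node_labels=labels,
    )


def write_cohort(cohort: CohortSpec, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_cohort(path) -> CohortSpec:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CohortSpec.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing column(s): {missing}")
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0])
        raise ValueError(f"{path}: NaN cell in cohort table at line {row + 2}")
    return CohortSpec(table=df)


def write_edge_matrix(df: pd.DataFrame, path, pair_map_path=None) -> Path:
    """Write a subject x edge CSV, optionally with its pair-map CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True, float_format=FLOAT_FMT)
    if pair_map_path is not None:
        n = _n_nodes_for(df.shape[1])
        pairs = edge_pairs(n)
        pd.DataFrame(
            {
                "edge": edge_columns(n),
                "node_i": pairs[:, 0],
                "node_j": pairs[:, 1],
            }
        ).to_csv(pair_map_path, index=False)
    return path


def read_edge_matrix(path, n_nodes: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    m = df.shape[1]
    if n_nodes is not None and m != n_edges(n_nodes):
        raise ValueError(
            f"{path}: {m} edge columns do not match {n_nodes} nodes "
            f"(expected {n_edges(n_nodes)})"
        )
    n = _n_nodes_for(m)
    if list(df.columns) != edge_columns(n):
        raise ValueError(f"{path}: edge columns are not the canonical edge_0001..")
    return df


def _n_nodes_for(m: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n_edges(n) != m:
        raise ValueError(f"{m} columns is not a valid unique-edge count")
    return n


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
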