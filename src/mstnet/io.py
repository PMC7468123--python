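"""Plain-text serialization of panels, traces, matrices and tables.

Everything is inspectable delimited text: panels are TSV with a node-id
first column and one column per frame; motion traces are single-column text;
connectivity matrices are square TSV with a node-id header row and a JSON
sidecar recording the estimation settings; tabular outputs are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, TimeSeriesPanel
from .cohort import SubjectRecord
from .qc import MotionTrace

FLOAT_FMT = "%.10g"  # 10 significant digits for text-serialized matrices


class FormatError(ValueError):
    """A file does not conform to the documented format."""


def write_panel(panel: TimeSeriesPanel, path: Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for nid, row in zip(panel.node_ids, panel.values):
            fh.write(nid + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_panel(path: Path, sampling_interval: float,
               subject_id: str = "") -> TimeSeriesPanel:
    path = Path(path)
    node_ids: list[str] = []
    rows: list[list[float]] = []
    width = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected node id + values")
            node_ids.append(parts[0])
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                bad = next(
                    i for i, v in enumerate(parts[1:], start=2)
                    if not _is_float(v)
                )
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell in column {bad}"
                ) from exc
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(vals)} values, expected {width}"
                )
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty panel file")
    return TimeSeriesPanel(
        node_ids=node_ids,
        values=np.array(rows),
        sampling_interval=sampling_interval,
        subject_id=subject_id,
    )


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_trace(trace: MotionTrace, path: Path) -> None:
    np.savetxt(path, trace.displacements, fmt=FLOAT_FMT)


def read_trace(path: Path, subject_id: str = "") -> MotionTrace:
    path = Path(path)
    try:
        vals = np.loadtxt(path, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in motion trace") from exc
    return MotionTrace(displacements=vals, subject_id=subject_id)


def write_metadata(subjects: list[SubjectRecord], path: Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id, "group": s.group,
                "age": s.age, "sex": s.sex, "education": s.education,
                "antipsychotic": s.antipsychotic, "lithium": s.lithium,
            }
            for s in subjects
        ]
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_metadata(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "education",
                "antipsychotic", "lithium"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def write_matrix(matrix: ConnectivityMatrix, path: Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(matrix.node_ids) + "\n")
        for row in matrix.weights:
            fh.write("\t".join(FLOAT_FMT % v for v in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(matrix.metadata, indent=2, sort_keys=True))


def read_matrix(path: Path) -> ConnectivityMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    w = np.array(rows)
    if w.shape != (len(header), len(header)):
        raise FormatError(f"{path}: matrix is not square with header size")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ConnectivityMatrix(node_ids=header, weights=w, metadata=meta)
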