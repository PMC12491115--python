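"""Persist a simulated cohort as STL files plus a CSV manifest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_io import read_stl, sidecar_path, write_stl
from .rigid_registration import RigidTransform
from .synthetic_dentition import CohortScan

__all__ = ["save_cohort", "load_cohort"]

MANIFEST = "manifest.csv"


def _transform_row(T: RigidTransform) -> list[float]:
    """Rotation + translation as 12 numbers, row-major [R | t]."""
    return [float(x) for x in np.hstack([T.rotation, T.translation[:, None]]).ravel()]


def _transform_from_row(values) -> RigidTransform:
    M = np.asarray(values, float).reshape(3, 4)
    return RigidTransform(M[:, :3], M[:, 3])


def save_cohort(cohort: list[CohortScan], out_dir, dialect: str = "binary") -> Path:
    """Write every scan as STL (+label sidecar) and a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in cohort:
        stem = f"{scan.participant_id}_{scan.arch}_{scan.capture}.stl"
        path = out / stem
        write_stl(scan.mesh, path, dialect=dialect)
        row = {"participant_id": scan.participant_id, "arch": scan.arch,
               "capture": scan.capture, "stl_path": stem,
               "label_path": sidecar_path(path).name}
        for i, v in enumerate(_transform_row(scan.truth_transform)):
            row[f"t{i:02d}"] = v
        rows.append(row)
    manifest = out / MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(in_dir) -> list[CohortScan]:
    """Read a cohort back from a directory written by :func:`save_cohort`."""
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / MANIFEST)
    scans = []
    tcols = [f"t{i:02d}" for i in range(12)]
    for _, row in df.iterrows():
        mesh = read_stl(in_dir / row["stl_path"])
        scans.append(CohortScan(str(row["participant_id"]), row["arch"],
                                row["capture"], mesh,
                                _transform_from_row(row[tcols].to_numpy())))
    return scans
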