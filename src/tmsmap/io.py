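"""Readers and writers for surfaces, event tables and EMG traces.

Surfaces come in three dialects:

* FreeSurfer binary geometry/curvature/annot files (via :mod:`nibabel`),
* GIFTI surface files (via :mod:`nibabel`),
* a plain-text fixture dialect: a header line ``"N M"``, then N vertex
  lines ``"x y z curv label"``, then M face lines ``"i j k"`` (0-based).
  An optional sidecar with N ``"sx sy sz"`` lines carries the
  unit-sphere registration.

Event tables and per-pulse MEP tables travel as CSV through pandas.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .surface import StimulationEvent, TriSurface

__all__ = [
    "read_surface_txt",
    "write_surface_txt",
    "read_sphere_txt",
    "write_sphere_txt",
    "read_freesurfer_surface",
    "read_gifti_surface",
    "read_labels_csv",
    "events_to_frame",
    "frame_to_events",
    "write_events_csv",
    "read_events_csv",
    "write_emg_csv",
    "read_emg_csv",
]


# -- plain-text mesh dialect ---------------------------------------------


def write_surface_txt(surface: TriSurface, path: str | Path) -> None:
    """Write the plain-text dialect: ``N M`` header, vertex lines, face lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{surface.n_vertices} {surface.n_faces}\n")
        for (x, y, z), c, lab in zip(
            surface.vertices, surface.curvature, surface.atlas_labels
        ):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {c:.9g} {lab}\n")
        for i, j, k in surface.faces:
            fh.write(f"{i} {j} {k}\n")


def read_surface_txt(path: str | Path, sphere_path: str | Path | None = None) -> TriSurface:
    """Read the plain-text dialect written by :func:`write_surface_txt`."""
    path = Path(path)
    with path.open() as fh:
        n, m = (int(tok) for tok in fh.readline().split())
        verts = np.empty((n, 3))
        curv = np.empty(n)
        labels = []
        for i in range(n):
            toks = fh.readline().split(maxsplit=4)
            verts[i] = [float(t) for t in toks[:3]]
            curv[i] = float(toks[3])
            labels.append(toks[4].strip() if len(toks) > 4 else "")
        faces = np.empty((m, 3), dtype=np.int64)
        for j in range(m):
            faces[j] = [int(t) for t in fh.readline().split()]
    sphere = read_sphere_txt(sphere_path) if sphere_path is not None else None
    return TriSurface(verts, faces, curv, np.array(labels), sphere=sphere)


def write_sphere_txt(sphere: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(sphere, dtype=float), fmt="%.12g")


def read_sphere_txt(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float).reshape(-1, 3)


# -- FreeSurfer / GIFTI ---------------------------------------------------


def read_freesurfer_surface(
    geometry_path: str | Path,
    curvature_path: str | Path | None = None,
    annot_path: str | Path | None = None,
    sphere_geometry_path: str | Path | None = None,
) -> TriSurface:
    """Assemble a :class:`TriSurface` from FreeSurfer binary files.

    ``sphere_geometry_path`` (a ``?h.sphere.reg``-convention geometry
    file) is normalised to unit vectors; curvature defaults to zeros and
    labels to ``"unknown"`` when the sidecars are absent.
    """
    import nibabel.freesurfer as nfs

    verts, faces = nfs.read_geometry(str(geometry_path))
    n = len(verts)
    curv = (
        nfs.read_morph_data(str(curvature_path))
        if curvature_path is not None
        else np.zeros(n)
    )
    if annot_path is not None:
        ids, _, names = nfs.read_annot(str(annot_path))
        names = [nm.decode() if isinstance(nm, bytes) else str(nm) for nm in names]
        labels = np.array([names[i] if 0 <= i < len(names) else "unknown" for i in ids])
    else:
        labels = np.full(n, "unknown", dtype=object)
    sphere = None
    if sphere_geometry_path is not None:
        sverts, _ = nfs.read_geometry(str(sphere_geometry_path))
        sphere = sverts / np.linalg.norm(sverts, axis=1, keepdims=True)
    return TriSurface(verts, faces.astype(np.int64), np.asarray(curv, float), labels, sphere)


def read_gifti_surface(
    path: str | Path,
    curvature_path: str | Path | None = None,
    labels: np.ndarray | None = None,
) -> TriSurface:
    """Read a GIFTI surface (pointset + triangle arrays)."""
    import nibabel as nib

    img = nib.load(str(path))
    verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    n = len(verts)
    if curvature_path is not None:
        cimg = nib.load(str(curvature_path))
        curv = np.asarray(cimg.darrays[0].data, dtype=float)
    else:
        curv = np.zeros(n)
    if labels is None:
        labels = np.full(n, "unknown", dtype=object)
    return TriSurface(np.asarray(verts, float), np.asarray(faces, np.int64), curv, labels)


def read_labels_csv(path: str | Path, n_vertices: int) -> np.ndarray:
    """Atlas labels from a 2-column CSV sidecar (vertex_id, label)."""
    df = pd.read_csv(path)
    labels = np.full(n_vertices, "unknown", dtype=object)
    labels[df.iloc[:, 0].to_numpy(dtype=int)] = df.iloc[:, 1].astype(str).to_numpy()
    return labels


# -- stimulation events ---------------------------------------------------

_EVENT_COLUMNS = [
    "subject",
    "event_id",
    "time_s",
    "x_mm",
    "y_mm",
    "z_mm",
    "ox",
    "oy",
    "oz",
    "intensity_condition",
]


def events_to_frame(events: Sequence[StimulationEvent], subject: str) -> pd.DataFrame:
    rows = [
        {
            "subject": subject,
            "event_id": ev.event_id,
            "time_s": ev.time_s,
            "x_mm": ev.coil_position[0],
            "y_mm": ev.coil_position[1],
            "z_mm": ev.coil_position[2],
            "ox": ev.coil_orientation[0],
            "oy": ev.coil_orientation[1],
            "oz": ev.coil_orientation[2],
            "intensity_condition": ev.intensity_condition,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[StimulationEvent]:
    return [
        StimulationEvent(
            event_id=int(r.event_id),
            time_s=float(r.time_s),
            coil_position=np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float),
            coil_orientation=np.array([r.ox, r.oy, r.oz], dtype=float),
            intensity_condition=str(r.intensity_condition),
        )
        for r in df.itertuples(index=False)
    ]


def write_events_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- EMG traces ------------------------------------------------------------


def write_emg_csv(path: str | Path, traces: dict[int, "np.ndarray"], rate_hz: float, t0_s: float) -> None:
    """One columnar file per subject x muscle: event_id, time_s, value_uV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event_id", "time_s", "value_uV"])
        for event_id, samples in traces.items():
            t = t0_s + np.arange(len(samples)) / rate_hz
            for ti, vi in zip(t, samples):
                w.writerow([event_id, f"{ti:.6f}", f"{vi:.6f}"])


def read_emg_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
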