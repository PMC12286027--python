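"""Plain-text exporters: RFC-4180 CSV tables and Wavefront OBJ geometry.

Each writer drops a companion ``<name>.config.json`` next to its output
with the :class:`~neuroactin.config.RunConfig` that produced it.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .config import RunConfig

__all__ = [
    "write_trace_csv",
    "write_contours_csv",
    "write_nodes_csv",
    "write_signal_csv",
    "write_mesh_obj",
    "write_polyline_obj",
]


def _sidecar(path: Path, config: RunConfig | None) -> None:
    if config is not None:
        Path(str(path) + ".config.json").write_text(config.to_json())


def write_trace_csv(trace, path, config: RunConfig | None = None) -> Path:
    """Membrane-potential trace: path_s, MB_mV, m, variant, masked."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path_s", "MB_mV", "m", "variant", "masked"])
        for s, mb, msk in zip(trace.s, trace.mb_mV, trace.mask):
            w.writerow(
                [f"{s:.10g}", "" if msk else f"{mb:.10g}", f"{trace.m:.10g}",
                 trace.variant, int(bool(msk))]
            )
    _sidecar(path, config)
    return path


def write_contours_csv(contours, path, config: RunConfig | None = None) -> Path:
    """Contour point sets: contour id, x, y columns."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["contour", "x", "y"])
        for ci, pts in enumerate(contours):
            for px, py in np.asarray(pts):
                w.writerow([ci, f"{px:.10g}", f"{py:.10g}"])
    _sidecar(path, config)
    return path


def write_nodes_csv(layout, path, config: RunConfig | None = None) -> Path:
    """Network node table: id, x, y, z (um)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "z"])
        for i, (px, py, pz) in enumerate(np.asarray(layout.positions), start=1):
            w.writerow([i, f"{px:.10g}", f"{py:.10g}", f"{pz:.10g}"])
    _sidecar(path, config)
    return path


def write_signal_csv(sig, path, config: RunConfig | None = None) -> Path:
    """Cilia signal field: x, y, z, Re/Im of L and U."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "re_L", "im_L", "re_U", "im_U"])
        flat = zip(
            sig.x.ravel(), sig.y.ravel(), sig.z.ravel(),
            sig.L.ravel(), sig.U.ravel(), sig.mask.ravel(),
        )
        for px, py, pz, L, U, msk in flat:
            if msk:
                continue
            w.writerow(
                [f"{px:.10g}", f"{py:.10g}", f"{pz:.10g}",
                 f"{L.real:.10g}", f"{L.imag:.10g}",
                 f"{U.real:.10g}", f"{U.imag:.10g}"]
            )
    _sidecar(path, config)
    return path


def write_mesh_obj(vertices, faces, path, config: RunConfig | None = None) -> Path:
    """Triangle mesh as Wavefront OBJ (1-based face indices)."""
    path = Path(path)
    with path.open("w") as fh:
        for v in np.asarray(vertices):
            fh.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for f in np.asarray(faces):
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    _sidecar(path, config)
    return path


def write_polyline_obj(points, path, config: RunConfig | None = None) -> Path:
    """Open polyline as Wavefront OBJ line elements."""
    path = Path(path)
    pts = np.asarray(points)
    with path.open("w") as fh:
        for v in pts:
            fh.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        idx = " ".join(str(i + 1) for i in range(len(pts)))
        fh.write(f"l {idx}\n")
    _sidecar(path, config)
    return path
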