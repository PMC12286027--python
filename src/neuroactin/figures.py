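"""Figure regeneration: one panel per model capability.

Each panel is produced by the same library calls the CLI uses; rendering
is deterministic (no randomness, fixed colormaps), so reruns yield
identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import sympy as sp

from . import cilia, electrophysiology as ep, morphology, organoid
from .fields import COORDS, GridSpec, evaluate_on_grid

__all__ = ["regenerate_figures", "FIGURE_BUILDERS"]


def _save(fig, path: Path) -> Path:
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def figure_ramification(outdir: Path) -> list:
    """Four branching-field contour panels (f1-f4), one image each."""
    out = []
    for which in ("f1", "f2", "f3", "f4"):
        rf = morphology.ramification_field(which, c=1.0)
        grid = GridSpec(((-4.0, 4.0, 201), (-4.0, 4.0, 201)))
        sg = evaluate_on_grid(rf.as_scalar_field(), grid)
        vals = np.real(sg.values).astype(float)
        fig, ax = plt.subplots(figsize=(4, 4))
        xs, ys = grid.points()
        with np.errstate(all="ignore"):
            ax.contour(xs, ys, np.clip(vals.T, -50, 50), levels=15, cmap="viridis")
        ax.set_title(f"branching field {which}")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        out.append(_save(fig, outdir / f"ramification_{which}.png"))
    return out


def figure_soma_branches(outdir: Path) -> list:
    """Soma circle (A0) and branch curves (A1-A3) at z = 1."""
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.6))
    mats = [morphology.matrix_A0(), morphology.matrix_A1(),
            morphology.matrix_A2(), morphology.matrix_A3()]
    for ax, A in zip(axes, mats):
        C = morphology.characteristic_poly(A)
        for pts in morphology.branch_locus(C):
            ax.plot(pts[:, 0], pts[:, 1], lw=1.0,
                    color="crimson" if A.label == "A0" else "steelblue")
        ax.set_title(f"{A.label}: det(zI-A)=0, z=1")
        ax.set_aspect("equal")
    fig.tight_layout()
    return [_save(fig, outdir / "soma_branches.png")]


def figure_actin_rings(outdir: Path) -> list:
    """Ring-field density |H| on an (x, z) slice showing the ring stack."""
    ring = morphology.actin_ring_field()
    expr = ring.H.subs({COORDS[1]: 0})  # H(x, 0, z) on the (x, z) plane
    zsym = COORDS[2]
    xs = np.linspace(-3, 3, 161)
    zs = np.linspace(0.05, 3.0, 161)
    fn = sp.lambdify((COORDS[0], zsym), expr, "numpy")
    Xg, Zg = np.meshgrid(xs, zs, indexing="ij")
    with np.errstate(all="ignore"):
        vals = np.asarray(fn(Xg, Zg), dtype=complex)
    mag = np.abs(np.real(vals))
    mag[~np.isfinite(mag)] = np.nan
    fig, ax = plt.subplots(figsize=(5, 4))
    pc = ax.pcolormesh(xs, zs, np.clip(mag.T, 0, 30), cmap="magma", shading="auto")
    fig.colorbar(pc, ax=ax, label="|H| (ring density)")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("z (um)")
    ax.set_title("actin ring field, y = 0 slice")
    return [_save(fig, outdir / "actin_rings.png")]


def figure_vdp_2d(outdir: Path) -> list:
    """Streamlines of the planar van der Pol and actin fields."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.8))
    xs = ys = np.linspace(-2, 2, 41)
    Xg, Yg = np.meshgrid(xs, ys, indexing="xy")
    fields = [
        ("van der Pol (m=1)", ep.vdp_field_2d(ep.VdpParams(1.0))),
        ("concentric actin", ep.actin_field_2d()),
    ]
    from .fields import lie_bracket

    fields.append(("Lie bracket [actin, vdp]",
                   lie_bracket(ep.actin_field_2d(),
                               ep.vdp_field_2d(ep.VdpParams(1.0)))))
    for ax, (title, f) in zip(axes, fields):
        comps = f.lift().bound_components()
        fu = sp.lambdify(COORDS, comps[0], "numpy")
        fv = sp.lambdify(COORDS, comps[1], "numpy")
        with np.errstate(all="ignore"):
            U = np.asarray(fu(Xg, Yg, np.ones_like(Xg)), dtype=complex).real
            V = np.asarray(fv(Xg, Yg, np.ones_like(Xg)), dtype=complex).real
        U = np.where(np.isfinite(U), U, 0.0)
        V = np.where(np.isfinite(V), V, 0.0)
        ax.streamplot(xs, ys, U, V, density=1.0, color="orangered", linewidth=0.8)
        ax.set_title(title)
        ax.set_aspect("equal")
    fig.tight_layout()
    return [_save(fig, outdir / "vdp_actin_2d.png")]


def figure_membrane_potential(outdir: Path) -> list:
    """m-swept traces for the gradient and vector-Laplacian variants."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for ax, variant in zip(axes, ("gradient", "vector_laplacian")):
        for trace in ep.sweep_membrane_potential(
            m_values=np.linspace(0.1, 4.0, 8), variant=variant
        ):
            mb = np.where(trace.mask, np.nan, trace.mb_mV)
            ax.plot(trace.s, mb, lw=0.8, label=f"m={trace.m:.1f}")
        ax.set_title(f"membrane potential, {variant}")
        ax.set_xlabel("path parameter s")
        ax.set_ylabel("MB (mV)")
    axes[0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    return [_save(fig, outdir / "membrane_potential.png")]


def figure_cilia(outdir: Path) -> list:
    """Magnitude surfaces of the Shh signal pair at z = -2.5."""
    sig = cilia.shh_field(nz=3)
    k = 1  # middle z slice
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (name, arr) in zip(axes, (("U = P(x+iy, z)", sig.U), ("L = Q(x+iy, z)", sig.L))):
        mag = np.abs(arr[:, :, k])
        mag[sig.mask[:, :, k]] = np.nan
        pc = ax.pcolormesh(sig.x[:, 0, k], sig.y[0, :, k], np.log10(mag).T,
                           cmap="viridis", shading="auto")
        fig.colorbar(pc, ax=ax, label="log10 |signal|")
        ax.set_title(f"{name}, z={sig.z[0, 0, k]:.2f}")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
    fig.tight_layout()
    return [_save(fig, outdir / "cilia_signal.png")]


def figure_network(outdir: Path) -> list:
    """N = 4 and N = 7 networks with their potential traces."""
    fig = plt.figure(figsize=(11, 7))
    for col, N in enumerate((4, 7)):
        layout = organoid.place_nodes(organoid.GuidanceParams(N=N))
        trace = organoid.network_potential(layout)
        ax3 = fig.add_subplot(2, 2, col + 1, projection="3d")
        pos = layout.positions
        ax3.plot(pos[:, 0], pos[:, 1], pos[:, 2], "o-", color="firebrick")
        ax3.set_title(f"network layout, N={N}")
        ax2 = fig.add_subplot(2, 2, col + 3)
        mb = np.where(trace.mask, np.nan, trace.mb_mV)
        ax2.plot(trace.s, mb, color="navy", lw=0.9)
        ax2.set_xlabel("path length (um)")
        ax2.set_ylabel("MB (mV)")
        ax2.set_title(f"network potential, N={N}")
    fig.tight_layout()
    return [_save(fig, outdir / "organoid_network.png")]


FIGURE_BUILDERS = {
    "ramification": figure_ramification,
    "soma_branches": figure_soma_branches,
    "actin_rings": figure_actin_rings,
    "vdp_2d": figure_vdp_2d,
    "membrane_potential": figure_membrane_potential,
    "cilia": figure_cilia,
    "network": figure_network,
}


def regenerate_figures(outdir, which=None) -> list:
    """Regenerate the requested figure panels (all by default).

    ``which`` is an iterable of builder names from
    :data:`FIGURE_BUILDERS`; an empty list produces no files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(FIGURE_BUILDERS) if which is None else list(which)
    files = []
    for name in names:
        if name not in FIGURE_BUILDERS:
            raise KeyError(f"unknown figure {name!r}; choose from {sorted(FIGURE_BUILDERS)}")
        files.extend(FIGURE_BUILDERS[name](outdir))
    return files
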