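# neuroactin

A deterministic, symbolic-geometric simulator of neuronal morphology and
electrical activity built around the actin cytoskeleton. It is aimed at
computational neuroscientists and mathematical biologists who want a
fully closed-form, reproducible counterpart to biophysical neuron
simulators: every construction is an exact sympy expression in the
spatial coordinates `x, y, z` (µm), sampled numerically only at the end
with explicit singularity masking, and nothing anywhere is random.

The package models four connected pieces:

* **Morphology** — the soma boundary and neurite branches as zero sets
  of characteristic polynomials `det(zI − A)` of symbolic 2×2 complex
  matrices; ramification (branching) fields; and the periodic actin
  rings along axons as level sets of `h = (x²+y²)/sin(kz) − 4`, with the
  physical wavenumber `k = 2π/λ = 33.1 rad/µm` from the ~190 nm ring
  periodicity.
* **Electrophysiology** — a van der Pol excitability field
  `g = (y/(rz), −(xz + m·y·(x²z²−1)·z)/r, 0)` coupled to a concentric
  actin field `f = (y²/(rz²), x²/(rz²), 0)` through the iterated Lie
  bracket `ad_f^(t) g`. The bracket result `Z` yields a scalar potential
  `V = Z₁ + Z₂`, an electric field `EF = −∇V` (or, comparatively, the
  vector Laplacian of `Z`), and a membrane potential in millivolts via
  the Nernst decade prefactor: `MB = 61.5·ln(EFT·m)` where `EFT = ‖EF‖`.
* **Ciliary signaling** — Sonic Hedgehog reception at the primary cilium
  as the regularized incomplete gamma pair at complex argument,
  `U = P(x+iy, z)`, `L = Q(x+iy, z) = 1 − U`, evaluated by a Kummer
  series valid for all complex arguments.
* **Organoid growth** — an N-neuron network placed deterministically by
  Vandermonde-inverse Lagrange interpolation of guidance fields
  (an elliptic-curve-style polynomial plus an actin/oscillator
  interaction scalar), with the membrane-potential pipeline traced along
  the node path.

See `docs/methods.md` for the model's assumptions, parse decisions,
numerical choices and limitations.

## Worked example

```python
from neuroactin import (
    actin_wavenumber, nernst, membrane_potential_pipeline,
    sweep_membrane_potential,
)
from neuroactin.electrophysiology import VdpParams

print(actin_wavenumber(190.0))   # 33.1   rad/um from the 190 nm ring spacing
print(round(nernst(10.0), 1))    # 61.5   mV per tenfold concentration ratio

single = membrane_potential_pipeline(p=VdpParams(1.0))
print(f"[{single.min_mV:.1f}, {single.max_mV:.1f}]")   # [-21.1, 67.7]
```

The last line is the membrane-potential span in mV along the default
diagonal path `(s, s, 1)`, `s ∈ [0.1, 2]`, at damping `m = 1`: the
potential rises where the coupled fields interact strongly (large
`‖∇V‖`) and falls toward the mask near vanishing interaction. Sweeping
the damping parameter and comparing pipeline variants:

```python
for variant in ("gradient", "vector_laplacian"):
    traces = sweep_membrane_potential(variant=variant)
    print(variant, min(t.min_mV for t in traces), max(t.max_mV for t in traces))
# gradient         -211.12  219.65
# vector_laplacian  -81.87  258.28
```

The two variants never agree — the model's argument for preferring the
gradient route — and the band is controlled by where the evaluation path
runs relative to the fields' interaction structure (see the sensitivity
note in `docs/methods.md`).

The `examples/` directory has one short narrative script per
capability (`lie_bracket_basics.py`, `membrane_potential.py`,
`soma_and_branches.py`, `actin_rings.py`, `cilia_signaling.py`,
`organoid_network.py`); each builds a small input, runs the method and
prints what the numbers mean.

## Command line

A thin CLI wraps the same library calls:

```sh
neuroactin units                     # the model's unit ledger
neuroactin actin-rings               # ring field + wavenumber
neuroactin membrane-potential --variant vector_laplacian
neuroactin organoid --neurons 7      # network nodes, OBJ polyline, trace CSV
neuroactin figures                   # regenerate all figure panels
```

Every output CSV/OBJ gets a `.config.json` sidecar with the exact run
configuration that produced it.

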