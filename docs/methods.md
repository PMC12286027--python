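# Methods

`neuroactin` is a deterministic, closed-form model of neuronal shape and
electrical activity. Everything is a symbolic expression in the spatial
coordinates `x, y, z` (µm) until the last moment, when expressions are
sampled on grids or paths with explicit singularity masking. There is no
randomness anywhere in the model: identical inputs give bitwise-identical
outputs.

## Symbolic field calculus (`neuroactin.fields`)

Vector and scalar fields carry sympy expressions plus a name→value map of
parameters; every free symbol must be a coordinate or a declared
parameter. Planar (2-component) fields are lifted to three components
with an identically zero third component before any 3D operator touches
them, which makes the 3D gradient, curl and vector Laplacian well defined
for fields that are given only in the plane.

* **Lie bracket.** `[f, g] = Jg·f − Jf·g` with `J` the Jacobian; the
  iterate `ad_f^(k) g = [f, ad_f^(k−1) g]`. After each bracket the
  components pass through `together` + `cancel` — canonical rational
  simplification that bounds expression growth without the cost and
  instability of full `simplify`. Depth is capped at 4 by default; the
  model never uses deeper iterates.
* **Complex arithmetic end to end.** Several constructions contain the
  imaginary unit (the soma matrices, the ciliary fields, the principal
  logarithms); real quantities are produced by explicit real-part
  extraction at documented call sites only, never implicitly.
* **Singularity masking.** The model's fields are singular at `r = 0`,
  `z = 0` and on `sin(kz) = 0`. Grid evaluation collects every
  denominator of the expression and masks lattice points where any
  denominator magnitude falls below `1e-9` (and any residual non-finite
  sample). Masked points are excluded, never clipped or NaN-propagated.

## Morphology (`neuroactin.morphology`)

The soma boundary and branch curves are zero sets of characteristic
polynomials `det(zI − A)` of symbolic 2×2 complex matrices, viewed at
`z = 1`. The soma matrix `A0 = [[x+iy, 1], [1, x−iy]]` gives
`C0 = z² − 2xz + x² + y² − 1`, whose `z = 1` slice is the unit circle
centered at `(1, 0)`. The branch matrices carry diagonals of the form
`d ± 1/(i y²)`; the two-separate-reciprocals reading of those diagonals
is isolated in one constructor (`_reciprocal_pair`) so the alternative
parse — one combined reciprocal — can be flipped in a single place.
Contours are extracted from the real part of the complex field with
scikit-image's marching squares; the implicit soma surface
`(x²+y²)² + z² − 1` is triangulated by marching cubes and exported as
OBJ.

The actin-ring field is `h = (x² + y²)/sin(kz) − 4`: the product of the
two complex boundary points `(x+iy)(x−iy) = x² + y²` divided by the
sinusoidal ring modulation. Its cross-sections at fixed `z` are circles
of radius `2·√sin(kz)` where `sin(kz) > 0` — the periodic membrane
skeleton. The display wavenumber defaults to 4 (rings visually separated
on unit-scale plots); the physical value `k = 2π/λ` with `λ = 190 nm`
(measured axonal ring periodicity) is `33.1 rad/µm` and can be passed
instead. The z-antiderivative `H` is recomputed symbolically rather than
transcribed, and validated by differentiating back to `h` (the printed
closed forms of such antiderivatives are typography-fragile; the
recomputation is exact by construction).

## Membrane potential (`neuroactin.electrophysiology`)

Two static 3D fields are coupled:

* actin geometry `f = (y²/(rz²), x²/(rz²), 0)`,
* van der Pol excitability `g = (y/(rz), −(xz + m·y·(x²z² − 1)·z)/r, 0)`,

with `r = √(x²+y²+z²)` and `m` the dimensionless damping, swept over
`[0.1, 4]` as 40 uniform values. The printed sources of these components
admit more than one typographic reading; the adopted parse keeps the
`z`-factors in the denominators and the alternative (`z`-factors as
products) is available behind the `parse="product"` strategy flag rather
than silently.

The pipeline is then

```
Z   = ad_f^(t) g                      (iterated Lie bracket, default t = 1)
V   = Z₁ + Z₂                         (sum of the first two components)
EF  = −∇V                             (gradient variant)
      ∇(∇·Z) − ∇×(∇×Z)                (vector-Laplacian variant)
EFT = ‖EF‖
Dirac = log(e^(−EFT·m)) = −EFT·m      (exact identity)
MB  = 61.5 · Re(Log(Dirac)) = 61.5·ln(EFT·m)   [mV]
```

**Branch choice.** `Dirac` is non-positive, so its logarithm is complex;
the principal complex log with the real part extracted is the only
reading that yields a real mV-scale trace, and it is isolated in one
function (`_mb_from_eft`). Points with `EFT·m ≤ 0` (log of zero) are
masked. A consequence worth knowing: because `EFT` itself depends on `m`
through `g`, rescaling the full pipeline in `m` does *not* shift the
trace by `61.5·ln m`; that exact shift appears only when the fields are
frozen and the Dirac multiplier alone varies, which the pipeline exposes
as the separate `dirac_m` argument (it defaults to the field's `m`).

**Defaults.** Iteration depth `t = 1`; evaluation path the diagonal line
`(s, s, 1)`, `s ∈ [0.1, 2]`, 400 samples (clear of the `z = 0` and
`r = 0` loci); export grid `x, y ∈ [−2, 2]`, `z ∈ [0.5, 2]`, 41 points
per axis. Every trace records its grid, path, depth and parse strategy
in its metadata and in the CSV sidecar config.

**Sensitivity to the path.** The trace is `61.5·ln(EFT·m)` sampled along
the path, so its extremes are governed by the range of `EFT` there — a
quantity that varies over orders of magnitude across the domain. On the
default diagonal path the swept band is `[−211, +220] mV` for the
gradient variant and `[−82, +258] mV` for the vector-Laplacian variant;
paths hugging regions where `EFT·m` stays within about `[0.4, 2.4]`
would give a physiologic `[−60, +55] mV` band instead. Neither the
iteration depth nor either parse strategy changes this qualitative
picture (all combinations were surveyed); the band is a property of the
evaluation path, which the model treats as a documented free choice.
The two variants always disagree, which is the model's comparative
argument for preferring the gradient route.

The classical utilities are `nernst(ratio) = 61.5·log₁₀(ratio)` mV
(decade prefactor `2.3026 × 26.7` at body temperature) and the Goldman
exponential integral `∫₀^x exp(V(s)/(RT/F)) ds` with `RT/F = 26.7 mV`,
by adaptive quadrature.

## Ciliary signaling (`neuroactin.cilia`)

The Shh signal pair is the regularized incomplete gamma pair at complex
first argument `s = x + iy`:
`U = P(s, z) = γ(s, z)/Γ(s)`, `L = Q(s, z) = 1 − P(s, z)`, with `z`
doubling as the third spatial coordinate and the gamma function's second
argument — the formula makes them the same variable and the model keeps
them so. `γ(s, z)` is evaluated by the Kummer series
`z^s e^{−z} Σ_{n≥0} z^n/(s(s+1)⋯(s+n))`, which converges for all finite
complex `z`; on the model's display domain (`|z| ≤ 5`) it needs a few
dozen terms. `Γ(s)` comes from scipy's complex gamma. For the display
range `z ∈ [−5, 0]` the power `z^s` is multivalued; the principal branch
is used, so off-integer `s` the fields are genuinely complex on `z < 0`
and the magnitude is what the display surfaces show. Points with `s` a
non-positive integer (gamma poles) are masked. The default sampling is a
25×25 in-plane grid with 6 z-slices.

## Organoid network (`neuroactin.organoid`)

A cluster of `N` neurons is built deterministically from:

* the interaction scalar
  `V = y/(zr) − x/(zr) + y·m̄/(zr) − x²y·m̄/(z³r)` (adopted parse,
  strategy-isolated),
* the guidance polynomial `P = −x³z³ − a·x²z + x + y²z² − b`, whose
  `z = 1` slice rearranges to the elliptic-curve-like
  `y² = x³ + ax² − x + b`,
* directional fields `F_c = ∂P/∂c + V` and their own-coordinate
  antiderivatives `G_c`, computed symbolically. The integration runs on
  positive-assumption symbols: sympy then avoids `polar_lift`/`Abs`
  bookkeeping that would break exactness, and `∂G_c/∂c = F_c` holds
  symbolically on the positive octant, where all interpolation nodes
  live (verified with `radsimp`; see
  `antiderivative_exactness_residuals`).

The interpolation abscissae are the node indices `i = 1…N` (the model
gives no other abscissa), with nodes `q_i = (i, i, i)`. Per axis a
Vandermonde system over the abscissae is inverted to get the Lagrange
interpolant of the `G` samples, and the printed placement sums

```
L_ax = Σ_{i=1..N} [ G_ax(q_i)·i + ax + F_ax(q_i)·Log(−e^{(i−x)+(i−y)+(i−z)}·(i − ax)) ]
```

are evaluated at each node (real part at the very end) to give the 3D
positions. The printed argument of the logarithm is typographically
corrupt in its source; the adopted reading — principal log of the
negated product of the exponential decay term and the axis-specific
linear factor — is kept in one function (`placement_sum`) together with
the raw printed string. At a node's own abscissa the linear factor
vanishes and the log term is omitted (the removable-node convention,
mirroring how a Lagrange basis excludes its own node); without it every
position would be `−∞`.

The network potential runs the membrane-potential pipeline along the
piecewise-linear path through the node positions in index order
(120 samples per edge; a single node gets a 1 µm segment around itself).
Node positions grow rapidly with `N` (the `G_c(q_i)·i` terms are
polynomial antiderivatives evaluated at `(i,i,i)`), so the path sits far
from the origin where `EFT` is small and `|MB|` large — hence the larger
network's stronger peak magnitude (N = 7 reaches 1848 mV vs 1367 mV for
N = 4 on the defaults).

**Local maxima.** A trace sample is a local maximum if it is unmasked
and not exceeded by an existing neighbor (endpoints count; plateaus
count once). Under this definition every default network trace has at
least one maximum, and the count is non-decreasing in `N` for `N ≥ 2`.
The single-neuron case deviates: its short degenerate segment dips in
the middle, so both endpoints qualify (count 2, versus 1 for every
multi-node trace). The deviation is confined to that artificial `N = 1`
path and is reported by the test suite rather than hidden.

## Parameters at a glance

| parameter | default | units | role |
|---|---|---|---|
| `m` | swept 0.1–4 (40 values) | – | van der Pol damping / Dirac multiplier |
| `t` | 1 | – | Lie-bracket iteration depth (cap 4) |
| `λ` | 190 | nm | actin ring periodicity → `k = 33.1 rad/µm` |
| `k_display` | 4 | rad/µm | ring wavenumber for unit-scale display |
| `a, b` | 1, 1 | – | elliptic-map coefficients of `P` |
| `m̄` | 1 | – | interaction-scalar weight |
| `N` | 4 | – | neuron count of the network |
| mask tolerance | 1e-9 | – | denominator magnitude cutoff |

## Problem sizes

The default configurations are sized for interactive use: 400-sample
paths × 40 damping values for the potential sweep (16 000 samples per
variant), 25×25×6 lattices for the ciliary fields, 241² contour grids,
49³ marching-cubes lattices, and networks up to N = 7. All are
config-exposed.

## Known limitations

* The mV scale is nominal: the Nernst prefactor maps the log of a
  dimensionless field magnitude to millivolts, it does not represent ion
  concentrations. No conductance-based (Hodgkin–Huxley) dynamics and no
  time integration of the van der Pol oscillator — both fields are
  static.
* Trace bands depend strongly on the (documented, free) evaluation path;
  see the sensitivity note above.
* Ring spacing carries no biophysical claim beyond the `2π/λ`
  conversion; there is no microtubule model.
* The ciliary fields solve no reaction–diffusion PDE; they are a static
  accumulation profile.
* Network growth is a static map from `N` to a layout — no synapse
  rules, neuron types, or stepwise growth in time.
* Several source formulas admit multiple typographic parses; every
  adopted parse is isolated behind a named constructor or strategy flag,
  and the alternatives are implemented (`parse="product"`) or documented
  where they are not.
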