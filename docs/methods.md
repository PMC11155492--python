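# Methods

## The solver

`nladmm` implements linearized ADMM for
`min f(x) + g(y) : Ax + By = c` with `f = fc + fd`, `g = gc + gd`,
`fc, gc` convex proper lower-semicontinuous and `fd, gd` twice
differentiable. Per sweep, the differentiable parts are replaced by their
linearization at the previous iterate and a proximal term
`½‖x − x_t‖²_Hf` (resp. `Hg`) is added, so each block update is the prox
of the convex part in the metric `Df = Hf + AᵀΣA` (resp.
`Eg = Hg + BᵀΣB`); the dual step is `u ← u + Σ(Ax + By − c)`.

The step-size matrices must satisfy `Hf ⪰ 0`, `Hf + AᵀΣA ≻ 0` and
`Hf ⪰ ∇²fd(x)` on the domain (and the `g` analogues). The engine's fast
path takes the *summed* metrics `Df, Eg` directly as positive diagonal
vectors — the updates never use `Hf` alone, and both bundled applications
choose `Hf` precisely so the sum is diagonal. `verify_step_conditions`
checks the conditions by dense eigendecomposition on small instances.

Convergence in the nonconvex regime is stated for the running averages
`x̄_T = (1/T)Σ_{t≤1..T} x_t`: under restricted strong convexity around an
approximately stationary target, their squared error is bounded by
`C/T` plus tolerance terms. Accordingly the engine accumulates exact
running sums from the first iterate (no burn-in by default; burn-in is
configurable, and tail averaging is what one uses to read off the limit
of a linearly convergent run). A fixed iteration budget `T` is the
primary stopping rule; an optional residual-based early stop exists but
is off by default. Domain violations return `+inf` from value oracles;
prox oracles must return in-domain points. Default initialization is
zero for all three blocks, which is in-domain for both applications.

## Sparse quantile regression

The problem is
`min_x (1/n) Σ_i ℓ_q(w_i − φ_iᵀx) + λ Σ_j β log(1+|x_j|/β)` with an
optional ball constraint `‖x‖₂ ≤ R` (default `R = ∞`; the iterates stay
bounded in practice). Splitting `y = Φx` gives `A = Φ`, `B = −I`,
`c = 0`, with

* `fc(x) = λ‖x‖₁ + δ_{‖x‖≤R}` — the ℓ1 majorant of the penalty plus the
  constraint; its prox is soft-thresholding followed by ball projection
  (in that order the composition is exact);
* `fd(x) = λ Σ_j (β log(1+|x_j|/β) − |x_j|)` — smooth, concave, with
  per-coordinate curvature bounded below by `−λ/β`, so any PSD `Hf`
  dominates `∇²fd` automatically;
* `gc(y) = (1/n) Σ_i ℓ_q(w_i − y_i)` with the per-coordinate quantile
  prox; `gd ≡ 0`.

With `Σ = σIₙ` we take `Hf = σ(γI − ΦᵀΦ)` where `γ` is the squared
spectral norm of `Φ` (power iteration, tolerance 1e-8, inflated by
`1+1e-7` — an order above the estimate's tolerance — so `Hf` stays PSD in
floating point). This makes `Df = σγI` diagonal and both updates
closed-form. A `γ` below `‖Φ‖²` is rejected as a configuration error.
`β = +∞` is a separate code path recovering the plain ℓ1 penalty.

### Scaled-down study design

The simulation study uses `n = 200`, `d = 250`, a 5-sparse all-ones
signal, i.i.d. standard normal design and t(5) noise, `q = 0.5`,
`β = 0.5`, `T = 1000`. The generator's full-size defaults are
`n = 2000`, `d = 2500`, `s* = 10`.

* `λ = 0.6·√(log d / n) ≈ 0.0997`. The proportionality rule is
  `λ ∝ √(log d/n)`; the constant is set so `λ` sits at the loss-subgradient
  noise level `max(q,1−q)·√(2 log d/n)` (≈0.117 here). A larger constant
  (e.g. carrying over the ratio implied by the full-size setting) pushes
  `λ` past the scale-free subgradient bound at the origin (≈0.15), at
  which point `x = 0` becomes a fixed point of the iteration and the
  study degenerates.
* `σ = 2e-3`, chosen by scanning `σ` on the scaled problem exactly as
  the full-size study scans it: small `σ` (≤5e-4) destabilizes the
  averaged-loss trajectory while support recovery and final RMSE are
  unchanged across the scanned range (2e-4…5e-3); 2e-3 is the start of
  the stable plateau.

## Spectral CT reconstruction

### Forward model

A parallel-beam scanner with `n_angles` evenly spaced over `[0, 2π)` and
`n_cells` uniformly spaced detector cells spanning the image diagonal
produces rays parameterized by (angle, perpendicular offset). The
projection matrix holds exact Siddon ray–pixel intersection lengths (cm);
row sums equal the analytic chord through the square support to 1e-8,
and segments under 1e-12 cm are dropped as numerical noise. An image
`x ∈ R^{nk×nm}` of per-pixel material fractions projects to per-ray
material path lengths `y = Px`; expected window counts are
`Σ_i S_{wℓi} exp(−Σ_m μ_{mi} y_{ℓm})` and the measured counts are
independent Poisson draws.

### Reconstruction

Maximum likelihood in `x` splits over `Px = y` with `f ≡ 0` and
`g(y) = Σ_{wℓ}[Λ_{wℓ}(y) − C_{wℓ} log Λ_{wℓ}(y)]`,
`Λ_{wℓ} = Σ_i S_{wℓi}·qexp(−Σ_m μ_{mi} y_{ℓm})`, where `qexp` is the
exponential for nonpositive arguments and its quadratic Taylor
continuation for positive ones. This bounds the curvature so transient
negative path lengths cannot destabilize the optimization, and equals
the exact likelihood whenever the iterate is physically feasible.
Zero-count terms contribute only through the convex part; no flooring of
`Λ` is applied for them.

Operators are Kronecker products applied per material column — never
materialized; vectorization is pixel-major with the material index
fastest so `(P⊗I)vec(x) = vec(Px)`. The preconditioners are
`(Qf)_kk = σ·Σ_ℓ P_ℓk` and `Σ̃_ℓℓ = σ / Σ_k P_ℓk`. This reciprocal
pairing is what makes `Hf = Qf⊗I − (P⊗I)ᵀ(Σ̃⊗I)(P⊗I)` provably PSD: the
row sums of `PᵀΣ̃P` equal the `Qf` diagonal exactly, so `Hf` is
diagonally dominant with nonnegative diagonal (the standard diagonal
preconditioning lemma for nonnegative matrices; pairing `Σ̃` with the
row sum itself instead of its reciprocal makes `Hf` indefinite and the
iteration diverges within a few sweeps). Zero row/column sums are
floored at `1e-12·max(P)` so untouched pixels and image-missing rays are
frozen rather than divided by.

The x update is the closed form
`x ← x − Qf⁻¹ Pᵀ(u + Σ̃⊙(Px − y))` per material. The y update separates
into one strictly convex smooth `nm`-dimensional problem per ray
(`Hg = 0`; the concave count term is linearized at `y_t`), solved by
damped Newton with Armijo backtracking (halving, ≤30 backtracks),
started from the previous `y_ℓ`. Two floating-point guards make the
nominal gradient tolerance (default 1e-10) meaningful at count scales of
1e5–1e6: the per-ray tolerance is widened to the rounding floor of the
gradient's own assembly (`64·eps·Σ|terms|`), and once the Newton
decrement falls below the rounding resolution of the objective the full
step is taken without a line search (it is provably tiny there). A
Newton failure beyond these floors raises with the offending ray index.
With `Hg = 0` the condition `Hg ⪰ ∇²gd` is guaranteed only where all
exponent arguments are nonpositive; a warning is surfaced once per run
if an iterate leaves that region.

### Diagnostics

For simulated data with known truth `x̃`, `ỹ = Px̃`:

* RSC ratio per iteration, from the staggered pairs `(x_{t+1}, y_t)`:
  `α_t = [⟨y_t−ỹ, ∇g(y_t)−∇g(ỹ)⟩ + ½‖Px_{t+1}−y_t‖²_Σ] / ‖y_t−ỹ‖²`;
  entries with `‖y_t−ỹ‖ ≤ 1e-12` are reported as undefined. A minimum
  bounded away from zero validates restricted strong convexity along the
  algorithm's path.
* Stationarity ratio `‖∇g(ỹ)‖₂/‖∇g(0)‖₂`. With counts replaced by their
  exact expectations this is zero to machine precision — the forward
  model and the reconstruction share one code path for the window
  intensities, so the cancellation is exact — which doubles as an
  end-to-end consistency check of the gradient code.

## Synthetic fixtures

The generators are pure functions of their arguments including the seed.

* Beam spectrum: a Beta-shaped bump over 20–120 keV discretized to `ni`
  bins, normalized to the photon budget per ray (1e6 at full scale, 1e5
  in the small preset); window responses are products of logistic
  threshold functions (defaults: thresholds 50 and 80 keV, blur 3 keV)
  that sum exactly to 1 at every energy, so the windows partition the
  beam. Zero blur recovers a hard partition.
* Attenuation curves are synthetic parametric stand-ins, not physical
  reference data, but carry the qualitative structure the reconstruction
  exercises *and needs for identifiability*: three spectrally distinct
  shapes — a Compton-dominated plastic (PMMA, low), a
  photoelectric-dominated metal (aluminum, above PMMA at every energy),
  and a dilute K-edge contrast agent (gadolinium, with a single upward
  jump at 50.2 keV, between the two window thresholds). An earlier
  parametrization that made PMMA and aluminum affinely dependent left
  the three-material decomposition nearly unidentifiable; distinctness
  of the spectral shapes, not their absolute values, is what the study
  conditions require.
* Phantom presets: a PMMA background disk (radius 4 cm, fraction 1) with
  one aluminum and one gadolinium disk insert (radius 1 cm) punched out
  of the background. Rasterization is by pixel-center membership;
  overfull pixels (material sum > 1) are a validation error.
* Quantile data: `Φ` i.i.d. N(0,1), `x̃` all-ones on the leading `s*`
  coordinates, noise t(5) (heavy-tailed), gaussian, or none.

What the fixtures do not emulate: scanner calibration error, scatter,
detector blur, polychromatic beam-hardening beyond the spectral model,
and physically accurate attenuation values. Passing tests therefore
demonstrate the optimization behavior of the method under a correctly
specified model, not clinical reconstruction quality.

## Study sizes, descent measurement, and known limitations

The test suite and the acceptance script run scaled-down studies chosen
to keep the whole suite fast: QPs of dimension ≤10 at `T = 2000`; the
quantile study at `n=200, d=250, s*=5, T=1000` over 10 seeds; the CT
study on a 16×16 grid with 24×24 rays, 20 energy bins, 1e5 photons,
`σ ∈ {1,10,100}`, `T = 300`; the stationarity ratio additionally at the
full 25×25 / 50×50 / 1e6-photon scale.

Loss-descent fractions are measured up to the relative tolerance
`1e-6·(1+|Loss|)`: near convergence both applications' loss trajectories
carry a ripple that is orders of magnitude below the loss scale (for the
CT study ~1e-8 relative, a slowly rotating dual mode with a period of
tens of sweeps on this ill-conditioned material space), and a strict
float comparison would count those machine-level wiggles as ascent.
Both the strict and the tolerance-based fractions are reported by the
acceptance script.

Known limitations:

* The three-material decomposition at the small preset's photon budget
  is statistically very hard: the Fisher information at the truth is
  singular (corner pixels and near-collinear material directions), so
  the fully-converged unpenalized MLE has a large error floor. The
  solver's error at `T = 300` from a zero init is *below* that floor
  (early stopping regularizes implicitly), decreasing roughly 4–7× from
  the initial error; driving the error down an order of magnitude at
  this budget would require regularization (e.g. total variation), which
  is outside this package's scope. In the noiseless limit and at the
  full-scale preset the error decreases monotonically toward zero.
* The engine supports a dense SPD `Σ` only on small instances (the
  applications use diagonal `Σ`).
* Multi-block splittings, nonlinear constraints, and stochastic
  mini-batch variants are not implemented.
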