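# Methods

This note documents the model as implemented: its assumptions, the
surrogate inputs, the parameters that matter, and the numerical and design
choices made where the formalism leaves room.

## Model structure

Survival is computed as a Poisson mixture over radiation impacts.  An
impact is one primary particle (an ion track, or for the reference photon
field one photon interaction) with all its secondaries.  Impacts are
independent; per impact the cell accumulates

* a deterministic local **core** exponent `(Vc/Vs)·⟨F(z)⟩`, where the
  expectation of the effective lethal function runs over the nanotarget
  dose spectrum of that radiation quality (the core term uses the
  track-type *average* restricted specific energy — the index asymmetry of
  the core/penumbra factorization),
* a stochastic local **penumbra** exponent `α_p (Vp/Vs) Z_p,k` with the
  per-impact penumbra energy drawn from the quality table, and
* a contribution to the **chemical specific energy**
  `Z̃ += rc(T)·(Vc/Vs)·Z_c,k + rp(T)·(Vp/Vs)·Z_p,k`, using the per-impact
  (stochastic) energies and the •OH yield ratios at time `TRCE`.

A configuration's survival is `exp(−local) · Cnorm · exp(−βG Z̃²)` (the
global linear coefficient αG is zero in this model version).  Impact-free
Monte Carlo configurations score survival 1 — an unhit cell is
unirradiated — so `S̄(0) = 1` exactly while `Cnorm` still normalizes every
irradiated configuration.  Applying `Cnorm` once per configuration (not
once per impact) is the only reading under which a constant can reproduce
the reference LQ response at all doses; a per-impact factor would make the
normalization dose-dependent.

Because per-impact energies are modeled as compound-Poisson counts of
fixed 40 eV transfers, each `Z` is Gamma-distributed and the sum over `K`
impacts is again Gamma.  The engine therefore draws one Gamma variate per
configuration and region instead of `K`, which makes the Monte Carlo cost
independent of the impact count.  `survival_one_configuration` retains the
explicit per-impact form and the two are tested against each other.

## Reference radiation and calibration

The photon field has no track core.  Its total restricted specific energy
in the sensitive volume is Gaussian-like with mean `η·D`; the coefficient
of variation is 5% at 2 Gy and scales as `D^(-1/2)` (photon impact counts
grow linearly with dose).  `Cnorm` is the ratio of the experimental LQ
survival to the model's uncalibrated mean survival at the calibration dose
(default 2 Gy, the SF2 anchor); since `Cnorm` enters linearly, calibration
is a single seeded Monte Carlo estimate and a division.  The Jensen gap of
the convex survival exponent puts `Cnorm` slightly below 1 (≈0.999 for
HSG at the default spread).

The penumbra coefficient acts on *restricted* specific energy, whose mean
is `η·D`, so the verbatim choice `α_p = α_r` underestimates the linear
reference response by the factor η; no constant `Cnorm` can then reproduce
the reference LQ curve away from the calibration dose.  The implementation
keeps the verbatim behavior as the library default and offers
`penumbra_alpha_rescale` (use `α_r/η`), which makes the reference closure
exact at every dose.  The packaged cell configs enable the rescale: the
shipped study conditions reproduce `exp(−α_r D − β_r D²)` to better than
1% over 0.5–6 Gy, which we regard as the intended meaning of the
normalization.

`α_r` is not part of the published parameter sets; it is derived from the
surviving fraction at 2 Gy via `−ln SF2 = 2α_r + 4β_r` (0.3108 Gy⁻¹ for
HSG, 0.1636 for V79, 0.1924 for CHO-K1 from SF2 = 0.42, 0.65, 0.58).
Configs may override it explicitly.

## Surrogate quality tables

The per-quality physical/chemical inputs normally produced by dedicated
track-structure and radiolysis codes are emulated by an amorphous-track
surrogate.  What it reproduces:

* a flat radial dose core of 10 nm and a `1/r²` penumbra truncated at
  `rmax(E) = clip(0.062·E^1.7, 0.1, 4.5) μm`;
* discrete energy-transfer points of 40 eV, Poisson-sampled so the
  restricted energy per unit path is exactly `η·LET` in expectation —
  energy conservation `E[Zc·Vc + Zp·Vp] = η·c·LET·LVs` holds by
  construction and is tested to 3 Monte Carlo standard errors;
* nanotarget dose spectra from cylindrical 10 nm targets tossed uniformly
  in the core parallelepiped (axis parallel to the beam; periodic wrap
  along the beam axis avoids end effects), histogrammed into an explicit
  zero bin plus 256 log-spaced bins over 1–10⁷ Gy;
* •OH yield ratios `G/Gr(T) = g∞ + (1−g∞)·exp(−T/τ)` with
  `g∞ = 0.3 + 0.7/(1 + LET/100)` and `τ = 3 ns/(1 + LET/50)`: denser
  tracks recombine more and faster; the penumbra uses the same law at a
  ten-fold lower effective LET.  Ratios are non-increasing in time, so a
  longer radical-diffusion time weakens the shoulder.

What it does **not** reproduce: electron transport physics, realistic
radial dose tails beyond the truncation radius, the continuous
energy-transfer spectrum (the fixed 40 eV quantum makes the nanotarget
spectrum discrete with ≈2 kGy spacing), or the absolute chemical yields.
Consequently the packaged ELF parameter sets do not reproduce published
absolute α(LET) magnitudes on surrogate tables; tests and scenarios assert
exact arithmetic, analytic limits, orderings and invariances instead of
the published sensitivity magnitudes, which depend on the original codes'
unpublished tables.

The truncation cap of 4.5 μm keeps the whole penumbra inside the smallest
sensitive volume studied (radius 4.9 μm).  This makes the penumbra energy
per impact geometry-independent, which in turn makes the low-LET
superposition of α across sensitive-volume radii essentially exact here,
and it means a single table per ion serves all geometries
(`adapt_quality` rescales the penumbra moment to the target volume).  A
side effect is that the sensitive-volume *length* is almost exactly inert
in this implementation (deposited energy and volumes both scale linearly
with length): the published small-but-nonzero length sensitivity stems
from three-dimensional track ends that the surrogate does not model.

The fixture LET(E) mapping is a single power law per ion,
`LET = 1155·(Z²/36)·E^(−0.82) keV/μm`, chosen once so the packaged
minimal-dataset carbon energies fall in the intermediate (55–75) and high
(150–200 keV/μm) windows; it is a bookkeeping convention, not a stopping
power model.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| RVs, LVs | μm | per cell line, LVs = 1 | sensitive-volume (nucleus) cylinder |
| core side | μm | 0.1 | track-core parallelepiped |
| RVt, LVt | nm | 10 | nanometric target cylinder |
| z0, σ, h | Gy, Gy, – | per cell line | ELF threshold, width, saturation |
| α_r, β_r | Gy⁻¹, Gy⁻² | per cell line | reference photon LQ response |
| η | – | 0.80 | restricted-to-total specific energy ratio |
| β_G | Gy⁻² | β_r/η² | global quadratic coefficient |
| TRCE | s | 10⁻¹¹ | radical-yield evaluation time |
| Cnorm | – | calibrated | reference normalization |

## ELF fitting

The fit minimizes the plain (unweighted) sum of squared residuals between
measured α values and the closed-form low-fluence α of the forward model,
over `(z0, σ, h)` in log-parameterization with a trust-region
least-squares solver, from the standard initial point
(10 000, 5 000, 100 000) plus four deterministically perturbed restarts.
The photon record enters through the reference constraint (its α is α_r
by construction after calibration), matching its inclusion in every
dataset.  σ is weakly identified whenever it is small against the spacing
of the nanotarget spectrum — the regime of all packaged parameter sets —
which is why minimal (3-point) and standard datasets give nearly the same
predictions at intermediate and high LET.

## Numerical choices

* Histogram representative z per bin: geometric mean of the edges (exact
  for degenerate bins; 0 for the zero bin).
* Penumbra single-impact survival expectation in the closed-form α: the
  Gamma moment-generating function `(1 + a·θ)^(−k)`, no sampling.
* LQ fits: weighted non-negative least squares of `−ln S̄` on `(D, D²)`,
  weights from the Monte Carlo standard errors; parameter errors from the
  unconstrained WLS covariance.
* `Dx%`: the cancellation-stable positive quadratic root
  `2·ln(1/x) / (α + sqrt(α² + 4β·ln(1/x)))`.
* Default problem sizes: 160–256 tracks × 96–128 targets per quality
  table, 3 000–20 000 Monte Carlo configurations per dose point, 100 000
  for calibration; all entry points take explicit seeds and identical
  seeds give bit-identical outputs.

## Known limitations

* The surrogate's discrete 40 eV quantum produces atomic nanotarget
  spectra; ELF fits on surrogate tables are only well-posed down to that
  granularity.
* Constant-volume geometry arithmetic gives 49/24.01 = 2.0408 μm for the
  HSG shape variation; the corresponding published table prints 2.1 μm,
  which matches no rounding of the exact value (the V79 and CHO-K1 rows
  match nearest-0.1 rounding).  The package reports the exact value and
  its nearest-0.1 rounding.
* With yield ratios non-increasing in time, a longer TRCE can only weaken
  the shoulder (D1% non-decreasing).  α is exactly TRCE- and
  β_r-independent by construction.
* Mixed fields, spread-out Bragg peaks, cell-cycle and cell-to-cell
  effects are out of scope.
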