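# Methods

## The problem

Spin-echo small-angle neutron scattering (SESANS) measures the
polarization `P(z)` of a neutron beam as a function of the spin-echo
length `z`, a real-space distance that can reach microns.  For an
isotropic sample, `P(z)` is governed by the projected correlation
function `G(z)`, the Abel transform (line projection) of the Debye
correlation function `gamma(r)` of the scattering-length-density
fluctuations; `gamma(r)` in turn is the inverse Fourier transform of the
SANS intensity `I(Q)`.  For a Gaussian polymer chain the classical route
breaks down: the Debye form factor decays as `Q^-2`, so its inverse
Fourier transform diverges like `1/r` at the origin and the Hankel
projection of the truncated intensity diverges at `z -> 0`, leaving no
normalizable model to fit SESANS spectra with.  This package implements
a family of non-divergent real-space correlation functions for the
Gaussian chain, their projections and the resulting polarization model,
plus the simulation and estimation machinery to validate that fitting
those functions to data recovers the chain's radius of gyration.

## The model functions

All results are expressed through two shape functions

    g(x) = sqrt(pi) (1/x + 2x) erfc(x) - 2 exp(-x^2)
    f(x) = (1 + x) E1(x) - exp(-x)

with `erfc` the complementary error function and `E1` the exponential
integral.

**Divergent correlation.**  The intra-chain pair correlation of a
continuous Gaussian chain is a mixture of Gaussian kernels over the
contour separation `u` in (0, 1] with mixture measure `(1-u) u^{-3/2}`
(two monomers a contour fraction `u` apart are separated by a Gaussian
displacement of variance `6 u Rg^2`).  Integrating the mixture gives, in
`eta = r/Rg`,

    gamma_div(r) = 2 (4 pi Rg^2)^{-3/2} g(eta/2),

which is exactly the spherical inverse Fourier transform of the Debye
form factor `F(x) = 2(e^{-x} - 1 + x)/x^2`, `x = Q^2 Rg^2` (the package
verifies this identity numerically against sin-weighted quadrature).
The `u -> 0` end of the measure is what produces the `sqrt(pi)/x` pole
of `g`, i.e. the `1/r` divergence.

**Non-divergent correlation.**  The divergence is removed by replacing
the mixture measure below the contour cutoff `u = 1/16` with the
integrable measure `15 u^{-1/2}`, continuously matched at the cutoff.
This is the minimal two-term regularization expressible in the same
shape function: the only combinations `g(eta/2) - 2b g(b eta)` cancel
the pole, and `b = 2` (cutoff 1/16) is the member whose deviation from
the divergent form is already below 1% at `eta = 1` — the regularization
is confined to separations well inside the coil.  Hence

    gamma_auto(eta) = [g(eta/2) - 4 g(2 eta)] / 12,

normalized to 1 at the origin (the bracket tends to 12).  Because the
mixture form survives the regularization, the Abel projection is exact
in closed form: with `zeta = z/Rg` and `c = zeta^2/4`,

    G0(zeta) = [f(c) - f(16 c)] / (4 ln 2),        G0(0) = 1,

and the unnormalized projection of the labeled-melt correlation at the
origin is

    G(0) = N_c phi (1 - phi) (beta_H - beta_D)^2 N^2 ln(2) / (8 pi Rg^2)

for `N_c` chains of `N` bonds with deuterated fraction `phi` and
monomer scattering lengths `beta_H`, `beta_D` (the `ln 2` is the
integral of the regularized measure over `1/u`).  The polarization with
multiple scattering is

    P(z) = exp[ Sigma (G0(z) - 1) ],
    Sigma = lambda^2 l n_c phi(1-phi) (beta_H - beta_D)^2 N^2 ln(2) / (8 pi Rg^2),

where `lambda` is the neutron wavelength, `l` the sample thickness and
`n_c` the chain number density.  `Sigma` ("opacity") is dimensionless
and is the only place instrument constants enter; single scattering is
the first-order expansion `1 + Sigma (G0 - 1)` and the saturation value
is `P(inf) = exp(-Sigma)`.

**What the regularization trades away.**  `gamma_auto` and `gamma_div`
agree to <= 1% for `eta >= 1` and their difference decays like
`exp(-eta^2/4)`; conversely, the Fourier image of `gamma_auto` departs
from the Debye function at high `Q` (beyond `Q Rg ~ 1.5`), because the
modified origin region carries the high-`Q` content.  Real-space fits
with a free amplitude are therefore the intended use; the model is a
large-separation description and is *not* a sub-monomer-scale model.

## Units

All lengths are unit-agnostic: pick one unit for `r`, `z`, `Rg` and
`1/Q` and use it consistently.  The MD engine uses reduced
Lennard-Jones units (`sigma = epsilon = m = k_B = 1`,
`tau = sigma sqrt(m/epsilon)`).

## Simulation engines

**Ideal-chain sampler.**  Chains with independent isotropic Gaussian
bond vectors, `<bond^2> = b^2`.  Exact, used for oracle comparisons; the
finite-chain radius of gyration obeys
`<Rg^2> = b^2 N(N+2) / (6(N+1))` for `N` bonds.

**Bead-spring Langevin MD.**  The coarse-grained Theta-solution model:
FENE bonds `U = -K r0^2/2 ln[1-(r/r0)^2]` plus a WCA core (truncated at
`2^{1/6} sigma`, shifted by `epsilon`), and an attractive 12-6
Lennard-Jones potential between non-bonded beads, truncated at
`2.5 sigma` and shifted to zero there.  First-neighbor (bonded) pairs
are excluded from the pair potential.  Defaults: `K = 30`, `r0 = 1.5`,
`Gamma = 0.5`, `dt = 0.006`, and the Theta temperature `T = 3.18` of
this force field, at which dilute chains show ideal (Gaussian) global
statistics.  The combined bond potential has its minimum at
`r = 0.961 sigma`.

The integrator is the Gronbech-Jensen/Farago (GJF) discretization of
Langevin dynamics — a velocity-Verlet-based step with one white-noise
impulse per step.  It was chosen because its half-step velocity
satisfies the fluctuation-dissipation balance exactly for harmonic
modes at any `dt`: with the stiff FENE bonds (`omega dt ~ 0.27`) a
conventional full-step velocity underestimates the kinetic temperature
by ~2%, while the GJF half-step estimate is exact to within sampling
noise (measured: 3.1800 at target 3.18).  At `Gamma = 0` the scheme is
exactly velocity Verlet, which is how the NVE conservation limit is
tested (bonded-only system, because the truncated LJ pair force is
discontinuous at the cutoff and no integrator conserves energy exactly
across such a discontinuity).

Default operating mode is *dilute*: chains are isolated molecules (no
inter-chain interactions, no box), which is the cheap emulation of a
dilute Theta solution.  Each chain draws from its own stream derived
from the master seed, so adding chains never perturbs existing ones and
runs are bit-reproducible.  Non-bonded pairs use a
displacement-triggered Verlet neighbor list (skin 0.4 sigma) over an
O(beads^2) candidate loop — ample at the few-thousand-bead scale this
package targets.

**Problem sizes.**  The validation protocol runs 20 dilute chains of
100 beads for 5e5 equilibration + 5e5 production steps (3000 tau each,
roughly 30 Rouse times of a 100-bead chain), recording 500 frames.
This is a deliberately reduced re-enactment of melt-scale protocols
(tens of chains in periodic boxes, 1e8-1e9 steps): the dilute-limit
physics it probes — ideal chain statistics at the Theta point and the
recovery of `Rg` from correlation fits — does not require melt sizes.
The initial-configuration builder can, however, generate the melt
geometry (50 chains x 100 beads in a box of side 300) for export.

## Estimators

* **Direct Rg** — per-chain, per-frame root-mean-square distance from
  the center of mass, then averaged ("mean" definition).  The "rms"
  definition `sqrt(<Rg^2>)` is also provided: it is the moment that
  enters the Debye function and the Rg-b relation, and for ideal chains
  it sits ~3% above the mean (per-chain `Rg^2` fluctuates strongly;
  Jensen's inequality).  Which definition a comparison uses is stated
  in each test.
* **Bond route** — `b = sqrt(<bond^2>)` over adjacent pairs, inserted
  into the ideal-chain Rg-b relation.  For bead-spring chains this
  route inherits the local-stiffness bias (the Theta condition fixes
  the large-scale exponent, not the prefactor; measured
  `C_inf = <R^2>/(N b^2) ~ 1.9`), so it is a hard consistency criterion
  only for ideal-chain ensembles.
* **gamma(r)** — histogram of all intra-chain `i != j` pair distances
  over chains and frames, divided by each bin's spherical shell volume;
  Poisson counting errors; default 200 linear bins on `(0, 6 Rg]`.
  Self-pairs are excluded (they are a delta at the origin); the
  counting identity `sum(value * shell_volume) = pairs per chain` is
  exact.
* **F(Q)** — exact Debye double sum `<sum_ij sinc(Q r_ij)>/(N+1)^2`
  including self-pairs (hence `F(0) = 1`), averaged over chains and
  frames.  The inclusion asymmetry between the two estimators is
  deliberate: it mirrors the definitions of the observables.
* Standard errors of frame series use block averaging with 10 blocks.

## Fitting

Weighted (when counting errors exist) nonlinear least squares via
Levenberg-Marquardt; models: `A * gamma_auto(r/Rg)` (amplitude free, so
no extrapolation of data to `r = 0` is ever needed), the Debye function
(unit amplitude — form-factor data are normalized at zero by
construction), and the two-parameter `(Rg, Sigma)` polarization model.
Initialization from the half-value abscissa (`gamma_auto = 0.5` at
`eta = 0.290`, `G0 = 0.5` at `zeta = 0.50`) or a Guinier-regime estimate
for `F(Q)`; bounded restarts at 0.5x and 2x on failure.  Flat
polarization data raise an identifiability error rather than returning
an unconstrained fit.

**Fit window for bead-spring data.**  A coarse-grained trajectory's
`gamma(r)` contains monomer-scale structure the Gaussian-chain model
does not describe: the bonded-neighbor peak at `r ~ 0.96 sigma`, the
correlation hole below `~0.9 sigma`, and LJ-liquid order out to the
pair cutoff.  In a counting-error-weighted fit the bond peak alone
(99 pairs per chain concentrated in one bin) overwhelms every
coil-scale bin, so correlation fits of bead-spring data use a lower
window edge of `3 sigma` — just beyond the `2.5 sigma` interaction
cutoff, the first scale at which the model can apply.  Ideal-chain data
have no such structure and are fit over the full range.  Both defaults
are caller-overridable (`r_min`/`r_max`).

## Numerical choices

* `g`, `f` are evaluated through `erfc`/`E1`; below `eta, zeta = 1e-3`
  second-order series (including the `c ln c` term of the projection)
  replace the cancellation-prone differences, stitched to <= 1e-10 at
  the switch point.  The Debye function switches to its series below
  `x = 1e-4`, where `expm1` cancellation reaches ~1e-10.
* Abel projections substitute `u^2 = r^2 - z^2`, removing the
  inverse-square-root endpoint singularity exactly; adaptive
  Gauss-Kronrod on the smooth remainder; upper limit where the
  integrand falls below 1e-12 of its near-origin magnitude; inputs
  whose tail does not beat `1/r` are rejected.
* The Hankel projection requires the truncation `Q_max` explicitly
  (truncation is the source of the `z -> 0` artifact, so it is never a
  silent default) and reports a truncation estimate; Bessel oscillations
  are resolved by subdividing at the kernel zeros.
* The inverse Fourier transform uses sin-weighted quadrature and, when
  the form factor exhibits a `Q^-2` tail, corrects the truncated part
  in closed form via the sine integral.
* Transform constants are pinned by cycle closure on the Gaussian pair
  `gamma = exp(-r^2/a^2)  <->  I = pi^{3/2} a^3 exp(-Q^2 a^2/4)  <->
  G = sqrt(pi) a exp(-z^2/a^2)` (conventions table in the transforms
  module docstring).

## What the synthetic generators do and do not emulate

The ideal sampler produces mathematically ideal chains — it validates
the estimators and the model's large-separation behavior, not any
solvent physics.  The dilute bead-spring runs add excluded volume,
bonded stiffness and Theta-point attraction, i.e. realistic local
structure on an ideal global scaffold; they do not include inter-chain
packing, solvent-mediated hydrodynamics, or melt entanglement.  Passing
tests therefore demonstrate that the correlation model recovers chain
size from data whose coil-scale statistics are Gaussian; they say
nothing about chains under good- or poor-solvent conditions, about
polydisperse samples, or about instrument resolution effects, all of
which are out of scope.

## Known limitations

* The correlation model is monodisperse and strictly Gaussian
  (fractal exponent 2); excluded-volume form factors are not provided.
* The model's finite origin is a regularization, not a microstructure
  model: fits to data including sub-monomer separations are
  intentionally unsupported by the defaults.
* The measured pair density of a finite discrete chain exceeds any
  continuum model's counting precision near the origin; at ~5e7-pair
  statistics a reduced chi-square against the model is dominated by
  that finite-N, small-r systematic (the model is validated through Rg
  recovery and large-separation agreement instead).
* The bond route to Rg is biased for locally stiff chains (see above).
* The MD engine integrates isolated chains by design; periodic-box
  many-chain dynamics with inter-chain forces is out of scope (the
  builder only generates such configurations).
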