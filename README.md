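# polysesans

Real-space correlation functions of Gaussian polymer chains for
spin-echo small-angle neutron scattering (SESANS), as a fit-ready model
suite — plus the simulation and estimation machinery that validates
them.

## Who this is for

SESANS encodes structure in the neutron polarization `P(z)` versus
spin-echo length `z` instead of intensity versus `Q`.  For Gaussian
(ideal) polymer chains the textbook route into real space fails: the
Debye form factor decays as `Q^-2`, its inverse Fourier transform
diverges like `1/r` at the origin, and the Hankel projection of the
truncated intensity diverges at `z -> 0` — so there was no normalizable
real-space model to fit polymer SESANS data with.  This package
provides one, for scattering scientists analyzing polymer or
biomacromolecule SESANS spectra and for simulators validating
coarse-grained chain models.

## The model

With `eta = r/Rg`, `zeta = z/Rg`, `c = zeta^2/4` and the shape functions

    g(x) = sqrt(pi) (1/x + 2x) erfc(x) - 2 exp(-x^2)
    f(x) = (1 + x) E1(x) - exp(-x)

the suite is

| quantity | closed form | property |
|---|---|---|
| form factor | `F = 2(e^{-x} - 1 + x)/x^2`, `x = Q^2 Rg^2` | Debye function |
| divergent correlation | `gamma_div ∝ g(eta/2)` | inverse FT of `F`; `~1/r` at 0 |
| non-divergent correlation | `gamma_auto = [g(eta/2) - 4 g(2 eta)]/12` | finite, `gamma_auto(0) = 1` |
| projected correlation | `G0 = [f(c) - f(16c)] / (4 ln 2)` | Abel transform of `gamma_auto`; `G0(0) = 1` |
| polarization | `P(z) = exp[Sigma (G0(z) - 1)]` | multiple scattering; `P(inf) = e^{-Sigma}` |

`gamma_auto` agrees with the divergent correlation to better than 1%
for `r >= Rg` and differs only inside the coil, where the divergent
measure over contour separations is regularized into an integrable one.
The opacity `Sigma = lambda^2 l n_c phi(1-phi)(beta_H-beta_D)^2 N^2
ln(2) / (8 pi Rg^2)` collapses all instrument and contrast constants
into one dimensionless number.  Derivations, assumptions and numerical
choices are documented in [docs/methods.md](docs/methods.md).

Alongside the models: Fourier/Abel/Hankel transform utilities, an
ideal-chain sampler, a FENE/Lennard-Jones bead-spring Langevin engine
for dilute Theta-condition chains (reduced units, `T_Theta = 3.18`),
four independent radius-of-gyration estimators, and least-squares fits
of `gamma(r)`, `F(Q)` and `P(z)` with `Rg` as the fit parameter.

## Worked example

Simulate dilute Theta-condition bead-spring chains, estimate their
intra-chain correlation, and fit it for `Rg`:

```python
import numpy as np
import polysesans as ps

cfg = ps.MDConfig(seed=7, schedule=ps.Schedule(100_000, 100_000, 1_000))
ens = ps.run_langevin(cfg, ps.build_initial_ensemble(8, 100, seed=8))

rg = ps.ensemble_rg(ens)
curve = ps.gamma_from_trajectory(ens, ps.default_gamma_bins(rg.value))
fit = ps.fit_gamma(curve, init=rg.value, r_min=3.0)  # skip monomer-scale structure

print(f"kinetic T  : {ens.kinetic_temps.mean():.4f}")
print(f"direct Rg  : {rg.value:.3f} +/- {rg.stderr:.3f}")
print(f"fitted Rg  : {fit.Rg_hat:.3f} +/- {fit.Rg_stderr:.3f}")
print(f"deviation  : {abs(fit.Rg_hat - rg.value) / rg.value * 100:.2f}%")
```

Output (seeds as shown):

    kinetic T  : 3.1787
    direct Rg  : 5.238 +/- 0.090
    fitted Rg  : 5.111 +/- 0.021
    deviation  : 2.42%

The thermostat holds the Theta temperature 3.18 to better than 0.1%;
the radius of gyration fitted from the real-space correlation agrees
with the direct coordinate-based value to ~2.4% on this short run
(well under the 3.5% tolerance the full validation enforces; the full
protocol runs 20 chains five times longer).  A SESANS spectrum is
fit the same way:

```python
m = ps.GaussianChainModel(Rg=15.0)
z = np.linspace(0.5, 90, 40)
spectrum = ps.Curve(axis="z", grid=z, values=ps.polarization(z, m, opacity=0.4))
res = ps.fit_sesans(spectrum)          # -> Rg_hat = 15.0, opacity_hat = 0.4
```

There is also a CLI: `polysesans simulate | gamma | formfactor |
project | fit | validate` (see `polysesans --help`), where `validate`
runs the whole simulate → estimate → fit → report battery from a JSON
config.

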