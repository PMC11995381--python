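"""Chain-ensemble generation: ideal-chain sampling and bead-spring Langevin MD.

Two generators produce the ensembles used to validate the analytic models:

* :func:`sample_ideal_ensemble` draws ideal (phantom) Gaussian chains
  directly -- independent isotropic Gaussian bond vectors with
  ``<bond^2> = b^2`` -- which is exact and fast.
* :func:`run_langevin` integrates the coarse-grained bead-spring model:
  FENE bonds (stiffness ``K``, maximum extension ``r0``) plus a truncated
  and shifted attractive Lennard-Jones potential between non-bonded
  beads, thermostatted by Langevin dynamics with friction ``Gamma`` and
  fluctuation-dissipation-balanced white noise.  At the Theta temperature
  of this force field (``T = 3.18`` in reduced Lennard-Jones units) dilute
  chains reproduce ideal Gaussian statistics.

Reduced units throughout: ``sigma = epsilon = m = k_B = 1``; time unit
``tau = sigma sqrt(m / epsilon)``.

The integrator is the Gronbech-Jensen/Farago (GJF) discretization of
Langevin dynamics: a velocity-Verlet-based step with the friction and a
single white-noise impulse applied per step, whose half-step velocity
satisfies the fluctuation-dissipation balance exactly for harmonic modes
at any time step (so the measured kinetic temperature is free of the
usual O(dt^2) stiff-bond bias).  With the friction switched off it
reduces exactly to velocity Verlet, which is how the NVE
energy-conservation limit is tested.  In the default dilute mode every
chain is an isolated molecule coupled only to the heat bath -- the cheap
emulation of a dilute Theta solution -- and each chain consumes its own
counter-derived random stream, so results for chain ``i`` do not depend
on how many chains are run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Optional, Tuple, Union

import numpy as np
from numba import njit

__all__ = [
    "Schedule",
    "MDConfig",
    "ChainEnsemble",
    "SimulationError",
    "PackingError",
    "sample_ideal_chain",
    "sample_ideal_ensemble",
    "lj_potential",
    "fene_bond_potential",
    "bead_spring_forces",
    "run_langevin",
    "run_nve",
    "build_initial_ensemble",
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
]


class SimulationError(RuntimeError):
    """Integration failure (bond blow-up or non-finite coordinates)."""


class PackingError(RuntimeError):
    """Initial-configuration builder could not place the chains."""


@dataclass(frozen=True)
class Schedule:
    """Step counts of an MD run: equilibration, production, dump interval."""

    equilibration: int = 50_000
    production: int = 50_000
    dump_every: int = 1_000

    def __post_init__(self) -> None:
        if self.production < 1 or self.dump_every < 1 or self.equilibration < 0:
            raise ValueError("invalid schedule")


@dataclass(frozen=True)
class MDConfig:
    """Force-field, thermostat and schedule parameters of the bead-spring model.

    Defaults are the standard Kremer-Grest-type choices for this model:
    ``K = 30``, ``r0 = 1.5``, LJ cutoff ``2.5 sigma`` (shifted to zero at
    the cutoff), ``Gamma = 0.5``, ``dt = 0.006`` and the Theta temperature
    ``T = 3.18``.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    lj_cutoff: float = 2.5
    K: float = 30.0
    r0: float = 1.5
    Gamma: float = 0.5
    dt: float = 0.006
    T: float = 3.18
    seed: int = 0
    schedule: Schedule = field(default_factory=Schedule)

    def __post_init__(self) -> None:
        if self.r0 <= self.sigma:
            raise ValueError("r0 must exceed sigma")
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.lj_cutoff < 2 ** (1 / 6) * self.sigma:
            raise ValueError("lj_cutoff must be at least the LJ minimum 2^(1/6) sigma")


@dataclass
class ChainEnsemble:
    """Trajectory container: ``frames x chains x beads x 3`` coordinates.

    ``box`` (if set) holds periodic box edge lengths; ``time_per_frame``
    is the simulated time between stored frames.  ``kinetic_temps`` is
    filled by :func:`run_langevin` with the per-frame mean kinetic
    temperature (useful for thermostat diagnostics).
    """

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None
    time_per_frame: float = 0.0
    kinetic_temps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 4 or self.coordinates.shape[-1] != 3:
            raise ValueError("coordinates must have shape (frames, chains, beads, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            bonds = np.linalg.norm(np.diff(self.coordinates, axis=2), axis=-1)
            if bonds.size and np.any(self.box <= 2.0 * bonds.max()):
                raise ValueError("box edges must exceed twice the maximum bond length")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_chains(self) -> int:
        return self.coordinates.shape[1]

    @property
    def beads_per_chain(self) -> int:
        return self.coordinates.shape[2]


# ---------------------------------------------------------------------------
# ideal-chain sampling
# ---------------------------------------------------------------------------

def sample_ideal_chain(
    beads: int, b: float, seed: Union[int, np.random.Generator] = 0
) -> np.ndarray:
    """Draw one ideal chain: independent isotropic Gaussian bonds.

    Bond vectors have ``<bond^2> = b^2`` (per-component standard deviation
    ``b / sqrt(3)``); the first bead sits at the origin.
    """
    if beads < 2:
        raise ValueError("an ideal chain needs at least 2 beads")
    if b <= 0:
        raise ValueError("bond length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bonds = rng.normal(0.0, b / math.sqrt(3.0), size=(beads - 1, 3))
    x = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
    return x


def sample_ideal_ensemble(
    chains: int, beads: int, b: float = 1.0, seed: int = 0, frames: int = 1
) -> ChainEnsemble:
    """Draw an ensemble of independent ideal chains (one or more frames)."""
    rng = np.random.default_rng(seed)
    bonds = rng.normal(0.0, b / math.sqrt(3.0), size=(frames, chains, beads - 1, 3))
    x = np.concatenate(
        [np.zeros((frames, chains, 1, 3)), np.cumsum(bonds, axis=2)], axis=2
    )
    return ChainEnsemble(coordinates=x)


# ---------------------------------------------------------------------------
# potentials (reference implementations; the MD kernel inlines the same math)
# ---------------------------------------------------------------------------

def lj_potential(r, cfg: MDConfig):
    """Truncated-and-shifted 12-6 Lennard-Jones pair potential.

    ``U(r) = 4 eps [(sig/r)^12 - (sig/r)^6] - U_cut`` for ``r < lj_cutoff``
    and exactly 0 beyond, with ``U_cut`` the unshifted value at the cutoff
    (so the potential is continuous and vanishes there).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ potential is singular at r = 0")
    sr6 = (cfg.sigma / r) ** 6
    rc6 = (cfg.sigma / cfg.lj_cutoff) ** 6
    shift = 4.0 * cfg.epsilon * (rc6 * rc6 - rc6)
    u = np.where(r < cfg.lj_cutoff, 4.0 * cfg.epsilon * (sr6 * sr6 - sr6) - shift, 0.0)
    return u if u.ndim else float(u)


def fene_bond_potential(r, cfg: MDConfig):
    """FENE bond potential plus its purely repulsive (WCA) core.

    ``U(r) = -K r0^2/2 ln[1 - (r/r0)^2] + U_WCA(r)`` where the WCA part is
    the 12-6 potential truncated at ``2^{1/6} sigma`` and shifted up by
    ``epsilon`` (zero beyond the truncation).  Diverges as ``r -> r0``;
    evaluation at ``r >= r0`` is an infinite-extension error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond potential is singular at r = 0")
    if np.any(r >= cfg.r0):
        raise ValueError(
            f"FENE bond evaluated at r >= r0 = {cfg.r0}: the bond potential is "
            "infinite beyond the maximum extension"
        )
    fene = -0.5 * cfg.K * cfg.r0**2 * np.log1p(-((r / cfg.r0) ** 2))
    sr6 = (cfg.sigma / r) ** 6
    wca = np.where(
        r < 2 ** (1 / 6) * cfg.sigma,
        4.0 * cfg.epsilon * (sr6 * sr6 - sr6) + cfg.epsilon,
        0.0,
    )
    u = fene + wca
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _chain_forces(x, F, K, r0, eps, sig, rc, nbr_i, nbr_j, n_nbr):
    """Forces and potential energy of one isolated chain.

    Bonds (consecutive beads): FENE + WCA.  Non-bonded pairs from the
    neighbor list: attractive LJ truncated at ``rc`` and shifted to zero.
    Returns (U, ok); ok=False when a bond reached r0.
    """
    B = x.shape[0]
    F[:] = 0.0
    U = 0.0
    r02 = r0 * r0
    sig2 = sig * sig
    wca2 = 2.0 ** (1.0 / 3.0) * sig2
    rc2 = rc * rc
    src6 = (sig2 / rc2) ** 3
    shift = 4.0 * eps * (src6 * src6 - src6)
    for i in range(B - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return 0.0, False
        U += -0.5 * K * r02 * math.log(1.0 - r2 / r02)
        fmag = -K / (1.0 - r2 / r02)  # dU/dr / r for the FENE part
        if r2 < wca2:
            sr6 = (sig2 / r2) ** 3
            U += 4.0 * eps * (sr6 * sr6 - sr6) + eps
            fmag += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        F[i + 1, 0] += fmag * dx
        F[i + 1, 1] += fmag * dy
        F[i + 1, 2] += fmag * dz
        F[i, 0] -= fmag * dx
        F[i, 1] -= fmag * dy
        F[i, 2] -= fmag * dz
    for k in range(n_nbr):
        i = nbr_i[k]
        j = nbr_j[k]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            sr6 = (sig2 / r2) ** 3
            U += 4.0 * eps * (sr6 * sr6 - sr6) - shift
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            F[j, 0] += fmag * dx
            F[j, 1] += fmag * dy
            F[j, 2] += fmag * dz
            F[i, 0] -= fmag * dx
            F[i, 1] -= fmag * dy
            F[i, 2] -= fmag * dz
    return U, True


@njit(cache=True)
def _build_neighbor_list(x, cutoff2, nbr_i, nbr_j):
    """All intra-chain pairs |i-j| >= 2 within sqrt(cutoff2); O(B^2)."""
    B = x.shape[0]
    n = 0
    for i in range(B - 2):
        for j in range(i + 2, B):
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            if dx * dx + dy * dy + dz * dz < cutoff2:
                nbr_i[n] = i
                nbr_j[n] = j
                n += 1
    return n


@njit(cache=True)
def _run_chain(
    x, nsteps, dt, T, fric, K, r0, eps, sig, rc, skin, dump_every, seed, frames, ktemps
):
    """Langevin integration of one isolated chain (GJF scheme).

    Velocity-Verlet-based splitting with the friction and the white noise
    applied once per step (Gronbech-Jensen/Farago discretization, m = 1):

        a = (1 - Gamma dt/2) / (1 + Gamma dt/2),  b = 1 / (1 + Gamma dt/2)
        beta ~ N(0, 2 Gamma T dt)  per component
        x' = x + b dt v + (b dt^2 / 2) F + (b dt / 2) beta
        v' = a v + (dt / 2)(a F + F') + b beta

    The fluctuation-dissipation balance is exact for the half-step
    velocity u = (x' - x) / (sqrt(b) dt), whose mean square equals the
    target temperature for harmonic modes at any time step; the recorded
    kinetic temperatures use u.  With ``fric = 0`` the scheme reduces
    exactly to velocity Verlet (the NVE limit).

    Returns (status, step): status 0 = ok, 1 = bond reached r0,
    2 = non-finite coordinates.  Frames (and the mean kinetic temperature
    over each dump interval) are recorded every ``dump_every`` steps.
    """
    np.random.seed(seed)
    B = x.shape[0]
    v = np.random.standard_normal((B, 3)) * math.sqrt(T)
    F = np.zeros((B, 3))
    maxpairs = B * (B - 1) // 2
    nbr_i = np.empty(maxpairs, dtype=np.int32)
    nbr_j = np.empty(maxpairs, dtype=np.int32)
    x_ref = x.copy()
    n_nbr = _build_neighbor_list(x, (rc + skin) * (rc + skin), nbr_i, nbr_j)
    U, ok = _chain_forces(x, F, K, r0, eps, sig, rc, nbr_i, nbr_j, n_nbr)
    if not ok:
        return 1, 0
    a = (1.0 - 0.5 * fric * dt) / (1.0 + 0.5 * fric * dt)
    b = 1.0 / (1.0 + 0.5 * fric * dt)
    noise_std = math.sqrt(2.0 * fric * T * dt)
    sqrtb_dt = math.sqrt(b) * dt
    ke_acc = 0.0
    ke_n = 0
    iframe = 0
    for step in range(1, nsteps + 1):
        if noise_std > 0.0:
            beta = np.random.standard_normal((B, 3)) * noise_std
        else:
            beta = np.zeros((B, 3))
        ke = 0.0
        for i in range(B):
            for d in range(3):
                dxs = b * dt * v[i, d] + 0.5 * b * dt * dt * F[i, d] + 0.5 * b * dt * beta[i, d]
                x[i, d] += dxs
                u = dxs / sqrtb_dt
                ke += u * u
                # first half of the velocity update (needs old F)
                v[i, d] = a * v[i, d] + 0.5 * dt * a * F[i, d] + b * beta[i, d]
        ke_acc += ke
        ke_n += 1
        # displacement-triggered neighbor-list rebuild
        dmax2 = 0.0
        for i in range(B):
            dx = x[i, 0] - x_ref[i, 0]
            dy = x[i, 1] - x_ref[i, 1]
            dz = x[i, 2] - x_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > dmax2:
                dmax2 = d2
        if dmax2 > 0.25 * skin * skin:
            x_ref[:] = x
            n_nbr = _build_neighbor_list(x, (rc + skin) * (rc + skin), nbr_i, nbr_j)
        U, ok = _chain_forces(x, F, K, r0, eps, sig, rc, nbr_i, nbr_j, n_nbr)
        if not ok:
            return 1, step
        for i in range(B):
            for d in range(3):
                v[i, d] += 0.5 * dt * F[i, d]
        if step % dump_every == 0:
            if not math.isfinite(x[0, 0]):
                return 2, step
            frames[iframe] = x
            ktemps[iframe] = ke_acc / (ke_n * 3.0 * B)
            ke_acc = 0.0
            ke_n = 0
            iframe += 1
    if not math.isfinite(x[0, 0]):
        return 2, nsteps
    return 0, nsteps


@njit(cache=True)
def _nve_chain(x, v, nsteps, dt, K, r0, eps, sig, rc, skin, energies):
    """Velocity-Verlet (NVE) integration of one chain, recording total energy."""
    B = x.shape[0]
    F = np.zeros((B, 3))
    maxpairs = B * (B - 1) // 2
    nbr_i = np.empty(maxpairs, dtype=np.int32)
    nbr_j = np.empty(maxpairs, dtype=np.int32)
    x_ref = x.copy()
    n_nbr = _build_neighbor_list(x, (rc + skin) * (rc + skin), nbr_i, nbr_j)
    U, ok = _chain_forces(x, F, K, r0, eps, sig, rc, nbr_i, nbr_j, n_nbr)
    if not ok:
        return 1
    half = 0.5 * dt
    for step in range(nsteps):
        for i in range(B):
            for d in range(3):
                v[i, d] += half * F[i, d]
                x[i, d] += dt * v[i, d]
        dmax2 = 0.0
        for i in range(B):
            dx = x[i, 0] - x_ref[i, 0]
            dy = x[i, 1] - x_ref[i, 1]
            dz = x[i, 2] - x_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > dmax2:
                dmax2 = d2
        if dmax2 > 0.25 * skin * skin:
            x_ref[:] = x
            n_nbr = _build_neighbor_list(x, (rc + skin) * (rc + skin), nbr_i, nbr_j)
        U, ok = _chain_forces(x, F, K, r0, eps, sig, rc, nbr_i, nbr_j, n_nbr)
        if not ok:
            return 1
        ke = 0.0
        for i in range(B):
            for d in range(3):
                v[i, d] += half * F[i, d]
                ke += v[i, d] * v[i, d]
        energies[step] = U + 0.5 * ke
    return 0


def bead_spring_forces(coords: np.ndarray, cfg: MDConfig) -> Tuple[np.ndarray, float]:
    """Forces and potential energy of one chain configuration (beads x 3).

    Python-facing wrapper around the MD force kernel; used for gradient
    consistency checks and energy diagnostics.
    """
    x = np.ascontiguousarray(coords, dtype=float)
    B = x.shape[0]
    F = np.zeros_like(x)
    nbr_i = np.empty(B * (B - 1) // 2, dtype=np.int32)
    nbr_j = np.empty_like(nbr_i)
    n = _build_neighbor_list(x, (cfg.lj_cutoff + 1.0) ** 2, nbr_i, nbr_j)
    U, ok = _chain_forces(
        x, F, cfg.K, cfg.r0, cfg.epsilon, cfg.sigma, cfg.lj_cutoff, nbr_i, nbr_j, n
    )
    if not ok:
        raise SimulationError("a bond exceeds the FENE maximum extension r0")
    return F, U


def run_nve(
    cfg: MDConfig, coords: np.ndarray, nsteps: int, seed: int = 0,
    bonded_only: bool = False,
) -> np.ndarray:
    """Frictionless (NVE) velocity-Verlet run of one chain; returns the
    total-energy series.

    This is the ``Gamma = 0``, noise-off limit of the Langevin integrator,
    used to verify energy conservation of the deterministic part of the
    scheme.  Initial velocities are Maxwell-Boltzmann at ``cfg.T``.
    ``bonded_only`` switches the non-bonded pair interactions off, leaving
    the smooth FENE+WCA bond Hamiltonian (the truncated LJ pair force is
    discontinuous at the cutoff, which makes exact long-time conservation
    impossible for any integrator).
    """
    x = np.ascontiguousarray(coords, dtype=float)
    rng = np.random.default_rng(seed)
    v = np.ascontiguousarray(rng.normal(0.0, math.sqrt(cfg.T), size=x.shape))
    energies = np.empty(nsteps)
    # shrinking the pair cutoff to zero reach disables non-bonded terms
    lj_cutoff = 1e-12 if bonded_only else cfg.lj_cutoff
    status = _nve_chain(
        x, v, nsteps, cfg.dt, cfg.K, cfg.r0, cfg.epsilon, cfg.sigma,
        lj_cutoff, 0.4 * cfg.sigma, energies,
    )
    if status != 0:
        raise SimulationError("bond reached r0 during NVE integration")
    return energies


def run_langevin(
    cfg: MDConfig,
    initial: ChainEnsemble,
    dilute: bool = True,
    include_equilibration_frames: bool = False,
) -> ChainEnsemble:
    """Integrate the bead-spring model with the BAOAB Langevin thermostat.

    Takes the last frame of ``initial`` as the starting configuration,
    runs ``schedule.equilibration`` discarded steps followed by
    ``schedule.production`` recorded steps (frames every
    ``schedule.dump_every``), and returns the production trajectory with
    per-frame kinetic temperatures attached.

    In the default dilute mode chains are isolated molecules: no
    inter-chain interactions, no periodic box, one independent
    counter-derived noise stream per chain (so the trajectory of chain
    ``i`` is independent of the total number of chains).  Bit-reproducible
    for a given config on one platform.

    Raises
    ------
    SimulationError
        If a bond reaches the FENE maximum extension or coordinates go
        non-finite, naming the chain and step.
    """
    if not dilute:
        raise NotImplementedError(
            "only the dilute (isolated-chain) mode is implemented; it is the "
            "validation default -- inter-chain interactions are negligible at "
            "the dilutions this package emulates"
        )
    x0 = initial.coordinates[-1]
    nchains, B = x0.shape[0], x0.shape[1]
    # starting-configuration preconditions
    bonds = np.linalg.norm(np.diff(x0, axis=1), axis=-1)
    if np.any(bonds >= cfg.r0):
        raise SimulationError("initial configuration has a bond >= r0")
    sched = cfg.schedule
    if include_equilibration_frames:
        nsteps = sched.equilibration + sched.production
        skip = 0
    else:
        nsteps = sched.equilibration + sched.production
        skip = sched.equilibration // sched.dump_every
    nframes_tot = nsteps // sched.dump_every
    frames = np.empty((nchains, nframes_tot, B, 3))
    ktemps = np.empty((nchains, nframes_tot))
    seeds = np.random.SeedSequence(cfg.seed).generate_state(max(nchains, 2))
    skin = 0.4 * cfg.sigma
    for c in range(nchains):
        x = np.ascontiguousarray(x0[c].copy())
        status, step = _run_chain(
            x,
            nsteps,
            cfg.dt,
            cfg.T,
            cfg.Gamma,
            cfg.K,
            cfg.r0,
            cfg.epsilon,
            cfg.sigma,
            cfg.lj_cutoff,
            skin,
            sched.dump_every,
            int(seeds[c] & 0x7FFFFFFF),
            frames[c],
            ktemps[c],
        )
        if status == 1:
            raise SimulationError(f"chain {c}: bond reached r0 at step {step}")
        if status == 2:
            raise SimulationError(f"chain {c}: non-finite coordinates at step {step}")
    out = np.transpose(frames[:, skip:], (1, 0, 2, 3))
    return ChainEnsemble(
        coordinates=out,
        time_per_frame=cfg.dt * sched.dump_every,
        kinetic_temps=ktemps[:, skip:].mean(axis=0),
    )


# ---------------------------------------------------------------------------
# initial configurations
# ---------------------------------------------------------------------------

def build_initial_ensemble(
    chains: int,
    beads: int,
    box: Optional[np.ndarray] = None,
    seed: int = 0,
    bond_length: float = 0.961,
    min_separation: float = 0.8,
    max_retries: int = 200,
) -> ChainEnsemble:
    """Grow chains as constrained random walks with near-equilibrium bonds.

    Each bond has the length of the FENE+WCA minimum (~0.961 sigma); a new
    bead is re-drawn until it clears every earlier bead of the same chain
    by ``min_separation`` (minimum-image when a box is given, in which
    case other chains are cleared too).  Chains in a box are started at
    random positions; without a box, chains are placed on a wide lattice
    so they never overlap (the dilute convention).

    Raises
    ------
    PackingError
        When the requested density leaves no room (upfront check) or
        placement keeps failing after bounded retries.
    """
    rng = np.random.default_rng(seed)
    if box is not None:
        box = np.asarray(box, dtype=float)
        if chains * beads * 1.0 > 0.5 * np.prod(box):
            raise PackingError(
                f"{chains} chains x {beads} beads cannot fit in box {box} "
                "below half of close packing"
            )
    coords = np.empty((chains, beads, 3))
    placed: list[np.ndarray] = []
    for c in range(chains):
        for attempt in range(max_retries):
            chain = _grow_chain(beads, bond_length, min_separation, rng, box, placed)
            if chain is not None:
                break
        else:
            raise PackingError(f"failed to place chain {c} after {max_retries} retries")
        if box is not None:
            placed.append(chain)
        else:
            # dilute: keep chains far apart on a coarse lattice
            offset = np.array([c * (4.0 * bond_length * beads), 0.0, 0.0])
            chain = chain + offset
        coords[c] = chain
    return ChainEnsemble(coordinates=coords[None], box=box)


def _grow_chain(beads, bond_length, min_sep, rng, box, placed):
    start = rng.uniform(0, box, size=3) if box is not None else np.zeros(3)
    x = np.empty((beads, 3))
    x[0] = start
    min_sep2 = min_sep * min_sep
    for i in range(1, beads):
        for _ in range(100):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = x[i - 1] + bond_length * u
            prev = x[: max(i - 1, 0)]  # bead i-1 is bonded; clearance applies further back
            if _clear(cand, prev, min_sep2, box) and all(
                _clear(cand, other, min_sep2, box) for other in placed
            ):
                x[i] = cand
                break
        else:
            return None
    return x


def _clear(cand, others, min_sep2, box):
    if len(others) == 0:
        return True
    d = others - cand
    if box is not None:
        d -= box * np.round(d / box)
    return bool(np.min(np.einsum("ij,ij->i", d, d)) > min_sep2)


# ---------------------------------------------------------------------------
# trajectory text formats
# ---------------------------------------------------------------------------

def write_xyz(ensemble: ChainEnsemble, path_or_file: Union[str, IO[str]]) -> None:
    """Write an XYZ-like text trajectory (one block per frame).

    The comment line records ``chains=<C> beads=<B> time=<t>`` so the
    reader can restore the (chains, beads) structure; atoms are labeled by
    chain index.
    """
    fh, close = _open(path_or_file, "w")
    try:
        F, C, B, _ = ensemble.coordinates.shape
        for fidx in range(F):
            fh.write(f"{C * B}\n")
            fh.write(
                f"chains={C} beads={B} time={fidx * ensemble.time_per_frame:.6g}\n"
            )
            for c in range(C):
                for bead in ensemble.coordinates[fidx, c]:
                    fh.write(f"C{c} {bead[0]:.10g} {bead[1]:.10g} {bead[2]:.10g}\n")
    finally:
        if close:
            fh.close()


def read_xyz(path_or_file: Union[str, IO[str]]) -> ChainEnsemble:
    """Read a trajectory written by :func:`write_xyz`."""
    fh, close = _open(path_or_file, "r")
    try:
        frames = []
        tpf = 0.0
        line = fh.readline()
        while line:
            natoms = int(line)
            header = dict(kv.split("=") for kv in fh.readline().split())
            C, B = int(header["chains"]), int(header["beads"])
            if C * B != natoms:
                raise ValueError("atom count does not match chains*beads")
            if len(frames) == 1:
                tpf = float(header.get("time", 0.0))
            xyz = np.empty((natoms, 3))
            for i in range(natoms):
                parts = fh.readline().split()
                xyz[i] = [float(p) for p in parts[1:4]]
            frames.append(xyz.reshape(C, B, 3))
            line = fh.readline()
        return ChainEnsemble(coordinates=np.array(frames), time_per_frame=tpf)
    finally:
        if close:
            fh.close()


def write_lammps_dump(ensemble: ChainEnsemble, path_or_file: Union[str, IO[str]]) -> None:
    """Write the LAMMPS-dump-style subset: TIMESTEP / NUMBER OF ATOMS /
    BOX BOUNDS / ATOMS id mol x y z."""
    fh, close = _open(path_or_file, "w")
    try:
        F, C, B, _ = ensemble.coordinates.shape
        box = ensemble.box
        if box is None:
            lo = ensemble.coordinates.min(axis=(0, 1, 2)) - 1.0
            hi = ensemble.coordinates.max(axis=(0, 1, 2)) + 1.0
        else:
            lo, hi = np.zeros(3), box
        for fidx in range(F):
            fh.write("ITEM: TIMESTEP\n%d\n" % fidx)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % (C * B))
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"{lo[d]:.10g} {hi[d]:.10g}\n")
            fh.write("ITEM: ATOMS id mol x y z\n")
            aid = 1
            for c in range(C):
                for bead in ensemble.coordinates[fidx, c]:
                    fh.write(
                        f"{aid} {c + 1} {bead[0]:.10g} {bead[1]:.10g} {bead[2]:.10g}\n"
                    )
                    aid += 1
    finally:
        if close:
            fh.close()


def read_lammps_dump(path_or_file: Union[str, IO[str]]) -> ChainEnsemble:
    """Read the LAMMPS-dump-style subset written by :func:`write_lammps_dump`.

    Beads are regrouped into chains by their ``mol`` column; every
    molecule must have the same bead count.
    """
    fh, close = _open(path_or_file, "r")
    try:
        frames = []
        line = fh.readline()
        while line:
            if not line.startswith("ITEM: TIMESTEP"):
                raise ValueError(f"expected ITEM: TIMESTEP, got {line!r}")
            fh.readline()
            assert fh.readline().startswith("ITEM: NUMBER OF ATOMS")
            natoms = int(fh.readline())
            assert fh.readline().startswith("ITEM: BOX BOUNDS")
            for _ in range(3):
                fh.readline()
            cols = fh.readline().split()[2:]
            idx = {name: k for k, name in enumerate(cols)}
            data = np.empty((natoms, len(cols)))
            for i in range(natoms):
                data[i] = [float(p) for p in fh.readline().split()]
            order = np.argsort(data[:, idx["id"]], kind="stable")
            data = data[order]
            mols = data[:, idx["mol"]].astype(int)
            C = len(np.unique(mols))
            if natoms % C:
                raise ValueError("unequal bead counts per molecule")
            xyz = data[:, [idx["x"], idx["y"], idx["z"]]].reshape(C, natoms // C, 3)
            frames.append(xyz)
            line = fh.readline()
        return ChainEnsemble(coordinates=np.array(frames))
    finally:
        if close:
            fh.close()


def _open(path_or_file, mode):
    if isinstance(path_or_file, str):
        return open(path_or_file, mode), True
    return path_or_file, False
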