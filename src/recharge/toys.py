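"""Self-contained statistical-mechanics fixtures.

A Metropolis Monte Carlo sampler for small charged Lennard-Jones fluids
(minimum-image, truncated Coulomb — a fixture-only approximation, no Ewald)
that emits everything :class:`~recharge.reweight.Ensemble` needs: per-frame
energies, analytic charge-derivatives, virial pressure-tensor diagonals and
structural observables. Plus generators for noisy stationary tension series
and for particle distributions carrying a known planted free-energy profile.

These stand in for the MD engine: they validate estimators and the charge
optimizer, not force-field physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import constants as const
from .errors import ValidationError
from .frames import FrameTable
from .interfacial import TensionSeries
from .reweight import Ensemble, MeanCI, reweight, reweighted_mean_ci, uniform_weights
from .topology import ChargeSet


@dataclass
class ToySystem:
    """Small periodic LJ+Coulomb fluid whose charges are ChargeSet parameters.

    ``charge_set`` supplies per-particle charges, the free-parameter groups
    (particles sharing one optimizable charge) and the frozen particles.
    """

    charge_set: ChargeSet
    box: np.ndarray                 # (3,) nm
    sigma: np.ndarray               # (n,) nm
    epsilon: np.ndarray             # (n,) kJ/mol
    temperature: float = const.DEFAULT_TEMPERATURE
    cutoff: float | None = None     # nm; default min(box)/2
    external: Callable[[np.ndarray], np.ndarray] | None = None  # per-particle U

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.box.min() <= 2.0 * self.sigma.max():
            raise ValidationError("box must exceed 2*max(sigma) in every dimension")
        if self.cutoff is None:
            self.cutoff = float(self.box.min()) / 2.0

    @property
    def n_particles(self) -> int:
        return self.charge_set.n_atoms

    @property
    def beta(self) -> float:
        return const.beta_kj(self.temperature)

    def with_charges(self, cs: ChargeSet) -> "ToySystem":
        return ToySystem(
            cs, self.box.copy(), self.sigma, self.epsilon,
            self.temperature, self.cutoff, self.external,
        )


def two_species_fluid(
    n_pos: int,
    n_neg: int,
    q: float,
    box: float | tuple = 2.5,
    sigma: float = 0.3,
    epsilon: float = 0.5,
    temperature: float = const.DEFAULT_TEMPERATURE,
) -> ToySystem:
    """Symmetric two-species fluid: n_pos particles at +q, n_neg at -q*n_pos/n_neg,
    each species one equivalence group (two free parameters, neutrality ties them)."""
    n = n_pos + n_neg
    q_neg = -q * n_pos / n_neg
    charges = np.array([q] * n_pos + [q_neg] * n_neg)
    cs = ChargeSet(
        atom_names=tuple(f"P{i:03d}" for i in range(n)),
        charges=charges,
        reference_charges=charges.copy(),
        equivalence_groups=(tuple(range(n_pos)), tuple(range(n_pos, n))),
    )
    box = np.full(3, box, dtype=float) if np.isscalar(box) else np.asarray(box)
    return ToySystem(
        cs, box, np.full(n, sigma), np.full(n, epsilon), temperature
    )


@dataclass
class ToyEnergyModel:
    """Exact quadratic Coulomb decomposition of toy-sampler frames.

    U(q) = U_LJ + U_ext + ke * [ sum_a p_a^2 S_aa + sum_{a<b} p_a p_b S_ab
                                 + sum_a p_a C_a + D ]
    with per-frame pair sums S (free-group x free-group), C (free x frozen)
    and D (frozen-frozen), so reweighting to any charge vector is exact.
    """

    u_static: np.ndarray            # (n_frames,) LJ + external, kJ/mol
    S: np.ndarray                   # (n_frames, P, P), 1/r pair sums
    C: np.ndarray                   # (n_frames, P)
    D: np.ndarray                   # (n_frames,)
    param_groups: list[np.ndarray]

    def _params(self, charges: np.ndarray) -> np.ndarray:
        return np.array([charges[g[0]] for g in self.param_groups])

    def potential(self, charges: np.ndarray) -> np.ndarray:
        p = self._params(charges)
        quad = np.einsum("a,fab,b->f", p, self.S, p)
        diag = np.einsum("a,faa->f", p**2, self.S)
        # S is stored symmetric-with-intra-diagonal: full quad counts cross
        # pairs twice and intra once via diagonal, so combine accordingly
        cross = (quad - diag) / 2.0
        return self.u_static + const.KE_COULOMB * (
            diag + cross + self.C @ p + self.D
        )

    def potential_gradient(self, charges: np.ndarray) -> np.ndarray:
        p = self._params(charges)
        diag = np.einsum("faa->fa", self.S)
        cross = np.einsum("fab,b->fa", self.S, p) - diag * p
        return const.KE_COULOMB * (2.0 * p * diag + cross + self.C)


def _pair_tables(sys: ToySystem):
    """Index bookkeeping: particle -> free param id (or -1), frozen charges."""
    groups = sys.charge_set.free_param_groups()
    pid = np.full(sys.n_particles, -1, dtype=int)
    for a, g in enumerate(groups):
        pid[g] = a
    frozen_q = np.where(pid < 0, sys.charge_set.charges, 0.0)
    return groups, pid, frozen_q


def _min_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    return dr - box * np.round(dr / box)


try:  # jit-compiled displacement sweep; falls back to pure python
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _mc_sweep(pos, sigma, epsilon, charges, box, cutoff2, beta, ke,
                  idx, disp, accept_u, burn_in, stride, frames_out):
        n = pos.shape[0]
        n_steps = idx.shape[0]
        accepted = 0
        frame = 0
        for s in range(n_steps):
            i = idx[s]
            du = 0.0
            nx = (pos[i, 0] + disp[s, 0]) % box[0]
            ny = (pos[i, 1] + disp[s, 1]) % box[1]
            nz = (pos[i, 2] + disp[s, 2]) % box[2]
            for j in range(n):
                if j == i:
                    continue
                # old contribution
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cutoff2:
                    sij = 0.5 * (sigma[i] + sigma[j])
                    eij = (epsilon[i] * epsilon[j]) ** 0.5
                    sr6 = (sij * sij / r2) ** 3
                    du -= 4.0 * eij * (sr6 * sr6 - sr6)
                    du -= ke * charges[i] * charges[j] / r2 ** 0.5
                # new contribution
                dx = pos[j, 0] - nx
                dy = pos[j, 1] - ny
                dz = pos[j, 2] - nz
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cutoff2:
                    sij = 0.5 * (sigma[i] + sigma[j])
                    eij = (epsilon[i] * epsilon[j]) ** 0.5
                    sr6 = (sij * sij / r2) ** 3
                    du += 4.0 * eij * (sr6 * sr6 - sr6)
                    du += ke * charges[i] * charges[j] / r2 ** 0.5
            if du <= 0.0 or accept_u[s] < np.exp(-beta * du):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                accepted += 1
            if s >= burn_in and (s - burn_in) % stride == stride - 1:
                for a in range(n):
                    frames_out[frame, a, 0] = pos[a, 0]
                    frames_out[frame, a, 1] = pos[a, 1]
                    frames_out[frame, a, 2] = pos[a, 2]
                frame += 1
        return accepted

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    _HAVE_NUMBA = False


def _particle_energy(sys, pos, i, charges):
    """Interaction energy of particle i with all others (+ its external term)."""
    dr = _min_image(pos - pos[i], sys.box)
    r2 = np.einsum("ij,ij->i", dr, dr)
    r2[i] = np.inf
    mask = r2 < sys.cutoff**2
    r = np.sqrt(r2[mask])
    sij = 0.5 * (sys.sigma[mask] + sys.sigma[i])
    eij = np.sqrt(sys.epsilon[mask] * sys.epsilon[i])
    sr6 = (sij / r) ** 6
    u = np.sum(4.0 * eij * (sr6**2 - sr6))
    u += const.KE_COULOMB * charges[i] * np.sum(charges[mask] / r)
    if sys.external is not None:
        u += float(np.sum(sys.external(pos[i : i + 1])))
    return u


def _frame_terms(sys, pos, pid, frozen_q, n_params):
    """Full O(n^2) per-frame quantities: LJ energy, Coulomb pair sums,
    virial pressure diagonals."""
    n = sys.n_particles
    iu, ju = np.triu_indices(n, k=1)
    dr = _min_image(pos[iu] - pos[ju], sys.box)
    r2 = np.einsum("ij,ij->i", dr, dr)
    mask = r2 < sys.cutoff**2
    iu, ju, dr, r2 = iu[mask], ju[mask], dr[mask], r2[mask]
    r = np.sqrt(r2)
    sij = 0.5 * (sys.sigma[iu] + sys.sigma[ju])
    eij = np.sqrt(sys.epsilon[iu] * sys.epsilon[ju])
    sr6 = (sij / r) ** 6
    u_lj = float(np.sum(4.0 * eij * (sr6**2 - sr6)))
    inv_r = 1.0 / r

    S = np.zeros((n_params, n_params))
    C = np.zeros(n_params)
    D = 0.0
    a, b = pid[iu], pid[ju]
    both = (a >= 0) & (b >= 0)
    np.add.at(S, (a[both], b[both]), inv_r[both])
    np.add.at(S, (b[both], a[both]), inv_r[both])
    intra = both & (a == b)
    # undo double count on the diagonal: each intra pair added twice above
    np.add.at(S, (a[intra], a[intra]), -inv_r[intra])
    free_frozen = (a >= 0) & (b < 0)
    np.add.at(C, a[free_frozen], frozen_q[ju[free_frozen]] * inv_r[free_frozen])
    frozen_free = (a < 0) & (b >= 0)
    np.add.at(C, b[frozen_free], frozen_q[iu[frozen_free]] * inv_r[frozen_free])
    neither = (a < 0) & (b < 0)
    D = float(np.sum(frozen_q[iu[neither]] * frozen_q[ju[neither]] * inv_r[neither]))

    charges = sys.charge_set.charges
    qq = charges[iu] * charges[ju]
    # -du/dr * r per pair
    w = 4.0 * eij * (12.0 * sr6**2 - 6.0 * sr6) + const.KE_COULOMB * qq * inv_r
    volume = float(np.prod(sys.box))
    kin = sys.n_particles * const.kt_kj(sys.temperature)
    p_diag = (kin + np.einsum("i,ij->j", w / r2, dr**2)) / volume
    p_diag = p_diag * const.KJ_PER_MOL_NM3_TO_BAR

    inv_r_cross = float(np.sum(inv_r[both & (a != b)]))
    u_coul = const.KE_COULOMB * float(np.sum(qq * inv_r))
    return u_lj, u_coul, S, C, D, p_diag, inv_r_cross, float(np.sum(inv_r))


def _initial_positions(sys: ToySystem, rng: np.random.Generator) -> np.ndarray:
    n = sys.n_particles
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.stack(
        np.meshgrid(*[np.arange(per_side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    rng.shuffle(grid)
    pos = (grid[:n] + 0.5) / per_side * sys.box
    return pos


def metropolis_sample(
    sys: ToySystem,
    n_steps: int,
    step_size: float = 0.2,
    seed: int | np.random.Generator = 0,
    *,
    burn_in_frac: float = 0.2,
    stride: int = 10,
    record_positions: bool = False,
) -> Ensemble:
    """Single-particle-displacement Metropolis sampling at fixed beta.

    Records, every ``stride`` accepted-or-rejected moves after burn-in:
    total/LJ/Coulomb energies, the exact Coulomb charge-decomposition (so
    the returned Ensemble reweights exactly), virial pressure diagonals
    (bar) and the structural observable ``inv_r_cross`` (sum of 1/r over
    unlike-free-group pairs, nm^-1 — charge-independent, charge-sensitive
    through the ensemble).
    """
    rng = np.random.default_rng(seed)
    groups, pid, frozen_q = _pair_tables(sys)
    n_params = len(groups)
    charges = sys.charge_set.charges
    pos = _initial_positions(sys, rng)

    # reject pathological overlaps at start
    if sys.n_particles > 1:
        iu, ju = np.triu_indices(sys.n_particles, k=1)
        dr = _min_image(pos[iu] - pos[ju], sys.box)
        if np.sqrt(np.min(np.einsum("ij,ij->i", dr, dr))) < 1e-6:
            raise ValidationError("overlapping initial coordinates")

    beta = sys.beta
    burn_in = int(burn_in_frac * n_steps)
    n_frames = max((n_steps - burn_in) // stride, 0)
    if n_frames < 2:
        raise ValidationError("n_steps too small for burn-in and stride")

    # pre-draw all randomness so the jitted and python paths are identical
    idx = rng.integers(0, sys.n_particles, size=n_steps)
    disp = rng.uniform(-step_size, step_size, size=(n_steps, 3))
    accept_u = rng.random(n_steps)

    frames_pos = np.empty((n_frames, sys.n_particles, 3))
    if _HAVE_NUMBA and sys.external is None:
        accepted = int(
            _mc_sweep(
                pos, sys.sigma, sys.epsilon, charges, sys.box,
                sys.cutoff**2, beta, const.KE_COULOMB,
                idx, disp, accept_u, burn_in, stride, frames_pos,
            )
        )
    else:
        accepted = 0
        frame = 0
        for step in range(n_steps):
            i = int(idx[step])
            old_u = _particle_energy(sys, pos, i, charges)
            old_pos = pos[i].copy()
            pos[i] = np.mod(pos[i] + disp[step], sys.box)
            new_u = _particle_energy(sys, pos, i, charges)
            du = new_u - old_u
            if du <= 0 or accept_u[step] < np.exp(-beta * du):
                accepted += 1
            else:
                pos[i] = old_pos
            if step >= burn_in and (step - burn_in) % stride == stride - 1:
                frames_pos[frame] = pos
                frame += 1

    u_static = np.empty(n_frames)
    u_total = np.empty(n_frames)
    u_lj_arr = np.empty(n_frames)
    u_coul_arr = np.empty(n_frames)
    S = np.empty((n_frames, n_params, n_params))
    C = np.empty((n_frames, n_params))
    D = np.empty(n_frames)
    press = np.empty((n_frames, 3))
    invr_cross = np.empty(n_frames)
    invr_tot = np.empty(n_frames)
    for frame in range(n_frames):
        u_lj, u_coul, s, c, d, p_diag, irc, irt = _frame_terms(
            sys, frames_pos[frame], pid, frozen_q, n_params
        )
        u_ext = (
            float(np.sum(sys.external(frames_pos[frame])))
            if sys.external is not None
            else 0.0
        )
        u_static[frame] = u_lj + u_ext
        u_lj_arr[frame] = u_lj
        u_coul_arr[frame] = u_coul
        u_total[frame] = u_lj + u_ext + u_coul
        S[frame], C[frame], D[frame] = s, c, d
        press[frame] = p_diag
        invr_cross[frame] = irc
        invr_tot[frame] = irt
    positions = list(frames_pos) if record_positions else None

    model = ToyEnergyModel(u_static, S, C, D, groups)
    obs = {
        "energy": u_total,
        "lj_energy": u_lj_arr,
        "coulomb_energy": u_coul_arr,
        "pxx": press[:, 0],
        "pyy": press[:, 1],
        "pzz": press[:, 2],
        "pressure": press.mean(axis=1),
        "inv_r_cross": invr_cross,
        "inv_r_total": invr_tot,
    }
    ens = Ensemble(
        beta=beta,
        base_charges=sys.charge_set,
        observables=obs,
        energy_model=model,
        base_energies=model.potential(charges),
        metadata={
            "acceptance_rate": accepted / n_steps,
            "n_steps": n_steps,
            "stride": stride,
            "burn_in": burn_in,
            "seed": repr(seed),
            "positions": positions,
        },
    )
    return ens


@dataclass
class OracleResult:
    direct: MeanCI
    reweighted: MeanCI
    ess_fraction: float

    @property
    def agree_within_ci(self) -> bool:
        combined = np.hypot(self.direct.ci95, self.reweighted.ci95)
        return abs(self.direct.mean - self.reweighted.mean) <= combined


def resimulation_oracle(
    sys: ToySystem,
    q_a: ChargeSet,
    q_b: ChargeSet,
    obs_key: str,
    *,
    n_steps: int = 40000,
    step_size: float = 0.2,
    stride: int = 25,
    seed: int = 0,
    n_blocks: int = 10,
    n_boot: int = 500,
    ess_floor: float = 0.05,
) -> OracleResult:
    """Direct mean at q_b vs reweighted-from-q_a mean, both with 95% CIs.

    The validation harness for the reweighting estimator: samples once at
    q_a and reweights to q_b, samples independently at q_b and averages
    directly, and reports whether the two agree within combined CIs.
    """
    root = np.random.SeedSequence(seed)
    s_a, s_b, s_boot = root.spawn(3)
    ens_a = metropolis_sample(
        sys.with_charges(q_a), n_steps, step_size,
        np.random.default_rng(s_a), stride=stride,
    )
    w = reweight(ens_a, q_b)
    rew = reweighted_mean_ci(
        ens_a, obs_key, w,
        n_blocks=n_blocks, n_boot=n_boot,
        rng=np.random.default_rng(s_boot), ess_floor=ess_floor,
    )
    ens_b = metropolis_sample(
        sys.with_charges(q_b), n_steps, step_size,
        np.random.default_rng(s_b), stride=stride,
    )
    direct = reweighted_mean_ci(
        ens_b, obs_key, uniform_weights(ens_b.n_frames),
        n_blocks=n_blocks, n_boot=n_boot,
        rng=np.random.default_rng(s_boot), ess_floor=0.0,
    )
    return OracleResult(direct, rew, w.ess / ens_a.n_frames)


def synth_tension_series(
    mean_anisotropy: float,
    lz: float,
    ar1_phi: float,
    noise_sd: float,
    n: int,
    seed: int | np.random.Generator = 0,
    dt_ns: float = 0.1,
) -> TensionSeries:
    """AR(1) pressure-anisotropy series with known analytic tension.

    pzz carries the anisotropy (pxx = pyy = 0), stationary sd equals
    ``noise_sd``; the analytic tension is 0.1 * (lz/2) * mean_anisotropy
    mN/m.
    """
    if not abs(ar1_phi) < 1:
        raise ValidationError("|ar1_phi| must be < 1")
    rng = np.random.default_rng(seed)
    innov_sd = noise_sd * np.sqrt(1.0 - ar1_phi**2)
    eps = rng.normal(0.0, 1.0, size=n)
    a = np.empty(n)
    prev = 0.0
    for t in range(n):
        prev = ar1_phi * prev + innov_sd * eps[t]
        a[t] = prev
    a += mean_anisotropy
    time = np.arange(n) * dt_ns
    zeros = np.zeros(n)
    return TensionSeries(
        time=time, pxx=zeros, pyy=zeros.copy(), pzz=a, lz=np.full(n, lz)
    )


def synth_bilayer_frames(
    potential: Callable[[np.ndarray], np.ndarray],
    z_range: tuple[float, float],
    n_samples: int,
    *,
    n_frames: int = 1,
    temperature: float = const.DEFAULT_TEMPERATURE,
    seed: int | np.random.Generator = 0,
    lateral: float = 6.0,
    resname: str = "OIL",
    atomname: str = "C2",
    mass: float = 12.011,
    grid_points: int = 4001,
) -> FrameTable:
    """Inverse-CDF sampling of z from exp(-V(z)/kT) with known planted V.

    ``potential`` takes z (nm) and returns V in kcal/mol, bounded on
    ``z_range``. x, y are uniform over the lateral box. The output is
    labelled so the density-profile and PMF selections work; the planted V
    is the recovery target.
    """
    rng = np.random.default_rng(seed)
    lo, hi = z_range
    grid = np.linspace(lo, hi, grid_points)
    v = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("potential must be bounded on z_range")
    kt = const.kt_kcal(temperature)
    dens = np.exp(-(v - v.min()) / kt)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0)])
    cdf /= cdf[-1]
    u = rng.random(n_samples)
    z = np.interp(u, cdf, grid)
    x = rng.uniform(0.0, lateral, n_samples)
    y = rng.uniform(0.0, lateral, n_samples)
    frame = np.repeat(np.arange(n_frames), np.diff(
        np.linspace(0, n_samples, n_frames + 1).astype(int)
    ))
    table = pd.DataFrame(
        {
            "frame": frame,
            "time": frame.astype(float),
            "resname": resname,
            "atomname": atomname,
            "x": x,
            "y": y,
            "z": z,
            "mass": mass,
        }
    )
    boxes = pd.DataFrame(
        {
            "lx": lateral,
            "ly": lateral,
            "lz": hi - lo,
        },
        index=pd.Index(np.arange(n_frames), name="frame"),
    )
    return FrameTable(table, boxes)
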