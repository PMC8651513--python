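"""Thermodynamic reweighting of a fixed sampled ensemble.

Given frames sampled at a base charge set, estimates means, confidence
intervals and charge-gradients of observables under perturbed charges via
importance weights w_i ∝ exp(-beta * [U(x_i; q') - U(x_i; q)]), computed in
log space with a log-sum-exp guard.

The energy model contract only requires U and dU/dq: charges are the sole
varied parameters, so the perturbation is Coulomb-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import logsumexp

from .errors import ContractError, EssTooLowError, ValidationError
from .topology import ChargeSet

BASE_ENERGY_TOL = 1e-8

#: Fraction of n_frames below which reweighted estimates are refused.
DEFAULT_ESS_FLOOR = 0.2


@runtime_checkable
class EnergyModel(Protocol):
    """Potential energy as a function of the per-atom charge vector.

    ``potential`` returns per-frame energies (kJ/mol) for a full per-atom
    charge array; ``potential_gradient`` returns the (n_frames, n_params)
    array of dU/dq_k, where parameter k is the k-th free parameter of the
    base ChargeSet (equivalence-group members summed into their shared
    parameter).
    """

    def potential(self, charges: np.ndarray) -> np.ndarray: ...

    def potential_gradient(self, charges: np.ndarray) -> np.ndarray: ...


@dataclass
class TabulatedEnergyModel:
    """First-order energy model for hand-built test ensembles:
    U(q) = U_base + G @ (params - params_base)."""

    base_energies: np.ndarray          # (n_frames,)
    gradients: np.ndarray              # (n_frames, n_params)
    base_params: np.ndarray            # (n_params,)
    param_groups: list[np.ndarray]     # atom indices per parameter

    def _params(self, charges: np.ndarray) -> np.ndarray:
        return np.array([charges[g[0]] for g in self.param_groups])

    def potential(self, charges: np.ndarray) -> np.ndarray:
        dp = self._params(charges) - self.base_params
        return self.base_energies + self.gradients @ dp

    def potential_gradient(self, charges: np.ndarray) -> np.ndarray:
        return self.gradients


@dataclass
class Ensemble:
    """Frames sampled at ``base_charges`` with per-frame observables.

    ``beta`` is 1/(k_B T) in mol/kJ. ``observables`` maps names to per-frame
    scalar series (tension in mN/m, density in g/cm^3, ...). The stored
    ``base_energies`` must be reproduced by the energy model at the base
    charges (checked by :meth:`validate`).
    """

    beta: float
    base_charges: ChargeSet
    observables: dict[str, np.ndarray]
    energy_model: EnergyModel
    base_energies: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.base_energies)

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("ensemble needs at least 2 frames")
        for key, series in self.observables.items():
            if len(series) != self.n_frames:
                raise ValidationError(
                    f"observable {key!r} has length {len(series)}, "
                    f"expected {self.n_frames}"
                )
        u0 = self.energy_model.potential(self.base_charges.charges)
        err = float(np.max(np.abs(u0 - self.base_energies)))
        if err > BASE_ENERGY_TOL:
            raise ContractError(
                f"energy model does not reproduce base energies "
                f"(max deviation {err:.3e} kJ/mol)"
            )

    def observable(self, key: str) -> np.ndarray:
        if key not in self.observables:
            raise ValidationError(
                f"unknown observable {key!r}; have {sorted(self.observables)}"
            )
        return np.asarray(self.observables[key], dtype=float)


@dataclass
class WeightVector:
    """Normalized importance weights with their Kish effective sample size."""

    weights: np.ndarray
    log_unnormalized: np.ndarray

    @property
    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def validate(self) -> None:
        if np.any(self.weights < 0):
            raise ValidationError("negative weight")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights do not sum to 1")
        n = len(self.weights)
        if not (1.0 - 1e-9 <= self.ess <= n + 1e-9):
            raise ValidationError(f"ESS {self.ess} outside [1, {n}]")


def uniform_weights(n: int) -> WeightVector:
    return WeightVector(np.full(n, 1.0 / n), np.zeros(n))


def reweight(ens: Ensemble, q_new: ChargeSet) -> WeightVector:
    """Importance weights for re-estimating averages at ``q_new``.

    log w_i = -beta * [U(x_i; q_new) - U(x_i; q_base)], normalized with the
    log-sum-exp guard. ``q_new`` may only differ from the base set on free
    atoms.
    """
    frozen = ens.base_charges.frozen_mask
    if np.any(
        np.abs(q_new.charges[frozen] - ens.base_charges.charges[frozen]) > 1e-12
    ):
        raise ValidationError("q_new modifies frozen atoms")
    u_new = np.asarray(ens.energy_model.potential(q_new.charges), dtype=float)
    if not np.all(np.isfinite(u_new)):
        bad = int(np.flatnonzero(~np.isfinite(u_new))[0])
        raise ValidationError(f"non-finite energy at frame {bad}")
    log_un = -ens.beta * (u_new - ens.base_energies)
    weights = np.exp(log_un - logsumexp(log_un))
    weights /= weights.sum()  # kill residual rounding
    return WeightVector(weights, log_un)


@dataclass
class MeanCI:
    mean: float
    ci95: float
    ess: float
    n_blocks: int


def reweighted_mean_ci(
    ens: Ensemble,
    obs_key: str,
    w: WeightVector,
    *,
    n_blocks: int = 10,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
    ess_floor: float = DEFAULT_ESS_FLOOR,
    method: str = "block-t",
) -> MeanCI:
    """Weighted mean and 95% CI half-width of an observable.

    Both CI methods work on consecutive fixed-length blocks of frames, which
    respects autocorrelation in the sampled series. ``block-t`` (default)
    applies a Student-t interval to the weighted per-block means — the
    t quantile corrects for the small number of blocks, where a percentile
    bootstrap is known to undercover. ``bootstrap`` resamples blocks with
    replacement (seeded). Refuses to answer when the ESS is below
    ``ess_floor * n_frames``.
    """
    series = ens.observable(obs_key)
    n = ens.n_frames
    if w.ess < ess_floor * n:
        raise EssTooLowError(w.ess, ess_floor * n)
    mean = float(np.dot(w.weights, series))
    n_blocks = min(n_blocks, n)
    if n_blocks < 2:
        return MeanCI(mean, 0.0, w.ess, n_blocks)
    block_len = n // n_blocks
    used = block_len * n_blocks
    obs_blocks = series[:used].reshape(n_blocks, block_len)
    wt_blocks = w.weights[:used].reshape(n_blocks, block_len)
    num = np.sum(obs_blocks * wt_blocks, axis=1)
    den = np.sum(wt_blocks, axis=1)
    if method == "block-t":
        from scipy import stats

        ok = den > 0
        m_b = num[ok] / den[ok]
        nb = int(ok.sum())
        if nb < 2:
            return MeanCI(mean, 0.0, w.ess, nb)
        # weighted dispersion of block means about the global weighted mean
        wt = den[ok] / den[ok].sum()
        var = float(np.sum(wt * (m_b - mean) ** 2)) * nb / (nb - 1)
        ci = float(stats.t.ppf(0.975, nb - 1) * np.sqrt(var / nb))
        return MeanCI(mean, ci, w.ess, nb)
    if method == "bootstrap":
        gen = np.random.default_rng(rng)
        picks = gen.integers(0, n_blocks, size=(n_boot, n_blocks))
        boot_num = num[picks].sum(axis=1)
        boot_den = den[picks].sum(axis=1)
        ok = boot_den > 0
        boot_means = boot_num[ok] / boot_den[ok]
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        return MeanCI(mean, float((hi - lo) / 2.0), w.ess, n_blocks)
    raise ValidationError(f"unknown CI method {method!r}")


def observable_gradient(
    ens: Ensemble,
    obs_key: str,
    q: ChargeSet,
    w: WeightVector | None = None,
) -> np.ndarray:
    """d<O>/dq_k = -beta * ( <O * dU/dq_k>_w - <O>_w <dU/dq_k>_w ).

    Averages are taken under the importance weights at ``q``; the returned
    vector has one entry per free parameter of the base charge set (atoms in
    one equivalence group contribute to their single shared parameter).
    """
    if w is None:
        w = reweight(ens, q)
    series = ens.observable(obs_key)
    try:
        grads = np.asarray(ens.energy_model.potential_gradient(q.charges), dtype=float)
    except AttributeError as exc:
        raise ContractError("energy model lacks potential_gradient") from exc
    if grads.ndim != 2 or grads.shape[0] != ens.n_frames:
        raise ContractError(
            f"potential_gradient returned shape {grads.shape}, expected "
            f"({ens.n_frames}, n_params)"
        )
    mean_o = np.dot(w.weights, series)
    mean_g = w.weights @ grads
    mean_og = (w.weights * series) @ grads
    return -ens.beta * (mean_og - mean_o * mean_g)
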