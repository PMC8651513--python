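"""Density profiles along the bilayer normal and Boltzmann-inversion PMFs.

The free-energy profile along z is obtained as -kT ln(rho(z)/rho_max) from a
binned density profile; flip-flop barriers are read off at the bilayer
midplane relative to the profile minimum, and replicas are aggregated
bin-wise after per-curve anchoring.

Conventions: bin intervals are half-open [lo, hi), z in nm, midplane at 0,
PMF in kcal/mol anchored at its global minimum (offsets do not affect
barriers). Bins with zero density are masked (NaN), not set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as const
from .errors import ValidationError
from .frames import FrameTable

DEFAULT_BIN_WIDTH = 0.07  # nm


@dataclass
class DensityProfile:
    """Binned (mass or number) density along z, averaged over frames."""

    bin_centers: np.ndarray
    density: np.ndarray          # mass per nm^3 if area known, else per nm
    bin_width: float
    selection: str = ""
    n_frames: int = 1
    total_weight: float = 0.0    # selected mass (or count) per frame, averaged
    area: float | None = None    # lateral box area (nm^2) if uniform

    def __post_init__(self):
        if len(self.bin_centers) != len(self.density):
            raise ValidationError("bin_centers and density lengths differ")
        if len(self.bin_centers) > 1:
            widths = np.diff(self.bin_centers)
            if np.max(np.abs(widths - self.bin_width)) > 1e-9:
                raise ValidationError("bins must be uniform")
        if np.any(self.density < 0):
            raise ValidationError("density must be non-negative")


def compute_midplane(z_phos: np.ndarray) -> float:
    """Midpoint between the two phosphate layers: split the z values at
    their median and average the two leaflet means."""
    med = np.median(z_phos)
    upper = z_phos[z_phos >= med]
    lower = z_phos[z_phos < med]
    if len(lower) == 0 or len(upper) == 0:
        return float(med)
    return float((upper.mean() + lower.mean()) / 2.0)


def lateral_density_profile(
    frames: FrameTable,
    selection: dict | None = None,
    *,
    bin_width: float = DEFAULT_BIN_WIDTH,
    z_range: tuple[float, float] | None = None,
    center: str | None = None,
    center_selection: dict | None = None,
    mass_weighted: bool = True,
) -> DensityProfile:
    """Histogram selected atom z-coordinates into uniform bins, frame-averaged.

    ``selection``/``center_selection`` are dicts with optional ``resname``
    and ``atomname`` keys. With ``center='midplane'`` each frame is
    recentered so the midpoint between the two layers of the centering
    selection (e.g. POPC phosphates) sits at z = 0, removing slab drift.
    Mass-weighted by default; density is per nm^3 when the lateral box area
    is uniform across frames, per nm otherwise.
    """
    sel = frames.select(**(selection or {}))
    if sel.table.empty:
        raise ValidationError(f"empty selection {selection}")
    if z_range is None:
        zmin = float(sel.table["z"].min())
        zmax = float(sel.table["z"].max())
    else:
        zmin, zmax = z_range
    n_bins = max(int(np.ceil((zmax - zmin) / bin_width - 1e-9)), 1)
    edges = zmin + np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    totals = []
    areas = set()
    n_frames = 0
    for fid, df, box in sel.iter_frames():
        z = df["z"].to_numpy(float)
        if center == "midplane":
            ref = frames.select(**(center_selection or {}))
            ref_df = ref.table[ref.table["frame"] == fid]
            if ref_df.empty:
                raise ValidationError(f"frame {fid}: empty centering selection")
            z = z - compute_midplane(ref_df["z"].to_numpy(float))
        w = df["mass"].to_numpy(float) if mass_weighted else np.ones(len(df))
        h, _ = np.histogram(z, bins=edges, weights=w)
        hist += h
        totals.append(w.sum())
        areas.add((round(float(box.lx), 9), round(float(box.ly), 9)))
        n_frames += 1
    hist /= n_frames
    area = None
    norm = bin_width
    if len(areas) == 1:
        lx, ly = next(iter(areas))
        area = lx * ly
        norm = bin_width * area
    centers = edges[:-1] + bin_width / 2.0
    return DensityProfile(
        bin_centers=centers,
        density=hist / norm,
        bin_width=bin_width,
        selection=str(selection),
        n_frames=n_frames,
        total_weight=float(np.mean(totals)),
        area=area,
    )


@dataclass
class PMFCurve:
    """Binned free-energy profile (kcal/mol) along z.

    ``pmf`` is NaN where the underlying density was zero. Under the
    "anchor at minimum" convention the minimum over defined bins is 0.
    """

    z: np.ndarray
    pmf: np.ndarray
    bin_width: float
    reference_convention: str = "min-zero"
    replica_mean: np.ndarray | None = None
    replica_sd: np.ndarray | None = None
    n_replicas: int = 1

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.pmf)

    def anchored(self) -> "PMFCurve":
        if not self.defined.any():
            raise ValidationError("PMF has no defined bins")
        shift = np.nanmin(self.pmf)
        return PMFCurve(
            self.z, self.pmf - shift, self.bin_width,
            self.reference_convention, self.replica_mean, self.replica_sd,
            self.n_replicas,
        )


def boltzmann_invert(
    p: DensityProfile, temperature: float = const.DEFAULT_TEMPERATURE
) -> PMFCurve:
    """pmf(z) = -k_B T ln(rho(z)/rho_max), anchored so the minimum is 0.

    Bins with zero density are masked as NaN (the free energy is undefined
    there, not zero).
    """
    dens = np.asarray(p.density, dtype=float)
    if not np.any(dens > 0):
        raise ValidationError("all-zero density profile")
    kt = const.kt_kcal(temperature)
    with np.errstate(divide="ignore"):
        pmf = np.where(dens > 0, -kt * np.log(dens / dens.max()), np.nan)
    return PMFCurve(p.bin_centers.copy(), pmf, p.bin_width).anchored()


def _value_at(curve: PMFCurve, z0: float) -> float:
    i = int(np.argmin(np.abs(curve.z - z0)))
    if abs(curve.z[i] - z0) > curve.bin_width / 2.0 + 1e-9:
        raise ValidationError(f"no bin at z = {z0}")
    v = curve.pmf[i]
    if not np.isfinite(v):
        raise ValidationError(f"PMF undefined (masked) at z = {z0}")
    return float(v)


def flip_flop_barrier(
    p: PMFCurve,
    membrane_span: tuple[float, float],
    *,
    midplane: float = 0.0,
    convention: str = "midplane",
) -> float:
    """Flip-flop barrier from a PMF across the bilayer midplane (kcal/mol).

    Default convention: pmf(midplane) - min pmf within ``membrane_span``.
    ``convention='max'`` instead uses the maximum within the span (the two
    coincide for midplane-peaked profiles).
    """
    lo, hi = membrane_span
    sel = (p.z >= lo) & (p.z <= hi) & p.defined
    if not sel.any():
        raise ValidationError("PMF undefined over the membrane span")
    floor = float(np.min(p.pmf[sel]))
    if convention == "midplane":
        top = _value_at(p, midplane)
    elif convention == "max":
        top = float(np.max(p.pmf[sel]))
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    return top - floor


def surface_access_cost(p: PMFCurve, phosphate_z: float) -> float:
    """Cost of reaching the bilayer surface: pmf at the phosphate peak level
    minus the PMF minimum."""
    return _value_at(p, phosphate_z) - float(np.nanmin(p.pmf))


def replica_aggregate(curves: list[PMFCurve]) -> PMFCurve:
    """Bin-wise mean and sample SD over replicas, after per-curve anchoring."""
    if len(curves) < 2:
        raise ValidationError("need at least 2 replicas")
    z0 = curves[0].z
    for c in curves[1:]:
        if len(c.z) != len(z0) or np.max(np.abs(c.z - z0)) > 1e-9:
            raise ValidationError("replica binning mismatch")
    stack = np.vstack([c.anchored().pmf for c in curves])
    finite = np.isfinite(stack)
    cnt = finite.sum(axis=0)
    vals = np.where(finite, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, vals.sum(axis=0) / np.maximum(cnt, 1), np.nan)
        var = np.where(
            cnt >= 2,
            (np.where(finite, (stack - mean) ** 2, 0.0)).sum(axis=0)
            / np.maximum(cnt - 1, 1),
            np.nan,
        )
        sd = np.sqrt(var)
    out = PMFCurve(
        z0.copy(),
        mean,
        curves[0].bin_width,
        replica_mean=mean,
        replica_sd=sd,
        n_replicas=len(curves),
    )
    return out.anchored()


def replica_barrier_stats(
    curves: list[PMFCurve],
    membrane_span: tuple[float, float],
    **kwargs,
) -> tuple[float, float]:
    """Barrier statistics propagated as mean +/- sample SD of per-replica
    barriers."""
    barriers = np.array(
        [flip_flop_barrier(c, membrane_span, **kwargs) for c in curves]
    )
    return float(barriers.mean()), float(barriers.std(ddof=1))
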