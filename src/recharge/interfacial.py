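"""Interfacial observables from MD output series.

Surface/interfacial tension via the mechanical (Kirkwood-Irving) route from
pressure-tensor diagonals, running/blocking averages with Student-t
confidence intervals, water content inside an oil core, and
hydration-plateau equilibration detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as const
from .errors import FormatError, ValidationError
from .frames import FrameTable

DEFAULT_BIN_WIDTH = 0.07  # nm, shared with the density-profile module
DEFAULT_CORE_FRACTION = 0.5


def read_xvg(path) -> np.ndarray:
    """Read a GROMACS .xvg table ('#'/'@'/'&' comment lines, whitespace
    columns) into a 2-D float array."""
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s[0] in "#@&":
                continue
            rows.append([float(v) for v in s.split()])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


@dataclass
class TensionSeries:
    """Per-frame pressure-tensor diagonals (bar) plus box length along z (nm)."""

    time: np.ndarray   # ns
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    lz: np.ndarray

    def __post_init__(self):
        arrays = [self.time, self.pxx, self.pyy, self.pzz, self.lz]
        n = len(self.time)
        if any(len(a) != n for a in arrays):
            raise ValidationError("tension series columns have unequal lengths")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.lz <= 0):
            raise ValidationError("box length must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @classmethod
    def from_xvg(cls, pressure_path, lz, time_unit_ns: float = 1e-3) -> "TensionSeries":
        """Build from a pressure .xvg with columns t, Pxx, Pyy, Pzz.

        ``lz`` is either a constant (nm) or the path of a box .xvg whose
        columns are t, Lz (nm). GROMACS times are ps; ``time_unit_ns``
        converts to ns.
        """
        data = read_xvg(pressure_path)
        if data.shape[1] < 4:
            raise FormatError("pressure .xvg needs columns t, Pxx, Pyy, Pzz")
        time = data[:, 0] * time_unit_ns
        if isinstance(lz, (int, float)):
            lz_arr = np.full(len(time), float(lz))
        else:
            box = read_xvg(lz)
            if len(box) != len(time):
                raise ValidationError("box series length differs from pressure series")
            lz_arr = box[:, 1]
        return cls(time, data[:, 1], data[:, 2], data[:, 3], lz_arr)

    @classmethod
    def from_csv(cls, path) -> "TensionSeries":
        df = pd.read_csv(path)
        need = {"time", "pxx", "pyy", "pzz", "lz"}
        if not need <= set(df.columns):
            raise FormatError(f"tension CSV needs columns {sorted(need)}")
        return cls(
            df["time"].to_numpy(float),
            df["pxx"].to_numpy(float),
            df["pyy"].to_numpy(float),
            df["pzz"].to_numpy(float),
            df["lz"].to_numpy(float),
        )


def kirkwood_irving_tension(
    s: TensionSeries, frame_range: slice | None = None
) -> tuple[np.ndarray, float]:
    """Per-frame tension gamma_i = (lz_i/2)(Pzz_i - (Pxx_i+Pyy_i)/2) in mN/m.

    The 1/2 prefactor accounts for the two interfaces of a periodic slab;
    bar*nm converts to mN/m by exactly 0.1. Returns the per-frame series and
    its mean over ``frame_range``.
    """
    if frame_range is None:
        frame_range = slice(None)
    anisotropy = s.pzz - (s.pxx + s.pyy) / 2.0
    gamma = const.BAR_NM_TO_MN_PER_M * (s.lz / 2.0) * anisotropy
    window = gamma[frame_range]
    if window.size == 0:
        raise ValidationError("empty frame range")
    return gamma, float(window.mean())


@dataclass
class BlockStats:
    """Running average, blocking averages and a Student-t 95% CI."""

    running_average: np.ndarray
    block_means: np.ndarray
    block_duration: float
    mean: float
    ci95: float | None

    @property
    def has_ci(self) -> bool:
        return self.ci95 is not None


def running_and_block_stats(
    time: np.ndarray, values: np.ndarray, block_duration: float
) -> BlockStats:
    """Cumulative running average plus consecutive fixed-duration block means.

    Blocks are consecutive windows of ``block_duration`` (same unit as
    ``time``); an incomplete trailing block is dropped. The CI is
    t_{0.975, n-1} * s / sqrt(n) over block means, undefined (None) with
    fewer than two complete blocks.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(time) != len(values) or len(time) == 0:
        raise ValidationError("time and values must be equal-length, non-empty")
    running = np.cumsum(values) / np.arange(1, len(values) + 1)
    t0 = time[0]
    idx = np.floor((time - t0) / block_duration).astype(int)
    # block b is complete if its whole span is covered by the sampling grid
    dt = float(np.median(np.diff(time))) if len(time) > 1 else block_duration
    n_complete = int(
        np.floor((time[-1] - t0 + dt + 1e-12) / block_duration)
    )
    n_complete = min(n_complete, int(idx.max()) + 1)
    block_means = np.array(
        [values[idx == b].mean() for b in range(n_complete)]
    )
    if len(block_means) >= 2:
        n = len(block_means)
        sd = block_means.std(ddof=1)
        ci = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
        mean = float(block_means.mean())
    elif len(block_means) == 1:
        ci = None
        mean = float(block_means[0])
    else:
        ci = None
        mean = float(values.mean())
    return BlockStats(running, block_means, block_duration, mean, ci)


@dataclass
class HydrationSeries:
    """Water content inside the oil core, per frame."""

    time: np.ndarray            # ns
    water_mass: np.ndarray      # g/mol per frame snapshot (bookkeeping units)
    oil_mass: np.ndarray        # g/mol
    content: np.ndarray         # g water / kg oil

    def __post_init__(self):
        if np.any(self.water_mass < 0) or np.any(self.oil_mass <= 0):
            raise ValidationError("masses must be non-negative (oil positive)")
        expected = 1000.0 * self.water_mass / self.oil_mass
        if np.max(np.abs(expected - self.content)) > 1e-9:
            raise ValidationError("content != 1000*water_mass/oil_mass")


def _oil_core_interval(
    z: np.ndarray,
    weights: np.ndarray,
    lz: float,
    bin_width: float,
    core_fraction: float,
):
    """Contiguous (periodic-aware) z-interval where the oil mass density is
    at least ``core_fraction`` of its plateau value. Returns (roll_shift,
    lo, hi) in rolled coordinates.

    Detection uses a coarser histogram than the profile bin width when the
    system is sparse (at most 48 bins across the box), so a handful of
    lumped oil pseudo-atoms still yields a contiguous core.
    """
    n_bins = max(min(int(round(lz / bin_width)), 48), 4)
    edges = np.linspace(0.0, lz, n_bins + 1)
    hist, _ = np.histogram(np.mod(z, lz), bins=edges, weights=weights)
    # rotate so the emptiest bin sits at the boundary: the core then cannot
    # straddle the periodic wrap
    shift = int(np.argmin(hist))
    rolled = np.roll(hist, -shift)
    # periodic 3-bin boxcar: edge bins must not be depressed by zero padding
    smooth = (np.roll(rolled, 1) + rolled + np.roll(rolled, -1)) / 3.0
    plateau = smooth.max()
    if plateau <= 0:
        raise ValidationError("no oil density found")
    mask = smooth >= core_fraction * plateau
    if mask.all():
        raise ValidationError(
            "oil density has no interface: core spans the whole box "
            "(not a slab system)"
        )
    peak = int(np.argmax(smooth))
    lo = peak
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = peak
    while hi < n_bins - 1 and mask[hi + 1]:
        hi += 1
    bin_w = lz / n_bins
    return shift * bin_w, lo * bin_w, (hi + 1) * bin_w


def water_in_oil_content(
    frames: FrameTable,
    oil_resnames,
    water_resname: str = "SOL",
    *,
    bin_width: float = DEFAULT_BIN_WIDTH,
    core_fraction: float = DEFAULT_CORE_FRACTION,
    water_molar_mass: float = const.WATER_MOLAR_MASS,
) -> HydrationSeries:
    """Water content of the oil core in g water per kg oil, per frame.

    Per frame: builds the oil mass-density profile along z, takes the
    contiguous region at >= ``core_fraction`` of the plateau density as the
    core, counts water molecules whose oxygen lies inside, and reports
    1000 * water mass / total oil mass.
    """
    if isinstance(oil_resnames, str):
        oil_resnames = [oil_resnames]
    times, wmass, omass, content = [], [], [], []
    for fid, df, box in frames.iter_frames():
        lz = float(box.lz)
        oil = df[df["resname"].isin(oil_resnames)]
        if oil.empty:
            raise ValidationError(f"frame {fid}: no oil residues")
        shift, lo, hi = _oil_core_interval(
            oil["z"].to_numpy(float),
            oil["mass"].to_numpy(float),
            lz,
            bin_width,
            core_fraction,
        )
        water = df[
            (df["resname"] == water_resname)
            & (df["atomname"].str.upper().str.startswith("O"))
        ]
        zw = np.mod(water["z"].to_numpy(float) - shift, lz)
        n_inside = int(np.count_nonzero((zw >= lo) & (zw < hi)))
        wm = n_inside * water_molar_mass
        om = float(oil["mass"].sum())
        times.append(float(df["time"].iloc[0]))
        wmass.append(wm)
        omass.append(om)
        content.append(1000.0 * wm / om)
    return HydrationSeries(
        np.asarray(times), np.asarray(wmass), np.asarray(omass), np.asarray(content)
    )


def detect_equilibration(
    time: np.ndarray,
    values: np.ndarray,
    *,
    window: float = 100.0,
    slope_tol: float = 0.05,
) -> float | None:
    """Earliest window start after which the series is flat.

    Slides a window of duration ``window`` (same unit as ``time``);
    converged when |fitted linear slope| * window <= slope_tol * |window
    mean|. Returns the window start time, or None for "not converged". The
    post-convergence region is the part of a trajectory trusted for mean
    estimates.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time[-1] - time[0] < window:
        raise ValidationError("series shorter than the detection window")
    starts = time[time <= time[-1] - window]
    for t0 in starts:
        sel = (time >= t0) & (time <= t0 + window)
        if sel.sum() < 2:
            continue
        slope = np.polyfit(time[sel], values[sel], 1)[0]
        if abs(slope) * window <= slope_tol * abs(values[sel].mean()):
            return float(t0)
    return None
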