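"""Alternating-energy (AllIons/DIA) fragment assignment by EIC correlation.

Frame data is a long table with columns ``rt_min, dt_ms, mz, intensity,
energy, ce_ev`` where ``energy`` is ``"low"`` (intact precursors) or ``"high"``
(fragments).  Because there is no precursor isolation, a fragment is assigned
to a precursor by showing that its extracted ion chromatogram (EIC), taken in
the precursor's drift-time window, co-elutes with the precursor's EIC:
fragments with a Pearson correlation coefficient > 0.9 over the precursor's
elution region are retained.

Default extraction windows follow the acquisition practice for this class:
0.05 Da total m/z width and about 2 ms total drift width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chem import (
    FragmentSpec,
    TREHALOSE_FRAGMENT_H2O,
    TREHALOSE_FRAGMENT_2H2O,
)
from .library import FeatureRecord

__all__ = [
    "FRAME_COLUMNS",
    "EICTrace",
    "ReconstructedSpectrum",
    "smooth_frames",
    "smooth_trace",
    "extract_eic",
    "pearson_correlation",
    "assign_fragments",
    "detect_peaks",
    "diagnostic_screen",
    "read_frames",
    "write_frames",
]

#: canonical long-table frame schema
FRAME_COLUMNS = ("rt_min", "dt_ms", "mz", "intensity", "energy", "ce_ev")

DEFAULT_MZ_WIDTH = 0.05  # Da, total window width
DEFAULT_DRIFT_WIDTH = 2.0  # ms, total window width
CORRELATION_THRESHOLD = 0.9
MIN_OVERLAP_POINTS = 5


@dataclass
class EICTrace:
    """An extracted ion chromatogram on a strictly increasing RT grid."""

    rt: np.ndarray
    intensity: np.ndarray
    mz_center: float
    mz_width: float
    drift_center: float | None
    drift_width: float | None
    energy: str

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size != self.intensity.size:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("RT grid must be strictly increasing")

    def restrict(self, rt_min: float, rt_max: float) -> "EICTrace":
        sel = (self.rt >= rt_min) & (self.rt <= rt_max)
        return EICTrace(
            self.rt[sel], self.intensity[sel], self.mz_center, self.mz_width,
            self.drift_center, self.drift_width, self.energy,
        )


@dataclass
class ReconstructedSpectrum:
    """DIA MS2 spectrum rebuilt from correlation-retained fragments."""

    precursor_mz: float
    precursor_rt: float
    collision_energy: float
    peaks: list[tuple[FragmentSpec, float, float]]  # (fragment, apex intensity, r)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _validate_frames(frames: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"frame table is missing columns: {missing}")
    return frames


def _moving_average(values: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges."""
    if window % 2 != 1 or window < 1:
        raise ValueError(f"smoothing window must be an odd positive integer, got {window}")
    if window == 1:
        return values
    kernel = np.ones(window)
    half = window // 2

    def conv(v: np.ndarray) -> np.ndarray:
        s = np.convolve(v, kernel, mode="full")[half : half + v.size]
        c = np.convolve(np.ones_like(v), kernel, mode="full")[half : half + v.size]
        return s / c

    return np.apply_along_axis(conv, axis, values)


def smooth_frames(
    frames: pd.DataFrame, rt_window: int = 3, drift_window: int = 5
) -> pd.DataFrame:
    """Moving-average smoothing of frame intensities along RT and drift time.

    Applied independently per (energy level, m/z) on the pivoted RT x drift
    grid: 3 points along RT and 5 along drift by default.  Windows shrink at
    the grid edges so total intensity is approximately preserved for peaks
    away from the borders.
    """
    _validate_frames(frames)
    if rt_window % 2 != 1 or drift_window % 2 != 1:
        raise ValueError("smoothing windows must be odd")
    out_parts = []
    for (energy, ce, mz), grp in frames.groupby(["energy", "ce_ev", "mz"], sort=False):
        pivot = grp.pivot_table(
            index="rt_min", columns="dt_ms", values="intensity", aggfunc="sum", fill_value=0.0
        )
        vals = pivot.to_numpy(dtype=float)
        vals = _moving_average(vals, rt_window, axis=0)
        vals = _moving_average(vals, drift_window, axis=1)
        long = pd.DataFrame(vals, index=pivot.index, columns=pivot.columns).stack()
        long = long[long > 0].reset_index()
        long.columns = ["rt_min", "dt_ms", "intensity"]
        long["mz"] = mz
        long["energy"] = energy
        long["ce_ev"] = ce
        out_parts.append(long[list(FRAME_COLUMNS)])
    if not out_parts:
        return frames.iloc[0:0].copy()
    return pd.concat(out_parts, ignore_index=True)


def smooth_trace(trace: EICTrace, window: int = 3) -> EICTrace:
    """Centered moving average of a single EIC along RT (shrunken edge windows)."""
    smoothed = _moving_average(trace.intensity[None, :], window, axis=1)[0]
    return EICTrace(
        trace.rt, smoothed, trace.mz_center, trace.mz_width,
        trace.drift_center, trace.drift_width, trace.energy,
    )


def extract_eic(
    frames: pd.DataFrame,
    mz_center: float,
    mz_width: float = DEFAULT_MZ_WIDTH,
    drift_center: float | None = None,
    drift_width: float = DEFAULT_DRIFT_WIDTH,
    energy: str = "high",
    rt_grid: np.ndarray | None = None,
) -> EICTrace:
    """Sum intensities inside the m/z (and optionally drift) window per RT bin.

    Widths are *total* window widths (half-width on each side of the center).
    RT bins with no points inside the window are zero-filled on ``rt_grid``
    (default: all RTs present at the requested energy level).
    """
    if mz_width <= 0 or drift_width <= 0:
        raise ValueError("window widths must be positive")
    _validate_frames(frames)
    lvl = frames[frames["energy"] == energy]
    if rt_grid is None:
        rt_grid = np.unique(lvl["rt_min"].to_numpy(dtype=float))
    else:
        rt_grid = np.unique(np.asarray(rt_grid, dtype=float))
    sel = lvl[np.abs(lvl["mz"] - mz_center) <= mz_width / 2.0]
    if drift_center is not None:
        sel = sel[np.abs(sel["dt_ms"] - drift_center) <= drift_width / 2.0]
    summed = sel.groupby("rt_min")["intensity"].sum()
    intensity = np.zeros(rt_grid.size)
    if len(summed):
        idx = np.searchsorted(rt_grid, summed.index.to_numpy(dtype=float))
        ok = (idx < rt_grid.size) & np.isclose(
            rt_grid[np.clip(idx, 0, rt_grid.size - 1)], summed.index.to_numpy(), atol=1e-9
        )
        intensity[idx[ok]] = summed.to_numpy()[ok]
    return EICTrace(
        rt_grid, intensity, mz_center, mz_width,
        drift_center, drift_width if drift_center is not None else None, energy,
    )


def pearson_correlation(
    a: EICTrace,
    b: EICTrace,
    rt_region: tuple[float, float] | None = None,
    min_points: int = MIN_OVERLAP_POINTS,
) -> float:
    """Pearson r between two EICs on their common RT grid within *rt_region*.

    Returns ``nan`` (treated downstream as "not retained") when fewer than
    *min_points* grid points overlap or either trace has zero variance.
    """
    grid = np.union1d(a.rt, b.rt)
    if rt_region is not None:
        grid = grid[(grid >= rt_region[0]) & (grid <= rt_region[1])]

    def on_grid(trace: EICTrace) -> np.ndarray:
        out = np.zeros(grid.size)
        idx = np.searchsorted(grid, trace.rt)
        ok = (idx < grid.size) & np.isclose(
            grid[np.clip(idx, 0, grid.size - 1)], trace.rt, atol=1e-9
        )
        out[idx[ok]] = trace.intensity[ok]
        return out

    va, vb = on_grid(a), on_grid(b)
    if grid.size < min_points:
        return float("nan")
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def _peak_region(trace: EICTrace, width_factor: float = 3.0) -> tuple[float, float]:
    """Apex +- width_factor * sigma, sigma estimated from the FWHM of the apex peak."""
    if trace.rt.size == 0 or np.all(trace.intensity <= 0):
        raise ValueError("precursor trace is empty")
    apex_i = int(np.argmax(trace.intensity))
    apex_rt = trace.rt[apex_i]
    half = trace.intensity[apex_i] / 2.0
    left = apex_i
    while left > 0 and trace.intensity[left] > half:
        left -= 1
    right = apex_i
    while right < trace.rt.size - 1 and trace.intensity[right] > half:
        right += 1
    fwhm = max(trace.rt[right] - trace.rt[left], np.min(np.diff(trace.rt)) if trace.rt.size > 1 else 0.05)
    sigma = fwhm / 2.3548
    return apex_rt - width_factor * sigma, apex_rt + width_factor * sigma


def assign_fragments(
    precursor: FeatureRecord,
    candidate_fragments: Sequence[FragmentSpec],
    frames: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    mz_width: float = DEFAULT_MZ_WIDTH,
    drift_width: float = DEFAULT_DRIFT_WIDTH,
    collision_energy: float | None = None,
    smooth: bool = True,
) -> ReconstructedSpectrum:
    """Correlation-gated DIA MS2 reconstruction for one precursor.

    The precursor EIC comes from the low-energy frames; each candidate
    fragment EIC from the high-energy frames, both restricted to the
    precursor's drift window.  Fragments whose EIC correlates with the
    precursor EIC with r > *threshold* over the precursor's elution region
    are retained, sorted by m/z.
    """
    _validate_frames(frames)
    if precursor.drift_time is None:
        raise ValueError("precursor needs a drift time for DIA assignment")
    work = frames
    if collision_energy is not None:
        work = frames[frames["ce_ev"] == collision_energy]
    grid = np.unique(work["rt_min"].to_numpy(dtype=float))
    prec_trace = extract_eic(
        work, precursor.mz, mz_width, precursor.drift_time, drift_width,
        energy="low", rt_grid=grid,
    )
    if np.all(prec_trace.intensity <= 0):
        raise ValueError(
            f"precursor m/z {precursor.mz:.4f} not found in low-energy frames"
        )
    if smooth:
        prec_trace = smooth_trace(prec_trace)
    region = _peak_region(prec_trace)

    ce = collision_energy
    if ce is None:
        high = work[work["energy"] == "high"]
        ce = float(high["ce_ev"].iloc[0]) if len(high) else float("nan")

    retained: list[tuple[FragmentSpec, float, float]] = []
    for frag in candidate_fragments:
        trace = extract_eic(
            work, frag.mz, mz_width, precursor.drift_time, drift_width,
            energy="high", rt_grid=grid,
        )
        if smooth:
            trace = smooth_trace(trace)
        r = pearson_correlation(prec_trace, trace, rt_region=region)
        if not math.isnan(r) and r > threshold:
            local = trace.restrict(*region)
            apex = float(local.intensity.max()) if local.rt.size else 0.0
            retained.append((frag, apex, r))
    retained.sort(key=lambda t: t[0].mz)
    return ReconstructedSpectrum(
        precursor_mz=precursor.mz,
        precursor_rt=precursor.rt,
        collision_energy=ce,
        peaks=retained,
    )


def detect_peaks(
    trace: EICTrace, min_height: float = 0.0
) -> list[tuple[float, float]]:
    """Local maxima of an EIC above *min_height*: (apex RT, apex intensity)."""
    if trace.rt.size == 0:
        return []
    idx, props = find_peaks(trace.intensity, height=min_height if min_height > 0 else None)
    out = [(float(trace.rt[i]), float(trace.intensity[i])) for i in idx]
    if min_height > 0:
        out = [(rt, h) for rt, h in out if h > min_height]
    return out


def diagnostic_screen(
    frames: pd.DataFrame,
    collision_energy: float = 20.0,
    min_height: float = 0.0,
    coelution_steps: int = 2,
    smooth: bool = True,
) -> list[dict]:
    """Screen high-energy frames for the trehalose head-group fragments.

    EICs for m/z 323.0984 ([Tre-H2O-H]-) and 305.0878 ([Tre-2H2O-H]-) are
    extracted over the whole run without drift filtering.  A peak where both
    fragments co-elute (apex distance <= *coelution_steps* RT steps) hints at
    a maradolipid; a 323 peak without a 305 partner hints at a
    lysomaradolipid.  Returns dicts with ``rt``, ``rt_region`` and ``hint``.
    """
    _validate_frames(frames)
    work = frames[frames["ce_ev"] == collision_energy] if "ce_ev" in frames else frames
    if not len(work):
        return []
    grid = np.unique(work["rt_min"].to_numpy(dtype=float))
    if grid.size == 0:
        return []
    step = float(np.median(np.diff(grid))) if grid.size > 1 else 0.05
    tol = coelution_steps * step

    t323 = extract_eic(work, TREHALOSE_FRAGMENT_H2O, energy="high", rt_grid=grid)
    t305 = extract_eic(work, TREHALOSE_FRAGMENT_2H2O, energy="high", rt_grid=grid)
    if smooth:
        t323, t305 = smooth_trace(t323), smooth_trace(t305)
    peaks323 = detect_peaks(t323, min_height)
    peaks305 = detect_peaks(t305, min_height)

    hints: list[dict] = []
    for rt, height in peaks323:
        partner = any(abs(rt - rt2) <= tol + 1e-12 for rt2, _ in peaks305)
        hints.append(
            {
                "rt": rt,
                "rt_region": (rt - 3 * step, rt + 3 * step),
                "hint": "Mar" if partner else "LysoMar",
                "intensity_323": height,
            }
        )
    return hints


def read_frames(path) -> pd.DataFrame:
    """Read the long-table frame format (CSV with the canonical columns)."""
    frames = pd.read_csv(path)
    return _validate_frames(frames)


def write_frames(frames: pd.DataFrame, path) -> None:
    _validate_frames(frames)[list(FRAME_COLUMNS)].to_csv(path, index=False)
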