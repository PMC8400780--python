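"""PRM-style chromatogram quantitation.

Re-implements the desk half of targeted PRM quantitation: extract each
target's fragment ion chromatograms inside the retention-time window, sum
them into a composite trace, detect the isomer peaks, and integrate each
peak above a local linear baseline. Isomer identity across patients is
positional: isomer 1 is the earliest-eluting peak in the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .glyco_model import GlycopeptideTarget

__all__ = [
    "ChromatogramSet",
    "EIC",
    "QuantParams",
    "IsomerPeak",
    "QuantTable",
    "extract_eic",
    "detect_isomer_peaks",
    "integrate_peak",
    "quantify_target",
    "build_quant_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ChromatogramSet:
    """Per-patient fragment traces on a shared time grid.

    ``traces`` maps ``(target_key, fragment_mz)`` to an intensity array the
    same length as ``time``; ``target_key`` is the ``site|code`` form
    identifier (PRM traces are precursor-isolated, so fragments with equal
    m/z from different precursors stay separate).
    """

    time: np.ndarray  # minutes, strictly increasing
    traces: dict[tuple[str, float], np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time grid must be a 1-D array of length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def fragment_mzs(self, target_key: str) -> list[float]:
        return [mz for (key, mz) in self.traces if key == target_key]


@dataclass
class EIC:
    """Extracted ion chromatogram for one fragment m/z."""

    time: np.ndarray
    intensity: np.ndarray
    mz: float
    tolerance_ppm: float
    missing: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if not self.missing and np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class QuantParams:
    """Windows and peak-picking conventions for the quantitation step.

    ``rt_window`` (±min) and ``precursor_mass_range`` (±Da) mirror the
    acquisition-side PRM windows; the mass range is carried as provenance
    only, since the fixture traces are already precursor-isolated.
    """

    rt_window: float = 3.0
    precursor_mass_range: float = 2.0
    fragment_ppm_tol: float = 10.0
    peak_min_prominence: float = 0.05  # fraction of tallest apex
    boundary_frac: float = 0.01        # bound where trace falls to 1% of apex
    min_isomer_separation: float = 1.0  # minutes

    def __post_init__(self) -> None:
        for name in (
            "rt_window",
            "precursor_mass_range",
            "fragment_ppm_tol",
            "peak_min_prominence",
            "boundary_frac",
            "min_isomer_separation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class IsomerPeak:
    apex_rt: float
    left: float
    right: float
    area: float = 0.0
    isomer_index: int = 0
    apex_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not self.left < self.apex_rt < self.right:
            raise ValueError("peak bounds must bracket the apex")


@dataclass
class QuantTable:
    """Patients × isomer entries peak areas with apex RTs and missing flags."""

    areas: pd.DataFrame      # rows = patient_id, cols = "site|code|isomer"
    apex_rts: pd.DataFrame   # same shape; NaN where undetected
    missing: pd.DataFrame    # boolean, True where no peak was detected

    @staticmethod
    def site_of(column: str) -> str:
        return column.split("|")[0]

    @staticmethod
    def code_of(column: str) -> str:
        return column.split("|")[1]


def extract_eic(
    chromset: ChromatogramSet,
    mz: float,
    params: QuantParams,
    expected_rt: float,
    rt_halfwidth: float | None = None,
    target_key: str | None = None,
) -> EIC:
    """Extract one fragment EIC around ``expected_rt``.

    Sums every stored trace whose m/z lies within ``fragment_ppm_tol`` of
    the target m/z (restricted to ``target_key`` traces when given), clipped
    to ``expected_rt ± rt_halfwidth`` (default: ``params.rt_window``). With
    no trace inside the tolerance the EIC comes back empty and flagged
    missing.
    """
    half = params.rt_window if rt_halfwidth is None else rt_halfwidth
    mask = (chromset.time >= expected_rt - half) & (chromset.time <= expected_rt + half)
    t = chromset.time[mask]
    tol = params.fragment_ppm_tol * 1e-6 * mz
    total = None
    for (key, trace_mz), intensity in chromset.traces.items():
        if target_key is not None and key != target_key:
            continue
        if abs(trace_mz - mz) <= tol:
            clipped = intensity[mask]
            total = clipped.copy() if total is None else total + clipped
    if total is None:
        return EIC(t, np.zeros_like(t), mz, params.fragment_ppm_tol, missing=True)
    return EIC(t, total, mz, params.fragment_ppm_tol)


def detect_isomer_peaks(composite: EIC, params: QuantParams) -> list[IsomerPeak]:
    """Detect isomer apexes on a composite trace and set their bounds.

    Local maxima with prominence above ``peak_min_prominence`` of the
    tallest apex; adjacent peaks split at the valley between them; outer
    bounds where the trace falls to ``boundary_frac`` of the apex (whichever
    comes first). Peaks are indexed 1..k in ascending retention time.
    """
    y = composite.intensity
    t = composite.time
    if len(y) < 3 or np.all(y <= 0):
        return []
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(params.min_isomer_separation / dt)))
    apex_idx, _ = find_peaks(y, prominence=params.peak_min_prominence * float(y.max()), distance=distance)
    if len(apex_idx) == 0:
        return []
    peaks: list[IsomerPeak] = []
    for rank, i in enumerate(apex_idx):
        apex = y[i]
        floor = params.boundary_frac * apex
        # valley split against neighbours
        left_limit = 0 if rank == 0 else apex_idx[rank - 1] + int(np.argmin(y[apex_idx[rank - 1] : i + 1]))
        right_limit = (
            len(y) - 1
            if rank == len(apex_idx) - 1
            else i + int(np.argmin(y[i : apex_idx[rank + 1] + 1]))
        )
        lo = i
        while lo > left_limit and y[lo - 1] > floor:
            lo -= 1
        hi = i
        while hi < right_limit and y[hi + 1] > floor:
            hi += 1
        hi = min(hi, right_limit)
        # guard: bounds must bracket the apex on the grid
        lo = min(lo, i - 1) if i > 0 else 0
        hi = max(hi, i + 1) if i < len(y) - 1 else len(y) - 1
        peaks.append(
            IsomerPeak(
                apex_rt=float(t[i]),
                left=float(t[lo]),
                right=float(t[hi]),
                isomer_index=rank + 1,
                apex_intensity=float(apex),
            )
        )
    return peaks


def integrate_peak(eic: EIC, bounds: tuple[float, float]) -> float:
    """Trapezoidal peak area above a local linear baseline (floored at 0).

    The baseline interpolates linearly between the trace intensities at the
    two bounds, the Xcalibur-like local convention.
    """
    lo, hi = bounds
    if hi <= lo:
        raise ValueError(f"inverted integration bounds ({lo}, {hi})")
    mask = (eic.time >= lo) & (eic.time <= hi)
    t = eic.time[mask]
    y = eic.intensity[mask]
    if len(t) < 2:
        return 0.0
    baseline = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    area = float(np.trapezoid(y - baseline, t))
    return max(area, 0.0)


def quantify_target(
    chromset: ChromatogramSet,
    entries: Sequence[GlycopeptideTarget] | GlycopeptideTarget,
    params: QuantParams,
) -> list[tuple[int, float, float]]:
    """Quantify every isomer of one glycoform.

    ``entries`` are the isomer entries of a single (site, composition) form
    (a lone target is accepted). The six fragment EICs are extracted over a
    window spanning all expected isomer RTs ± ``rt_window``, summed into a
    composite, and each detected peak is integrated on the composite.
    Detected peaks map to isomer indices in RT order; surplus detections
    keep the tallest ``n_isomers`` apexes (logged), undetected isomers
    report area 0.

    Returns ``[(isomer_index, area, apex_rt), ...]`` with ``apex_rt`` NaN
    for undetected isomers.
    """
    if isinstance(entries, GlycopeptideTarget):
        entries = [entries]
    if not entries:
        raise ValueError("no target entries given")
    keys = {e.key for e in entries}
    if len(keys) > 1:
        raise ValueError(f"entries span multiple glycoforms: {sorted(keys)}")
    key = entries[0].key
    n_isomers = max(e.n_isomers for e in entries)
    rts = [e.expected_rt for e in entries]
    center = 0.5 * (min(rts) + max(rts))
    half = 0.5 * (max(rts) - min(rts)) + params.rt_window
    if not entries[0].fragment_mzs:
        raise ValueError(f"target {key} has an empty fragment list")

    eics = [
        extract_eic(chromset, mz, params, center, rt_halfwidth=half, target_key=key)
        for mz in entries[0].fragment_mzs
    ]
    if all(e.missing for e in eics):
        logger.warning("no fragment traces found for %s; reporting zero areas", key)
        return [(i, 0.0, float("nan")) for i in range(1, n_isomers + 1)]
    time = eics[0].time
    composite = EIC(time, np.sum([e.intensity for e in eics], axis=0), 0.0, params.fragment_ppm_tol)
    peaks = detect_isomer_peaks(composite, params)
    if len(peaks) > n_isomers:
        logger.info(
            "%s: %d apexes detected for %d expected isomers; keeping the tallest",
            key,
            len(peaks),
            n_isomers,
        )
        peaks = sorted(peaks, key=lambda p: -p.apex_intensity)[:n_isomers]
        peaks = sorted(peaks, key=lambda p: p.apex_rt)
    out: list[tuple[int, float, float]] = []
    for idx in range(1, n_isomers + 1):
        if idx <= len(peaks):
            p = peaks[idx - 1]
            p.area = integrate_peak(composite, (p.left, p.right))
            p.isomer_index = idx
            out.append((idx, p.area, p.apex_rt))
        else:
            out.append((idx, 0.0, float("nan")))
    return out


def build_quant_table(
    chromatograms: Mapping[str, ChromatogramSet],
    targets: Iterable[GlycopeptideTarget],
    params: QuantParams | None = None,
) -> QuantTable:
    """Quantify the whole cohort into a patients × isomer-entries table."""
    params = params or QuantParams()
    targets = list(targets)
    forms: dict[str, list[GlycopeptideTarget]] = {}
    for t in targets:
        forms.setdefault(t.key, []).append(t)
    columns = [e.entry_key for key in forms for e in sorted(forms[key], key=lambda x: x.isomer_index)]
    patient_ids = sorted(chromatograms)
    areas = pd.DataFrame(0.0, index=patient_ids, columns=columns)
    apex = pd.DataFrame(np.nan, index=patient_ids, columns=columns)
    missing = pd.DataFrame(False, index=patient_ids, columns=columns)
    for pid in patient_ids:
        chromset = chromatograms[pid]
        for key, entries in forms.items():
            entries = sorted(entries, key=lambda e: e.isomer_index)
            for idx, area, apex_rt in quantify_target(chromset, entries, params):
                col = f"{key}|{idx}"
                areas.loc[pid, col] = area
                apex.loc[pid, col] = apex_rt
                missing.loc[pid, col] = not np.isfinite(apex_rt)
    areas.index.name = apex.index.name = missing.index.name = "patient_id"
    return QuantTable(areas=areas, apex_rts=apex, missing=missing)
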