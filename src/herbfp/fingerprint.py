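"""Common-peak fingerprint construction and similarity scoring.

Pipeline order: per-batch peak lists are first put on a common retention
scale by marker-anchored piecewise-linear warping, then matched to a
reference batch's peaks inside a fixed time window; peaks matched in every
batch form the common set.  The reference fingerprint is the column-wise
average of the common-peak area table, and each batch is scored against it
with the congruence (cosine) coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peaks import Peak
from .synthetic import Chromatogram

__all__ = [
    "PeakTable",
    "ReferenceFingerprint",
    "correct_retention_times",
    "match_common_peaks",
    "build_reference_fingerprint",
    "similarity",
    "similarity_table",
    "profile_similarity",
]


@dataclass
class PeakTable:
    """Aligned batches × common-peaks tables of areas and apex times."""

    areas: pd.DataFrame                  # batches x peak ids
    apex_times: pd.DataFrame             # batches x peak ids
    reference_times: pd.Series           # peak id -> reference apex (min)
    reference_batch: str
    window: float
    markers: dict[str, str] = field(default_factory=dict)  # peak id -> analyte
    dropped_batches: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.areas <= 0).any().any():
            raise ValidationError(
                "every common peak must have positive area in every batch")

    @property
    def batches(self) -> list[str]:
        return list(self.areas.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.columns)

    def marker_peak(self, analyte: str) -> str:
        for pid, name in self.markers.items():
            if name == analyte:
                return pid
        raise KeyError(f"no common peak annotated as {analyte!r}")


@dataclass
class ReferenceFingerprint:
    reference_times: pd.Series
    mean_areas: pd.Series
    method: str = "average"


def _warp_times(times: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Piecewise-linear map sending src anchors onto dst, with linear
    extrapolation beyond the terminal anchors."""
    times = np.asarray(times, dtype=float)
    out = np.interp(times, src, dst)
    lo = times < src[0]
    if lo.any():
        slope = (dst[1] - dst[0]) / (src[1] - src[0])
        out[lo] = dst[0] + slope * (times[lo] - src[0])
    hi = times > src[-1]
    if hi.any():
        slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
        out[hi] = dst[-1] + slope * (times[hi] - src[-1])
    return out


def correct_retention_times(
    peak_lists: dict[str, list[Peak]],
    markers: dict[str, list[float]],
    reference_markers: list[float],
) -> dict[str, list[Peak]]:
    """Warp each batch's peak times so its marker apexes land exactly on the
    reference marker times.

    ``markers[batch]`` and ``reference_markers`` are equal-length, strictly
    increasing apex-time sequences (>= 2 anchors).  Non-marker apexes are
    interpolated piecewise-linearly and extrapolated linearly beyond the
    terminal markers; the warp is monotone by construction.
    """
    ref = np.asarray(reference_markers, dtype=float)
    if ref.size < 2:
        raise ValidationError("need at least 2 markers")
    if np.any(np.diff(ref) <= 0):
        raise ValidationError("reference markers must be strictly increasing")
    corrected: dict[str, list[Peak]] = {}
    for batch, peaks in peak_lists.items():
        if batch not in markers:
            raise ValidationError(f"no markers for batch {batch}")
        src = np.asarray(markers[batch], dtype=float)
        if src.size != ref.size:
            raise ValidationError(
                f"batch {batch}: marker count {src.size} != reference {ref.size}")
        if np.any(np.diff(src) <= 0):
            raise ValidationError(
                f"batch {batch}: non-monotone marker correspondence")
        warped = []
        for p in peaks:
            apex, left, right = _warp_times(
                np.array([p.apex_time, p.left_bound, p.right_bound]), src, ref)
            warped.append(p.warped(apex, left, right))
        corrected[batch] = warped
    return corrected


def _greedy_match(ref_times: np.ndarray, times: np.ndarray,
                  window: float) -> dict[int, int]:
    """One-pass greedy matching: candidate pairs within the window sorted by
    |dt| then earlier apex; each side used at most once."""
    pairs = []
    for i, rt in enumerate(ref_times):
        for j, t in enumerate(times):
            dt = abs(t - rt)
            if dt <= window:
                pairs.append((dt, t, i, j))
    pairs.sort(key=lambda x: (x[0], x[1]))
    used_ref, used_pk, match = set(), set(), {}
    for _, _, i, j in pairs:
        if i in used_ref or j in used_pk:
            continue
        used_ref.add(i)
        used_pk.add(j)
        match[i] = j
    return match


def match_common_peaks(
    corrected: dict[str, list[Peak]],
    reference_batch: str,
    window: float = 0.1,
    allow_missing_batches: bool = False,
) -> PeakTable:
    """Match each batch's peaks to the reference batch's peaks.

    Peaks of the reference batch matched (within ± ``window`` minutes) in
    every batch form the common set.  A batch with an empty peak list
    aborts the match unless ``allow_missing_batches`` is set, in which case
    it is dropped with a warning and reported via
    ``PeakTable.dropped_batches``.
    """
    if window <= 0:
        raise ValidationError("window must be > 0")
    if reference_batch not in corrected:
        raise ValidationError(f"reference batch {reference_batch!r} missing")
    empty = [b for b, pk in corrected.items() if len(pk) == 0]
    if empty:
        if not allow_missing_batches:
            raise ValidationError(
                f"empty peak list for batches: {empty}")
        warnings.warn(f"dropping batches with no peaks: {empty}")
        corrected = {b: pk for b, pk in corrected.items() if pk}
        if reference_batch not in corrected:
            raise ValidationError("reference batch has no peaks")

    ref_peaks = sorted(corrected[reference_batch], key=lambda p: p.apex_time)
    ref_times = np.array([p.apex_time for p in ref_peaks])
    batches = list(corrected)

    matched: dict[str, dict[int, Peak]] = {}
    for batch in batches:
        pks = sorted(corrected[batch], key=lambda p: p.apex_time)
        times = np.array([p.apex_time for p in pks])
        m = _greedy_match(ref_times, times, window)
        matched[batch] = {i: pks[j] for i, j in m.items()}

    common = [i for i in range(len(ref_peaks))
              if all(i in matched[b] for b in batches)]
    peak_ids = [f"peak_{k + 1:02d}" for k in range(len(common))]
    areas = pd.DataFrame(
        {pid: [matched[b][i].area for b in batches]
         for pid, i in zip(peak_ids, common)}, index=batches)
    apexes = pd.DataFrame(
        {pid: [matched[b][i].apex_time for b in batches]
         for pid, i in zip(peak_ids, common)}, index=batches)
    ref_series = pd.Series(
        {pid: apexes[pid].mean() for pid in peak_ids}, name="reference_time")
    return PeakTable(
        areas=areas,
        apex_times=apexes,
        reference_times=ref_series,
        reference_batch=reference_batch,
        window=window,
        dropped_batches=tuple(empty) if empty else (),
    )


def build_reference_fingerprint(table: PeakTable,
                                method: str = "average") -> ReferenceFingerprint:
    """Averaged reference fingerprint: per-peak arithmetic mean of areas."""
    if method != "average":
        raise ValidationError(f"unsupported fingerprint method {method!r}")
    if table.areas.empty:
        raise ValidationError("empty peak table")
    return ReferenceFingerprint(
        reference_times=table.reference_times.copy(),
        mean_areas=table.areas.mean(axis=0),
        method=method,
    )


def similarity(batch_vector, reference_vector) -> float:
    """Congruence (cosine) coefficient between two common-peak area vectors."""
    x = np.asarray(batch_vector, dtype=float)
    y = np.asarray(reference_vector, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("vectors must be 1-D and of equal length >= 1")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValidationError("zero vector")
    return float(x @ y / (nx * ny))


def similarity_table(table: PeakTable,
                     reference: ReferenceFingerprint | None = None) -> pd.Series:
    """Per-batch similarity of the common-peak area vector to the averaged
    reference fingerprint."""
    if reference is None:
        reference = build_reference_fingerprint(table)
    ref = reference.mean_areas.reindex(table.peak_ids).to_numpy()
    return pd.Series(
        {b: similarity(table.areas.loc[b].to_numpy(), ref)
         for b in table.batches}, name="similarity")


def profile_similarity(a: Chromatogram, b: Chromatogram) -> float:
    """Full-curve cosine similarity on a shared time grid (comparison
    variant; the common-peak vector is the primary metric)."""
    lo = max(a.time[0], b.time[0])
    hi = min(a.time[-1], b.time[-1])
    if hi <= lo:
        raise ValidationError("chromatograms do not overlap in time")
    grid = np.linspace(lo, hi, 2000)
    ya = np.interp(grid, a.time, a.intensity)
    yb = np.interp(grid, b.time, b.intensity)
    return similarity(ya, yb)
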