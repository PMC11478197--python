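"""Peak detection, integration and noise/LOD estimation for chromatograms.

Conventions (documented, configurable):

- smoothing: Savitzky–Golay, default 11-point window, order 3;
- baseline: morphological opening (rolling-minimum erosion followed by
  dilation) of the smoothed trace, with a structuring window much wider
  than a peak;
- signal-to-noise: baseline-corrected peak height divided by the noise
  standard deviation;
- peak bounds: flanking valley minima between neighbouring peaks, else the
  points where the signal falls below a small fraction of the peak height
  (perpendicular drop; no deconvolution of fused peaks);
- LOD/LOQ: concentrations at signal-to-noise 3 and 10 given the calibration
  sensitivity expressed as height per concentration unit, so
  ``loq = (10/3) * lod`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_opening
from scipy.signal import detrend, find_peaks, savgol_coeffs, savgol_filter

from .errors import ValidationError
from .synthetic import Chromatogram

__all__ = [
    "Peak",
    "NoiseEstimate",
    "estimate_noise",
    "detect_peaks",
    "lod_loq",
]


@dataclass(frozen=True)
class Peak:
    """A detected peak on the baseline-corrected signal."""

    apex_time: float
    left_bound: float
    right_bound: float
    height: float
    area: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.left_bound < self.apex_time < self.right_bound):
            raise ValidationError("peak bounds must bracket the apex")
        if self.height <= 0:
            raise ValidationError("peak height must be > 0")
        if self.area < 0:
            raise ValidationError("peak area must be >= 0")

    def shifted(self, offset: float) -> "Peak":
        return Peak(self.apex_time + offset, self.left_bound + offset,
                    self.right_bound + offset, self.height, self.area,
                    self.snr)

    def warped(self, apex: float, left: float, right: float) -> "Peak":
        return Peak(apex, left, right, self.height, self.area, self.snr)


@dataclass(frozen=True)
class NoiseEstimate:
    sd: float
    region: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if self.region[1] <= self.region[0]:
            raise ValidationError("noise region must be non-empty")


def estimate_noise(chrom: Chromatogram, region: tuple[float, float],
                   min_samples: int = 20) -> NoiseEstimate:
    """Standard deviation of the linearly detrended intensity in ``region``.

    The region must lie within the time grid, span at least ``min_samples``
    points and be peak-free: a detrended excursion far beyond the robust
    noise scale raises ``ValidationError``.
    """
    lo, hi = region
    if lo < chrom.time[0] - 1e-12 or hi > chrom.time[-1] + 1e-12 or hi <= lo:
        raise ValidationError("noise region outside the time grid")
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    if int(mask.sum()) < min_samples:
        raise ValidationError(
            f"noise region too short ({int(mask.sum())} < {min_samples} samples)")
    resid = detrend(chrom.intensity[mask], type="linear")
    floor = 1e-10 * max(1.0, float(np.max(np.abs(chrom.intensity[mask]))))
    resid[np.abs(resid) < floor] = 0.0   # detrend float residue
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    peak_excursion = float(np.max(np.abs(resid)))
    if robust_sd == 0.0:
        if peak_excursion > 1e-9 * max(1.0, float(np.max(np.abs(chrom.intensity)))):
            raise ValidationError("noise region overlaps a peak")
        return NoiseEstimate(sd=0.0, region=(lo, hi))
    if peak_excursion > 8.0 * robust_sd:
        raise ValidationError("noise region overlaps a peak")
    return NoiseEstimate(sd=float(np.std(resid, ddof=1)), region=(lo, hi))


def _raw_noise_sd(y: np.ndarray) -> float:
    """Robust white-noise scale from first differences."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(
    chrom: Chromatogram,
    min_snr: float = 5.0,
    smooth_window: int = 11,
    smooth_order: int = 3,
    baseline_window: float = 1.0,
    noise_sd: float | None = None,
    bound_height_frac: float = 0.005,
) -> list[Peak]:
    """Detect and integrate peaks.

    Peaks are local maxima of the smoothed, baseline-subtracted signal with
    prominence at least ``min_snr`` times the (raw) noise standard
    deviation.  ``baseline_window`` is the width, in minutes, of the
    morphological-opening structuring element.  Returns peaks sorted by
    apex time; an all-flat trace yields an empty list.
    """
    if min_snr <= 0:
        raise ValidationError("min_snr must be > 0")
    y = chrom.intensity
    n = len(y)
    win = min(smooth_window, n if n % 2 else n - 1)
    if win > smooth_order + 1:
        smooth = savgol_filter(y, win, smooth_order)
    else:
        smooth = y.copy()
    size = max(3, int(round(baseline_window / chrom.dt)) | 1)
    baseline = grey_opening(smooth, size=min(size, n))
    signal = smooth - baseline

    sd = _raw_noise_sd(y) if noise_sd is None else float(noise_sd)
    scale = float(np.max(np.abs(signal))) if n else 0.0
    if scale <= 0:
        return []
    if sd < 1e-12 * scale:
        sd = 0.0   # numerically noiseless
    prominence = max(min_snr * sd, 1e-9 * scale)
    idx, _ = find_peaks(signal, prominence=prominence)
    if len(idx) == 0:
        return []

    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        height = float(signal[apex])
        floor = bound_height_frac * height
        # left bound: valley towards previous apex, else drop below floor
        left_stop = idx[k - 1] if k > 0 else 0
        if k > 0:
            left = left_stop + int(np.argmin(signal[left_stop:apex + 1]))
        else:
            left = apex
            while left > 0 and signal[left - 1] > floor:
                left -= 1
        right_stop = idx[k + 1] if k + 1 < len(idx) else n - 1
        if k + 1 < len(idx):
            right = apex + int(np.argmin(signal[apex:right_stop + 1]))
        else:
            right = apex
            while right < n - 1 and signal[right + 1] > floor:
                right += 1
        if right <= left:
            continue
        area = float(np.trapezoid(np.clip(signal[left:right + 1], 0.0, None),
                                  chrom.time[left:right + 1]))
        snr = height / sd if sd > 0 else float("inf")
        peaks.append(Peak(
            apex_time=float(chrom.time[apex]),
            left_bound=float(chrom.time[left]),
            right_bound=float(chrom.time[right]),
            height=height,
            area=area,
            snr=snr,
        ))
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def smoothed_noise_factor(window: int = 11, order: int = 3) -> float:
    """L2 norm of the Savitzky–Golay impulse response: the factor by which
    white-noise sd shrinks after smoothing."""
    return float(np.linalg.norm(savgol_coeffs(window, order)))


def lod_loq(noise: NoiseEstimate | float, height_per_conc: float) -> tuple[float, float]:
    """Detection and quantification limits at signal-to-noise 3 and 10.

    ``height_per_conc`` is the calibration sensitivity expressed as
    baseline-corrected peak height per concentration unit.  Returns
    ``(lod, loq)`` with ``loq = (10/3) * lod`` exactly.
    """
    sd = noise.sd if isinstance(noise, NoiseEstimate) else float(noise)
    if sd < 0:
        raise ValidationError("noise sd must be >= 0")
    if height_per_conc <= 0:
        raise ValidationError("sensitivity must be > 0")
    lod = 3.0 * sd / height_per_conc
    loq = 10.0 * sd / height_per_conc
    return lod, loq
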