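"""Synthetic HPLC-ELSD chromatogram generator.

Generates single traces, five-level calibration series and multi-batch
panels with the statistical structure the downstream fingerprint /
chemometrics / QAMS stages assume: shared constituents with group-wise
fold-changes, retention-time drift (a systematic per-batch shift plus
per-peak jitter), multiplicative area noise, optional baseline drift and
additive detector noise, and optional batch-specific extra peaks.

The signal model is a sum of Gaussian (optionally exponentially-modified
Gaussian) peaks on a low-order baseline.  Each constituent's peak *area* is
tied to its concentration through a detector response line
``area = slope * C + intercept`` (floored at zero), so that integrating a
noiseless trace recovers the response line exactly up to discretization
error.  A classical ELSD power-law response ``area = slope * C**b`` is
available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .defaults import CALIBRATIONS, NAMED_ANALYTES, RETENTION_TIMES
from .errors import ValidationError

__all__ = [
    "ConstituentSpec",
    "Chromatogram",
    "PanelConfig",
    "Panel",
    "default_constituents",
    "simulate_chromatogram",
    "simulate_panel",
    "simulate_calibration_series",
    "ideal_areas",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ConstituentSpec:
    """One simulated constituent: where it elutes and how the detector responds.

    ``response_slope``/``response_intercept`` define the linear area
    response (area units per µg/mL and area units); ``power_exponent`` is
    only used in the power-law response mode.
    """

    id: str
    retention_time: float
    response_slope: float
    peak_sigma: float = 0.06
    response_intercept: float = 0.0
    base_concentration: float = 50.0
    power_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValidationError(f"{self.id}: retention_time must be > 0")
        if self.peak_sigma <= 0:
            raise ValidationError(f"{self.id}: peak_sigma must be > 0")
        if self.response_slope <= 0:
            raise ValidationError(f"{self.id}: response_slope must be > 0")
        if self.base_concentration < 0:
            raise ValidationError(
                f"{self.id}: base_concentration must be >= 0")

    def ideal_area(self, concentration: float, response: str = "linear") -> float:
        """Detector peak area for a concentration, floored at zero."""
        if concentration < 0:
            raise ValidationError(
                f"{self.id}: negative concentration {concentration}")
        if response == "linear":
            area = self.response_slope * concentration + self.response_intercept
        elif response == "power":
            area = self.response_slope * concentration ** self.power_exponent
        else:
            raise ValidationError(f"unknown response mode {response!r}")
        return max(area, 0.0)


@dataclass
class Chromatogram:
    """A time/intensity trace plus free-form sample metadata.

    The time grid must be strictly increasing and uniform (relative spacing
    tolerance 1e-9); intensity must be finite and of equal length.
    """

    time: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("time and intensity must be 1-D")
        if len(self.time) != len(self.intensity) or len(self.time) < 2:
            raise ValidationError(
                "time and intensity must have equal length >= 2")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity must be finite")
        step = dt[0]
        if np.any(np.abs(dt - step) > 1e-9 * max(abs(step), 1.0)):
            raise ValidationError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def _gaussian(t: np.ndarray, rt: float, sigma: float, area: float) -> np.ndarray:
    height = area / (sigma * _SQRT2PI)
    z = (t - rt) / sigma
    return height * np.exp(-0.5 * z * z)


def _emg(t: np.ndarray, rt: float, sigma: float, area: float,
         tau: float) -> np.ndarray:
    # exponentially-modified Gaussian; area-normalized analytic form
    from scipy.stats import exponnorm
    k = tau / sigma
    return area * exponnorm.pdf(t, k, loc=rt, scale=sigma)


def ideal_areas(constituents, concentrations, response: str = "linear") -> np.ndarray:
    """Noise-free peak areas for each constituent at given concentrations."""
    concentrations = np.asarray(concentrations, dtype=float)
    if len(concentrations) != len(constituents):
        raise ValidationError(
            "concentrations must match constituents in length")
    return np.array([c.ideal_area(conc, response)
                     for c, conc in zip(constituents, concentrations)])


def _render(constituents, concentrations, time, rng, *, area_noise_cv=0.0,
            rt_jitter_sd=0.0, rt_shift=0.0, drift_amplitude=0.0,
            detector_noise_sd=0.0, peak_shape="gaussian", emg_tau=0.05,
            response="linear"):
    """Render a trace; returns (intensity, realized_areas, apex_times)."""
    base_areas = ideal_areas(constituents, concentrations, response)
    n = len(constituents)
    factors = np.ones(n)
    if area_noise_cv > 0:
        factors = 1.0 + rng.normal(0.0, area_noise_cv, size=n)
        factors = np.clip(factors, 0.0, None)
    jitter = np.zeros(n)
    if rt_jitter_sd > 0:
        jitter = rng.normal(0.0, rt_jitter_sd, size=n)
    areas = base_areas * factors
    apexes = np.array([c.retention_time for c in constituents]) + rt_shift + jitter

    y = np.zeros_like(time)
    for spec, area, rt in zip(constituents, areas, apexes):
        if area <= 0:
            continue
        if peak_shape == "gaussian":
            y += _gaussian(time, rt, spec.peak_sigma, area)
        elif peak_shape == "emg":
            y += _emg(time, rt, spec.peak_sigma, area, emg_tau)
        else:
            raise ValidationError(f"unknown peak_shape {peak_shape!r}")
    if drift_amplitude:
        span = time[-1] - time[0]
        y += drift_amplitude * 0.5 * (
            1.0 - np.cos(2.0 * math.pi * (time - time[0]) / span))
    if detector_noise_sd > 0:
        y += rng.normal(0.0, detector_noise_sd, size=len(time))
    return y, areas, apexes


def simulate_chromatogram(
    constituents,
    concentrations,
    *,
    time_range: tuple[float, float] | None = None,
    dt: float = 0.01,
    area_noise_cv: float = 0.0,
    rt_jitter_sd: float = 0.0,
    rt_shift: float = 0.0,
    drift_amplitude: float = 0.0,
    detector_noise_sd: float = 0.0,
    peak_shape: str = "gaussian",
    emg_tau: float = 0.05,
    response: str = "linear",
    seed: int = 0,
    meta: dict | None = None,
) -> Chromatogram:
    """Simulate a single chromatogram.

    The time grid defaults to covering every retention time ± 6 peak sigmas
    (with a margin), and is validated to cover at least ± 4 sigmas.
    Deterministic for a fixed seed.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(concentrations) != len(constituents):
        raise ValidationError(
            "concentrations must match constituents in length")
    if np.any(concentrations < 0):
        raise ValidationError("negative concentration rejected")
    if time_range is None:
        lo = min(c.retention_time - 6 * c.peak_sigma for c in constituents)
        hi = max(c.retention_time + 6 * c.peak_sigma for c in constituents)
        time_range = (max(0.0, lo - 1.0), hi + 1.0)
    t0, t1 = time_range
    if t1 <= t0:
        raise ValidationError("empty time range")
    for c in constituents:
        if (c.retention_time - 4 * c.peak_sigma < t0
                or c.retention_time + 4 * c.peak_sigma > t1):
            raise ValidationError(
                f"retention time of {c.id} outside the time grid "
                f"({c.retention_time:.3f} min not within "
                f"[{t0:.3f}, {t1:.3f}] ± 4 sigma)")
    time = t0 + dt * np.arange(int(round((t1 - t0) / dt)) + 1)
    rng = np.random.default_rng(seed)
    y, _, _ = _render(
        constituents, concentrations, time, rng,
        area_noise_cv=area_noise_cv, rt_jitter_sd=rt_jitter_sd,
        rt_shift=rt_shift, drift_amplitude=drift_amplitude,
        detector_noise_sd=detector_noise_sd, peak_shape=peak_shape,
        emg_tau=emg_tau, response=response)
    return Chromatogram(time=time, intensity=y, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Panels

#: Vocabulary for per-batch processing methods.
PROCESSING_METHODS = ("post_steaming_dried", "directly_dried", "freeze_dried")

#: Vocabulary for panel groups.
GROUPS = ("southern", "northern_freeze_dried", "northern_heat_dried")


def _default_group_assignment(n_batches: int = 18) -> dict[str, str]:
    """Default 18-batch layout: S10–S15 southern; S3/S6/S9/S18 freeze-dried
    northern; the remaining northern batches heat dried (directly or
    post-steaming)."""
    if n_batches != 18:
        # generic: split thirds
        out = {}
        for i in range(n_batches):
            out[f"S{i + 1}"] = GROUPS[i * 3 // n_batches]
        return out
    assignment = {}
    for i in range(1, 19):
        b = f"S{i}"
        if 10 <= i <= 15:
            assignment[b] = "southern"
        elif i in (3, 6, 9, 18):
            assignment[b] = "northern_freeze_dried"
        else:
            assignment[b] = "northern_heat_dried"
    return assignment


def _default_processing(n_batches: int = 18) -> dict[str, str]:
    """Processing-method metadata rotating post-steaming/directly/freeze."""
    return {f"S{i + 1}": PROCESSING_METHODS[i % 3] for i in range(n_batches)}


@dataclass
class PanelConfig:
    """Configuration for a multi-batch synthetic panel.

    ``origin_subset`` constituents are boosted ``origin_effect``-fold in the
    ``southern`` group; ``processing_subset`` constituents are boosted
    ``processing_effect``-fold in the ``northern_heat_dried`` group.  The
    two subsets must be disjoint unless ``allow_subset_overlap`` is set.
    """

    n_batches: int = 18
    group_assignment: dict[str, str] = field(default_factory=_default_group_assignment)
    processing_methods: dict[str, str] = field(default_factory=_default_processing)
    n_shared_constituents: int = 30
    origin_effect: float = 2.5
    processing_effect: float = 2.5
    origin_subset: tuple[str, ...] | None = None       # None -> defaults
    processing_subset: tuple[str, ...] | None = None
    allow_subset_overlap: bool = False
    area_noise_cv: float = 0.01
    rt_jitter_sd: float = 0.01
    rt_shift_sd: float = 0.05
    drift_amplitude: float = 0.0
    detector_noise_sd: float = 0.0
    extra_peaks: int = 2
    dt: float = 0.01
    time_range: tuple[float, float] = (0.0, 52.0)
    peak_shape: str = "gaussian"
    response: str = "linear"
    seed: int = 0

    def batches(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_batches)]

    def validate(self) -> None:
        if self.n_batches < 2:
            raise ValidationError("n_batches must be >= 2")
        for b in self.batches():
            if b not in self.group_assignment:
                raise ValidationError(f"group_assignment missing batch {b}")
            if self.group_assignment[b] not in GROUPS:
                raise ValidationError(
                    f"unknown group {self.group_assignment[b]!r} for {b}")
        if self.area_noise_cv < 0 or self.rt_jitter_sd < 0 or self.rt_shift_sd < 0:
            raise ValidationError("noise parameters must be >= 0")
        if self.n_shared_constituents < len(NAMED_ANALYTES):
            raise ValidationError(
                f"need at least {len(NAMED_ANALYTES)} shared constituents")


def default_constituents(n: int = 30) -> list[ConstituentSpec]:
    """The default shared-constituent set: the six identified analytes with
    their published response lines, padded with generic constituents on a
    regular retention grid."""
    if n < len(NAMED_ANALYTES):
        raise ValidationError(
            f"n must be >= {len(NAMED_ANALYTES)}")
    specs = []
    for name in NAMED_ANALYTES:
        cal = CALIBRATIONS[name]
        mid = 0.5 * (cal["c_min"] + cal["c_max"])
        specs.append(ConstituentSpec(
            id=name,
            retention_time=RETENTION_TIMES[name],
            response_slope=cal["slope"],
            response_intercept=cal["intercept"],
            base_concentration=round(mid, 2),
        ))
    n_generic = n - len(NAMED_ANALYTES)
    for k in range(n_generic):
        rt = 8.5 + 1.1 * k
        specs.append(ConstituentSpec(
            id=f"x{k + 1:02d}",
            retention_time=rt,
            response_slope=800.0 + 70.0 * (k % 11),
            response_intercept=-50.0 - 3.0 * k,
            base_concentration=30.0 + 2.0 * (k % 7),
        ))
    specs.sort(key=lambda s: s.retention_time)
    return specs


def _default_subsets(constituents) -> tuple[tuple[str, ...], tuple[str, ...]]:
    # sized so that, after unit-variance scaling, the origin contrast carries
    # the most variance (dominant PC) while the processing contrast still
    # separates cleanly and silhouette selection recovers three clusters
    generic = [c.id for c in constituents if c.id not in NAMED_ANALYTES]
    origin = tuple(generic[:13])
    processing = (
        "macrostemonoside_t", "macrostemonoside_a", "macrostemonoside_u",
    ) + tuple(generic[13:21])
    return origin, processing


@dataclass
class Panel:
    """A simulated panel plus its generator ground truth."""

    chromatograms: list[Chromatogram]
    constituents: list[ConstituentSpec]
    concentrations: pd.DataFrame     # batches x constituents, post-effect
    ideal_areas: pd.DataFrame        # noise-free areas
    realized_areas: pd.DataFrame     # areas after multiplicative noise
    apex_times: pd.DataFrame         # jittered + shifted apex times
    rt_shifts: pd.Series             # per-batch systematic shift
    manifest: list[dict]
    config: PanelConfig

    @property
    def batches(self) -> list[str]:
        return list(self.concentrations.index)

    def group_of(self, batch: str) -> str:
        return self.config.group_assignment[batch]


def simulate_panel(config: PanelConfig | None = None,
                   constituents: list[ConstituentSpec] | None = None) -> Panel:
    """Simulate an ``n_batches`` panel of chromatograms.

    Reproducible: identical config (and constituent list) gives a
    bit-identical panel.  Group effects are multiplicative on the configured
    constituent subsets; each batch additionally receives a systematic
    retention shift, per-peak jitter, multiplicative area noise and,
    optionally, ``extra_peaks`` batch-specific peaks eluting after the
    shared window.
    """
    config = config or PanelConfig()
    config.validate()
    if constituents is None:
        constituents = default_constituents(config.n_shared_constituents)
    if len(constituents) != config.n_shared_constituents:
        raise ValidationError("constituent list does not match config")
    ids = [c.id for c in constituents]
    origin_subset = config.origin_subset
    processing_subset = config.processing_subset
    if origin_subset is None or processing_subset is None:
        d_o, d_p = _default_subsets(constituents)
        origin_subset = d_o if origin_subset is None else origin_subset
        processing_subset = d_p if processing_subset is None else processing_subset
    unknown = (set(origin_subset) | set(processing_subset)) - set(ids)
    if unknown:
        raise ValidationError(f"effect subsets name unknown constituents: {sorted(unknown)}")
    overlap = set(origin_subset) & set(processing_subset)
    if overlap and not config.allow_subset_overlap:
        raise ValidationError(
            f"origin and processing subsets overlap: {sorted(overlap)}")

    rng = np.random.default_rng(config.seed)
    batches = config.batches()
    shifts = pd.Series(
        rng.normal(0.0, config.rt_shift_sd, size=len(batches))
        if config.rt_shift_sd > 0 else np.zeros(len(batches)),
        index=batches, name="rt_shift")

    t0, t1 = config.time_range
    time = t0 + config.dt * np.arange(int(round((t1 - t0) / config.dt)) + 1)

    conc_rows, ideal_rows, real_rows, apex_rows = [], [], [], []
    chroms, manifest = [], []
    for bi, batch in enumerate(batches):
        group = config.group_assignment[batch]
        conc = np.array([c.base_concentration for c in constituents])
        if group == "southern":
            for j, cid in enumerate(ids):
                if cid in origin_subset:
                    conc[j] *= config.origin_effect
        elif group == "northern_heat_dried":
            for j, cid in enumerate(ids):
                if cid in processing_subset:
                    conc[j] *= config.processing_effect
        specs = list(constituents)
        concentrations = conc
        if config.extra_peaks > 0:
            for e in range(config.extra_peaks):
                specs = specs + [ConstituentSpec(
                    id=f"{batch}_extra{e + 1}",
                    retention_time=44.0 + 0.35 * bi + 0.18 * e,
                    response_slope=1000.0,
                    base_concentration=30.0,
                )]
            concentrations = np.concatenate(
                [conc, np.full(config.extra_peaks, 30.0)])

        y, areas, apexes = _render(
            specs, concentrations, time, rng,
            area_noise_cv=config.area_noise_cv,
            rt_jitter_sd=config.rt_jitter_sd,
            rt_shift=float(shifts[batch]),
            drift_amplitude=config.drift_amplitude,
            detector_noise_sd=config.detector_noise_sd,
            peak_shape=config.peak_shape,
            response=config.response)

        processing = config.processing_methods.get(batch, "directly_dried")
        meta = {
            "batch": batch,
            "group": group,
            "origin": "southern" if group == "southern" else "northern",
            "processing_method": processing,
        }
        chroms.append(Chromatogram(time=time.copy(), intensity=y, meta=meta))
        manifest.append(meta)
        n_shared = len(constituents)
        conc_rows.append(conc)
        ideal_rows.append(ideal_areas(constituents, conc, config.response))
        real_rows.append(areas[:n_shared])
        apex_rows.append(apexes[:n_shared])

    def _df(rows):
        return pd.DataFrame(np.vstack(rows), index=batches, columns=ids)

    return Panel(
        chromatograms=chroms,
        constituents=list(constituents),
        concentrations=_df(conc_rows),
        ideal_areas=_df(ideal_rows),
        realized_areas=_df(real_rows),
        apex_times=_df(apex_rows),
        rt_shifts=shifts,
        manifest=manifest,
        config=replace(config),
    )


def simulate_calibration_series(
    constituent: ConstituentSpec,
    levels,
    replicate_cv: float = 0.0,
    seed: int = 0,
    *,
    area_scale: float = 1.0,
    response: str = "linear",
) -> pd.DataFrame:
    """Simulate a calibration series (one area per concentration level).

    Areas follow the constituent's response line with multiplicative noise
    of coefficient of variation ``replicate_cv``; ``area_scale`` applies a
    systematic multiplier (used by durability perturbations).  Returns a
    DataFrame with ``concentration`` and ``area`` columns.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise ValidationError("need at least 2 calibration levels")
    if np.any(levels <= 0):
        raise ValidationError("calibration levels must be positive")
    if replicate_cv < 0:
        raise ValidationError("replicate_cv must be >= 0")
    rng = np.random.default_rng(seed)
    areas = np.array([constituent.ideal_area(c, response) for c in levels])
    if replicate_cv > 0:
        areas = areas * np.clip(
            1.0 + rng.normal(0.0, replicate_cv, size=levels.size), 0.0, None)
    areas = areas * area_scale
    return pd.DataFrame({"concentration": levels, "area": areas})
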