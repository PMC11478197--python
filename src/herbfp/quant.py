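"""Calibration, external-standard and single-marker (QAMS) quantification.

Definitions used throughout:

- relative correction factor, computed level-by-level from paired
  calibration points of the internal reference s and analyte i:
  ``RCF = (A_s / C_s) / (A_i / C_i)``;
- QAMS concentration of the analyte in a sample:
  ``C_i = RCF * A_i * C_s / A_s`` (the exact inverse of the definition);
- relative retention time ``R_t = t_i / t_s`` for peak localization;
- relative deviation between the two quantifications:
  ``RD = (QAMS - ESM) / ESM * 100`` reported to two decimals with
  half-away-from-zero rounding.

Contents are reported in µg/g with default sample mass 2.00 g and extract
volume 2 mL, so concentration (µg/mL) and content coincide numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import CALIBRATIONS, DURABILITY_RSD_BOUND
from .errors import NotLocatedError, ValidationError
from .peaks import Peak
from .synthetic import ConstituentSpec, simulate_calibration_series

__all__ = [
    "CalibrationCurve",
    "RCFRecord",
    "ContentResult",
    "QuantResult",
    "DurabilityCondition",
    "DurabilityResult",
    "fit_calibration",
    "esm_quantify",
    "compute_rcf",
    "locate_peak_by_rrt",
    "qams_quantify",
    "relative_deviation",
    "round_half_away",
    "durability_study",
    "default_durability_factors",
    "validation_metrics",
]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (table-formatting convention).

    Decimal-based so that shortest-repr ties like 1.005 round up rather
    than falling to the binary float below the tie.
    """
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line area = slope * C + intercept with its valid range."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    c_min: float
    c_max: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"{self.analyte}: slope must be > 0")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError(f"{self.analyte}: R^2 must be in [0, 1]")
        if self.c_min >= self.c_max:
            raise ValidationError(f"{self.analyte}: empty range")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def invert(self, area: float) -> float:
        return (area - self.intercept) / self.slope

    def in_range(self, concentration: float) -> bool:
        return self.c_min <= concentration <= self.c_max

    @classmethod
    def from_defaults(cls, analyte: str) -> "CalibrationCurve":
        cal = CALIBRATIONS[analyte]
        return cls(analyte=analyte, slope=cal["slope"],
                   intercept=cal["intercept"], r_squared=cal["r_squared"],
                   c_min=cal["c_min"], c_max=cal["c_max"])


def fit_calibration(points, analyte: str = "") -> CalibrationCurve:
    """Ordinary least squares of area on concentration.

    ``points`` is an iterable of (concentration, area) pairs or a DataFrame
    with ``concentration``/``area`` columns.  R² is the squared Pearson
    correlation; the valid range is [min, max] of the input concentrations.
    """
    if isinstance(points, pd.DataFrame):
        conc = points["concentration"].to_numpy(dtype=float)
        area = points["area"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("points must be (concentration, area) pairs")
        conc, area = arr[:, 0], arr[:, 1]
    if len(conc) < 2:
        raise ValidationError("need at least 2 calibration points")
    if np.ptp(conc) == 0:
        raise ValidationError(
            "degenerate calibration design: all concentrations equal")
    res = stats.linregress(conc, area)
    r2 = float(res.rvalue ** 2) if np.ptp(area) > 0 else 1.0
    return CalibrationCurve(
        analyte=analyte, slope=float(res.slope),
        intercept=float(res.intercept), r_squared=min(max(r2, 0.0), 1.0),
        c_min=float(conc.min()), c_max=float(conc.max()))


@dataclass(frozen=True)
class ContentResult:
    """A single external-standard or QAMS determination."""

    content: float               # µg/g
    concentration: float         # µg/mL in the extract
    extrapolated: bool = False
    clipped: bool = False

    def __float__(self) -> float:
        return self.content


def esm_quantify(area: float, curve: CalibrationCurve,
                 sample_mass: float = 2.0,
                 extract_volume: float = 2.0) -> ContentResult:
    """External-standard content: invert the calibration line, then convert
    concentration to content via extract volume / sample mass.

    An area below the curve's prediction at zero concentration is clipped
    to zero content with a warning; a concentration outside the calibrated
    range is flagged ``extrapolated``.
    """
    if sample_mass <= 0 or extract_volume <= 0:
        raise ValidationError("sample mass and extract volume must be > 0")
    conc = curve.invert(area)
    clipped = False
    if conc < 0:
        warnings.warn(
            f"{curve.analyte}: area below the calibration intercept; "
            "content clipped to 0")
        conc = 0.0
        clipped = True
    content = conc * extract_volume / sample_mass
    return ContentResult(content=content, concentration=conc,
                         extrapolated=not curve.in_range(conc) and not clipped,
                         clipped=clipped)


@dataclass
class RCFRecord:
    """Relative correction factor of an analyte versus the internal reference."""

    analyte: str
    internal_ref: str
    per_level_rcf: list[float]
    mean_rcf: float
    rcf_rsd: float               # %
    mean_rrt: float = float("nan")
    rrt_rsd: float = float("nan")

    def __post_init__(self) -> None:
        if self.mean_rcf <= 0 or any(v <= 0 for v in self.per_level_rcf):
            raise ValidationError("RCF values must be positive")
        if self.rcf_rsd < 0:
            raise ValidationError("RCF RSD must be >= 0")


def _rsd(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / mean * 100.0)


def compute_rcf(ref_points, analyte_points, analyte: str = "analyte",
                internal_ref: str = "internal_ref",
                ref_times=None, analyte_times=None) -> RCFRecord:
    """Per-level RCF = (A_s/C_s) / (A_i/C_i), paired by level index.

    ``ref_points`` / ``analyte_points`` are (concentration, area) pairs (or
    DataFrames as accepted by :func:`fit_calibration`) with equal level
    count >= 3.  Optional retention times per level yield relative
    retention-time statistics.
    """
    def _unpack(pts):
        if isinstance(pts, pd.DataFrame):
            return (pts["concentration"].to_numpy(dtype=float),
                    pts["area"].to_numpy(dtype=float))
        arr = np.asarray(list(pts), dtype=float)
        return arr[:, 0], arr[:, 1]

    c_s, a_s = _unpack(ref_points)
    c_i, a_i = _unpack(analyte_points)
    if len(c_s) != len(c_i):
        raise ValidationError("mismatched level counts")
    if len(c_s) < 3:
        raise ValidationError("need at least 3 levels")
    if np.any(a_s <= 0) or np.any(a_i <= 0) or np.any(c_s <= 0) or np.any(c_i <= 0):
        raise ValidationError("areas and concentrations must be positive")
    per_level = (a_s / c_s) / (a_i / c_i)
    mean_rrt = rrt_rsd = float("nan")
    if ref_times is not None and analyte_times is not None:
        t_s = np.asarray(ref_times, dtype=float)
        t_i = np.asarray(analyte_times, dtype=float)
        rrt = t_i / t_s
        mean_rrt = float(np.mean(rrt))
        rrt_rsd = _rsd(rrt)
    return RCFRecord(
        analyte=analyte, internal_ref=internal_ref,
        per_level_rcf=[float(v) for v in per_level],
        mean_rcf=float(np.mean(per_level)),
        rcf_rsd=_rsd(per_level),
        mean_rrt=mean_rrt, rrt_rsd=rrt_rsd)


@dataclass(frozen=True)
class LocatedPeak:
    peak: Peak
    rrt: float
    deviation: float


def locate_peak_by_rrt(peaks: list[Peak], internal_ref_peak: Peak,
                       expected_rrt: float, tolerance: float = 0.005) -> LocatedPeak:
    """Pick the peak whose apex/t_s is closest to the expected relative
    retention time, requiring relative deviation <= tolerance.

    Raises :class:`NotLocatedError` (naming the nearest candidate) when no
    peak qualifies.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    t_s = internal_ref_peak.apex_time
    if t_s <= 0:
        raise ValidationError("internal reference peak has non-positive time")
    if not peaks:
        raise NotLocatedError("empty peak list")
    best, best_dev, best_rrt = None, np.inf, np.nan
    for p in peaks:
        rrt = p.apex_time / t_s
        dev = abs(rrt - expected_rrt) / expected_rrt
        if dev < best_dev:
            best, best_dev, best_rrt = p, dev, rrt
    if best_dev > tolerance:
        raise NotLocatedError(
            f"no peak within {tolerance:.3%} of R_t {expected_rrt}; nearest "
            f"candidate at {best.apex_time:.3f} min (R_t {best_rrt:.4f}, "
            f"deviation {best_dev:.3%})")
    return LocatedPeak(peak=best, rrt=float(best_rrt), deviation=float(best_dev))


def qams_quantify(a_i: float, a_s: float, c_s: float, rcf: float,
                  sample_mass: float = 2.0,
                  extract_volume: float = 2.0) -> ContentResult:
    """Single-marker content: C_i = RCF * A_i * C_s / A_s, then volume/mass
    conversion as in :func:`esm_quantify`."""
    if a_s <= 0:
        raise ValidationError("internal reference peak area missing (A_s <= 0)")
    if a_i <= 0 or c_s <= 0 or rcf <= 0:
        raise ValidationError("QAMS inputs must be positive")
    if sample_mass <= 0 or extract_volume <= 0:
        raise ValidationError("sample mass and extract volume must be > 0")
    conc = rcf * a_i * c_s / a_s
    return ContentResult(content=conc * extract_volume / sample_mass,
                         concentration=conc)


def relative_deviation(esm: float, qams: float, decimals: int = 2) -> float:
    """RD = (QAMS - ESM)/ESM * 100, rounded half-away-from-zero."""
    if esm <= 0:
        raise ValidationError("ESM content must be > 0")
    rd = (qams - esm) / esm * 100.0
    return round_half_away(rd, decimals) if decimals is not None else rd


@dataclass(frozen=True)
class QuantResult:
    """One batch/analyte row of the ESM-versus-QAMS comparison."""

    batch: str
    analyte: str
    esm_content: float
    qams_content: float
    rd: float

    def __post_init__(self) -> None:
        if self.esm_content < 0 or self.qams_content < 0:
            raise ValidationError("contents must be >= 0")


# ---------------------------------------------------------------------------
# Durability

@dataclass(frozen=True)
class DurabilityCondition:
    """One level of a durability factor.

    ``area_scale`` is a global multiplicative response change;
    ``rt_scale`` rescales retention (no effect on RCF, by construction);
    ``selectivity`` holds small per-analyte response multipliers.
    """

    name: str
    area_scale: float = 1.0
    rt_scale: float = 1.0
    selectivity: dict[str, float] = field(default_factory=dict)


def default_durability_factors() -> dict[str, list[DurabilityCondition]]:
    """Chromatographic column, flow rate, column temperature and injection
    volume, three levels each; selectivity perturbations are kept small
    (|delta| <= 0.5%) so that only area noise and mild selectivity move the
    RCF."""
    sel = DurabilityCondition
    return {
        "column": [
            sel("Hypersil_ODS", selectivity={
                "macrostemonoside_t": 1.004, "macrostemonoside_u": 0.996}),
            sel("Agilent_TC-C18"),
            sel("COSMOSIL_5C18-MS-II", selectivity={
                "macrostemonoside_t": 0.995, "macrostemonoside_u": 1.005}),
        ],
        "flow_rate": [
            sel("0.6_mL_min", area_scale=1.08),
            sel("0.8_mL_min"),
            sel("1.0_mL_min", area_scale=0.93),
        ],
        "column_temperature": [
            sel("25_C", rt_scale=1.02),
            sel("30_C", rt_scale=1.01),
            sel("35_C"),
        ],
        "injection_volume": [
            sel("10_uL", area_scale=0.50),
            sel("15_uL", area_scale=0.75),
            sel("20_uL"),
        ],
    }


@dataclass
class DurabilityResult:
    records: pd.DataFrame        # factor, condition, analyte, mean_rcf
    rsd: pd.DataFrame            # factor x analyte, RSD %
    verdicts: dict[str, bool]    # factor -> all-analyte RSD < bound
    bound: float


def _calibration_levels(spec: ConstituentSpec, n_levels: int = 5):
    cal = CALIBRATIONS.get(spec.id)
    if cal is not None:
        return np.linspace(cal["c_min"], cal["c_max"], n_levels)
    c = spec.base_concentration
    return np.linspace(0.4 * c, 1.6 * c, n_levels)


def durability_study(
    internal_ref: ConstituentSpec,
    analytes: list[ConstituentSpec],
    factors: dict[str, list[DurabilityCondition]] | None = None,
    area_noise_cv: float = 0.01,
    n_levels: int = 5,
    seed: int = 0,
    bound: float = DURABILITY_RSD_BOUND,
) -> DurabilityResult:
    """Recompute the RCF of each analyte under perturbed conditions.

    For every factor level, calibration series for the internal reference
    and each analyte are simulated with multiplicative area noise and the
    condition's response perturbations, the RCF recomputed, and the RSD
    across the factor's levels reported.  Verdict per factor: every
    analyte's RSD below ``bound`` (%).  Empty factors are skipped with a
    warning.
    """
    factors = default_durability_factors() if factors is None else factors
    rows = []
    counter = 0
    for factor, conditions in factors.items():
        if len(conditions) < 2:
            warnings.warn(f"factor {factor!r} has < 2 conditions; skipped")
            continue
        for cond in conditions:
            levels_s = _calibration_levels(internal_ref, n_levels)
            series_s = simulate_calibration_series(
                internal_ref, levels_s, replicate_cv=area_noise_cv,
                seed=seed * 100003 + counter,
                area_scale=cond.area_scale)
            counter += 1
            for analyte in analytes:
                scale = cond.area_scale * cond.selectivity.get(analyte.id, 1.0)
                levels_i = _calibration_levels(analyte, n_levels)
                series_i = simulate_calibration_series(
                    analyte, levels_i, replicate_cv=area_noise_cv,
                    seed=seed * 100003 + counter,
                    area_scale=scale)
                counter += 1
                rec = compute_rcf(series_s, series_i, analyte=analyte.id,
                                  internal_ref=internal_ref.id)
                rows.append((factor, cond.name, analyte.id, rec.mean_rcf))
    if not rows:
        raise ValidationError("no durability factors to evaluate")
    records = pd.DataFrame(
        rows, columns=["factor", "condition", "analyte", "mean_rcf"])
    rsd = records.pivot_table(
        index="factor", columns="analyte", values="mean_rcf",
        aggfunc=lambda v: _rsd(np.asarray(v, dtype=float)))
    verdicts = {f: bool((rsd.loc[f] < bound).all()) for f in rsd.index}
    return DurabilityResult(records=records, rsd=rsd, verdicts=verdicts,
                            bound=bound)


def validation_metrics(replicates, base: float | None = None,
                       spiked: float | None = None,
                       measured_total: float | None = None) -> dict[str, float]:
    """Replicate RSD and, when spike data are given, spike recovery.

    ``rsd`` uses the sample standard deviation (n-1);
    ``recovery = (measured_total - base) / spiked * 100``.
    """
    values = np.asarray(list(replicates), dtype=float)
    if len(values) < 2:
        raise ValidationError("need at least 2 replicates for RSD")
    out = {"rsd": _rsd(values)}
    if base is not None or spiked is not None or measured_total is not None:
        if base is None or spiked is None or measured_total is None:
            raise ValidationError(
                "recovery needs base, spiked and measured_total")
        if base <= 0 or spiked <= 0:
            raise ValidationError("base content and spiked amount must be > 0")
        out["recovery"] = (measured_total - base) / spiked * 100.0
    return out
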