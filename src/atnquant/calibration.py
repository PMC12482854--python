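"""Centiloid and CenTauR calibration: two-point Level-1 anchoring,
Level-2 cross-tracer regression, bundled printed conversion constants, and
calibration-validity checking.

The Centiloid (CL) scale anchors PiB SUVr linearly so that the young
cognitively-normal amyloid-negative group mean maps to 0 and the AD-dementia
group mean maps to 100:

    CL = 100 * (SUVr - m_yCN) / (m_AD - m_yCN)

Level-2 maps another amyloid tracer to PiB by ordinary least squares on
paired scans, then composes that regression with the PiB conversion by
exact algebra (no refit).  The CenTauR Level-1 step regresses pipeline FTP
SUVr on published SUVr_CTR and reports the inverse map
SUVr_CTR = (S - a)/b.  A calibration is considered valid when regressing
computed on published values gives slope in [0.98, 1.02], intercept within
+/-2 CL and R^2 > 0.98 (the intercept bound is a CL-scale criterion and is
reported but not enforced for CenTauRz).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TwoPointAnchors",
    "LinearConversion",
    "CalibrationReport",
    "AMYLOID_TRACERS",
    "TAU_TRACERS",
    "bundled_conversions",
    "fit_level1_centiloid",
    "expand_two_point",
    "fit_level2",
    "fit_centaur_level1",
    "convert",
    "validate_calibration",
    "select_best_mask",
    "deming_regression",
]

AMYLOID_TRACERS = ("PiB", "FBP", "FBB", "FTM", "NAV")
TAU_TRACERS = ("FTP", "RO", "MK", "GTP", "PBB3", "PI")

SLOPE_RANGE = (0.98, 1.02)
INTERCEPT_BOUND_CL = 2.0
R2_MIN = 0.98


@dataclass(frozen=True)
class TwoPointAnchors:
    """Group-mean SUVr anchors of the two-point Level-1 calibration."""

    m_ycn: float
    m_ad: float

    def __post_init__(self):
        if not self.m_ad > self.m_ycn:
            raise ValueError(
                f"inverted anchors: AD mean ({self.m_ad}) must exceed "
                f"young-CN mean ({self.m_ycn})")


@dataclass(frozen=True)
class LinearConversion:
    """Tracer-specific affine map from SUVr to CL, CTRz or SUVr_CTR."""

    tracer: str
    modality: str  # 'amyloid->CL', 'tau->CTRz' or 'tau->SUVr_CTR'
    slope: float
    intercept: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")

    def __call__(self, suvr):
        return self.slope * np.asarray(suvr, dtype=float) + self.intercept

    def rounded(self, decimals: int = 4) -> "LinearConversion":
        return LinearConversion(self.tracer, self.modality,
                                round(self.slope, decimals),
                                round(self.intercept, decimals), dict(self.meta))

    def to_dict(self) -> dict:
        return {"tracer": self.tracer, "modality": self.modality,
                "slope": self.slope, "intercept": self.intercept,
                "meta": self.meta}


@lru_cache(maxsize=1)
def bundled_conversions() -> dict:
    """The bundled printed conversion coefficients (versioned data file)."""
    path = importlib.resources.files("atnquant").joinpath(
        "data", "conversions_v1.json")
    with open(str(path)) as f:
        return json.load(f)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS of y on x -> (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired lists must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError(f">=3 pairs required, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = _sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def expand_two_point(anchors: TwoPointAnchors,
                     tracer: str = "PiB") -> LinearConversion:
    """Expand the two-point form into slope/intercept.

    CL = 100*(S - m_yCN)/(m_AD - m_yCN), hence slope = 100/span and
    intercept = -100*m_yCN/span.  Unrounded coefficients map the anchors to
    exactly (0, 100).
    """
    span = anchors.m_ad - anchors.m_ycn
    if span <= 0:
        raise ValueError("zero or negative anchor span")
    return LinearConversion(
        tracer=tracer, modality="amyloid->CL",
        slope=100.0 / span, intercept=-100.0 * anchors.m_ycn / span,
        meta={"anchors": [anchors.m_ycn, anchors.m_ad], "level": 1})


def fit_level1_centiloid(ycn_suvrs, ad_suvrs
                         ) -> tuple[TwoPointAnchors, LinearConversion]:
    """Two-point Level-1 calibration from the group SUVr distributions."""
    ycn = np.asarray(ycn_suvrs, dtype=float)
    ad = np.asarray(ad_suvrs, dtype=float)
    if len(ycn) < 2 or len(ad) < 2:
        raise ValueError("need >=2 subjects per group")
    anchors = TwoPointAnchors(m_ycn=float(ycn.mean()), m_ad=float(ad.mean()))
    return anchors, expand_two_point(anchors)


def fit_level2(tracer_suvrs, pib_suvrs,
               pib_conversion: LinearConversion,
               tracer: str = "tracer") -> LinearConversion:
    """Compose an OLS tracer->PiB fit with the PiB->CL map, exactly.

    With PiB = b*S + a, the direct map is
    CL = pib_slope*b*S + (pib_slope*a + pib_intercept).
    """
    b, a, r2 = _ols(tracer_suvrs, pib_suvrs)
    return LinearConversion(
        tracer=tracer, modality="amyloid->CL",
        slope=pib_conversion.slope * b,
        intercept=pib_conversion.slope * a + pib_conversion.intercept,
        meta={"level": 2, "pib_regression": {"slope": b, "intercept": a,
                                             "r2": r2}})


def fit_centaur_level1(petbrain_suvrs, published_ctr_suvrs,
                       tracer: str = "FTP") -> LinearConversion:
    """CenTauR Level-1: OLS of pipeline SUVr on published SUVr_CTR.

    The regression S = b*C + a is reported in the inverse form
    SUVr_CTR = (S - a)/b, i.e. slope 1/b and intercept -a/b; the raw (a, b)
    pair is kept in ``meta``.
    """
    b, a, r2 = _ols(published_ctr_suvrs, petbrain_suvrs)
    if b <= 0:
        raise ValueError("non-positive regression slope; pairs inconsistent")
    return LinearConversion(
        tracer=tracer, modality="tau->SUVr_CTR",
        slope=1.0 / b, intercept=-a / b,
        meta={"a": a, "b": b, "r2": r2, "level": 1})


def convert(tracer: str, value, table: dict | None = None) -> float:
    """Apply the bundled printed conversion for a tracer (SUVr -> CL/CTRz)."""
    table = table if table is not None else bundled_conversions()
    for modality in ("amyloid", "tau"):
        if tracer in table.get(modality, {}):
            row = table[modality][tracer]
            return float(row["slope"] * np.asarray(value, dtype=float)
                         + row["intercept"])
    known = sorted(table.get("amyloid", {})) + sorted(table.get("tau", {}))
    raise KeyError(f"unknown tracer {tracer!r}; known tracers: {known}")


@dataclass(frozen=True)
class CalibrationReport:
    """Computed-vs-published regression with per-criterion pass flags."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    modality: str
    slope_ok: bool
    intercept_ok: bool
    r2_ok: bool
    intercept_enforced: bool

    @property
    def passed(self) -> bool:
        ok = self.slope_ok and self.r2_ok
        if self.intercept_enforced:
            ok = ok and self.intercept_ok
        return ok

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "n": self.n,
            "modality": self.modality,
            "criteria": {
                "slope_in_[0.98,1.02]": self.slope_ok,
                "abs_intercept_<=_2": self.intercept_ok,
                "r2_>_0.98": self.r2_ok,
            },
            "intercept_enforced": self.intercept_enforced,
            "passed": self.passed,
        }


def validate_calibration(computed, published,
                         modality: str = "CL") -> CalibrationReport:
    """Check a calibration against the Centiloid-project validity criteria.

    OLS of computed on published values; pass requires slope in
    [0.98, 1.02] and R^2 > 0.98, plus |intercept| <= 2 for the CL scale.
    For CTRz the intercept is computed and reported but not enforced (the
    published criterion is stated in CL units).
    """
    slope, intercept, r2 = _ols(published, computed)
    n = len(np.asarray(computed))
    enforced = modality.upper() == "CL"
    return CalibrationReport(
        slope=slope, intercept=intercept, r_squared=r2, n=n,
        modality=modality,
        slope_ok=SLOPE_RANGE[0] <= slope <= SLOPE_RANGE[1],
        intercept_ok=abs(intercept) <= INTERCEPT_BOUND_CL,
        r2_ok=r2 > R2_MIN,
        intercept_enforced=enforced)


def select_best_mask(candidates: dict) -> tuple[str, "pd.DataFrame"]:
    """Pick the candidate mask whose pairs regress with the highest R^2.

    ``candidates`` maps mask name -> (published SUVr_CTR, pipeline SUVr)
    paired lists.  Ties within 1e-12 go to the lexicographically smallest
    name and are flagged in the returned table (column ``tie``).
    """
    import pandas as pd

    if not candidates:
        raise ValueError("no candidate masks supplied")
    rows = []
    for name in sorted(candidates):
        published, petbrain = candidates[name]
        _, _, r2 = _ols(published, petbrain)
        rows.append({"mask": name, "r_squared": r2})
    table = pd.DataFrame(rows)
    best_r2 = table["r_squared"].max()
    tied = table[table["r_squared"] >= best_r2 - 1e-12]["mask"].tolist()
    table["tie"] = table["mask"].isin(tied) & (len(tied) > 1)
    return sorted(tied)[0], table


def deming_regression(x, y, delta: float = 1.0) -> tuple[float, float]:
    """Errors-in-variables alternative to OLS (variance ratio ``delta``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(">=3 pairs required")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        raise ValueError("zero covariance; slope undefined")
    slope = ((syy - delta * sxx
              + np.sqrt((syy - delta * sxx) ** 2 + 4 * delta * sxy**2))
             / (2 * sxy))
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)
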