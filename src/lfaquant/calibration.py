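"""Calibration models mapping T/C ratio to 25-hydroxyvitamin-D3 concentration.

A competitive lateral-flow assay produces a test/control line-intensity ratio
(T/C) that *decreases* with analyte concentration: sample analyte occupies the
antibody binding sites on the gold-nanoparticle conjugates and prevents them
from binding at the test line.  Two model families cover the response shapes
seen in practice:

* :class:`LinearCalibration` — ``tc = a * conc + b`` with a negative slope,
  adequate over a narrow working range;
* :class:`FourPLCalibration` — the four-parameter logistic
  ``tc = d + (a - d) / (1 + (conc / c) ** b)``, the standard sigmoid for
  immunoassay dose-response curves, with upper asymptote ``a`` (signal at
  zero analyte), lower asymptote ``d``, inflection concentration ``c`` and
  slope exponent ``b``.

Both families support forward prediction, closed-form inversion (concentration
from a measured T/C), least-squares fitting with diagnostics, and JSON
serialization.  Inversions falling outside the invertible range are returned
as censored estimates ("< limit" / "> limit") rather than raised as errors,
matching how clinical assays report out-of-range results.

The module also ships the published calibrations of the vitamin-D3 assay this
package models (standard buffer, commercial serum calibrators, human serum,
finger-stick blood); they serve as reference forward models for simulation
and for round-trip validation of the fitting code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, InputError, InvalidModelError, SingularFitError

__all__ = [
    "LinearCalibration",
    "FourPLCalibration",
    "FitDiagnostics",
    "ConcentrationEstimate",
    "ReplicateSet",
    "fit_linear",
    "fit_4pl",
    "predict_tc",
    "invert",
    "replicate_cv",
    "read_points_csv",
    "save_calibration",
    "load_calibration",
    "STANDARD_BUFFER_LINEAR",
    "SERUM_CALIBRATOR_4PL",
    "HUMAN_SERUM_LINEAR",
    "FINGERSTICK_BLOOD_LINEAR",
]


# --------------------------------------------------------------------------
# model families
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearCalibration:
    """Straight-line calibration ``tc = a * conc + b``.

    Parameters
    ----------
    a : slope in T/C units per nmol/L; must be nonzero for invertibility and
        is negative for a competitive assay.
    b : intercept, the T/C ratio at zero analyte.
    conc_range : optional (low, high) concentration range over which the
        calibration was established, in nmol/L.
    """

    a: float
    b: float
    conc_range: tuple[float, float] | None = None

    def __post_init__(self):
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise InvalidModelError("linear calibration parameters must be finite")
        if self.a == 0:
            raise InvalidModelError("linear calibration slope must be nonzero")

    def predict(self, conc):
        conc = _check_conc(conc)
        return self.a * conc + self.b

    def invert(self, tc: float) -> "ConcentrationEstimate":
        conc = (tc - self.b) / self.a
        if conc < 0:
            # below the quantifiable range; clinical convention is "< LoQ"
            return ConcentrationEstimate(0.0, censored="below", limit=0.0)
        return ConcentrationEstimate(float(conc))


@dataclass(frozen=True)
class FourPLCalibration:
    """Four-parameter logistic ``tc = d + (a - d) / (1 + (conc / c) ** b)``.

    With ``a > d`` and ``b > 0`` the curve decreases strictly from ``a`` at
    zero concentration to ``d`` at infinite concentration, crossing the
    midpoint ``(a + d) / 2`` exactly at ``conc = c``; the inverse is unique
    on the open interval ``(d, a)``.
    """

    a: float
    b: float
    c: float
    d: float
    conc_range: tuple[float, float] | None = None

    def __post_init__(self):
        for name in "abcd":
            if not math.isfinite(getattr(self, name)):
                raise InvalidModelError("4PL parameters must be finite")
        if self.c <= 0:
            raise InvalidModelError("4PL inflection concentration c must be > 0")
        if self.b <= 0:
            raise InvalidModelError("4PL slope exponent b must be > 0")
        if self.a <= self.d:
            raise InvalidModelError("4PL requires a > d for a decreasing competitive curve")

    def predict(self, conc):
        conc = _check_conc(conc)
        # (0 / c) ** b == 0 for b > 0, so conc = 0 returns a exactly
        return self.d + (self.a - self.d) / (1.0 + (conc / self.c) ** self.b)

    def invert(self, tc: float) -> "ConcentrationEstimate":
        hi = self.conc_range[1] if self.conc_range is not None else None
        if tc <= self.d:
            # at or below the lower asymptote: concentration above the range
            return ConcentrationEstimate(
                float(hi) if hi is not None else math.inf, censored="above", limit=hi
            )
        if tc > self.a:
            return ConcentrationEstimate(0.0, censored="below", limit=0.0)
        if tc == self.a:
            return ConcentrationEstimate(0.0)
        conc = self.c * ((self.a - self.d) / (tc - self.d) - 1.0) ** (1.0 / self.b)
        return ConcentrationEstimate(float(conc))


CalibrationModel = LinearCalibration | FourPLCalibration


def _check_conc(conc):
    arr = np.asarray(conc, dtype=float)
    if np.any(arr < 0):
        raise DomainError("concentration must be >= 0 nmol/L")
    return arr if arr.ndim else float(arr)


def predict_tc(model: CalibrationModel, conc):
    """Forward-evaluate a calibration model: T/C ratio at ``conc`` nmol/L."""
    return model.predict(conc)


def invert(model: CalibrationModel, tc: float) -> "ConcentrationEstimate":
    """Concentration (nmol/L) whose forward T/C equals ``tc``.

    Out-of-range ratios yield a censored :class:`ConcentrationEstimate`
    rather than an exception.
    """
    return model.invert(float(tc))


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A concentration from calibration inversion, possibly censored.

    ``censored`` is ``None`` for an in-range value, ``"below"`` when the
    measured T/C implies a concentration under the quantifiable range (value
    clamped to 0), or ``"above"`` when it exceeds it (value set to the upper
    range limit, or +inf when the model records no range).
    """

    value: float
    censored: str | None = None
    limit: float | None = None

    @property
    def is_censored(self) -> bool:
        return self.censored is not None

    def __str__(self) -> str:
        if self.censored == "below":
            return f"<{0.0 if self.limit is None else self.limit:g}"
        if self.censored == "above":
            return ">?" if self.limit is None else f">{self.limit:g}"
        return f"{self.value:.1f}"


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary for a calibration fit."""

    r_squared: float
    residuals: np.ndarray  # observed - fitted, in T/C units
    n_points: int
    converged: bool
    rmse_tc: float


def _diagnostics(observed: np.ndarray, fitted: np.ndarray, converged: bool) -> FitDiagnostics:
    resid = observed - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return FitDiagnostics(
        r_squared=r2,
        residuals=resid,
        n_points=len(observed),
        converged=converged,
        rmse_tc=math.sqrt(ss_res / len(observed)),
    )


def fit_linear(
    conc: Sequence[float],
    tc: Sequence[float],
    weights: Sequence[float] | None = None,
) -> tuple[LinearCalibration, FitDiagnostics]:
    """Ordinary (or optionally weighted) least squares of T/C on concentration.

    Raises :class:`SingularFitError` when fewer than two distinct
    concentrations are supplied.
    """
    conc = np.asarray(conc, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if conc.shape != tc.shape or conc.ndim != 1:
        raise InputError("conc and tc must be 1-D arrays of equal length")
    if len(np.unique(conc)) < 2:
        raise SingularFitError("need at least two distinct concentrations to fit a line")
    w = None if weights is None else np.asarray(weights, dtype=float)
    a, b = np.polyfit(conc, tc, 1, w=w)
    model = LinearCalibration(float(a), float(b), conc_range=(float(conc.min()), float(conc.max())))
    return model, _diagnostics(tc, model.predict(conc), converged=True)


def _fourpl(conc, a, b, c, d):
    return d + (a - d) / (1.0 + (conc / c) ** b)


def fit_4pl(
    conc: Sequence[float],
    tc: Sequence[float],
    weights: Sequence[float] | None = None,
) -> tuple[FourPLCalibration, FitDiagnostics]:
    """Nonlinear least squares for the four-parameter logistic.

    Initialization: ``a0 = max(tc)``, ``d0 = min(tc)``, ``c0 = median(conc)``,
    ``b0 = 1``; bounds keep ``b > 0`` and ``c > 0``.  Non-convergence or a
    degenerate solution is reported through the ``converged`` flag of the
    diagnostics, never as a silent success and never as a crash.
    """
    conc = np.asarray(conc, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if conc.shape != tc.shape or conc.ndim != 1:
        raise InputError("conc and tc must be 1-D arrays of equal length")
    if len(conc) < 5:
        raise SingularFitError("need at least 5 points to fit a 4PL")
    pos = conc[conc > 0]
    c0 = float(np.median(pos)) if len(pos) else 1.0
    p0 = np.array([float(tc.max()), 1.0, c0, float(tc.min())])
    w = np.ones_like(tc) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    def resid(p):
        return w * (_fourpl(conc, *p) - tc)

    lo = [-np.inf, 1e-9, 1e-9, -np.inf]
    hi = [np.inf, np.inf, np.inf, np.inf]
    res = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    a, b, c, d = (float(v) for v in res.x)
    converged = bool(res.success) and a > d and b > 0 and c > 0
    if a <= d or b <= 0 or c <= 0:
        # non-identifiable (e.g. straight-line input): return best-effort
        # parameters nudged into the valid region, flagged unconverged
        a, d = max(a, d) + 1e-12, min(a, d)
        b, c = max(b, 1e-9), max(c, 1e-9)
        converged = False
    model = FourPLCalibration(a, b, c, d, conc_range=(float(conc.min()), float(conc.max())))
    return model, _diagnostics(tc, np.asarray(model.predict(conc)), converged=converged)


# --------------------------------------------------------------------------
# replicate precision
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate T/C measurements of one nominal concentration."""

    concentration: float
    tc_values: tuple[float, ...]
    mean: float = field(init=False)
    sd: float = field(init=False)
    cv_percent: float | None = field(init=False)

    def __post_init__(self):
        vals = np.asarray(self.tc_values, dtype=float)
        if len(vals) < 2:
            raise InputError("a ReplicateSet needs n >= 2 replicates")
        m = float(vals.mean())
        s = float(vals.std(ddof=1))
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)
        object.__setattr__(self, "cv_percent", 100.0 * s / m if m > 0 else None)


def replicate_cv(sets: Iterable[ReplicateSet]) -> pd.DataFrame:
    """Per-concentration coefficient of variation, 100 * sd / mean.

    Sets with non-positive mean get a NaN CV and an ``undefined_cv`` flag.
    """
    rows = [
        {
            "conc_nmol_L": s.concentration,
            "n": len(s.tc_values),
            "mean_tc": s.mean,
            "sd_tc": s.sd,
            "cv_percent": np.nan if s.cv_percent is None else s.cv_percent,
            "undefined_cv": s.cv_percent is None,
        }
        for s in sets
    ]
    if not rows:
        raise InputError("no replicate sets supplied")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CSV and JSON I/O
# --------------------------------------------------------------------------


def read_points_csv(path, aggregate: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Read calibration points from CSV columns ``conc_nmol_L, tc_ratio``.

    ``aggregate="mean"`` (default) averages replicate strips at each
    concentration before fitting; ``"none"`` keeps per-strip points.
    """
    df = pd.read_csv(path)
    for col in ("conc_nmol_L", "tc_ratio"):
        if col not in df.columns:
            raise InputError(f"calibration CSV is missing required column {col!r}")
    if aggregate == "mean":
        g = df.groupby("conc_nmol_L", as_index=False)["tc_ratio"].mean()
        return g["conc_nmol_L"].to_numpy(float), g["tc_ratio"].to_numpy(float)
    if aggregate == "none":
        return df["conc_nmol_L"].to_numpy(float), df["tc_ratio"].to_numpy(float)
    raise InputError(f"unknown aggregation mode {aggregate!r}")


def save_calibration(
    path,
    model: CalibrationModel,
    diagnostics: FitDiagnostics | None = None,
    batch_id: str | None = None,
) -> None:
    """Serialize a calibration to JSON.

    Calibrations are batch-specific (line dispensing and conjugate activity
    vary between strip batches), so the document carries a batch identifier
    alongside the parameters and fit diagnostics.
    """
    if isinstance(model, LinearCalibration):
        doc = {"family": "linear", "params": {"a": model.a, "b": model.b}}
    elif isinstance(model, FourPLCalibration):
        doc = {
            "family": "4pl",
            "params": {"a": model.a, "b": model.b, "c": model.c, "d": model.d},
        }
    else:  # pragma: no cover
        raise InvalidModelError(f"unsupported model type {type(model).__name__}")
    doc["conc_range"] = list(model.conc_range) if model.conc_range else None
    doc["batch_id"] = batch_id
    if diagnostics is not None:
        doc["diagnostics"] = {
            "r_squared": diagnostics.r_squared,
            "rmse_tc": diagnostics.rmse_tc,
            "n_points": diagnostics.n_points,
            "converged": diagnostics.converged,
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_calibration(path) -> tuple[CalibrationModel, dict]:
    """Load a calibration JSON written by :func:`save_calibration`.

    Returns the model and the remaining metadata (batch id, diagnostics).
    """
    doc = json.loads(Path(path).read_text())
    rng = tuple(doc["conc_range"]) if doc.get("conc_range") else None
    params = doc["params"]
    if doc["family"] == "linear":
        model = LinearCalibration(params["a"], params["b"], conc_range=rng)
    elif doc["family"] == "4pl":
        model = FourPLCalibration(params["a"], params["b"], params["c"], params["d"], conc_range=rng)
    else:
        raise InvalidModelError(f"unknown calibration family {doc['family']!r}")
    meta = {k: v for k, v in doc.items() if k not in ("family", "params", "conc_range")}
    return model, meta


# --------------------------------------------------------------------------
# published calibrations of the modeled vitamin-D3 assay
# --------------------------------------------------------------------------

#: Linear fit in standard buffer solutions, 0-150 nmol/L.
STANDARD_BUFFER_LINEAR = LinearCalibration(a=-0.0251, b=3.983, conc_range=(0.0, 150.0))

#: Four-parameter logistic fit in commercial serum-based calibrators.
SERUM_CALIBRATOR_4PL = FourPLCalibration(a=2.81, b=2.63, c=26.2, d=1.52, conc_range=(0.0, 150.0))

#: Canonical serum-calibrator concentration design (nmol/L): dense below the
#: inflection (~26 nmol/L) where a competitive curve carries most information,
#: spanning the physiological range; two strips are run per level.
SERUM_CALIBRATOR_LEVELS = (0.0, 10.0, 20.0, 30.0, 42.5, 55.0, 70.0, 85.0, 100.0, 125.0, 150.0)

#: Linear fit on native human serum samples (batch-specific).
HUMAN_SERUM_LINEAR = LinearCalibration(a=-0.075, b=5.689, conc_range=(0.0, 70.0))

#: Linear fit on finger-stick whole-blood samples.
FINGERSTICK_BLOOD_LINEAR = LinearCalibration(a=-0.033, b=2.9925, conc_range=(20.0, 60.0))
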