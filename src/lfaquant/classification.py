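"""Vitamin-D status classification from a 25(OH)D3 concentration.

Guideline thresholds partition the concentration axis into three statuses:
under the Endocrine Society guideline a serum 25(OH)D concentration below
50 nmol/L is deficient, between 50 and 75 nmol/L (inclusive at both ends)
insufficient, and above 75 nmol/L sufficient.  Institute of Medicine style
binary cutoffs (50 and 30 nmol/L) are provided for ROC dichotomization.

Boundary convention: "lower than 50" is read strictly, so exactly 50 and
exactly 75 both classify as insufficient.  The thresholds are named presets
in a JSON registry and can be overridden by constructing a custom
:class:`ThresholdSet`.

Censored concentration estimates (see
:class:`~lfaquant.calibration.ConcentrationEstimate`) classify when the
censoring limit is decisive — "< limit" at or under the deficiency bound is
deficient, "> limit" at or over the sufficiency bound is sufficient — and
are indeterminate otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources

from .calibration import ConcentrationEstimate
from .errors import ConfigError, DomainError

__all__ = [
    "Status",
    "ThresholdSet",
    "ENDOCRINE_SOCIETY",
    "threshold_registry",
    "get_threshold_set",
    "get_cutoff",
    "classify",
    "binarize",
]


class Status(str, Enum):
    DEFICIENT = "deficient"
    INSUFFICIENT = "insufficient"
    SUFFICIENT = "sufficient"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ThresholdSet:
    """Named pair of guideline cut-points, in nmol/L."""

    name: str
    deficient_below: float
    sufficient_above: float

    def __post_init__(self):
        if not (0 < self.deficient_below <= self.sufficient_above):
            raise ConfigError("require 0 < deficient_below <= sufficient_above")


def threshold_registry() -> dict:
    """The shipped JSON registry of threshold presets and binary cutoffs."""
    text = resources.files("lfaquant.data").joinpath("thresholds.json").read_text()
    return json.loads(text)


def get_threshold_set(name: str) -> ThresholdSet:
    reg = threshold_registry()["threshold_sets"]
    if name not in reg:
        raise ConfigError(f"unknown threshold preset {name!r}; known: {sorted(reg)}")
    entry = reg[name]
    return ThresholdSet(name, entry["deficient_below"], entry["sufficient_above"])


def get_cutoff(name: str) -> float:
    reg = threshold_registry()["binary_cutoffs"]
    if name not in reg:
        raise ConfigError(f"unknown cutoff preset {name!r}; known: {sorted(reg)}")
    return float(reg[name])


ENDOCRINE_SOCIETY = ThresholdSet("endocrine_society", 50.0, 75.0)


def classify(conc, thresholds: ThresholdSet = ENDOCRINE_SOCIETY) -> Status:
    """Map a concentration (nmol/L) to a vitamin-D status.

    ``conc`` may be a plain number or a censored
    :class:`~lfaquant.calibration.ConcentrationEstimate`.
    """
    if isinstance(conc, ConcentrationEstimate):
        if conc.censored == "below":
            limit = 0.0 if conc.limit is None else conc.limit
            return Status.DEFICIENT if limit <= thresholds.deficient_below else Status.INDETERMINATE
        if conc.censored == "above":
            if conc.limit is None:
                return Status.INDETERMINATE
            return (
                Status.SUFFICIENT
                if conc.limit >= thresholds.sufficient_above
                else Status.INDETERMINATE
            )
        conc = conc.value
    conc = float(conc)
    if conc < 0:
        raise DomainError("concentration must be >= 0 nmol/L")
    if conc < thresholds.deficient_below:
        return Status.DEFICIENT
    if conc <= thresholds.sufficient_above:
        return Status.INSUFFICIENT
    return Status.SUFFICIENT


def binarize(conc, cutoff: float) -> str:
    """Dichotomize a concentration at ``cutoff`` nmol/L.

    Returns ``"below"`` iff conc < cutoff, else ``"at_or_above"`` (the
    boundary value counts as at-or-above).  Censored estimates resolve by
    their limit when decisive and raise :class:`DomainError` otherwise.
    """
    if isinstance(conc, ConcentrationEstimate):
        if conc.censored == "below":
            limit = 0.0 if conc.limit is None else conc.limit
            if limit <= cutoff:
                return "below"
            raise DomainError("censoring limit does not resolve the cutoff")
        if conc.censored == "above":
            if conc.limit is not None and conc.limit >= cutoff:
                return "at_or_above"
            raise DomainError("censoring limit does not resolve the cutoff")
        conc = conc.value
    conc = float(conc)
    if conc < 0:
        raise DomainError("concentration must be >= 0 nmol/L")
    return "below" if conc < cutoff else "at_or_above"
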