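"""Model parameters for the anticoagulation net-benefit model.

This module holds the complete calibrated configuration of the Markov
decision model: risk-dependent baseline event rates, treatment relative
risks, event-severity distributions, post-event mortality, utility
weights, and simulation/PSA settings.

The model is indexed throughout by the *annual nonanticoagulated ischemic
stroke risk* (a fraction per year in [0, 0.10]).  Baseline major-bleeding
and all-cause mortality rates are linear functions of that risk, anchored
at a 1% and a 6% annual stroke rate.  Treatment effects of DOAC therapy
(direct oral anticoagulants, modelled as a single class) are expressed as
relative risks: the stroke relative reduction rises linearly from 32% at
a 1% stroke risk to 68% at 6% and is constant above; the mortality
reduction is zero below 1% and rises linearly to 43% at 6%; the bleeding
relative risk is a constant 1.91 applied identically to all bleed types.

All annual probabilities are converted to monthly cycle probabilities via
the constant-hazard complement formula ``1 - (1 - p)**(1/12)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "EVENT_TYPES",
    "SEVERITIES",
    "RISK_MAX",
    "annual_to_monthly",
    "baseline_bleed_rate",
    "baseline_mortality_rate",
    "stroke_rr",
    "mortality_rr",
    "bleed_rr",
    "fit_line_least_squares",
    "LinearRate",
    "EffectAnchors",
    "BleedTypeSplit",
    "SeverityTable",
    "PostEventMortality",
    "UtilityTable",
    "SimulationSettings",
    "PSASettings",
    "ParameterSet",
    "ParameterValidationError",
    "load_parameters",
    "save_parameters",
]

#: Upper bound of the supported annual stroke-risk range.
RISK_MAX = 0.10

#: Event types in the fixed order used by the engine and the oracle.
EVENT_TYPES = (
    "ischemic_stroke",
    "hemorrhagic_stroke",
    "other_intracranial_bleed",
    "extracranial_bleed",
)

#: Severity categories for stroke and intracranial bleeding events
#: (extracranial bleeds use {fatal, disabling, nondisabling}).
SEVERITIES = ("fatal", "severe", "moderate", "mild")

_ECB_SEVERITIES = ("fatal", "disabling", "nondisabling")

# Printed anchors of the risk-dependent lines and effects:
# (annual stroke risk, value).
_BLEED_ANCHORS = ((0.01, 0.009), (0.06, 0.022))
_MORTALITY_ANCHORS = ((0.01, 0.037), (0.06, 0.120))
_STROKE_REDUCTION_ANCHORS = ((0.01, 0.32), (0.06, 0.68))
_MORTALITY_REDUCTION_ANCHORS = ((0.01, 0.00), (0.06, 0.43))
_BLEED_RR = 1.91  # 2.22 x 0.86 from the warfarin / DOAC meta-analyses


class ParameterValidationError(ValueError):
    """Raised when a parameter set or config file violates an invariant."""


# ---------------------------------------------------------------------------
# probability conversion and rate / effect functions
# ---------------------------------------------------------------------------

def annual_to_monthly(p_annual):
    """Convert an annual probability to a 1-month cycle probability.

    Uses the constant-hazard complement formula
    ``p_month = 1 - (1 - p_annual)**(1/12)``, which is exact under
    12-cycle compounding: ``1 - (1 - p_month)**12 == p_annual``.

    Parameters
    ----------
    p_annual : float or ndarray
        Annual probability in [0, 1].

    Returns
    -------
    float or ndarray
        Equivalent monthly probability; monotone increasing in input.
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(
            f"annual probability must be within [0, 1], got {p_annual!r}"
        )
    out = 1.0 - (1.0 - p) ** (1.0 / 12.0)
    return float(out) if np.isscalar(p_annual) else out


def _check_risk(risk) -> np.ndarray:
    r = np.asarray(risk, dtype=float)
    if np.any(r < 0) or np.any(r > RISK_MAX):
        raise ValueError(
            f"annual stroke risk must be within [0, {RISK_MAX}], got {risk!r}"
        )
    return r


def _line(anchors) -> tuple[float, float]:
    (x1, y1), (x2, y2) = anchors
    slope = (y2 - y1) / (x2 - x1)
    return slope, y1 - slope * x1


def baseline_bleed_rate(risk):
    """Annual major-bleeding rate without anticoagulation at ``risk``.

    Linear through (1%, 0.9%) and (6%, 2.2%); clipped below at 0.
    """
    r = _check_risk(risk)
    slope, intercept = _line(_BLEED_ANCHORS)
    out = np.maximum(intercept + slope * r, 0.0)
    return float(out) if np.isscalar(risk) else out


def baseline_mortality_rate(risk):
    """Annual background mortality without anticoagulation at ``risk``.

    Linear through (1%, 3.7%) and (6%, 12.0%); clipped below at 0.
    """
    r = _check_risk(risk)
    slope, intercept = _line(_MORTALITY_ANCHORS)
    out = np.maximum(intercept + slope * r, 0.0)
    return float(out) if np.isscalar(risk) else out


def stroke_rr(risk):
    """Relative risk of ischemic stroke on DOAC therapy at ``risk``.

    The relative reduction follows the line through (1%, 32%) and
    (6%, 68%), extended along the same line below 1% (floored at zero
    reduction) and held constant at 68% above a 6% annual stroke risk.
    """
    r = _check_risk(risk)
    slope, intercept = _line(_STROKE_REDUCTION_ANCHORS)
    reduction = np.clip(intercept + slope * np.minimum(r, 0.06), 0.0, 1.0)
    out = 1.0 - reduction
    return float(out) if np.isscalar(risk) else out


def mortality_rr(risk):
    """Relative risk of all-cause mortality on DOAC therapy at ``risk``.

    No mortality effect below a 1% annual stroke risk; the reduction then
    rises linearly to 43% at 6% and stays constant above.
    """
    r = _check_risk(risk)
    slope, intercept = _line(_MORTALITY_REDUCTION_ANCHORS)
    reduction = np.clip(intercept + slope * np.minimum(r, 0.06), 0.0, 1.0)
    out = 1.0 - reduction
    return float(out) if np.isscalar(risk) else out


def bleed_rr(risk=None):
    """Relative risk of major bleeding on DOAC therapy (constant 1.91)."""
    if risk is not None:
        _check_risk(risk)
    return _BLEED_RR


def fit_line_least_squares(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least-squares straight-line fit through ``points``.

    With exactly two points the returned line passes through both.

    Parameters
    ----------
    points : sequence of (x, y) pairs
        At least two points; the x values must not all be equal.

    Returns
    -------
    (slope, intercept)
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values are equal")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# parameter-set dataclasses
# ---------------------------------------------------------------------------

def _prob(name: str, value: float) -> float:
    v = float(value)
    if not 0.0 <= v <= 1.0:
        raise ParameterValidationError(f"{name} must be in [0, 1], got {value!r}")
    return v


@dataclass
class LinearRate:
    """Annual rate as a linear function of annual stroke risk, floored at 0."""

    slope: float
    intercept: float

    def __call__(self, risk):
        r = np.asarray(risk, dtype=float)
        out = np.maximum(self.intercept + self.slope * r, 0.0)
        return float(out) if np.isscalar(risk) else out


@dataclass
class EffectAnchors:
    """Relative-reduction line anchored at two stroke-risk levels.

    The reduction is linear between (and, for the stroke effect, below)
    the anchors and constant above the upper anchor; ``floor_below_lower``
    holds the reduction at the lower-anchor value below it instead of
    extrapolating (used for the mortality effect, which is zero below 1%).
    """

    risk_lo: float
    reduction_lo: float
    risk_hi: float
    reduction_hi: float
    floor_below_lower: bool = False

    def reduction(self, risk):
        r = np.asarray(risk, dtype=float)
        slope = (self.reduction_hi - self.reduction_lo) / (self.risk_hi - self.risk_lo)
        rr = np.minimum(r, self.risk_hi)
        if self.floor_below_lower:
            rr = np.maximum(rr, self.risk_lo)
        out = np.clip(self.reduction_lo + slope * (rr - self.risk_lo), 0.0, 1.0)
        return float(out) if np.isscalar(risk) else out

    def relative_risk(self, risk):
        red = self.reduction(risk)
        return 1.0 - red


@dataclass
class BleedTypeSplit:
    """Proportions of major bleeds by type (must sum to 1)."""

    hemorrhagic_stroke: float
    other_intracranial: float
    extracranial: float

    def validate(self) -> None:
        vals = [self.hemorrhagic_stroke, self.other_intracranial, self.extracranial]
        for name, v in zip(
            ("hemorrhagic_stroke", "other_intracranial", "extracranial"), vals
        ):
            _prob(f"bleed_type_split.{name}", v)
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ParameterValidationError(
                f"bleed_type_split must sum to 1, got {sum(vals)!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.hemorrhagic_stroke, self.other_intracranial, self.extracranial]
        )


@dataclass
class SeverityTable:
    """Severity distributions per event type and treatment status.

    ``by_event[event_type][arm_key]`` maps severity category to
    probability; ``arm_key`` is ``"untreated"`` or ``"treated"``
    (treated = on active DOAC therapy at the time of the event).  Stroke
    and intracranial events use {fatal, severe, moderate, mild};
    extracranial bleeds use {fatal, disabling, nondisabling}.  ``fatal``
    is the 30-day case fatality folded into the event draw.
    """

    by_event: dict

    def validate(self) -> None:
        for ev in EVENT_TYPES:
            if ev not in self.by_event:
                raise ParameterValidationError(f"severity.{ev} is missing")
            cats = _ECB_SEVERITIES if ev == "extracranial_bleed" else SEVERITIES
            for arm_key in ("untreated", "treated"):
                if arm_key not in self.by_event[ev]:
                    raise ParameterValidationError(
                        f"severity.{ev}.{arm_key} is missing"
                    )
                dist = self.by_event[ev][arm_key]
                extra = set(dist) - set(cats)
                if extra:
                    raise ParameterValidationError(
                        f"severity.{ev}.{arm_key} has unknown categories {sorted(extra)}"
                    )
                total = 0.0
                for cat in cats:
                    if cat not in dist:
                        raise ParameterValidationError(
                            f"severity.{ev}.{arm_key}.{cat} is missing"
                        )
                    total += _prob(f"severity.{ev}.{arm_key}.{cat}", dist[cat])
                if abs(total - 1.0) > 1e-9:
                    raise ParameterValidationError(
                        f"severity.{ev}.{arm_key} must sum to 1, got {total!r}"
                    )
        # Prior anticoagulation makes ischemic strokes stochastically milder
        # and bleeding events stochastically more severe.
        self._check_ordering("ischemic_stroke", milder="treated")
        for ev in ("hemorrhagic_stroke", "other_intracranial_bleed",
                   "extracranial_bleed"):
            self._check_ordering(ev, milder="untreated")

    def _check_ordering(self, ev: str, milder: str) -> None:
        cats = _ECB_SEVERITIES if ev == "extracranial_bleed" else SEVERITIES
        worse = "untreated" if milder == "treated" else "treated"
        cum_mild = cum_worse = 0.0
        for cat in cats[:-1]:  # cumulative from the severe end
            cum_mild += self.by_event[ev][milder][cat]
            cum_worse += self.by_event[ev][worse][cat]
            if cum_mild > cum_worse + 1e-9:
                raise ParameterValidationError(
                    f"severity.{ev}: {milder} distribution must be stochastically "
                    f"no more severe than {worse} (violated at {cat!r})"
                )

    def matrix(self, treated: bool) -> np.ndarray:
        """(4 event types, 4 categories) probability matrix for one status.

        Extracranial-bleed rows are padded: columns are
        [fatal, disabling, nondisabling, 0].
        """
        key = "treated" if treated else "untreated"
        out = np.zeros((len(EVENT_TYPES), 4))
        for i, ev in enumerate(EVENT_TYPES):
            cats = _ECB_SEVERITIES if ev == "extracranial_bleed" else SEVERITIES
            for j, cat in enumerate(cats):
                out[i, j] = self.by_event[ev][key][cat]
        return out


@dataclass
class PostEventMortality:
    """Elevated annual mortality in the year after a stroke or ICH."""

    annual_after_ischemic_stroke: float = 0.14
    annual_after_intracranial_bleed: float = 0.16
    elevated_months: int = 12

    def validate(self) -> None:
        _prob("post_event_mortality.annual_after_ischemic_stroke",
              self.annual_after_ischemic_stroke)
        _prob("post_event_mortality.annual_after_intracranial_bleed",
              self.annual_after_intracranial_bleed)
        if int(self.elevated_months) < 1:
            raise ParameterValidationError(
                "post_event_mortality.elevated_months must be >= 1"
            )


@dataclass
class UtilityTable:
    """Age-specific baseline utility weights and severity utility ratios.

    ``baseline_by_age_band`` maps the lower edge of a 5-year age band to
    the general-population utility weight used while a patient's age falls
    in that band; ``baseline_age`` selects which band the cohort starts in
    (the 60/70/80-year variants of the analysis change only this).
    ``severity_ratios`` are the multiplicative quality-of-life ratios
    applied on a nonfatal event; repeated events compound multiplicatively.
    ``extracranial_disability_ratio`` is applied on a permanently
    disabling extracranial bleed (same ratio scale, keyed by disability
    grade).
    """

    baseline_by_age_band: dict
    severity_ratios: dict
    extracranial_disability_ratio: float
    baseline_age: int = 70

    def validate(self) -> None:
        if not self.baseline_by_age_band:
            raise ParameterValidationError("utilities.baseline_by_age_band is empty")
        ages = sorted(self.baseline_by_age_band)
        prev = None
        for a in ages:
            w = _prob(f"utilities.baseline_by_age_band.{a}",
                      self.baseline_by_age_band[a])
            if prev is not None and w > prev + 1e-12:
                raise ParameterValidationError(
                    "utilities.baseline_by_age_band must be non-increasing with age"
                )
            prev = w
        for cat in ("severe", "moderate", "mild"):
            if cat not in self.severity_ratios:
                raise ParameterValidationError(
                    f"utilities.severity_ratios.{cat} is missing"
                )
            r = float(self.severity_ratios[cat])
            if not 0.0 < r <= 1.0:
                raise ParameterValidationError(
                    f"utilities.severity_ratios.{cat} must be in (0, 1], got {r!r}"
                )
        r = float(self.extracranial_disability_ratio)
        if not 0.0 < r <= 1.0:
            raise ParameterValidationError(
                "utilities.extracranial_disability_ratio must be in (0, 1]"
            )

    def baseline(self, age) -> np.ndarray:
        """Step-function lookup of the baseline weight at ``age`` (years)."""
        ages = np.asarray(sorted(self.baseline_by_age_band), dtype=float)
        weights = np.asarray(
            [self.baseline_by_age_band[a] for a in sorted(self.baseline_by_age_band)]
        )
        a = np.asarray(age, dtype=float)
        if np.any(a < ages[0]):
            raise ValueError(f"age {age!r} below the supported range")
        # ages beyond the last band use the last band's weight
        idx = np.clip(np.searchsorted(ages, a, side="right") - 1, 0, len(ages) - 1)
        out = weights[idx]
        return float(out) if np.isscalar(age) else out

    def ratio_matrix(self) -> np.ndarray:
        """(4 event types, 4 severity categories) utility-ratio matrix.

        Column 0 (fatal) is unused; extracranial rows map the disabling
        category to ``extracranial_disability_ratio`` and nondisabling to 1.
        """
        r = self.severity_ratios
        stroke_row = [1.0, r["severe"], r["moderate"], r["mild"]]
        ecb_row = [1.0, self.extracranial_disability_ratio, 1.0, 1.0]
        return np.array([stroke_row, stroke_row, stroke_row, ecb_row])


@dataclass
class SimulationSettings:
    """Main-model run settings (1-month cycles over a 20-year horizon)."""

    cycle_length_months: int = 1
    horizon_years: float = 20.0
    n_per_arm: int = 10_000
    start_age: float = 70.0
    seed: int = 12345

    def validate(self) -> None:
        if self.cycle_length_months != 1:
            raise ParameterValidationError(
                "simulation.cycle_length_months must be 1"
            )
        if self.horizon_years <= 0 or self.n_per_arm < 1:
            raise ParameterValidationError(
                "simulation horizon and n_per_arm must be positive"
            )

    @property
    def horizon_months(self) -> int:
        return int(round(self.horizon_years * 12))


@dataclass
class PSASettings:
    """Probabilistic-sensitivity-analysis settings.

    Standard errors are on the log relative-risk scale, from the
    meta-analysis of placebo-controlled anticoagulant trials.
    """

    se_log_stroke_rr: float = 0.16
    se_log_bleed_rr: float = 0.30
    se_log_mortality_rr: float = 0.13
    iterations: int = 1000
    n_per_arm: int = 5000

    def validate(self) -> None:
        for name in ("se_log_stroke_rr", "se_log_bleed_rr", "se_log_mortality_rr"):
            if getattr(self, name) < 0:
                raise ParameterValidationError(f"psa.{name} must be >= 0")
        if self.iterations < 1 or self.n_per_arm < 1:
            raise ParameterValidationError("psa.iterations and psa.n_per_arm must be >= 1")


@dataclass
class ParameterSet:
    """The complete calibrated configuration of the decision model."""

    bleed_rate: LinearRate
    mortality_rate: LinearRate
    stroke_effect: EffectAnchors
    mortality_effect: EffectAnchors
    bleed_relative_risk: float
    bleed_type_split: BleedTypeSplit
    severity: SeverityTable
    post_event_mortality: PostEventMortality
    utilities: UtilityTable
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    psa: PSASettings = field(default_factory=PSASettings)

    def validate(self) -> "ParameterSet":
        if self.bleed_relative_risk <= 0:
            raise ParameterValidationError("effects.bleed_rr must be > 0")
        self.bleed_type_split.validate()
        self.severity.validate()
        self.post_event_mortality.validate()
        self.utilities.validate()
        self.simulation.validate()
        self.psa.validate()
        return self

    # -- effect / rate accessors -------------------------------------------
    def stroke_rr(self, risk):
        return self.stroke_effect.relative_risk(risk)

    def mortality_rr(self, risk):
        return self.mortality_effect.relative_risk(risk)

    def bleed_rr(self, risk=None):
        return self.bleed_relative_risk

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rates": {
                "bleed_line": {"slope": self.bleed_rate.slope,
                               "intercept": self.bleed_rate.intercept},
                "mortality_line": {"slope": self.mortality_rate.slope,
                                   "intercept": self.mortality_rate.intercept},
            },
            "effects": {
                "stroke_reduction_anchors": _anchors_dict(self.stroke_effect),
                "mortality_reduction_anchors": _anchors_dict(self.mortality_effect),
                "bleed_rr": self.bleed_relative_risk,
            },
            "bleed_type_split": dataclasses.asdict(self.bleed_type_split),
            "severity": self.severity.by_event,
            "post_event_mortality": dataclasses.asdict(self.post_event_mortality),
            "utilities": {
                "baseline_age": self.utilities.baseline_age,
                "baseline_by_age_band": dict(self.utilities.baseline_by_age_band),
                "severity_ratios": dict(self.utilities.severity_ratios),
                "extracranial_disability_ratio":
                    self.utilities.extracranial_disability_ratio,
            },
            "simulation": dataclasses.asdict(self.simulation),
            "psa": dataclasses.asdict(self.psa),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        _reject_unknown(data, {
            "rates", "effects", "bleed_type_split", "severity",
            "post_event_mortality", "utilities", "simulation", "psa",
        }, where="top level")
        rates = _require(data, "rates")
        _reject_unknown(rates, {"bleed_line", "mortality_line"}, where="rates")
        effects = _require(data, "effects")
        _reject_unknown(effects, {
            "stroke_reduction_anchors", "mortality_reduction_anchors", "bleed_rr",
        }, where="effects")
        util = _require(data, "utilities")
        _reject_unknown(util, {
            "baseline_age", "baseline_by_age_band", "severity_ratios",
            "extracranial_disability_ratio",
        }, where="utilities")
        ps = cls(
            bleed_rate=LinearRate(**_require(rates, "bleed_line")),
            mortality_rate=LinearRate(**_require(rates, "mortality_line")),
            stroke_effect=_anchors_from_dict(
                _require(effects, "stroke_reduction_anchors")),
            mortality_effect=_anchors_from_dict(
                _require(effects, "mortality_reduction_anchors")),
            bleed_relative_risk=float(_require(effects, "bleed_rr")),
            bleed_type_split=BleedTypeSplit(**_require(data, "bleed_type_split")),
            severity=SeverityTable(by_event=_require(data, "severity")),
            post_event_mortality=PostEventMortality(
                **_require(data, "post_event_mortality")),
            utilities=UtilityTable(
                baseline_age=int(_require(util, "baseline_age")),
                baseline_by_age_band={
                    int(k): float(v)
                    for k, v in _require(util, "baseline_by_age_band").items()
                },
                severity_ratios={
                    str(k): float(v)
                    for k, v in _require(util, "severity_ratios").items()
                },
                extracranial_disability_ratio=float(
                    _require(util, "extracranial_disability_ratio")),
            ),
            simulation=SimulationSettings(**data.get("simulation", {})),
            psa=PSASettings(**data.get("psa", {})),
        )
        return ps.validate()


def _anchors_dict(eff: EffectAnchors) -> dict:
    return {
        "risk_lo": eff.risk_lo, "reduction_lo": eff.reduction_lo,
        "risk_hi": eff.risk_hi, "reduction_hi": eff.reduction_hi,
        "floor_below_lower": eff.floor_below_lower,
    }


def _anchors_from_dict(d: Mapping) -> EffectAnchors:
    _reject_unknown(d, {
        "risk_lo", "reduction_lo", "risk_hi", "reduction_hi", "floor_below_lower",
    }, where="effect anchors")
    return EffectAnchors(**d)


def _require(mapping: Mapping, key: str):
    if key not in mapping:
        raise ParameterValidationError(f"missing required config key {key!r}")
    return mapping[key]


def _reject_unknown(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterValidationError(
            f"unknown config key(s) {sorted(unknown)} at {where}"
        )


def load_parameters(path) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterValidationError(f"config file {path} is not a mapping")
    return ParameterSet.from_dict(data)


def save_parameters(params: ParameterSet, path) -> None:
    """Write a :class:`ParameterSet` to YAML (or JSON by extension).

    ``load_parameters(save_parameters(p)) == p`` field-for-field: floats
    are serialized with full repr precision.
    """
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
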