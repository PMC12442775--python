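"""Canonical default parameters and degenerate test fixtures.

The default :class:`~oacbenefit.params.ParameterSet` combines two kinds
of values:

* quantities stated directly by the model's sources: the baseline
  bleeding/mortality rate anchors (0.9%/3.7% at a 1% annual stroke risk,
  2.2%/12.0% at 6%), the bleed-type split 11/7/82, the treatment-effect
  anchors (stroke reduction 32% at 1% -> 68% at 6%; mortality reduction
  0 below 1% -> 43% at 6%; bleeding relative risk 1.91), the 14%/16%
  one-year post-event mortality, and the PSA standard errors
  0.16/0.30/0.13; and
* **calibration values** for the event-severity distributions, 30-day
  case fatality, extracranial disability probability, age-specific
  baseline utilities and severity utility ratios.  These are anchored to
  published severity and quality-of-life data and jointly tuned, with
  the deterministic cohort oracle, so that the model reproduces its
  reference QALY-difference curve; they are exposed here (and in the
  generated config file) as ordinary parameters.

Degenerate parameter sets (zero-event, no-treatment-effect,
certain-death, unit-utility) back the identity test suites.
"""

from __future__ import annotations

import copy
from pathlib import Path

from .params import (
    BleedTypeSplit,
    EffectAnchors,
    LinearRate,
    ParameterSet,
    PostEventMortality,
    PSASettings,
    SeverityTable,
    SimulationSettings,
    UtilityTable,
    save_parameters,
)

__all__ = [
    "default_parameters",
    "generate_default_fixture",
    "generate_degenerate_fixtures",
    "zero_event_parameters",
    "no_effect_parameters",
    "certain_death_parameters",
    "unit_utility_parameters",
]

# Calibration defaults (severity distributions include the 30-day case
# fatality as the "fatal" category; extracranial bleeds distinguish
# permanently disabling from nondisabling courses).
_DEFAULT_SEVERITY = {
    "ischemic_stroke": {
        # cardioembolic strokes: high 30-day case fatality; prior DOAC
        # therapy shifts the distribution toward mild courses
        "untreated": {"fatal": 0.111, "severe": 0.100, "moderate": 0.280,
                      "mild": 0.509},
        "treated": {"fatal": 0.049, "severe": 0.045, "moderate": 0.280,
                    "mild": 0.626},
    },
    "hemorrhagic_stroke": {
        "untreated": {"fatal": 0.480, "severe": 0.300, "moderate": 0.200,
                      "mild": 0.020},
        "treated": {"fatal": 0.480, "severe": 0.300, "moderate": 0.200,
                    "mild": 0.020},
    },
    "other_intracranial_bleed": {
        "untreated": {"fatal": 0.298, "severe": 0.220, "moderate": 0.250,
                      "mild": 0.232},
        "treated": {"fatal": 0.298, "severe": 0.220, "moderate": 0.250,
                    "mild": 0.232},
    },
    "extracranial_bleed": {
        # mostly gastrointestinal; rarely fatal or permanently disabling
        "untreated": {"fatal": 0.0050, "disabling": 0.0020,
                      "nondisabling": 0.9930},
        "treated": {"fatal": 0.0066, "disabling": 0.0030,
                    "nondisabling": 0.9904},
    },
}

# General-population baseline utility by 5-year age band (calibration
# defaults in the range of published Swedish population values).
_DEFAULT_BASELINE_UTILITY = {
    60: 0.84, 65: 0.82, 70: 0.80, 75: 0.77,
    80: 0.74, 85: 0.71, 90: 0.68, 95: 0.66,
}

# Post-event utility ratios by severity (calibration defaults, jointly
# tuned with the severity distributions; see the methods note).
_DEFAULT_SEVERITY_RATIOS = {"severe": 0.08, "moderate": 0.30, "mild": 0.75}
_DEFAULT_ECB_DISABILITY_RATIO = 0.08


def default_parameters() -> ParameterSet:
    """The canonical default :class:`ParameterSet` of the model."""
    ps = ParameterSet(
        bleed_rate=LinearRate(slope=0.26, intercept=0.0064),
        mortality_rate=LinearRate(slope=1.66, intercept=0.0204),
        stroke_effect=EffectAnchors(
            risk_lo=0.01, reduction_lo=0.32, risk_hi=0.06, reduction_hi=0.68,
            floor_below_lower=False,
        ),
        mortality_effect=EffectAnchors(
            risk_lo=0.01, reduction_lo=0.0, risk_hi=0.06, reduction_hi=0.43,
            floor_below_lower=True,
        ),
        bleed_relative_risk=1.91,
        bleed_type_split=BleedTypeSplit(
            hemorrhagic_stroke=0.11, other_intracranial=0.07, extracranial=0.82,
        ),
        severity=SeverityTable(by_event=copy.deepcopy(_DEFAULT_SEVERITY)),
        post_event_mortality=PostEventMortality(),
        utilities=UtilityTable(
            baseline_by_age_band=dict(_DEFAULT_BASELINE_UTILITY),
            severity_ratios=dict(_DEFAULT_SEVERITY_RATIOS),
            extracranial_disability_ratio=_DEFAULT_ECB_DISABILITY_RATIO,
            baseline_age=70,
        ),
        simulation=SimulationSettings(),
        psa=PSASettings(),
    )
    return ps.validate()


def zero_event_parameters() -> ParameterSet:
    """All event and mortality rates zero (use at stroke risk 0).

    Both arms then follow identical, event-free trajectories and accrue
    the closed-form sum of age-indexed baseline utilities.
    """
    ps = default_parameters()
    ps.bleed_rate = LinearRate(slope=0.0, intercept=0.0)
    ps.mortality_rate = LinearRate(slope=0.0, intercept=0.0)
    return ps.validate()


def no_effect_parameters() -> ParameterSet:
    """DOAC therapy with no effect on anything (all relative risks 1).

    Severity distributions are shared between arms, so under common
    random numbers the two arms are identical patient by patient.
    """
    ps = default_parameters()
    ps.stroke_effect = EffectAnchors(
        risk_lo=0.01, reduction_lo=0.0, risk_hi=0.06, reduction_hi=0.0)
    ps.mortality_effect = EffectAnchors(
        risk_lo=0.01, reduction_lo=0.0, risk_hi=0.06, reduction_hi=0.0,
        floor_below_lower=True)
    ps.bleed_relative_risk = 1.0
    for ev in ps.severity.by_event.values():
        ev["treated"] = dict(ev["untreated"])
    return ps.validate()


def certain_death_parameters() -> ParameterSet:
    """Certain death from other causes in the first cycle (risk 0).

    Annual background mortality 1.0 with all event rates zero: every
    patient dies in cycle 1 and accrues zero QALYs.
    """
    ps = default_parameters()
    ps.bleed_rate = LinearRate(slope=0.0, intercept=0.0)
    ps.mortality_rate = LinearRate(slope=0.0, intercept=1.0)
    return ps.validate()


def unit_utility_parameters() -> ParameterSet:
    """Baseline utility 1 at every age with unit severity ratios."""
    ps = default_parameters()
    ps.utilities = UtilityTable(
        baseline_by_age_band={a: 1.0 for a in _DEFAULT_BASELINE_UTILITY},
        severity_ratios={"severe": 1.0, "moderate": 1.0, "mild": 1.0},
        extracranial_disability_ratio=1.0,
        baseline_age=70,
    )
    return ps.validate()


def generate_default_fixture(path) -> Path:
    """Write the canonical default parameter file (YAML) to ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    save_parameters(default_parameters(), path)
    return path


def generate_degenerate_fixtures(out_dir) -> dict:
    """Write the degenerate parameter files; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    builders = {
        "zero_event": zero_event_parameters,
        "no_effect": no_effect_parameters,
        "certain_death": certain_death_parameters,
        "unit_utility": unit_utility_parameters,
    }
    paths = {}
    for name, build in builders.items():
        p = out_dir / f"{name}.yaml"
        save_parameters(build(), p)
        paths[name] = p
    return paths
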