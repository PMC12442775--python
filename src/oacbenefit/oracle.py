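"""Deterministic cohort (transition-matrix) oracle.

Computes the *exact* expected QALYs and disability-free life years of
one treatment arm by forward propagation of a state-occupancy
distribution, without Monte-Carlo error.  It serves as the independent
verification target for the patient-level microsimulation and as the
fast inner model for calibration.

The enumerable state space is the product of

* post-event mortality window: none, or (ischemic stroke | intracranial
  bleed) with a months-since-event timer 0..11,
* DOAC pause flag (0/1),
* severely-disabled flag (0/1),

plus an absorbing dead state.  The continuous multiplicative utility
decrement is handled exactly by propagating, alongside the occupancy
mass of each state, the expected utility-ratio mass (linearity of
expectation: an event multiplies the ratio by a constant independent of
history, so expectations close under the transition map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import monthly_prob_table, severity_cumulative
from .params import ParameterSet

__all__ = ["OracleResult", "expected_arm_outcome"]


@dataclass
class OracleResult:
    """Exact expected outcomes of one arm at one risk level."""

    risk: float
    arm: str
    horizon_months: int
    mean_qalys: float
    mean_disability_free_years: float
    survival: float  # probability alive at the horizon
    occupancy_error: float  # max |total mass - 1| over cycles


def _state_index(n_wt: int):
    # state = ((wt * 2) + pause) * 2 + disabled ; dead handled separately
    def idx(wt, pause, disabled):
        return (wt * 2 + pause) * 2 + disabled
    return idx, n_wt * 4


def expected_arm_outcome(
    risk: float,
    arm: str,
    params: ParameterSet,
    horizon_months: int | None = None,
    multipliers: np.ndarray | None = None,
) -> OracleResult:
    """Expected mean QALYs in ``arm`` at ``risk`` by cohort propagation.

    ``multipliers`` optionally perturbs the (stroke, bleed, mortality)
    relative risks, shape ``(3,)`` — the hook used to evaluate sampled
    effect sets without Monte-Carlo noise.
    """
    if arm not in ("doac", "none"):
        raise ValueError(f"unknown arm {arm!r}")
    doac = arm == "doac"
    if horizon_months is None:
        horizon_months = params.simulation.horizon_months
    E = int(params.post_event_mortality.elevated_months)
    n_wt = 1 + 2 * E  # none + (IS, t) + (ICH, t)
    idx, n_states = _state_index(n_wt)

    mult = None
    if multipliers is not None:
        mult = np.asarray(multipliers, dtype=float).reshape(1, 3)
    table = monthly_prob_table(risk, params, mult)[0]  # (2, 3, 5)
    sev_cum = severity_cumulative(params)  # (2, 4, 3)
    sev_mat = np.zeros((2, 4, 4))
    sev_mat[:, :, 0] = sev_cum[:, :, 0]
    sev_mat[:, :, 1:3] = np.diff(sev_cum, axis=2)
    sev_mat[:, :, 3] = 1.0 - sev_cum[:, :, 2]
    ratio_mat = params.utilities.ratio_matrix()

    def wt_kind(wt):  # 0 none, 1 IS window, 2 ICH window
        if wt == 0:
            return 0
        return 1 if wt <= E else 2

    def wt_next(wt):
        if wt == 0:
            return 0
        t = (wt - 1) % E
        return 0 if t == E - 1 else wt + 1

    # Transition matrices: T_mass[src, dst], T_util additionally weighted by
    # the utility ratio applied on the transition.  Time-invariant, so built
    # once and iterated.
    T_mass = np.zeros((n_states, n_states))
    T_util = np.zeros((n_states, n_states))
    death = np.zeros(n_states)

    wt_is, wt_ich = 1, 1 + E  # window states with timer 0
    for wt in range(n_wt):
        for pause in (0, 1):
            for dis in (0, 1):
                src = idx(wt, pause, dis)
                active = 1 if (doac and pause == 0) else 0
                probs = table[active, wt_kind(wt)]  # (5,)
                p_events, p_mort = probs[:4], probs[4]
                p_none = 1.0 - p_events.sum() - p_mort

                death[src] += p_mort
                adv = wt_next(wt)
                T_mass[src, idx(adv, 0, dis)] += p_none
                T_util[src, idx(adv, 0, dis)] += p_none

                for e in range(4):
                    pe = p_events[e]
                    if pe == 0.0:
                        continue
                    death[src] += pe * sev_mat[active, e, 0]
                    n_cats = 3 if e == 3 else 4
                    for sev in range(1, n_cats):
                        p = pe * sev_mat[active, e, sev]
                        if p == 0.0:
                            continue
                        newly_dis = dis or (sev == 1)
                        if e <= 2:
                            dst_wt = wt_is if e == 0 else wt_ich
                        else:
                            dst_wt = adv
                        dst_pause = 1 if (doac and e >= 1) else 0
                        dst = idx(dst_wt, dst_pause, int(newly_dis))
                        T_mass[src, dst] += p
                        T_util[src, dst] += p * ratio_mat[e, sev]

    mass = np.zeros(n_states)
    util = np.zeros(n_states)
    mass[idx(0, 0, 0)] = 1.0
    util[idx(0, 0, 0)] = 1.0
    dead = 0.0

    utab = params.utilities
    start_age = float(utab.baseline_age)
    not_disabled = np.array(
        [1.0 - (s % 2) for s in range(n_states)]
    )

    qalys = 0.0
    df_years = 0.0
    occ_err = 0.0
    for t in range(horizon_months):
        dead += mass @ death
        mass = mass @ T_mass
        util = util @ T_util
        occ_err = max(occ_err, abs(mass.sum() + dead - 1.0))
        base_u = utab.baseline(start_age + t / 12.0)
        qalys += util.sum() * base_u / 12.0
        df_years += (mass * not_disabled).sum() / 12.0

    return OracleResult(
        risk=float(risk),
        arm=arm,
        horizon_months=horizon_months,
        mean_qalys=float(qalys),
        mean_disability_free_years=float(df_years),
        survival=float(mass.sum()),
        occupancy_error=float(occ_err),
    )
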