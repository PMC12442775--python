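"""Probabilistic sensitivity analysis over the treatment effects.

The three DOAC relative risks (ischemic stroke, major bleeding,
all-cause mortality) are the only uncertain quantities; everything else
is held at its point value.  Each iteration draws one standard-normal z
per effect and multiplies the risk-dependent point relative risk by
``exp(z * SE)`` (log-normal uncertainty with standard errors 0.16, 0.30
and 0.13 on the log-RR scale), applied uniformly across the whole
baseline-risk spectrum — including, for mortality, the region below a 1%
stroke risk where the point relative risk is exactly 1.  Sampled
relative risks may therefore exceed 1.

For every risk-grid point all iterations are simulated (both arms under
common random numbers) and the proportion of iterations in which DOAC
therapy yields more cumulative QALYs is recorded.  The proportion curve
is smoothed by isotonic regression before probability thresholds (the
smallest risk at which the proportion exceeds 0.5, 0.90, ...) are read
off, since raw proportions at practical iteration counts carry a few
percent of binomial noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .engine import simulate_arm
from .params import ParameterSet, PSASettings
from .threshold import point_seed

__all__ = [
    "PSAResult",
    "sample_effects",
    "run_psa",
    "probability_thresholds",
]


def sample_effects(
    params: ParameterSet,
    psa_settings: Optional[PSASettings] = None,
    rng: Optional[np.random.Generator] = None,
    size: int = 1,
) -> np.ndarray:
    """Sample multiplicative relative-risk perturbations, shape (size, 3).

    Columns are (stroke, bleed, mortality); the sampled relative risk at
    a given stroke-risk level is the point relative risk times the
    multiplier, so each multiplier is ``exp(z * SE)`` with one z per
    effect per iteration, shared across the whole risk grid.  Draws are
    antithetic (each z paired with -z) for variance reduction.  With SE = 0
    the sample equals the point estimate (multiplier 1); the median
    multiplier is 1, so median sampled RRs reproduce the point RRs.
    """
    cfg = psa_settings or params.psa
    rng = rng or np.random.default_rng()
    ses = np.array([cfg.se_log_stroke_rr, cfg.se_log_bleed_rr,
                    cfg.se_log_mortality_rr])
    # Antithetic pairs (z, -z): each draw is still marginally standard
    # normal, but the sample mean of every z column is (near) zero, which
    # removes the common-mode error that one shared effect sample would
    # otherwise impose on the whole risk grid.
    half = rng.standard_normal(((size + 1) // 2, 3))
    z = np.concatenate([half, -half])[:size]
    return np.exp(z * ses)


@dataclass
class PSAResult:
    """Per-grid-point distribution of the paired QALY difference."""

    risks: np.ndarray
    proportion_favoring_doac: np.ndarray  # raw, per grid point
    proportion_smoothed: np.ndarray  # isotonic (non-decreasing in risk)
    mean_qaly_doac: np.ndarray  # across iterations and patients
    mean_qaly_none: np.ndarray
    delta_by_iteration: np.ndarray  # (iterations, n grid points)
    multipliers: np.ndarray  # (iterations, 3) sampled RR perturbations
    iterations: int
    n_per_arm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "risk": self.risks,
            "proportion_favoring_doac": self.proportion_favoring_doac,
            "proportion_smoothed": self.proportion_smoothed,
            "mean_qaly_doac": self.mean_qaly_doac,
            "mean_qaly_none": self.mean_qaly_none,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_psa(
    params: ParameterSet,
    grid: Optional[Sequence[float]] = None,
    psa_settings: Optional[PSASettings] = None,
    horizon_months: Optional[int] = None,
    seed: int = 0,
) -> PSAResult:
    """Run the probabilistic sensitivity analysis over ``grid``.

    One effect sample per iteration is drawn up front and applied at all
    grid points.  At each point the control arm and the DOAC arm are
    simulated with common random numbers (iterations stacked into a
    single vectorized run); the per-iteration paired mean QALY
    difference determines which arm the iteration favors.
    """
    cfg = psa_settings or params.psa
    if grid is None:
        grid = np.round(np.arange(0.0, 0.1001, 0.001), 6)
    grid = np.asarray(grid, dtype=float)
    if horizon_months is None:
        horizon_months = params.simulation.horizon_months

    rng = np.random.default_rng(seed)
    multipliers = sample_effects(params, cfg, rng, size=cfg.iterations)
    iter_index = np.repeat(np.arange(cfg.iterations), cfg.n_per_arm)
    n_total = cfg.iterations * cfg.n_per_arm

    props = np.empty(len(grid))
    mean_d = np.empty(len(grid))
    mean_n = np.empty(len(grid))
    deltas = np.empty((cfg.iterations, len(grid)))
    for j, risk in enumerate(grid):
        ps = point_seed(seed, risk)
        none = simulate_arm(risk, "none", params, n=n_total,
                            horizon_months=horizon_months, seed=ps)
        doac = simulate_arm(risk, "doac", params, n=n_total,
                            horizon_months=horizon_months, seed=ps,
                            multipliers=multipliers, iter_index=iter_index)
        diff = (doac.qalys - none.qalys).reshape(cfg.iterations, cfg.n_per_arm)
        d_iter = diff.mean(axis=1)
        deltas[:, j] = d_iter
        props[j] = float(np.mean(d_iter > 0))
        mean_d[j] = doac.mean_qalys
        mean_n[j] = none.mean_qalys

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    smoothed = iso.fit_transform(grid, props)

    return PSAResult(
        risks=grid,
        proportion_favoring_doac=props,
        proportion_smoothed=smoothed,
        mean_qaly_doac=mean_d,
        mean_qaly_none=mean_n,
        delta_by_iteration=deltas,
        multipliers=multipliers,
        iterations=cfg.iterations,
        n_per_arm=cfg.n_per_arm,
        seed=seed,
    )


def probability_thresholds(
    result: PSAResult, levels: Sequence[float] = (0.90, 0.95)
) -> dict:
    """Smallest grid risk at which the smoothed proportion exceeds each level.

    Returns ``{level: risk or None}``; a level that is never exceeded
    (e.g. anything above 1) maps to ``None``.
    """
    out = {}
    for level in levels:
        above = result.proportion_smoothed > level
        out[float(level)] = (
            float(result.risks[np.argmax(above)]) if above.any() else None
        )
    return out
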