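"""Quantitative bias analysis for outcome misclassification.

A phenotype algorithm is an imperfect classifier; the prevalence or
incidence observed through it is biased by false positives and negatives.
Given the algorithm's sensitivity and specificity, the Rogan–Gladen
estimator inverts the misclassification:

    p_true = (p_obs + sp − 1) / (se + sp − 1)

valid when se + sp > 1 (an informative classifier).  Uncertainty in
(se, sp) is propagated by drawing both from Beta distributions
moment-matched to their point estimates and 95% CIs and applying the
deterministic correction per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class QbaResult:
    observed: float
    corrected: float
    interval: tuple[float, float]
    se_used: float
    sp_used: float
    n_draws: int


def _check_informative(sensitivity: float, specificity: float) -> None:
    if sensitivity + specificity <= 1.0:
        raise ValueError(
            f"non-informative classifier: sensitivity ({sensitivity}) + "
            f"specificity ({specificity}) must exceed 1")


def correct_prevalence(p_obs: float, sensitivity: float,
                       specificity: float) -> float:
    """Rogan–Gladen–corrected prevalence, clipped to [0, 1]."""
    _check_informative(sensitivity, specificity)
    raw = (p_obs + specificity - 1.0) / (sensitivity + specificity - 1.0)
    return float(np.clip(raw, 0.0, 1.0))


def correct_incidence(events: float, person_years: float, n_at_risk: float,
                      sensitivity: float, specificity: float) -> float:
    """Misclassification-corrected incidence rate per 100,000 person-years.

    The observed event count is assumed to contain ``(1 − sp) · n_at_risk``
    false positives; the corrected count is floored at zero.
    """
    _check_informative(sensitivity, specificity)
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    corrected_events = (events - (1.0 - specificity) * n_at_risk) / (
        sensitivity + specificity - 1.0)
    corrected_events = max(corrected_events, 0.0)
    return 1e5 * corrected_events / person_years


def _beta_params(point: float, ci: tuple[float, float]) -> tuple[float, float] | None:
    """Moment-match a Beta to a point estimate and 95% CI; None if degenerate."""
    lo, hi = ci
    se = (hi - lo) / 3.92
    if se <= 0:
        return None
    var = min(se * se, point * (1 - point) * 0.999) if 0 < point < 1 else se * se
    if var <= 0 or not 0 < point < 1:
        return None
    nu = point * (1 - point) / var - 1.0
    if nu <= 0:
        return None
    return point * nu, (1 - point) * nu


def _draw(rng, point: float, ci: tuple[float, float], n: int) -> np.ndarray:
    params = _beta_params(point, ci)
    if params is None:
        return np.full(n, point)
    return rng.beta(params[0], params[1], n)


def probabilistic_interval(p_obs: float, sensitivity: float,
                           se_ci: tuple[float, float], specificity: float,
                           sp_ci: tuple[float, float], n_draws: int = 1000,
                           seed: int = 0) -> QbaResult:
    """Corrected prevalence with a 95% simulation interval.

    Draws (se, sp) from moment-matched Betas, corrects per draw (draws with
    se + sp ≤ 1 are discarded as non-informative), and reports the
    2.5/97.5 percentiles.  Degenerate (zero-width) CIs collapse to the
    deterministic correction.
    """
    _check_informative(sensitivity, specificity)
    corrected = correct_prevalence(p_obs, sensitivity, specificity)
    rng = np.random.default_rng(seed)
    se = _draw(rng, sensitivity, se_ci, n_draws)
    sp = _draw(rng, specificity, sp_ci, n_draws)
    ok = se + sp > 1.0
    if not ok.any():
        interval = (corrected, corrected)
    else:
        vals = np.clip((p_obs + sp[ok] - 1.0) / (se[ok] + sp[ok] - 1.0), 0.0, 1.0)
        interval = (float(np.percentile(vals, 2.5)),
                    float(np.percentile(vals, 97.5)))
    return QbaResult(observed=p_obs, corrected=corrected, interval=interval,
                     se_used=sensitivity, sp_used=specificity, n_draws=n_draws)


def probabilistic_incidence_interval(events: float, person_years: float,
                                     n_at_risk: float, sensitivity: float,
                                     se_ci: tuple[float, float],
                                     specificity: float,
                                     sp_ci: tuple[float, float],
                                     n_draws: int = 1000,
                                     seed: int = 0) -> QbaResult:
    """Corrected incidence rate (per 100,000 PY) with a 95% simulation interval."""
    _check_informative(sensitivity, specificity)
    corrected = correct_incidence(events, person_years, n_at_risk,
                                  sensitivity, specificity)
    rng = np.random.default_rng(seed)
    se = _draw(rng, sensitivity, se_ci, n_draws)
    sp = _draw(rng, specificity, sp_ci, n_draws)
    ok = se + sp > 1.0
    if not ok.any():
        interval = (corrected, corrected)
    else:
        ev = np.maximum((events - (1.0 - sp[ok]) * n_at_risk)
                        / (se[ok] + sp[ok] - 1.0), 0.0)
        vals = 1e5 * ev / person_years
        interval = (float(np.percentile(vals, 2.5)),
                    float(np.percentile(vals, 97.5)))
    observed = 1e5 * events / person_years
    return QbaResult(observed=observed, corrected=corrected, interval=interval,
                     se_used=sensitivity, sp_used=specificity, n_draws=n_draws)
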