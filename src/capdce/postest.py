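"""Post-estimation: willingness-to-accept and relative-importance scores.

WTA for attribute k is -beta_k / beta_cost (currency units per unit of the
attribute's code), with a delta-method standard error propagated through the
cluster-robust covariance.  Relative importance multiplies |beta_k| by the
attribute's code span (max - min level code) to get the maximum utility
effect, then normalizes the effects to shares.  The opt-out ASC is excluded
from both by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .estimate import MNLResult
from .schema import OPTOUT_NAME, AttributeSet

__all__ = ["PostEstimates", "PostEstimationError", "wta", "relative_importance", "post_estimates"]

_COST_FLOOR = 1e-12


class PostEstimationError(ValueError):
    pass


@dataclass
class PostEstimates:
    """WTA point estimates/SEs and importance max-effects/shares by attribute."""

    wta: dict[str, tuple[float, float]]
    importance: dict[str, tuple[float, float]]


def wta(res: MNLResult, cost_attribute: str, include_asc: bool = False,
        use_robust: bool = True) -> dict[str, tuple[float, float]]:
    """Delta-method WTA for every non-cost coefficient.

    Returns attribute name -> (estimate, se).  The gradient of
    w = -b_k/b_c is (-1/b_c, b_k/b_c^2), applied to the relevant 2x2
    covariance block (robust by default).
    """
    if cost_attribute not in res.param_names:
        raise PostEstimationError(f"cost attribute {cost_attribute!r} not among fitted coefficients")
    c = res.param_names.index(cost_attribute)
    b_cost = res.beta_hat[c]
    if abs(b_cost) < _COST_FLOOR:
        raise PostEstimationError(f"cost coefficient {b_cost!r} too close to zero; WTA undefined")
    cov = res.cov_robust if use_robust else res.cov_classical
    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(res.param_names):
        if name == cost_attribute:
            continue
        if name == OPTOUT_NAME and not include_asc:
            continue
        b_k = res.beta_hat[i]
        est = -b_k / b_cost
        grad = np.array([-1.0 / b_cost, b_k / b_cost**2])
        block = cov[np.ix_([i, c], [i, c])]
        var = float(grad @ block @ grad)
        out[name] = (float(est), float(np.sqrt(max(var, 0.0))))
    return out


def _max_effect(name: str, beta: Mapping[str, float], attrs: AttributeSet) -> float:
    spec = attrs.attribute(name)
    if spec.coding == "linear":
        return abs(float(beta[name])) * spec.span
    # indicator coding: spread of the level utilities, reference level at 0
    utils = [0.0] + [float(beta[p]) for p in spec.param_names]
    return max(utils) - min(utils)


def relative_importance(beta: Mapping[str, float], attrs: AttributeSet) -> dict[str, tuple[float, float]]:
    """Attribute name -> (max_effect, share); shares sum to 1 (ASC excluded).

    ``beta`` maps coefficient names to estimates and must cover every
    attribute parameter; an all-zero vector leaves shares undefined.
    """
    missing = [p for a in attrs.attributes for p in a.param_names if p not in beta]
    if missing:
        raise PostEstimationError(f"beta missing coefficient(s): {missing}")
    effects = {a.name: _max_effect(a.name, beta, attrs) for a in attrs.attributes}
    total = sum(effects.values())
    if total <= 0:
        raise PostEstimationError("all coefficients are zero; importance shares undefined")
    return {name: (eff, eff / total) for name, eff in effects.items()}


def post_estimates(res: MNLResult, attrs: AttributeSet,
                   include_asc_wta: bool = False) -> PostEstimates:
    """Convenience wrapper combining WTA and relative importance for a fit."""
    cost = attrs.cost_attribute
    if cost is None:
        raise PostEstimationError("attribute set has no cost attribute; WTA undefined")
    beta = dict(zip(res.param_names, res.beta_hat))
    return PostEstimates(
        wta=wta(res, cost.name, include_asc=include_asc_wta),
        importance=relative_importance(beta, attrs),
    )
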