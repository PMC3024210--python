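"""Marshall-type empirical-Bayes smoothing of small-area disease rates.

Each raw rate t_i = y_i / n_i is shrunk toward a prior mean m_i with a
weight governed by a method-of-moments estimate of the prior variance:

    theta_hat_i = w_i * t_i + (1 - w_i) * m_i,   w_i = A / (A + m / n_i)

The *global* estimator pools the whole map: m~ = sum(y) / sum(n),
s^2 = sum(n_i (t_i - m~)^2) / sum(n_i), n_bar = sum(n_i) / K and
A~ = s^2 - m~ / n_bar, clamped at 0 (complete shrinkage) when the moment
estimate goes negative.  The *local* estimator evaluates the same
formulas on each area's first-order neighbourhood — the area itself plus
its adjacent areas by default — so rates are shrunk toward a local rather
than a map-wide mean.  Smoothing matters most for maps with many
zero-case areas, where raw rates would give those areas zero replication
probability in the Monte Carlo intensity procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .map_model import AreaMap, CaseVector, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SmoothedRates", "marshall_global", "marshall_local", "smoothed_probabilities"]


@dataclass(frozen=True)
class SmoothedRates:
    """Smoothed rates theta_hat with their shrinkage weights and prior moments."""

    theta_hat: np.ndarray
    weights: np.ndarray
    prior_mean: np.ndarray
    prior_var: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if ((w < 0) | (w > 1)).any():
            raise ValidationError("shrinkage weights must lie in [0, 1]")
        if (np.asarray(self.theta_hat) < 0).any():
            raise ValidationError("smoothed rates must be nonnegative")


def _shrink(y: np.ndarray, n: np.ndarray, m: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """w_i = A / (A + m / n_i); theta_hat = w t + (1 - w) m.  w = 0 when both
    the prior variance and the sampling variance vanish."""
    t = y / n
    denom = A + m / n
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, A / np.where(denom > 0, denom, 1.0), 0.0)
    return w * t + (1.0 - w) * m, w


def marshall_global(cases: CaseVector, amap: AreaMap) -> SmoothedRates:
    """Global empirical-Bayes smoothing toward the map-wide mean rate."""
    y = cases.counts.astype(float)
    n = amap.populations.astype(float)
    if (n <= 0).any():
        bad = amap.ids[int(np.argmax(n <= 0))]
        raise ValidationError(f"area {bad!r} has zero population; rate undefined")
    if amap.n_areas < 2:
        raise ValidationError("global smoothing needs at least 2 areas")
    K = amap.n_areas
    t = y / n
    m_tilde = y.sum() / n.sum()
    s2 = float((n * (t - m_tilde) ** 2).sum() / n.sum())
    n_bar = n.sum() / K
    A_tilde = max(0.0, s2 - m_tilde / n_bar)
    theta, w = _shrink(y, n, np.full(K, m_tilde), np.full(K, A_tilde))
    return SmoothedRates(theta, w, np.full(K, m_tilde), np.full(K, A_tilde), "global")


def marshall_local(
    cases: CaseVector, amap: AreaMap, include_self: bool = True
) -> SmoothedRates:
    """Local empirical-Bayes smoothing over first-order neighbourhoods.

    For each area i the global moment formulas are evaluated on
    N(i) = {i} ∪ neighbours(i) (or the neighbours alone when
    ``include_self=False``), so the prior mean M_i and variance A_i vary
    across the map.  An isolated area degenerates to a single-element
    neighbourhood with zero prior variance, leaving its raw rate
    untouched (a warning is logged).
    """
    y = cases.counts.astype(float)
    n = amap.populations.astype(float)
    if (n <= 0).any():
        bad = amap.ids[int(np.argmax(n <= 0))]
        raise ValidationError(f"area {bad!r} has zero population; rate undefined")
    nbrs = amap.neighbor_indices()
    K = amap.n_areas
    theta = np.empty(K)
    w_out = np.empty(K)
    M_out = np.empty(K)
    A_out = np.empty(K)
    for i in range(K):
        hood = nbrs[i]
        if include_self or hood.size == 0:
            hood = np.append(hood, i)
        if hood.size == 1 and nbrs[i].size == 0:
            logger.warning(
                "area %r is isolated; its rate is not smoothed", amap.ids[i]
            )
        yh, nh = y[hood], n[hood]
        if nh.sum() <= 0:
            raise ValidationError(
                f"neighbourhood of area {amap.ids[i]!r} has zero total population"
            )
        th = yh / nh
        M_i = yh.sum() / nh.sum()
        s2_i = float((nh * (th - M_i) ** 2).sum() / nh.sum())
        n_bar_i = nh.sum() / hood.size
        A_i = max(0.0, s2_i - M_i / n_bar_i)
        theta_i, w_i = _shrink(y[i : i + 1], n[i : i + 1], np.array([M_i]), np.array([A_i]))
        theta[i], w_out[i] = theta_i[0], w_i[0]
        M_out[i], A_out[i] = M_i, A_i
    return SmoothedRates(theta, w_out, M_out, A_out, "local")


def smoothed_probabilities(sm: SmoothedRates, amap: AreaMap) -> np.ndarray:
    """Replication probabilities from smoothed expected counts.

    p_i = n_i * theta_hat_i / sum_j n_j * theta_hat_j — the multinomial
    cell probabilities for the smoothed mean model.  Zero-case areas get
    positive probability whenever their neighbourhood carries cases.
    """
    expected = amap.populations * sm.theta_hat
    total = expected.sum()
    if total <= 0:
        raise ValidationError("all smoothed rates are zero; no probabilities defined")
    return expected / total
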