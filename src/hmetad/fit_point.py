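"""Single-subject meta-d' estimation by constrained MLE or sum-of-squared error.

Both routines hold the first-order parameters (d', c) at their observed
values, anchor the meta-level criterion through meta-c' = c' (so the
meta-level observer shows the same relative response bias as the decisions)
and search over meta-d' and the 2(k-1) type 2 criteria.  Ordering of the
criteria is enforced by construction: criteria are parameterized as meta-c
plus cumulative positive increments, so the optimizer runs unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .sdt_core import (
    ConfidenceCounts,
    MetaDParams,
    Type1Stats,
    cell_probabilities,
    type1_stats,
)

__all__ = ["MetaDFit", "loglik_type2", "loglik_matrix", "fit_mle", "fit_sse"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaDFit:
    """Result of a single-subject meta-d' fit."""

    type1: Type1Stats
    params: MetaDParams
    mratio: float
    logL: float  # maximized log-likelihood (MLE) or minimized SSE (SSE fit)
    converged: bool
    padding_used: float
    method: str = "mle"


def loglik_matrix(
    nmat: np.ndarray,
    meta_d: np.ndarray,
    meta_c: np.ndarray,
    cS1: np.ndarray,
    cS2: np.ndarray,
) -> np.ndarray:
    """Multinomial type 2 log-likelihood, batched.

    ``nmat`` has shape ``(..., 2, 2k)`` — counts per stimulus in the
    evidence-ordered cell convention — and broadcasts against the batch
    axes of the parameters.  Cells with zero count contribute 0 even when
    the model assigns them zero probability; a positive count on a
    zero-probability cell yields -inf.
    """
    cells, mass_s1 = cell_probabilities(meta_d, meta_c, cS1, cS2)
    k = np.asarray(cS1).shape[-1] + 1
    denom = np.concatenate(
        [
            np.repeat(mass_s1[..., None], k, axis=-1),
            np.repeat((1.0 - mass_s1)[..., None], k, axis=-1),
        ],
        axis=-1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(cells > 0, np.log(cells) - np.log(denom), -np.inf)
        term = np.where(nmat > 0, nmat * logp, 0.0)
    return term.sum(axis=(-1, -2))


def _cond_probs_matrix(meta_d, meta_c, cS1, cS2) -> np.ndarray:
    """P(cell | stim, response region) in the (2, 2k) cell layout."""
    cells, mass_s1 = cell_probabilities(meta_d, meta_c, cS1, cS2)
    k = np.asarray(cS1).shape[-1] + 1
    denom = np.concatenate(
        [
            np.repeat(mass_s1[..., None], k, axis=-1),
            np.repeat((1.0 - mass_s1)[..., None], k, axis=-1),
        ],
        axis=-1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, cells / denom, 0.0)


def loglik_type2(params: MetaDParams, counts: ConfidenceCounts) -> float:
    """Log-likelihood of the confidence counts under the type 2 model."""
    if params.k != counts.k:
        raise ValueError("params and counts disagree on the number of rating levels")
    return float(
        loglik_matrix(
            counts.as_matrix(),
            np.float64(params.meta_d),
            np.float64(params.meta_c),
            params.cS1,
            params.cS2,
        )
    )


def _unpack(theta: np.ndarray, anchor: tuple[str, float], k: int):
    """theta = [meta_d, z1 (k-1), z2 (k-1)] -> ordered criteria via positive increments.

    ``anchor`` is ("relative", c') in the regular case (meta_c = c' * meta_d)
    or ("absolute", c) in the degenerate d' = 0 case (meta_c fixed at c).
    """
    meta_d = theta[0]
    kind, val = anchor
    meta_c = val * meta_d if kind == "relative" else val
    inc1 = np.exp(theta[1:k])
    inc2 = np.exp(theta[k : 2 * k - 1])
    cS1 = meta_c - np.cumsum(inc1)[::-1]
    cS2 = meta_c + np.cumsum(inc2)
    return meta_d, meta_c, cS1, cS2


def _fit(counts: ConfidenceCounts, padding: float, objective: str) -> MetaDFit:
    t1 = type1_stats(counts, padding=padding)
    if np.isfinite(t1.c_rel):
        anchor = ("relative", t1.c_rel)
    else:
        # d' = 0: c' = c/d' is undefined, so anchor the meta-level criterion
        # at the observed absolute criterion instead
        logger.warning("d' = 0 for this subject; anchoring meta_c at the absolute criterion c")
        anchor = ("absolute", t1.c)
    k = counts.k
    nmat = counts.as_matrix() + padding

    if objective == "sse":
        # observed conditional type 2 probabilities on the padded counts
        totals = np.stack([nmat[:, :k].sum(axis=1), nmat[:, k:].sum(axis=1)], axis=1)
        denom = np.concatenate(
            [np.repeat(totals[:, :1], k, axis=1), np.repeat(totals[:, 1:], k, axis=1)],
            axis=1,
        )
        obs = np.where(denom > 0, nmat / denom, 0.0)
        use = denom > 0

        def fun(theta):
            model = _cond_probs_matrix(*_unpack(theta, anchor, k))
            return float(((obs - model) ** 2)[use].sum())

    else:

        def fun(theta):
            ll = loglik_matrix(nmat, *_unpack(theta, anchor, k))
            return float(-ll) if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(0)
    x0 = np.concatenate([[t1.d_prime], np.full(2 * (k - 1), np.log(0.5))])
    best = None
    ok = False
    bounds = [(-10.0, 10.0)] + [(-7.0, 3.0)] * (2 * (k - 1))
    for start in range(5):
        x = x0 if start == 0 else x0 + rng.normal(0.0, 0.3, size=x0.shape)
        res = minimize(fun, x, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or bool(res.success)
    if not ok:
        logger.warning("meta-d' optimizer did not report convergence: %s", best.message)
    meta_d, meta_c, cS1, cS2 = _unpack(best.x, anchor, k)
    params = MetaDParams(meta_d=float(meta_d), meta_c=float(meta_c), cS1=cS1, cS2=cS2)
    value = -best.fun if objective == "mle" else best.fun
    with np.errstate(divide="ignore", invalid="ignore"):
        mratio = float(np.float64(meta_d) / t1.d_prime)  # +-inf/nan when d' = 0
    return MetaDFit(
        type1=t1,
        params=params,
        mratio=mratio,
        logL=float(value),
        converged=ok,
        padding_used=padding,
        method=objective,
    )


def fit_mle(counts: ConfidenceCounts, padding: float = 0.25) -> MetaDFit:
    """Maximum-likelihood meta-d' fit with edge correction.

    ``padding`` is added to all 4k cells before both the first-order rates
    and the type 2 likelihood are computed (default 0.25, the multi-cell
    log-linear correction); it guards against zero counts in, e.g., the
    high-confidence-error cells.
    """
    return _fit(counts, padding, "mle")


def fit_sse(counts: ConfidenceCounts, padding: float = 0.25) -> MetaDFit:
    """Least-squares meta-d' fit: minimizes the unweighted sum of squared
    differences between observed and model conditional type 2 probabilities
    over the same constrained parameter space as :func:`fit_mle`."""
    return _fit(counts, padding, "sse")
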