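"""Core signal detection theory types and the type 2 probability model.

The type 1 task is a two-choice discrimination between stimulus classes S1
and S2; the type 2 task is rating confidence that one's own type 1 response
was correct.  Everything in this module is expressed in the equal-variance
Gaussian SDT framework: evidence ``x ~ Normal(-d'/2, 1)`` for S1 stimuli and
``x ~ Normal(+d'/2, 1)`` for S2 stimuli, response "S2" iff ``x > c``.

The meta-level model replaces ``d'`` and ``c`` with ``meta_d`` and
``meta_c`` and partitions the evidence axis further by response-conditional
type 2 criteria, yielding a multinomial distribution over confidence
ratings conditional on (stimulus, response).  That distribution is the
likelihood all fitting routines in this package share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "ConfidenceCounts",
    "Type1Stats",
    "MetaDParams",
    "Type2ProbTable",
    "type1_stats",
    "type2_probs",
    "type2_roc",
    "auroc2",
    "cell_probabilities",
]


@dataclass(frozen=True)
class ConfidenceCounts:
    """Confidence-rating counts conditional on the stimulus class.

    ``nR_S1`` and ``nR_S2`` each have length ``2k`` for ``k`` rating
    levels.  Entry 1 counts maximum-confidence "S1" responses, entry ``k``
    minimum-confidence "S1" responses, entry ``k + 1`` minimum-confidence
    "S2" responses and entry ``2k`` maximum-confidence "S2" responses; the
    vector therefore runs along the evidence axis from strong S1 evidence
    to strong S2 evidence.
    """

    nR_S1: np.ndarray
    nR_S2: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.nR_S1, dtype=np.int64)
        b = np.asarray(self.nR_S2, dtype=np.int64)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise ValueError("nR_S1 and nR_S2 must be 1-D vectors of equal length")
        if a.size % 2 or a.size < 4:
            raise ValueError("count vectors must have even length 2k with k >= 2")
        if (a < 0).any() or (b < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "nR_S1", a)
        object.__setattr__(self, "nR_S2", b)

    @property
    def k(self) -> int:
        """Number of confidence levels."""
        return self.nR_S1.size // 2

    @property
    def n_trials(self) -> int:
        return int(self.nR_S1.sum() + self.nR_S2.sum())

    def as_matrix(self) -> np.ndarray:
        """Counts as a (stimulus, cell) array; rows S1, S2; 2k cells."""
        return np.stack([self.nR_S1, self.nR_S2]).astype(float)

    def correct_incorrect(self) -> tuple[np.ndarray, np.ndarray]:
        """Rating counts (confidence 1..k) pooled over correct / incorrect trials."""
        k = self.k
        correct = self.nR_S1[:k][::-1] + self.nR_S2[k:]
        incorrect = self.nR_S2[:k][::-1] + self.nR_S1[k:]
        return correct.astype(np.int64), incorrect.astype(np.int64)


@dataclass(frozen=True)
class Type1Stats:
    """First-order sensitivity and bias.

    ``c_rel`` is the relative criterion c' = c/d'; it is NaN when d' = 0
    (callers should skip such subjects rather than divide by zero).
    """

    d_prime: float
    c: float
    c_rel: float = field(init=False)

    def __post_init__(self) -> None:
        c_rel = self.c / self.d_prime if self.d_prime != 0.0 else float("nan")
        object.__setattr__(self, "c_rel", c_rel)


@dataclass(frozen=True)
class MetaDParams:
    """Generative parameters of the type 2 (meta-level) observer.

    ``cS1`` are the k-1 type 2 criteria below ``meta_c`` (ascending) used
    after "S1" responses; ``cS2`` the k-1 criteria above ``meta_c`` used
    after "S2" responses.  The concatenation (cS1, meta_c, cS2) must be
    nondecreasing.
    """

    meta_d: float
    meta_c: float
    cS1: np.ndarray
    cS2: np.ndarray

    def __post_init__(self) -> None:
        c1 = np.asarray(self.cS1, dtype=float)
        c2 = np.asarray(self.cS2, dtype=float)
        if c1.ndim != 1 or c2.ndim != 1 or c1.size != c2.size or c1.size < 1:
            raise ValueError("cS1 and cS2 must be 1-D with equal length k-1 >= 1")
        full = np.concatenate([c1, [self.meta_c], c2])
        if np.any(np.diff(full) < 0):
            raise ValueError("criteria must satisfy cS1 <= meta_c <= cS2, each ascending")
        object.__setattr__(self, "cS1", c1)
        object.__setattr__(self, "cS2", c2)

    @property
    def k(self) -> int:
        return self.cS1.size + 1


@dataclass(frozen=True)
class Type2ProbTable:
    """P(confidence | stimulus, response), shape (2 stim, 2 resp, k)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 3 or p.shape[:2] != (2, 2):
            raise ValueError("probability table must have shape (2, 2, k)")
        object.__setattr__(self, "p", p)

    @property
    def k(self) -> int:
        return self.p.shape[2]


def type1_stats(counts: ConfidenceCounts, padding: float = 0.0) -> Type1Stats:
    """First-order d' and criterion from hit and false-alarm rates.

    HR = P("S2" response | S2 stimulus), FAR = P("S2" response | S1);
    d' = z(HR) - z(FAR) and c = -0.5 (z(HR) + z(FAR)).  ``padding`` is
    added to every rating cell before rates are formed (the multi-cell
    generalization of the log-linear edge correction); with padding 0 an
    extreme rate of exactly 0 or 1 is an error.
    """
    if padding < 0:
        raise ValueError("padding must be non-negative")
    k = counts.k
    s1 = counts.nR_S1 + padding
    s2 = counts.nR_S2 + padding
    far = s1[k:].sum() / s1.sum()
    hr = s2[k:].sum() / s2.sum()
    if padding == 0.0 and (hr in (0.0, 1.0) or far in (0.0, 1.0)):
        raise ValueError(
            "hit or false-alarm rate is exactly 0 or 1; "
            "re-run with padding > 0 (e.g. 0.25 or 1/(2k)) to apply edge correction"
        )
    z_hr, z_far = ndtri(hr), ndtri(far)
    return Type1Stats(d_prime=float(z_hr - z_far), c=float(-0.5 * (z_hr + z_far)))


def cell_probabilities(
    meta_d: np.ndarray,
    meta_c: np.ndarray,
    cS1: np.ndarray,
    cS2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint cell masses P(cell | stimulus) for the 2k nR-ordered cells.

    Batched over arbitrary leading axes: ``meta_d``/``meta_c`` shape
    ``(...)``, ``cS1``/``cS2`` shape ``(..., k-1)``.  Returns
    ``(cells, mass_S1)`` with ``cells`` of shape ``(..., 2, 2k)`` (stimulus
    axis first, cells running from strong-S1 to strong-S2 evidence, i.e. in
    the count-vector convention) and ``mass_S1`` of shape ``(..., 2)``, the
    probability of an "S1" response given each stimulus.  Conditioning the
    first k / last k cells on the response mass yields the type 2
    probabilities.
    """
    meta_d = np.asarray(meta_d, dtype=float)
    meta_c = np.asarray(meta_c, dtype=float)
    cS1 = np.asarray(cS1, dtype=float)
    cS2 = np.asarray(cS2, dtype=float)
    bounds = np.concatenate(
        [cS1, meta_c[..., None], cS2], axis=-1
    )  # (..., 2k-1) interior boundaries, ascending
    mu = np.stack([-meta_d / 2.0, meta_d / 2.0], axis=-1)  # (..., 2)
    cdf = ndtr(bounds[..., None, :] - mu[..., :, None])  # (..., 2, 2k-1)
    ones = np.ones(cdf.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    cdf_full = np.concatenate([zeros, cdf, ones], axis=-1)  # (..., 2, 2k+1)
    cells = np.diff(cdf_full, axis=-1)  # (..., 2, 2k)
    k = cS1.shape[-1] + 1
    mass_S1 = cdf_full[..., :, k]  # P(x < meta_c | stim)
    return cells, mass_S1


def type2_probs(params: MetaDParams) -> Type2ProbTable:
    """Confidence distribution P(conf | stim, resp) implied by the meta-level model.

    The evidence axis is partitioned by (cS1, meta_c, cS2); within the
    "S1"-response region confidence increases towards more negative
    evidence, within the "S2" region towards more positive evidence, and
    each (stimulus, response) slice is normalized by the mass of its
    response region.
    """
    cells, mass_s1 = cell_probabilities(
        np.float64(params.meta_d), np.float64(params.meta_c), params.cS1, params.cS2
    )
    k = params.k
    with np.errstate(divide="ignore", invalid="ignore"):
        # resp S1: cells 0..k-1 hold conf k..1; flip so index = conf-1
        p_s1 = cells[:, :k][:, ::-1] / mass_s1[:, None]
        p_s2 = cells[:, k:] / (1.0 - mass_s1)[:, None]
    table = np.stack([p_s1, p_s2], axis=1)  # (stim, resp, conf)
    if np.isnan(table).any():
        raise FloatingPointError(
            "type 2 probabilities are undefined: a response region has zero mass"
        )
    return Type2ProbTable(p=table)


def type2_roc(counts: ConfidenceCounts) -> np.ndarray:
    """Response-collapsed type 2 ROC points, shape (k+1, 2) of (FAR2, HR2).

    HR2 at level y is P(conf >= y | correct), FAR2 is P(conf >= y |
    incorrect); sweeping y from k down to 1 traces the curve from (0, 0)
    to (1, 1).
    """
    correct, incorrect = counts.correct_incorrect()
    n_c, n_i = correct.sum(), incorrect.sum()
    if n_c == 0 or n_i == 0:
        raise ValueError("type 2 ROC requires at least one correct and one incorrect trial")
    # cumulate from the high-confidence end
    hr2 = np.cumsum(correct[::-1]) / n_c
    far2 = np.cumsum(incorrect[::-1]) / n_i
    pts = np.column_stack([np.concatenate([[0.0], far2]), np.concatenate([[0.0], hr2])])
    return pts


def auroc2(counts: ConfidenceCounts) -> float:
    """Area under the type 2 ROC: how well ratings discriminate correct from error trials."""
    pts = type2_roc(counts)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
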