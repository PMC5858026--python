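"""Synthetic confidence-rating data with independently controlled d' and meta-d'.

Two generators are provided.  ``metad_sim`` draws the four type 1 response
classes (hits, false alarms, misses, correct rejections) from the standard
first-order SDT model and then draws confidence counts within each class
from the multinomial type 2 model, so first-order performance (d', c) and
metacognitive efficiency (meta-d'/d') are controlled separately.
``simulate_noisy_confidence`` is a trial-level observer whose confidence is
based on the decision evidence corrupted by additional Gaussian noise — the
canonical mechanism by which meta-d' falls below d'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .sdt_core import ConfidenceCounts, MetaDParams, type2_probs

__all__ = [
    "SimSpec",
    "GroupSimSpec",
    "metad_sim",
    "simulate_group",
    "simulate_correlated_group",
    "simulate_noisy_confidence",
]

#: smallest admissible subject-level d' when drawing groups
D_PRIME_FLOOR = 0.1


@dataclass(frozen=True)
class SimSpec:
    """Generative settings for one subject's confidence counts.

    ``c2_S2`` holds the k-1 positive, ascending type 2 criterion offsets
    above the meta-level criterion; the "S1"-response criteria mirror them
    below it.  ``mratio`` is the target meta-d'/d', so the implied
    meta-sensitivity is ``mratio * d_prime``.
    """

    d_prime: float
    c: float = 0.0
    c2_S2: np.ndarray = field(default_factory=lambda: np.array([0.5, 1.0, 1.5]))
    n_trials: int = 400
    mratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        c2 = np.asarray(self.c2_S2, dtype=float)
        if c2.ndim != 1 or c2.size < 1:
            raise ValueError("c2_S2 must be a 1-D vector of k-1 >= 1 offsets")
        if (c2 <= 0).any() or np.any(np.diff(c2) < 0):
            raise ValueError("c2_S2 offsets must be positive and ascending")
        if self.d_prime <= 0:
            raise ValueError("d_prime must be positive")
        if self.mratio <= 0:
            raise ValueError("mratio must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")
        object.__setattr__(self, "c2_S2", c2)

    @property
    def k(self) -> int:
        return self.c2_S2.size + 1

    def meta_params(self) -> MetaDParams:
        """The type 2 observer implied by the spec (meta-c' anchored at c')."""
        meta_d = self.mratio * self.d_prime
        meta_c = (self.c / self.d_prime) * meta_d
        return MetaDParams(
            meta_d=meta_d,
            meta_c=meta_c,
            cS1=meta_c - self.c2_S2[::-1],
            cS2=meta_c + self.c2_S2,
        )


@dataclass(frozen=True)
class GroupSimSpec:
    """Settings for a simulated group: per-subject d' ~ Normal(mean, sd), floored."""

    n_subjects: int = 20
    d_prime_mean: float = 2.0
    d_prime_sd: float = 0.2
    c: float = 0.0
    c2_S2: np.ndarray = field(default_factory=lambda: np.array([0.5, 1.0, 1.5]))
    n_trials: int = 400
    mratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.d_prime_sd < 0:
            raise ValueError("d_prime_sd must be >= 0")
        object.__setattr__(self, "c2_S2", np.asarray(self.c2_S2, dtype=float))


def _metad_sim(spec: SimSpec, rng: np.random.Generator) -> ConfidenceCounts:
    n_s1 = spec.n_trials // 2
    n_s2 = spec.n_trials - n_s1
    # type 1 response-class counts from the first-order model
    p_resp_s2 = {
        "S1": 1.0 - ndtr(spec.c + spec.d_prime / 2.0),  # false-alarm rate
        "S2": 1.0 - ndtr(spec.c - spec.d_prime / 2.0),  # hit rate
    }
    fa = rng.binomial(n_s1, p_resp_s2["S1"])
    hits = rng.binomial(n_s2, p_resp_s2["S2"])
    class_n = {  # (stim, resp) -> count
        (0, 0): n_s1 - fa,
        (0, 1): fa,
        (1, 0): n_s2 - hits,
        (1, 1): hits,
    }
    probs = type2_probs(spec.meta_params()).p
    k = spec.k
    nR = np.zeros((2, 2 * k), dtype=np.int64)
    for (stim, resp), n in class_n.items():
        conf = rng.multinomial(n, probs[stim, resp])
        if resp == 0:  # "S1" responses fill cells k-1..0 as confidence rises
            nR[stim, :k] += conf[::-1]
        else:
            nR[stim, k:] += conf
    return ConfidenceCounts(nR_S1=nR[0], nR_S2=nR[1])


def metad_sim(spec: SimSpec) -> ConfidenceCounts:
    """Draw one subject's confidence counts; deterministic given ``spec.seed``."""
    return _metad_sim(spec, np.random.default_rng(spec.seed))


def simulate_group(spec: GroupSimSpec) -> list[ConfidenceCounts]:
    """Draw one ConfidenceCounts per subject.

    Each subject consumes an independent stream seeded by (seed, subject
    index), so subject s's data do not depend on ``n_subjects``.
    """
    out = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, s])
        d = max(float(rng.normal(spec.d_prime_mean, spec.d_prime_sd)), D_PRIME_FLOOR)
        sub = SimSpec(
            d_prime=d,
            c=spec.c,
            c2_S2=spec.c2_S2,
            n_trials=spec.n_trials,
            mratio=spec.mratio,
            seed=0,
        )
        out.append(_metad_sim(sub, rng))
    return out


def simulate_correlated_group(
    n_subjects: int,
    mean_mratio: float = 0.8,
    sd_logmratio: float = 0.5,
    rho: float = 0.6,
    d_prime_mean: float = 2.0,
    d_prime_sd: float = 0.2,
    c: float = 0.0,
    c2_S2: np.ndarray | list[float] = (0.5, 1.0, 1.5),
    n_trials: int = 400,
    seed: int = 0,
) -> tuple[list[ConfidenceCounts], list[ConfidenceCounts], np.ndarray]:
    """Two-task group with correlated per-subject log efficiencies.

    ``(log M1_s, log M2_s)`` is drawn from a bivariate Gaussian with both
    means ``log(mean_mratio)``, both SDs ``sd_logmratio`` and correlation
    ``rho``; each task gets its own d' draw from Normal(d_prime_mean,
    d_prime_sd), floored.  Returns (task1 counts, task2 counts, logM array
    of shape (n_subjects, 2)).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    mu = np.log(mean_mratio)
    cov = sd_logmratio**2 * np.array([[1.0, rho], [rho, 1.0]])
    data1: list[ConfidenceCounts] = []
    data2: list[ConfidenceCounts] = []
    logm = np.empty((n_subjects, 2))
    for s in range(n_subjects):
        rng = np.random.default_rng([seed, s])
        logm[s] = rng.multivariate_normal([mu, mu], cov)
        for t, lst in ((0, data1), (1, data2)):
            d = max(float(rng.normal(d_prime_mean, d_prime_sd)), D_PRIME_FLOOR)
            sub = SimSpec(
                d_prime=d,
                c=c,
                c2_S2=np.asarray(c2_S2, dtype=float),
                n_trials=n_trials,
                mratio=float(np.exp(logm[s, t])),
                seed=0,
            )
            lst.append(_metad_sim(sub, rng))
    return data1, data2, logm


def simulate_noisy_confidence(
    d_prime: float,
    c: float,
    c2: np.ndarray,
    noise_sd: float,
    n_trials: int,
    seed: int = 0,
) -> ConfidenceCounts:
    """Trial-level observer whose ratings use noise-corrupted decision evidence.

    The decision compares the evidence sample ``x`` with ``c``; the rating
    bins ``x + Normal(0, noise_sd)`` by the type 2 criteria ``c ± c2`` on
    the chosen-response side.  A noisy value that crosses back over the
    decision criterion does not revise the decision — it clamps to the
    lowest-confidence bin of the chosen response.  With ``noise_sd = 0``
    this is the ideal observer, whose meta-d' equals d'.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    c2 = np.asarray(c2, dtype=float)
    k = c2.size + 1
    rng = np.random.default_rng(seed)
    n_s1 = n_trials // 2
    n_s2 = n_trials - n_s1
    stim = np.repeat([0, 1], [n_s1, n_s2])
    x = rng.normal(np.where(stim == 0, -d_prime / 2.0, d_prime / 2.0), 1.0)
    resp = (x > c).astype(np.int64)
    y = x + rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else x
    cS1 = c - c2[::-1]
    cS2 = c + c2
    conf = np.empty(n_trials, dtype=np.int64)
    m2 = resp == 1
    conf[m2] = np.searchsorted(cS2, y[m2], side="right") + 1
    conf[~m2] = k - np.searchsorted(cS1, y[~m2], side="left")
    np.clip(conf, 1, k, out=conf)
    # cell index along the evidence-ordered count vector
    cell = np.where(resp == 0, k - conf, k - 1 + conf)
    nR = np.zeros((2, 2 * k), dtype=np.int64)
    for s in (0, 1):
        nR[s] = np.bincount(cell[stim == s], minlength=2 * k)
    return ConfidenceCounts(nR_S1=nR[0], nR_S2=nR[1])
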