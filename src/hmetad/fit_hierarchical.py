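"""Hierarchical Bayesian estimation of group-level metacognitive efficiency.

The group model treats each subject's first-order parameters (d'_s, c_s) as
fixed point estimates and places the inferential weight on
``log M_s = log(meta-d'_s / d'_s)``, the subject's log metacognitive
efficiency.  Subject efficiencies are partially pooled through a Gaussian
group prior whose scale is sampled with a parameter-expansion
reparameterization

    log M_s = mu_M + xi_M * delta_s,      delta_s ~ Normal(0, sigma_delta),

so the hierarchical SD is recovered per sample as
``sigma_M = |xi_M| * sigma_delta``; the redundant multiplier ``xi_M``
prevents the scale from sticking near zero during sampling.  Type 2
criteria are subject-level parameters with mirrored per-criterion group
priors.  Because the multinomial confidence likelihood handles empty cells
natively, no edge correction is applied to the data.

Priors (overridable through :class:`HierModelSpec`):

    mu_M ~ Normal(0, 1)          xi_M ~ Beta(1, 1)        sigma_delta ~ HalfNormal(1)
    mu_c2[j] ~ Normal(0, 10)     sigma_c2[j] ~ HalfNormal(10)
    cS1_s[j] ~ Normal(-mu_c2[mirror j], sigma_c2)   cS2_s[j] ~ Normal(+mu_c2[j], sigma_c2)

subject criteria being jointly restricted to the ordering
cS1 ascending <= meta_c_s <= cS2 ascending.

Sampling uses an adaptive Metropolis-within-Gibbs scheme vectorized across
chains and subjects; proposal scales adapt only during burn-in.  A
translation move that shifts ``mu_M`` against ``delta`` at fixed ``log M``
decorrelates the group mean from the subject offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fit_point import fit_mle, loglik_matrix
from .sdt_core import ConfidenceCounts, type1_stats

__all__ = [
    "HierModelSpec",
    "HierPosterior",
    "CredInterval",
    "GroupDifference",
    "fit_group",
    "fit_group_correlation",
    "rhat",
    "calc_ci",
    "calc_hdi",
    "dic",
    "group_difference",
]

logger = logging.getLogger(__name__)

_ADAPT_WINDOW = 50
_TARGET_ACC = 0.44


@dataclass(frozen=True)
class HierModelSpec:
    """Priors and MCMC settings for the hierarchical fits."""

    mu_c2_prior_sd: float = 10.0
    sigma_c2_prior_sd: float = 10.0
    mu_M_prior_sd: float = 1.0
    sigma_delta_prior_sd: float = 1.0
    n_chains: int = 3
    n_samples: int = 10_000
    n_burnin: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if self.n_burnin < 1 or self.n_samples <= 0:
            raise ValueError("need n_samples > 0 and n_burnin >= 1")


@dataclass(frozen=True)
class CredInterval:
    lo: float
    hi: float
    level: float = 0.95
    kind: str = "symmetric-CI"

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("interval bounds out of order")

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass
class HierPosterior:
    """Per-chain MCMC samples plus diagnostics for a hierarchical fit.

    ``samples`` maps parameter names to arrays whose first two axes are
    (chain, draw); subject-level parameters carry a trailing subject axis.
    """

    samples: dict[str, np.ndarray]
    rhat: dict[str, np.ndarray]
    dic: float
    d_prime: np.ndarray
    c: np.ndarray
    subjects_used: np.ndarray

    def pooled(self, name: str) -> np.ndarray:
        """All chains' draws of one parameter, concatenated."""
        x = self.samples[name]
        return x.reshape(-1, *x.shape[2:])

    @property
    def mean_mratio(self) -> float:
        """Posterior mean of group metacognitive efficiency exp(mu_logMratio)."""
        return float(np.mean(np.exp(self.pooled("mu_logMratio"))))

    def ci_mratio(self) -> CredInterval:
        return calc_ci(np.exp(self.pooled("mu_logMratio")))


@dataclass(frozen=True)
class GroupDifference:
    """Posterior of the group difference mu_M,A - mu_M,B (log units)."""

    samples: np.ndarray
    ci: CredInterval
    excludes_zero: bool


# ---------------------------------------------------------------------------
# diagnostics


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Values near 1 indicate the
    chains sample the same distribution; values above ~1.1 indicate
    non-convergence.  Zero variance in every chain returns 1 by convention,
    and sampling noise that would push the statistic below 1 is floored at 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    m, n = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return 1.0
    b_over_n = means.var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    return float(max(1.0, np.sqrt(var_plus / w)))


def calc_ci(samples: np.ndarray, level: float = 0.95) -> CredInterval:
    """Symmetric credible interval from percentiles (linear interpolation)."""
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < 40:
        raise ValueError("need at least 40 samples for a stable interval")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(s, [alpha, 100.0 - alpha])
    return CredInterval(lo=float(lo), hi=float(hi), level=level, kind="symmetric-CI")


def calc_hdi(samples: np.ndarray, level: float = 0.95) -> CredInterval:
    """Highest-density interval: shortest window containing ``level`` mass."""
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    if s.size < 40:
        raise ValueError("need at least 40 samples for a stable interval")
    n_in = int(np.ceil(level * s.size))
    widths = s[n_in - 1 :] - s[: s.size - n_in + 1]
    i = int(np.argmin(widths))
    return CredInterval(lo=float(s[i]), hi=float(s[i + n_in - 1]), level=level, kind="HDI")


def dic(deviance_trace: np.ndarray, deviance_at_mean: float) -> float:
    """Deviance information criterion: mean deviance + p_D.

    ``p_D = mean(deviance) - deviance(posterior-mean parameters)`` — the
    classical effective-parameter count.  Not comparable with DIC values
    computed under the half-variance-of-deviance convention.
    """
    d_bar = float(np.mean(deviance_trace))
    return d_bar + (d_bar - float(deviance_at_mean))


def group_difference(postA: HierPosterior, postB: HierPosterior, seed: int = 0) -> GroupDifference:
    """Posterior of mu_M,A - mu_M,B from pooled samples.

    If the two posteriors hold different numbers of draws, the longer one
    is randomly subsampled (fixed seed) to pair draws one-to-one.
    """
    for name, post in (("A", postA), ("B", postB)):
        bad = {k: v for k, v in post.rhat.items() if np.any(np.asarray(v) >= 1.1)}
        if bad:
            logger.warning("group %s fit has R-hat >= 1.1 for %s", name, sorted(bad))
    a = postA.pooled("mu_logMratio")
    b = postB.pooled("mu_logMratio")
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        n = min(a.size, b.size)
        if a.size > n:
            a = rng.choice(a, size=n, replace=False)
        if b.size > n:
            b = rng.choice(b, size=n, replace=False)
    d = a - b
    ci = calc_ci(d)
    return GroupDifference(samples=d, ci=ci, excludes_zero=not ci.contains(0.0))


# ---------------------------------------------------------------------------
# shared sampler machinery


def _log_normal_pdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def _log_half_normal(x, sd):
    out = np.where(x > 0, -0.5 * (x / sd) ** 2, -np.inf)
    return out


class _Adaptive:
    """Per-component proposal scales with window-based burn-in adaptation."""

    def __init__(self, shape, init):
        self.step = np.full(shape, float(init))
        self.acc = np.zeros(shape)

    def tally(self, accepted):
        self.acc += accepted

    def adapt(self):
        rate = self.acc / _ADAPT_WINDOW
        self.step *= np.clip(np.exp(rate - _TARGET_ACC), 0.5, 2.0)
        self.acc[:] = 0.0


def _prepare_subjects(data: list[ConfidenceCounts]):
    """Fixed (d'_s, c_s) point estimates from 1/(2k)-adjusted rates.

    Subjects with noisy, even non-positive, d' estimates are retained: the
    model scales each subject's meta-sensitivity as meta_d_s = M_s * d'_s
    and its meta-criterion as meta_c_s = c_s * M_s (the constraint
    meta-c' = c' expressed without dividing by d'), both of which remain
    well-defined whatever the sign of d'_s.
    """
    d, c, keep = [], [], []
    for i, counts in enumerate(data):
        # a 1/(2k) adjustment on the type 1 rate computation keeps every
        # subject's (d', c) finite; the confidence counts themselves stay
        # unpadded — the multinomial likelihood needs no edge correction
        t1 = type1_stats(counts, padding=1.0 / (2.0 * counts.k))
        d.append(t1.d_prime)
        c.append(t1.c)
        keep.append(i)
    if len(keep) < 2:
        raise ValueError("need at least 2 usable subjects")
    return np.array(d), np.array(c), np.array(keep, dtype=int)


def _init_from_mle(data, idx):
    """Per-subject MLE point fits used only to initialize the chains."""
    logm, cs1, cs2 = [], [], []
    for i in idx:
        f = fit_mle(data[i], padding=0.25)
        m = f.mratio if np.isfinite(f.mratio) else 1.0  # d' = 0 subjects: neutral start
        logm.append(np.log(np.clip(m, 0.05, 20.0)))
        cs1.append(f.params.cS1)
        cs2.append(f.params.cS2)
    return np.array(logm), np.array(cs1), np.array(cs2)


def _enforce_order(cs1, cs2, meta_c, gap=1e-3):
    """Project criteria into the ordered region around meta_c (in place)."""
    cs1.sort(axis=-1)
    cs2.sort(axis=-1)
    km1 = cs1.shape[-1]
    off = gap * np.arange(km1, 0, -1)
    np.minimum(cs1, meta_c[..., None] - off, out=cs1)
    np.maximum(cs2, meta_c[..., None] + off[::-1], out=cs2)
    cs1.sort(axis=-1)
    cs2.sort(axis=-1)


def _neighbor_bounds(arr, j, lo_edge, hi_edge):
    """Admissible interval for coordinate j of an ascending criteria block."""
    lo = arr[..., j - 1] if j > 0 else lo_edge
    hi = arr[..., j + 1] if j < arr.shape[-1] - 1 else hi_edge
    return lo, hi


# ---------------------------------------------------------------------------
# single-group model


class _GroupSampler:
    def __init__(self, data, spec: HierModelSpec):
        self.spec = spec
        self.d, self.c, self.idx = _prepare_subjects(data)
        self.k = data[0].k
        self.nmat = np.stack([data[i].as_matrix() for i in self.idx])  # (S, 2, 2k)
        self.S = len(self.idx)
        self.C = spec.n_chains
        self.rng = np.random.default_rng([spec.seed, 2_000_001])
        self._init_state(data)

    # -- model pieces ------------------------------------------------------

    def _derived(self, mu, xi, delta):
        # meta_d = M * d' and meta_c = M * c (the meta-c' = c' anchor written
        # without dividing by d', so noisy non-positive d' estimates are fine)
        logm = mu[:, None] + xi[:, None] * delta
        m = np.exp(logm)
        return logm, m * self.d, m * self.c

    def _ll(self, meta_d, meta_c, cs1, cs2):
        return loglik_matrix(self.nmat, meta_d, meta_c, cs1, cs2)  # (C, S)

    def _init_state(self, data):
        C, S, km1 = self.C, self.S, self.k - 1
        logm0, cs1_0, cs2_0 = _init_from_mle(data, self.idx)
        r = self.rng
        self.mu = logm0.mean() + r.normal(0.0, 0.05, C)
        self.xi = r.uniform(0.3, 0.7, C)
        self.sig_delta = np.clip(logm0.std() + 0.05, 0.1, 2.0) / self.xi
        self.delta = (logm0[None, :] + r.normal(0.0, 0.05, (C, S)) - self.mu[:, None]) / self.xi[:, None]
        self.cs1 = np.tile(cs1_0, (C, 1, 1)) + r.normal(0.0, 0.02, (C, S, km1))
        self.cs2 = np.tile(cs2_0, (C, 1, 1)) + r.normal(0.0, 0.02, (C, S, km1))
        mirror = 0.5 * (cs2_0 - cs1_0[:, ::-1])
        self.mu_c2 = np.tile(mirror.mean(axis=0), (C, 1)) + r.normal(0.0, 0.02, (C, km1))
        self.sig_c2 = np.clip(mirror.std(axis=0), 0.1, 2.0) * np.ones((C, km1))
        _, meta_d, meta_c = self._derived(self.mu, self.xi, self.delta)
        _enforce_order(self.cs1, self.cs2, meta_c)
        self.ll = self._ll(meta_d, meta_c, self.cs1, self.cs2)
        # proposal scales
        self.a_delta = _Adaptive((C, S), 0.15)
        self.a_cs1 = _Adaptive((C, S, km1), 0.1)
        self.a_cs2 = _Adaptive((C, S, km1), 0.1)
        self.a_mu = _Adaptive((C,), 0.05)
        self.a_xi = _Adaptive((C,), 0.1)
        self.a_sd = _Adaptive((C,), 0.2)
        self.a_shift = _Adaptive((C,), 0.1)
        self.a_sigc2 = _Adaptive((C, km1), 0.1)
        self.a_blk1 = _Adaptive((C, S), 0.1)
        self.a_blk2 = _Adaptive((C, S), 0.1)
        self._adaptives = [
            self.a_delta, self.a_cs1, self.a_cs2, self.a_mu, self.a_xi,
            self.a_sd, self.a_shift, self.a_sigc2, self.a_blk1, self.a_blk2,
        ]

    # -- update blocks -----------------------------------------------------

    def _update_delta(self):
        r = self.rng
        prop = self.delta + self.a_delta.step * r.standard_normal((self.C, self.S))
        _, meta_d, meta_c = self._derived(self.mu, self.xi, prop)
        ok = (self.cs1[..., -1] <= meta_c) & (meta_c <= self.cs2[..., 0])
        ll_new = self._ll(meta_d, meta_c, self.cs1, self.cs2)
        sd = self.sig_delta[:, None]
        logr = ll_new - self.ll + _log_normal_pdf(prop, 0.0, sd) - _log_normal_pdf(self.delta, 0.0, sd)
        acc = ok & (np.log(r.random((self.C, self.S))) < logr)
        self.delta = np.where(acc, prop, self.delta)
        self.ll = np.where(acc, ll_new, self.ll)
        self.a_delta.tally(acc)

    def _update_criteria(self):
        r = self.rng
        _, meta_d, meta_c = self._derived(self.mu, self.xi, self.delta)
        km1 = self.k - 1
        for j in range(km1):  # cS1 coordinates, ascending block below meta_c
            cur = self.cs1[..., j]
            prop = cur + self.a_cs1.step[..., j] * r.standard_normal((self.C, self.S))
            lo, hi = _neighbor_bounds(self.cs1, j, -np.inf, meta_c)
            ok = (prop > lo) & (prop < hi)
            cand = self.cs1.copy()
            cand[..., j] = np.where(ok, prop, cur)
            ll_new = self._ll(meta_d, meta_c, cand, self.cs2)
            m, s = -self.mu_c2[:, None, km1 - 1 - j], self.sig_c2[:, None, km1 - 1 - j]
            logr = ll_new - self.ll + _log_normal_pdf(prop, m, s) - _log_normal_pdf(cur, m, s)
            acc = ok & (np.log(r.random((self.C, self.S))) < logr)
            self.cs1[..., j] = np.where(acc, prop, cur)
            self.ll = np.where(acc, ll_new, self.ll)
            self.a_cs1.acc[..., j] += acc
        for j in range(km1):  # cS2 coordinates, ascending block above meta_c
            cur = self.cs2[..., j]
            prop = cur + self.a_cs2.step[..., j] * r.standard_normal((self.C, self.S))
            lo, hi = _neighbor_bounds(self.cs2, j, meta_c, np.inf)
            ok = (prop > lo) & (prop < hi)
            cand = self.cs2.copy()
            cand[..., j] = np.where(ok, prop, cur)
            ll_new = self._ll(meta_d, meta_c, self.cs1, cand)
            m, s = self.mu_c2[:, None, j], self.sig_c2[:, None, j]
            logr = ll_new - self.ll + _log_normal_pdf(prop, m, s) - _log_normal_pdf(cur, m, s)
            acc = ok & (np.log(r.random((self.C, self.S))) < logr)
            self.cs2[..., j] = np.where(acc, prop, cur)
            self.ll = np.where(acc, ll_new, self.ll)
            self.a_cs2.acc[..., j] += acc
        self._update_criteria_blocks(meta_d, meta_c)

    def _update_criteria_blocks(self, meta_d, meta_c):
        """Shift each subject's whole cS1 (then cS2) block by a common offset;
        targets the strong within-block posterior correlation of the criteria."""
        r = self.rng
        for side in (0, 1):
            arr = self.cs1 if side == 0 else self.cs2
            step = (self.a_blk1 if side == 0 else self.a_blk2).step
            eps = step * r.standard_normal((self.C, self.S))
            cand = arr + eps[..., None]
            ok = (cand[..., -1] <= meta_c) if side == 0 else (cand[..., 0] >= meta_c)
            ll_new = (
                self._ll(meta_d, meta_c, cand, self.cs2)
                if side == 0
                else self._ll(meta_d, meta_c, self.cs1, cand)
            )
            if side == 0:
                m = -self.mu_c2[:, None, ::-1]
            else:
                m = self.mu_c2[:, None, :]
            s = self.sig_c2[:, None, ::-1] if side == 0 else self.sig_c2[:, None, :]
            dprior = (_log_normal_pdf(cand, m, s) - _log_normal_pdf(arr, m, s)).sum(axis=-1)
            logr = ll_new - self.ll + dprior
            acc = ok & (np.log(r.random((self.C, self.S))) < logr)
            if side == 0:
                self.cs1 = np.where(acc[..., None], cand, self.cs1)
                self.a_blk1.tally(acc)
            else:
                self.cs2 = np.where(acc[..., None], cand, self.cs2)
                self.a_blk2.tally(acc)
            self.ll = np.where(acc, ll_new, self.ll)

    def _update_group_scalar(self, name):
        """Random-walk update of mu_M or xi_M (likelihood touches all subjects)."""
        r = self.rng
        cur = self.mu if name == "mu" else self.xi
        step = (self.a_mu if name == "mu" else self.a_xi).step
        prop = cur + step * r.standard_normal(self.C)
        mu = prop if name == "mu" else self.mu
        xi = prop if name == "xi" else self.xi
        _, meta_d, meta_c = self._derived(mu, xi, self.delta)
        ok_ord = ((self.cs1[..., -1] <= meta_c) & (meta_c <= self.cs2[..., 0])).all(axis=1)
        ll_new = self._ll(meta_d, meta_c, self.cs1, self.cs2)
        if name == "mu":
            prior = _log_normal_pdf(prop, 0.0, self.spec.mu_M_prior_sd) - _log_normal_pdf(
                cur, 0.0, self.spec.mu_M_prior_sd
            )
            ok = ok_ord
        else:
            prior = np.zeros(self.C)  # Beta(1,1): flat on (0,1)
            ok = ok_ord & (prop > 0.0) & (prop < 1.0)
        logr = ll_new.sum(axis=1) - self.ll.sum(axis=1) + prior
        acc = ok & (np.log(r.random(self.C)) < logr)
        new = np.where(acc, prop, cur)
        if name == "mu":
            self.mu = new
            self.a_mu.tally(acc)
        else:
            self.xi = new
            self.a_xi.tally(acc)
        self.ll = np.where(acc[:, None], ll_new, self.ll)

    def _update_shift(self):
        """Translate mu_M against delta at fixed log M (likelihood-invariant)."""
        r = self.rng
        eps = self.a_shift.step * r.standard_normal(self.C)
        mu_p = self.mu + eps
        delta_p = self.delta - (eps / self.xi)[:, None]
        sd = self.sig_delta[:, None]
        logr = (
            _log_normal_pdf(mu_p, 0.0, self.spec.mu_M_prior_sd)
            - _log_normal_pdf(self.mu, 0.0, self.spec.mu_M_prior_sd)
            + (_log_normal_pdf(delta_p, 0.0, sd) - _log_normal_pdf(self.delta, 0.0, sd)).sum(axis=1)
        )
        acc = np.log(r.random(self.C)) < logr
        self.mu = np.where(acc, mu_p, self.mu)
        self.delta = np.where(acc[:, None], delta_p, self.delta)
        self.a_shift.tally(acc)

    def _update_sigma_delta(self):
        r = self.rng
        prop = self.sig_delta + self.a_sd.step * r.standard_normal(self.C)
        ok = prop > 0
        safe = np.where(ok, prop, 1.0)
        logr = (
            _log_half_normal(safe, self.spec.sigma_delta_prior_sd)
            - _log_half_normal(self.sig_delta, self.spec.sigma_delta_prior_sd)
            + (
                _log_normal_pdf(self.delta, 0.0, safe[:, None])
                - _log_normal_pdf(self.delta, 0.0, self.sig_delta[:, None])
            ).sum(axis=1)
        )
        acc = ok & (np.log(r.random(self.C)) < logr)
        self.sig_delta = np.where(acc, prop, self.sig_delta)
        self.a_sd.tally(acc)

    def _update_criteria_hyper(self):
        r = self.rng
        km1 = self.k - 1
        cs1m = self.cs1[..., ::-1]  # mirror-aligned with mu_c2 index
        # mu_c2: conditionally conjugate given criteria (Gibbs draw); each of
        # the 2S mirrored criteria is a Normal(mu_c2_j, sigma_c2_j) observation
        obs_sum = (self.cs2 - cs1m).sum(axis=1)  # (C, km1)
        prec = 1.0 / self.spec.mu_c2_prior_sd**2 + 2.0 * self.S / self.sig_c2**2
        mean = (obs_sum / self.sig_c2**2) / prec
        self.mu_c2 = mean + r.standard_normal((self.C, km1)) / np.sqrt(prec)
        # sigma_c2
        prop = self.sig_c2 + self.a_sigc2.step * r.standard_normal((self.C, km1))
        ok = prop > 0
        safe = np.where(ok, prop, 1.0)
        d_prior = _log_half_normal(safe, self.spec.sigma_c2_prior_sd) - _log_half_normal(
            self.sig_c2, self.spec.sigma_c2_prior_sd
        )
        m1, m2 = -self.mu_c2[:, None, :], self.mu_c2[:, None, :]
        d_sub = (
            _log_normal_pdf(cs1m, m1, safe[:, None, :])
            - _log_normal_pdf(cs1m, m1, self.sig_c2[:, None, :])
            + _log_normal_pdf(self.cs2, m2, safe[:, None, :])
            - _log_normal_pdf(self.cs2, m2, self.sig_c2[:, None, :])
        ).sum(axis=1)
        acc = ok & (np.log(r.random((self.C, km1))) < d_prior + d_sub)
        self.sig_c2 = np.where(acc, prop, self.sig_c2)
        self.a_sigc2.tally(acc)

    def _iterate(self):
        self._update_delta()
        self._update_criteria()
        self._update_group_scalar("mu")
        self._update_group_scalar("xi")
        self._update_shift()
        self._update_sigma_delta()
        self._update_criteria_hyper()

    # -- driver ------------------------------------------------------------

    def run(self) -> HierPosterior:
        spec = self.spec
        C, S, km1, N = self.C, self.S, self.k - 1, spec.n_samples
        with np.errstate(invalid="ignore"):
            return self._run(C, S, km1, N)

    def _run(self, C, S, km1, N) -> HierPosterior:
        spec = self.spec
        for it in range(spec.n_burnin):
            self._iterate()
            if (it + 1) % _ADAPT_WINDOW == 0:
                for a in self._adaptives:
                    a.adapt()
        store = {
            "mu_logMratio": np.empty((C, N)),
            "xi": np.empty((C, N)),
            "sigma_delta": np.empty((C, N)),
            "sigma_logMratio": np.empty((C, N)),
            "delta": np.empty((C, N, S)),
            "logMratio": np.empty((C, N, S)),
            "cS1": np.empty((C, N, S, km1)),
            "cS2": np.empty((C, N, S, km1)),
            "mu_c2": np.empty((C, N, km1)),
            "sigma_c2": np.empty((C, N, km1)),
            "deviance": np.empty((C, N)),
        }
        for it in range(N):
            self._iterate()
            store["mu_logMratio"][:, it] = self.mu
            store["xi"][:, it] = self.xi
            store["sigma_delta"][:, it] = self.sig_delta
            store["sigma_logMratio"][:, it] = np.abs(self.xi) * self.sig_delta
            store["delta"][:, it] = self.delta
            store["logMratio"][:, it] = self.mu[:, None] + self.xi[:, None] * self.delta
            store["cS1"][:, it] = self.cs1
            store["cS2"][:, it] = self.cs2
            store["mu_c2"][:, it] = self.mu_c2
            store["sigma_c2"][:, it] = self.sig_c2
            store["deviance"][:, it] = -2.0 * self.ll.sum(axis=1)
        # DIC at the posterior mean of the continuous parameters
        logm_bar = store["logMratio"].mean(axis=(0, 1))
        cs1_bar = store["cS1"].mean(axis=(0, 1))
        cs2_bar = store["cS2"].mean(axis=(0, 1))
        meta_d = np.exp(logm_bar) * self.d
        meta_c = np.exp(logm_bar) * self.c
        _enforce_order(cs1_bar, cs2_bar, meta_c)
        d_hat = -2.0 * float(
            loglik_matrix(self.nmat, meta_d, meta_c, cs1_bar, cs2_bar).sum()
        )
        dic_val = dic(store["deviance"], d_hat)
        rh = _rhat_dict(store, skip=("delta", "deviance"))
        _warn_rhat(rh)
        return HierPosterior(
            samples=store,
            rhat=rh,
            dic=dic_val,
            d_prime=self.d,
            c=self.c,
            subjects_used=self.idx,
        )


def _rhat_dict(store, skip=()):
    out = {}
    for name, x in store.items():
        if name in skip:
            continue
        flat = x.reshape(x.shape[0], x.shape[1], -1)
        out[name] = np.array(
            [rhat(flat[:, :, i]) for i in range(flat.shape[2])]
        ).reshape(x.shape[2:] or (1,))
    return out


#: parameters that are individually non-identified under parameter expansion
#: (only |xi| * sigma_delta is meaningful); excluded from convergence warnings
_EXPANSION_ONLY = {"xi", "sigma_delta", "delta"}


def _warn_rhat(rh):
    bad = {
        k: float(np.max(v))
        for k, v in rh.items()
        if k not in _EXPANSION_ONLY and np.any(np.asarray(v) >= 1.1)
    }
    if bad:
        logger.warning("possible non-convergence: R-hat >= 1.1 for %s", bad)


def fit_group(data: list[ConfidenceCounts], spec: HierModelSpec | None = None) -> HierPosterior:
    """Fit the hierarchical metacognitive-efficiency model to a group.

    Each subject contributes a :class:`ConfidenceCounts`; no edge
    correction is applied to the confidence counts (the multinomial
    likelihood handles empty cells).  Returns per-chain samples of the
    group mean ``mu_logMratio`` (efficiency is ``exp`` of it), the
    recovered hierarchical SD, subject-level efficiencies and criteria,
    R-hat per parameter, and the DIC.
    """
    spec = spec or HierModelSpec()
    if len(data) < 2:
        raise ValueError("need at least 2 subjects for a group fit")
    ks = {d.k for d in data}
    if len(ks) != 1:
        raise ValueError("all subjects must share the same number of rating levels")
    return _GroupSampler(data, spec).run()


# ---------------------------------------------------------------------------
# bivariate (two-task correlation) extension


class _CorrSampler:
    """Joint model of two tasks with bivariate-Gaussian subject efficiencies.

    (log M1_s, log M2_s) ~ BVN((mu_M1, mu_M2), [[s1^2, r s1 s2], [r s1 s2, s2^2]])
    with mu_Mt ~ Normal(0,1), sigma_Mt ~ InvSqrtGamma(0.001, 0.001) and
    rho ~ Uniform(-1, 1); no parameter expansion.  Criteria are modelled per
    task exactly as in the single-group model.
    """

    IG_A = 0.001
    IG_B = 0.001

    def __init__(self, data1, data2, spec: HierModelSpec):
        if len(data1) != len(data2):
            raise ValueError("both tasks must contain the same subjects")
        if len(data1) < 5:
            raise ValueError("need at least 5 subjects for the correlation model")
        self.spec = spec
        d1, c1, i1 = _prepare_subjects(data1)
        d2, c2, i2 = _prepare_subjects(data2)
        common = np.intersect1d(i1, i2)
        if common.size < 5:
            raise ValueError("fewer than 5 subjects usable in both tasks")
        sel1 = np.searchsorted(i1, common)
        sel2 = np.searchsorted(i2, common)
        self.idx = common
        self.d = np.stack([d1[sel1], d2[sel2]])  # (2, S)
        self.c_task = np.stack([c1[sel1], c2[sel2]])
        self.k = data1[0].k
        self.nmat = np.stack(
            [
                np.stack([data1[i].as_matrix() for i in common]),
                np.stack([data2[i].as_matrix() for i in common]),
            ]
        )  # (2, S, 2, 2k)
        self.S = common.size
        self.C = spec.n_chains
        self.rng = np.random.default_rng([spec.seed, 3_000_017])
        self._init_state(data1, data2)

    def _meta(self, t, logm_t):
        m = np.exp(logm_t)
        return m * self.d[t], m * self.c_task[t]

    def _ll_task(self, t, logm_t, cs1, cs2):
        meta_d, meta_c = self._meta(t, logm_t)
        return loglik_matrix(self.nmat[t], meta_d, meta_c, cs1, cs2)

    def _bvn_logpdf(self, x1, x2, mu1, mu2, s1, s2, rho):
        z1 = (x1 - mu1[:, None]) / s1[:, None]
        z2 = (x2 - mu2[:, None]) / s2[:, None]
        r = rho[:, None]
        q = (z1 * z1 - 2.0 * r * z1 * z2 + z2 * z2) / (1.0 - r * r)
        return (
            -0.5 * q
            - np.log(2.0 * np.pi * s1[:, None] * s2[:, None] * np.sqrt(1.0 - r * r))
        )

    def _prior_pairs(self):
        return self._bvn_logpdf(
            self.logm[..., 0], self.logm[..., 1],
            self.mu[:, 0], self.mu[:, 1], self.sig[:, 0], self.sig[:, 1], self.rho,
        )  # (C, S)

    def _init_state(self, data1, data2):
        C, S, km1 = self.C, self.S, self.k - 1
        r = self.rng
        logm0 = np.empty((S, 2))
        cs1_0 = np.empty((2, S, km1))
        cs2_0 = np.empty((2, S, km1))
        for t, data in enumerate((data1, data2)):
            lm, a, b = _init_from_mle(data, self.idx)
            logm0[:, t] = lm
            cs1_0[t], cs2_0[t] = a, b
        self.mu = logm0.mean(axis=0)[None, :] + r.normal(0.0, 0.05, (C, 2))
        self.sig = np.clip(logm0.std(axis=0), 0.1, 2.0)[None, :] * np.exp(
            r.normal(0.0, 0.05, (C, 2))
        )
        rho0 = np.clip(np.corrcoef(logm0[:, 0], logm0[:, 1])[0, 1], -0.8, 0.8)
        self.rho = np.clip(rho0 + r.normal(0.0, 0.05, C), -0.95, 0.95)
        self.logm = np.tile(logm0, (C, 1, 1)) + r.normal(0.0, 0.05, (C, S, 2))
        self.cs1 = np.tile(cs1_0[:, None], (1, C, 1, 1)) + r.normal(0.0, 0.02, (2, C, S, km1))
        self.cs2 = np.tile(cs2_0[:, None], (1, C, 1, 1)) + r.normal(0.0, 0.02, (2, C, S, km1))
        mirror = 0.5 * (cs2_0 - cs1_0[..., ::-1])  # (2, S, km1)
        self.mu_c2 = np.tile(mirror.mean(axis=1)[:, None], (1, C, 1)) + r.normal(
            0.0, 0.02, (2, C, km1)
        )
        self.sig_c2 = np.tile(
            np.clip(mirror.std(axis=1), 0.1, 2.0)[:, None], (1, C, 1)
        )
        self.ll = np.empty((2, C, S))
        for t in range(2):
            _, meta_c = self._meta(t, self.logm[..., t])
            _enforce_order(self.cs1[t], self.cs2[t], meta_c)
            self.ll[t] = self._ll_task(t, self.logm[..., t], self.cs1[t], self.cs2[t])
        self.a_logm = _Adaptive((2, C, S), 0.15)
        self.a_cs1 = _Adaptive((2, C, S, km1), 0.1)
        self.a_cs2 = _Adaptive((2, C, S, km1), 0.1)
        self.a_mu = _Adaptive((C, 2), 0.1)
        self.a_sig = _Adaptive((C, 2), 0.1)
        self.a_rho = _Adaptive((C,), 0.1)
        self.a_blk1 = _Adaptive((2, C, S), 0.1)
        self.a_blk2 = _Adaptive((2, C, S), 0.1)
        self._adaptives = [
            self.a_logm, self.a_cs1, self.a_cs2, self.a_mu, self.a_sig, self.a_rho,
            self.a_blk1, self.a_blk2,
        ]

    def _update_logm(self):
        r = self.rng
        for t in range(2):
            cur = self.logm[..., t]
            prop = cur + self.a_logm.step[t] * r.standard_normal((self.C, self.S))
            meta_d, meta_c = self._meta(t, prop)
            ok = (self.cs1[t][..., -1] <= meta_c) & (meta_c <= self.cs2[t][..., 0])
            ll_new = loglik_matrix(self.nmat[t], meta_d, meta_c, self.cs1[t], self.cs2[t])
            prior_cur = self._prior_pairs()
            saved = cur.copy()
            self.logm[..., t] = prop
            prior_new = self._prior_pairs()
            self.logm[..., t] = saved
            logr = ll_new - self.ll[t] + prior_new - prior_cur
            acc = ok & (np.log(r.random((self.C, self.S))) < logr)
            self.logm[..., t] = np.where(acc, prop, cur)
            self.ll[t] = np.where(acc, ll_new, self.ll[t])
            self.a_logm.acc[t] += acc

    def _update_criteria(self):
        r = self.rng
        km1 = self.k - 1
        for t in range(2):
            _, meta_c = self._meta(t, self.logm[..., t])
            for j in range(km1):
                cur = self.cs1[t][..., j]
                prop = cur + self.a_cs1.step[t][..., j] * r.standard_normal((self.C, self.S))
                lo, hi = _neighbor_bounds(self.cs1[t], j, -np.inf, meta_c)
                ok = (prop > lo) & (prop < hi)
                cand = self.cs1[t].copy()
                cand[..., j] = np.where(ok, prop, cur)
                ll_new = self._ll_task(t, self.logm[..., t], cand, self.cs2[t])
                m = -self.mu_c2[t][:, None, km1 - 1 - j]
                s = self.sig_c2[t][:, None, km1 - 1 - j]
                logr = ll_new - self.ll[t] + _log_normal_pdf(prop, m, s) - _log_normal_pdf(cur, m, s)
                acc = ok & (np.log(r.random((self.C, self.S))) < logr)
                self.cs1[t][..., j] = np.where(acc, prop, cur)
                self.ll[t] = np.where(acc, ll_new, self.ll[t])
                self.a_cs1.acc[t][..., j] += acc
            for j in range(km1):
                cur = self.cs2[t][..., j]
                prop = cur + self.a_cs2.step[t][..., j] * r.standard_normal((self.C, self.S))
                lo, hi = _neighbor_bounds(self.cs2[t], j, meta_c, np.inf)
                ok = (prop > lo) & (prop < hi)
                cand = self.cs2[t].copy()
                cand[..., j] = np.where(ok, prop, cur)
                ll_new = self._ll_task(t, self.logm[..., t], self.cs1[t], cand)
                m = self.mu_c2[t][:, None, j]
                s = self.sig_c2[t][:, None, j]
                logr = ll_new - self.ll[t] + _log_normal_pdf(prop, m, s) - _log_normal_pdf(cur, m, s)
                acc = ok & (np.log(r.random((self.C, self.S))) < logr)
                self.cs2[t][..., j] = np.where(acc, prop, cur)
                self.ll[t] = np.where(acc, ll_new, self.ll[t])
                self.a_cs2.acc[t][..., j] += acc
            self._update_criteria_blocks(t, meta_c)

    def _update_criteria_blocks(self, t, meta_c):
        """Common-offset shifts of each subject's criteria blocks (per task)."""
        r = self.rng
        for side in (0, 1):
            arr = self.cs1[t] if side == 0 else self.cs2[t]
            step = (self.a_blk1 if side == 0 else self.a_blk2).step[t]
            eps = step * r.standard_normal((self.C, self.S))
            cand = arr + eps[..., None]
            ok = (cand[..., -1] <= meta_c) if side == 0 else (cand[..., 0] >= meta_c)
            ll_new = (
                self._ll_task(t, self.logm[..., t], cand, self.cs2[t])
                if side == 0
                else self._ll_task(t, self.logm[..., t], self.cs1[t], cand)
            )
            m = -self.mu_c2[t][:, None, ::-1] if side == 0 else self.mu_c2[t][:, None, :]
            s = self.sig_c2[t][:, None, ::-1] if side == 0 else self.sig_c2[t][:, None, :]
            dprior = (_log_normal_pdf(cand, m, s) - _log_normal_pdf(arr, m, s)).sum(axis=-1)
            logr = ll_new - self.ll[t] + dprior
            acc = ok & (np.log(r.random((self.C, self.S))) < logr)
            if side == 0:
                self.cs1[t] = np.where(acc[..., None], cand, self.cs1[t])
                self.a_blk1.acc[t] += acc
            else:
                self.cs2[t] = np.where(acc[..., None], cand, self.cs2[t])
                self.a_blk2.acc[t] += acc
            self.ll[t] = np.where(acc, ll_new, self.ll[t])

    def _update_group(self):
        r = self.rng
        # group means (prior-only: likelihood unaffected)
        for t in range(2):
            prop = self.mu[:, t] + self.a_mu.step[:, t] * r.standard_normal(self.C)
            prior_cur = self._prior_pairs().sum(axis=1)
            saved = self.mu[:, t].copy()
            self.mu[:, t] = prop
            prior_new = self._prior_pairs().sum(axis=1)
            self.mu[:, t] = saved
            logr = (
                prior_new
                - prior_cur
                + _log_normal_pdf(prop, 0.0, 1.0)
                - _log_normal_pdf(saved, 0.0, 1.0)
            )
            acc = np.log(r.random(self.C)) < logr
            self.mu[:, t] = np.where(acc, prop, saved)
            self.a_mu.acc[:, t] += acc
        # group SDs, sigma = 1/sqrt(tau), tau ~ Gamma(a, b)
        for t in range(2):
            prop = self.sig[:, t] + self.a_sig.step[:, t] * r.standard_normal(self.C)
            ok = prop > 0
            safe = np.where(ok, prop, 1.0)
            prior_cur = self._prior_pairs().sum(axis=1)
            saved = self.sig[:, t].copy()
            self.sig[:, t] = safe
            prior_new = self._prior_pairs().sum(axis=1)
            self.sig[:, t] = saved

            def lp(s):
                return (2.0 * self.IG_A + 1.0) * np.log(s) * -1.0 - self.IG_B / (s * s)

            logr = prior_new - prior_cur + lp(safe) - lp(saved)
            acc = ok & (np.log(r.random(self.C)) < logr)
            self.sig[:, t] = np.where(acc, prop, saved)
            self.a_sig.acc[:, t] += acc
        # correlation, flat prior on (-1, 1)
        prop = self.rho + self.a_rho.step * r.standard_normal(self.C)
        ok = np.abs(prop) < 1.0
        safe = np.where(ok, prop, 0.0)
        prior_cur = self._prior_pairs().sum(axis=1)
        saved = self.rho.copy()
        self.rho = safe
        prior_new = self._prior_pairs().sum(axis=1)
        self.rho = saved
        acc = ok & (np.log(r.random(self.C)) < prior_new - prior_cur)
        self.rho = np.where(acc, prop, saved)
        self.a_rho.tally(acc)

    def _update_criteria_hyper(self):
        r = self.rng
        km1 = self.k - 1
        for t in range(2):
            cs1m = self.cs1[t][..., ::-1]
            obs_sum = (self.cs2[t] - cs1m).sum(axis=1)
            prec = 1.0 / self.spec.mu_c2_prior_sd**2 + 2.0 * self.S / self.sig_c2[t] ** 2
            mean = (obs_sum / self.sig_c2[t] ** 2) / prec
            self.mu_c2[t] = mean + r.standard_normal((self.C, km1)) / np.sqrt(prec)
            prop = self.sig_c2[t] + 0.1 * r.standard_normal((self.C, km1))
            ok = prop > 0
            safe = np.where(ok, prop, 1.0)
            d_prior = _log_half_normal(safe, self.spec.sigma_c2_prior_sd) - _log_half_normal(
                self.sig_c2[t], self.spec.sigma_c2_prior_sd
            )
            m1, m2 = -self.mu_c2[t][:, None, :], self.mu_c2[t][:, None, :]
            d_sub = (
                _log_normal_pdf(cs1m, m1, safe[:, None, :])
                - _log_normal_pdf(cs1m, m1, self.sig_c2[t][:, None, :])
                + _log_normal_pdf(self.cs2[t], m2, safe[:, None, :])
                - _log_normal_pdf(self.cs2[t], m2, self.sig_c2[t][:, None, :])
            ).sum(axis=1)
            acc = ok & (np.log(r.random((self.C, km1))) < d_prior + d_sub)
            self.sig_c2[t] = np.where(acc, prop, self.sig_c2[t])

    def _iterate(self):
        self._update_logm()
        self._update_criteria()
        self._update_group()
        self._update_criteria_hyper()

    def run(self) -> HierPosterior:
        spec = self.spec
        C, S, N = self.C, self.S, spec.n_samples
        with np.errstate(invalid="ignore"):
            return self._run(C, S, N)

    def _run(self, C, S, N) -> HierPosterior:
        spec = self.spec
        for it in range(spec.n_burnin):
            self._iterate()
            if (it + 1) % _ADAPT_WINDOW == 0:
                for a in self._adaptives:
                    a.adapt()
        store = {
            "rho": np.empty((C, N)),
            "mu_logMratio_1": np.empty((C, N)),
            "mu_logMratio_2": np.empty((C, N)),
            "sigma_logMratio_1": np.empty((C, N)),
            "sigma_logMratio_2": np.empty((C, N)),
            "logMratio": np.empty((C, N, S, 2)),
            "deviance": np.empty((C, N)),
        }
        for it in range(N):
            self._iterate()
            store["rho"][:, it] = self.rho
            store["mu_logMratio_1"][:, it] = self.mu[:, 0]
            store["mu_logMratio_2"][:, it] = self.mu[:, 1]
            store["sigma_logMratio_1"][:, it] = self.sig[:, 0]
            store["sigma_logMratio_2"][:, it] = self.sig[:, 1]
            store["logMratio"][:, it] = self.logm
            store["deviance"][:, it] = -2.0 * self.ll.sum(axis=(0, 2))
        logm_bar = store["logMratio"].mean(axis=(0, 1))  # (S, 2)
        d_hat = 0.0
        for t in range(2):
            meta_d, meta_c = self._meta(t, logm_bar[:, t])
            cs1_bar = self.cs1[t].mean(axis=0)
            cs2_bar = self.cs2[t].mean(axis=0)
            _enforce_order(cs1_bar, cs2_bar, meta_c)
            d_hat += -2.0 * float(
                loglik_matrix(self.nmat[t], meta_d, meta_c, cs1_bar, cs2_bar).sum()
            )
        rh = _rhat_dict(store, skip=("logMratio", "deviance"))
        _warn_rhat(rh)
        return HierPosterior(
            samples=store,
            rhat=rh,
            dic=dic(store["deviance"], d_hat),
            d_prime=self.d,
            c=self.c_task,
            subjects_used=self.idx,
        )


def fit_group_correlation(
    dataTask1: list[ConfidenceCounts],
    dataTask2: list[ConfidenceCounts],
    spec: HierModelSpec | None = None,
) -> HierPosterior:
    """Joint two-task fit returning the posterior of the cross-task
    correlation ``rho`` between subject log efficiencies, along with each
    task's group mean and SD.  Subjects must be matched across tasks."""
    spec = spec or HierModelSpec()
    return _CorrSampler(dataTask1, dataTask2, spec).run()
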