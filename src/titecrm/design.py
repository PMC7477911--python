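"""Dose-toxicity model underlying the TiTE-CRM.

The continual reassessment method (CRM) models the probability of a
dose-limiting toxicity (DLT) at dose level ``k`` with the one-parameter
empiric ("power") curve

    F(d_k, beta) = d_k ** exp(beta),

where the dose labels ``d_1 < ... < d_K`` are calibrated so that, at the
prior mean of ``beta``, the fitted probabilities equal the clinician-supplied
skeleton of prior DLT probability guesses.  The time-to-event extension
(TiTE-CRM) multiplies each not-yet-toxic participant's contribution by a
follow-up weight ``w in [0, 1]``, so partially followed participants inform
the curve in proportion to their observed time at risk.

This module is purely computational: calibration, the weighted likelihood,
posterior summaries of ``beta`` under a normal prior (via adaptive
quadrature), plug-in toxicity estimates and selection of the maximum
tolerated dose (MTD).  Trial-conduct rules live in :mod:`titecrm.conduct`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "DesignSpec",
    "ParticipantSnapshot",
    "PosteriorSummary",
    "MtdSelection",
    "Posterior",
    "compute_dose_labels",
    "dose_toxicity_f",
    "weighted_likelihood",
    "posterior_mean",
    "posterior_interval",
    "prob_toxicity_exceeds",
    "plug_in_probs",
    "select_mtd",
    "posterior_summary",
]

#: Default prior standard deviation for beta, a conventional choice for the
#: empiric one-parameter CRM model; override in DesignSpec as needed.
DEFAULT_PRIOR_SD = 1.34

_MTD_RULES = ("highest_below", "closest")


def _validate_skeleton(skeleton: Sequence[float]) -> np.ndarray:
    sk = np.asarray(skeleton, dtype=float)
    if sk.ndim != 1 or sk.size == 0:
        raise ValueError("skeleton must be a non-empty 1-d sequence of probabilities")
    for i, p in enumerate(sk):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"skeleton[{i}] = {p} is outside the open interval (0, 1)"
            )
    for i in range(1, sk.size):
        if sk[i] <= sk[i - 1]:
            raise ValueError(
                f"skeleton must be strictly increasing; skeleton[{i}] = "
                f"{sk[i]} does not exceed skeleton[{i - 1}] = {sk[i - 1]}"
            )
    return sk


@dataclass(frozen=True)
class DesignSpec:
    """Statistical design of a TiTE-CRM trial.

    Parameters
    ----------
    skeleton
        Prior DLT probability at each dose, strictly increasing, each in
        (0, 1).  Its length fixes the number of dose levels ``K``.
    ttl
        Target toxicity level: the acceptable DLT probability.
    dlt_window
        Length ``T`` of the DLT observation window, in days.
    n_max
        Maximum number of participants.
    prior_mean, prior_sd
        Normal prior ``beta ~ N(prior_mean, prior_sd**2)``.
    mtd_rule
        ``"highest_below"`` — highest dose with estimated DLT probability
        below the TTL; ``"closest"`` — dose with estimate closest to the TTL
        (ties broken to the lower dose).
    starting_dose_index
        1-based dose level given to the initial cohort.
    """

    skeleton: tuple[float, ...]
    ttl: float
    dlt_window: float
    n_max: int
    prior_mean: float = 0.0
    prior_sd: float = DEFAULT_PRIOR_SD
    mtd_rule: str = "highest_below"
    starting_dose_index: int = 1

    def __post_init__(self) -> None:
        sk = _validate_skeleton(self.skeleton)
        object.__setattr__(self, "skeleton", tuple(float(p) for p in sk))
        if not 0.0 < self.ttl < 1.0:
            raise ValueError(f"ttl = {self.ttl} must lie in (0, 1)")
        if self.dlt_window <= 0:
            raise ValueError(f"dlt_window = {self.dlt_window} must be positive")
        if self.n_max < 1:
            raise ValueError(f"n_max = {self.n_max} must be a positive integer")
        if self.prior_sd <= 0:
            raise ValueError(f"prior_sd = {self.prior_sd} must be positive")
        if self.mtd_rule not in _MTD_RULES:
            raise ValueError(
                f"mtd_rule = {self.mtd_rule!r}; expected one of {_MTD_RULES}"
            )
        if not 1 <= self.starting_dose_index <= self.n_doses:
            raise ValueError(
                f"starting_dose_index = {self.starting_dose_index} outside "
                f"1..{self.n_doses}"
            )

    @property
    def n_doses(self) -> int:
        return len(self.skeleton)

    def dose_labels(self) -> np.ndarray:
        """Calibrated dose labels (see :func:`compute_dose_labels`)."""
        return compute_dose_labels(self.skeleton, self.prior_mean)


@dataclass(frozen=True)
class ParticipantSnapshot:
    """One participant's contribution to the model at a decision time.

    ``tox`` is the DLT indicator within the observation window; ``weight``
    is the likelihood weight (1 whenever ``tox`` is 1, otherwise a function
    of follow-up).  ``dose_label`` is the calibrated label, not the clinical
    dose.
    """

    participant_id: str
    dose_index: int
    dose_label: float
    tox: int
    followup: float
    weight: float

    def __post_init__(self) -> None:
        if self.tox not in (0, 1):
            raise ValueError(f"tox must be 0 or 1, got {self.tox}")
        if not 0.0 < self.dose_label < 1.0:
            raise ValueError(
                f"dose_label = {self.dose_label} outside (0, 1) "
                f"for participant {self.participant_id!r}"
            )
        if self.followup < 0:
            raise ValueError(
                f"negative follow-up for participant {self.participant_id!r}"
            )
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(
                f"weight = {self.weight} outside [0, 1] "
                f"for participant {self.participant_id!r}"
            )
        if self.tox == 1 and self.weight != 1.0:
            raise ValueError(
                f"participant {self.participant_id!r} has a DLT but weight "
                f"{self.weight} != 1; a DLT always contributes full weight"
            )


class MtdSelection(NamedTuple):
    """Result of MTD selection: 1-based dose index plus a flag set when every
    estimated DLT probability is at or above the target."""

    index: int
    all_above_target: bool


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean of beta, optional equal-tailed credible interval
    ``(level, lower, upper)``, plug-in DLT probabilities per dose, and the
    selected MTD."""

    beta_hat: float
    beta_interval: Optional[tuple[float, float, float]]
    pi_hat: np.ndarray
    mtd_index: int
    all_above_target: bool = False


def compute_dose_labels(
    skeleton: Sequence[float], prior_mean: float = 0.0
) -> np.ndarray:
    """Calibrate dose labels so the prior-mean model reproduces the skeleton.

    Solving ``F(d_k, prior_mean) = pi_0k`` for the power curve gives
    ``d_k = pi_0k ** (1 / exp(prior_mean))``, so at trial start the model
    fits the prior DLT probability guesses exactly.
    """
    sk = _validate_skeleton(skeleton)
    return sk ** (1.0 / math.exp(prior_mean))


def dose_toxicity_f(dose_label, beta: float):
    """Power-model DLT probability ``dose_label ** exp(beta)``.

    Accepts a scalar or array of dose labels, each required to lie strictly
    inside (0, 1) so the curve is a proper probability for every beta.
    """
    d = np.asarray(dose_label, dtype=float)
    if np.any(d <= 0.0) or np.any(d >= 1.0):
        raise ValueError(f"dose label(s) {dose_label!r} outside the open interval (0, 1)")
    out = d ** math.exp(beta)
    return float(out) if np.isscalar(dose_label) else out


def _snapshot_arrays(
    snapshots: Iterable[ParticipantSnapshot],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    snaps = list(snapshots)
    x = np.array([s.dose_label for s in snaps], dtype=float)
    y = np.array([s.tox for s in snaps], dtype=float)
    w = np.array([s.weight for s in snaps], dtype=float)
    return x, y, w


def weighted_likelihood(
    snapshots: Sequence[ParticipantSnapshot], beta: float
) -> float:
    """TiTE-CRM weighted likelihood at ``beta``.

    ``prod_j [F(x_j, beta) * w_j]**y_j * [1 - F(x_j, beta) * w_j]**(1 - y_j)``.
    With every weight equal to 1 this is exactly the standard CRM binomial
    likelihood.  An empty snapshot list yields 1.
    """
    x, y, w = _snapshot_arrays(snapshots)
    if x.size == 0:
        return 1.0
    p = (x ** math.exp(beta)) * w
    if np.any(p < 0.0) or np.any(p > 1.0):  # impossible under the invariants
        raise RuntimeError("weighted toxicity probability escaped [0, 1]")
    return float(np.prod(np.where(y == 1.0, p, 1.0 - p)))


# ---------------------------------------------------------------------------
# Posterior computation.
#
# The unnormalized log-posterior is evaluated in the log domain and shifted
# by its maximum over a coarse grid before exponentiation, so the adaptive
# quadrature operates on an O(1) integrand even for ~100 participants (whose
# raw likelihood underflows double precision).  The shift cancels in every
# reported ratio.

_QUAD_SIGMAS = 10.0  # integration bounds: prior_mean +/- 10 prior sd
_QUAD_EPSABS = 1e-10
_TINY = 1e-300  # log-domain underflow guard only; never alters results at tolerance


def _log_posterior_factory(snapshots, prior_mean, prior_sd):
    x, y, w = _snapshot_arrays(snapshots)

    def log_post(beta):
        scalar = np.ndim(beta) == 0
        b = np.atleast_1d(np.asarray(beta, dtype=float))
        lp = -0.5 * ((b - prior_mean) / prior_sd) ** 2
        if x.size:
            p = (x[None, :] ** np.exp(b)[:, None]) * w[None, :]
            p = np.clip(p, _TINY, 1.0 - 1e-16)
            lp = lp + (y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum(axis=-1)
        return float(lp[0]) if scalar else lp

    return log_post


class Posterior:
    """Quadrature workspace for the posterior of beta given snapshots.

    Evaluates the unnormalized posterior shifted by its coarse-grid maximum,
    then answers mean/CDF/quantile queries by adaptive quadrature over
    ``prior_mean +/- 10 prior_sd``.  Building one workspace and querying it
    repeatedly (as the decision engine does) avoids recomputing the
    normalizing constant.
    """

    def __init__(self, snapshots, prior_mean: float = 0.0,
                 prior_sd: float = DEFAULT_PRIOR_SD):
        if prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        self.prior_mean = float(prior_mean)
        self.prior_sd = float(prior_sd)
        log_post = _log_posterior_factory(snapshots, prior_mean, prior_sd)
        self._a = prior_mean - _QUAD_SIGMAS * prior_sd
        self._b = prior_mean + _QUAD_SIGMAS * prior_sd
        grid = np.linspace(self._a, self._b, 401)
        lg = log_post(grid)
        self._shift = float(np.max(lg))
        self._peak = float(grid[int(np.argmax(lg))])
        self._log_post = log_post
        self._g = lambda beta: math.exp(log_post(float(beta)) - self._shift)
        self._z: Optional[float] = None
        self._mean: Optional[float] = None

    def _quad(self, lo: float, hi: float, fn=None) -> float:
        fn = fn if fn is not None else self._g
        pts = [self._peak] if lo < self._peak < hi else None
        val, _ = integrate.quad(fn, lo, hi, epsabs=_QUAD_EPSABS, epsrel=1e-10,
                                limit=200, points=pts)
        return val

    @property
    def normalizer(self) -> float:
        if self._z is None:
            z = self._quad(self._a, self._b)
            if not np.isfinite(z) or z <= 1e-250:
                raise RuntimeError(
                    "posterior normalizing constant vanished numerically; "
                    "the posterior mass may lie outside prior_mean +/- 10 "
                    "prior_sd — widen the integration bounds (check prior_sd "
                    "and the data)"
                )
            self._z = z
        return self._z

    def mean(self) -> float:
        if self._mean is None:
            num = self._quad(self._a, self._b,
                             fn=lambda t: t * self._g(t))
            self._mean = num / self.normalizer
        return self._mean

    def cdf(self, c: float) -> float:
        if c <= self._a:
            return 0.0
        if c >= self._b:
            return 1.0
        return min(1.0, max(0.0, self._quad(self._a, c) / self.normalizer))

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level {q} must lie in (0, 1)")
        return optimize.brentq(lambda c: self.cdf(c) - q, self._a, self._b,
                               xtol=1e-10, rtol=1e-12)

    def interval(self, level: float = 0.90) -> tuple[float, float]:
        if not 0.0 < level < 1.0:
            raise ValueError(f"level = {level} must lie in (0, 1)")
        alpha = (1.0 - level) / 2.0
        return self.quantile(alpha), self.quantile(1.0 - alpha)


def posterior_mean(
    snapshots: Sequence[ParticipantSnapshot],
    prior_mean: float = 0.0,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> float:
    """Posterior mean of beta under the normal prior and weighted likelihood.

    Computed by adaptive quadrature of the unnormalized posterior over
    ``prior_mean +/- 10 prior_sd``; with no data this returns the prior mean
    (to quadrature tolerance).
    """
    return Posterior(snapshots, prior_mean, prior_sd).mean()


def posterior_interval(
    snapshots: Sequence[ParticipantSnapshot],
    prior_mean: float = 0.0,
    prior_sd: float = DEFAULT_PRIOR_SD,
    level: float = 0.90,
) -> tuple[float, float]:
    """Equal-tailed credible interval for beta at the given level.

    Obtained by root-finding on the quadrature-based posterior CDF.
    """
    return Posterior(snapshots, prior_mean, prior_sd).interval(level)


def prob_toxicity_exceeds(
    snapshots: Sequence[ParticipantSnapshot],
    dose_label: float,
    threshold_prob: float,
    prior_mean: float = 0.0,
    prior_sd: float = DEFAULT_PRIOR_SD,
    posterior: Optional[Posterior] = None,
) -> float:
    """Posterior probability that the DLT probability at ``dose_label``
    exceeds ``threshold_prob``.

    For the power model, F(d, beta) is decreasing in beta (0 < d < 1), so
    ``P[F(d, beta) > p0] = P[beta < log(log p0 / log d)]`` — a single
    posterior CDF evaluation.  Used by the safety stopping rule.  An
    already-built :class:`Posterior` may be passed to reuse its quadrature.
    """
    if not 0.0 < dose_label < 1.0:
        raise ValueError("dose_label must lie in (0, 1)")
    if not 0.0 < threshold_prob < 1.0:
        raise ValueError("threshold_prob must lie in (0, 1)")
    c = math.log(math.log(threshold_prob) / math.log(dose_label))
    if posterior is None:
        posterior = Posterior(snapshots, prior_mean, prior_sd)
    return posterior.cdf(c)


def plug_in_probs(labels: Sequence[float], beta_hat: float) -> np.ndarray:
    """Plug-in DLT probability estimates ``d_k ** exp(beta_hat)`` per dose."""
    d = np.asarray(labels, dtype=float)
    if np.any(d <= 0.0) or np.any(d >= 1.0):
        raise ValueError("dose labels must lie strictly inside (0, 1)")
    if np.any(np.diff(d) <= 0.0):
        raise ValueError("dose labels must be strictly increasing")
    return d ** math.exp(beta_hat)


def select_mtd(
    pi_hat: Sequence[float], ttl: float, rule: str = "highest_below"
) -> MtdSelection:
    """Select the MTD from plug-in DLT probability estimates.

    ``highest_below``: the highest dose whose estimate is below the TTL; if
    every dose is at or above the target, dose 1 is returned with
    ``all_above_target`` set (the conduct layer decides whether to stop).
    ``closest``: the dose whose estimate is closest to the TTL, ties broken
    to the lower (safer) dose.
    """
    pi = np.asarray(pi_hat, dtype=float)
    if pi.ndim != 1 or pi.size == 0:
        raise ValueError("pi_hat must be a non-empty 1-d probability vector")
    if np.any(np.diff(pi) <= 0.0):
        raise ValueError("pi_hat must be strictly increasing across doses")
    if rule not in _MTD_RULES:
        raise ValueError(f"rule = {rule!r}; expected one of {_MTD_RULES}")
    all_above = bool(np.all(pi >= ttl))
    if rule == "highest_below":
        below = np.nonzero(pi < ttl)[0]
        if below.size == 0:
            return MtdSelection(1, True)
        return MtdSelection(int(below[-1]) + 1, False)
    # closest: np.argmin returns the first minimizer, i.e. the lower dose on ties
    idx = int(np.argmin(np.abs(pi - ttl)))
    return MtdSelection(idx + 1, all_above)


def posterior_summary(
    snapshots: Sequence[ParticipantSnapshot],
    design: DesignSpec,
    level: float = 0.90,
    with_interval: bool = True,
    posterior: Optional["Posterior"] = None,
) -> PosteriorSummary:
    """Full posterior summary: beta-hat, optional credible interval, plug-in
    probabilities and the MTD under the design's rule.  A pre-built
    :class:`Posterior` workspace may be supplied to reuse its quadrature."""
    if posterior is None:
        posterior = Posterior(snapshots, design.prior_mean, design.prior_sd)
    beta_hat = posterior.mean()
    pi = plug_in_probs(design.dose_labels(), beta_hat)
    sel = select_mtd(pi, design.ttl, design.mtd_rule)
    interval = None
    if with_interval:
        lo, hi = posterior.interval(level)
        interval = (level, lo, hi)
    return PosteriorSummary(
        beta_hat=beta_hat,
        beta_interval=interval,
        pi_hat=pi,
        mtd_index=sel.index,
        all_above_target=sel.all_above_target,
    )
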