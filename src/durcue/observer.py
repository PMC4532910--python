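"""Bayesian observer models for 2AFC duration comparison.

The observer receives noisy, biased sensory measurements of two log durations
(the first measurement optionally degraded by memory decay), forms a
likelihood of each duration, combines it with a prior belief about the
duration distributions, and reports which stimulus lasted longer based on the
posterior probability of the decision variable.  Models form a 4 x 2 x 3
factorial family:

* combination rule for the paired HL stimulus: ``weighting`` (free weight
  ``w_H``), ``optimal_integration`` (precision weighting), ``selection``
  (one element per trial with probability ``c_H``), ``reliable_stimulus``
  (always the element with smaller measurement SD);
* memory ``decay`` (first-stimulus SD inflated by ``m`` >= 1) or ``no_decay``;
* prior structure: ``flat`` (improper uniform, posterior = likelihood),
  ``single`` (one pooled smoothed mixture for both stimuli), or ``double``
  (separate reference / comparison distributions, marginalised over the
  unknown display order).

Everything is computed on the natural-log duration scale.  The trial-level
choice probability marginalises the decision over the generative measurement
distributions: a Gauss--Hermite quadrature (order 7 by default) over the
first measurement, with the decision boundary in the second measurement found
by bracketed bisection.  For flat priors the boundary is exactly x2 = x1 and
the integral is evaluated in closed form.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .schedules import REFERENCE_MS, Schedule

logger = logging.getLogger(__name__)

LOG_REF = float(np.log(REFERENCE_MS))

COMBINATIONS = ("weighting", "optimal_integration", "selection",
                "reliable_stimulus")
DECAYS = ("decay", "no_decay")
PRIORS = ("flat", "single", "double")

#: Chebyshev nodes for the interpolated boundary fast path; the pooled
#: single prior's boundary has finer structure and needs more nodes
N_CHEB_DOUBLE = 24
N_CHEB_SINGLE = 24
#: bisection tolerance on the decision boundary (log-duration units)
BOUNDARY_XTOL = 1e-10
#: points in the coarse monotonicity scan preceding bisection
N_SCAN = 16


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the factorial model space."""

    combination: str
    decay: str
    prior: str

    def __post_init__(self):
        if self.combination not in COMBINATIONS:
            raise ValueError(f"unknown combination rule {self.combination!r}")
        if self.decay not in DECAYS:
            raise ValueError(f"unknown decay assumption {self.decay!r}")
        if self.prior not in PRIORS:
            raise ValueError(f"unknown prior structure {self.prior!r}")

    @property
    def name(self) -> str:
        return f"{self.combination}/{self.decay}/{self.prior}"

    def free_parameters(self) -> tuple[str, ...]:
        names = ["b_H", "b_L", "sigma_H", "sigma_L", "lapse"]
        if self.combination == "weighting":
            names.append("w_H")
        elif self.combination == "selection":
            names.append("c_H")
        if self.decay == "decay":
            names.append("m")
        if self.prior != "flat":
            names.append("kappa")
        return tuple(names)


@dataclass
class ObserverParams:
    """Generative / inference parameters of one observer.

    ``b_H``/``b_L`` bias and ``sigma_H``/``sigma_L`` SD of the log-duration
    measurements; ``w_H`` weight of the H element (weighting rule); ``c_H``
    probability of attending H (selection rule); ``m`` memory-decay factor
    (>= 1); ``lapse`` guessing probability; ``kappa`` prior-kernel SD
    (non-flat priors).  Fields irrelevant to a model must be left ``None``.
    """

    b_H: float
    b_L: float
    sigma_H: float
    sigma_L: float
    w_H: float | None = None
    c_H: float | None = None
    m: float | None = None
    lapse: float = 0.0
    kappa: float | None = None

    def decay_scale(self, model: ModelSpec, position: str) -> float:
        if model.decay == "decay" and position == "first":
            return float(self.m)
        return 1.0


#: study-condition generating parameters for synthetic observers: element
#: SDs from the illustrative values sigma_H = 0.2, sigma_L = 0.24, biases
#: giving the H-vs-L distortion scale seen empirically (b_H - b_L ~ 0.37
#: log-units), overweighting of H (w_H = 0.7), moderate memory decay and
#: prior smoothing, and a 5% lapse rate.
DEFAULT_GENERATING = {
    "b_H": 0.25, "b_L": -0.12, "sigma_H": 0.2, "sigma_L": 0.24,
    "w_H": 0.7, "c_H": 0.6, "m": 1.5, "lapse": 0.05, "kappa": 0.3,
}


def default_observer(model: ModelSpec, **overrides) -> ObserverParams:
    """Study-condition parameters restricted to ``model``'s free set."""
    values = {**DEFAULT_GENERATING, **overrides}
    kw = {n: values[n] for n in model.free_parameters()}
    return ObserverParams(**kw)


def validate_params(model: ModelSpec, params: ObserverParams) -> None:
    """Reject parameter sets inconsistent with ``model`` (with explanation)."""
    if params.sigma_H <= 0 or params.sigma_L <= 0:
        raise ValueError("sigma_H and sigma_L must be positive")
    if not 0.0 <= params.lapse <= 1.0:
        raise ValueError("lapse must lie in [0, 1]")
    if model.combination == "weighting":
        if params.w_H is None or not 0.0 <= params.w_H <= 1.0:
            raise ValueError("weighting models require w_H in [0, 1]")
        if params.c_H is not None:
            raise ValueError("c_H is meaningless for a weighting model")
    elif model.combination == "selection":
        if params.c_H is None or not 0.0 <= params.c_H <= 1.0:
            raise ValueError("selection models require c_H in [0, 1]")
        if params.w_H is not None:
            raise ValueError("w_H is meaningless for a selection model")
    else:
        if params.w_H is not None:
            raise ValueError(f"w_H is meaningless for a "
                             f"{model.combination} model")
        if params.c_H is not None:
            raise ValueError(f"c_H is meaningless for a "
                             f"{model.combination} model")
    if model.decay == "decay":
        if params.m is None or params.m < 1.0:
            raise ValueError("decay models require a decay factor m >= 1")
    elif params.m is not None and params.m != 1.0:
        raise ValueError("m must be unset (or 1) for a no_decay model")
    if model.prior != "flat":
        if params.kappa is None or params.kappa <= 0:
            raise ValueError("non-flat priors require a kernel SD kappa > 0")
    elif params.kappa is not None:
        raise ValueError("kappa is meaningless for a flat-prior model")


@dataclass
class GaussianMixtureBelief:
    """Weighted Gaussian components on log duration (priors and posteriors)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        self.means = np.atleast_1d(np.asarray(self.means, float))
        self.variances = np.atleast_1d(np.asarray(self.variances, float))
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("mixture variances must be positive")

    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))


@dataclass
class Priors:
    """Prior beliefs of an observer, built from a trial schedule.

    ``kind`` is "flat", "single" or "double".  For the double hypothesis,
    ``p_r`` is the reference prior (Gaussian at log 600, SD kappa) and
    ``p_c`` a mixture over the log comparison durations weighted by their
    scheduled incidence; the single hypothesis pools them half/half.
    """

    kind: str
    kappa: float | None = None
    mu_r: np.ndarray | None = None
    w_r: np.ndarray | None = None
    mu_c: np.ndarray | None = None
    w_c: np.ndarray | None = None

    @property
    def p_r(self) -> GaussianMixtureBelief:
        self._require_nonflat()
        return GaussianMixtureBelief(self.w_r, self.mu_r,
                                     np.full_like(self.mu_r, self.kappa ** 2))

    @property
    def p_c(self) -> GaussianMixtureBelief:
        self._require_nonflat()
        return GaussianMixtureBelief(self.w_c, self.mu_c,
                                     np.full_like(self.mu_c, self.kappa ** 2))

    @property
    def pooled(self) -> GaussianMixtureBelief:
        self._require_nonflat()
        mu = np.concatenate([self.mu_r, self.mu_c])
        w = np.concatenate([0.5 * self.w_r, 0.5 * self.w_c])
        return GaussianMixtureBelief(w, mu, np.full_like(mu, self.kappa ** 2))

    def _require_nonflat(self):
        if self.kind == "flat":
            raise ValueError("flat prior has no mixture representation")


@dataclass(frozen=True)
class PriorSupport:
    """Schedule-derived support of the comparison prior (pre-kernel)."""

    mu_c: np.ndarray
    w_c: np.ndarray

    @classmethod
    def from_schedule(cls, schedule: Schedule) -> "PriorSupport":
        if len(schedule) == 0:
            raise ValueError("cannot build priors from an empty schedule")
        counts = schedule.comparison_counts()
        mu = np.log(counts.index.to_numpy(float))
        w = counts.to_numpy(float)
        return cls(mu, w / w.sum())


def build_priors(schedule, prior_hypothesis: str, kappa: float | None) -> Priors:
    """Construct the observer's prior beliefs for one prior hypothesis.

    ``schedule`` may be a :class:`Schedule` or a precomputed
    :class:`PriorSupport`.  Non-flat hypotheses smooth the scheduled duration
    distributions with a Gaussian kernel of SD ``kappa``.
    """
    if prior_hypothesis == "flat":
        return Priors("flat")
    if kappa is None or kappa <= 0:
        raise ValueError("non-flat priors require kappa > 0")
    support = (schedule if isinstance(schedule, PriorSupport)
               else PriorSupport.from_schedule(schedule))
    mu_r = np.array([LOG_REF])
    w_r = np.array([1.0])
    if prior_hypothesis == "double":
        return Priors("double", kappa, mu_r, w_r, support.mu_c, support.w_c)
    if prior_hypothesis == "single":
        return Priors("single", kappa, mu_r, w_r, support.mu_c, support.w_c)
    raise ValueError(f"unknown prior hypothesis {prior_hypothesis!r}")


# ---------------------------------------------------------------------------
# elementary distribution predictions (closed forms used in Experiment 2)

@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float


def measurement_distribution(stim_type: str, t_log, params: ObserverParams,
                             position: str = "second", decay: bool = False):
    """Distribution of the sensory measurement(s) of one stimulus.

    H and L yield a single Gaussian on log duration; HL yields an independent
    pair, each element distributed exactly as when shown alone.  Under decay
    the SD of a first-position measurement is inflated by ``m``.
    """
    scale = float(params.m) if (decay and position == "first") else 1.0
    if stim_type == "H":
        return NormalSpec(t_log + params.b_H, params.sigma_H * scale)
    if stim_type == "L":
        return NormalSpec(t_log + params.b_L, params.sigma_L * scale)
    if stim_type == "HL":
        return (NormalSpec(t_log + params.b_H, params.sigma_H * scale),
                NormalSpec(t_log + params.b_L, params.sigma_L * scale))
    raise ValueError(f"unknown stimulus type {stim_type!r}")


def combine_weighting(x_H, x_L, w_H):
    """Weighted average of the two element measurements."""
    if np.any(np.asarray(w_H) < 0) or np.any(np.asarray(w_H) > 1):
        raise ValueError("w_H must lie in [0, 1]")
    return w_H * x_H + (1.0 - w_H) * x_L


def predict_sd_weighting(w_H, sigma_H, sigma_L):
    """SD of the weighted combined measurement."""
    return np.sqrt(w_H ** 2 * sigma_H ** 2 + (1.0 - w_H) ** 2 * sigma_L ** 2)


def predict_mean_sd_weighting(w_H, b_H, b_L, sigma_H, sigma_L):
    """(mean offset, SD) of the combined HL measurement under weighting."""
    return (combine_weighting(b_H, b_L, w_H),
            predict_sd_weighting(w_H, sigma_H, sigma_L))


def predict_sd_optimal(sigma_H, sigma_L):
    """SD of the precision-weighted (statistically optimal) combination;
    strictly smaller than either element SD."""
    sigma_H = np.asarray(sigma_H, float)
    sigma_L = np.asarray(sigma_L, float)
    if np.any(sigma_H <= 0) or np.any(sigma_L <= 0):
        raise ValueError("SDs must be positive")
    return sigma_H * sigma_L / np.sqrt(sigma_H ** 2 + sigma_L ** 2)


def optimal_weight(sigma_H, sigma_L):
    """Weight of the H element under precision weighting."""
    return sigma_L ** 2 / (sigma_H ** 2 + sigma_L ** 2)


def predict_mean_sd_selection(c_H, b_H, b_L, sigma_H, sigma_L):
    """(mean offset, across-trial SD) of the HL measurement when one element
    is selected per trial with probability ``c_H``; the SD is never below the
    smaller element SD."""
    if np.any(np.asarray(c_H) < 0) or np.any(np.asarray(c_H) > 1):
        raise ValueError("c_H must lie in [0, 1]")
    mean = c_H * b_H + (1.0 - c_H) * b_L
    var = (c_H * sigma_H ** 2 + (1.0 - c_H) * sigma_L ** 2
           + c_H * (1.0 - c_H) * (b_H - b_L) ** 2)
    return mean, np.sqrt(var)


def reliable_element(params: ObserverParams) -> str:
    """Element used by the reliable-stimulus rule (ties resolved toward H)."""
    return "H" if params.sigma_H <= params.sigma_L else "L"


def likelihood_of_duration(stim_type: str, measurements, model: ModelSpec,
                           params: ObserverParams, position: str = "second",
                           selected_element: str | None = None
                           ) -> GaussianMixtureBelief:
    """Single-Gaussian likelihood of the true duration given the measurements.

    The likelihood is centred on the (combined) measurement -- the biases are
    not accessible to the observer at the inference stage -- with SD equal to
    the generative SD of the combined statistic, scaled by ``m`` for a
    first-position stimulus under decay.
    """
    scale = params.decay_scale(model, position)
    if stim_type in ("H", "L"):
        x = float(np.asarray(measurements).reshape(()))
        sd = (params.sigma_H if stim_type == "H" else params.sigma_L) * scale
        return GaussianMixtureBelief([1.0], [x], [sd ** 2])
    if stim_type != "HL":
        raise ValueError(f"unknown stimulus type {stim_type!r}")
    x_H, x_L = measurements
    if model.combination == "weighting":
        centre = combine_weighting(x_H, x_L, params.w_H)
        sd = predict_sd_weighting(params.w_H, params.sigma_H,
                                  params.sigma_L) * scale
    elif model.combination == "optimal_integration":
        w = optimal_weight(params.sigma_H, params.sigma_L)
        centre = combine_weighting(x_H, x_L, w)
        sd = predict_sd_optimal(params.sigma_H, params.sigma_L) * scale
    elif model.combination == "selection":
        if selected_element not in ("H", "L"):
            raise ValueError("selection models need selected_element "
                             "('H' or 'L') for an HL stimulus")
        centre = x_H if selected_element == "H" else x_L
        sd = (params.sigma_H if selected_element == "H"
              else params.sigma_L) * scale
    else:  # reliable_stimulus
        elem = reliable_element(params)
        centre = x_H if elem == "H" else x_L
        sd = (params.sigma_H if elem == "H" else params.sigma_L) * scale
    return GaussianMixtureBelief([1.0], [float(centre)], [float(sd ** 2)])


def reduce_hl(model: ModelSpec, params: ObserverParams, x_h, x_l,
              scale: float, rng: np.random.Generator):
    """Reduce paired HL measurements to the scalar inference statistic.

    Returns ``(y, tau)`` where ``tau`` is the SD of the observer's likelihood
    for that statistic.  For the selection rule the attended element is drawn
    per trial with probability ``c_H``.
    """
    x_h = np.asarray(x_h, float)
    x_l = np.asarray(x_l, float)
    if model.combination == "weighting":
        y = combine_weighting(x_h, x_l, params.w_H)
        tau = predict_sd_weighting(params.w_H, params.sigma_H,
                                   params.sigma_L) * scale
    elif model.combination == "optimal_integration":
        w = optimal_weight(params.sigma_H, params.sigma_L)
        y = combine_weighting(x_h, x_l, w)
        tau = predict_sd_optimal(params.sigma_H, params.sigma_L) * scale
    elif model.combination == "selection":
        pick_h = rng.random(x_h.shape) < params.c_H
        y = np.where(pick_h, x_h, x_l)
        tau = np.where(pick_h, params.sigma_H, params.sigma_L) * scale
        return y, tau
    else:
        elem = reliable_element(params)
        y = x_h if elem == "H" else x_l
        tau = (params.sigma_H if elem == "H" else params.sigma_L) * scale
    return y, np.broadcast_to(np.asarray(tau, float), y.shape).copy()


# ---------------------------------------------------------------------------
# decision function

def _posterior_components(y, tau, mu, w, kappa):
    """Conjugate posterior mixture for likelihood N(t; y, tau^2) under a
    Gaussian-mixture prior with common component SD kappa.

    ``y``/``tau`` broadcast arrays, ``mu``/``w`` 1-D of length K.  Returns
    (weights, means, variance) with a trailing K axis.
    """
    y = np.asarray(y, float)[..., None]
    tau = np.asarray(tau, float)[..., None]
    t2, k2 = tau ** 2, kappa ** 2
    s = t2 + k2
    loga = np.log(w) - 0.5 * (y - mu) ** 2 / s - 0.5 * np.log(s)
    loga -= loga.max(axis=-1, keepdims=True)
    a = np.exp(loga)
    a /= a.sum(axis=-1, keepdims=True)
    m = (k2 * y + t2 * mu) / s
    v = t2 * k2 / s
    return a, m, v


def _scenario_p_first_longer(y1, tau1, mu1, w1, y2, tau2, mu2, w2, kappa):
    """P(t1 > t2) for independent mixture posteriors under one prior
    assignment."""
    a1, m1, v1 = _posterior_components(y1, tau1, mu1, w1, kappa)
    a2, m2, v2 = _posterior_components(y2, tau2, mu2, w2, kappa)
    diff = m1[..., :, None] - m2[..., None, :]
    var = v1[..., :, None] + v2[..., None, :]
    phi = ndtr(diff / np.sqrt(var))
    return np.einsum("...i,...j,...ij->...", a1, a2, phi)


def p_first_longer(y1, y2, tau1, tau2, priors: Priors):
    """Posterior probability that the first duration was longer, p(D=0).

    Vectorised over broadcastable measurement statistics ``y1``/``y2`` with
    likelihood SDs ``tau1``/``tau2``.  Under double priors the two possible
    assignments of the reference/comparison priors to the two positions are
    averaged (the observer does not know the display order).
    """
    y1, y2, tau1, tau2 = np.broadcast_arrays(
        *(np.asarray(a, float) for a in (y1, y2, tau1, tau2)))
    if priors.kind == "flat":
        return ndtr((y1 - y2) / np.sqrt(tau1 ** 2 + tau2 ** 2))
    k = priors.kappa
    if priors.kind == "single":
        pool = priors.pooled
        mu, w = pool.means, pool.weights
        return _scenario_p_first_longer(y1, tau1, mu, w, y2, tau2, mu, w, k)
    # double: O = "c-r" puts the comparison prior on position 1
    p_cr = _scenario_p_first_longer(y1, tau1, priors.mu_c, priors.w_c,
                                    y2, tau2, priors.mu_r, priors.w_r, k)
    p_rc = _scenario_p_first_longer(y1, tau1, priors.mu_r, priors.w_r,
                                    y2, tau2, priors.mu_c, priors.w_c, k)
    return 0.5 * (p_cr + p_rc)


def posterior_decision_prob(lik1: GaussianMixtureBelief,
                            lik2: GaussianMixtureBelief,
                            priors: Priors) -> tuple[float, float]:
    """(p(D=0), p(D=1)) -- first/second duration longer -- from the two
    single-component likelihood beliefs and the prior structure."""
    if lik1.means.size != 1 or lik2.means.size != 1:
        raise ValueError("likelihood beliefs must be single-component")
    y1, tau1 = float(lik1.means[0]), float(np.sqrt(lik1.variances[0]))
    y2, tau2 = float(lik2.means[0]), float(np.sqrt(lik2.variances[0]))
    p0 = float(p_first_longer(y1, y2, tau1, tau2, priors))
    return p0, 1.0 - p0


# ---------------------------------------------------------------------------
# decision boundary search

def _prior_arrays(priors: Priors):
    """(kind code, mixture means/log-weights, kappa) for the numba kernels."""
    from . import _kernels as K
    if priors.kind == "flat":
        dummy = np.ones(1)
        return K.KIND_FLAT, dummy, dummy, dummy, dummy, 0.0
    if priors.kind == "single":
        pool = priors.pooled
        logw = np.log(pool.weights)
        return K.KIND_SINGLE, pool.means, logw, pool.means, logw, float(priors.kappa)
    return (K.KIND_DOUBLE, priors.mu_c, np.log(priors.w_c), priors.mu_r,
            np.log(priors.w_r), float(priors.kappa))


def boundary_roots(y1, tau1, tau2, priors: Priors, xtol: float = BOUNDARY_XTOL,
                   check_monotone: bool = True):
    """For each first-position statistic ``y1``, the second-position statistic
    at which the decision flips (p(D=0) = p(D=1)).

    Expands a bracket around ``y1`` until the decision function changes sign
    (hard limit: 8 doublings), optionally scans 16 points to assert that
    p(D=0) is non-increasing in x2, then bisects to ``xtol``.  If no sign
    change is found the whole axis is classified by the sign at the bracket
    midpoint and the root is pushed to +/- infinity (logged).  For flat
    priors the boundary is exactly x2 = x1.
    """
    from . import _kernels as K
    y1 = np.ascontiguousarray(np.asarray(y1, float))
    if priors.kind == "flat":
        return y1.copy()
    tau1 = np.ascontiguousarray(np.broadcast_to(np.asarray(tau1, float),
                                                y1.shape))
    tau2 = np.ascontiguousarray(np.broadcast_to(np.asarray(tau2, float),
                                                y1.shape))
    kind, mu_a, w_a, mu_b, w_b, kappa = _prior_arrays(priors)
    roots, status, n_nonmono = K.boundary_kernel(
        y1.ravel(), tau1.ravel(), tau2.ravel(), kind, mu_a, w_a, mu_b, w_b,
        kappa, xtol, N_SCAN, check_monotone)
    if np.any(status != 0):
        # expected at extreme parameters (near-delta priors push the
        # boundary beyond the bracket limit); the classification is exact
        # there because the generative tail mass at the limit is 0 or 1
        logger.debug("decision boundary not bracketed for %d point(s); "
                     "classified the whole axis",
                     int(np.count_nonzero(status)))
    if n_nonmono:
        logger.warning("decision function not monotone in x2 at %d "
                       "scan point(s)", int(n_nonmono))
    return roots.reshape(y1.shape)


# ---------------------------------------------------------------------------
# choice probability

@functools.lru_cache(maxsize=8)
def _gh_nodes(order: int):
    u, w = np.polynomial.hermite.hermgauss(order)
    return u, w / np.sqrt(np.pi)


@functools.lru_cache(maxsize=4)
def _cheb_nodes_proj(n: int):
    """First-kind Chebyshev points on [-1, 1] and the interpolation
    projection matrix (coefficients = proj @ values)."""
    k = np.arange(n)
    theta = (2 * k + 1) * np.pi / (2 * n)
    x = np.cos(theta)
    proj = 2.0 / n * np.cos(np.outer(k, theta))
    proj[0] *= 0.5
    return x, proj


@dataclass
class CellData:
    """Precomputed arrays for a table of trial cells (fit hot path)."""

    ref_first: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    type1: np.ndarray
    type2: np.ndarray
    n_longer: np.ndarray | None = None
    n_total: np.ndarray | None = None

    def __len__(self) -> int:
        return self.t1.size

    @classmethod
    def from_cells(cls, cells: pd.DataFrame) -> "CellData":
        ref_first = (cells["order"] == "r-c").to_numpy()
        t_ref = np.log(cells["ref_duration_ms"].to_numpy(float))
        t_comp = np.log(cells["comp_duration_ms"].to_numpy(float))
        ref_type = cells["ref_type"].to_numpy()
        comp_type = cells["comp_type"].to_numpy()
        return cls(
            ref_first=ref_first,
            t1=np.where(ref_first, t_ref, t_comp),
            t2=np.where(ref_first, t_comp, t_ref),
            type1=np.where(ref_first, ref_type, comp_type),
            type2=np.where(ref_first, comp_type, ref_type),
            n_longer=(cells["n_longer"].to_numpy(float)
                      if "n_longer" in cells else None),
            n_total=(cells["n_total"].to_numpy(float)
                     if "n_total" in cells else None),
        )


def _branch_table(cd: CellData, model: ModelSpec, params: ObserverParams):
    """Expand trial cells into weighted single-Gaussian branches.

    Returns (cell_index, weight, mu1, sd1, mu2, sd2) arrays; ``sd`` is both
    the generative SD of the scalar statistic and the observer's likelihood
    SD (they coincide for every combination rule).
    """
    t1, t2, type1, type2 = cd.t1, cd.t2, cd.type1, cd.type2

    def position_options(types, t, scale):
        """Two (weight, mean, sd) options per row; option 1 has weight 0
        except for HL under the selection rule."""
        mean0 = np.empty_like(t)
        sd0 = np.empty_like(t)
        w0 = np.ones_like(t)
        mean1 = np.zeros_like(t)
        sd1 = np.ones_like(t)
        w1 = np.zeros_like(t)
        for stim in ("H", "L"):
            mask = types == stim
            b = params.b_H if stim == "H" else params.b_L
            s = params.sigma_H if stim == "H" else params.sigma_L
            mean0[mask] = t[mask] + b
            sd0[mask] = s * scale
        mask = types == "HL"
        if mask.any():
            if model.combination == "weighting":
                off, sd = predict_mean_sd_weighting(
                    params.w_H, params.b_H, params.b_L,
                    params.sigma_H, params.sigma_L)
            elif model.combination == "optimal_integration":
                w = optimal_weight(params.sigma_H, params.sigma_L)
                off = combine_weighting(params.b_H, params.b_L, w)
                sd = predict_sd_optimal(params.sigma_H, params.sigma_L)
            elif model.combination == "reliable_stimulus":
                elem = reliable_element(params)
                off = params.b_H if elem == "H" else params.b_L
                sd = params.sigma_H if elem == "H" else params.sigma_L
            else:  # selection: option0 = H attended, option1 = L attended
                mean0[mask] = t[mask] + params.b_H
                sd0[mask] = params.sigma_H * scale
                w0[mask] = params.c_H
                mean1[mask] = t[mask] + params.b_L
                sd1[mask] = params.sigma_L * scale
                w1[mask] = 1.0 - params.c_H
                return (w0, mean0, sd0), (w1, mean1, sd1)
            mean0[mask] = t[mask] + off
            sd0[mask] = sd * scale
        return (w0, mean0, sd0), (w1, mean1, sd1)

    opts1 = position_options(type1, t1, params.decay_scale(model, "first"))
    opts2 = position_options(type2, t2, params.decay_scale(model, "second"))

    idx = np.arange(len(cd))
    out = []
    for (w1, m1, s1), (w2, m2, s2) in itertools.product(opts1, opts2):
        w = w1 * w2
        keep = w > 0
        if keep.any():
            out.append((idx[keep], w[keep], m1[keep], s1[keep],
                        m2[keep], s2[keep]))
    cell_idx = np.concatenate([o[0] for o in out])
    cols = [np.concatenate([o[i] for o in out]) for i in range(1, 6)]
    return (cell_idx, *cols)


def _interp_roots(nodes: np.ndarray, sd1: np.ndarray, sd2: np.ndarray,
                  priors: Priors, check_monotone: bool) -> np.ndarray:
    """Decision-boundary roots at every quadrature node via interpolation.

    The boundary x2*(x1) depends only on the two likelihood SDs (and the
    priors), not on the stimulus durations, so it is solved once per SD pair
    at Chebyshev points spanning that pair's quadrature nodes and evaluated
    elsewhere by the interpolating polynomial.  All root solves across SD
    pairs are batched into a single vectorised bisection.
    """
    n_cheb = N_CHEB_SINGLE if priors.kind == "single" else N_CHEB_DOUBLE
    cheb = np.polynomial.chebyshev
    xc_unit, proj = _cheb_nodes_proj(n_cheb)
    pair_key = np.stack([sd1, sd2], axis=1).round(15)
    _, first, inv = np.unique(pair_key, axis=0, return_index=True,
                              return_inverse=True)
    queries, q_t1, q_t2, plans = [], [], [], []
    for gid, row0 in enumerate(first):
        rows = inv == gid
        pts = nodes[rows]
        t1s, t2s = sd1[row0], sd2[row0]
        a, b = float(pts.min()), float(pts.max())
        if pts.size <= n_cheb or b - a < 1e-9:
            q = pts.ravel()
            plans.append(("direct", rows, None))
        else:
            q = 0.5 * (a + b) + 0.5 * (b - a) * xc_unit
            plans.append(("cheb", rows, (a, b)))
        queries.append(q)
        q_t1.append(np.full(q.size, t1s))
        q_t2.append(np.full(q.size, t2s))
    sol = boundary_roots(np.concatenate(queries), np.concatenate(q_t1),
                         np.concatenate(q_t2), priors,
                         check_monotone=check_monotone)
    roots = np.empty_like(nodes)
    pos = 0
    for q, (kind, rows, ab) in zip(queries, plans):
        rc = sol[pos:pos + q.size]
        pos += q.size
        pts = nodes[rows]
        if kind == "direct" or not np.all(np.isfinite(rc)):
            if kind != "direct":  # fallback: solve every node directly
                rc = boundary_roots(pts.ravel(), sd1[rows][0], sd2[rows][0],
                                    priors, check_monotone=check_monotone)
            roots[rows] = rc.reshape(pts.shape)
            continue
        a, b = ab
        coef = proj @ rc
        roots[rows] = cheb.chebval((2.0 * pts - (a + b)) / (b - a), coef)
    return roots


#: backwards-compatible alias for the default node count
N_CHEB = N_CHEB_DOUBLE


def _core_prob_rows(mu1, sd1, mu2, sd2, priors: Priors, quad_order: int,
                    method: str, check_monotone: bool):
    """P(second judged longer) per branch row, before lapse."""
    if priors.kind == "flat":
        # boundary is exactly x2 = x1: closed form
        return ndtr((mu2 - mu1) / np.sqrt(sd1 ** 2 + sd2 ** 2))
    u, wq = _gh_nodes(quad_order)
    n = mu1.size
    nodes = mu1[:, None] + np.sqrt(2.0) * sd1[:, None] * u[None, :]
    if method == "exact":
        roots = boundary_roots(nodes.ravel(),
                               np.repeat(sd1, quad_order),
                               np.repeat(sd2, quad_order), priors,
                               check_monotone=check_monotone)
        roots = roots.reshape(n, quad_order)
    elif method == "interp":
        roots = _interp_roots(nodes, sd1, sd2, priors, check_monotone)
    else:
        raise ValueError(f"unknown method {method!r}")
    tail = 1.0 - ndtr((roots - mu2[:, None]) / sd2[:, None])
    return tail @ wq


def choice_prob_cells(cells, model: ModelSpec,
                      params: ObserverParams, priors: Priors,
                      quad_order: int = 7, method: str = "exact",
                      check_monotone: bool = True) -> np.ndarray:
    """P("second longer") for each row of a trial-cell table.

    ``cells`` is a DataFrame with columns condition, order, ref_type,
    comp_type, ref_duration_ms, comp_duration_ms (or a precomputed
    :class:`CellData`).  ``method`` "exact" solves the decision boundary at
    every quadrature node; "interp" solves it at Chebyshev nodes per
    likelihood-SD context and interpolates (the boundary does not depend on
    the stimulus durations), which is what model fitting uses.
    """
    validate_params(model, params)
    cd = cells if isinstance(cells, CellData) else CellData.from_cells(cells)
    cell_idx, w, mu1, sd1, mu2, sd2 = _branch_table(cd, model, params)
    core = _core_prob_rows(mu1, sd1, mu2, sd2, priors, quad_order, method,
                           check_monotone)
    p = np.zeros(len(cd))
    np.add.at(p, cell_idx, w * core)
    return params.lapse / 2.0 + (1.0 - params.lapse) * p


def choice_probability(trial, model: ModelSpec, params: ObserverParams,
                       priors: Priors, quad_order: int = 7,
                       method: str = "exact") -> float:
    """Model probability of responding "second longer" on one trial."""
    if isinstance(trial, pd.Series):
        trial = trial.to_dict()
    elif not isinstance(trial, dict):
        trial = {k: getattr(trial, k) for k in
                 ("condition", "order", "ref_type", "comp_type",
                  "ref_duration_ms", "comp_duration_ms")}
    cells = pd.DataFrame([trial])
    return float(choice_prob_cells(cells, model, params, priors,
                                   quad_order=quad_order, method=method)[0])


# ---------------------------------------------------------------------------
# dataset log-likelihood

CELL_KEYS = ["condition", "order", "ref_type", "comp_type",
             "ref_duration_ms", "comp_duration_ms"]


def response_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse responded trials to unique cells with response counts."""
    t = trials.dropna(subset=["response"])
    grouped = t.groupby(CELL_KEYS, sort=True)["response"]
    out = grouped.agg(n_total="size",
                      n_longer=lambda r: int((r == "second_longer").sum()))
    return out.reset_index()


def log_likelihood(cells, model: ModelSpec,
                   params: ObserverParams, priors: Priors,
                   quad_order: int = 7, method: str = "interp") -> float:
    """Summed log choice probability of the responses in a cell table."""
    cd = cells if isinstance(cells, CellData) else CellData.from_cells(cells)
    if cd.n_longer is None or cd.n_total is None:
        raise ValueError("cells must carry n_longer / n_total counts")
    p = choice_prob_cells(cd, model, params, priors,
                          quad_order=quad_order, method=method,
                          check_monotone=False)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    n1 = cd.n_longer
    n0 = cd.n_total - n1
    return float(n1 @ np.log(p) + n0 @ np.log1p(-p))
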