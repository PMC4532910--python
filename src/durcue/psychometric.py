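"""Lapse-augmented cumulative-Gaussian psychometric fits on log duration.

Each condition of an experiment is summarised by the probability that the
comparison stimulus is judged longer than the 600 ms reference,

    p(comp judged longer) = (1 - lam) * Phi((t + b_c - t_ref) / sigma_c) + lam/2,

with ``t`` the log comparison duration, a per-condition bias ``b_c`` and JND
``sigma_c``, and a lapse rate ``lam`` shared across conditions.  All
conditions are fitted jointly by maximum likelihood; display orders are
pooled within condition.  The duration distortion ratio is DDR = exp(b_c):
the multiplicative factor by which the comparison's duration is perceived
relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .schedules import REFERENCE_MS, Schedule

T_REF_LOG = float(np.log(REFERENCE_MS))

BOUNDS_B = (-1.5, 1.5)
BOUNDS_SIGMA = (0.01, 2.0)
LAPSE_MAX = 0.5


def psychometric_prob(t_comp_log, b, sigma, lapse, t_ref_log=T_REF_LOG):
    """Probability that the comparison is judged longer than the reference."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(lapse) < 0) or np.any(np.asarray(lapse) > 1):
        raise ValueError("lapse must lie in [0, 1]")
    return (1.0 - lapse) * ndtr((t_comp_log + b - t_ref_log) / sigma) + lapse / 2.0


@dataclass
class PsychometricFit:
    """Joint psychometric fit of one observer's responses.

    Per-condition bias ``b`` and JND ``sigma`` (log-duration units), the
    shared lapse rate, the attained log-likelihood, and flags for conditions
    whose responses were perfectly separated (bias then sits at a bound).
    """

    conditions: tuple[str, ...]
    b: dict
    sigma: dict
    lapse: float
    log_likelihood: float
    degenerate: frozenset = field(default_factory=frozenset)

    def ddr(self, condition: str) -> float:
        """Duration distortion ratio exp(b) of one condition."""
        if condition not in self.b:
            raise KeyError(f"condition {condition!r} not in fit")
        return float(np.exp(self.b[condition]))

    def jnd(self, condition: str) -> float:
        if condition not in self.sigma:
            raise KeyError(f"condition {condition!r} not in fit")
        return float(self.sigma[condition])

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "b": {c: float(v) for c, v in self.b.items()},
            "sigma": {c: float(v) for c, v in self.sigma.items()},
            "ddr": {c: self.ddr(c) for c in self.conditions},
            "jnd": {c: self.jnd(c) for c in self.conditions},
            "lapse": float(self.lapse),
            "log_likelihood": float(self.log_likelihood),
            "degenerate": sorted(self.degenerate),
        }


def ddr(fit: PsychometricFit, condition: str) -> float:
    """Duration distortion ratio of one fitted condition."""
    return fit.ddr(condition)


def _comparison_longer(frame: pd.DataFrame) -> np.ndarray:
    """Whether each response judged the *comparison* stimulus longer."""
    second_longer = frame["response"] == "second_longer"
    ref_first = frame["order"] == "r-c"
    return np.where(ref_first, second_longer, ~second_longer)


def _condition_cells(frame: pd.DataFrame):
    """Per condition: log durations, n judged-longer, n total (orders pooled)."""
    frame = frame.dropna(subset=["response"]).copy()
    frame["comp_longer"] = _comparison_longer(frame)
    cells = (frame.groupby(["condition", "comp_duration_ms"], sort=True)
             ["comp_longer"].agg(n_longer="sum", n_total="size").reset_index())
    out = {}
    for cond, sub in cells.groupby("condition", sort=True):
        out[cond] = (np.log(sub["comp_duration_ms"].to_numpy(float)),
                     sub["n_longer"].to_numpy(float),
                     sub["n_total"].to_numpy(float))
    return out


def fit_psychometric(trials, restarts: int = 10, seed: int = 0,
                     t_ref_log: float = T_REF_LOG) -> PsychometricFit:
    """Joint maximum-likelihood psychometric fit across conditions.

    ``trials`` is a :class:`Schedule` or trial DataFrame with responses.
    Uses bounded L-BFGS-B from a heuristic start plus ``restarts - 1`` seeded
    random starts; the shared lapse rate is bounded by ``LAPSE_MAX``.
    Conditions whose responses are all identical are flagged degenerate (the
    bias lands at a bound) rather than raising.
    """
    frame = trials.trials if isinstance(trials, Schedule) else trials
    cells = _condition_cells(frame)
    if not cells:
        raise ValueError("no responded trials to fit")
    conds = tuple(sorted(cells))
    for cond, (t, n1, nt) in cells.items():
        if len(t) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 comparison "
                             "durations with responses")
    degenerate = frozenset(
        cond for cond, (t, n1, nt) in cells.items()
        if n1.sum() == 0 or n1.sum() == nt.sum())

    n_cond = len(conds)

    def unpack(x):
        return x[:n_cond], x[n_cond:2 * n_cond], x[-1]

    def nll(x):
        bs, sigmas, lam = unpack(x)
        total = 0.0
        for i, cond in enumerate(conds):
            t, n1, nt = cells[cond]
            p = psychometric_prob(t, bs[i], sigmas[i], lam, t_ref_log)
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
            total += n1 @ np.log(p) + (nt - n1) @ np.log1p(-p)
        return -total

    bounds = ([BOUNDS_B] * n_cond + [BOUNDS_SIGMA] * n_cond
              + [(0.0, LAPSE_MAX)])
    rng = np.random.default_rng(seed)
    starts = [np.concatenate([np.zeros(n_cond), np.full(n_cond, 0.3), [0.02]])]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(max(0, restarts - 1)):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    bs, sigmas, lam = unpack(best.x)
    return PsychometricFit(
        conditions=conds,
        b={c: float(bs[i]) for i, c in enumerate(conds)},
        sigma={c: float(sigmas[i]) for i, c in enumerate(conds)},
        lapse=float(lam),
        log_likelihood=float(-best.fun),
        degenerate=degenerate,
    )
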