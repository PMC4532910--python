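"""Factorial model space, maximum-likelihood fitting, and 12-fold
cross-validated model comparison.

Each of the 24 observer models (4 combination rules x 2 memory assumptions x
3 prior structures) is fitted to training trials by maximising the product of
trial choice probabilities, and scored by the summed log choice probability
of held-out trials over a stratified 12-fold partition.  Models are compared
by the difference of total cross-validated log-likelihood (CVLL) from the
best model; at the group level, paired t-tests against the best model are
corrected with the Holm-Bonferroni procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from . import observer
from .observer import (ModelSpec, ObserverParams, PriorSupport, build_priors,
                       COMBINATIONS, DECAYS, PRIORS)
from .schedules import Schedule

PARAM_BOUNDS = {
    "b_H": (-1.5, 1.5),
    "b_L": (-1.5, 1.5),
    "sigma_H": (0.02, 1.5),
    "sigma_L": (0.02, 1.5),
    "lapse": (0.0, 0.5),
    "w_H": (0.0, 1.0),
    "c_H": (0.0, 1.0),
    "m": (1.0, 3.0),
    "kappa": (0.05, 2.0),
}

_HEURISTIC_START = {
    "b_H": 0.15, "b_L": -0.15, "sigma_H": 0.25, "sigma_L": 0.25,
    "lapse": 0.02, "w_H": 0.5, "c_H": 0.5, "m": 1.3, "kappa": 0.4,
}


def enumerate_models() -> list[ModelSpec]:
    """The full 24-model factorial space, in deterministic order."""
    return [ModelSpec(c, d, p) for c, d, p
            in itertools.product(COMBINATIONS, DECAYS, PRIORS)]


def params_from_vector(model: ModelSpec, x) -> ObserverParams:
    names = model.free_parameters()
    kw = dict(zip(names, (float(v) for v in x)))
    return ObserverParams(**kw)


def vector_from_params(model: ModelSpec, params: ObserverParams) -> np.ndarray:
    return np.array([getattr(params, n) for n in model.free_parameters()],
                    float)


def make_folds(trials: pd.DataFrame, n_folds: int = 12,
               seed: int = 0) -> np.ndarray:
    """Stratified fold assignment for every row of ``trials``.

    Within each (condition x order) cell the trials are shuffled and dealt
    round-robin; the dealing position carries over between cells so both the
    per-cell and the total fold sizes differ by at most one.
    """
    if n_folds > len(trials):
        raise ValueError("more folds than trials")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(trials), dtype=int)
    pos = np.arange(len(trials))
    offset = 0
    keys = trials[["condition", "order"]]
    for _, idx in sorted(pos_groups(keys).items()):
        perm = rng.permutation(idx)
        folds[perm] = (offset + np.arange(len(perm))) % n_folds
        offset = (offset + len(perm)) % n_folds
    return folds


def pos_groups(keys: pd.DataFrame) -> dict:
    """Positional indices grouped by the rows of ``keys``."""
    groups: dict = {}
    for i, key in enumerate(map(tuple, keys.to_numpy())):
        groups.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


@dataclass
class FitResult:
    model: ModelSpec
    params: ObserverParams
    loglik: float
    x: np.ndarray
    converged: bool


@dataclass
class CVResult:
    """Cross-validation score of one model on one dataset."""

    model: ModelSpec
    fold_loglik: list[float]
    fitted_params_per_fold: list[ObserverParams]
    fold_assignment: np.ndarray = field(repr=False)

    @property
    def total_cvll(self) -> float:
        return float(np.sum(self.fold_loglik))

    def fold_signature(self) -> bytes:
        return self.fold_assignment.tobytes()


def fit_model(trials: pd.DataFrame, model: ModelSpec,
              prior_support: PriorSupport | Schedule, seed: int = 0,
              restarts: int = 10, maxiter: int = 100,
              quad_order: int = 7, method: str = "interp",
              x0: np.ndarray | None = None) -> FitResult:
    """Bounded multi-start MLE of one model on responded trials.

    Starts from a fixed heuristic point (plus ``x0`` if given) and seeded
    uniform draws within bounds; returns the best restart.  Priors are built
    from ``prior_support`` -- the full schedule, not the training split.
    """
    if isinstance(prior_support, Schedule):
        prior_support = PriorSupport.from_schedule(prior_support)
    cells = observer.response_cells(trials)
    if cells.empty:
        raise ValueError("trials have no responses to fit")
    cd = observer.CellData.from_cells(cells)
    names = model.free_parameters()
    bounds = [PARAM_BOUNDS[n] for n in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def nll(x):
        params = params_from_vector(model, x)
        priors = build_priors(prior_support, model.prior, params.kappa)
        return -observer.log_likelihood(cd, model, params, priors,
                                        quad_order=quad_order, method=method)

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, float), lo, hi))
    starts.append(np.array([_HEURISTIC_START[n] for n in names]))
    while len(starts) < restarts:
        starts.append(lo + rng.random(len(names)) * (hi - lo))
    starts = starts[:max(restarts, 1)]

    best = None
    any_converged = False
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return FitResult(model, params_from_vector(model, best.x),
                     float(-best.fun), best.x, any_converged)


def cross_validate(trials: pd.DataFrame, model: ModelSpec,
                   prior_support: PriorSupport | Schedule,
                   n_folds: int = 12, seed: int = 0, restarts: int = 10,
                   fold_restarts: int | None = None,
                   maxiter: int = 100, fold_maxiter: int | None = None,
                   quad_order: int = 7, method: str = "interp",
                   folds: np.ndarray | None = None) -> CVResult:
    """12-fold cross-validated log-likelihood of one model.

    Fits the model once on the full data, then refits on each training split
    warm-started from the full-data optimum (plus ``fold_restarts - 1``
    random restarts) and evaluates the summed log choice probability of the
    held-out fold.  Passing ``folds`` fixes the assignment so that every
    model is scored on identical splits.
    """
    if isinstance(prior_support, Schedule):
        prior_support = PriorSupport.from_schedule(prior_support)
    if folds is None:
        folds = make_folds(trials, n_folds, seed)
    folds = np.asarray(folds)
    if len(folds) != len(trials):
        raise ValueError("fold assignment length mismatch")
    if fold_restarts is None:
        fold_restarts = restarts
    if fold_maxiter is None:
        fold_maxiter = maxiter

    full = fit_model(trials, model, prior_support, seed=seed,
                     restarts=restarts, maxiter=maxiter,
                     quad_order=quad_order, method=method)
    fold_ll: list[float] = []
    fold_params: list[ObserverParams] = []
    for k in range(int(folds.max()) + 1):
        train = trials.iloc[folds != k]
        test = trials.iloc[folds == k]
        fit = fit_model(train, model, prior_support,
                        seed=seed + 1000 * (k + 1),
                        restarts=fold_restarts, maxiter=fold_maxiter,
                        quad_order=quad_order, method=method, x0=full.x)
        priors = build_priors(prior_support, model.prior, fit.params.kappa)
        cells = observer.response_cells(test)
        ll = observer.log_likelihood(cells, model, fit.params, priors,
                                     quad_order=quad_order, method=method)
        fold_ll.append(float(ll))
        fold_params.append(fit.params)
    return CVResult(model, fold_ll, fold_params, folds)


def compare_models(cv_results: list[CVResult],
                   group: list[list[CVResult]] | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Rank models by cross-validated log-likelihood.

    For a single dataset, returns each model's total CVLL and its difference
    from the dataset's best model.  With ``group`` (one result list per
    dataset, identical model sets), returns mean ΔCVLL from the group-best
    model, paired two-sided t-tests of every model against it, and
    Holm-Bonferroni significance at ``alpha``.  Results within a dataset
    must share the same fold assignment.
    """
    if group is None:
        _check_folds(cv_results)
        totals = {r.model.name: r.total_cvll for r in cv_results}
        best = max(totals.values())
        rows = [{"model": name, "total_cvll": t, "delta_cvll": t - best,
                 "is_best": t == best} for name, t in totals.items()]
        return (pd.DataFrame(rows)
                .sort_values("delta_cvll", ascending=False)
                .reset_index(drop=True))

    names = [r.model.name for r in group[0]]
    mat = np.empty((len(group), len(names)))
    for d, results in enumerate(group):
        _check_folds(results)
        by_name = {r.model.name: r.total_cvll for r in results}
        if set(by_name) != set(names):
            raise ValueError("datasets must share the same model set")
        mat[d] = [by_name[n] for n in names]
    mean_cvll = mat.mean(axis=0)
    best_j = int(np.argmax(mean_cvll))
    deltas = mat - mat[:, [best_j]]
    pvals, tvals, dvals = [], [], []
    for j in range(len(names)):
        if j == best_j:
            tvals.append(0.0)
            pvals.append(1.0)
            dvals.append(0.0)
            continue
        t, p = stats.ttest_rel(mat[:, j], mat[:, best_j])
        diff = mat[:, j] - mat[:, best_j]
        sd = diff.std(ddof=1)
        tvals.append(float(t))
        pvals.append(float(p))
        dvals.append(float(diff.mean() / sd) if sd > 0 else 0.0)
    reject = holm_bonferroni(np.array(pvals), alpha)
    reject[best_j] = False
    return pd.DataFrame({
        "model": names,
        "mean_cvll": mean_cvll,
        "mean_delta_cvll": deltas.mean(axis=0),
        "t_vs_best": tvals,
        "p_vs_best": pvals,
        "cohens_d": dvals,
        "significant": reject,
        "is_best": [j == best_j for j in range(len(names))],
    }).sort_values("mean_delta_cvll", ascending=False).reset_index(drop=True)


def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down multiple-comparison procedure; returns reject flags."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, bool)
    for rank, j in enumerate(order):
        if pvals[j] <= alpha / (m - rank):
            reject[j] = True
        else:
            break
    return reject


def _check_folds(results: list[CVResult]) -> None:
    sigs = {r.fold_signature() for r in results}
    if len(sigs) > 1:
        raise ValueError("CV results were computed on different fold "
                         "assignments; comparison refused")
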