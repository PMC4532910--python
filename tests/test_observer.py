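"""Observer model: measurement distributions, combination rules, priors,
posterior decision probabilities and trial choice probabilities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from durcue import (ModelSpec, ObserverParams, build_priors,
                    choice_probability, combine_weighting,
                    likelihood_of_duration, measurement_distribution,
                    posterior_decision_prob, predict_mean_sd_selection,
                    predict_mean_sd_weighting, predict_sd_optimal)
from durcue import observer as O
from durcue.observer import (GaussianMixtureBelief, LOG_REF, choice_prob_cells,
                             optimal_weight, p_first_longer, predict_sd_weighting)


def cell(condition, order, ref_type, comp_type, comp_ms):
    return dict(condition=condition, order=order, ref_type=ref_type,
                comp_type=comp_type, ref_duration_ms=600.0,
                comp_duration_ms=float(comp_ms))


# ---------------------------------------------------------------------------
# closed-form predictions (Experiment-2 hypothesis tests)

def test_measurement_distribution():
    p = ObserverParams(b_H=0.1, b_L=-0.1, sigma_H=0.2, sigma_L=0.24, m=1.5)
    d = measurement_distribution("H", np.log(600.0), p)
    assert d.mean == pytest.approx(np.log(600.0) + 0.1)
    assert d.sd == pytest.approx(0.2)
    d1 = measurement_distribution("H", 0.0, p, position="first", decay=True)
    assert d1.sd == pytest.approx(0.3)  # 0.2 * 1.5
    dh, dl = measurement_distribution("HL", 0.0, p)
    assert dh.sd == pytest.approx(0.2)  # element SDs unchanged in a pair
    assert dl.sd == pytest.approx(0.24)


def test_combine_weighting_values_and_distribution():
    assert combine_weighting(0.7, -0.3, 1.0) == pytest.approx(0.7)
    assert combine_weighting(1.0, 0.8, 0.5) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        combine_weighting(0.0, 0.0, 1.2)
    # combined SD, checked against a 1e6-draw Monte-Carlo
    sd = predict_sd_weighting(0.5, 0.2, 0.24)
    assert sd == pytest.approx(np.sqrt(0.25 * 0.04 + 0.25 * 0.0576))
    assert sd == pytest.approx(0.1562, abs=5e-5)
    rng = np.random.default_rng(0)
    draws = combine_weighting(rng.normal(0, 0.2, 10 ** 6),
                              rng.normal(0, 0.24, 10 ** 6), 0.5)
    assert draws.std() == pytest.approx(sd, rel=5e-3)


def test_predict_sd_optimal():
    assert predict_sd_optimal(0.3, 0.3) == pytest.approx(0.3 / np.sqrt(2))
    assert predict_sd_optimal(0.2, 0.24) == pytest.approx(0.15364, abs=5e-6)
    assert predict_sd_optimal(0.2, 1e9) == pytest.approx(0.2)  # limit
    with pytest.raises(ValueError):
        predict_sd_optimal(-0.1, 0.2)
    # cross-check by Monte-Carlo precision-weighted averaging
    rng = np.random.default_rng(1)
    w = optimal_weight(0.2, 0.24)
    draws = w * rng.normal(0, 0.2, 10 ** 6) + (1 - w) * rng.normal(0, 0.24, 10 ** 6)
    assert draws.std() == pytest.approx(predict_sd_optimal(0.2, 0.24), rel=5e-3)


def test_predict_mean_sd_selection():
    mean, sd = predict_mean_sd_selection(1.0, 0.25, -0.12, 0.2, 0.24)
    assert (mean, sd) == (pytest.approx(0.25), pytest.approx(0.2))
    _, sd = predict_mean_sd_selection(0.5, 0.2, 0.0, 0.2, 0.24)
    assert sd == pytest.approx(np.sqrt(0.0588), abs=1e-9)
    assert sd == pytest.approx(0.24249, abs=5e-6)
    _, sd0 = predict_mean_sd_selection(0.5, 0.1, 0.1, 0.3, 0.3)
    assert sd0 == pytest.approx(0.3)  # collapse when biases and SDs agree
    # Monte-Carlo of the two-component mixture
    rng = np.random.default_rng(2)
    pick = rng.random(10 ** 6) < 0.5
    draws = np.where(pick, rng.normal(0.2, 0.2, 10 ** 6),
                     rng.normal(0.0, 0.24, 10 ** 6))
    assert draws.std() == pytest.approx(np.sqrt(0.0588), rel=5e-3)


def test_sd_ordering_across_rules():
    """Orderings behind the hypothesis comparison: the optimal SD is below
    both element SDs and is the minimum of the weighting SD over weights;
    weighting never exceeds the larger element SD; selection never drops
    below the smaller one."""
    sH, sL, dB = 0.2, 0.24, 0.2
    lo, hi = min(sH, sL), max(sH, sL)
    opt = predict_sd_optimal(sH, sL)
    assert opt < lo
    for w in np.linspace(0, 1, 21):
        sdw = predict_sd_weighting(w, sH, sL)
        assert opt - 1e-12 <= sdw <= hi + 1e-12
        _, sds = predict_mean_sd_selection(w, dB, 0.0, sH, sL)
        assert sds >= lo - 1e-12
    assert predict_sd_weighting(optimal_weight(sH, sL), sH, sL) == \
        pytest.approx(opt, abs=1e-12)


# ---------------------------------------------------------------------------
# likelihoods and priors

def test_likelihood_of_duration_rules():
    p = ObserverParams(b_H=0.1, b_L=-0.1, sigma_H=0.2, sigma_L=0.24,
                       w_H=0.7, m=1.5)
    wgt = ModelSpec("weighting", "decay", "flat")
    lik = likelihood_of_duration("H", 0.1, wgt, p)
    assert lik.means[0] == pytest.approx(0.1)
    assert lik.variances[0] == pytest.approx(0.04)
    # first-position likelihood SD inflated by m
    lik1 = likelihood_of_duration("H", 0.1, wgt, p, position="first")
    assert np.sqrt(lik1.variances[0]) == pytest.approx(0.3)
    lik_w = likelihood_of_duration("HL", (0.0, 0.2), wgt, p)
    assert lik_w.means[0] == pytest.approx(0.7 * 0.0 + 0.3 * 0.2)
    opt = ModelSpec("optimal_integration", "no_decay", "flat")
    p_opt = ObserverParams(b_H=0.1, b_L=-0.1, sigma_H=0.2, sigma_L=0.2)
    lik_o = likelihood_of_duration("HL", (0.0, 0.2), opt, p_opt)
    assert lik_o.means[0] == pytest.approx(0.1)  # symmetric product
    sel = ModelSpec("selection", "no_decay", "flat")
    p_sel = ObserverParams(b_H=0.1, b_L=-0.1, sigma_H=0.2, sigma_L=0.24,
                           c_H=0.6)
    with pytest.raises(ValueError, match="selected_element"):
        likelihood_of_duration("HL", (0.0, 0.2), sel, p_sel)
    lik_s = likelihood_of_duration("HL", (0.0, 0.2), sel, p_sel,
                                   selected_element="L")
    assert lik_s.means[0] == pytest.approx(0.2)
    rel = ModelSpec("reliable_stimulus", "no_decay", "flat")
    p_rel = ObserverParams(b_H=0.1, b_L=-0.1, sigma_H=0.2, sigma_L=0.24)
    lik_r = likelihood_of_duration("HL", (0.0, 0.2), rel, p_rel)
    assert lik_r.means[0] == pytest.approx(0.0)  # H has the smaller SD


def test_build_priors(exp1, exp3):
    pri = build_priors(exp3, "double", 0.3)
    assert pri.p_c.means.size == 26
    assert pri.p_c.weights.sum() == pytest.approx(1.0)
    assert pri.p_r.mean() == pytest.approx(LOG_REF)
    # pooled mixture mean equals the direct weighted sum
    pooled = build_priors(exp1, "single", 0.3).pooled
    counts = exp1.comparison_counts()
    mu_c = np.log(counts.index.to_numpy(float))
    w_c = counts.to_numpy(float) / counts.sum()
    expected = 0.5 * LOG_REF + 0.5 * (w_c @ mu_c)
    assert pooled.mean() == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        build_priors(exp3, "double", None)
    from durcue.schedules import Schedule
    empty = Schedule(exp3.trials.iloc[:0], "exp3", 0)
    with pytest.raises(ValueError):
        build_priors(empty, "single", 0.3)


def test_gaussian_mixture_belief_validation():
    with pytest.raises(ValueError):
        GaussianMixtureBelief([0.5, 0.4], [0.0, 1.0], [0.1, 0.1])
    with pytest.raises(ValueError):
        GaussianMixtureBelief([1.0], [0.0], [0.0])


# ---------------------------------------------------------------------------
# decision probabilities

def grid_p_first_longer(y1, tau1, y2, tau2, priors, n=20001):
    """Independent dense-grid double integral of P(t1 > t2)."""
    mix = priors.pooled

    def posterior(y, tau):
        t = np.linspace(2.0, 11.0, n)
        lik = np.exp(-0.5 * ((y - t) / tau) ** 2)
        w, mu, var = mix.weights, mix.means, mix.variances
        pr = (w[None, :] * np.exp(-0.5 * (t[:, None] - mu) ** 2 / var)
              / np.sqrt(var)).sum(axis=1)
        dens = lik * pr
        dens /= np.trapezoid(dens, t)
        return t, dens

    t1g, d1 = posterior(y1, tau1)
    t2g, d2 = posterior(y2, tau2)
    cdf2 = np.concatenate([[0.0], np.cumsum((d2[1:] + d2[:-1]) / 2
                                            * np.diff(t2g))])
    cdf2 /= cdf2[-1]
    return float(np.trapezoid(d1 * np.interp(t1g, t2g, cdf2), t1g))


def test_posterior_decision_symmetry():
    pri = build_priors.__wrapped__ if False else None
    priors = O.Priors("single", 0.3, np.array([LOG_REF]), np.array([1.0]),
                      np.array([LOG_REF]), np.array([1.0]))
    lik = GaussianMixtureBelief([1.0], [LOG_REF], [0.04])
    p0, p1 = posterior_decision_prob(lik, lik, priors)
    assert p0 == pytest.approx(0.5, abs=1e-12)
    assert p0 + p1 == pytest.approx(1.0)


def test_posterior_decision_flat_closed_form():
    priors = O.Priors("flat")
    v = 0.04
    d = 0.15
    lik1 = GaussianMixtureBelief([1.0], [6.0], [v])
    lik2 = GaussianMixtureBelief([1.0], [6.0 + d], [v])
    p0, p1 = posterior_decision_prob(lik1, lik2, priors)
    assert p1 == pytest.approx(ndtr(d / np.sqrt(2 * v)), abs=1e-12)


def test_posterior_decision_matches_grid_integral(exp3):
    """Mixture-posterior P(t1 > t2) agrees with a dense-grid double integral
    to 1e-6 (single prior restricted to a 2-component mixture)."""
    priors = O.Priors("single", 0.25, np.array([np.log(400.0)]),
                      np.array([1.0]), np.array([np.log(800.0)]),
                      np.array([1.0]))
    for y1, y2, t1, t2 in [(6.2, 6.4, 0.2, 0.24), (6.5, 6.0, 0.3, 0.2),
                           (5.9, 6.6, 0.25, 0.35)]:
        p0 = float(p_first_longer(y1, y2, t1, t2, priors))
        ref = grid_p_first_longer(y1, t1, y2, t2, priors)
        assert p0 == pytest.approx(ref, abs=1e-6)


def test_numpy_and_kernel_decision_functions_agree(exp3):
    from durcue import _kernels as K
    rng = np.random.default_rng(3)
    for kind in ("single", "double"):
        priors = build_priors(exp3, kind, 0.3)
        y1 = rng.uniform(4.5, 7.5, 50)
        y2 = rng.uniform(4.5, 7.5, 50)
        t1 = rng.uniform(0.1, 0.5, 50)
        t2 = rng.uniform(0.1, 0.5, 50)
        ref = p_first_longer(y1, y2, t1, t2, priors)
        code, mu_a, lw_a, mu_b, lw_b, kap = O._prior_arrays(priors)
        out = K.pd0_points(y1, y2, t1, t2, code, mu_a, lw_a, mu_b, lw_b, kap)
        np.testing.assert_allclose(out, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# choice probabilities

def test_choice_probability_flat_closed_form(exp3):
    """H-vs-H, flat prior, no decay: choice probability equals the probit
    closed form Phi(delta / (sigma * sqrt(2)))."""
    model = ModelSpec("weighting", "no_decay", "flat")
    params = ObserverParams(b_H=0.0, b_L=0.0, sigma_H=0.2, sigma_L=0.24,
                            w_H=0.5, lapse=0.0)
    priors = build_priors(exp3, "flat", None)
    delta = 0.2
    trial = cell("HvsH", "r-c", "H", "H", 600.0 * np.exp(delta))
    p = choice_probability(trial, model, params, priors)
    assert p == pytest.approx(ndtr(delta / (0.2 * np.sqrt(2))), abs=1e-9)
    # exchangeable case
    trial0 = cell("HvsH", "r-c", "H", "H", 600.0)
    assert choice_probability(trial0, model, params, priors) == pytest.approx(0.5)


def test_optimal_equals_weighting_at_wstar(exp3):
    """The optimal-integration rule is the weighting rule at
    w* = sigma_L^2 / (sigma_H^2 + sigma_L^2) with the precision-combined SD."""
    priors = build_priors(exp3, "double", 0.3)
    cells = pd.DataFrame([cell("HvsHL", "r-c", "HL", "H", 420.0),
                          cell("LvsHL", "c-r", "HL", "L", 820.0),
                          cell("HLvsHL", "r-c", "HL", "HL", 600.0),
                          cell("HLvsHL", "c-r", "HL", "HL", 260.0)])
    for sH, sL, m in [(0.2, 0.24, 1.5), (0.3, 0.18, 1.2), (0.25, 0.25, 2.0)]:
        wstar = optimal_weight(sH, sL)
        po = choice_prob_cells(cells, ModelSpec("optimal_integration", "decay", "double"),
                               ObserverParams(b_H=0.25, b_L=-0.12, sigma_H=sH,
                                              sigma_L=sL, m=m, kappa=0.3),
                               priors)
        pw = choice_prob_cells(cells, ModelSpec("weighting", "decay", "double"),
                               ObserverParams(b_H=0.25, b_L=-0.12, sigma_H=sH,
                                              sigma_L=sL, w_H=wstar, m=m,
                                              kappa=0.3),
                               priors)
        np.testing.assert_allclose(po, pw, atol=1e-8)


def test_choice_probability_bounds_and_monotone(exp3, best_model, best_params):
    priors = build_priors(exp3, "double", best_params.kappa)
    durs = np.array([100.0, 260.0, 420.0, 600.0, 780.0, 940.0, 1100.0])
    cells_ = pd.DataFrame([cell("HvsHL", "r-c", "HL", "H", d) for d in durs])
    p = choice_prob_cells(cells_, best_model, best_params, priors)
    lam = best_params.lapse
    assert np.all(p >= lam / 2 - 1e-12) and np.all(p <= 1 - lam / 2 + 1e-12)
    # flat-prior model: strictly increasing in the second duration
    flat = ModelSpec("weighting", "no_decay", "flat")
    fp = ObserverParams(b_H=0.25, b_L=-0.12, sigma_H=0.2, sigma_L=0.24,
                        w_H=0.7, lapse=0.05)
    pf = choice_prob_cells(cells_, flat, fp, build_priors(exp3, "flat", None))
    assert np.all(np.diff(pf) > 0)


def test_order_swap_mirror_for_flat_no_decay(exp3):
    """(no_decay, flat): swapping display order mirrors the probability."""
    model = ModelSpec("selection", "no_decay", "flat")
    params = ObserverParams(b_H=0.25, b_L=-0.12, sigma_H=0.2, sigma_L=0.24,
                            c_H=0.6, lapse=0.04)
    priors = build_priors(exp3, "flat", None)
    for d in (180.0, 600.0, 900.0):
        p_rc = choice_probability(cell("HvsHL", "r-c", "HL", "H", d),
                                  model, params, priors)
        p_cr = choice_probability(cell("HvsHL", "c-r", "HL", "H", d),
                                  model, params, priors)
        assert p_rc == pytest.approx(1.0 - p_cr, abs=1e-12)


def test_exact_and_interp_paths_agree(exp3, best_model, best_params):
    priors = build_priors(exp3, "double", best_params.kappa)
    cells_ = exp3.trials.drop_duplicates(subset=O.CELL_KEYS)[O.CELL_KEYS]
    cells_ = cells_.reset_index(drop=True)
    pe = choice_prob_cells(cells_, best_model, best_params, priors,
                           method="exact")
    pi = choice_prob_cells(cells_, best_model, best_params, priors,
                           method="interp", check_monotone=False)
    assert np.abs(pe - pi).max() < 5e-5


def test_choice_probability_matches_monte_carlo(exp3):
    """Quadrature choice probability vs simulation of the full generative +
    inference process (a scaled-down version of the acceptance check)."""
    from durcue.schedules import Schedule, simulate_responses
    model = ModelSpec("selection", "decay", "double")
    params = O.default_observer(model)
    priors = build_priors(exp3, "double", params.kappa)
    reps = 20000
    picks = [cell("HvsHL", "c-r", "HL", "H", 460.0),
             cell("HLvsHL", "r-c", "HL", "HL", 820.0),
             cell("LvsH", "r-c", "H", "L", 300.0)]
    sub = pd.DataFrame(picks)
    p_model = choice_prob_cells(sub, model, params, priors, method="exact")
    rows = sub.loc[sub.index.repeat(reps)].reset_index(drop=True)
    rows["experiment_id"] = "exp3"
    rows["response"] = None
    simmed = simulate_responses(Schedule(rows, "exp3", 0), model, params,
                                seed=13, priors=priors).trials
    emp = (simmed["response"] == "second_longer").to_numpy()
    emp = emp.reshape(len(sub), reps).mean(axis=1)
    se = np.sqrt(p_model * (1 - p_model) / reps)
    assert np.all(np.abs(emp - p_model) <= 3 * se)


def order_curves(model, params, priors, ref_type, comp_type, durs):
    """P(comparison judged longer) per order of display."""
    rc = pd.DataFrame([cell("c", "r-c", ref_type, comp_type, d) for d in durs])
    cr = pd.DataFrame([cell("c", "c-r", ref_type, comp_type, d) for d in durs])
    p_rc = choice_prob_cells(rc, model, params, priors, method="exact")
    p_cr = choice_prob_cells(cr, model, params, priors, method="exact")
    return p_rc, 1.0 - p_cr  # comparison judged longer in each order


def test_no_decay_models_show_no_order_effect(exp3):
    durs = np.array([180.0, 340.0, 500.0, 600.0, 740.0, 900.0, 1060.0])
    for prior in ("flat", "single", "double"):
        model = ModelSpec("weighting", "no_decay", prior)
        params = O.default_observer(model)
        priors = build_priors(exp3, prior, params.kappa)
        a, b = order_curves(model, params, priors, "HL", "H", durs)
        tol = 1e-12 if prior == "flat" else 1e-3  # quadrature asymmetry
        assert np.abs(a - b).max() < tol


def test_decay_double_gives_steeper_reference_first_curve(exp3):
    """decay + double priors: the psychometric curve is steeper (smaller
    fitted probit sigma) when the reference is shown first."""
    from scipy.optimize import curve_fit
    model = ModelSpec("weighting", "decay", "double")
    params = O.default_observer(model)
    priors = build_priors(exp3, "double", params.kappa)
    durs = np.linspace(np.log(150), np.log(1050), 15)
    a, b = order_curves(model, params, priors, "H", "H", np.exp(durs))

    def probit(t, b0, s):
        return ndtr((t + b0 - LOG_REF) / s)

    (_, s_rc), _ = curve_fit(probit, durs, a, p0=(0.0, 0.3))
    (_, s_cr), _ = curve_fit(probit, durs, b, p0=(0.0, 0.3))
    assert s_rc < s_cr
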