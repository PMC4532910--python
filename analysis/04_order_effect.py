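#!/usr/bin/env python
"""Predicted psychometric curves per display order for key model classes.

Shows that only models combining memory decay with a non-flat prior predict
a steeper curve when the reference is shown first (the time-order effect);
no-decay models predict coincident curves.  Writes the predicted curves and
fitted probit slopes under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import ndtr

from durcue import ModelSpec, build_priors
from durcue.observer import LOG_REF, choice_prob_cells, default_observer
from durcue.schedules import build_schedule_exp3

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def probit(t, b0, s):
    return ndtr((t + b0 - LOG_REF) / s)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    schedule = build_schedule_exp3(SEED)
    durs = np.linspace(np.log(150.0), np.log(1050.0), 19)
    specs = [ModelSpec("weighting", "decay", "double"),
             ModelSpec("weighting", "decay", "single"),
             ModelSpec("weighting", "no_decay", "double"),
             ModelSpec("weighting", "no_decay", "flat")]
    curves, slopes = [], []
    for spec in specs:
        params = default_observer(spec)
        priors = build_priors(schedule, spec.prior, params.kappa)
        for order in ("r-c", "c-r"):
            cells = pd.DataFrame([
                dict(condition="HvsH", order=order, ref_type="H",
                     comp_type="H", ref_duration_ms=600.0,
                     comp_duration_ms=float(np.exp(t))) for t in durs])
            p = choice_prob_cells(cells, spec, params, priors,
                                  method="exact")
            p_comp = p if order == "r-c" else 1.0 - p
            (_, s), _ = curve_fit(probit, durs, p_comp, p0=(0.0, 0.3))
            slopes.append({"model": spec.name, "order": order,
                           "probit_sigma": float(s)})
            for t, pi in zip(durs, p_comp):
                curves.append({"model": spec.name, "order": order,
                               "log_comp": float(t),
                               "p_comp_longer": float(pi)})
    pd.DataFrame(curves).to_csv(OUT / "order_effect_curves.csv", index=False)
    tab = pd.DataFrame(slopes)
    tab.to_csv(OUT / "order_effect_slopes.csv", index=False)
    wide = tab.pivot(index="model", columns="order", values="probit_sigma")
    wide["order_effect"] = wide["c-r"] - wide["r-c"]
    print(wide.round(4).to_string())
    print("\npositive order_effect = steeper curve with the reference "
          "shown first; only decay + non-flat-prior models show it")


if __name__ == "__main__":
    main()
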