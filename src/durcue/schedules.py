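"""Trial schedules and response simulation for the duration-discrimination task.

Three two-alternative forced-choice (2AFC) experiments share a common design: on
every trial a *reference* stimulus of 600 ms and a *comparison* stimulus of one
of 26 durations (100--1100 ms in 40 ms steps) are shown in sequence, and the
observer reports whether the second stimulus lasted longer.  Stimuli are
drifting Gabor patches of high (H, 6 Hz) or low (L, 1 Hz) temporal frequency,
or a simultaneous pair (HL).  Over a session the comparison durations follow a
fixed incidence list approximating a Gaussian centred on 600 ms (SD 300 ms).

This module generates those schedules exactly (integer incidence counts) and
simulates responses from any observer model, so the downstream fitting and
model-comparison stages can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

REFERENCE_MS = 600
COMPARISON_DURATIONS_MS = tuple(range(100, 1101, 40))  # 26 levels

#: per order of display, per condition (sum 90; two orders -> 180 trials/condition)
INCIDENCE_EXP1 = (1, 2, 2, 2, 3, 3, 4, 4, 4, 5, 5, 5, 5, 5, 5, 5, 5,
                  4, 4, 4, 3, 3, 2, 2, 2, 1)
#: per condition, single order of display (sum 148)
INCIDENCE_EXP2 = (2, 2, 4, 4, 4, 6, 6, 6, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8,
                  6, 6, 6, 4, 4, 4, 2, 2)
#: per order of display, per condition, over all three sessions (sum 114)
INCIDENCE_EXP3 = (3,) * 7 + (6,) * 12 + (3,) * 7

#: (condition label, reference type, comparison type)
CONDITIONS_EXP1 = (("LvsH", "H", "L"), ("HvsL", "L", "H"))
CONDITIONS_EXP2 = (("LvsHL", "HL", "L"), ("HvsHL", "HL", "H"),
                   ("HLvsHL", "HL", "HL"))
CONDITIONS_EXP3 = (("HvsH", "H", "H"), ("LvsH", "H", "L"),
                   ("HvsL", "L", "H"), ("LvsL", "L", "L"),
                   ("HvsHL", "HL", "H"), ("LvsHL", "HL", "L"),
                   ("HLvsHL", "HL", "HL"))

TRIAL_COLUMNS = ["experiment_id", "condition", "ref_type", "comp_type",
                 "order", "ref_duration_ms", "comp_duration_ms", "response"]

RESPONSE_LONGER = "second_longer"
RESPONSE_SHORTER = "second_shorter"


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial; ``response`` is None on schedule-only records."""

    experiment_id: str
    condition: str
    ref_type: str
    comp_type: str
    order: str                      # "r-c" (reference first) or "c-r"
    ref_duration_ms: float
    comp_duration_ms: float
    response: str | None = None


@dataclass
class Schedule:
    """An ordered trial table plus the seed that shuffled it.

    ``trials`` is a DataFrame with the columns of :data:`TRIAL_COLUMNS`
    (plus a ``session`` annotation for Experiment 3, which no analysis uses).
    """

    trials: pd.DataFrame
    experiment_id: str
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def records(self):
        for row in self.trials.itertuples(index=False):
            yield TrialRecord(row.experiment_id, row.condition, row.ref_type,
                              row.comp_type, row.order,
                              row.ref_duration_ms, row.comp_duration_ms,
                              None if pd.isna(row.response) else row.response)

    def comparison_counts(self) -> pd.Series:
        """Incidence of each comparison duration over the whole schedule."""
        return (self.trials["comp_duration_ms"].value_counts().sort_index())


def _expand(experiment_id: str, conditions, incidence, orders, session_split=1):
    rows = []
    for cond, ref_type, comp_type in conditions:
        for order in orders:
            for dur, count in zip(COMPARISON_DURATIONS_MS, incidence):
                per_session, rem = divmod(count, session_split)
                assert rem == 0, "incidence must divide evenly across sessions"
                for session in range(1, session_split + 1):
                    for _ in range(per_session):
                        rows.append((experiment_id, cond, ref_type, comp_type,
                                     order, float(REFERENCE_MS), float(dur),
                                     None, session))
    frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS + ["session"])
    return frame


def _shuffled(frame: pd.DataFrame, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(frame))  # Fisher-Yates under the hood
    return frame.iloc[perm].reset_index(drop=True)


def build_schedule_exp1(seed: int) -> Schedule:
    """Experiment 1: conditions LvsH and HvsL, both display orders.

    Per order of display the 26 comparison durations occur with the printed
    incidence list (sum 90), giving 180 trials per condition.
    """
    frame = _expand("exp1", CONDITIONS_EXP1, INCIDENCE_EXP1, ("r-c", "c-r"))
    return Schedule(_shuffled(frame, seed), "exp1", seed)


def build_schedule_exp2(seed: int) -> Schedule:
    """Experiment 2: HL reference shown first on every trial; 148 trials per
    condition (LvsHL, HvsHL, HLvsHL)."""
    frame = _expand("exp2", CONDITIONS_EXP2, INCIDENCE_EXP2, ("r-c",))
    return Schedule(_shuffled(frame, seed), "exp2", seed)


def build_schedule_exp3(seed: int) -> Schedule:
    """Experiment 3: seven conditions crossing reference type {H, L, HL} with
    comparison type {H, L} (plus HLvsHL), both display orders, 228 trials per
    condition.  The three experimental sessions are flattened into one
    schedule; a ``session`` column is kept as an annotation only."""
    frame = _expand("exp3", CONDITIONS_EXP3, INCIDENCE_EXP3, ("r-c", "c-r"),
                    session_split=3)
    return Schedule(_shuffled(frame, seed), "exp3", seed)


BUILDERS = {"exp1": build_schedule_exp1, "exp2": build_schedule_exp2,
            "exp3": build_schedule_exp3}


def simulate_responses(schedule: Schedule, model, params, seed: int,
                       priors=None) -> Schedule:
    """Simulate an observer's responses on every trial of ``schedule``.

    Sensory measurements are drawn from the generative model (the SD of the
    first stimulus's measurement is inflated by ``m`` under decay models), the
    model's inference rule maps the measurements to a decision, and with
    probability ``lapse`` the decision is replaced by a fair coin flip.
    Deterministic given ``seed``.  The observer's priors default to the ones
    learned from ``schedule`` itself; pass ``priors`` to override (e.g. when
    simulating replications of a subset of trials).
    """
    from . import observer  # local import to avoid a cycle

    observer.validate_params(model, params)
    if priors is None:
        priors = observer.build_priors(schedule, model.prior, params.kappa)
    rng = np.random.default_rng(seed)
    frame = schedule.trials

    n = len(frame)
    ref_first = (frame["order"] == "r-c").to_numpy()
    t1_ms = np.where(ref_first, frame["ref_duration_ms"],
                     frame["comp_duration_ms"]).astype(float)
    t2_ms = np.where(ref_first, frame["comp_duration_ms"],
                     frame["ref_duration_ms"]).astype(float)
    type1 = np.where(ref_first, frame["ref_type"], frame["comp_type"])
    type2 = np.where(ref_first, frame["comp_type"], frame["ref_type"])

    y = np.empty((2, n))
    tau = np.empty((2, n))
    for pos, (types, t_ms) in enumerate([(type1, t1_ms), (type2, t2_ms)]):
        t_log = np.log(t_ms)
        scale = params.decay_scale(model, position="first" if pos == 0 else "second")
        for stim in ("H", "L", "HL"):
            mask = types == stim
            if not mask.any():
                continue
            t = t_log[mask]
            k = mask.sum()
            if stim == "HL":
                x_h = rng.normal(t + params.b_H, params.sigma_H * scale)
                x_l = rng.normal(t + params.b_L, params.sigma_L * scale)
                y_m, tau_m = observer.reduce_hl(model, params, x_h, x_l,
                                                scale, rng)
            else:
                b = params.b_H if stim == "H" else params.b_L
                s = (params.sigma_H if stim == "H" else params.sigma_L) * scale
                y_m = rng.normal(t + b, s)
                tau_m = np.full(k, s)
            y[pos, mask] = y_m
            tau[pos, mask] = tau_m

    p_d0 = observer.p_first_longer(y[0], y[1], tau[0], tau[1], priors)
    second_longer = p_d0 <= 0.5  # ties resolved as "second longer"
    lapse = rng.random(n) < params.lapse
    coin = rng.random(n) < 0.5
    second_longer = np.where(lapse, coin, second_longer)

    out = frame.copy()
    out["response"] = np.where(second_longer, RESPONSE_LONGER, RESPONSE_SHORTER)
    return replace(schedule, trials=out)
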