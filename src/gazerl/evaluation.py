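"""Posterior-predictive checks and descriptive analyses.

Given fitted parameters and a participant's trial table, this module
produces the standard diagnostics for gaze-constrained RL-LBA models:
trial-by-trial choice-prediction accuracy from repeated simulation,
learning curves, gaze-quintile effects on accuracy and RT, transfer-test
categorization (congruent / neutral / incongruent pairs), and parameter
recovery reporting for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import learning
from .gaze import quintile_bins
from .inference import DESettings, Params, fit_map, sample_prior
from .lba import RT_WINDOW, simulate_trials
from .linking import PARAM_NAMES, drift_rates, get_model

__all__ = [
    "PredictionReport",
    "predict_choices",
    "learning_curves",
    "gaze_effect_curves",
    "transfer_report",
    "recovery_report",
    "parameter_recovery",
]


@dataclass(frozen=True)
class PredictionReport:
    """Trial-level simulation-based choice predictions and their accuracy.

    ``per_trial`` has one row per evaluated trial with the simulated
    proportion of correct (value-maximizing) choices and whether the
    prediction agreed with the participant's actual choice. ``accuracy`` is
    the mean agreement; ``breakdown`` splits it into four cells by whether
    the participant chose correctly and whether they gazed longer at the
    correct option.
    """

    per_trial: pd.DataFrame
    accuracy: float
    breakdown: pd.DataFrame
    n_sim: int


def _correct_option(avail, evs):
    a, b = avail
    if evs[a] == evs[b]:
        return None
    return a if evs[a] > evs[b] else b


def predict_choices(
    trials,
    params: Params,
    model,
    evs: Mapping[str, float],
    n_sim: int = 100,
    seed: Optional[int] = None,
    rt_window=RT_WINDOW,
    global_mode: str = "running",
) -> PredictionReport:
    """Simulation-based one-step choice prediction for every trial.

    Each trial is simulated ``n_sim`` times with the participant's *actual*
    gaze vector and the value trajectory driven by the participant's actual
    feedback (with full feedback the trajectory is choice-independent). A
    trial's prediction is scored correct iff the participant chose the
    value-maximizing option and the simulated proportion of maximizing
    choices exceeds 0.5, or the participant erred and the proportion is
    below 0.5; a proportion of exactly 0.5 satisfies neither clause and
    counts as a miss. Equal-EV trials have no defined correct option and are
    excluded.
    """
    model = get_model(model)
    trials = list(trials)
    for tr in trials:
        if not tr.gaze:
            raise ValueError(f"trial {tr.trial} has no recorded gaze")
    rng = np.random.default_rng(seed)
    rp = params.race()
    traj = learning.run_learning(trials, params.learn(), global_mode=global_mode)

    rows = []
    for t, tr in enumerate(trials):
        corr = _correct_option(tr.avail, evs)
        if corr is None:
            continue
        ci = tr.avail.index(corr)
        q = np.array([traj[t].q[o] for o in tr.avail])
        g = np.array([tr.gaze.get(o, 0.0) for o in tr.avail])
        ds = drift_rates(model, q, g, params)
        choices, _ = simulate_trials(ds.v, rp, rng, n=n_sim, rt_window=rt_window)
        p_corr = float(np.mean(choices == ci))
        was_correct = tr.choice == corr
        predicted = (was_correct and p_corr > 0.5) or ((not was_correct) and p_corr < 0.5)
        gi = float(g[ci] - g[1 - ci])
        rows.append({
            "trial": tr.trial, "phase": tr.phase,
            "participant_correct": was_correct,
            "gazed_correct": gi > 0,
            "gaze_diff": gi,
            "sim_p_correct": p_corr,
            "predicted": bool(predicted),
        })
    per_trial = pd.DataFrame(rows)
    accuracy = float(per_trial["predicted"].mean()) if len(per_trial) else float("nan")
    breakdown = (
        per_trial.groupby(["participant_correct", "gazed_correct"])["predicted"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "accuracy", "count": "n"})
        .reset_index()
    )
    return PredictionReport(per_trial=per_trial, accuracy=accuracy, breakdown=breakdown, n_sim=n_sim)


def _trial_frame(trials, evs) -> pd.DataFrame:
    rows = []
    for tr in trials:
        corr = _correct_option(tr.avail, evs)
        row = {
            "participant": tr.participant, "phase": tr.phase, "trial": tr.trial,
            "rt_ms": tr.rt_ms, "correct_id": corr,
            "accuracy": np.nan if corr is None else float(tr.choice == corr),
        }
        if corr is not None and len(tr.avail) == 2:
            gi = tr.gaze.get(corr, 0.0)
            go = tr.gaze.get(tr.avail[1 - tr.avail.index(corr)], 0.0)
            row["gaze_diff"] = gi - go
        else:
            row["gaze_diff"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def learning_curves(trial_tables: Sequence, evs: Mapping[str, float], phase: str = "learning") -> pd.DataFrame:
    """Mean accuracy and RT per trial index, aggregated over participants.

    ``trial_tables`` is an iterable of per-participant trial-record lists
    (observed or model-simulated — pass simulated tables through the same
    function to overlay model curves). SEM is computed over participants.
    """
    frames = [_trial_frame([tr for tr in tt if tr.phase == phase], evs) for tt in trial_tables]
    df = pd.concat(frames, ignore_index=True)
    per = df.groupby(["participant", "trial"]).agg(
        accuracy=("accuracy", "mean"), rt_ms=("rt_ms", "mean")
    ).reset_index()
    g = per.groupby("trial")
    out = g.agg(
        accuracy=("accuracy", "mean"),
        accuracy_sem=("accuracy", "sem"),
        rt_ms=("rt_ms", "mean"),
        rt_sem=("rt_ms", "sem"),
        n=("accuracy", "count"),
    ).reset_index()
    return out


def gaze_effect_curves(trial_tables: Sequence, evs: Mapping[str, float], phase: str = "learning") -> pd.DataFrame:
    """Accuracy and mean RT per gaze-difference quintile.

    The correct-minus-incorrect gaze difference is binned into five
    equal-size quintiles separately for each participant; cell means are
    then averaged over participants (SEM over participants). The per-
    participant difference between the 5th and 1st quintile's accuracy is
    the individual "gaze effect" statistic, returned in ``attrs``.
    """
    per_rows = []
    effects = {}
    for tt in trial_tables:
        df = _trial_frame([tr for tr in tt if tr.phase == phase], evs)
        df = df.dropna(subset=["gaze_diff", "accuracy"])
        if len(df) < 5:
            raise ValueError(
                f"participant {df['participant'].iloc[0] if len(df) else '?'} has "
                "fewer than 5 scored trials"
            )
        df = df.reset_index(drop=True)
        df["quintile"] = quintile_bins(df["gaze_diff"].to_numpy())
        per = df.groupby("quintile").agg(
            accuracy=("accuracy", "mean"), rt_ms=("rt_ms", "mean")
        ).reset_index()
        per["participant"] = df["participant"].iloc[0]
        per_rows.append(per)
        acc = per.set_index("quintile")["accuracy"]
        if 1 in acc.index and 5 in acc.index:
            effects[df["participant"].iloc[0]] = float(acc[5] - acc[1])
    allper = pd.concat(per_rows, ignore_index=True)
    out = allper.groupby("quintile").agg(
        accuracy=("accuracy", "mean"),
        accuracy_sem=("accuracy", "sem"),
        rt_ms=("rt_ms", "mean"),
        rt_sem=("rt_ms", "sem"),
        n=("accuracy", "count"),
    ).reset_index()
    out.attrs["gaze_effects"] = effects
    return out


def categorize_transfer(pair, evs: Mapping[str, float], ranks: Mapping[str, int]):
    """Label a transfer pair C / N++ / N-- / I from within-context ranks.

    The correct option is the one with the higher absolute EV. Congruent
    (C): the correct option also had the higher relative rank in its
    original context; Incongruent (I): the correct option had the lower
    rank; N++ / N--: both options were the better / worse members of their
    contexts. Equal-EV pairs have no defined correct option (label None).
    """
    corr = _correct_option(pair, evs)
    if corr is None:
        r = (ranks[pair[0]], ranks[pair[1]])
        return None, ("N++" if r == (1, 1) else "N--" if r == (0, 0) else None)
    inc = pair[1 - pair.index(corr)] if isinstance(pair, tuple) else [o for o in pair if o != corr][0]
    dr = ranks[corr] - ranks[inc]
    if dr == 1:
        return corr, "C"
    if dr == -1:
        return corr, "I"
    return corr, "N++" if ranks[corr] == 1 else "N--"


def transfer_report(
    transfer_trials,
    evs: Mapping[str, float],
    ranks: Mapping[str, int],
) -> pd.DataFrame:
    """Per-category accuracy and mean RT for the transfer test.

    Equal-EV pairs are excluded from accuracy (no defined correct option)
    but retained for RT. Categories: C, N++, N--, I.
    """
    rows = []
    for tr in transfer_trials:
        corr, cat = categorize_transfer(tuple(tr.avail), evs, ranks)
        if cat is None:
            continue
        rows.append({
            "participant": tr.participant, "category": cat, "rt_ms": tr.rt_ms,
            "accuracy": np.nan if corr is None else float(tr.choice == corr),
        })
    df = pd.DataFrame(rows)
    per = df.groupby(["participant", "category"]).agg(
        accuracy=("accuracy", "mean"), rt_ms=("rt_ms", "mean")
    ).reset_index()
    out = per.groupby("category").agg(
        accuracy=("accuracy", "mean"),
        accuracy_sem=("accuracy", "sem"),
        rt_ms=("rt_ms", "mean"),
        rt_sem=("rt_ms", "sem"),
        n=("accuracy", "count"),
    ).reindex(["C", "N++", "N--", "I"]).reset_index()
    return out


def recovery_report(true_params: Sequence[Params], fitted_params: Sequence[Params], names=None) -> pd.DataFrame:
    """Per-parameter Pearson correlations between generating and recovered values."""
    names = list(names or PARAM_NAMES)
    t = np.array([[getattr(p, n) for n in names] for p in true_params], dtype=float)
    f = np.array([[getattr(p, n) for n in names] for p in fitted_params], dtype=float)
    if t.shape != f.shape:
        raise ValueError("true and fitted parameter lists differ in length")
    rows = []
    for j, n in enumerate(names):
        tj, fj = t[:, j], f[:, j]
        if np.std(tj) == 0 or np.std(fj) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(tj, fj)[0, 1])
        rows.append({
            "param": n, "r": r,
            "true_mean": float(tj.mean()), "fitted_mean": float(fj.mean()),
            "rmse": float(np.sqrt(np.mean((fj - tj) ** 2))),
        })
    return pd.DataFrame(rows)


def parameter_recovery(
    n_agents: int,
    model,
    seed: int,
    de: Optional[DESettings] = None,
    design=None,
    gcfg=None,
    fixed: Optional[Mapping] = None,
    verbose: bool = False,
):
    """Full prior-predictive recovery protocol on a synthetic task.

    Draws ``n_agents`` parameter vectors from the priors (box-truncated),
    simulates each agent on the task (default: the 232-trial two-option
    design with learning and transfer phases), refits by MAP, and reports
    generating-versus-recovered correlations. Agents whose simulation cannot
    produce RTs inside the admissible window (pathological prior draws) are
    replaced by a fresh draw. Returns (report, true_params, fitted_params).
    """
    from .task import GazeGenConfig, build_design, generate_outcomes, simulate_agent

    model = get_model(model)
    de = de or DESettings()
    root = np.random.default_rng(seed)
    if design is None:
        design = build_design("exp2", seed=int(root.integers(2**31 - 1)))
    gcfg = gcfg or GazeGenConfig()

    true: List[Params] = []
    fitted: List[Params] = []
    draws = 0
    while len(true) < n_agents and draws < 5 * n_agents:
        draws += 1
        p = sample_prior(root, model=model, fixed=fixed)
        agent_seed = int(root.integers(2**31 - 1))
        try:
            outcomes = generate_outcomes(design, seed=agent_seed)
            trials = simulate_agent(
                design, outcomes, p, model, gcfg=gcfg, seed=agent_seed,
                participant=f"agent{len(true)}",
            )
            fit = fit_map(trials, model, de=de, seed=agent_seed, fixed=fixed)
        except (RuntimeError, ValueError):
            continue  # pathological draw; replace
        true.append(p)
        fitted.append(fit.params)
        if verbose:
            print(f"  agent {len(true)}/{n_agents} fitted", flush=True)
    if len(true) < n_agents:
        raise RuntimeError("too many pathological prior draws; could not assemble cohort")
    report = recovery_report(true, fitted, names=model.free_params)
    return report, true, fitted
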