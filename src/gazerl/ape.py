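"""Accumulative one-step-ahead prediction error (APE) model comparison.

APE scores a model by its ability to predict each next observation in a
participant's trial sequence given only the observations before it: the
model is refit to every growing prefix and charged the negative log
predictive density of the following (choice, RT) pair. Summing these terms
from a minimum prefix length ``n_min`` to the end of the sequence yields a
prequential out-of-sample score that never uses the future to predict the
past and penalizes complexity through a model's actual generalization
behavior rather than a parameter count. The model with the lowest APE
generalizes best.

Trials with RTs outside the admissible window count neither as training
observations nor as predicted observations, but their feedback still
advances the learner (the participant saw it). Models are compared across
participants with one-sample t-tests on per-participant APE differences
against the winning model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import DESettings, FitResult, fit_map, trial_logdensity
from .lba import RT_WINDOW
from .linking import get_model

__all__ = ["APEResult", "ape", "ape_compare"]


@dataclass(frozen=True)
class APEResult:
    """Per-step negative log predictive densities and their sum."""

    model_id: int
    participant: str
    terms: np.ndarray
    n_min: int
    n_obs: int
    fits: Optional[List[FitResult]] = None

    @property
    def total(self) -> float:
        return float(np.sum(self.terms))


def _step_seed(seed: int, step: int) -> int:
    # Deterministic per-step substream, kept below 2**31 for portability.
    return int(np.random.SeedSequence([seed, step]).generate_state(1)[0] % (2**31 - 1))


def ape(
    trials,
    model,
    n_min: int = 5,
    seed: int = 0,
    de: Optional[DESettings] = None,
    fixed: Optional[Mapping] = None,
    warm_start: bool = True,
    keep_fits: bool = False,
    rt_window=RT_WINDOW,
) -> APEResult:
    """Accumulative one-step-ahead prediction error of one model on one sequence.

    For each usable observation index i from ``n_min`` to N-1 (0-based: the
    prediction targets are observations n_min+1 .. N), the model is MAP-fit
    to the trial prefix ending at the i-th usable observation and evaluated
    on the log density of the next one, with the value trajectory propagated
    through every intervening trial's feedback. ``warm_start`` injects each
    step's optimum into the next step's initial population (the objective
    changes by a single trial between steps, so the previous optimum is an
    excellent seed).
    """
    model = get_model(model)
    trials = list(trials)
    de = de or DESettings()
    lo, hi = rt_window
    usable_pos = [k for k, tr in enumerate(trials) if lo <= tr.rt_ms <= hi]
    n_obs = len(usable_pos)
    if n_obs <= n_min:
        raise ValueError(f"need more than n_min={n_min} usable observations, got {n_obs}")

    participant = trials[0].participant if trials else "?"
    terms = []
    fits: List[FitResult] = []
    x0 = None
    for i in range(n_min, n_obs):
        prefix = trials[: usable_pos[i - 1] + 1]
        fit = fit_map(
            prefix, model, de=de, seed=_step_seed(seed, i),
            fixed=fixed, x0=x0, rt_window=rt_window,
        )
        if warm_start:
            x0 = fit.params
        target = usable_pos[i]
        ld = trial_logdensity(fit.params, trials, model, target)
        terms.append(-ld)
        if keep_fits:
            fits.append(fit)
    return APEResult(
        model_id=model.id, participant=participant,
        terms=np.asarray(terms), n_min=n_min, n_obs=n_obs,
        fits=fits if keep_fits else None,
    )


def ape_compare(results) -> pd.DataFrame:
    """Aggregate APE totals across participants and models.

    ``results`` is an iterable of :class:`APEResult` (or a DataFrame with
    columns participant, model_id, ape); every participant must have a score
    for every model. Returns one row per model with its mean APE, the mean
    difference from the winning (lowest-mean) model, and a one-sample t-test
    of that difference against zero. Degenerate comparisons (all differences
    identically zero) are flagged rather than tested.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            [{"participant": r.participant, "model_id": r.model_id, "ape": r.total} for r in results]
        )
    wide = df.pivot_table(index="participant", columns="model_id", values="ape")
    if wide.isna().any().any():
        missing = wide.isna().stack()
        bad = missing[missing].index.tolist()
        raise ValueError(f"unbalanced input: missing APE for (participant, model) {bad}")

    means = wide.mean(axis=0)
    winner = int(means.idxmin())
    rows = []
    for mid in wide.columns:
        diffs = (wide[mid] - wide[winner]).to_numpy()
        row = {
            "model_id": int(mid),
            "model": get_model(int(mid)).name,
            "mean_ape": float(means[mid]),
            "mean_diff": float(diffs.mean()),
            "is_winner": int(mid) == winner,
            "t": np.nan,
            "p": np.nan,
            "degenerate": False,
        }
        if int(mid) != winner:
            if diffs.size < 2 or np.allclose(diffs, 0.0):
                row["degenerate"] = True
            else:
                t, p = stats.ttest_1samp(diffs, 0.0)
                row["t"], row["p"] = float(t), float(p)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("mean_ape").reset_index(drop=True)
    out.attrs["winner"] = winner
    return out
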