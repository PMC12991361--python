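"""Delta-rule value learning with weighted range normalization.

Outcomes (points) are encoded as subjective rewards in [0, 1] by mixing two
range normalizations: a *global* one that anchors the outcome against the
minimum and maximum of everything observed so far, and a *local* one that
anchors it against the outcomes displayed on the current trial alone. The
mixing weight ``wrel`` interpolates between absolute (context-independent,
wrel = 0) and relative (fully context-dependent, wrel = 1) valuation.
Encoded rewards drive a standard delta rule; with full feedback every shown
option is updated each trial, so the learned trajectory does not depend on
the agent's own choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "QState",
    "LearnParams",
    "Q_INIT",
    "subjective_reward",
    "update_q",
    "run_learning",
]

#: Initial value estimate for every option.
Q_INIT = 0.5


@dataclass(frozen=True)
class LearnParams:
    """Learning rate and relative-encoding weight, both in [0, 1]."""

    alpha: float
    wrel: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if not (0.0 <= self.wrel <= 1.0):
            raise ValueError(f"wrel must be in [0,1], got {self.wrel}")


@dataclass(frozen=True)
class QState:
    """Per-option value estimates plus the running global outcome extremes."""

    q: dict
    global_min: float = np.inf
    global_max: float = -np.inf

    def observe(self, outcomes) -> "QState":
        """Fold a trial's outcomes into the global extremes."""
        xs = list(outcomes)
        if not xs:
            return self
        return replace(
            self,
            global_min=min(self.global_min, min(xs)),
            global_max=max(self.global_max, max(xs)),
        )


def _range_norm(x: float, lo: float, hi: float) -> float:
    # Degenerate range (first trial with identical outcomes, or a single
    # displayed value): midpoint keeps the encoding unbiased and continuous.
    if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo <= 0.0:
        return 0.5
    return (x - lo) / (hi - lo)


def subjective_reward(x: float, local_min: float, local_max: float, state: QState, wrel: float) -> float:
    """Encode an outcome as a weighted mix of global and local normalization.

    The caller must have already folded the current trial's outcomes into
    ``state`` (so the global extremes include them) and computed the local
    extremes over the outcomes displayed on the current trial.
    """
    g = _range_norm(x, state.global_min, state.global_max)
    l = _range_norm(x, local_min, local_max)
    return (1.0 - wrel) * g + wrel * l


def update_q(q_i: float, R: float, alpha: float) -> float:
    """One delta-rule step: move the estimate toward the encoded reward."""
    return q_i + alpha * (R - q_i)


def run_learning(trials, lp: LearnParams, q_init: float = Q_INIT, global_mode: str = "running"):
    """Run the learner over a chronological trial sequence.

    Parameters
    ----------
    trials
        Sequence of trial records. Each must expose ``phase`` ("learning" or
        "transfer"), ``shown`` (option ids displayed) and, for learning
        trials, ``outcomes`` (mapping option id -> points).
    lp
        Learning parameters.
    global_mode
        "running" (default): global extremes accumulate causally, so the
        value trajectory before trial t depends only on trials < t.
        "fixed": extremes are taken over the whole session's outcomes up
        front (retrospective normalization).

    Returns
    -------
    list of :class:`QState` of length ``len(trials) + 1``; element ``t`` is
    the state *before* trial ``t`` and the last element is the final state.
    """
    if global_mode not in ("running", "fixed"):
        raise ValueError(f"unknown global_mode {global_mode!r}")

    options = []
    for tr in trials:
        for oid in tr.shown:
            if oid not in options:
                options.append(oid)
    state = QState(q={oid: q_init for oid in options})

    if global_mode == "fixed":
        all_x = [x for tr in trials if tr.phase == "learning" for x in tr.outcomes.values()]
        if all_x:
            state = state.observe(all_x)

    trajectory = [state]
    for tr in trials:
        if tr.phase == "learning":
            try:
                xs = {oid: tr.outcomes[oid] for oid in tr.shown}
            except KeyError as e:
                raise ValueError(
                    f"learning trial {getattr(tr, 'trial', '?')} is missing an "
                    f"outcome for shown option {e.args[0]!r}"
                ) from None
            if global_mode == "running":
                state = state.observe(xs.values())
            lmin, lmax = min(xs.values()), max(xs.values())
            q = dict(state.q)
            for oid, x in xs.items():
                R = subjective_reward(x, lmin, lmax, state, lp.wrel)
                q[oid] = update_q(q[oid], R, lp.alpha)
            state = replace(state, q=q)
        trajectory.append(state)
    return trajectory
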