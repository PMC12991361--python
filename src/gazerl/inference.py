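"""MAP estimation of model parameters from a participant's trial sequence.

The objective is the log-posterior: the summed defective log-likelihood of
all usable (choice, RT) pairs under the race model — with drifts produced by
the chosen linking function from the deterministically propagated value
trajectory — plus independent, moderately informative priors:

    alpha ~ Beta(1.3, 3.7)        wrel ~ Beta(1.1, 1.1)
    beta_q, beta_gaze ~ Gamma(2, 0.5)      theta ~ Gamma(2, 20)
    A, b_sep ~ Gamma(6, 100)      t0 ~ Gamma(6, 30)

(Gammas in shape-scale parameterization; the nonnegative prior on the
threshold separation b_sep guarantees b = A + b_sep >= A.) The drift SD is
fixed at 0.1 and Q-values initialize at 0.5. Trials with RTs below 250 ms or
above 10 s are skipped in the likelihood but still advance the learner,
since their feedback was observed.

The search uses differential evolution over box constraints with an explicit
population (NP members), an early-stopping rule after a fixed number of
stagnant generations, and a bounded quasi-Newton polish. The likelihood is
evaluated for a whole candidate population at once (vectorized over both
candidates and trials), which is what makes the one-step-ahead model
comparison in :mod:`gazerl.ape` affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import learning
from .lba import DRIFT_SD, LOG_FLOOR, RT_WINDOW, RaceParams, defective_logpdf, trial_loglik
from .linking import PARAM_NAMES, ModelSpec, drift_rates, get_model

__all__ = [
    "Params",
    "DESettings",
    "FitResult",
    "BOUNDS",
    "PRIORS",
    "log_prior",
    "sample_prior",
    "sequence_loglik",
    "trial_logdensity",
    "fit_map",
]

#: Box constraints for the optimizer. Wide enough to cover the priors'
#: effective mass and empirically plausible estimates with large margins.
BOUNDS = {
    "alpha": (0.0, 1.0),
    "wrel": (0.0, 1.0),
    "beta_q": (0.0, 10.0),
    "beta_gaze": (0.0, 10.0),
    "theta": (0.0, 100.0),
    "A": (0.0, 3000.0),
    "b_sep": (0.0, 3000.0),
    "t0": (0.0, 1500.0),
}

#: Frozen prior distributions (Gamma in shape-scale parameterization).
PRIORS = {
    "alpha": stats.beta(1.3, 3.7),
    "wrel": stats.beta(1.1, 1.1),
    "beta_q": stats.gamma(2.0, scale=0.5),
    "beta_gaze": stats.gamma(2.0, scale=0.5),
    "theta": stats.gamma(2.0, scale=20.0),
    "A": stats.gamma(6.0, scale=100.0),
    "b_sep": stats.gamma(6.0, scale=100.0),
    "t0": stats.gamma(6.0, scale=30.0),
}


@dataclass(frozen=True)
class Params:
    """The full parameter vector; masked-out entries sit at neutral defaults."""

    alpha: float
    beta_q: float
    A: float
    b_sep: float
    t0: float
    wrel: float = 0.0
    beta_gaze: float = 0.0
    theta: float = 0.0
    s: float = DRIFT_SD

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if not (0.0 <= self.wrel <= 1.0):
            raise ValueError(f"wrel must be in [0,1], got {self.wrel}")
        for name in ("beta_q", "beta_gaze", "theta", "A", "b_sep", "t0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def b(self) -> float:
        return self.A + self.b_sep

    def race(self) -> RaceParams:
        return RaceParams.from_sep(self.A, self.b_sep, self.t0, self.s)

    def learn(self) -> learning.LearnParams:
        return learning.LearnParams(alpha=self.alpha, wrel=self.wrel)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "Params":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(x, dtype=float))))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class DESettings:
    """Differential-evolution budget and operators.

    ``popsize`` is the total population size (NP), ``itermax`` the maximum
    number of generations, and ``steptol`` the number of consecutive
    generations without improvement of the best member after which the
    search stops early.
    """

    popsize: int = 100
    itermax: int = 1000
    steptol: int = 250
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7
    tol: float = 1e-4
    polish: bool = True
    polish_maxiter: int = 200

    def scaled(self, factor: float) -> "DESettings":
        """A reduced-budget copy (population, generations, patience scaled)."""
        return DESettings(
            popsize=max(8, int(self.popsize * factor)),
            itermax=max(10, int(self.itermax * factor)),
            steptol=max(5, int(self.steptol * factor)),
            mutation=self.mutation,
            recombination=self.recombination,
            tol=self.tol,
            polish=self.polish,
            polish_maxiter=self.polish_maxiter,
        )


@dataclass(frozen=True)
class FitResult:
    """Point estimates and diagnostics from one MAP fit."""

    model_id: int
    params: Params
    log_posterior: float
    n_used: int
    n_skipped: int
    nit: int
    nfev: int
    seed: Optional[int]
    popsize: int
    message: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def log_prior(params, mask: Sequence[str]) -> float:
    """Sum of log prior densities over the masked-in (free) parameters.

    Values outside a prior's support yield ``-inf``. Parameters excluded
    from the mask contribute 0, so the prior never depends on them.
    """
    total = 0.0
    for name in mask:
        x = params[name] if isinstance(params, Mapping) else getattr(params, name)
        lp = PRIORS[name].logpdf(x)
        if not np.isfinite(lp):
            return -math.inf
        total += float(lp)
    return total


def sample_prior(rng: np.random.Generator, model=None, fixed: Optional[Mapping] = None) -> Params:
    """Draw one parameter vector from the priors (box-truncated).

    Draws are rejection-truncated to the optimizer's search box so that a
    generating vector in a recovery study is always reachable by the fit.
    Parameters outside the model's mask, and any in ``fixed``, are set to
    their fixed values (0 by default).
    """
    free = set(PARAM_NAMES if model is None else get_model(model).free_params)
    fixed = dict(fixed or {})
    vals = {}
    for name in PARAM_NAMES:
        if name in fixed:
            vals[name] = float(fixed[name])
        elif name in free:
            lo, hi = BOUNDS[name]
            for _ in range(1000):
                x = float(PRIORS[name].rvs(random_state=rng))
                if lo <= x <= hi:
                    break
            vals[name] = x
        else:
            vals[name] = 0.0
    return Params(**vals)


# ---------------------------------------------------------------------------
# Compiled trial sequence
# ---------------------------------------------------------------------------

class _SeqData:
    """Trial sequence compiled to flat arrays for the vectorized objective.

    The range-normalized encodings of every displayed outcome depend only on
    the data (the running or session-wide extremes), never on the candidate
    parameters, so they are precomputed once per sequence.
    """

    def __init__(self, trials, rt_window=RT_WINDOW, global_mode: str = "running"):
        self.trials = list(trials)
        T = len(self.trials)
        options: list = []
        for tr in self.trials:
            for oid in tr.shown:
                if oid not in options:
                    options.append(oid)
        self.options = options
        idx = {oid: i for i, oid in enumerate(options)}

        self.is_learning = np.array([tr.phase == "learning" for tr in self.trials])
        self.avail_idx = np.array(
            [[idx[o] for o in tr.avail] for tr in self.trials], dtype=np.intp
        ).reshape(T, -1)
        self.choice_pos = np.array(
            [tr.avail.index(tr.choice) for tr in self.trials], dtype=np.intp
        )
        self.rt = np.array([tr.rt_ms for tr in self.trials], dtype=float)
        self.gaze = np.array(
            [[tr.gaze.get(o, 0.0) for o in tr.avail] for tr in self.trials], dtype=float
        ).reshape(T, -1)
        lo, hi = rt_window
        self.usable = (self.rt >= lo) & (self.rt <= hi)

        self.shown_idx: list = []
        self.gnorm: list = []
        self.lnorm: list = []
        if global_mode == "fixed":
            all_x = [
                x for tr in self.trials if tr.phase == "learning"
                for x in tr.outcomes.values()
            ]
            gmin = min(all_x) if all_x else math.inf
            gmax = max(all_x) if all_x else -math.inf
        else:
            gmin, gmax = math.inf, -math.inf
        for tr in self.trials:
            if tr.phase != "learning":
                self.shown_idx.append(None)
                self.gnorm.append(None)
                self.lnorm.append(None)
                continue
            xs = np.array([tr.outcomes[o] for o in tr.shown], dtype=float)
            if global_mode == "running":
                gmin = min(gmin, xs.min())
                gmax = max(gmax, xs.max())
            self.shown_idx.append(np.array([idx[o] for o in tr.shown], dtype=np.intp))
            self.gnorm.append(_norm(xs, gmin, gmax))
            self.lnorm.append(_norm(xs, xs.min(), xs.max()))

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


def _norm(xs, lo, hi):
    if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo <= 0:
        return np.full_like(xs, 0.5)
    return (xs - lo) / (hi - lo)


def _batch_q_avail(seq: _SeqData, alpha: np.ndarray, wrel: np.ndarray) -> np.ndarray:
    """Pre-choice Q of the available options per trial, per candidate.

    Returns shape (P, T, K). Under full feedback the trajectory is driven
    only by the displayed outcomes, so it is deterministic given the data.
    """
    P = alpha.shape[0]
    T = len(seq.trials)
    Q = np.full((P, len(seq.options)), learning.Q_INIT)
    qa = np.empty((P, T, seq.avail_idx.shape[1]))
    a = alpha[:, None]
    w = wrel[:, None]
    for t in range(T):
        qa[:, t, :] = Q[:, seq.avail_idx[t]]
        sh = seq.shown_idx[t]
        if sh is not None:
            R = (1.0 - w) * seq.gnorm[t] + w * seq.lnorm[t]
            Q[:, sh] += a * (R - Q[:, sh])
    return qa


def _batch_objective(seq: _SeqData, model: ModelSpec, free: Sequence[str], fixed: Mapping):
    """Return f(theta_matrix) -> negative log-posterior per candidate row."""
    free = list(free)
    fixed = dict(fixed)
    needs_gaze = model.gaze_mode != "none"

    def fun(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        P = theta.shape[0]
        cols = {n: theta[:, i] for i, n in enumerate(free)}
        for n, vv in fixed.items():
            cols[n] = np.full(P, float(vv))
        for n in PARAM_NAMES:
            cols.setdefault(n, np.zeros(P))

        qa = _batch_q_avail(seq, cols["alpha"], cols["wrel"])
        pmap = {
            "beta_q": cols["beta_q"][:, None, None],
            "beta_gaze": cols["beta_gaze"][:, None, None],
            "theta": cols["theta"][:, None, None],
        }
        g = seq.gaze[None, :, :] if needs_gaze else np.zeros_like(qa)
        v = drift_rates(model, qa, g, pmap).v

        A = cols["A"][:, None]
        b = (cols["A"] + cols["b_sep"])[:, None]
        t0 = cols["t0"][:, None]
        ld = defective_logpdf(seq.rt[None, :], v, seq.choice_pos[None, :], A, b, t0, DRIFT_SD)
        ll = (ld * seq.usable[None, :]).sum(axis=1)

        lp = np.zeros(P)
        for n in free:
            lp += PRIORS[n].logpdf(cols[n])
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        out = -(ll + lp)
        return np.where(np.isfinite(out), out, 1e12)

    return fun


# ---------------------------------------------------------------------------
# Reference (scalar) likelihood path
# ---------------------------------------------------------------------------

def sequence_loglik(params: Params, trials, model, rt_window=RT_WINDOW, global_mode="running") -> float:
    """Summed log-likelihood of a trial sequence (readable reference path).

    Runs the learner forward, evaluates the linking function and the race
    likelihood trial by trial, and sums over usable trials (RT inside the
    window). Transfer trials contribute likelihood but no learning. An empty
    usable set gives 0. The vectorized engine used by :func:`fit_map` is
    checked against this composition in the test suite.
    """
    model = get_model(model)
    trials = list(trials)
    traj = learning.run_learning(trials, params.learn(), global_mode=global_mode)
    rp = params.race()
    lo, hi = rt_window
    total = 0.0
    for t, tr in enumerate(trials):
        if not (lo <= tr.rt_ms <= hi):
            continue
        q = np.array([traj[t].q[o] for o in tr.avail])
        g = np.array([tr.gaze.get(o, 0.0) for o in tr.avail])
        ds = drift_rates(model, q, g, params)
        total += trial_loglik(tr.avail.index(tr.choice), tr.rt_ms, ds, rp).log_density
    return total


def trial_logdensity(params: Params, trials, model, index: int, global_mode="running") -> float:
    """Log predictive density of trial ``index`` given all earlier trials.

    The value trajectory is propagated deterministically through trial
    ``index - 1`` (outcomes are data, available regardless of the model's
    own choices), then the (choice, RT) density of trial ``index`` is
    evaluated. Used as the one-step-ahead score in the APE comparison.
    """
    model = get_model(model)
    trials = list(trials)
    traj = learning.run_learning(trials[: index + 1], params.learn(), global_mode=global_mode)
    tr = trials[index]
    q = np.array([traj[index].q[o] for o in tr.avail])
    g = np.array([tr.gaze.get(o, 0.0) for o in tr.avail])
    ds = drift_rates(model, q, g, params)
    return trial_loglik(tr.avail.index(tr.choice), tr.rt_ms, ds, params.race()).log_density


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

class _Stagnation:
    """Stop the search after `patience` generations without improvement."""

    def __init__(self, patience: int, atol: float = 1e-8):
        self.patience = patience
        self.atol = atol
        self.best = math.inf
        self.stall = 0

    def __call__(self, intermediate_result):
        f = float(intermediate_result.fun)
        if f < self.best - self.atol:
            self.best = f
            self.stall = 0
        else:
            self.stall += 1
        if self.stall >= self.patience:
            raise StopIteration
        return False


def _init_population(rng, free, de: DESettings, x0=None):
    """NP-member initial population: prior draws plus uniform box coverage."""
    k = len(free)
    n = max(de.popsize, 5)
    pop = np.empty((n, k))
    lo = np.array([BOUNDS[f][0] for f in free])
    hi = np.array([BOUNDS[f][1] for f in free])
    n_prior = n // 2
    for j, name in enumerate(free):
        draws = PRIORS[name].rvs(size=n_prior, random_state=rng)
        pop[:n_prior, j] = np.clip(draws, lo[j], hi[j])
        pop[n_prior:, j] = rng.uniform(lo[j], hi[j], size=n - n_prior)
    if x0 is not None:
        pop[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    return pop


def _polish(fun, x0, free, maxiter):
    """Bounded L-BFGS-B refinement with batched central-difference gradients."""
    lo = np.array([BOUNDS[f][0] for f in free])
    hi = np.array([BOUNDS[f][1] for f in free])
    span = hi - lo
    eps = 1e-7 * span + 1e-10
    k = len(free)

    def scalar(x):
        return float(fun(x[None, :])[0])

    def grad(x):
        pts = np.repeat(x[None, :], 2 * k, axis=0)
        for i in range(k):
            pts[2 * i, i] = min(x[i] + eps[i], hi[i])
            pts[2 * i + 1, i] = max(x[i] - eps[i], lo[i])
        vals = fun(pts)
        g = np.zeros(k)
        for i in range(k):
            dx = pts[2 * i, i] - pts[2 * i + 1, i]
            g[i] = (vals[2 * i] - vals[2 * i + 1]) / dx if dx > 0 else 0.0
        return g

    return optimize.minimize(
        scalar, x0, jac=grad, method="L-BFGS-B",
        bounds=list(zip(lo, hi)), options={"maxiter": maxiter},
    )


def fit_map(
    trials,
    model,
    de: Optional[DESettings] = None,
    seed: Optional[int] = None,
    fixed: Optional[Mapping] = None,
    x0: Optional[Mapping] = None,
    rt_window=RT_WINDOW,
    global_mode: str = "running",
) -> FitResult:
    """MAP-fit a model to one participant's trial sequence.

    Parameters
    ----------
    trials
        Chronological trial records (learning and, optionally, transfer).
    model
        Model id, name, or :class:`~gazerl.linking.ModelSpec`.
    de
        Optimizer budget; defaults to :class:`DESettings` (NP = 100,
        itermax = 1000, steptol = 250).
    fixed
        Parameters to clamp rather than estimate, e.g. ``{"wrel": 0.0}``
        when a design cannot identify relative encoding.
    x0
        Optional warm start (mapping of parameter name -> value) injected
        into the initial population.
    """
    model = get_model(model)
    de = de or DESettings()
    fixed = dict(fixed or {})
    seq = _SeqData(trials, rt_window=rt_window, global_mode=global_mode)
    if seq.n_usable < 1:
        raise ValueError("no usable trials (all RTs outside the admissible window)")
    free = [n for n in model.free_params if n not in fixed]
    fun = _batch_objective(seq, model, free, fixed)

    rng = np.random.default_rng(seed)
    x0_vec = None
    if x0 is not None:
        x0_vec = np.array(
            [x0[n] if isinstance(x0, Mapping) else getattr(x0, n) for n in free], dtype=float
        )
    init = _init_population(rng, free, de, x0=x0_vec)

    def de_fun(x):
        # scipy's vectorized mode sends candidates as columns (N, S)
        x = np.asarray(x)
        if x.ndim == 1:
            return fun(x[None, :])[0]
        return fun(x.T)

    res = optimize.differential_evolution(
        de_fun,
        bounds=[BOUNDS[f] for f in free],
        init=init,
        maxiter=de.itermax,
        mutation=de.mutation,
        recombination=de.recombination,
        tol=de.tol,
        seed=rng,
        polish=False,
        vectorized=True,
        updating="deferred",
        callback=_Stagnation(de.steptol),
    )
    x_best, f_best, nit, nfev = res.x, float(res.fun), res.nit, res.nfev
    if de.polish:
        pres = _polish(fun, x_best, free, de.polish_maxiter)
        if np.isfinite(pres.fun) and pres.fun <= f_best:
            x_best, f_best = pres.x, float(pres.fun)
        nfev += int(pres.nfev) * (1 + 2 * len(free))
    if not np.isfinite(f_best) or f_best >= 1e12:
        raise RuntimeError("objective is non-finite everywhere the optimizer searched")

    vals = dict(zip(free, x_best))
    vals.update(fixed)
    params = Params(**{n: float(vals.get(n, 0.0)) for n in PARAM_NAMES})
    return FitResult(
        model_id=model.id,
        params=params,
        log_posterior=-f_best,
        n_used=seq.n_usable,
        n_skipped=len(seq.trials) - seq.n_usable,
        nit=int(nit),
        nfev=int(nfev),
        seed=seed,
        popsize=de.popsize,
        message=str(res.message),
    )
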