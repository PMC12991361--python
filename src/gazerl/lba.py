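"""Linear ballistic accumulator (LBA) race model.

Each available option has one independent accumulator. On a trial the
accumulator for option *i* starts at evidence level ``z_i ~ Uniform(0, A)``
and grows linearly at rate ``d_i ~ Normal(v_i, s)``. The first accumulator
to reach the threshold ``b`` determines the choice, and the response time is
the passage time of the winner plus a nondecision time ``t0``. Because the
accumulators are independent and linear, the first-passage density and
distribution function have closed forms, which makes the defective
likelihood of a (choice, RT) pair analytically tractable.

All times are in milliseconds and evidence is in arbitrary units; with
thresholds on the order of 10^3 and drift rates on the order of 10^-1, RTs
come out on the scale of seconds, matching human choice data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "RaceParams",
    "TrialLik",
    "LOG_FLOOR",
    "RT_WINDOW",
    "DRIFT_SD",
    "lba_pdf",
    "lba_cdf",
    "trial_loglik",
    "simulate_trial",
    "simulate_trials",
    "SimulationError",
]

#: Fixed drift-rate standard deviation (scaling convention of the model).
DRIFT_SD = 0.1

#: Per-trial log-density floor. Keeps the optimizer finite on observations
#: that are impossible under a candidate parameter vector (e.g. rt <= t0).
LOG_FLOOR = float(np.log(1e-29))

#: Admissible response-time window in ms; trials outside it are discarded
#: by the fitting routines and resampled by the simulator.
RT_WINDOW = (250.0, 10_000.0)

# Below this start-point range the uniform-start formulas lose precision and
# the analytic A -> 0 limit is used instead.
_A_MIN = 1e-6

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


def _npdf(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


class SimulationError(RuntimeError):
    """Raised when trial resampling cannot produce an RT inside the window."""


@dataclass(frozen=True)
class RaceParams:
    """Race-level parameters: start-point bound, threshold, nondecision time.

    The threshold is parameterized as ``b = A + b_sep`` upstream so that the
    start point can never exceed the threshold; this class stores the
    resolved ``b``.
    """

    A: float
    b: float
    t0: float
    s: float = DRIFT_SD

    def __post_init__(self):
        if not (0.0 <= self.A <= self.b):
            raise ValueError(f"require 0 <= A <= b, got A={self.A}, b={self.b}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")

    @classmethod
    def from_sep(cls, A: float, b_sep: float, t0: float, s: float = DRIFT_SD) -> "RaceParams":
        return cls(A=A, b=A + b_sep, t0=t0, s=s)


@dataclass(frozen=True)
class TrialLik:
    """Log of the defective density of one (choice, RT) observation."""

    log_density: float


# ---------------------------------------------------------------------------
# Analytic first-passage density / CDF of a single accumulator
# ---------------------------------------------------------------------------

def _pdf_cdf_arrays(t, v, A, b, s):
    """First-passage pdf and CDF, broadcasting over all arguments.

    ``t`` is decision time (> 0). Drifts follow the untruncated normal, so the
    distribution is defective: a fraction of races never terminate. The
    ``A -> 0`` limit (deterministic start point) is handled analytically.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)

    t, v, A, b, s = np.broadcast_arrays(t, v, A, b, s)
    ts = np.where(t > 0, t * s, 1.0)  # guarded; t <= 0 masked at the end

    small_A = A <= _A_MIN
    A_safe = np.where(small_A, 1.0, A)

    u1 = (b - A - t * v) / ts
    u2 = (b - t * v) / ts
    phi1, phi2 = _npdf(u1), _npdf(u2)
    Phi1, Phi2 = ndtr(u1), ndtr(u2)

    pdf_full = (-v * Phi1 + s * phi1 + v * Phi2 - s * phi2) / A_safe
    cdf_full = (
        1.0
        + (b - A - t * v) / A_safe * Phi1
        - (b - t * v) / A_safe * Phi2
        + ts / A_safe * (phi1 - phi2)
    )

    # A -> 0: passage time is b/d with d ~ N(v, s); P(T <= t) = P(d >= b/t).
    t_safe = np.where(t > 0, t, 1.0)
    z = (t * v - b) / ts
    pdf_zero = b / (s * t_safe * t_safe) * _npdf(z)
    cdf_zero = ndtr(z)

    pdf = np.where(small_A, pdf_zero, pdf_full)
    cdf = np.where(small_A, cdf_zero, cdf_full)

    invalid = ~(t > 0)
    pdf = np.where(invalid, 0.0, np.clip(pdf, 0.0, None))
    cdf = np.where(invalid, 0.0, np.clip(cdf, 0.0, 1.0))
    return pdf, cdf


def lba_pdf(t, v, rp: RaceParams):
    """First-passage density of a single accumulator at decision time ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0")
    pdf, _ = _pdf_cdf_arrays(t, v, rp.A, rp.b, rp.s)
    return pdf if pdf.ndim else float(pdf)


def lba_cdf(t, v, rp: RaceParams):
    """First-passage distribution function of a single accumulator."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0")
    _, cdf = _pdf_cdf_arrays(t, v, rp.A, rp.b, rp.s)
    return cdf if cdf.ndim else float(cdf)


# ---------------------------------------------------------------------------
# Defective trial likelihood
# ---------------------------------------------------------------------------

def defective_logpdf(rt, v, choice, A, b, t0, s=DRIFT_SD):
    """Log defective density of (choice, rt) for a K-accumulator race.

    Vectorized over leading axes: ``v`` has shape (..., K); ``rt``, ``choice``
    and the race parameters broadcast against the leading shape. Observations
    with ``rt <= t0`` — impossible under the candidate parameters — and
    numerically vanishing densities are floored at :data:`LOG_FLOOR`.
    """
    v = np.asarray(v, dtype=float)
    K = v.shape[-1]
    rt = np.asarray(rt, dtype=float)
    choice = np.asarray(choice)
    lead = np.broadcast_shapes(rt.shape, choice.shape, v.shape[:-1])

    t = np.broadcast_to(rt, lead) - np.broadcast_to(t0, lead)
    t_e = t[..., None]
    A_e = np.broadcast_to(np.asarray(A, dtype=float), lead)[..., None]
    b_e = np.broadcast_to(np.asarray(b, dtype=float), lead)[..., None]
    s_e = np.broadcast_to(np.asarray(s, dtype=float), lead)[..., None]
    v_e = np.broadcast_to(v, lead + (K,))

    pdf, cdf = _pdf_cdf_arrays(t_e, v_e, A_e, b_e, s_e)
    surv = np.clip(1.0 - cdf, 1e-300, None)
    logpdf = np.log(np.clip(pdf, 1e-300, None))
    logsurv = np.log(surv)

    c = np.broadcast_to(choice, lead)[..., None]
    log_f_choice = np.take_along_axis(logpdf, c, axis=-1)[..., 0]
    log_s_all = logsurv.sum(axis=-1)
    log_s_choice = np.take_along_axis(logsurv, c, axis=-1)[..., 0]

    out = log_f_choice + log_s_all - log_s_choice
    out = np.where(t > 0, out, LOG_FLOOR)
    return np.maximum(out, LOG_FLOOR)


def trial_loglik(choice: int, rt: float, drifts, rp: RaceParams) -> TrialLik:
    """Log-likelihood of one observed (choice, RT) pair under the race.

    ``drifts`` is anything exposing mean drift rates per available option
    (an array or an object with a ``v`` attribute and optional ``s``).
    """
    v = np.asarray(getattr(drifts, "v", drifts), dtype=float)
    s = float(getattr(drifts, "s", rp.s))
    ld = defective_logpdf(rt, v, int(choice), rp.A, rp.b, rp.t0, s)
    return TrialLik(log_density=float(ld))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    v,
    rp: RaceParams,
    rng: np.random.Generator,
    n: int = 1,
    rt_window=RT_WINDOW,
    max_attempts: int = 10_000,
):
    """Simulate ``n`` independent race trials; returns (choices, rts).

    Start points are uniform on [0, A]; drift rates are normal with negative
    draws reset to zero (a zero drift never reaches threshold). Trials whose
    RT falls outside ``rt_window`` are resampled, so the returned RTs are
    draws from the window-conditioned distribution, mirroring how overly fast
    or slow responses are excluded from analysis.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("v must be a 1-D array with at least one accumulator")
    lo, hi = rt_window
    choices = np.zeros(n, dtype=np.intp)
    rts = np.full(n, np.nan)
    pending = np.arange(n)
    for _ in range(max_attempts):
        m = pending.size
        if m == 0:
            break
        z = rng.uniform(0.0, rp.A, size=(m, v.size)) if rp.A > 0 else np.zeros((m, v.size))
        d = rng.normal(v, rp.s, size=(m, v.size))
        d = np.clip(d, 0.0, None)
        with np.errstate(divide="ignore"):
            times = np.where(d > 0, (rp.b - z) / np.where(d > 0, d, 1.0), np.inf)
        win = times.argmin(axis=1)
        tmin = times[np.arange(m), win]
        rt = rp.t0 + tmin
        ok = (rt >= lo) & (rt <= hi) & np.isfinite(rt)
        idx = pending[ok]
        choices[idx] = win[ok]
        rts[idx] = rt[ok]
        pending = pending[~ok]
    if pending.size:
        raise SimulationError(
            f"{pending.size} trial(s) produced no RT in {rt_window} after "
            f"{max_attempts} resampling attempts (drifts {v}, A={rp.A}, "
            f"b={rp.b}, t0={rp.t0})"
        )
    return choices, rts


def simulate_trial(drifts, rp: RaceParams, rng: np.random.Generator, rt_window=RT_WINDOW):
    """Simulate one race trial; returns (choice index, rt in ms)."""
    v = np.asarray(getattr(drifts, "v", drifts), dtype=float)
    c, t = simulate_trials(v, rp, rng, n=1, rt_window=rt_window)
    return int(c[0]), float(t[0])
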