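"""Linking functions: map Q-values and gaze onto mean drift rates.

The linking function is what joins the learning module to the race model.
Eight variants are provided, crossing (a) linear versus softmax integration
of Q-values and (b) no gaze effect, an additive gaze bonus independent of
value, or a multiplicative effect in which gaze amplifies value:

====  ===================  ========  =============================================
id    name                 gaze      mean drift rate for available option i
====  ===================  ========  =============================================
1     Q                    none      bQ * Q_i
2     Q*gaze               mult.     bQ * Q_i * (1 + bG * gaze_i)
3     Q+gaze               additive  bQ * Q_i + bG * gaze_i
4     softmax(Q)           none      bQ * softmax(th * Q)_i
5     softmax(Q*gaze)      mult.     bQ * softmax(th * Q * (1 + bG * gaze))_i
6     softmax(Q)*gaze      mult.     bQ * softmax(th * Q)_i * (1 + bG * gaze_i)
7     softmax(Q)+gaze      additive  bQ * softmax(th * Q)_i + bG * gaze_i
8     softmax(Q+gaze)      mult.     bQ * softmax(th * (Q + bG * gaze))_i
====  ===================  ========  =============================================

(bQ = beta_q, bG = beta_gaze, th = softmax inverse temperature.) Model 8
looks additive but the exponential inside the softmax turns the gaze term
into a multiplicative factor on the drift ratio, so it behaves as a
multiplicative gaze model whose gaze sensitivity scales with the product
theta * beta_gaze. The softmax is computed over the available options only,
which makes drifts depend on Q *differences* and keeps them positive.

Custom variants can be built by constructing a :class:`ModelSpec` with a
different ``link`` callable; ``model_registry`` returns the canonical eight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Union

import numpy as np

from .lba import DRIFT_SD

__all__ = ["ModelSpec", "DriftSpec", "drift_rates", "model_registry", "get_model", "MODELS"]

#: Canonical parameter order used throughout fitting.
PARAM_NAMES = ("alpha", "wrel", "beta_q", "beta_gaze", "theta", "A", "b_sep", "t0")


@dataclass(frozen=True)
class DriftSpec:
    """Mean drift rate per available option, plus the fixed drift SD."""

    v: np.ndarray
    s: float = DRIFT_SD


@dataclass(frozen=True)
class ModelSpec:
    """One linking-function variant with its free-parameter mask."""

    id: int
    name: str
    uses_softmax: bool
    gaze_mode: str  # none | additive | multiplicative
    free_params: tuple
    link: Callable

    def __post_init__(self):
        if self.gaze_mode not in ("none", "additive", "multiplicative"):
            raise ValueError(f"bad gaze_mode {self.gaze_mode!r}")
        if (self.gaze_mode == "none") == ("beta_gaze" in self.free_params):
            raise ValueError("beta_gaze must be free exactly when the model uses gaze")
        if self.uses_softmax != ("theta" in self.free_params):
            raise ValueError("theta must be free exactly for softmax models")


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max subtraction) along ``axis``."""
    x = np.asarray(x, dtype=float)
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _p(params, name):
    if isinstance(params, Mapping):
        if name not in params:
            raise KeyError(name)
        return params[name]
    try:
        return getattr(params, name)
    except AttributeError:
        raise KeyError(name) from None


def _link_1(q, g, bq, bg, th):
    return bq * q


def _link_2(q, g, bq, bg, th):
    return bq * q * (1.0 + bg * g)


def _link_3(q, g, bq, bg, th):
    return bq * q + bg * g


def _link_4(q, g, bq, bg, th):
    return bq * softmax(th * q)


def _link_5(q, g, bq, bg, th):
    return bq * softmax(th * q * (1.0 + bg * g))


def _link_6(q, g, bq, bg, th):
    return bq * softmax(th * q) * (1.0 + bg * g)


def _link_7(q, g, bq, bg, th):
    return bq * softmax(th * q) + bg * g


def _link_8(q, g, bq, bg, th):
    return bq * softmax(th * (q + bg * g))


_BASE = ("alpha", "wrel", "beta_q", "A", "b_sep", "t0")

_DEFS = [
    (1, "Q", False, "none", _link_1),
    (2, "Q*gaze", False, "multiplicative", _link_2),
    (3, "Q+gaze", False, "additive", _link_3),
    (4, "softmax(Q)", True, "none", _link_4),
    (5, "softmax(Q*gaze)", True, "multiplicative", _link_5),
    (6, "softmax(Q)*gaze", True, "multiplicative", _link_6),
    (7, "softmax(Q)+gaze", True, "additive", _link_7),
    (8, "softmax(Q+gaze)", True, "multiplicative", _link_8),
]


def _make_spec(mid, name, uses_softmax, gaze_mode, link):
    free = list(_BASE)
    if gaze_mode != "none":
        free.insert(3, "beta_gaze")
    if uses_softmax:
        free.insert(free.index("A"), "theta")
    return ModelSpec(
        id=mid, name=name, uses_softmax=uses_softmax, gaze_mode=gaze_mode,
        free_params=tuple(free), link=link,
    )


MODELS = {d[0]: _make_spec(*d) for d in _DEFS}
_BY_NAME = {m.name: m for m in MODELS.values()}


def model_registry():
    """The eight canonical linking-function variants, in id order."""
    return [MODELS[i] for i in sorted(MODELS)]


def get_model(key: Union[int, str, ModelSpec]) -> ModelSpec:
    """Look a model up by id (1-8), by name (e.g. "softmax(Q)+gaze"), or pass through."""
    if isinstance(key, ModelSpec):
        return key
    if isinstance(key, (int, np.integer)):
        try:
            return MODELS[int(key)]
        except KeyError:
            raise KeyError(f"no model with id {key}; valid ids are 1-8") from None
    name = str(key).replace(" ", "")
    for m in MODELS.values():
        if m.name.replace(" ", "") == name:
            return m
    raise KeyError(f"no model named {key!r}; valid names: {sorted(_BY_NAME)}")


def drift_rates(model: Union[int, str, ModelSpec], q_avail, gaze, params) -> DriftSpec:
    """Evaluate a model's linking function on one trial's available options.

    ``q_avail`` and ``gaze`` are aligned arrays over the available options
    (trailing axis); ``params`` is a mapping or object providing the
    parameters the model's mask requires. Missing required parameters raise
    ``KeyError``. Broadcasts over leading axes, so whole trial sequences (and
    candidate batches) can be evaluated in one call.
    """
    model = get_model(model)
    q = np.asarray(q_avail, dtype=float)
    g = np.asarray(gaze, dtype=float)
    bq = np.asarray(_p(params, "beta_q"), dtype=float)
    bg = np.asarray(_p(params, "beta_gaze"), dtype=float) if model.gaze_mode != "none" else 0.0
    th = np.asarray(_p(params, "theta"), dtype=float) if model.uses_softmax else 0.0
    v = model.link(q, g, bq, bg, th)
    return DriftSpec(v=v, s=DRIFT_SD)
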