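"""Trustee utility models and exhaustive argmax behavioral prediction.

Four decision models describe how a Trustee chooses the integer return
``S2 in {0, ..., I*M2}``:

* **GR** (greed): ``U = pi2``, pure payoff maximization (no free parameters).
* **IA** (inequity aversion): ``U = pi2 - theta * Inequity2``.
* **GA** (guilt aversion): ``U = pi2 - theta * Guilt2``.
* **MS** (moral strategy): ``U = theta*pi2 - (1-theta) * min(Guilt2 + phi,
  Inequity2 - phi)`` — the integrative model whose ``min`` operator lets the
  Trustee satisfy whichever moral obligation (guilt or inequity) is cheaper
  on a given trial, producing moral opportunism at ``phi ~ 0``.

with the utility terms

* payoff fraction  ``pi2 = (I*M2 - S2) / (I*M2)``,
* guilt            ``Guilt2 = ((E2E1S2 - S2) / (E1M1 * I))**2``,
* inequity         ``Inequity2 = ((I*M2 - S2) / (endowment - I + I*M2) - 1/2)**2``,

where the second-order expectation is fixed at half of what the Investor
believes the Trustee holds: ``E2E1S2 = E1M1 * I / 2``.

Predicted behavior is the exact argmax of utility over the discrete strategy
space (no continuous relaxation); ties are broken toward the smallest
``S2``, i.e. toward the Trustee's own payoff.  Trials with ``I = 0`` leave
payoff and guilt undefined (zero denominators) and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tasks import TrialSpec

__all__ = [
    "ModelSpec",
    "MODELS",
    "MODEL_NAMES",
    "UndefinedTrialError",
    "payoff",
    "second_order_expectation",
    "guilt",
    "inequity",
    "utility",
    "predict",
    "predict_behavior_vector",
]


class UndefinedTrialError(ValueError):
    """Raised for trials with I = 0, where payoff and guilt are undefined."""


@dataclass(frozen=True)
class ModelSpec:
    """Name, free parameters and fitting bounds of one decision model."""

    name: str
    parameter_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    @property
    def k(self) -> int:
        """Number of free parameters (the AIC complexity term)."""
        return len(self.parameter_names)


#: The MS bounds are the classification grid's domain.  The unitary GA/IA
#: theta is a loss weight on a different scale: a moral-term weight of
#: theta_MS in the integrative model corresponds to (1 - theta_MS)/theta_MS
#: in the unitary models, so the bound 200 lets them span the same
#: payoff/moral trade-off range as the MS grid down to its resolution.
MODELS: dict[str, ModelSpec] = {
    "MS": ModelSpec("MS", ("theta", "phi"), ((0.0, 0.5), (-0.1, 0.1))),
    "GA": ModelSpec("GA", ("theta",), ((0.0, 200.0),)),
    "IA": ModelSpec("IA", ("theta",), ((0.0, 200.0),)),
    "GR": ModelSpec("GR", (), ()),
}

MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


def _get_model(model) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# Scalar utility terms (spec'd on single trials)


def payoff(trial: TrialSpec, s2: int) -> float:
    """Trustee's retained fraction of the multiplied investment."""
    total = trial.investment * trial.true_multiplier
    if total == 0:
        raise UndefinedTrialError("payoff undefined for I = 0")
    if not 0 <= s2 <= total:
        raise ValueError(f"S2={s2} outside [0, {total}]")
    return (total - s2) / total


def second_order_expectation(trial: TrialSpec) -> float:
    """E2(E1(S2)): half of the tokens the Investor believes the Trustee has."""
    return 0.5 * trial.believed_multiplier * trial.investment


def guilt(trial: TrialSpec, s2: int) -> float:
    """Squared shortfall from the Investor's (believed) expectation."""
    denom = trial.believed_multiplier * trial.investment
    if denom == 0:
        raise UndefinedTrialError("guilt undefined for I = 0")
    return ((second_order_expectation(trial) - s2) / denom) ** 2


def inequity(trial: TrialSpec, s2: int, endowment: int = 10) -> float:
    """Squared deviation of the Trustee's final share from an even split."""
    total = trial.investment * trial.true_multiplier
    pool = endowment - trial.investment + total
    if pool <= 0:
        raise ValueError("total token pool must be positive")
    return ((total - s2) / pool - 0.5) ** 2


def utility(model, params: Sequence[float], trial: TrialSpec, s2: int,
            endowment: int = 10) -> float:
    """Utility of returning ``s2`` tokens under one of the four models."""
    spec = _get_model(model)
    if len(params) != spec.k:
        raise ValueError(f"{spec.name} takes {spec.k} parameter(s), got {len(params)}")
    pi2 = payoff(trial, s2)
    if spec.name == "GR":
        return pi2
    if spec.name == "IA":
        return pi2 - params[0] * inequity(trial, s2, endowment)
    if spec.name == "GA":
        return pi2 - params[0] * guilt(trial, s2)
    theta, phi = params
    moral = min(guilt(trial, s2) + phi, inequity(trial, s2, endowment) - phi)
    return theta * pi2 - (1.0 - theta) * moral


# ---------------------------------------------------------------------------
# Vectorized prediction core

_CHUNK = 512  # parameter rows per block; bounds peak memory during batch argmax


def _trial_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(I, M2, E1M1) integer arrays from TrialSpecs, a DataFrame, or an array."""
    if hasattr(trials, "columns"):  # pandas DataFrame
        I = np.asarray(trials["investment"], dtype=int)
        m2 = np.asarray(trials["true_multiplier"], dtype=int)
        e1m1 = np.asarray(trials["believed_multiplier"], dtype=int)
    elif len(trials) and isinstance(trials[0], TrialSpec):
        I = np.array([t.investment for t in trials], dtype=int)
        m2 = np.array([t.true_multiplier for t in trials], dtype=int)
        e1m1 = np.array([t.believed_multiplier for t in trials], dtype=int)
    else:
        arr = np.asarray(trials, dtype=int)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                "trials must be TrialSpecs, a behavior DataFrame, or an "
                "(n, 3) array of (investment, true_multiplier, believed_multiplier)"
            )
        I, m2, e1m1 = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(I < 0) or np.any(m2 < 1) or np.any(e1m1 < 1):
        raise ValueError("invalid trial: need I >= 0 and multipliers >= 1")
    if np.any(I == 0):
        raise UndefinedTrialError(
            "trials with I = 0 leave payoff and guilt undefined; "
            "filter them out before prediction or fitting"
        )
    return I, m2, e1m1


def _term_tensors(I, m2, e1m1, endowment):
    """Per-trial utility-term matrices over the padded strategy axis.

    Returns ``(pi, g, q, mask, total)`` with shapes (T, Smax+1) for the first
    four; ``mask`` marks feasible strategies ``S2 <= I*M2``.
    """
    total = I * m2
    s = np.arange(int(total.max()) + 1, dtype=float)[None, :]
    totf = total[:, None].astype(float)
    mask = s <= totf
    pi = (totf - s) / totf
    expect = 0.5 * e1m1 * I
    g = ((expect[:, None] - s) / (e1m1 * I)[:, None].astype(float)) ** 2
    pool = (endowment - I + total)[:, None].astype(float)
    q = ((totf - s) / pool - 0.5) ** 2
    return pi, g, q, mask, total


def _utilities_block(name, params, pi, g, q):
    """Utilities for a (K, k) parameter block: shape (K, T, Smax+1)."""
    if name == "GR":
        return np.broadcast_to(pi[None], (max(len(params), 1),) + pi.shape)
    if name == "GA":
        return pi[None] - params[:, 0, None, None] * g[None]
    if name == "IA":
        return pi[None] - params[:, 0, None, None] * q[None]
    theta = params[:, 0, None, None]
    phi = params[:, 1, None, None]
    moral = np.minimum(g[None] + phi, q[None] - phi)
    return theta * pi[None] - (1.0 - theta) * moral


#: Utilities within this absolute distance of the maximum count as tied.
#: Genuine utility gaps between distinct integer strategies are many orders
#: larger on the model's O(1) utility scale; the tolerance only absorbs
#: last-ulp rounding noise so that exact mathematical ties resolve to the
#: smallest S2 regardless of summation order.
TIE_TOLERANCE = 1e-9


def _predict_many(model, params, terms) -> np.ndarray:
    """Argmax predictions for many parameter rows: shape (K, T).

    Ties (within ``TIE_TOLERANCE`` of the maximal utility) break toward the
    smallest S2 along the ascending strategy axis.
    """
    spec = _get_model(model)
    pi, g, q, mask, _ = terms
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if params.size == 0:
        params = params.reshape(1, 0)
    out = np.empty((params.shape[0], pi.shape[0]), dtype=int)
    for start in range(0, params.shape[0], _CHUNK):
        block = params[start:start + _CHUNK]
        u = _utilities_block(spec.name, block, pi, g, q)
        u = np.where(mask[None], u, -np.inf)
        top = np.max(u, axis=2, keepdims=True)
        out[start:start + block.shape[0]] = np.argmax(
            u >= top - TIE_TOLERANCE, axis=2
        )
    return out


def predict_behavior_vector(model, params, trials, endowment: int = 10) -> np.ndarray:
    """Argmax return ``S2hat`` for every trial, order preserved."""
    I, m2, e1m1 = _trial_arrays(trials)
    terms = _term_tensors(I, m2, e1m1, endowment)
    spec = _get_model(model)
    p = np.asarray(params, dtype=float).reshape(1, spec.k)
    return _predict_many(spec, p, terms)[0]


def predict(model, params, trial: TrialSpec, endowment: int = 10) -> int:
    """Exhaustive-argmax predicted return for a single trial."""
    return int(predict_behavior_vector(model, params, [trial], endowment)[0])
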