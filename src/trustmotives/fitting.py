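"""Per-participant model fitting, AIC model comparison, and fit tables.

Each decision model is fit to a participant's trial-level returns by
minimizing the sum of squared errors between the model's exhaustive-argmax
predictions and the observed integer returns.  Because the predictions are
piecewise constant in the parameters, the objective has zero gradient almost
everywhere; the optimizer is therefore a dense multi-start search (uniform
random starts within the parameter bounds, best-of-N selection) followed by
a shrinking pattern-search polish of the best start.  The polish can only
improve the solution, so the fit is never worse than the best raw start.

Model performance is compared with ``AIC = n*ln(SSE/n) + 2k``.  Participants
whose behavior is near-perfectly explained by any model (``SSE < 10``) are
flagged and omitted from AIC comparisons (``ln 0`` is undefined) while
remaining available for strategy classification.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .tasks import BehaviorRecord
from .utility import (
    MODELS,
    MODEL_NAMES,
    _get_model,
    _predict_many,
    _term_tensors,
    _trial_arrays,
    predict_behavior_vector,
)

__all__ = [
    "FitResult",
    "TrusteeModel",
    "sse",
    "aic",
    "fit_model",
    "fit_population",
    "exclude_near_perfect",
    "compare_models_paired",
    "prediction_table",
    "fits_to_frame",
]

SSE_EXCLUSION_THRESHOLD = 10.0


@dataclass
class FitResult:
    """Best-fitting parameters and fit statistics for one participant x model."""

    participant_id: str
    model: str
    params: dict[str, float]
    sse: float
    n_trials_used: int
    aic: float
    n_restarts: int
    seed: int | None = None
    block_id: str = ""
    excluded_near_perfect: bool = False


def aic(sse_value: float, n: int, k: int) -> float:
    """Akaike Information Criterion: ``n * ln(SSE / n) + 2k``."""
    if n <= 0:
        raise ValueError("AIC needs n > 0")
    if sse_value <= 0:
        raise ValueError("AIC undefined for SSE <= 0 (ln 0); see the exclusion rule")
    return n * np.log(sse_value / n) + 2 * k


def _record_arrays(record: BehaviorRecord):
    """Feasible (I > 0) trial arrays and aligned returns from a record."""
    keep = [i for i, t in enumerate(record.trials) if t.investment > 0]
    if not keep:
        raise ValueError(f"record {record.participant_id!r} has no feasible trials")
    trials = [record.trials[i] for i in keep]
    y = record.returns[keep]
    return trials, y


def sse(model, params: Sequence[float], record: BehaviorRecord,
        endowment: int = 10) -> float:
    """Sum of squared differences between argmax predictions and behavior."""
    trials, y = _record_arrays(record)
    preds = predict_behavior_vector(model, params, trials, endowment)
    return float(np.sum((y - preds) ** 2))


# ---------------------------------------------------------------------------
# Estimator


class TrusteeModel(RegressorMixin, BaseEstimator):
    """Fit one Trustee decision model to trial-level returns.

    Parameters
    ----------
    model : {"MS", "GA", "IA", "GR"}
        Decision model to fit.
    n_restarts : int
        Random starting points for the multi-start search (the greed model
        has no free parameters and needs none).
    random_state : int, Generator or None
        Seed for the restart sampler; fits are reproducible given a seed.
    endowment : int
        Investor endowment in tokens (enters the inequity term).
    refine : bool
        Apply the shrinking pattern-search polish to the best start.

    Attributes
    ----------
    params_ : dict
        Best-fitting parameters by name (empty for GR).
    sse_ : float
        Residual sum of squares at the optimum, in squared tokens.
    aic_ : float
        ``n*ln(SSE/n) + 2k``; NaN when SSE is 0.
    n_trials_used_ : int
        Number of (feasible) trials entering the fit.
    """

    def __init__(self, model: str = "MS", n_restarts: int = 1000,
                 random_state=None, endowment: int = 10, refine: bool = True):
        self.model = model
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.endowment = endowment
        self.refine = refine

    def fit(self, X, y):
        spec = _get_model(self.model)
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        I, m2, e1m1 = _trial_arrays(X)
        y = np.asarray(y, dtype=int)
        if y.shape != I.shape:
            raise ValueError("y must align 1:1 with the trials")
        total = I * m2
        if np.any(y < 0) or np.any(y > total):
            raise ValueError("returns must lie in [0, I*M2] on every trial")
        terms = _term_tensors(I, m2, e1m1, self.endowment)
        rng = np.random.default_rng(self.random_state)

        if spec.k == 0:
            best = np.empty(0)
            best_sse = self._sse_batch(spec, best.reshape(1, 0), terms, y)[0]
        else:
            lo = np.array([b[0] for b in spec.bounds])
            hi = np.array([b[1] for b in spec.bounds])
            starts = lo + rng.uniform(size=(self.n_restarts, spec.k)) * (hi - lo)
            sses = self._sse_batch(spec, starts, terms, y)
            idx = int(np.argmin(sses))
            best, best_sse = starts[idx], float(sses[idx])
            if self.refine:
                best, best_sse = self._polish(spec, best, best_sse, terms, y, lo, hi)

        self.params_ = dict(zip(spec.parameter_names, best))
        self.sse_ = float(best_sse)
        self.n_trials_used_ = int(len(y))
        self.k_ = spec.k
        self.aic_ = (
            aic(self.sse_, self.n_trials_used_, spec.k) if self.sse_ > 0 else np.nan
        )
        self.n_features_in_ = 3
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("TrusteeModel is not fitted yet; call fit first")
        return predict_behavior_vector(
            self.model, list(self.params_.values()), X, self.endowment
        )

    # -- internals --

    def _sse_batch(self, spec, params, terms, y) -> np.ndarray:
        preds = _predict_many(spec, params, terms)
        return np.sum((preds - y[None, :]) ** 2, axis=1).astype(float)

    def _polish(self, spec, p, s, terms, y, lo, hi, max_iter: int = 40):
        """Pattern search with step halving; monotone in SSE."""
        step = (hi - lo) / 16.0
        offsets = np.array(
            [o for o in itertools.product((-1.0, 0.0, 1.0), repeat=spec.k)
             if any(o)]
        )
        floor = (hi - lo) / 8192.0
        for _ in range(max_iter):
            cand = np.clip(p[None, :] + offsets * step[None, :], lo, hi)
            sses = self._sse_batch(spec, cand, terms, y)
            idx = int(np.argmin(sses))
            if sses[idx] < s:
                p, s = cand[idx], float(sses[idx])
            else:
                step = step / 2.0
                if np.all(step < floor):
                    break
        return p, s


# ---------------------------------------------------------------------------
# Functional wrappers and population-level fitting


def _child_seed(seed, participant_id: str, model: str) -> np.random.SeedSequence:
    """Deterministic per-(participant, model) seed, reproducible in isolation."""
    tags = [zlib.crc32(str(participant_id).encode()), zlib.crc32(model.encode())]
    entropy = ([int(seed)] if seed is not None else []) + tags
    return np.random.SeedSequence(entropy)


def fit_model(model, record: BehaviorRecord, n_restarts: int = 1000,
              seed=None, endowment: int = 10, refine: bool = True) -> FitResult:
    """Fit one model to one participant's record; deterministic given seed."""
    spec = _get_model(model)
    trials, y = _record_arrays(record)
    est = TrusteeModel(
        model=spec.name,
        n_restarts=n_restarts,
        random_state=np.random.default_rng(_child_seed(seed, record.participant_id, spec.name)),
        endowment=endowment,
        refine=refine,
    ).fit(trials, y)
    return FitResult(
        participant_id=record.participant_id,
        model=spec.name,
        params=est.params_,
        sse=est.sse_,
        n_trials_used=est.n_trials_used_,
        aic=est.aic_,
        n_restarts=n_restarts,
        seed=seed,
        block_id=record.block_id,
    )


def fit_population(records: Iterable[BehaviorRecord],
                   models: Sequence[str] = MODEL_NAMES,
                   n_restarts: int = 1000, seed=None,
                   endowment: int = 10) -> list[FitResult]:
    """Fit every model to every record with per-(participant, model) child seeds."""
    return [
        fit_model(m, rec, n_restarts=n_restarts, seed=seed, endowment=endowment)
        for rec in records
        for m in models
    ]


def exclude_near_perfect(fits: Sequence[FitResult],
                         threshold: float = SSE_EXCLUSION_THRESHOLD) -> list[FitResult]:
    """Flag participants any of whose models fits with SSE below threshold.

    Flagged participants are omitted from AIC model comparisons (log of a
    near-zero SSE is degenerate) but remain classifiable.  The comparison is
    strict: SSE exactly at the threshold is retained.
    """
    flagged_keys = {
        (f.participant_id, f.block_id) for f in fits if f.sse < threshold
    }
    return [
        replace(f, excluded_near_perfect=(f.participant_id, f.block_id) in flagged_keys)
        for f in fits
    ]


def compare_models_paired(aic_a, aic_b) -> tuple[float, int, float]:
    """Two-sided paired t-test on per-participant AIC vectors.

    Returns ``(t, df, p)``.  Identical vectors give ``(0, n-1, 1)``; constant
    nonzero differences have zero variance and raise.
    """
    a = np.asarray(aic_a, dtype=float)
    b = np.asarray(aic_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired AIC vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("paired t-test needs n >= 2")
    diffs = a - b
    if np.all(diffs == diffs[0]):
        if diffs[0] == 0:
            return 0.0, len(a) - 1, 1.0
        raise ValueError("differences have zero variance; paired t is undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)


def prediction_table(fits: Sequence[FitResult],
                     records: Sequence[BehaviorRecord],
                     endowment: int = 10) -> pd.DataFrame:
    """Posterior-predictive table: one row per participant x trial x model."""
    by_key: dict[tuple[str, str], BehaviorRecord] = {
        (r.participant_id, r.block_id): r for r in records
    }
    rows = []
    for f in fits:
        rec = by_key[(f.participant_id, f.block_id)]
        trials, y = _record_arrays(rec)
        preds = predict_behavior_vector(f.model, list(f.params.values()), trials,
                                        endowment)
        for trial, actual, pred in zip(trials, y, preds):
            rows.append(
                (f.participant_id, f.block_id, trial.trial_index,
                 trial.investment, trial.true_multiplier,
                 trial.believed_multiplier, int(actual), f.model, int(pred))
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "block_id", "trial_index", "investment",
                 "true_multiplier", "believed_multiplier", "actual", "model",
                 "predicted"],
    )


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Flat fits table (one row per participant x model), CSV-ready."""
    rows = []
    for f in fits:
        row = {
            "participant_id": f.participant_id,
            "block_id": f.block_id,
            "model": f.model,
            "sse": f.sse,
            "n": f.n_trials_used,
            "k": MODELS[f.model].k,
            "aic": f.aic,
            "n_restarts": f.n_restarts,
            "excluded_near_perfect": f.excluded_near_perfect,
        }
        for name, value in f.params.items():
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows)
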