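"""Trust-game task structures and behavior-table I/O.

The games modelled here are single-shot multiplier trust games played from
the Trustee's side.  An Investor invests ``I`` of an ``endowment`` (default
10) game tokens; the investment is multiplied by a *true* multiplier ``M2``
before reaching the Trustee, while the Investor *believes* the multiplier is
``E1M1``.  The Trustee then returns an integer number of tokens
``S2 in [0, I*M2]``.

Two families of task are supported:

* **HMTG** (hidden multiplier): the true multiplier varies across trials
  (e.g. x2/x4/x6) while the believed multiplier is fixed (x4).
* **FBMTG** (false-belief multiplier): the believed multiplier varies
  (x2/x4/x6) while the true multiplier is fixed (x4).

Setting both sets to a single shared value recovers the standard Trust Game.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialSpec",
    "Condition",
    "GameConfig",
    "BehaviorRecord",
    "make_hmtg_config",
    "make_fbmtg_config",
    "make_standard_config",
    "trustee_tokens",
    "read_behavior_table",
    "write_behavior_table",
    "records_to_frame",
    "frame_to_records",
    "read_config",
    "write_config",
]

BEHAVIOR_COLUMNS = [
    "participant_id",
    "block_id",
    "trial_index",
    "investment",
    "true_multiplier",
    "believed_multiplier",
    "returned",
]


@dataclass(frozen=True)
class TrialSpec:
    """One single-shot game round seen by the Trustee."""

    investment: int
    true_multiplier: int
    believed_multiplier: int
    trial_index: int = 0
    block_id: str = ""

    def __post_init__(self) -> None:
        for name in ("investment", "true_multiplier", "believed_multiplier"):
            value = getattr(self, name)
            if int(value) != value:
                raise ValueError(f"{name} must be an integer, got {value!r}")
            object.__setattr__(self, name, int(value))
        if self.investment < 0:
            raise ValueError("investment must be nonnegative")
        if self.true_multiplier < 1 or self.believed_multiplier < 1:
            raise ValueError("multipliers must be >= 1")


@dataclass(frozen=True)
class Condition:
    """A (true multiplier, believed multiplier) pairing with its trial share."""

    true_multiplier: int
    believed_multiplier: int
    proportion: float


@dataclass(frozen=True)
class GameConfig:
    """A block design: conditions with exact proportions, trial count, endowment.

    ``exchange_rate`` (currency per token) is carried as metadata only; all
    game accounting is in integer tokens.
    """

    conditions: tuple[Condition, ...]
    n_trials: int = 80
    endowment: int = 10
    exchange_rate: float = 0.40
    kind: str = "custom"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("config needs at least one condition")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.endowment < 1:
            raise ValueError("endowment must be positive")
        total = sum(c.proportion for c in self.conditions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"condition proportions sum to {total}, expected 1")
        for c in self.conditions:
            count = c.proportion * self.n_trials
            if abs(count - round(count)) > 1e-9:
                raise ValueError(
                    f"condition x{c.true_multiplier}/belief x{c.believed_multiplier} "
                    f"implies a non-integer trial count ({count:g}) for "
                    f"n_trials={self.n_trials}"
                )

    def trial_counts(self) -> list[int]:
        """Exact per-condition trial counts (in ``conditions`` order)."""
        return [int(round(c.proportion * self.n_trials)) for c in self.conditions]

    @property
    def true_multipliers(self) -> tuple[int, ...]:
        return tuple(c.true_multiplier for c in self.conditions)

    @property
    def believed_multipliers(self) -> tuple[int, ...]:
        return tuple(c.believed_multiplier for c in self.conditions)


@dataclass
class BehaviorRecord:
    """A participant's trials in one block, with integer returns aligned 1:1."""

    participant_id: str
    block_id: str
    trials: list[TrialSpec]
    returns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.returns = np.asarray(self.returns, dtype=int)
        if len(self.returns) != len(self.trials):
            raise ValueError(
                f"{len(self.returns)} returns for {len(self.trials)} trials"
            )
        for trial, s2 in zip(self.trials, self.returns):
            cap = trustee_tokens(trial)
            if not 0 <= s2 <= cap:
                raise ValueError(
                    f"return {s2} outside [0, {cap}] for trial "
                    f"{trial.trial_index} of participant {self.participant_id}"
                )

    def __len__(self) -> int:
        return len(self.trials)


def _weights(varying: Sequence[int], base: int) -> list[float]:
    """Proportions for the varying multiplier set.

    The base value (the fixed multiplier of the other role) takes 50% of
    trials when it is a member of the set, with the flanking values sharing
    the remainder equally; otherwise all members are weighted equally.  With
    the three-member sets used in practice this yields the 25/50/25 design.
    """
    values = list(varying)
    if not values:
        raise ValueError("multiplier set must be nonempty")
    if len(values) != len(set(values)):
        raise ValueError("multiplier set has duplicate entries")
    if len(values) == 1:
        return [1.0]
    if base in values:
        rest = (1.0 - 0.5) / (len(values) - 1)
        return [0.5 if v == base else rest for v in values]
    return [1.0 / len(values)] * len(values)


def make_hmtg_config(
    multiplier_set: Sequence[int],
    believed: int,
    n_trials: int = 80,
    endowment: int = 10,
    exchange_rate: float = 0.40,
) -> GameConfig:
    """Hidden-multiplier game: true multiplier varies, believed is fixed.

    For the canonical three-member sets the believed (base) multiplier is
    played on 50% of trials and the lowered/raised multipliers on 25% each.
    """
    ordered = sorted(multiplier_set)
    conditions = tuple(
        Condition(int(m), int(believed), w)
        for m, w in zip(ordered, _weights(ordered, believed))
    )
    return GameConfig(conditions, n_trials, endowment, exchange_rate, kind="hmtg")


def make_fbmtg_config(
    believed_set: Sequence[int],
    true_multiplier: int,
    n_trials: int = 80,
    endowment: int = 10,
    exchange_rate: float = 0.40,
) -> GameConfig:
    """False-belief game: believed multiplier varies, true multiplier is fixed."""
    conditions = tuple(
        Condition(int(true_multiplier), int(b), w)
        for b, w in zip(
            sorted(believed_set), _weights(sorted(believed_set), true_multiplier)
        )
    )
    return GameConfig(conditions, n_trials, endowment, exchange_rate, kind="fbmtg")


def make_standard_config(
    multiplier: int = 4, n_trials: int = 80, endowment: int = 10
) -> GameConfig:
    """Standard Trust Game: one multiplier, known to both players."""
    return GameConfig(
        (Condition(multiplier, multiplier, 1.0),),
        n_trials,
        endowment,
        kind="standard",
    )


def trustee_tokens(trial: TrialSpec) -> int:
    """Tokens available to the Trustee on a trial: I * M2."""
    return trial.investment * trial.true_multiplier


# ---------------------------------------------------------------------------
# Tabular I/O


def records_to_frame(records: Iterable[BehaviorRecord]) -> pd.DataFrame:
    """Long-format behavior table, one row per trial."""
    rows = []
    for rec in records:
        for trial, s2 in zip(rec.trials, rec.returns):
            rows.append(
                (
                    rec.participant_id,
                    rec.block_id,
                    trial.trial_index,
                    trial.investment,
                    trial.true_multiplier,
                    trial.believed_multiplier,
                    int(s2),
                )
            )
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[BehaviorRecord]:
    """Split a long-format behavior table into per-(participant, block) records."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"behavior table is missing columns: {missing}")
    for col in BEHAVIOR_COLUMNS[2:]:
        values = frame[col]
        bad = values[values != values.astype(int)]
        if len(bad):
            row = int(bad.index[0])
            raise ValueError(f"non-integer value {bad.iloc[0]!r} in {col} at row {row}")
    records = []
    for (pid, block), group in frame.groupby(
        ["participant_id", "block_id"], sort=True
    ):
        group = group.sort_values("trial_index")
        trials = []
        returns = []
        for row_index, row in group.iterrows():
            trial = TrialSpec(
                investment=int(row["investment"]),
                true_multiplier=int(row["true_multiplier"]),
                believed_multiplier=int(row["believed_multiplier"]),
                trial_index=int(row["trial_index"]),
                block_id=str(block),
            )
            s2 = int(row["returned"])
            cap = trustee_tokens(trial)
            if not 0 <= s2 <= cap:
                raise ValueError(
                    f"returned={s2} outside [0, {cap}] at row {row_index} "
                    f"(participant {pid}, block {block})"
                )
            trials.append(trial)
            returns.append(s2)
        records.append(BehaviorRecord(str(pid), str(block), trials, np.array(returns)))
    return records


def write_behavior_table(records: Iterable[BehaviorRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_behavior_table(path) -> list[BehaviorRecord]:
    return frame_to_records(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Config (de)serialization


def _config_to_dict(config: GameConfig) -> dict:
    return {
        "kind": config.kind,
        "n_trials": config.n_trials,
        "endowment": config.endowment,
        "exchange_rate": config.exchange_rate,
        "conditions": [
            {
                "true_multiplier": c.true_multiplier,
                "believed_multiplier": c.believed_multiplier,
                "proportion": c.proportion,
            }
            for c in config.conditions
        ],
    }


def write_config(config: GameConfig, path) -> None:
    path = Path(path)
    payload = _config_to_dict(config)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_config(path) -> GameConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    conditions = tuple(
        Condition(
            int(c["true_multiplier"]), int(c["believed_multiplier"]), float(c["proportion"])
        )
        for c in payload["conditions"]
    )
    return GameConfig(
        conditions,
        int(payload["n_trials"]),
        int(payload.get("endowment", 10)),
        float(payload.get("exchange_rate", 0.40)),
        str(payload.get("kind", "custom")),
    )
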