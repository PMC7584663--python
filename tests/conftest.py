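"""Shared fixtures: game configs, strategy maps (built once per session),
and an independent brute-force argmax oracle used to cross-check the
vectorized prediction path."""

from __future__ import annotations

import numpy as np
import pytest

import trustmotives as tm


def oracle_predict(model: str, params, I: int, M2: int, E1M1: int,
                   endowment: int = 10, tol: float = 1e-9) -> int:
    """Independent exhaustive utility evaluation over S2 in {0..I*M2}.

    Pure-Python re-derivation of the utility terms (payoff fraction, squared
    guilt, squared inequity) evaluated strategy by strategy; ties within
    ``tol`` keep the smaller S2.  Deliberately shares no code with the
    package's vectorized argmax.
    """
    total = I * M2
    expect = 0.5 * E1M1 * I
    best_s, best_u = None, None
    for s in range(total + 1):
        pi = (total - s) / total
        g = ((expect - s) / (E1M1 * I)) ** 2
        q = ((total - s) / (endowment - I + total) - 0.5) ** 2
        if model == "GR":
            u = pi
        elif model == "GA":
            u = pi - params[0] * g
        elif model == "IA":
            u = pi - params[0] * q
        else:
            theta, phi = params
            u = theta * pi - (1 - theta) * min(g + phi, q - phi)
        if best_u is None or u > best_u + tol:
            best_u, best_s = u, s
    return best_s


@pytest.fixture(scope="session")
def cfg236() -> tm.GameConfig:
    return tm.make_hmtg_config([2, 4, 6], believed=4, n_trials=80)


@pytest.fixture(scope="session")
def cfg468() -> tm.GameConfig:
    return tm.make_hmtg_config([4, 6, 8], believed=6, n_trials=80)


@pytest.fixture(scope="session")
def cfgfb() -> tm.GameConfig:
    return tm.make_fbmtg_config([2, 4, 6], true_multiplier=4, n_trials=80)


@pytest.fixture(scope="session")
def map236(cfg236) -> tm.StrategyMap:
    return tm.StrategyMap(config=cfg236).fit()


@pytest.fixture(scope="session")
def map468(cfg468) -> tm.StrategyMap:
    return tm.StrategyMap(config=cfg468).fit()


@pytest.fixture(scope="session")
def schedule236(cfg236):
    return tm.generate_investment_schedule(cfg236, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
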