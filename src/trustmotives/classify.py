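"""Model-driven strategy classification in theta-phi parameter space.

The moral-strategy model is simulated at equidistant points of its
theta-phi parameter space (theta on [0, 0.5], phi on [-0.1, 0.1]; 101 x 101
= 10,201 points by default) over every investment x multiplier-condition
stimulus of a game configuration.  Grid points are grouped by hierarchical
clustering of their pairwise Euclidean distance in simulated reciprocity
behavior, each cluster is labelled by its nearest archetypal behavior
pattern (greed GR, guilt aversion GA, inequity aversion IA, moral
opportunism MO), and same-labelled clusters are merged.  The resulting map
partitions the parameter space into four strategy zones — built purely from
model simulations, never from participant data — and a participant is
classified by the label of the grid point nearest to their best-fitting
(theta, phi) pair.

The dendrogram is cut adaptively: starting from four clusters, the cut is
deepened (merging same-labelled clusters) until all four archetypes are
represented.  In practice this cuts directly to four clusters for the
x4/x6/x8 game and to five clusters with a moral-opportunism merge for the
x2/x4/x6 and false-belief games, whose opportunistic zone splits in two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClassifierMixin

from .tasks import GameConfig, TrialSpec
from .utility import MODELS, _predict_many, _term_tensors, _trial_arrays

__all__ = [
    "STRATEGY_LABELS",
    "GridSimulation",
    "StrategyMap",
    "simulate_grid",
    "cluster_grid",
    "canonical_pattern",
    "label_clusters",
    "classify_participant",
]

STRATEGY_LABELS = ("GR", "GA", "IA", "MO")

THETA_DOMAIN = MODELS["MS"].bounds[0]
PHI_DOMAIN = MODELS["MS"].bounds[1]


def _stimulus_trials(config: GameConfig, investments: Sequence[int]) -> list[TrialSpec]:
    """All investment x condition combinations, in a fixed canonical order."""
    investments = sorted(set(int(i) for i in investments))
    if any(i < 1 for i in investments):
        raise ValueError("grid stimuli need investments >= 1")
    pairs = sorted({(c.true_multiplier, c.believed_multiplier) for c in config.conditions})
    return [
        TrialSpec(investment=i, true_multiplier=m2, believed_multiplier=e1m1)
        for (m2, e1m1) in pairs
        for i in investments
    ]


@dataclass
class GridSimulation:
    """Argmax behavior of the MS model at every theta-phi grid point."""

    theta_values: np.ndarray
    phi_values: np.ndarray
    stimuli: list[TrialSpec]
    behavior: np.ndarray  # (n_theta * n_phi, n_stimuli) integer returns
    config: GameConfig

    @property
    def points(self) -> np.ndarray:
        """Grid coordinates, theta-major: row = i_theta * n_phi + i_phi."""
        tt, pp = np.meshgrid(self.theta_values, self.phi_values, indexing="ij")
        return np.column_stack([tt.ravel(), pp.ravel()])


def simulate_grid(config: GameConfig, n_theta: int = 101, n_phi: int = 101,
                  investments: Sequence[int] = tuple(range(1, 11))) -> GridSimulation:
    """Simulate MS-model behavior on the full theta-phi Cartesian grid."""
    theta = np.linspace(*THETA_DOMAIN, n_theta)
    phi = np.linspace(*PHI_DOMAIN, n_phi)
    stimuli = _stimulus_trials(config, investments)
    terms = _term_tensors(*_trial_arrays(stimuli), config.endowment)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    params = np.column_stack([tt.ravel(), pp.ravel()])
    behavior = _predict_many("MS", params, terms)
    return GridSimulation(theta, phi, stimuli, behavior, config)


def cluster_grid(sim: GridSimulation, n_clusters: int,
                 method: str = "ward") -> np.ndarray:
    """Agglomerative clustering of grid rows; returns 1-based cluster ids."""
    X = np.asarray(sim.behavior, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("behavior matrix must be finite")
    n_distinct = len(np.unique(X, axis=0))
    if n_clusters > n_distinct:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds the {n_distinct} distinct behavior rows"
        )
    Z = linkage(X, method=method)
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def _tie_round(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, half-steps toward zero returns.

    Matches the argmax tie-break (among equally good integer strategies the
    smaller S2 wins, favoring the Trustee's own payoff).
    """
    return np.ceil(np.asarray(x, dtype=float) - 0.5)


def canonical_pattern(strategy: str, config: GameConfig,
                      investments: Sequence[int] = tuple(range(1, 11))) -> np.ndarray:
    """Archetypal return vector over the stimulus set for one strategy.

    GR returns nothing; GA returns the Investor's (believed) expectation
    ``E1M1 * I / 2``; IA returns the even split of all tokens in play; MO
    returns the cheaper of the GA and IA obligations per stimulus.
    """
    stimuli = _stimulus_trials(config, investments)
    I, m2, e1m1 = _trial_arrays(stimuli)
    total = I * m2
    ga = np.clip(_tie_round(0.5 * e1m1 * I), 0, total)
    even_split = 0.5 * (total + I - config.endowment)
    ia = np.clip(_tie_round(even_split), 0, total)
    patterns = {
        "GR": np.zeros_like(total, dtype=float),
        "GA": ga,
        "IA": ia,
        "MO": np.minimum(ga, ia),
    }
    if strategy not in patterns:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGY_LABELS}")
    return patterns[strategy].astype(int)


def _nearest_archetypes(sim: GridSimulation, cluster_ids: np.ndarray,
                        investments) -> dict[int, str]:
    """Label each cluster by the archetype nearest to its mean behavior."""
    archetypes = {
        lab: canonical_pattern(lab, sim.config, investments).astype(float)
        for lab in STRATEGY_LABELS
    }
    labels = {}
    for cid in np.unique(cluster_ids):
        mean_behavior = sim.behavior[cluster_ids == cid].mean(axis=0)
        dists = {lab: np.linalg.norm(mean_behavior - vec)
                 for lab, vec in archetypes.items()}
        labels[int(cid)] = min(dists, key=dists.get)
    return labels


def label_clusters(sim: GridSimulation, cluster_ids: np.ndarray,
                   investments: Sequence[int] = tuple(range(1, 11)),
                   allow_merge: Sequence[str] = ("MO",)) -> np.ndarray:
    """Per-grid-point strategy labels from a clustering.

    Clusters sharing a label in ``allow_merge`` are merged; two clusters
    mapping to the same label outside that set signal a mis-specified
    cluster count and raise.
    """
    by_cluster = _nearest_archetypes(sim, cluster_ids, investments)
    seen: dict[str, int] = {}
    for cid, lab in by_cluster.items():
        if lab in seen and lab not in allow_merge:
            raise ValueError(
                f"clusters {seen[lab]} and {cid} both map to archetype {lab}; "
                "the cluster count is mis-specified"
            )
        seen.setdefault(lab, cid)
    return np.array([by_cluster[int(c)] for c in cluster_ids])


class StrategyMap(ClassifierMixin, BaseEstimator):
    """Theta-phi strategy-zone classifier built from model simulations.

    ``fit`` ignores its arguments: the map is constructed purely from
    simulated model behavior for the given game configuration, so the
    classification of participants is independent of any observed data.

    Parameters
    ----------
    config : GameConfig
        Game the map is built for (conditions fix the stimulus set).
    n_theta, n_phi : int
        Grid resolution per axis (101 x 101 = 10,201 points by default).
    investments : sequence of int
        Investment levels spanning the stimulus space.
    linkage_method : str
        Agglomeration criterion for the hierarchical clustering.
    n_clusters : int or None
        Dendrogram cut.  None selects adaptively: the smallest cut >= 4
        whose archetype labels cover all four strategies, merging
        same-labelled clusters.

    Attributes
    ----------
    labels_ : ndarray of shape (n_theta * n_phi,)
        Strategy label per grid point (theta-major order).
    cluster_ids_ : ndarray
        Raw cluster id per grid point before archetype labelling.
    n_clusters_ : int
        Dendrogram cut actually used.
    """

    def __init__(self, config: GameConfig | None = None, n_theta: int = 101,
                 n_phi: int = 101, investments: Sequence[int] = tuple(range(1, 11)),
                 linkage_method: str = "ward", n_clusters: int | None = None):
        self.config = config
        self.n_theta = n_theta
        self.n_phi = n_phi
        self.investments = investments
        self.linkage_method = linkage_method
        self.n_clusters = n_clusters

    def fit(self, X=None, y=None):
        if self.config is None:
            raise ValueError("StrategyMap requires a GameConfig")
        sim = simulate_grid(self.config, self.n_theta, self.n_phi, self.investments)
        if self.n_clusters is not None:
            ids = cluster_grid(sim, self.n_clusters, self.linkage_method)
            # clusters landing on the same archetype are merged into one zone
            labels = label_clusters(sim, ids, self.investments,
                                    allow_merge=STRATEGY_LABELS)
            used = self.n_clusters
        else:
            ids = labels = None
            last_error = None
            for used in range(4, 9):
                candidate_ids = cluster_grid(sim, used, self.linkage_method)
                try:
                    candidate = label_clusters(
                        sim, candidate_ids, self.investments,
                        allow_merge=STRATEGY_LABELS,
                    )
                except ValueError as err:  # pragma: no cover - defensive
                    last_error = err
                    continue
                if set(candidate) == set(STRATEGY_LABELS):
                    ids, labels = candidate_ids, candidate
                    break
            if labels is None:
                raise ValueError(
                    "no dendrogram cut in 4..8 produced all four strategy zones"
                ) from last_error
        self.simulation_ = sim
        self.cluster_ids_ = ids
        self.labels_ = labels
        self.n_clusters_ = used
        self.classes_ = np.array(sorted(set(labels)))
        return self

    def _grid_index(self, values, axis_values) -> np.ndarray:
        lo, hi = axis_values[0], axis_values[-1]
        step = axis_values[1] - axis_values[0] if len(axis_values) > 1 else 1.0
        values = np.asarray(values, dtype=float)
        tol = 1e-9
        if np.any(values < lo - tol) or np.any(values > hi + tol):
            raise ValueError(
                f"parameter value outside the map domain [{lo}, {hi}]"
            )
        # nearest grid index; exact midpoints resolve to the lower index
        idx = np.ceil((values - lo) / step - 0.5).astype(int)
        return np.clip(idx, 0, len(axis_values) - 1)

    def predict(self, X) -> np.ndarray:
        """Strategy labels for (theta, phi) rows via nearest grid point."""
        if not hasattr(self, "labels_"):
            raise AttributeError("StrategyMap is not fitted yet; call fit first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (theta, phi)")
        ti = self._grid_index(X[:, 0], self.simulation_.theta_values)
        pi = self._grid_index(X[:, 1], self.simulation_.phi_values)
        return self.labels_[ti * len(self.simulation_.phi_values) + pi]

    def to_frame(self) -> pd.DataFrame:
        """Map export: one row per grid point (theta, phi, cluster, label)."""
        pts = self.simulation_.points
        return pd.DataFrame(
            {
                "theta": pts[:, 0],
                "phi": pts[:, 1],
                "cluster": self.cluster_ids_,
                "label": self.labels_,
            }
        )

    def plot(self, participants: pd.DataFrame | None = None, ax=None):
        """Zone scatter of the parameter space, optionally with participants.

        ``participants`` needs columns theta, phi and (optionally) label.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        frame = self.to_frame()
        zone_colors = {"GR": "#bbbbbb", "GA": "#1f77b4", "IA": "#d62728", "MO": "#2ca02c"}
        for lab, group in frame.groupby("label"):
            ax.scatter(group["theta"], group["phi"], s=4, marker="s",
                       color=zone_colors.get(lab, "k"), alpha=0.4, label=lab)
        if participants is not None:
            ax.scatter(participants["theta"], participants["phi"], s=24,
                       color="k", marker="o", label="participants")
        ax.set_xlabel("theta")
        ax.set_ylabel("phi")
        ax.legend(loc="upper right", fontsize=8)
        return ax


def classify_participant(theta: float, phi: float, strategy_map: StrategyMap) -> str:
    """Strategy label of the grid point nearest to (theta, phi)."""
    return str(strategy_map.predict([[theta, phi]])[0])
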