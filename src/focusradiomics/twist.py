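"""Evolutionary joint feature selection and train/test splitting.

A chromosome encodes a feature subset (one bit per feature) together with an
assignment of every case to group A or group B.  Its fitness is the mean of
the two crossed k-NN accuracies (train on A, test on B, and vice versa) on
the selected features, so the optimiser simultaneously searches for an
informative feature subset and a pair of statistically interchangeable
groups on which that subset generalises.  A standard generational genetic
algorithm is used: tournament selection, uniform crossover applied
independently to the feature and split segments, per-bit mutation, and
elitism (so the best fitness is non-decreasing across generations).

Because the crossed accuracy saturates (fitness 1 is reachable with several
different subsets once the classes separate), chromosomes of equal accuracy
are ranked by the mean classification margin — how decisively the k-NN
votes agree with the true class — so selection keeps a gradient toward
subsets whose neighbourhoods are consistently pure rather than marginally
correct.  The reported fitness remains the plain crossed-accuracy mean.

Chromosomes for which either group lacks at least k+1 cases of each class
(making the crossed k-NN ill-defined) receive fitness 0 rather than being
repaired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .knn import _as_labels, knn_vote_scores


@dataclass
class TwistConfig:
    population_size: int = 100
    generations: int = 200
    tournament_size: int = 2
    crossover_prob: float = 0.9
    mutation_prob: float | None = None   # default 1 / genome length
    elitism: int = 1
    k: int = 3
    seed: int = 0
    init_feature_prob: float = 0.2       # sparse start
    balanced_accuracy: bool = False
    parsimony_penalty: float = 0.0       # per selected feature, off by default

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.init_feature_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mutation_prob is not None and not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass
class TwistResult:
    selected_features: list
    group_A: list
    group_B: list
    best_fitness: float
    fitness_history: list                  # per generation: (best, mean)
    feature_mask: np.ndarray = field(repr=False, default=None)
    split_assignment: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "group_A": list(self.group_A),
            "group_B": list(self.group_B),
            "best_fitness": self.best_fitness,
            "fitness_history": [list(h) for h in self.fitness_history],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path, table: pd.DataFrame | None = None) -> "TwistResult":
        d = json.loads(Path(path).read_text())
        res = cls(d["selected_features"], d["group_A"], d["group_B"],
                  d["best_fitness"], [tuple(h) for h in d["fitness_history"]])
        if table is not None:
            cols = [c for c in table.columns if c != "label"]
            res.feature_mask = np.isin(cols, res.selected_features)
            res.split_assignment = np.isin(table.index.to_numpy(), res.group_A)
        return res


def _split_table(table: pd.DataFrame):
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    cols = [c for c in table.columns if c != "label"]
    X = table[cols].to_numpy(dtype=float)
    y = _as_labels(table["label"].to_numpy())
    return X, y, cols


def _crossed_scores(X, y, feat, split, k):
    """((acc A->B, acc B->A), (margin A->B, margin B->A)), or None when a
    group lacks k+1 cases of a class."""
    a, b = split, ~split
    for grp in (a, b):
        ny = int(y[grp].sum())
        if ny < k + 1 or int(grp.sum()) - ny < k + 1:
            return None
    Xa, Xb = X[a][:, feat], X[b][:, feat]
    try:
        acc_ab, m_ab = knn_vote_scores(Xa, y[a], Xb, y[b], k=k)
        acc_ba, m_ba = knn_vote_scores(Xb, y[b], Xa, y[a], k=k)
    except ValueError:         # all selected features constant in a group
        return None
    return (acc_ab, acc_ba), (m_ab, m_ba)


def fitness(feature_mask: np.ndarray, split_assignment: np.ndarray,
            table: pd.DataFrame, k: int = 3,
            parsimony_penalty: float = 0.0) -> float:
    """Mean of the two crossed k-NN accuracies for one chromosome.

    Invalid chromosomes (no feature selected, or a group with fewer than
    k+1 cases of either class) score 0.
    """
    X, y, _ = _split_table(table)
    feat = np.asarray(feature_mask, dtype=bool)
    split = np.asarray(split_assignment, dtype=bool)
    if feat.sum() == 0:
        return 0.0
    scores = _crossed_scores(X, y, feat, split, k)
    if scores is None:
        return 0.0
    f = float(np.mean(scores[0])) - parsimony_penalty * int(feat.sum())
    return max(0.0, min(1.0, f))


def evolve(table: pd.DataFrame, cfg: TwistConfig | None = None) -> TwistResult:
    """Run the genetic algorithm; fully reproducible from ``cfg.seed``."""
    cfg = cfg or TwistConfig()
    X, y, cols = _split_table(table)
    n, p = X.shape
    k = cfg.k
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 * (k + 1) or n_neg < 2 * (k + 1):
        raise ValueError(
            f"need at least {2 * (k + 1)} cases of each class to form two "
            "valid groups")
    rng = np.random.default_rng(cfg.seed)
    pm = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / (n + p)
    P = cfg.population_size

    def ensure_feature(feat_row):
        if not feat_row.any():
            feat_row[rng.integers(p)] = True
        return feat_row

    pop_feat = rng.random((P, p)) < cfg.init_feature_prob
    for row in pop_feat:
        ensure_feature(row)
    pop_split = rng.random((P, n)) < 0.5

    def evaluate(feat, split):
        """(fitness, margin): fitness is the crossed-accuracy mean in [0, 1];
        the margin only breaks ties between equal-fitness chromosomes."""
        if not feat.any():
            return 0.0, -1.0
        scores = _crossed_scores(X, y, feat, split, k)
        if scores is None:
            return 0.0, -1.0
        f = float(np.mean(scores[0])) - cfg.parsimony_penalty * int(feat.sum())
        return max(0.0, min(1.0, f)), float(np.mean(scores[1]))

    pairs = [evaluate(pop_feat[i], pop_split[i]) for i in range(P)]
    fit_vals = np.array([f for f, _ in pairs])
    margins = np.array([m for _, m in pairs])
    history = [(float(fit_vals.max()), float(fit_vals.mean()))]

    def rank_order():
        # lexicographic: accuracy first, margin second, stable in index
        return np.lexsort((np.arange(P), -margins, -fit_vals))

    def tournament():
        idx = rng.integers(0, P, size=cfg.tournament_size)
        return max(idx, key=lambda i: (fit_vals[i], margins[i], -i))

    for _ in range(cfg.generations):
        order = rank_order()
        new_feat = [pop_feat[i].copy() for i in order[:cfg.elitism]]
        new_split = [pop_split[i].copy() for i in order[:cfg.elitism]]
        while len(new_feat) < P:
            i1, i2 = tournament(), tournament()
            child_f = pop_feat[i1].copy()
            child_s = pop_split[i1].copy()
            if rng.random() < cfg.crossover_prob:    # uniform, per segment
                mix = rng.random(p) < 0.5
                child_f[mix] = pop_feat[i2][mix]
            if rng.random() < cfg.crossover_prob:
                mix = rng.random(n) < 0.5
                child_s[mix] = pop_split[i2][mix]
            child_f ^= rng.random(p) < pm
            child_s ^= rng.random(n) < pm
            ensure_feature(child_f)
            new_feat.append(child_f)
            new_split.append(child_s)
        pop_feat = np.array(new_feat)
        pop_split = np.array(new_split)
        pairs = [evaluate(pop_feat[i], pop_split[i]) for i in range(P)]
        fit_vals = np.array([f for f, _ in pairs])
        margins = np.array([m for _, m in pairs])
        history.append((float(fit_vals.max()), float(fit_vals.mean())))

    best = int(rank_order()[0])
    feat, split = pop_feat[best], pop_split[best]
    ids = table.index.to_numpy()
    return TwistResult(
        selected_features=[c for c, on in zip(cols, feat) if on],
        group_A=[str(i) for i in ids[split]],
        group_B=[str(i) for i in ids[~split]],
        best_fitness=float(fit_vals[best]),
        fitness_history=history,
        feature_mask=feat,
        split_assignment=split,
    )


def split_balance_report(result: TwistResult, table: pd.DataFrame,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per selected feature: Mann-Whitney comparison of groups A and B with
    Benjamini-Hochberg q-values, documenting the statistical homogeneity of
    the split (a homogeneous split should flag ~no features)."""
    rows = []
    in_a = table.index.isin(result.group_A)
    for feat in result.selected_features:
        a = table.loc[in_a, feat].to_numpy(dtype=float)
        b = table.loc[~in_a, feat].to_numpy(dtype=float)
        if len(a) == len(b) and np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0   # identical samples: no evidence of any difference
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": feat, "median_A": float(np.median(a)),
                     "median_B": float(np.median(b)), "p_value": p})
    report = pd.DataFrame(rows)
    if len(report):
        report["q_value"] = multipletests(report["p_value"], method="fdr_bh")[1]
        report["flagged"] = report["q_value"] < alpha
    return report
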