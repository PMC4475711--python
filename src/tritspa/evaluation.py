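"""Held-out evaluation: twofold split, Precision@N / Recall@N, grid search.

Protocol: split the records 50/50, build the network on the training half,
and try to recover the symptom–herb pairs that appear in the test half but
not in training. Training pairs are excluded from the candidate set (they
are known, not predictions). Per symptom with at least one held-out pair,

    Precision@N = |TopN ∩ T_p| / N,    Recall@N = |TopN ∩ T_p| / |T_p|,

macro-averaged over symptoms. Outcome tallies for the relevance filter are
taken from the full record set — the filter models outcome knowledge as a
dataset-level cleaning step, without which every unseen candidate pair
would be rejected for having no co-occurrence evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .network import TripartiteNetwork, build_network, observed_pairs
from .prediction import PredictionConfig, RankedPrediction, tri_tspa
from .records import PrescriptionRecord
from .similarity import SimilarityConfig


@dataclass
class EvaluationResult:
    """Per-N precision/recall plus the run's provenance."""

    metrics: dict[int, tuple[float, float]]  # N -> (precision, recall)
    n_symptoms_evaluated: int
    config: PredictionConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [(N, p, r) for N, (p, r) in sorted(self.metrics.items())]
        return pd.DataFrame(rows, columns=["N", "precision", "recall"])


def split_twofold(
    records: Sequence[PrescriptionRecord], seed: int
) -> tuple[list[PrescriptionRecord], list[PrescriptionRecord]]:
    """Random half/half record split, deterministic for a given seed."""
    if len(records) < 2:
        raise ValidationError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = len(records) // 2
    test_idx = set(order[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def precision_recall_at_n(
    predicted: Mapping[str, Sequence[RankedPrediction]],
    test_pairs: set[tuple[str, str]],
    N: int,
) -> tuple[float, float]:
    """Macro-averaged Precision@N and Recall@N against held-out pairs.

    Only symptoms with at least one held-out pair enter the average; with
    none at all the metrics are NaN.
    """
    if N < 1:
        raise ConfigurationError(f"N must be >= 1, got {N}")
    per_symptom: dict[str, set[str]] = {}
    for p, h in test_pairs:
        per_symptom.setdefault(p, set()).add(h)
    if not per_symptom:
        return float("nan"), float("nan")
    precisions, recalls = [], []
    for p, true_herbs in per_symptom.items():
        top = [rp.herb for rp in predicted.get(p, [])[:N]]
        hits = len(set(top) & true_herbs)
        precisions.append(hits / N)
        recalls.append(hits / len(true_herbs))
    return float(np.mean(precisions)), float(np.mean(recalls))


def held_out_pairs(
    train_net: TripartiteNetwork,
    train: Sequence[PrescriptionRecord],
    test: Sequence[PrescriptionRecord],
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """(train pairs, recoverable held-out pairs).

    A held-out pair must be absent from training and have both tokens in the
    training vocabulary — pairs with unseen tokens cannot be ranked by any
    method and are excluded from scoring.
    """
    train_pairs = observed_pairs(train, "PH")
    test_pairs = {
        (p, h)
        for (p, h) in observed_pairs(test, "PH")
        if (p, h) not in train_pairs
        and train_net.has_token("P", p)
        and train_net.has_token("H", h)
    }
    return train_pairs, test_pairs


def evaluate_split(
    train: Sequence[PrescriptionRecord],
    test: Sequence[PrescriptionRecord],
    cfg: PredictionConfig,
    N_grid: Sequence[int],
    seed: int = 0,
    relevance_records: Sequence[PrescriptionRecord] | None = None,
) -> EvaluationResult:
    """Score one explicit train/test split (see module docstring)."""
    if not N_grid:
        raise ConfigurationError("N_grid must be non-empty")
    net = build_network(train)
    train_pairs, test_pairs = held_out_pairs(net, train, test)
    if relevance_records is None:
        relevance_records = list(train) + list(test)
    relevance_net = build_network(list(relevance_records))
    max_n = max(N_grid)
    predicted = tri_tspa(
        net,
        cfg.with_top_n(max_n),
        symptoms=[p for p in net.symptom_vocab],
        exclude_pairs=train_pairs,
        relevance_network=relevance_net,
    )
    metrics = {
        int(N): precision_recall_at_n(predicted, test_pairs, int(N)) for N in N_grid
    }
    n_eval = len({p for p, _ in test_pairs})
    return EvaluationResult(
        metrics=metrics, n_symptoms_evaluated=n_eval, config=cfg, seed=seed
    )


def evaluate(
    records: Sequence[PrescriptionRecord],
    cfg: PredictionConfig,
    N_grid: Sequence[int],
    seed: int,
) -> EvaluationResult:
    """Twofold-split evaluation of one configuration."""
    train, test = split_twofold(records, seed)
    return evaluate_split(train, test, cfg, N_grid, seed=seed, relevance_records=records)


def chance_precision(
    train_net: TripartiteNetwork,
    train_pairs: set[tuple[str, str]],
    test_pairs: set[tuple[str, str]],
) -> float:
    """Analytic Precision@N of a uniformly random ranking.

    For a random ordering of the candidate herbs of symptom p, the expected
    fraction of hits in any prefix is |T_p| / |C_p|; macro-averaged over the
    evaluated symptoms it is the chance level every method must beat.
    """
    per_symptom: dict[str, set[str]] = {}
    for p, h in test_pairs:
        per_symptom.setdefault(p, set()).add(h)
    if not per_symptom:
        return float("nan")
    n_herbs = len(train_net.herb_vocab)
    levels = []
    for p, true_herbs in per_symptom.items():
        known = sum(1 for (pp, _) in train_pairs if pp == p)
        n_candidates = n_herbs - known
        levels.append(len(true_herbs) / n_candidates if n_candidates > 0 else 0.0)
    return float(np.mean(levels))


def planted_recovery(
    records: Sequence[PrescriptionRecord],
    planted: set[tuple[str, str]],
    cfg: PredictionConfig,
    N: int = 30,
) -> tuple[float, float, float]:
    """Recovery of a known ground-truth pair set by the full pipeline.

    Builds the network on all records, runs the three-step prediction, and
    scores each symptom's Top-N list against its planted herbs (macro
    Precision@N and Recall@N). The third return value is the analytic
    chance level: the expected Precision@N of a uniformly random ranking,
    i.e. the mean planted fraction of the herb vocabulary over the scored
    symptoms. Used with synthetic corpora where the mediating structure is
    known exactly.
    """
    net = build_network(records)
    predicted = tri_tspa(net, cfg.with_top_n(N))
    per_symptom: dict[str, set[str]] = {}
    for p, h in planted:
        if net.has_token("P", p):
            per_symptom.setdefault(p, set()).add(h)
    if not per_symptom:
        return float("nan"), float("nan"), float("nan")
    n_herbs = len(net.herb_vocab)
    precs, recs, chance = [], [], []
    for p, true_herbs in per_symptom.items():
        top = {rp.herb for rp in predicted.get(p, [])[:N]}
        hits = len(top & true_herbs)
        precs.append(hits / N)
        recs.append(hits / len(true_herbs))
        chance.append(len(true_herbs) / n_herbs)
    return float(np.mean(precs)), float(np.mean(recs)), float(np.mean(chance))


_FREE_PARAMS = ("lambda0", "alpha", "alpha0", "beta0", "theta", "K")


def grid_search(
    records: Sequence[PrescriptionRecord],
    path: str,
    scheme: str,
    grids: Mapping[str, Sequence[float]],
    seed: int,
    top_n: int = 30,
    full_simplex: bool = False,
) -> tuple[PredictionConfig, pd.DataFrame]:
    """Exhaustive parameter search on a validation split carved from train.

    In the default mode the nine mixture parameters collapse to six free
    dimensions via the simplex constraints (lambda1 = 1 − lambda0, beta =
    1 − alpha, alpha1 = 1 − alpha0, beta1 = 1 − beta0); ``grids`` maps any
    of lambda0, alpha, alpha0, beta0, theta, K to candidate values, with
    the tuned defaults filling unlisted parameters. ``full_simplex=True``
    additionally accepts lambda1, beta, alpha1, beta1 grids and skips
    combinations violating a simplex constraint. Returns the argmax by
    Precision@top_n (first in grid order on ties) and the full score table.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ConfigurationError("grids must be non-empty")
    allowed = set(_FREE_PARAMS) | (
        {"lambda1", "beta", "alpha1", "beta1"} if full_simplex else set()
    )
    unknown = set(grids) - allowed
    if unknown:
        raise ConfigurationError(f"unknown grid parameter(s): {sorted(unknown)}")

    train, _ = split_twofold(records, seed)
    subtrain, validation = split_twofold(train, seed + 1)

    defaults = SimilarityConfig()
    names = list(grids.keys())
    rows = []
    best_cfg: PredictionConfig | None = None
    best_score = -np.inf
    for combo in itertools.product(*(grids[n] for n in names)):
        point = dict(zip(names, combo))
        lam0 = float(point.get("lambda0", defaults.lambda0))
        alpha = float(point.get("alpha", defaults.alpha))
        a0 = float(point.get("alpha0", defaults.alpha0))
        b0 = float(point.get("beta0", defaults.beta0))
        lam1 = float(point.get("lambda1", 1.0 - lam0))
        beta = float(point.get("beta", 1.0 - alpha))
        a1 = float(point.get("alpha1", 1.0 - a0))
        b1 = float(point.get("beta1", 1.0 - b0))
        theta = float(point.get("theta", 0.5))
        K = int(point.get("K", 30))
        try:
            sim_cfg = SimilarityConfig(lam0, lam1, alpha, beta, a0, a1, b0, b1)
            cfg = PredictionConfig(
                path=path, scheme=scheme, K=K, theta=theta, top_n=top_n,
                sim_config=sim_cfg,
            )
        except ConfigurationError:
            if full_simplex:
                continue  # infeasible corner of the raw 9-dim grid
            raise
        result = evaluate_split(
            subtrain, validation, cfg, [top_n], seed=seed,
            relevance_records=train,
        )
        precision = result.metrics[top_n][0]
        rows.append({**point, "precision": precision})
        score = -np.inf if np.isnan(precision) else precision
        if score > best_score:
            best_score = score
            best_cfg = cfg
    if best_cfg is None:
        raise ConfigurationError("no feasible grid point")
    return best_cfg, pd.DataFrame(rows)
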