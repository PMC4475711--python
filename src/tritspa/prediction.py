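"""The three-step tripartite prediction algorithm (Tri-TSPA).

For every symptom the algorithm (1) discovers the K nearest entities under
a meta-path composite similarity, (2) predicts a rating for each candidate
symptom–herb pair by a KNN-weighted sum over the weighted co-occurrence
blocks, (3) ranks candidates by rating, drops pairs that fail the
outcome-based relevance filter, and truncates to a Top-N list.

Rating forms (M_* are blocks weighted under the configured scheme):

* direct path:   rating(p, h) = Σ_{p' ∈ KNN(p)} sim(p, p') · M_PH[p', h]
* mediated path: rating(p, h) = Σ_{d : M_PD[p,d] > 0} M_PD[p, d] ·
                     Σ_{d' ∈ {d} ∪ KNN(d)} sim(d, d') · M_DH[d', h]
  where the anchor syndrome d participates with similarity exactly 1 so
  direct p–d–h evidence is never discarded.

Sums are not normalized by the neighbour similarity mass; ratings are
ordinal scores, only their ranking matters.

The relevance filter R(p, h | θ) is 1 iff the pair co-occurs in at least
one record AND its good-outcome fraction good/(good+bad) lies in [θ, 1];
pairs never observed together are filtered out. Filtering runs AFTER
ranking but BEFORE truncation, so a Top-N list still holds N relevant
patterns when enough survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .network import TripartiteNetwork
from .similarity import (
    SimilarityConfig,
    k_nearest,
    sim_pdh_matrix,
    sim_ph_matrix,
)
from .weighting import Scheme, WeightedMatrix, weight_block


class MetaPath(str, Enum):
    PH = "PH"
    PDH = "PDH"


@dataclass(frozen=True)
class PredictionConfig:
    """Everything the predictor needs: meta-path, weighting scheme, K
    neighbours, relevance threshold θ, list length N, mixture coefficients."""

    path: MetaPath = MetaPath.PDH
    scheme: Scheme = Scheme.TFIDF
    K: int = 30
    theta: float = 0.5
    top_n: int = 30
    sim_config: SimilarityConfig = field(default_factory=SimilarityConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", MetaPath(self.path))
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if self.K < 1:
            raise ConfigurationError(f"K must be >= 1, got {self.K}")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError(f"theta must be in [0, 1], got {self.theta}")
        if self.top_n < 1:
            raise ConfigurationError(f"top_n must be >= 1, got {self.top_n}")

    def with_top_n(self, top_n: int) -> "PredictionConfig":
        return replace(self, top_n=top_n)


@dataclass(frozen=True)
class RankedPrediction:
    """One row of a symptom's Top-N list."""

    symptom: str
    herb: str
    rating: float
    rank: int


class Predictor:
    """Precomputed weighted blocks + similarity matrix for one config.

    Building the blocks once makes scoring all symptoms cheap; the scalar
    entry point :func:`predict_rating` wraps this for one-off queries.
    """

    def __init__(self, network: TripartiteNetwork, cfg: PredictionConfig):
        self.network = network
        self.cfg = cfg
        scheme = cfg.scheme
        if cfg.path is MetaPath.PH:
            self.M_PH = weight_block(network, "PH", scheme)
            self.M_PP = weight_block(network, "PP", scheme)
            self.sim = sim_ph_matrix(self.M_PH, self.M_PP, cfg.sim_config)
        else:
            self.M_PD = weight_block(network, "PD", scheme)
            self.M_DH = weight_block(network, "DH", scheme)
            self.M_DD = weight_block(network, "DD", scheme)
            self.sim = sim_pdh_matrix(self.M_PD, self.M_DH, self.M_DD, cfg.sim_config)
            self._agg_DH = self._aggregate_dh()

    def _aggregate_dh(self) -> np.ndarray:
        """Per-syndrome herb profile smoothed over its K nearest syndromes.

        agg[d] = M_DH[d] + Σ_{(d', s) ∈ KNN(d)} s · M_DH[d'] — the anchor
        enters with similarity 1 regardless of the similarity matrix.
        """
        m = len(self.network.syndrome_vocab)
        agg = np.array(self.M_DH.values, dtype=np.float64, copy=True)
        universe = range(m)
        for d in range(m):
            for d2, s in k_nearest(d, self.cfg.K, self.sim, universe):
                agg[d] += s * self.M_DH.values[d2]
        return agg

    def ratings(self, p: int) -> np.ndarray:
        """Predicted rating of symptom p against every herb."""
        if self.cfg.path is MetaPath.PH:
            q = len(self.network.symptom_vocab)
            out = np.zeros(len(self.network.herb_vocab), dtype=np.float64)
            for p2, s in k_nearest(p, self.cfg.K, self.sim, range(q)):
                out += s * self.M_PH.values[p2]
            return out
        row = self.M_PD.values[p]
        active = row > 0
        return row[active] @ self._agg_DH[active]


def predict_rating(
    p: int | str, h: int | str, network: TripartiteNetwork, cfg: PredictionConfig
) -> float:
    """Rating of one symptom–herb pair; accepts indices or tokens."""
    pi = network.index("P", p) if isinstance(p, str) else int(p)
    hi = network.index("H", h) if isinstance(h, str) else int(h)
    if not 0 <= pi < len(network.symptom_vocab):
        raise LookupError(f"symptom index {pi} out of range")
    if not 0 <= hi < len(network.herb_vocab):
        raise LookupError(f"herb index {hi} out of range")
    return float(Predictor(network, cfg).ratings(pi)[hi])


def relevance(
    symptom: str, herb: str, network: TripartiteNetwork, theta: float
) -> int:
    """Outcome filter R(p, h | θ): see module docstring. Unknown tokens
    count as never-observed and return 0."""
    if not (network.has_token("P", symptom) and network.has_token("H", herb)):
        return 0
    pi = network.index("P", symptom)
    hi = network.index("H", herb)
    good = int(network.outcome_good["PH"][pi, hi])
    bad = int(network.outcome_bad["PH"][pi, hi])
    total = good + bad
    if total == 0:
        return 0
    ratio = good / total
    return 1 if ratio >= theta else 0


def tri_tspa(
    network: TripartiteNetwork,
    cfg: PredictionConfig,
    symptoms: Iterable[str] | None = None,
    exclude_pairs: set[tuple[str, str]] | None = None,
    relevance_network: TripartiteNetwork | None = None,
) -> dict[str, list[RankedPrediction]]:
    """Run the full three-step prediction for each symptom.

    ``exclude_pairs`` removes already-known symptom–herb pairs from the
    candidate set (held-out evaluation); ``relevance_network`` supplies the
    outcome tallies for the filter and defaults to ``network`` itself.
    Stage order per symptom: score → rank (ties by herb vocabulary order)
    → relevance-filter → truncate to ``cfg.top_n``.
    """
    if relevance_network is None:
        relevance_network = network
    if symptoms is None:
        symptoms = network.symptom_vocab
    exclude_pairs = exclude_pairs or set()
    predictor = Predictor(network, cfg)
    herb_vocab = network.herb_vocab

    results: dict[str, list[RankedPrediction]] = {}
    for p_tok in symptoms:
        pi = network.index("P", p_tok)
        scores = predictor.ratings(pi)
        candidates = [
            hi for hi, h_tok in enumerate(herb_vocab) if (p_tok, h_tok) not in exclude_pairs
        ]
        candidates.sort(key=lambda hi: (-scores[hi], hi))
        kept = [
            hi
            for hi in candidates
            if relevance(p_tok, herb_vocab[hi], relevance_network, cfg.theta) == 1
        ]
        results[p_tok] = [
            RankedPrediction(p_tok, herb_vocab[hi], float(scores[hi]), rank)
            for rank, hi in enumerate(kept[: cfg.top_n], start=1)
        ]
    return results


def predictions_frame(predictions: Mapping[str, Sequence[RankedPrediction]]):
    """Flatten a prediction map into a (symptom, herb, rating, rank) table."""
    import pandas as pd

    rows = [
        (rp.symptom, rp.herb, rp.rating, rp.rank)
        for symptom in predictions
        for rp in predictions[symptom]
    ]
    return pd.DataFrame(rows, columns=["symptom", "herb", "rating", "rank"])
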