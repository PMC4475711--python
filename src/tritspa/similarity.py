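"""Meta-path composite similarities and K-nearest-neighbour retrieval.

Two symptoms are alike if they select similar herbs and co-occur with
similar symptoms; two syndromes are alike if they arise from similar
symptoms, prescribe similar herbs, and co-occur with similar syndromes.
Both notions are realized as convex mixtures of cosine similarities over
rows (or columns) of weighted co-occurrence blocks:

* direct path  (symptom → herb):
  sim(px, py) = λ0·cos(PH rows) + λ1·cos(PP rows),    λ0 + λ1 = 1
* mediated path (symptom → syndrome → herb), comparing syndromes:
  sim(dx, dy) = α·(α0·cos(PD cols) + α1·cos(DD rows))
              + β·(β0·cos(DH rows) + β1·cos(DD rows)),
  with α + β = 1, α0 + α1 = 1, β0 + β1 = 1.

The symptom×syndrome block is compared by COLUMNS because a column is a
syndrome's symptom profile. A zero vector has cosine 0 against everything,
so an unconnected entity has similarity 0 rather than NaN.

Default mixture coefficients are the values tuned on the infertility
validation split: λ0 = 0.8, α = 0.7, α0 = β0 = 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .weighting import WeightedMatrix

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityConfig:
    """Mixture coefficients for the two composite similarities.

    Each coefficient pair must be strictly positive and sum to 1 (within
    1e-9): (lambda0, lambda1) for the direct path, (alpha, beta) for the
    outer mediated mixture and (alpha0, alpha1), (beta0, beta1) for its two
    inner mixtures.
    """

    lambda0: float = 0.8
    lambda1: float = 0.2
    alpha: float = 0.7
    beta: float = 0.3
    alpha0: float = 0.8
    alpha1: float = 0.2
    beta0: float = 0.8
    beta1: float = 0.2

    def __post_init__(self) -> None:
        pairs = [
            ("lambda0", self.lambda0, "lambda1", self.lambda1),
            ("alpha", self.alpha, "beta", self.beta),
            ("alpha0", self.alpha0, "alpha1", self.alpha1),
            ("beta0", self.beta0, "beta1", self.beta1),
        ]
        for name_a, a, name_b, b in pairs:
            if a <= 0 or b <= 0:
                raise ConfigurationError(
                    f"{name_a}={a} and {name_b}={b} must both be > 0"
                )
            if abs(a + b - 1.0) > _SIMPLEX_TOL:
                raise ConfigurationError(
                    f"{name_a} + {name_b} must equal 1, got {a + b}"
                )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def cosine_rows(M: WeightedMatrix, i: int, j: int) -> float:
    """Cosine similarity between rows i and j of a weighted block."""
    return _cosine(M.values[i], M.values[j])


def cosine_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs row cosine matrix; zero rows yield zero similarity."""
    norms = np.linalg.norm(values, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = values / safe[:, None]
    sims = unit @ unit.T
    return np.clip(sims, 0.0, 1.0)


def sim_ph_path(
    px: int, py: int, M_PH: WeightedMatrix, M_PP: WeightedMatrix, cfg: SimilarityConfig
) -> float:
    """Direct-path symptom similarity: λ0·cos(PH rows) + λ1·cos(PP rows)."""
    return cfg.lambda0 * cosine_rows(M_PH, px, py) + cfg.lambda1 * cosine_rows(M_PP, px, py)


def sim_pdh_path(
    dx: int,
    dy: int,
    M_PD: WeightedMatrix,
    M_DH: WeightedMatrix,
    M_DD: WeightedMatrix,
    cfg: SimilarityConfig,
) -> float:
    """Mediated-path syndrome similarity (see module docstring)."""
    sim_pd = _cosine(M_PD.values[:, dx], M_PD.values[:, dy])
    sim_dh = cosine_rows(M_DH, dx, dy)
    sim_dd = cosine_rows(M_DD, dx, dy)
    inner1 = cfg.alpha0 * sim_pd + cfg.alpha1 * sim_dd
    inner2 = cfg.beta0 * sim_dh + cfg.beta1 * sim_dd
    return cfg.alpha * inner1 + cfg.beta * inner2


def sim_ph_matrix(
    M_PH: WeightedMatrix, M_PP: WeightedMatrix, cfg: SimilarityConfig
) -> np.ndarray:
    """All-pairs direct-path symptom similarity matrix."""
    return cfg.lambda0 * cosine_matrix(M_PH.values) + cfg.lambda1 * cosine_matrix(
        M_PP.values
    )


def sim_pdh_matrix(
    M_PD: WeightedMatrix,
    M_DH: WeightedMatrix,
    M_DD: WeightedMatrix,
    cfg: SimilarityConfig,
) -> np.ndarray:
    """All-pairs mediated-path syndrome similarity matrix."""
    c_pd = cosine_matrix(M_PD.values.T)
    c_dh = cosine_matrix(M_DH.values)
    c_dd = cosine_matrix(M_DD.values)
    inner1 = cfg.alpha0 * c_pd + cfg.alpha1 * c_dd
    inner2 = cfg.beta0 * c_dh + cfg.beta1 * c_dd
    return cfg.alpha * inner1 + cfg.beta * inner2


def k_nearest(
    entity: int,
    K: int,
    sim: np.ndarray | Callable[[int, int], float],
    universe: Sequence[int],
) -> list[tuple[int, float]]:
    """The K most similar entities to ``entity``, excluding itself.

    ``sim`` is either a pairwise similarity function or a precomputed
    square matrix. Ordered by descending similarity, ties broken by
    vocabulary (index) order; returns fewer than K when the universe is
    small, and an empty list for an empty universe.
    """
    if K < 1:
        raise ConfigurationError(f"K must be >= 1, got {K}")
    if isinstance(sim, np.ndarray):
        lookup = lambda i, j: float(sim[i, j])  # noqa: E731
    else:
        lookup = lambda i, j: float(sim(i, j))  # noqa: E731
    candidates = [(u, lookup(entity, u)) for u in universe if u != entity]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:K]
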