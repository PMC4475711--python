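"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's vectorized code paths:
they recompute everything with plain loops, scalar formulas and full sorts,
so agreement between the two routes is a real check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from tritspa.network import TripartiteNetwork, build_network
from tritspa.records import PrescriptionRecord, make_record


@pytest.fixture
def toy_records() -> list[PrescriptionRecord]:
    """Small hand-written corpus exercising all three entity types and both
    outcomes."""
    return [
        make_record("r1", ["fever", "cough"], ["wind-heat"], ["mint", "mulberry"], "good"),
        make_record("r2", ["fever"], ["wind-heat"], ["mint", "forsythia"], "good"),
        make_record("r3", ["cough", "fatigue"], ["qi-deficiency"], ["ginseng"], "bad"),
        make_record("r4", ["fatigue"], ["qi-deficiency"], ["ginseng", "astragalus"], "good"),
        make_record("r5", ["fever", "fatigue"], ["wind-heat", "qi-deficiency"],
                    ["mint", "ginseng"], "bad"),
    ]


@pytest.fixture
def toy_network(toy_records) -> TripartiteNetwork:
    return build_network(toy_records)


def random_records(
    rng: np.random.Generator,
    n_records: int = 30,
    q: int = 8,
    m: int = 4,
    n: int = 10,
    allow_empty_syndromes: bool = False,
) -> list[PrescriptionRecord]:
    """Unstructured random corpus for property and equivalence tests."""
    records = []
    for i in range(n_records):
        symptoms = rng.choice(q, size=rng.integers(1, 4), replace=False)
        n_synd = int(rng.integers(0 if allow_empty_syndromes else 1, 3))
        syndromes = rng.choice(m, size=n_synd, replace=False)
        herbs = rng.choice(n, size=rng.integers(1, 5), replace=False)
        outcome = "good" if rng.random() < 0.7 else "bad"
        records.append(
            make_record(
                f"r{i}",
                [f"p{int(x)}" for x in symptoms],
                [f"d{int(x)}" for x in syndromes],
                [f"h{int(x)}" for x in herbs],
                outcome,
            )
        )
    return records


# ---------------------------------------------------------------------------
# scalar / brute-force oracles
# ---------------------------------------------------------------------------


def oracle_pair_counts(records, left: str, right: str) -> dict[tuple[str, str], int]:
    """Record-by-record pair enumeration (the counting definition)."""
    fields = {"P": "symptoms", "D": "syndromes", "H": "herbs"}
    out: dict[tuple[str, str], int] = {}
    for rec in records:
        for a in getattr(rec, fields[left]):
            for b in getattr(rec, fields[right]):
                out[(a, b)] = out.get((a, b), 0) + 1
    return out


def oracle_weight(scheme: str, pair: int, f_row: int, f_col: int) -> float:
    """Scalar re-derivation of the four weighting formulas."""
    if scheme == "F":
        return float(pair)
    if scheme == "JC":
        union = f_row + f_col - pair
        return pair / union if union > 0 else 0.0
    if scheme == "AM":
        return pair / f_row if f_row > 0 else 0.0
    if scheme == "TFIDF":
        return pair * math.log(f_row / pair) if pair > 0 else 0.0
    raise ValueError(scheme)


def oracle_cosine(a, b) -> float:
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return sum(x * y for x, y in zip(a, b)) / (na * nb)


def oracle_tri_tspa(network, cfg, exclude_pairs=None, relevance_network=None):
    """Independent straight-line reimplementation of the three-step method.

    Scalar loops only: per-cell weighting, per-pair cosines, full sorts.
    Mirrors the contract of :func:`tritspa.tri_tspa`.
    """
    from tritspa.network import BLOCKS

    exclude_pairs = exclude_pairs or set()
    reln = relevance_network if relevance_network is not None else network
    scheme = cfg.scheme.value
    sc = cfg.sim_config

    freqs = {"P": network.entity_freq_P, "D": network.entity_freq_D,
             "H": network.entity_freq_H}

    def weighted(block):
        counts = network.block(block)
        f_row = freqs[BLOCKS[block][0]]
        f_col = freqs[BLOCKS[block][1]]
        rows, cols = counts.shape
        return [
            [
                oracle_weight(scheme, int(counts[i, j]), int(f_row[i]), int(f_col[j]))
                for j in range(cols)
            ]
            for i in range(rows)
        ]

    q = len(network.symptom_vocab)
    m = len(network.syndrome_vocab)
    n = len(network.herb_vocab)

    if cfg.path.value == "PH":
        W_PH = weighted("PH")
        W_PP = weighted("PP")

        def sim(i, j):
            return sc.lambda0 * oracle_cosine(W_PH[i], W_PH[j]) + sc.lambda1 * oracle_cosine(
                W_PP[i], W_PP[j]
            )

        def rating(p, h):
            neigh = sorted(
                ((sim(p, p2), -p2) for p2 in range(q) if p2 != p),
                key=lambda t: (-t[0], -t[1]),
            )[: cfg.K]
            return sum(s * W_PH[-negp2][h] for s, negp2 in neigh)

    else:
        W_PD = weighted("PD")
        W_DH = weighted("DH")
        W_DD = weighted("DD")

        def sim(i, j):
            col_i = [W_PD[p][i] for p in range(q)]
            col_j = [W_PD[p][j] for p in range(q)]
            inner1 = sc.alpha0 * oracle_cosine(col_i, col_j) + sc.alpha1 * oracle_cosine(
                W_DD[i], W_DD[j]
            )
            inner2 = sc.beta0 * oracle_cosine(W_DH[i], W_DH[j]) + sc.beta1 * oracle_cosine(
                W_DD[i], W_DD[j]
            )
            return sc.alpha * inner1 + sc.beta * inner2

        def rating(p, h):
            total = 0.0
            for d in range(m):
                if W_PD[p][d] <= 0:
                    continue
                neigh = sorted(
                    ((sim(d, d2), -d2) for d2 in range(m) if d2 != d),
                    key=lambda t: (-t[0], -t[1]),
                )[: cfg.K]
                inner = W_DH[d][h] + sum(s * W_DH[-negd2][h] for s, negd2 in neigh)
                total += W_PD[p][d] * inner
            return total

    def rel(p_tok, h_tok):
        if not (reln.has_token("P", p_tok) and reln.has_token("H", h_tok)):
            return 0
        pi, hi = reln.index("P", p_tok), reln.index("H", h_tok)
        good = int(reln.outcome_good["PH"][pi, hi])
        bad = int(reln.outcome_bad["PH"][pi, hi])
        if good + bad == 0:
            return 0
        return 1 if good / (good + bad) >= cfg.theta else 0

    results = {}
    for p, p_tok in enumerate(network.symptom_vocab):
        scored = [
            (rating(p, h), h)
            for h in range(n)
            if (p_tok, network.herb_vocab[h]) not in exclude_pairs
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        kept = [
            (r, h) for r, h in scored if rel(p_tok, network.herb_vocab[h]) == 1
        ][: cfg.top_n]
        results[p_tok] = [
            (p_tok, network.herb_vocab[h], r, rank)
            for rank, (r, h) in enumerate(kept, start=1)
        ]
    return results
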