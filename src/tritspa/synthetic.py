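"""Synthetic prescription corpus generator.

Real prescription corpora are private, so the generator emulates their
published structure. Each syndrome owns a characteristic symptom pool and
herb pool (drawn uniformly from the vocabularies, ordered from core to
peripheral members); pool sizes default to the cross-type sharing rates
clinical corpora show (a symptom associates with ~19% of syndromes, a herb
with ~23%). A record carries one or two syndromes drawn by Zipf prevalence,
and its tokens come from the chosen syndromes' pools with positionally
Zipf-decaying weights — popularity therefore cascades from syndrome
prevalence and pool position, producing the heavy-tailed entity and link
frequency tables such corpora exhibit. Record sizes are scaled to the
vocabulary (a prescription of ~14 herbs out of 251 becomes ~4.5 out of 80).

Noise enters two ways. Each symptom draw escapes, with probability
``noise_rate``, to a uniform draw over the whole symptom vocabulary. Herb
noise is per record: with probability ``noise_rate`` the entire herb set is
drawn uniformly from the vocabulary instead of the pools — a mismatched
prescription. The outcome mechanism ties the bad label to that mismatch, so
the outcome-based relevance filter has a true signal: a record whose herb
set overlaps its syndromes' pools by less than half is labelled bad with
probability ``mismatch_bad_prob``, otherwise good. Everything is
reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ConfigurationError
from .records import BAD, GOOD, PrescriptionRecord


@dataclass(frozen=True)
class GroundTruth:
    """The generator's latent structure: per-syndrome token pools, ordered
    from core to peripheral members."""

    symptom_pools: dict[str, tuple[str, ...]]
    herb_pools: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters.

    Defaults describe a mid-sized specialist-clinic corpus scaled down to
    desk size: 50 symptoms, 10 syndromes, 80 herbs, 3000 encounters. Each
    syndrome is characterised by 10 symptoms and 18 herbs, so a symptom
    belongs to ~2 syndromes and a herb to ~2.3 — the sharing rates reported
    for real corpora. A record draws 1–2 syndromes, ~1.5 symptoms and ~4.5
    herbs (prescription sizes scaled by vocabulary ratio); 20% noise; a
    mismatched prescription is labelled bad 80% of the time. ``drop_type``
    empties one entity type in every record to mimic corpora lacking
    syndromes or symptoms.
    """

    q_symptoms: int = 50
    m_syndromes: int = 10
    n_herbs: int = 80
    n_records: int = 3000
    zipf_exponent: float = 1.0
    symptoms_per_syndrome: int = 10
    herbs_per_syndrome: int = 18
    syndromes_per_record: int = 2
    symptoms_per_record: float = 1.5
    herbs_per_record: float = 4.5
    noise_rate: float = 0.2
    mismatch_bad_prob: float = 0.8
    drop_type: str = "none"  # none | syndromes | symptoms
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_symptoms", "m_syndromes", "n_herbs", "n_records",
                     "symptoms_per_syndrome", "herbs_per_syndrome",
                     "syndromes_per_record"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("symptoms_per_record", "herbs_per_record"):
            if getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.zipf_exponent <= 0:
            raise ConfigurationError("zipf_exponent must be > 0")
        for name in ("noise_rate", "mismatch_bad_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.symptoms_per_syndrome > self.q_symptoms:
            raise ConfigurationError("symptoms_per_syndrome exceeds q_symptoms")
        if self.herbs_per_syndrome > self.n_herbs:
            raise ConfigurationError("herbs_per_syndrome exceeds n_herbs")
        if self.syndromes_per_record > self.m_syndromes:
            raise ConfigurationError("syndromes_per_record exceeds m_syndromes")
        if self.drop_type not in ("none", "syndromes", "symptoms"):
            raise ConfigurationError(
                f"drop_type must be none|syndromes|symptoms, got {self.drop_type!r}"
            )


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=np.float64) ** (-s)
    return w / w.sum()


def generate(cfg: SyntheticConfig) -> tuple[list[PrescriptionRecord], GroundTruth]:
    """Draw a corpus plus its latent pool structure.

    Per record: pick 1..``syndromes_per_record`` syndromes by Zipf
    prevalence; draw symptom and herb counts as 1 + Poisson(mean − 1); draw
    symptoms from the chosen syndromes' pools with position-decaying
    weights, each draw escaping to the full vocabulary with probability
    ``noise_rate``; draw herbs the same way, except that with probability
    ``noise_rate`` the whole herb set is drawn uniformly from the
    vocabulary (a mismatched prescription); label the outcome from the
    herb/pool overlap. ``drop_type`` then blanks the corresponding field.
    """
    rng = np.random.default_rng(cfg.seed)
    q, m, n = cfg.q_symptoms, cfg.m_syndromes, cfg.n_herbs
    p_tokens = [f"P{i:03d}" for i in range(q)]
    d_tokens = [f"D{i:02d}" for i in range(m)]
    h_tokens = [f"H{i:03d}" for i in range(n)]

    w_d = _zipf_weights(m, cfg.zipf_exponent)
    sym_pools = {d: rng.choice(q, cfg.symptoms_per_syndrome, replace=False) for d in range(m)}
    herb_pools = {d: rng.choice(n, cfg.herbs_per_syndrome, replace=False) for d in range(m)}
    # positional weights inside a pool: core members dominate
    w_sym_pos = _zipf_weights(cfg.symptoms_per_syndrome, cfg.zipf_exponent)
    w_herb_pos = _zipf_weights(cfg.herbs_per_syndrome, cfg.zipf_exponent)

    records: list[PrescriptionRecord] = []
    for r in range(cfg.n_records):
        k = int(rng.integers(1, cfg.syndromes_per_record + 1))
        ds = rng.choice(m, size=k, replace=False, p=w_d)
        sym_u, sym_w = _pool_union(ds, sym_pools, w_sym_pos)
        herb_u, herb_w = _pool_union(ds, herb_pools, w_herb_pos)

        n_sym = 1 + int(rng.poisson(cfg.symptoms_per_record - 1.0))
        n_herb = 1 + int(rng.poisson(cfg.herbs_per_record - 1.0))

        sym_picks = []
        for _ in range(n_sym):
            if cfg.noise_rate > 0.0 and rng.random() < cfg.noise_rate:
                sym_picks.append(int(rng.integers(0, q)))
            else:
                sym_picks.append(int(sym_u[rng.choice(len(sym_u), p=sym_w)]))
        symptoms = np.unique(np.array(sym_picks, dtype=np.int64))

        if cfg.noise_rate > 0.0 and rng.random() < cfg.noise_rate:
            herbs = np.unique(rng.integers(0, n, size=n_herb))
        else:
            herbs = np.unique(herb_u[rng.choice(len(herb_u), size=n_herb, p=herb_w)])

        in_pool = float(np.isin(herbs, herb_u).mean())
        if in_pool >= 0.5:
            outcome = GOOD
        else:
            outcome = BAD if rng.random() < cfg.mismatch_bad_prob else GOOD

        rec_syms = frozenset(p_tokens[i] for i in symptoms)
        rec_ds = frozenset(d_tokens[int(d)] for d in ds)
        rec_herbs = frozenset(h_tokens[int(i)] for i in herbs)
        if cfg.drop_type == "syndromes":
            rec_ds = frozenset()
        elif cfg.drop_type == "symptoms":
            rec_syms = frozenset()
        records.append(
            PrescriptionRecord(
                record_id=f"r{r:05d}",
                symptoms=rec_syms,
                syndromes=rec_ds,
                herbs=rec_herbs,
                outcome=outcome,
            )
        )

    truth = GroundTruth(
        symptom_pools={
            d_tokens[d]: tuple(p_tokens[int(i)] for i in sym_pools[d]) for d in range(m)
        },
        herb_pools={
            d_tokens[d]: tuple(h_tokens[int(i)] for i in herb_pools[d]) for d in range(m)
        },
    )
    return records, truth


def _pool_union(
    ds: np.ndarray, pools: dict[int, np.ndarray], pos_weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Union of the chosen syndromes' pools with summed positional weights."""
    weight: dict[int, float] = {}
    for d in ds:
        for pos, tok in enumerate(pools[int(d)]):
            weight[int(tok)] = weight.get(int(tok), 0.0) + float(pos_weights[pos])
    toks = np.array(sorted(weight), dtype=np.int64)
    w = np.array([weight[int(t)] for t in toks], dtype=np.float64)
    return toks, w / w.sum()


def planted_pairs(truth: GroundTruth) -> set[tuple[str, str]]:
    """All (symptom, herb) pairs that share at least one syndrome's pools —
    the pairs a correct mediated-path method should rank highly."""
    pairs: set[tuple[str, str]] = set()
    for d in truth.symptom_pools:
        for p in truth.symptom_pools[d]:
            for h in truth.herb_pools[d]:
                pairs.add((p, h))
    return pairs


def shuffle_syndromes(
    records: Iterable[PrescriptionRecord], seed: int
) -> list[PrescriptionRecord]:
    """Permute syndrome sets across records, destroying symptom–syndrome and
    syndrome–herb mediation while preserving every marginal distribution.
    Used to show the mediated-path signal is real and not an artefact."""
    records = list(records)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    return [
        PrescriptionRecord(
            rec.record_id,
            rec.symptoms,
            records[perm[i]].syndromes,
            rec.herbs,
            rec.outcome,
        )
        for i, rec in enumerate(records)
    ]
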