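"""The symptom–syndrome–herb tripartite network.

The network is built from prescription records: nodes are the distinct
symptom (P), syndrome (D) and herb (H) tokens, and a cross-type pair
(p, d), (d, h) or (p, h) gains one count for every record that contains
both tokens. The three node sets are disjoint and no intra-type edge exists
in the tripartite counts; homogeneous projections (P–P, D–D, H–H) are kept
separately and count co-membership in *good-outcome* records only, because
same-type co-prescription is evidence of compatibility only when the
treatment worked.

Per cross-type pair the network also tallies how many of its records had a
good vs a bad outcome; the relevance filter consumes these tallies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .records import GOOD, PrescriptionRecord

# block name -> (row entity type, col entity type); types are "P", "D", "H"
BLOCKS = {
    "PD": ("P", "D"),
    "DH": ("D", "H"),
    "PH": ("P", "H"),
    "PP": ("P", "P"),
    "DD": ("D", "D"),
    "HH": ("H", "H"),
}
CROSS_BLOCKS = ("PD", "DH", "PH")


@dataclass
class TripartiteNetwork:
    """Typed vocabularies plus raw co-occurrence count blocks.

    Vocabularies are sorted token lists, so a network rebuilt from the same
    records (in any order) is identical. ``outcome_good``/``outcome_bad``
    map each cross block name to a matrix of per-pair good/bad record
    tallies; for every pair good + bad equals the pair's total count.
    """

    symptom_vocab: list[str]
    syndrome_vocab: list[str]
    herb_vocab: list[str]
    counts_PD: np.ndarray
    counts_DH: np.ndarray
    counts_PH: np.ndarray
    counts_PP: np.ndarray
    counts_DD: np.ndarray
    counts_HH: np.ndarray
    entity_freq_P: np.ndarray
    entity_freq_D: np.ndarray
    entity_freq_H: np.ndarray
    outcome_good: dict[str, np.ndarray]
    outcome_bad: dict[str, np.ndarray]
    n_records: int = 0
    _index: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {
                "P": {t: i for i, t in enumerate(self.symptom_vocab)},
                "D": {t: i for i, t in enumerate(self.syndrome_vocab)},
                "H": {t: i for i, t in enumerate(self.herb_vocab)},
            }

    # -- lookups ---------------------------------------------------------

    def vocab(self, entity_type: str) -> list[str]:
        return {
            "P": self.symptom_vocab,
            "D": self.syndrome_vocab,
            "H": self.herb_vocab,
        }[entity_type]

    def entity_freq(self, entity_type: str) -> np.ndarray:
        return {
            "P": self.entity_freq_P,
            "D": self.entity_freq_D,
            "H": self.entity_freq_H,
        }[entity_type]

    def index(self, entity_type: str, token: str) -> int:
        try:
            return self._index[entity_type][token]
        except KeyError:
            raise LookupError(
                f"unknown {entity_type} token {token!r}"
            ) from None

    def has_token(self, entity_type: str, token: str) -> bool:
        return token in self._index[entity_type]

    def block(self, name: str) -> np.ndarray:
        if name not in BLOCKS:
            raise ConfigurationError(f"unknown block {name!r}")
        return getattr(self, f"counts_{name}")


def build_network(records: Sequence[PrescriptionRecord]) -> TripartiteNetwork:
    """Aggregate records into the tripartite network.

    Cross-type counts use all records; homogeneous counts use good-outcome
    records only; entity frequencies count records containing the token.
    """
    if not records:
        raise ValidationError("cannot build a network from zero records")

    p_vocab = sorted({t for r in records for t in r.symptoms})
    d_vocab = sorted({t for r in records for t in r.syndromes})
    h_vocab = sorted({t for r in records for t in r.herbs})
    overlap = (set(p_vocab) & set(d_vocab)) | (set(p_vocab) & set(h_vocab)) | (
        set(d_vocab) & set(h_vocab)
    )
    if overlap:
        raise ValidationError(
            f"entity vocabularies must be disjoint; shared token(s): {sorted(overlap)[:5]}"
        )

    p_idx = {t: i for i, t in enumerate(p_vocab)}
    d_idx = {t: i for i, t in enumerate(d_vocab)}
    h_idx = {t: i for i, t in enumerate(h_vocab)}
    q, m, n = len(p_vocab), len(d_vocab), len(h_vocab)

    counts = {
        "PD": np.zeros((q, m), dtype=np.int64),
        "DH": np.zeros((m, n), dtype=np.int64),
        "PH": np.zeros((q, n), dtype=np.int64),
        "PP": np.zeros((q, q), dtype=np.int64),
        "DD": np.zeros((m, m), dtype=np.int64),
        "HH": np.zeros((n, n), dtype=np.int64),
    }
    good = {b: np.zeros_like(counts[b]) for b in CROSS_BLOCKS}
    freq_p = np.zeros(q, dtype=np.int64)
    freq_d = np.zeros(m, dtype=np.int64)
    freq_h = np.zeros(n, dtype=np.int64)

    for rec in records:
        ps = sorted(p_idx[t] for t in rec.symptoms)
        ds = sorted(d_idx[t] for t in rec.syndromes)
        hs = sorted(h_idx[t] for t in rec.herbs)
        freq_p[ps] += 1
        freq_d[ds] += 1
        freq_h[hs] += 1
        is_good = rec.is_good
        for i, j in itertools.product(ps, ds):
            counts["PD"][i, j] += 1
            if is_good:
                good["PD"][i, j] += 1
        for i, j in itertools.product(ds, hs):
            counts["DH"][i, j] += 1
            if is_good:
                good["DH"][i, j] += 1
        for i, j in itertools.product(ps, hs):
            counts["PH"][i, j] += 1
            if is_good:
                good["PH"][i, j] += 1
        if is_good:
            for i, j in itertools.combinations(ps, 2):
                counts["PP"][i, j] += 1
                counts["PP"][j, i] += 1
            for i, j in itertools.combinations(ds, 2):
                counts["DD"][i, j] += 1
                counts["DD"][j, i] += 1
            for i, j in itertools.combinations(hs, 2):
                counts["HH"][i, j] += 1
                counts["HH"][j, i] += 1

    bad = {b: counts[b] - good[b] for b in CROSS_BLOCKS}
    return TripartiteNetwork(
        symptom_vocab=p_vocab,
        syndrome_vocab=d_vocab,
        herb_vocab=h_vocab,
        counts_PD=counts["PD"],
        counts_DH=counts["DH"],
        counts_PH=counts["PH"],
        counts_PP=counts["PP"],
        counts_DD=counts["DD"],
        counts_HH=counts["HH"],
        entity_freq_P=freq_p,
        entity_freq_D=freq_d,
        entity_freq_H=freq_h,
        outcome_good=good,
        outcome_bad=bad,
        n_records=len(records),
    )


def construct_virtual_objects(
    records_missing: Sequence[PrescriptionRecord],
    reference: TripartiteNetwork,
    virtual_prefix: str = "VIRT_",
) -> list[PrescriptionRecord]:
    """Repair records that lack one entity type using a reference network.

    For a corpus with empty syndromes, every observed (symptom, herb) pair is
    checked against the reference: if some syndrome d links to both endpoints
    (a p–d–h path exists), the record receives every such d. A record with at
    least one pair that matches nothing — or with no repaired tokens at all —
    additionally receives one fresh virtual syndrome (``VIRT_0001``, numbered
    in record order), which then links to all the record's endpoints when the
    network is rebuilt. Corpora with empty symptoms are repaired symmetrically
    via (syndrome, herb) pairs. Records that already carry the missing type
    pass through unchanged.
    """
    missing = _missing_type(records_missing)
    if missing is None:
        return list(records_missing)
    if not reference.vocab(missing):
        raise ConfigurationError(
            f"reference network has no {'syndromes' if missing == 'D' else 'symptoms'}; "
            "cannot construct virtual objects"
        )

    repaired: list[PrescriptionRecord] = []
    counter = itertools.count(1)
    for rec in records_missing:
        current = rec.syndromes if missing == "D" else rec.symptoms
        if current:
            repaired.append(rec)
            continue
        matched, any_unmatched = _match_reference(rec, reference, missing)
        if any_unmatched or not matched:
            matched = matched | {f"{virtual_prefix}{next(counter):04d}"}
        if missing == "D":
            new = PrescriptionRecord(
                rec.record_id, rec.symptoms, frozenset(matched), rec.herbs, rec.outcome
            )
        else:
            new = PrescriptionRecord(
                rec.record_id, frozenset(matched), rec.syndromes, rec.herbs, rec.outcome
            )
        repaired.append(new)
    return repaired


def _missing_type(records: Sequence[PrescriptionRecord]) -> str | None:
    """Which entity type the corpus lacks: 'D', 'P', or None."""
    if any(not r.syndromes for r in records):
        return "D"
    if any(not r.symptoms for r in records):
        return "P"
    return None


def _match_reference(
    rec: PrescriptionRecord, ref: TripartiteNetwork, missing: str
) -> tuple[set[str], bool]:
    matched: set[str] = set()
    any_unmatched = False
    if missing == "D":
        pairs = itertools.product(sorted(rec.symptoms), sorted(rec.herbs))
        for p, h in pairs:
            if not (ref.has_token("P", p) and ref.has_token("H", h)):
                any_unmatched = True
                continue
            pi, hi = ref.index("P", p), ref.index("H", h)
            hits = np.flatnonzero((ref.counts_PD[pi, :] > 0) & (ref.counts_DH[:, hi] > 0))
            if hits.size:
                matched.update(ref.syndrome_vocab[d] for d in hits)
            else:
                any_unmatched = True
    else:
        pairs = itertools.product(sorted(rec.syndromes), sorted(rec.herbs))
        for d, h in pairs:
            if not (ref.has_token("D", d) and ref.has_token("H", h)):
                any_unmatched = True
                continue
            di, hi = ref.index("D", d), ref.index("H", h)
            hits = np.flatnonzero((ref.counts_PD[:, di] > 0) & (ref.counts_PH[:, hi] > 0))
            if hits.size:
                matched.update(ref.symptom_vocab[p] for p in hits)
            else:
                any_unmatched = True
    return matched, any_unmatched


def network_summary(network: TripartiteNetwork) -> pd.DataFrame:
    """Dataset-properties table: entity counts, block densities, mean fanouts.

    Mirrors the usual summary of a clinical prescription corpus (number of
    prescriptions/herbs/symptoms/syndromes and the mean number of partners
    per entity across each cross-type block).
    """

    def _density(block: np.ndarray) -> float:
        return float(np.count_nonzero(block) / block.size) if block.size else float("nan")

    def _mean_fanout(block: np.ndarray, axis: int) -> float:
        if block.size == 0:
            return float("nan")
        per_entity = np.count_nonzero(block, axis=axis)
        return float(per_entity.mean())

    rows = [
        ("number of prescriptions", network.n_records),
        ("number of herbs", len(network.herb_vocab)),
        ("number of symptoms", len(network.symptom_vocab)),
        ("number of syndromes", len(network.syndrome_vocab)),
        ("symptoms per herb", _mean_fanout(network.counts_PH, axis=0)),
        ("syndromes per herb", _mean_fanout(network.counts_DH, axis=0)),
        ("herbs per symptom", _mean_fanout(network.counts_PH, axis=1)),
        ("herbs per syndrome", _mean_fanout(network.counts_DH, axis=1)),
        ("density PD", _density(network.counts_PD)),
        ("density DH", _density(network.counts_DH)),
        ("density PH", _density(network.counts_PH)),
    ]
    return pd.DataFrame(rows, columns=["property", "value"])


def observed_pairs(
    records: Iterable[PrescriptionRecord], kind: str = "PH"
) -> set[tuple[str, str]]:
    """All cross-type token pairs co-occurring in at least one record."""
    if kind not in CROSS_BLOCKS:
        raise ConfigurationError(f"unknown cross block {kind!r}")
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        left = {"P": rec.symptoms, "D": rec.syndromes}[BLOCKS[kind][0]]
        right = {"D": rec.syndromes, "H": rec.herbs}[BLOCKS[kind][1]]
        pairs.update(itertools.product(left, right))
    return pairs
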