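"""Co-occurrence weighting schemes.

A raw pair count F(x, y) — the number of records containing both tokens —
can be re-scored under four measurement strategies before any similarity or
rating is computed:

* ``F``      — the raw frequency itself.
* ``JC``     — Jaccard coefficient F(x,y) / (F(x) + F(y) − F(x,y)), the
  overlap of the two tokens' record sets.
* ``AM``     — asymmetric measure F(x,y) / F(x): the conditional rate at
  which y appears given x.
* ``TFIDF``  — F(x,y) · ln(F(x) / F(x,y)): the co-occurrence frequency
  damped by how unspecific the pair is for x. It vanishes both for unseen
  pairs and for pairs that occur in *every* record of x (ln 1 = 0).

AM and TFIDF condition on the ROW entity of the block being weighted, so a
weighted block answers "how strongly does this row token select that column
token". All schemes map a zero count to exactly 0 and never return NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ConfigurationError, InconsistentCountsError
from .network import BLOCKS, TripartiteNetwork


class Scheme(str, Enum):
    F = "F"
    JC = "JC"
    AM = "AM"
    TFIDF = "TFIDF"


@dataclass(frozen=True)
class WeightedMatrix:
    """A co-occurrence block re-scored under one weighting scheme."""

    row_vocab: list[str]
    col_vocab: list[str]
    values: np.ndarray
    scheme: Scheme

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def frequency(pair_count: float) -> float:
    """Raw co-occurrence count as a weight (the identity scheme)."""
    if pair_count < 0:
        raise InconsistentCountsError(f"negative pair count {pair_count}")
    return float(pair_count)


def jaccard(pair_count: int, freq_x: int, freq_y: int) -> float:
    """|x ∩ y| / |x ∪ y| over the two tokens' record sets; 0 when both empty."""
    _check(pair_count, freq_x, "freq_x")
    _check(pair_count, freq_y, "freq_y")
    union = freq_x + freq_y - pair_count
    if union == 0:
        return 0.0
    return float(pair_count) / float(union)


def asymmetric(pair_count: int, freq_conditioning: int) -> float:
    """|x ∩ y| / |conditioning token|: conditional co-occurrence rate."""
    _check(pair_count, freq_conditioning, "freq_conditioning")
    if freq_conditioning == 0:
        return 0.0
    return float(pair_count) / float(freq_conditioning)


def tfidf(pair_count: int, freq_ref: int) -> float:
    """pair_count · ln(freq_ref / pair_count); 0 at pair_count ∈ {0, freq_ref}."""
    _check(pair_count, freq_ref, "freq_ref")
    if pair_count == 0:
        return 0.0
    return float(pair_count) * math.log(freq_ref / pair_count)


def _check(pair_count: float, freq: float, name: str) -> None:
    if pair_count < 0:
        raise InconsistentCountsError(f"negative pair count {pair_count}")
    if freq < 0:
        raise InconsistentCountsError(f"negative {name} {freq}")
    if pair_count > freq:
        raise InconsistentCountsError(
            f"pair count {pair_count} exceeds {name} {freq}: a pair cannot "
            "co-occur more often than either member occurs"
        )


# row/col frequency vectors per block: which entity frequency applies
_ROW_FREQ = {"PD": "P", "DH": "D", "PH": "P", "PP": "P", "DD": "D", "HH": "H"}
_COL_FREQ = {"PD": "D", "DH": "H", "PH": "H", "PP": "P", "DD": "D", "HH": "H"}


def weight_block(
    network: TripartiteNetwork, block: str, scheme: Scheme | str
) -> WeightedMatrix:
    """Apply one weighting scheme element-wise to a network block.

    AM and TFIDF use the row entity's record frequency as the conditioning
    denominator; JC uses both row and column frequencies. Vectorized but
    cell-for-cell identical to the scalar functions above.
    """
    scheme = Scheme(scheme)
    if block not in BLOCKS:
        raise ConfigurationError(f"unknown block {block!r}")
    counts = network.block(block).astype(np.float64)
    row_freq = network.entity_freq(_ROW_FREQ[block]).astype(np.float64)
    col_freq = network.entity_freq(_COL_FREQ[block]).astype(np.float64)
    if counts.size and counts.max(initial=0.0) > 0:
        if (counts > row_freq[:, None]).any() or (counts > col_freq[None, :]).any():
            raise InconsistentCountsError(
                f"block {block}: a pair count exceeds a member frequency"
            )

    if scheme is Scheme.F:
        values = counts.copy()
    elif scheme is Scheme.JC:
        union = row_freq[:, None] + col_freq[None, :] - counts
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(union > 0, counts / np.where(union > 0, union, 1.0), 0.0)
    elif scheme is Scheme.AM:
        denom = np.where(row_freq > 0, row_freq, 1.0)[:, None]
        values = np.where(row_freq[:, None] > 0, counts / denom, 0.0)
    else:  # TFIDF
        safe_counts = np.where(counts > 0, counts, 1.0)
        safe_freq = np.where(row_freq > 0, row_freq, 1.0)[:, None]
        values = np.where(counts > 0, counts * np.log(safe_freq / safe_counts), 0.0)

    row_vocab = network.vocab(BLOCKS[block][0])
    col_vocab = network.vocab(BLOCKS[block][1])
    return WeightedMatrix(row_vocab=row_vocab, col_vocab=col_vocab, values=values, scheme=scheme)


def weighted_frame(matrix: WeightedMatrix):
    """Weighted block as a pandas DataFrame with token row/column labels."""
    import pandas as pd

    return pd.DataFrame(matrix.values, index=matrix.row_vocab, columns=matrix.col_vocab)
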