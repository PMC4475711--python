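"""Structural observations on a prescription network.

Clinical prescription corpora show heavy-tailed structure: a few herbs
appear in a large share of prescriptions while most are rare, and the same
holds for co-occurrence links and one-to-many fan-outs (herbs per symptom,
syndromes per herb, ...). This module produces the ranked frequency tables
and fits a power-law exponent to the frequency-of-frequencies histogram:
if the number of entities observed exactly x times is proportional to
x^(−γ), least squares on log–log axes recovers γ as minus the slope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ConfigurationError, InsufficientDataError
from .network import BLOCKS, CROSS_BLOCKS, TripartiteNetwork

_ENTITY_TYPES = {"symptom": "P", "syndrome": "D", "herb": "H"}


@dataclass
class DistributionReport:
    """A ranked frequency table with its power-law fit and summary stats."""

    kind: str  # entity_freq | link_freq | fanout
    target: str
    table: list[tuple[str, int]]  # (label, count), descending
    gamma: float | None
    r_squared: float | None
    mean: float
    top_percent_share: float | None = None


def frequency_table(
    network: TripartiteNetwork, target: str
) -> list[tuple[str, int]]:
    """Ranked (label, count) table for an entity type or a link block.

    ``target`` is one of symptom/syndrome/herb or PD/DH/PH. Entity counts
    are record frequencies; link tables enumerate observed pairs only.
    Descending by count, ties by label.
    """
    if target in _ENTITY_TYPES:
        t = _ENTITY_TYPES[target]
        vocab = network.vocab(t)
        freq = network.entity_freq(t)
        items = [(tok, int(f)) for tok, f in zip(vocab, freq)]
    elif target in CROSS_BLOCKS:
        block = network.block(target)
        row_vocab = network.vocab(BLOCKS[target][0])
        col_vocab = network.vocab(BLOCKS[target][1])
        rows, cols = np.nonzero(block)
        items = [
            (f"{row_vocab[i]}--{col_vocab[j]}", int(block[i, j]))
            for i, j in zip(rows, cols)
        ]
    else:
        raise ConfigurationError(
            f"unknown frequency target {target!r} "
            f"(expected one of {sorted(_ENTITY_TYPES)} or {list(CROSS_BLOCKS)})"
        )
    items.sort(key=lambda t: (-t[1], t[0]))
    return items


def fit_power_law(counts: Sequence[int]) -> tuple[float, float]:
    """Least-squares power-law exponent of a count sample.

    Builds the frequency-of-frequencies histogram (how many observations
    have count exactly x), regresses log(histogram) on log(x), and returns
    (gamma, R²) with gamma = −slope. Requires at least 3 distinct positive
    count values.
    """
    counts = [int(c) for c in counts]
    if any(c <= 0 for c in counts):
        raise ConfigurationError("counts must be positive integers")
    hist = Counter(counts)
    if len(hist) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct count values to fit, got {len(hist)}"
        )
    xs = np.array(sorted(hist), dtype=np.float64)
    ys = np.array([hist[int(x)] for x in xs], dtype=np.float64)
    fit = stats.linregress(np.log(xs), np.log(ys))
    return float(-fit.slope), float(fit.rvalue**2)


def rank_frequency_fit(counts: Sequence[int]) -> tuple[float, float]:
    """Log–log rank–frequency regression (Zipf plot) of a count table.

    Sorts the counts descending and regresses log(count) on log(rank) —
    the layout of the published entity-distribution figures. Returns
    (slope magnitude, R²). Requires at least 3 positive counts.
    """
    vals = np.sort(np.array([c for c in counts if c > 0], dtype=np.float64))[::-1]
    if vals.size < 3:
        raise InsufficientDataError("need >= 3 positive counts for a rank fit")
    ranks = np.arange(1, vals.size + 1, dtype=np.float64)
    fit = stats.linregress(np.log(ranks), np.log(vals))
    return float(-fit.slope), float(fit.rvalue**2)


def fit_power_law_mle(counts: Sequence[int], x_min: int = 1) -> float:
    """Discrete maximum-likelihood power-law exponent (zeta distribution).

    Alternative estimator to the default log–log regression: maximizes the
    likelihood of P(x) = x^(−γ) / ζ(γ, x_min) over the counts ≥ x_min.
    """
    xs = np.array([c for c in counts if c >= x_min], dtype=np.float64)
    if xs.size < 3:
        raise InsufficientDataError("need >= 3 observations at or above x_min")
    log_sum = float(np.log(xs).sum())

    def nll(gamma: float) -> float:
        return gamma * log_sum + xs.size * np.log(special.zeta(gamma, x_min))

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 10.0), method="bounded")
    return float(res.x)


@dataclass
class FanoutStats:
    """Distinct-partner counts per entity plus summary statistics."""

    counts: list[tuple[str, int]]  # (entity, n distinct partners), descending
    mean: float
    top_percent_share: float  # share of links held by the top 1% of entities


def fanout_stats(
    network: TripartiteNetwork, from_type: str, to_type: str
) -> FanoutStats:
    """One-to-many relationship profile between two entity types.

    Counts the distinct ``to_type`` partners of every ``from_type`` entity
    (e.g. herbs per symptom), with the mean fanout and the share of all
    links captured by the top 1% (at least one) of entities.
    """
    f = _ENTITY_TYPES.get(from_type, from_type)
    t = _ENTITY_TYPES.get(to_type, to_type)
    pair = f + t
    if pair in CROSS_BLOCKS:
        block = network.block(pair)
    elif pair[::-1] in CROSS_BLOCKS:
        block = network.block(pair[::-1]).T
    else:
        raise ConfigurationError(f"no cross block between {from_type} and {to_type}")
    vocab = network.vocab(f)
    fanout = np.count_nonzero(block, axis=1)
    items = sorted(zip(vocab, fanout.tolist()), key=lambda it: (-it[1], it[0]))
    total = int(fanout.sum())
    n_top = max(1, int(np.ceil(len(vocab) * 0.01)))
    top_share = (
        sum(c for _, c in items[:n_top]) / total if total > 0 else float("nan")
    )
    return FanoutStats(counts=items, mean=float(fanout.mean()), top_percent_share=float(top_share))


def distribution_report(
    network: TripartiteNetwork,
    kind: str,
    target: str,
    to_type: str | None = None,
) -> DistributionReport:
    """Assemble a full report: table, exponent fit, summary statistics.

    ``kind`` is ``entity_freq``, ``link_freq`` or ``fanout`` (the latter
    needs ``to_type``). The exponent fit is omitted (None) when the counts
    carry fewer than 3 distinct values.
    """
    if kind == "fanout":
        if to_type is None:
            raise ConfigurationError("fanout reports need a to_type")
        st = fanout_stats(network, target, to_type)
        table = st.counts
        mean = st.mean
        share = st.top_percent_share
        label = f"{target}->{to_type}"
    elif kind in ("entity_freq", "link_freq"):
        table = frequency_table(network, target)
        mean = float(np.mean([c for _, c in table])) if table else float("nan")
        share = None
        label = target
    else:
        raise ConfigurationError(f"unknown report kind {kind!r}")
    positive = [c for _, c in table if c > 0]
    try:
        gamma, r2 = fit_power_law(positive)
    except (InsufficientDataError, ConfigurationError):
        gamma, r2 = None, None
    return DistributionReport(
        kind=kind,
        target=label,
        table=table,
        gamma=gamma,
        r_squared=r2,
        mean=mean,
        top_percent_share=share,
    )
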