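"""Matching function: from a Top-N list to an effective herb combination.

A Top-N list ranks herbs individually, but herbs act in combination. The
matching function keeps only the largest subset of the Top-N herbs that was
actually prescribed together in a single good-outcome record containing the
symptom — the "longest chain" of co-attested interacting herbs. Ties go to
the earliest record; the result preserves the Top-N rating order and never
re-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .prediction import RankedPrediction
from .records import PrescriptionRecord


@dataclass(frozen=True)
class EffectiveCombination:
    """The maximum set of Top-N herbs co-attested in one good record."""

    symptom: str
    herbs: tuple[tuple[str, float], ...]  # (herb, rating), Top-N order

    def __len__(self) -> int:
        return len(self.herbs)

    @property
    def herb_set(self) -> frozenset[str]:
        return frozenset(h for h, _ in self.herbs)


def matching_function(
    top_list: Sequence[RankedPrediction],
    good_records: Sequence[PrescriptionRecord],
    symptom: str | None = None,
) -> EffectiveCombination:
    """Reduce one symptom's Top-N list to its largest single-record subset.

    Scans good-outcome records containing the symptom, intersects each herb
    set with the Top-N herbs, and returns the single largest intersection
    (earliest record on ties). With no supporting record — or an empty
    Top-N list — the combination is empty.
    """
    if symptom is None:
        symptom = top_list[0].symptom if top_list else ""
    top_herbs = {rp.herb for rp in top_list}

    best: frozenset[str] = frozenset()
    for rec in good_records:
        if not rec.is_good or symptom not in rec.symptoms:
            continue
        overlap = rec.herbs & top_herbs
        if len(overlap) > len(best):
            best = frozenset(overlap)

    herbs = tuple((rp.herb, rp.rating) for rp in top_list if rp.herb in best)
    return EffectiveCombination(symptom=symptom, herbs=herbs)
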