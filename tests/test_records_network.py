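"""Record I/O, network construction, and virtual-object repair."""

import itertools

import numpy as np
import pytest

from conftest import oracle_pair_counts, random_records
from tritspa.errors import ConfigurationError, FormatError, ValidationError
from tritspa.network import (
    build_network,
    construct_virtual_objects,
    network_summary,
    observed_pairs,
)
from tritspa.records import load_records, make_record, write_records


class TestRecordIO:
    def test_csv_roundtrip_preserves_records(self, toy_records, tmp_path):
        path = tmp_path / "records.csv"
        write_records(toy_records, path)
        loaded = load_records(path)
        assert loaded == toy_records

    def test_jsonl_roundtrip_preserves_records(self, toy_records, tmp_path):
        path = tmp_path / "records.jsonl"
        write_records(toy_records, path, format="jsonl")
        assert load_records(path) == toy_records

    def test_multivalue_cells_split_on_semicolons(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "record_id,symptoms,syndromes,herbs,outcome\n"
            "r1,fever,a,b,good\n"
        )
        (rec,) = load_records(path)
        assert rec.symptoms == {"fever"}
        assert rec.syndromes == {"a"}
        assert rec.herbs == {"b"}
        assert rec.outcome == "good"

    def test_duplicate_tokens_deduplicated_at_load(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "record_id,symptoms,syndromes,herbs,outcome\n"
            "r1,x;x;y,d,h,good\n"
        )
        (rec,) = load_records(path)
        assert len(rec.symptoms) == 2

    def test_empty_cells_yield_empty_sets(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("record_id,symptoms,syndromes,herbs,outcome\nr1,,,h1,good\n")
        (rec,) = load_records(path)
        assert rec.symptoms == frozenset() and rec.syndromes == frozenset()

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("record_id,symptoms,herbs,outcome\nr1,a,h,good\n")
        with pytest.raises(FormatError, match="syndromes"):
            load_records(path)

    def test_unknown_outcome_names_the_record(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("record_id,symptoms,syndromes,herbs,outcome\nr9,a,d,h,meh\n")
        with pytest.raises(ValidationError, match="r9"):
            load_records(path)

    def test_empty_herbs_rejected(self):
        with pytest.raises(ValidationError, match="herbs"):
            make_record("r1", ["a"], ["d"], [], "good")

    def test_tokens_trimmed(self):
        rec = make_record("r1", [" fever "], [], ["mint", " mint"], "good")
        assert rec.symptoms == {"fever"}
        assert rec.herbs == {"mint"}


class TestBuildNetwork:
    def test_pair_counting_definition(self):
        records = [
            make_record("r1", ["p1"], ["d1"], ["h1"], "good"),
            make_record("r2", ["p1"], ["d1"], ["h2"], "bad"),
        ]
        net = build_network(records)
        pd = net.counts_PD[net.index("P", "p1"), net.index("D", "d1")]
        ph1 = net.counts_PH[net.index("P", "p1"), net.index("H", "h1")]
        assert pd == 2 and ph1 == 1
        p1, h2 = net.index("P", "p1"), net.index("H", "h2")
        assert net.outcome_good["PH"][p1, h2] == 0
        assert net.outcome_bad["PH"][p1, h2] == 1

    def test_homogeneous_counts_symmetric_zero_diagonal(self):
        net = build_network([make_record("r", ["p1", "p2"], ["d1"], ["h1"], "good")])
        i, j = net.index("P", "p1"), net.index("P", "p2")
        assert net.counts_PP[i, j] == net.counts_PP[j, i] == 1
        assert np.all(np.diag(net.counts_PP) == 0)

    def test_homogeneous_counts_use_good_records_only(self):
        net = build_network(
            [
                make_record("r1", ["p1", "p2"], ["d1"], ["h1", "h2"], "bad"),
                make_record("r2", ["p1"], ["d1"], ["h1"], "good"),
            ]
        )
        assert net.counts_PP.sum() == 0 and net.counts_HH.sum() == 0

    def test_counts_match_bruteforce_enumeration(self):
        rng = np.random.default_rng(42)
        records = random_records(rng, n_records=25)
        net = build_network(records)
        for block, (left, right) in [("PD", ("P", "D")), ("DH", ("D", "H")), ("PH", ("P", "H"))]:
            expected = oracle_pair_counts(records, left, right)
            counts = net.block(block)
            for i, a in enumerate(net.vocab(left)):
                for j, b in enumerate(net.vocab(right)):
                    assert counts[i, j] == expected.get((a, b), 0)

    def test_outcome_tallies_partition_counts(self):
        rng = np.random.default_rng(7)
        net = build_network(random_records(rng))
        for block in ("PD", "DH", "PH"):
            assert np.array_equal(
                net.outcome_good[block] + net.outcome_bad[block], net.block(block)
            )

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        records = random_records(rng)
        net1 = build_network(records)
        net2 = build_network(records[::-1])
        assert net1.symptom_vocab == net2.symptom_vocab
        for block in ("PD", "DH", "PH", "PP", "DD", "HH"):
            assert np.array_equal(net1.block(block), net2.block(block))

    def test_incidence_conservation(self):
        rng = np.random.default_rng(11)
        records = random_records(rng)
        net = build_network(records)
        assert net.entity_freq_H.sum() == sum(len(r.herbs) for r in records)

    def test_pair_count_bounded_by_member_frequencies(self):
        rng = np.random.default_rng(5)
        net = build_network(random_records(rng))
        fp, fh = net.entity_freq_P, net.entity_freq_H
        bound = np.minimum(fp[:, None], fh[None, :])
        assert np.all(net.counts_PH <= bound)

    def test_shared_token_across_types_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            build_network([make_record("r", ["x"], ["x"], ["h"], "good")])

    def test_summary_has_entity_counts(self, toy_network):
        frame = network_summary(toy_network)
        table = dict(zip(frame["property"], frame["value"]))
        assert table["number of prescriptions"] == 5
        assert table["number of herbs"] == len(toy_network.herb_vocab)


class TestVirtualObjects:
    def _reference(self):
        return build_network(
            [
                make_record("ref1", ["p1"], ["d1"], ["h1"], "good"),
                make_record("ref2", ["p2"], ["d1"], ["h1"], "good"),
                make_record("ref3", ["p3"], ["d2"], ["h2"], "good"),
            ]
        )

    def test_matched_pair_receives_reference_syndrome(self):
        repaired = construct_virtual_objects(
            [make_record("r", ["p1"], [], ["h1"], "good")], self._reference()
        )
        assert repaired[0].syndromes == {"d1"}

    def test_unmatched_pair_receives_fresh_virtual_token(self):
        repaired = construct_virtual_objects(
            [make_record("r", ["p9"], [], ["h9"], "good")], self._reference()
        )
        assert repaired[0].syndromes == {"VIRT_0001"}
        rebuilt = build_network(repaired)
        v = rebuilt.index("D", "VIRT_0001")
        assert rebuilt.counts_PD[rebuilt.index("P", "p9"), v] == 1
        assert rebuilt.counts_DH[v, rebuilt.index("H", "h9")] == 1

    def test_record_with_syndromes_passes_through(self):
        rec = make_record("r", ["p1"], ["d7"], ["h1"], "good")
        assert construct_virtual_objects([rec], self._reference()) == [rec]

    def test_missing_symptoms_repaired_symmetrically(self):
        repaired = construct_virtual_objects(
            [make_record("r", [], ["d1"], ["h1"], "good")], self._reference()
        )
        # p1 and p2 both link to d1 and to h1 in the reference
        assert repaired[0].symptoms == {"p1", "p2"}

    def test_reference_without_syndromes_rejected(self):
        ref = build_network([make_record("x", ["p1"], [], ["h1"], "good")])
        with pytest.raises(ConfigurationError):
            construct_virtual_objects(
                [make_record("r", ["p1"], [], ["h1"], "good")], ref
            )

    def test_repair_preserves_record_count_and_tokens(self):
        rng = np.random.default_rng(9)
        records = [
            make_record(r.record_id, r.symptoms, [], r.herbs, r.outcome)
            for r in random_records(rng, n_records=15)
        ]
        repaired = construct_virtual_objects(records, self._reference())
        assert len(repaired) == len(records)
        for before, after in zip(records, repaired):
            assert after.symptoms == before.symptoms
            assert after.herbs == before.herbs
            assert after.syndromes  # repaired type is non-empty

    def test_virtual_tokens_assigned_in_record_order(self):
        records = [
            make_record("a", ["p8"], [], ["h8"], "good"),
            make_record("b", ["p9"], [], ["h9"], "good"),
        ]
        repaired = construct_virtual_objects(records, self._reference())
        assert repaired[0].syndromes == {"VIRT_0001"}
        assert repaired[1].syndromes == {"VIRT_0002"}


def test_observed_pairs_matches_enumeration(toy_records):
    pairs = observed_pairs(toy_records, "PH")
    expected = {
        (p, h)
        for rec in toy_records
        for p, h in itertools.product(rec.symptoms, rec.herbs)
    }
    assert pairs == expected
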