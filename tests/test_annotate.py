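import random

import pytest

from smallrna.annotate import (
    CascadeConfig,
    build_index,
    cascade_annotate,
    classify_isomir,
    map_read,
)
from smallrna.core_io import ReferenceLibrary
from oracles import hamming_scan_oracle


def _lib(cls, entries, name=None):
    return ReferenceLibrary(name=name or cls, rna_class=cls, entries=entries)


class TestMapRead:
    def test_exact_unique_hit(self):
        idx = build_index(_lib("miRNA", [("m1", "TGAGGTAGTAGGTTGTATAGTT")]))
        assert map_read("TGAGGTAGTAGGTTGTATAGTT", idx, 0) == [("m1", 0, 0)]

    def test_absent_query_no_hits(self):
        idx = build_index(_lib("miRNA", [("m1", "TGAGGTAGTAGGTTGTATAGTT")]))
        assert map_read("CCCCCCCCCC", idx, 0) == []

    def test_read_longer_than_references(self):
        idx = build_index(_lib("miRNA", [("m1", "ACGTACGT")]))
        assert map_read("ACGTACGTACGT", idx, 1) == []

    def test_tie_break_by_library_entry_order(self):
        idx = build_index(_lib("miRNA", [("m1", "AAACGTACGTAA"), ("m0", "GGACGTACGTGG")]))
        hits = map_read("ACGTACGT", idx, 0)
        assert [h[0] for h in hits] == ["m1", "m0"]

    def test_n_bases_never_match(self):
        idx = build_index(_lib("miRNA", [("m1", "ACGNACGT")]))
        assert map_read("ACGNACGT", idx, 0) == []
        assert map_read("ACGNACGT", idx, 1) == [("m1", 0, 1)]

    def test_equals_naive_hamming_scan(self):
        """Indexed lookup reproduces an all-positions Hamming scan on
        random 20-mers vs random references."""
        rng = random.Random(11)
        entries = [
            (f"ref{i}", "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 200))))
            for i in range(50)
        ]
        idx = build_index(_lib("mRNA", entries))
        for m in (0, 1, 2):
            for _ in range(40):
                if rng.random() < 0.5:  # planted query with mutations
                    ref = rng.choice(entries)[1]
                    k = 20
                    s = rng.randint(0, len(ref) - k)
                    q = list(ref[s : s + k])
                    for _ in range(rng.randint(0, 2)):
                        q[rng.randrange(k)] = rng.choice("ACGT")
                    query = "".join(q)
                else:
                    query = "".join(rng.choice("ACGT") for _ in range(20))
                assert map_read(query, idx, m) == hamming_scan_oracle(query, entries, m)


class TestCascade:
    def test_first_match_wins_over_later_library(self):
        mature = "TGAGGTAGTAGGTTGTATAGTT"
        config = CascadeConfig(
            [
                _lib("miRNA", [("mir-a", mature)]),
                _lib("piRNA", [("pir-a", mature + "AAAACCCC")]),
            ],
            max_mismatches=0,
        )
        table, assigns, summary = cascade_annotate({mature: 7}, config)
        assert assigns[0].rna_class == "miRNA" and assigns[0].feature_id == "mir-a"
        assert summary.class_totals == {"miRNA": 7, "piRNA": 0}

    def test_unmatched_reads_are_unassigned(self):
        config = CascadeConfig([_lib("miRNA", [("m1", "ACGTACGTACGTACGTACGT")])], 0)
        table, assigns, summary = cascade_annotate({"TTTTTTTTTTGGGGG": 3}, config)
        assert assigns == [] and summary.unassigned == 3
        assert len(table.features) == 0

    def test_partition_conservation(self):
        rng = random.Random(3)
        mirna = _lib("miRNA", [("m1", "TGAGGTAGTAGGTTGTATAGTT"), ("m2", "ACCCGTAGATCCGAACTTGTG")])
        trna = _lib("tRNA", [("t1", "".join(rng.choice("ACGT") for _ in range(75)))])
        config = CascadeConfig([mirna, trna])
        collapsed = {
            "TGAGGTAGTAGGTTGTATAGTT": 10,
            "ACCCGTAGATCCGAACTTGTG": 5,
            trna.entries[0][1][10:35]: 4,
            "GGGGGGGGGGGGGGGGGGGG": 2,
        }
        _, _, summary = cascade_annotate(collapsed, config)
        assert sum(summary.class_totals.values()) + summary.unassigned == 21
        assert summary.class_totals == {"miRNA": 15, "tRNA": 4}

    def test_raising_mismatches_never_decreases_class_totals(self):
        rng = random.Random(5)
        ref = "".join(rng.choice("ACGT") for _ in range(100))
        lib = _lib("mRNA", [("r1", ref)])
        reads = {}
        for i in range(30):
            s = rng.randint(0, 80)
            q = list(ref[s : s + 20])
            for _ in range(rng.randint(0, 2)):
                q[rng.randrange(20)] = rng.choice("ACGT")
            reads["".join(q)] = reads.get("".join(q), 0) + 1
        totals = []
        for m in (0, 1, 2):
            _, _, summary = cascade_annotate(reads, CascadeConfig([lib], m))
            totals.append(summary.class_totals["mRNA"])
        assert totals[0] <= totals[1] <= totals[2]

    def test_multimapper_counted_once_at_best_hit(self):
        lib = _lib("miRNA", [("m1", "AACGTACGTACGTACGTACGTAA"), ("m2", "CACGTACGTACGTACGTACGTCC")])
        _, assigns, summary = cascade_annotate({"ACGTACGTACGTACGTACGT": 6}, CascadeConfig([lib], 0))
        assert len(assigns) == 1 and assigns[0].feature_id == "m1"
        assert summary.class_totals["miRNA"] == 6

    def test_empty_library_list_errors(self):
        with pytest.raises(ValueError):
            CascadeConfig([])


class TestIsomir:
    MATURE = "TGAGGTAGTAGGTTGTATAGTT"
    # reference carrying +/-4 nt flanks; canonical interval (4, 26)
    REF = "ACCA" + MATURE + "GTCA"
    CANON = (4, 26)

    def classify(self, seq, offset):
        return classify_isomir(seq, offset, self.REF, self.CANON)

    def test_exact_mature_is_canonical(self):
        assert self.classify(self.MATURE, 4) == "canonical"

    def test_3p_trim_is_3p_shift(self):
        assert self.classify(self.MATURE[:-1], 4) == "3p_shift"

    def test_3p_extension_is_3p_shift(self):
        assert self.classify(self.MATURE + "G", 4) == "3p_shift"

    def test_5p_trim_is_5p_shift(self):
        assert self.classify(self.MATURE[1:], 5) == "5p_shift"

    def test_both_ends_shifted(self):
        # one base further 5' and one base short at 3'
        assert self.classify(self.REF[3:25], 3) == "both_shift"

    def test_without_flanks_whole_entry_is_canonical(self):
        assert classify_isomir(self.MATURE, 0, self.MATURE) == "canonical"
        assert classify_isomir(self.MATURE[:-2], 0, self.MATURE) == "3p_shift"

    def test_non_mirna_is_not_applicable_in_cascade(self):
        lib = _lib("tRNA", [("t1", "ACGTACGTACGTACGTACGTACGTACGT")])
        _, assigns, _ = cascade_annotate({"ACGTACGTACGTACGT": 1}, CascadeConfig([lib], 0))
        assert assigns[0].isomir_class == "not_applicable"

    def test_cascade_reports_isomir_classes(self):
        lib = ReferenceLibrary(
            "mir", "miRNA", [("m1", self.REF)], metadata={"m1": {"canonical": self.CANON}}
        )
        collapsed = {self.MATURE: 5, self.MATURE[:-2]: 2}
        _, assigns, _ = cascade_annotate(collapsed, CascadeConfig([lib], 0))
        got = {a.seq: a.isomir_class for a in assigns}
        assert got == {self.MATURE: "canonical", self.MATURE[:-2]: "3p_shift"}
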