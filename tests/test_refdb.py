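"""Reference database: amplicon extraction, identity, synonymy, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietbarcoder.refdb import (
    EMP_V9_PRIMERS,
    AmbiguousAmplificationError,
    NotDiscriminableError,
    PrimerNotFoundError,
    ReferenceDatabase,
    TaxonRecord,
    diagnostic_positions,
    extract_amplicon,
    find_synonymy_groups,
    merge_local_into_base,
    pairwise_identity,
    reverse_complement,
)

from conftest import random_seq
from oracles import exact_synonymy_partition, nw_semiglobal_identity, variable_columns

PRIMERS = EMP_V9_PRIMERS


def _record(rid, seq, species=None):
    return TaxonRecord(rid, ("Eukaryota", species or rid), seq, is_amplicon=True)


class TestExtractAmplicon:
    def test_exact_construction(self, rng):
        insert = random_seq(rng, 130)
        rec = TaxonRecord(
            "full1",
            ("Eukaryota", "Sp one"),
            "AATT" + PRIMERS.forward + insert + PRIMERS.reverse_rc + "CCGG",
        )
        out = extract_amplicon(rec, PRIMERS)
        assert out.sequence == insert
        assert out.is_amplicon

    def test_reverse_strand_template(self, rng):
        insert = random_seq(rng, 125)
        template = PRIMERS.forward + insert + PRIMERS.reverse_rc
        rec = TaxonRecord("rc1", ("Eukaryota", "Sp rc"), reverse_complement(template))
        assert extract_amplicon(rec, PRIMERS).sequence == insert

    def test_missing_reverse_site_raises(self, rng):
        rec = TaxonRecord(
            "norev", ("Eukaryota", "Sp"), PRIMERS.forward + random_seq(rng, 300)
        )
        with pytest.raises(PrimerNotFoundError):
            extract_amplicon(rec, PRIMERS)

    def test_short_primerless_input_passes_through(self, rng):
        rec = TaxonRecord("amp", ("Eukaryota", "Sp"), random_seq(rng, 130))
        out = extract_amplicon(rec, PRIMERS)
        assert out.sequence == rec.sequence
        assert out.is_amplicon

    def test_multiple_sites_ambiguous(self, rng):
        insert = random_seq(rng, 60)
        seq = PRIMERS.forward + insert + PRIMERS.reverse_rc + insert + PRIMERS.reverse_rc
        with pytest.raises(AmbiguousAmplificationError):
            extract_amplicon(TaxonRecord("amb", ("E", "S"), seq), PRIMERS)

    def test_twenty_random_constructions_recover_insert_lengths(self):
        rng = np.random.default_rng(7)
        for i in range(20):
            length = int(rng.integers(120, 135))
            insert = random_seq(rng, length)
            rec = TaxonRecord(
                "r%02d" % i,
                ("Eukaryota", "Sp %d" % i),
                random_seq(rng, 40) + PRIMERS.forward + insert + PRIMERS.reverse_rc
                + random_seq(rng, 40),
            )
            out = extract_amplicon(rec, PRIMERS)
            assert out.sequence == insert
            assert len(out.sequence) == length


class TestPairwiseIdentity:
    def test_identical(self, rng):
        seq = random_seq(rng, 130)
        assert pairwise_identity(seq, seq) == (1.0, 130)

    def test_single_mismatch(self, rng):
        a = random_seq(rng, 130)
        b = a[:64] + ("A" if a[64] != "A" else "C") + a[65:]
        ident, alen = pairwise_identity(a, b)
        assert alen == 130
        assert ident == pytest.approx(129 / 130)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty-input"):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = random_seq(rng, int(rng.integers(30, 61)))
            b = list(a)
            # random substitutions and indels
            for _ in range(int(rng.integers(0, 6))):
                p = int(rng.integers(len(b)))
                op = rng.integers(3)
                if op == 0:
                    b[p] = "ACGT"[int(rng.integers(4))]
                elif op == 1 and len(b) > 5:
                    del b[p]
                else:
                    b.insert(p, "ACGT"[int(rng.integers(4))])
            b = "".join(b)
            assert pairwise_identity(a, b) == pytest.approx(
                nw_semiglobal_identity(a, b)
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=40),
        b=st.text(alphabet="ACGT", min_size=1, max_size=40),
    )
    def test_symmetric(self, a, b):
        assert pairwise_identity(a, b)[0] == pytest.approx(pairwise_identity(b, a)[0])


class TestSynonymyGroups:
    def test_eight_identical_plus_distinct(self, rng):
        shared = random_seq(rng, 128)
        db = ReferenceDatabase(
            [_record("g%02d" % i, shared) for i in range(8)]
            + [_record("u%02d" % i, random_seq(rng, 128)) for i in range(5)]
        )
        groups = find_synonymy_groups(db)
        assert len(groups) == 1
        assert groups[0].member_ids == frozenset("g%02d" % i for i in range(8))
        assert groups[0].shared_sequence == shared

    def test_all_distinct_empty(self, rng):
        db = ReferenceDatabase(
            [_record("d%02d" % i, random_seq(rng, 130)) for i in range(10)]
        )
        assert find_synonymy_groups(db) == []

    def test_planted_groups_match_bruteforce(self):
        rng = np.random.default_rng(23)
        records = []
        idx = 0
        for size in (3, 2, 2):
            shared = random_seq(rng, int(rng.integers(120, 135)))
            for _ in range(size):
                records.append(_record("p%02d" % idx, shared))
                idx += 1
        while idx < 30:
            records.append(_record("p%02d" % idx, random_seq(rng, 130)))
            idx += 1
        db = ReferenceDatabase(records)
        got = sorted(
            [sorted(g.member_ids) for g in find_synonymy_groups(db)],
            key=lambda g: g[0],
        )
        expected = exact_synonymy_partition({r.id: r.sequence for r in records})
        assert got == expected

    def test_containment_counts_as_synonymy(self, rng):
        long = random_seq(rng, 130)
        db = ReferenceDatabase([_record("lng", long), _record("sub", long[10:100])])
        groups = find_synonymy_groups(db, min_overlap=64)
        assert len(groups) == 1
        # but not when the shared stretch is below the minimum overlap
        db2 = ReferenceDatabase([_record("lng", long), _record("sub", long[10:60])])
        assert find_synonymy_groups(db2, min_overlap=64) == []

    def test_partition_property(self, rng):
        shared = random_seq(rng, 130)
        db = ReferenceDatabase(
            [_record("a%d" % i, shared) for i in range(4)]
            + [_record("b%d" % i, random_seq(rng, 127)) for i in range(6)]
        )
        groups = find_synonymy_groups(db)
        seen = set()
        for g in groups:
            assert not (g.member_ids & seen)
            seen |= g.member_ids
            for m in g.member_ids:
                ident, alen = pairwise_identity(db[m].sequence, g.shared_sequence)
                assert ident == 1.0 and alen >= 64


class TestDiagnosticPositions:
    def test_clupeid_style_key(self, rng):
        base = random_seq(rng, 134)
        tuples = {
            "Clupea harengus": ("C", "G", "C"),
            "Sprattus sprattus": ("C", "A", "T"),
            "Sardina pilchardus": ("T", "G", "C"),
            "Engraulis encrasicolus": ("C", "G", "T"),
        }
        cols = (31, 77, 102)
        seqs = {}
        for sp, tup in tuples.items():
            s = list(base)
            for c, ch in zip(cols, tup):
                s[c] = ch
            seqs[sp] = "".join(s)
        key = diagnostic_positions(seqs, "Clupea harengus")
        assert key.positions == cols
        assert len(key.code_map) == 4
        assert key.code_map[("C", "A", "T")] == "Sprattus sprattus"

    def test_identical_pair_not_discriminable(self, rng):
        seq = random_seq(rng, 100)
        with pytest.raises(NotDiscriminableError):
            diagnostic_positions({"a": seq, "b": seq}, "a")

    def test_matches_column_scan_oracle(self):
        rng = np.random.default_rng(31)
        base = random_seq(rng, 90)
        seqs = {}
        for i in range(6):
            s = list(base)
            for c in (5, 40, 41, 77):
                s[c] = "ACGT"[int(rng.integers(4))]
            seqs["sp%d" % i] = "".join(s)
        if len(set(seqs.values())) < 6:
            pytest.skip("degenerate draw")  # pragma: no cover
        try:
            key = diagnostic_positions(seqs, "sp0")
        except NotDiscriminableError:
            return
        assert list(key.positions) == variable_columns(seqs)


class TestMergeLocalIntoBase:
    def test_disjoint_union(self, rng):
        base = ReferenceDatabase([_record("b%d" % i, random_seq(rng, 130)) for i in range(10)])
        local = ReferenceDatabase([_record("l%d" % i, random_seq(rng, 130)) for i in range(5)])
        merged, report = merge_local_into_base(base, local)
        assert len(merged) == 15

    def test_local_base_synonymy_flagged(self, rng):
        shared = random_seq(rng, 130)
        base = ReferenceDatabase([_record("silva1", shared)])
        local = ReferenceDatabase([_record("Clupea_local", shared)])
        merged, report = merge_local_into_base(base, local)
        assert any({"silva1", "Clupea_local"} <= g.member_ids for g in report)

    def test_empty_local_identity(self, rng):
        base = ReferenceDatabase([_record("b%d" % i, random_seq(rng, 130)) for i in range(3)])
        merged, _ = merge_local_into_base(base, ReferenceDatabase())
        assert merged.ids() == base.ids()

    def test_local_wins_collision(self, rng):
        base = ReferenceDatabase([_record("dup", random_seq(rng, 130))])
        local_seq = random_seq(rng, 130)
        local = ReferenceDatabase([_record("dup", local_seq)])
        merged, _ = merge_local_into_base(base, local)
        assert merged["dup"].sequence == local_seq
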