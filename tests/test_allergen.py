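import numpy as np
import pytest

from oracle import naive_shared_kmers

from safescreen import (
    ScreenRule,
    SequenceRecord,
    count_kmer_windows,
    full_length_allergen_screen,
    kmer_epitope_scan,
    sliding_window_screen,
)
from safescreen.synth import DecoySpec, PlantedHomolog, make_decoy_db

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(seed, n, rid="p"):
    rng = np.random.default_rng(seed)
    return SequenceRecord(rid, "", "protein",
                          "".join(rng.choice(list(AA), size=n)))


class TestCountKmerWindows:
    def test_hcas9_eight_mers(self, hcas9):
        assert count_kmer_windows(hcas9, 8) == 1416

    def test_boundary_length_equals_k(self, make_protein):
        assert count_kmer_windows(make_protein("EHIANLAG"), 8) == 1

    def test_short_sequence_warns_and_returns_zero(self, make_protein):
        with pytest.warns(UserWarning, match="shorter"):
            assert count_kmer_windows(make_protein("EHIANLA"), 8) == 0

    def test_invalid_k(self, make_protein):
        with pytest.raises(ValueError):
            count_kmer_windows(make_protein("MK"), 0)


class TestKmerEpitopeScan:
    def test_hcas9_vs_hevb9_single_shared_octamer(self, hcas9, hevb9):
        matches = kmer_epitope_scan(hcas9, [hevb9], 8)
        assert len(matches) == 1
        assert matches[0].kmer_string == "EHIANLAG"
        assert matches[0].subject_id == hevb9.id

    def test_self_scan_matches_every_window(self, make_protein):
        q = random_protein(3, 30)
        matches = kmer_epitope_scan(q, [q], 8)
        by_kmer = {m.kmer_string: m for m in matches}
        for i in range(30 - 8 + 1):
            kmer = q.residues[i:i + 8]
            assert i in by_kmer[kmer].query_positions
            assert by_kmer[kmer].query_positions == by_kmer[
                kmer].subject_positions

    def test_planted_kmer_matches_naive_oracle(self, hcas9):
        spec = DecoySpec(n_records=4, length_range=(60, 200),
                         planted_epitopes=(("EHIANLAG", 1),), seed=5)
        db, manifest = make_decoy_db(spec)
        query = random_protein(6, 120, "q")
        query = SequenceRecord("q", "", "protein",
                               query.residues[:50] + "EHIANLAG"
                               + query.residues[58:])
        got = kmer_epitope_scan(query, db, 8)
        for subject in db:
            expected = naive_shared_kmers(query.residues, subject.residues, 8)
            mine = {m.kmer_string: m for m in got
                    if m.subject_id == subject.id}
            assert set(mine) == set(expected)
            for kmer, (qpos, spos) in expected.items():
                assert list(mine[kmer].query_positions) == sorted(qpos)
                assert list(mine[kmer].subject_positions) == sorted(spos)
        planted = [m for m in got if m.kmer_string == "EHIANLAG"
                   and m.subject_id == manifest[0]["record_id"]]
        assert planted and manifest[0]["offset"] in planted[0].subject_positions

    def test_kmers_containing_x_never_match(self):
        q = SequenceRecord("q", "", "protein", "MKVXLYAH" * 2)
        assert kmer_epitope_scan(q, [q], 8) == []

    def test_symmetry_of_shared_kmer_sets(self):
        a = random_protein(7, 60, "a")
        b = SequenceRecord("b", "", "protein",
                           a.residues[20:40] + random_protein(8, 40).residues)
        ab = {m.kmer_string for m in kmer_epitope_scan(a, [b], 8)}
        ba = {m.kmer_string for m in kmer_epitope_scan(b, [a], 8)}
        assert ab == ba

    def test_empty_database_warns(self, make_protein):
        with pytest.warns(UserWarning, match="empty"):
            assert kmer_epitope_scan(make_protein("EHIANLAG"), [], 8) == []


class TestSlidingWindowScreen:
    def test_hcas9_vs_hevb9_no_flagged_windows(self, hcas9, hevb9, blosum62,
                                               default_rule):
        hits = sliding_window_screen(hcas9, [hevb9], blosum62, default_rule)
        assert sum(w.flagged for w in hits) == 0

    def test_query_in_database_flags_all_windows(self, blosum62,
                                                 default_rule):
        q = random_protein(9, 200, "q")
        hits = sliding_window_screen(q, [q], blosum62, default_rule)
        flagged_starts = {w.window_start for w in hits if w.flagged}
        assert flagged_starts == set(range(200 - 80 + 1))

    def test_planted_homolog_flag_thresholds(self, hcas9, blosum62,
                                             default_rule):
        def screen(identity, seed):
            spec = DecoySpec(n_records=4, length_range=(150, 300),
                             planted_homologs=(
                                 PlantedHomolog(hcas9, identity, 100),),
                             seed=seed)
            db, manifest = make_decoy_db(spec)
            hits = sliding_window_screen(hcas9, db, blosum62, default_rule)
            return manifest[0], [w for w in hits if w.flagged]

        manifest, flagged = screen(0.45, 21)
        overlapping = [
            w for w in flagged
            if w.alignment.subject_id == manifest["record_id"]
            and w.alignment.subject_start < manifest["offset"] + 100
            and w.alignment.subject_end > manifest["offset"]]
        assert overlapping

        _, flagged_low = screen(0.25, 22)
        assert flagged_low == []

    def test_short_query_uses_full_length_window(self, blosum62,
                                                 default_rule):
        q = random_protein(10, 40, "q")
        hits = sliding_window_screen(q, [q], blosum62, default_rule)
        assert len(hits) == 1
        assert hits[0].window_length == 40
        assert hits[0].flagged  # 100% identity over min(80, 40) columns

    def test_raising_threshold_never_grows_flagged_set(self, blosum62):
        q = random_protein(11, 150, "q")
        spec = DecoySpec(n_records=3, length_range=(100, 200),
                         planted_homologs=(PlantedHomolog(q, 0.5, 90),),
                         seed=3)
        db, _ = make_decoy_db(spec)
        key = lambda w: (w.window_start, w.alignment.subject_id)
        previous = None
        for threshold in (20.0, 35.0, 50.0, 80.0):
            rule = ScreenRule(identity_threshold=threshold)
            flagged = {key(w) for w in
                       sliding_window_screen(q, db, blosum62, rule)
                       if w.flagged}
            if previous is not None:
                assert flagged <= previous
            previous = flagged

    def test_empty_database(self, make_protein, blosum62, default_rule):
        with pytest.warns(UserWarning, match="empty"):
            assert sliding_window_screen(make_protein("EHIANLAG" * 12), [],
                                         blosum62, default_rule) == []


class TestFullLengthScreen:
    def test_hcas9_vs_hevb9_nothing_significant(self, hcas9, hevb9, blosum62,
                                                default_rule):
        hits = full_length_allergen_screen(hcas9, [hevb9], blosum62,
                                           default_rule)
        assert all(not h.significant for h in hits)

    def test_query_vs_itself_significant(self, blosum62, default_rule):
        q = random_protein(12, 120, "q")
        hits = full_length_allergen_screen(q, [q], blosum62, default_rule)
        assert len(hits) == 1
        assert hits[0].significant
        assert hits[0].percent_identity == 100.0
        assert hits[0].alignment_length == 120

    def test_planted_40_120_homolog_significant_only(self, hcas9, blosum62,
                                                     default_rule):
        spec = DecoySpec(n_records=5, length_range=(150, 400),
                         planted_homologs=(PlantedHomolog(hcas9, 0.40, 120),),
                         seed=33)
        db, manifest = make_decoy_db(spec)
        hits = full_length_allergen_screen(hcas9, db, blosum62, default_rule)
        significant = {h.accession for h in hits if h.significant}
        assert significant == {manifest[0]["record_id"]}

    def test_window_screen_collapses_to_full_length(self, blosum62):
        # window == query length -> the single window IS the full query
        q = random_protein(13, 90, "q")
        spec = DecoySpec(n_records=4, length_range=(90, 150),
                         planted_homologs=(PlantedHomolog(q, 0.6, 85),),
                         seed=14)
        db, _ = make_decoy_db(spec)
        rule = ScreenRule(window=90)
        window_flags = {
            w.alignment.subject_id: w.flagged
            for w in sliding_window_screen(q, db, blosum62, rule)}
        full_flags = {
            h.accession: h.significant
            for h in full_length_allergen_screen(q, db, blosum62, rule)}
        shared = window_flags.keys() & full_flags.keys()
        assert shared
        for subject in shared:
            assert window_flags[subject] == full_flags[subject]
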