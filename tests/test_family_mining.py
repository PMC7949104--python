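"""Filters, FASTA parsing and greedy redundancy reduction."""

import itertools

import pytest

from trxmine.alignment import fraction_identity
from trxmine.errors import DataError, ParseError
from trxmine.family_mining import (
    DomainHit,
    SequenceRecord,
    filter_active_site_cysteine,
    filter_by_evalue,
    filter_complete,
    read_fasta,
    reduce_redundancy,
    run_filter_pipeline,
    write_fasta,
)


def hit(seq_id, evalue=1e-10, ali_from=1, ali_to=10, as_from=None, as_to=None):
    return DomainHit(seq_id=seq_id, model="TRX", evalue=evalue,
                     ali_from=ali_from, ali_to=ali_to,
                     active_site_from=as_from, active_site_to=as_to)


class TestReadFasta:
    def test_two_entries(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">A\nMCGPC\n>B desc here\nMAAA\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["A", "B"]
        assert recs[0].residues == "MCGPC"
        assert recs[1].description == "desc here"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_empty_body_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">A\nMCGPC\n>B\n>C\nMAAA\n")
        with pytest.raises(ParseError, match="line 3.*empty body"):
            read_fasta(p)

    def test_data_before_header(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("MCGPC\n>A\nMAAA\n")
        with pytest.raises(ParseError, match="line 1"):
            read_fasta(p)

    def test_round_trip(self, tmp_path):
        recs = [SequenceRecord(id="A", residues="MCGPC"),
                SequenceRecord(id="B", residues="MAAA" * 40)]
        p = tmp_path / "out.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [
            (r.id, r.residues) for r in recs]


class TestSequenceRecord:
    def test_rejects_empty_and_invalid(self):
        with pytest.raises(DataError):
            SequenceRecord(id="A", residues="")
        with pytest.raises(DataError):
            SequenceRecord(id="A", residues="MABZ")

    def test_x_allowed(self):
        assert SequenceRecord(id="A", residues="MXA").residues == "MXA"


class TestEvalueFilter:
    def test_strictly_below_threshold(self):
        kept = filter_by_evalue([hit("A", 1e-6), hit("B", 1e-4)])
        assert kept == {"A"}

    def test_exact_threshold_removed(self):
        assert filter_by_evalue([hit("A", 1e-5)]) == set()

    def test_best_hit_governs(self):
        assert filter_by_evalue([hit("A", 1e-3), hit("A", 1e-7)]) == {"A"}

    def test_empty_hits(self):
        assert filter_by_evalue([]) == set()


class TestCompletenessFilter:
    @pytest.mark.parametrize("start,stop,kept", [
        (True, True, True), (True, False, False),
        (False, True, False), (False, False, False),
    ])
    def test_truth_table(self, start, stop, kept):
        rec = SequenceRecord(id="A", residues="MA", has_start=start, has_stop=stop)
        result, removed = filter_complete([rec])
        assert (len(result) == 1) is kept
        assert (removed == ["A"]) is not kept

    def test_simulator_truth(self, sim_dataset):
        kept, removed = filter_complete(sim_dataset.records)
        truth = sim_dataset.truth
        expected = {sid for sid in truth.family_of
                    if truth.has_start[sid] and truth.has_stop[sid]}
        assert {r.id for r in kept} == expected


class TestCysteineFilter:
    def test_cgyc_window_kept(self):
        rec = SequenceRecord(id="A", residues="MAAACGYCAAA")
        kept, _ = filter_active_site_cysteine(
            [rec], [hit("A", ali_to=11, as_from=5, as_to=8)])
        assert [r.id for r in kept] == ["A"]

    def test_no_cysteine_window_removed(self):
        rec = SequenceRecord(id="A", residues="MAAASGYSAAA")
        kept, removed = filter_active_site_cysteine(
            [rec], [hit("A", ali_to=11, as_from=5, as_to=8)])
        assert kept == [] and removed == ["A"]

    def test_single_terminal_cysteine_kept(self):
        # only the resolving cysteine present: still a superfamily member
        rec = SequenceRecord(id="A", residues="MAAASGYCAAA")
        kept, _ = filter_active_site_cysteine(
            [rec], [hit("A", ali_to=11, as_from=5, as_to=8)])
        assert [r.id for r in kept] == ["A"]

    def test_fallback_regex_in_span(self):
        rec = SequenceRecord(id="A", residues="MAAACPYCAAA")
        kept, _ = filter_active_site_cysteine([rec], [hit("A", ali_to=11)])
        assert [r.id for r in kept] == ["A"]

    def test_fallback_outside_span_removed(self):
        # motif exists but outside the hit's alignment span
        rec = SequenceRecord(id="A", residues="AAAAAAACPYC")
        kept, removed = filter_active_site_cysteine([rec], [hit("A", ali_to=6)])
        assert removed == ["A"]

    def test_record_without_hit_errors(self):
        rec = SequenceRecord(id="A", residues="MCGPC")
        with pytest.raises(DataError, match="A"):
            filter_active_site_cysteine([rec], [])


class TestRedundancy:
    def test_identical_collapse(self):
        recs = [SequenceRecord(id="A", residues="MCGPCA"),
                SequenceRecord(id="B", residues="MCGPCA")]
        reps, members = reduce_redundancy(recs)
        assert len(reps) == 1
        assert members == {"A": "A", "B": "A"}

    def test_disjoint_stay_apart(self):
        recs = [SequenceRecord(id="A", residues="MMMMMM"),
                SequenceRecord(id="B", residues="GGGGGG")]
        reps, _ = reduce_redundancy(recs)
        assert len(reps) == 2

    def test_planted_duplicates_match_bruteforce(self, rng):
        # 20 sequences: 10 bases plus 10 near-identical (95%) copies
        bases = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
                 for _ in range(10)]
        recs = []
        for i, base in enumerate(bases):
            recs.append(SequenceRecord(id=f"b{i}", residues=base))
            mutated = list(base)
            pos = int(rng.integers(40))
            mutated[pos] = "A" if mutated[pos] != "A" else "G"
            recs.append(SequenceRecord(id=f"d{i}", residues="".join(mutated)))
        reps, members = reduce_redundancy(recs, 0.90)

        # oracle: replay greedy clustering from brute-force all-pairs identity
        order = sorted(recs, key=lambda r: (-len(r.residues), r.id))
        oracle_reps, oracle_members = [], {}
        for rec in order:
            for rep in oracle_reps:
                if fraction_identity(rep.residues, rec.residues) >= 0.90:
                    oracle_members[rec.id] = rep.id
                    break
            else:
                oracle_reps.append(rec)
                oracle_members[rec.id] = rec.id
        assert members == oracle_members
        assert len(reps) == len(oracle_reps) == 10

    def test_every_member_maps_to_valid_representative(self, sim_dataset):
        reps, members = reduce_redundancy(sim_dataset.records, 0.95)
        rep_ids = {r.id for r in reps}
        seqs = {r.id: r.residues for r in sim_dataset.records}
        assert set(members) == set(seqs)
        for member, rep in members.items():
            assert rep in rep_ids
            if member != rep:
                assert fraction_identity(seqs[member], seqs[rep]) >= 0.95

    def test_threshold_monotonicity(self, sim_dataset):
        counts = [len(reduce_redundancy(sim_dataset.records, thr)[0])
                  for thr in (0.99, 0.9, 0.7, 0.5)]
        assert counts == sorted(counts, reverse=True)


class TestFilterPipeline:
    def test_counts_conserve(self, sim_dataset):
        kept, report = run_filter_pipeline(
            sim_dataset.records, sim_dataset.hits)
        assert report.n_input == len(sim_dataset.records)
        assert (report.n_kept + report.n_removed_redundant
                + report.n_removed_evalue + report.n_removed_incomplete
                + report.n_removed_no_cys) == report.n_input
        all_ids = list(itertools.chain(report.kept_ids,
                                       *report.removed_ids.values()))
        assert sorted(all_ids) == sorted(r.id for r in sim_dataset.records)

    def test_conservation_under_any_order(self, sim_dataset):
        for order in itertools.permutations(
                ("redundancy", "evalue", "complete", "cysteine")):
            _, report = run_filter_pipeline(
                sim_dataset.records, sim_dataset.hits, order=order)
            report.check_conservation()

    def test_incomplete_removed_matches_truth(self, sim_dataset):
        truth = sim_dataset.truth
        _, report = run_filter_pipeline(sim_dataset.records, sim_dataset.hits)
        incomplete_truth = {sid for sid in truth.family_of
                            if not (truth.has_start[sid] and truth.has_stop[sid])}
        # removed-as-incomplete must be exactly the planted fragments that
        # survived earlier stages
        assert set(report.removed_ids["incomplete"]) <= incomplete_truth
        surviving = incomplete_truth - set(report.removed_ids["redundant"]) \
            - set(report.removed_ids["evalue"])
        assert set(report.removed_ids["incomplete"]) == surviving
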