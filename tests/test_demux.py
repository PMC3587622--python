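"""Read classification: matched / ambiguous / unmatched semantics."""

import random

import pytest

from barkit.demux import (AMBIGUOUS, MATCHED, UNMATCHED, DemuxParams,
                          DemuxResult, SequenceRead, classify_read,
                          demultiplex_fastq, extract_window,
                          quality_tie_break)
from barkit.distance import AlignmentResult, semi_global_align
from barkit.generator import BarcodeSet
from barkit.kmer_index import build_index
from barkit.simulator import ErrorModel, simulate_reads, write_fastq
from conftest import lev_oracle, random_dna

Q30 = chr(33 + 30)


def read_of(seq, qual=None, name="r"):
    return SequenceRead(identifier=name, sequence=seq,
                        qualities=qual or Q30 * len(seq))


class TestExtractWindow:
    def test_zero_slack_takes_the_barcode_span(self):
        read = read_of("ACGT" * 12 + "AC")  # 50 bases
        p = DemuxParams(barcode_start=0, positional_error=0)
        assert extract_window(read, p, 18) == (read.sequence[:18], 0)

    def test_slack_widens_both_sides(self):
        read = read_of(random_dna(random.Random(0), 30))
        p = DemuxParams(barcode_start=5, positional_error=1)
        assert extract_window(read, p, 18) == (read.sequence[4:24], 4)

    def test_unknown_position_scans_whole_read(self):
        read = read_of("ACGTACGT")
        p = DemuxParams(positional_error=-1)
        assert extract_window(read, p, 4) == ("ACGTACGT", 0)

    def test_start_beyond_read_end_yields_empty_window(self):
        read = read_of("ACGT")
        p = DemuxParams(barcode_start=10, positional_error=0)
        window, _ = extract_window(read, p, 4)
        assert window == ""


class TestQualityTieBreak:
    def _tied(self, positions_a, positions_b):
        return [(0, AlignmentResult(1, 0, positions_a)),
                (1, AlignmentResult(1, 0, positions_b))]

    def test_low_quality_mismatch_wins(self):
        # candidate 0's mismatch sits on a Q2 base, candidate 1's on Q40.
        qual = chr(33 + 2) + chr(33 + 40) + Q30 * 6
        read = read_of("ACGTACGT", qual)
        winners = quality_tie_break(self._tied((0,), (1,)), read)
        assert [ident for ident, _ in winners] == [0]

    def test_identical_qualities_stay_tied(self):
        read = read_of("ACGTACGT")
        winners = quality_tie_break(self._tied((0,), (1,)), read)
        assert len(winners) == 2

    def test_three_way_tie_keeps_the_two_lowest(self):
        qual = "".join(chr(33 + q) for q in (5, 5, 30, 40, 40, 40, 40, 40))
        read = read_of("ACGTACGT", qual)
        tied = [(0, AlignmentResult(2, 0, (0, 1))),
                (1, AlignmentResult(2, 0, (1, 0))),
                (2, AlignmentResult(2, 0, (2, 3)))]
        winners = quality_tie_break(tied, read)
        assert sorted(ident for ident, _ in winners) == [0, 1]


@pytest.fixture(scope="module")
def setup(small_barcode_set):
    bset = small_barcode_set  # 50 barcodes, L=12, pairs >= 4
    index = build_index(bset, 6)
    params = DemuxParams(barcode_start=0, positional_error=0, k=6,
                         max_distance=1)
    return bset, index, params


class TestClassifyRead:
    def test_verbatim_barcode_with_tail_matches_at_distance_0(self, setup):
        bset, index, params = setup
        rng = random.Random(1)
        for ident in range(len(bset)):
            read = read_of(bset[ident] + random_dna(rng, 8))
            res = classify_read(read, index, bset, params)
            assert res == DemuxResult("r", MATCHED, barcode_id=ident,
                                      distance=0, offset=0)

    def test_every_single_substitution_is_corrected(self, setup):
        """Sets with pairwise distance >= 4 correct any 1-substitution read;
        exhaustive over all barcodes, positions and bases."""
        bset, index, params = setup
        for ident in range(len(bset)):
            barcode = bset[ident]
            for pos in range(12):
                for base in "ACGT".replace(barcode[pos], ""):
                    mutated = barcode[:pos] + base + barcode[pos + 1:]
                    res = classify_read(read_of(mutated), index, bset, params)
                    assert res.status == MATCHED
                    assert res.barcode_id == ident
                    assert res.distance == 1

    def test_every_single_indel_is_corrected_with_whole_read_scan(self, setup):
        """The same guarantee holds for one insertion or deletion when the
        window tolerates the shift (positional error -1 scans the read)."""
        bset, index, _ = setup
        params = DemuxParams(positional_error=-1, k=6, max_distance=1)
        for ident in range(0, len(bset), 5):
            barcode = bset[ident]
            variants = [barcode[:p] + barcode[p + 1:] for p in range(12)]
            variants += [barcode[:p] + b + barcode[p:]
                         for p in range(13) for b in "ACGT"]
            for var in variants:
                res = classify_read(read_of(var), index, bset, params)
                assert (res.status, res.barcode_id) == (MATCHED, ident), var

    def test_equidistant_read_is_ambiguous_not_matched(self):
        """A read two substitutions from each of two distance-4 barcodes
        must never be returned as matched under uniform qualities."""
        b1 = "ACGTACGTACGT"
        b2 = "CCGAACCTAGGT"  # b1 with substitutions at positions 0, 3, 6, 9
        assert lev_oracle(b1, b2) == 4
        midpoint = "CCGAACGTACGT"  # the first two of those four applied
        assert lev_oracle(midpoint, b1) == 2 and lev_oracle(midpoint, b2) == 2
        bset = BarcodeSet(barcodes=[b1, b2], length=12, min_distance=3,
                          padding=0)
        index = build_index(bset, 3)
        params = DemuxParams(k=3, max_distance=2)
        res = classify_read(read_of(midpoint), index, bset, params)
        assert res.status == AMBIGUOUS

    def test_quality_resolves_the_same_tie(self):
        b1 = "ACGTACGTACGT"
        b2 = "CCGAACCTAGGT"
        midpoint = "CCGAACGTACGT"
        bset = BarcodeSet(barcodes=[b1, b2], length=12, min_distance=3,
                          padding=0)
        index = build_index(bset, 3)
        params = DemuxParams(k=3, max_distance=2)
        # b1's edit columns sit at read positions 0 and 3, b2's at 6 and 9
        # (disjoint); lowering quality at 0 and 3 makes b1's mismatches the
        # more plausible sequencing errors, so b1 wins the tie.
        aln1 = semi_global_align(b1, midpoint)
        aln2 = semi_global_align(b2, midpoint)
        assert not set(aln1.mismatch_positions) & set(aln2.mismatch_positions)
        qual = [30] * 12
        for pos in aln1.mismatch_positions:
            qual[pos] = 2
        read = read_of(midpoint, "".join(chr(33 + q) for q in qual))
        res = classify_read(read, index, bset, params)
        assert (res.status, res.barcode_id) == (MATCHED, 0)

    def test_no_candidates_is_unmatched(self, setup):
        bset, index, params = setup
        res = classify_read(read_of("N" * 12), index, bset, params)
        assert res.status == UNMATCHED

    def test_distance_beyond_cutoff_is_unmatched(self, setup):
        bset, index, params = setup
        barcode = bset[0]
        mutated = list(barcode)
        for pos in (0, 4, 8):  # three substitutions > max_distance 1
            mutated[pos] = "ACGT".replace(barcode[pos], "")[0]
        res = classify_read(read_of("".join(mutated)), index, bset, params)
        assert res.status == UNMATCHED

    def test_index_route_equals_brute_force_route(self, small_barcode_set):
        """At the recommended k, index retrieval plus alignment agrees with
        aligning every barcode (reads within the recall condition)."""
        bset = small_barcode_set
        index = build_index(bset, 6)
        params = DemuxParams(barcode_start=0, positional_error=0, k=6,
                             max_distance=1)
        sim = simulate_reads(bset, 300, ErrorModel.substitutions_only(0.02),
                             seed=11)
        for read in sim.reads:
            got = classify_read(read, index, bset, params)
            window = read.sequence[:12]
            dists = [semi_global_align(b, window).distance for b in bset]
            best = min(dists)
            tied = [i for i, d in enumerate(dists) if d == best]
            if best > 1:
                assert got.status == UNMATCHED
            elif len(tied) == 1:
                assert (got.status, got.barcode_id) == (MATCHED, tied[0])
            else:
                assert got.status == AMBIGUOUS  # uniform qualities


@pytest.fixture(scope="module")
def demux_run(small_barcode_set, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("demux")
    bset = small_barcode_set
    sim = simulate_reads(bset, 200, ErrorModel(), seed=3)
    fq = tmp / "reads.fastq"
    write_fastq(sim, fq)
    params = DemuxParams(barcode_start=0, positional_error=0, k=6,
                         max_distance=1)
    counts, results = demultiplex_fastq(fq, bset, params, tmp / "out")
    return tmp, sim, counts, results


class TestDemultiplexFastq:
    def test_error_free_reads_all_match(self, demux_run):
        _, sim, counts, results = demux_run
        assert counts == {MATCHED: 200, AMBIGUOUS: 0, UNMATCHED: 0}
        for res in results:
            assert res.barcode_id == sim.truth[res.read_id]

    def test_matched_records_carry_annotation(self, demux_run, small_barcode_set):
        tmp, _, _, results = demux_run
        lines = (tmp / "out.matched.fastq").read_text().splitlines()
        assert len(lines) == 4 * 200
        first = results[0]
        expected = (f"+BC:{small_barcode_set[first.barcode_id]} "
                    f"ID:{first.barcode_id} ED:{first.distance}")
        assert lines[2] == expected

    def test_results_keep_input_order(self, demux_run):
        _, sim, _, results = demux_run
        assert [r.read_id for r in results] == [r.identifier for r in sim.reads]

    def test_threads_do_not_change_results(self, demux_run, small_barcode_set,
                                           tmp_path):
        tmp, _, counts, results = demux_run
        params = DemuxParams(barcode_start=0, positional_error=0, k=6,
                             max_distance=1)
        counts2, results2 = demultiplex_fastq(
            tmp / "reads.fastq", small_barcode_set, params,
            tmp_path / "out2", threads=3)
        assert counts2 == counts and results2 == results

    def test_empty_fastq(self, small_barcode_set, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        params = DemuxParams(k=6, max_distance=1)
        counts, results = demultiplex_fastq(fq, small_barcode_set, params,
                                            tmp_path / "out")
        assert counts == {MATCHED: 0, AMBIGUOUS: 0, UNMATCHED: 0}
        assert results == []
        assert (tmp_path / "out.matched.fastq").read_text() == ""

    def test_paired_end_mate_inherits_assignment(self, small_barcode_set,
                                                 tmp_path):
        bset = small_barcode_set
        sim = simulate_reads(bset, 20, ErrorModel(), seed=4)
        fq1 = tmp_path / "r1.fastq"
        write_fastq(sim, fq1)
        rng = random.Random(5)
        with open(tmp_path / "r2.fastq", "w") as fh:
            for r in sim.reads:
                fh.write(f"@{r.identifier}\n{random_dna(rng, 20)}\n+\n"
                         f"{Q30 * 20}\n")
        params = DemuxParams(k=6, max_distance=1)
        counts, _ = demultiplex_fastq(fq1, bset, params, tmp_path / "pe",
                                      fastq2=tmp_path / "r2.fastq")
        assert counts[MATCHED] == 20
        r1 = (tmp_path / "pe.matched.R1.fastq").read_text().splitlines()
        r2 = (tmp_path / "pe.matched.R2.fastq").read_text().splitlines()
        assert len(r1) == len(r2) == 80
        assert r1[2] == r2[2]  # the mate inherits read 1's annotation

    def test_paired_record_count_mismatch_is_an_error(self, small_barcode_set,
                                                      tmp_path):
        sim = simulate_reads(small_barcode_set, 3, ErrorModel(), seed=6)
        fq1 = tmp_path / "r1.fastq"
        write_fastq(sim, fq1)
        (tmp_path / "r2.fastq").write_text("@only\nACGT\n+\nIIII\n")
        params = DemuxParams(k=6, max_distance=1)
        with pytest.raises(ValueError, match="record count"):
            demultiplex_fastq(fq1, small_barcode_set, params,
                              tmp_path / "pe", fastq2=tmp_path / "r2.fastq")

    def test_malformed_record_names_its_index(self, small_barcode_set,
                                              tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@ok\nACGTACGTACGT\n+\n" + Q30 * 12 + "\n"
                      "@bad\nACGT\n+\nII\n")
        params = DemuxParams(k=6, max_distance=1)
        with pytest.raises(ValueError, match="record 1"):
            demultiplex_fastq(fq, small_barcode_set, params, tmp_path / "out")


def test_bare_barcode_list_requires_explicit_cutoff(small_barcode_set,
                                                    tmp_path):
    from barkit.generator import write_barcodes

    fq = tmp_path / "r.fastq"
    sim = simulate_reads(small_barcode_set, 2, ErrorModel(), seed=7)
    write_fastq(sim, fq)
    bc = tmp_path / "bc.txt"
    write_barcodes(small_barcode_set, bc)
    with pytest.raises(ValueError, match="max_distance"):
        demultiplex_fastq(fq, bc, DemuxParams(), tmp_path / "out")
    counts, _ = demultiplex_fastq(fq, bc, DemuxParams(k=6, max_distance=1),
                                  tmp_path / "out2")
    assert counts[MATCHED] == 2
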