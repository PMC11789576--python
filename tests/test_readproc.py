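"""Trimming, barcode correction, k-mer assignment, UMI counting, demux."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpipe
from snpipe.readproc import BarcodeCorrector, KmerIndex, SegmentedCorrector

LAYOUT = snpipe.BarcodeLayout(primer="ACGTACGTAC", min_dA_run=4)


def brute_force_correct(observed: str, whitelist: list[str], max_hamming: int):
    """Independent all-pairs Hamming oracle for barcode correction."""
    dists = [(sum(a != b for a, b in zip(observed, w)), w) for w in whitelist]
    dmin = min(d for d, _ in dists)
    if dmin == 0:
        return ("exact", observed, 0)
    within = [w for d, w in dists if d <= max_hamming]
    if not within:
        return ("unmatched", None, dmin)
    if len(within) > 1:
        return ("ambiguous", None, dmin)
    return ("corrected", within[0], dmin)


class TestTrimInsert:
    def test_primer_and_tail_removed(self):
        trimmed, short = snpipe.trim_insert("ACGTACGTAC" + "TTGGCC" + "AAAAAA", LAYOUT)
        assert trimmed == "TTGGCC" and not short

    def test_primer_with_one_mismatch_removed(self):
        trimmed, _ = snpipe.trim_insert("ACGTACGTAG" + "TTGGCC", LAYOUT)
        assert trimmed == "TTGGCC"

    def test_two_mismatches_left_alone(self):
        seq = "ACGTACGTGG" + "TTGGCC"
        assert snpipe.trim_insert(seq, LAYOUT) == (seq, False)

    def test_no_primer_no_tail_noop(self):
        assert snpipe.trim_insert("TTGGCCTTGG", LAYOUT) == ("TTGGCCTTGG", False)

    def test_short_tail_kept(self):
        assert snpipe.trim_insert("TTGGCCAAA", LAYOUT)[0] == "TTGGCCAAA"  # run of 3 < 4

    def test_entirely_primer_and_tail_flags_too_short(self):
        _, short = snpipe.trim_insert("ACGTACGTAC" + "AAAAAAAA", LAYOUT)
        assert short


class TestParseR1:
    LAYOUT = snpipe.BarcodeLayout()

    def test_exact_length_slices(self):
        seq = "A" * 30 + "C" * 8
        assert snpipe.parse_r1(seq, self.LAYOUT) == ("A" * 30, "C" * 8)

    def test_short_read_discarded(self):
        assert snpipe.parse_r1("A" * 37, self.LAYOUT) is None

    def test_extra_bases_ignored(self):
        seq = "A" * 30 + "C" * 8 + "GGGGGGG"
        assert snpipe.parse_r1(seq, self.LAYOUT) == ("A" * 30, "C" * 8)


class TestCorrectBarcode:
    def test_exact_hit(self):
        res = snpipe.correct_barcode("ACGT", {"ACGT"}, 2)
        assert (res.status, res.acceptor, res.distance) == ("exact", "ACGT", 0)

    def test_unique_neighbour_corrected(self):
        res = snpipe.correct_barcode("ACGA", {"ACGT", "TTTT"}, 2)
        assert (res.status, res.acceptor, res.distance) == ("corrected", "ACGT", 1)

    def test_equidistant_hits_ambiguous(self):
        res = snpipe.correct_barcode("AATT", {"AAAA", "TTTT"}, 2)
        assert res.status == "ambiguous" and res.acceptor is None and res.distance == 2

    def test_far_query_unmatched(self):
        res = snpipe.correct_barcode("GGGG", {"AAAA", "TTTT"}, 2)
        assert res.status == "unmatched" and res.acceptor is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            snpipe.correct_barcode("ACG", {"ACGT"}, 2)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        whitelist = ["".join(r) for r in bases[rng.integers(0, 4, (100, 12))]]
        whitelist = list(dict.fromkeys(whitelist))
        corrector = BarcodeCorrector(whitelist, max_hamming=2)
        for _ in range(300):
            base = whitelist[rng.integers(len(whitelist))]
            q = list(base)
            for pos in rng.choice(12, rng.integers(0, 4), replace=False):
                q[pos] = bases[rng.integers(4)]
            got = corrector.correct("".join(q))
            assert (got.status, got.acceptor, got.distance) == brute_force_correct(
                "".join(q), whitelist, 2
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_property_random_whitelists(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        wl = list(dict.fromkeys("".join(r) for r in bases[rng.integers(0, 4, (20, 8))]))
        corrector = BarcodeCorrector(wl, max_hamming=2)
        q = "".join(bases[rng.integers(0, 4, 8)])
        got = corrector.correct(q)
        assert (got.status, got.acceptor, got.distance) == brute_force_correct(q, wl, 2)


class TestSegmentedCorrector:
    LAYOUT = snpipe.BarcodeLayout(preindex_len=4, droplet_len=26)

    def test_combines_segment_statuses(self):
        pre = ["AAAA", "CCCC"]
        drop = ["A" * 26, "C" * 26]
        sc = SegmentedCorrector(self.LAYOUT, pre, drop)
        exact = sc.correct("AAAA" + "A" * 26)
        assert exact.status == "exact" and exact.acceptor == "AAAA" + "A" * 26
        fixed = sc.correct("AAAT" + "A" * 26)
        assert fixed.status == "corrected" and fixed.distance == 1
        assert sc.correct("GGGG" + "A" * 26).status == "unmatched"


class TestKmerAssignment:
    def test_verbatim_insert_assigned(self, tiny_transcriptome):
        _, seqs = tiny_transcriptome
        index = KmerIndex(seqs, k=31)
        gid, seq = next(iter(seqs.items()))
        assert index.assign(seq[10:160], stride=4) == gid

    def test_random_sequence_unmapped(self, tiny_transcriptome):
        _, seqs = tiny_transcriptome
        index = KmerIndex(seqs, k=31)
        rng = np.random.default_rng(0)
        probe = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        assert index.assign(probe) == "unmapped"  # no 31-mer collision whp

    def test_chimeric_insert_multimapped(self, tiny_transcriptome):
        _, seqs = tiny_transcriptome
        index = KmerIndex(seqs, k=31)
        gids = list(seqs)
        chimera = seqs[gids[0]][:50] + seqs[gids[1]][:50]
        assert index.assign(chimera, stride=1) == "multimapped"

    def test_short_insert_unmapped(self, tiny_transcriptome):
        _, seqs = tiny_transcriptome
        assert KmerIndex(seqs, k=31).assign("ACGT") == "unmapped"


class TestCountUmis:
    GENES = ["g1", "g2"]

    def test_identical_triples_collapse(self):
        cm = snpipe.count_umis([("bc1", "U1", "g1"), ("bc1", "U1", "g1")], self.GENES)
        assert cm.to_dense().tolist() == [[1, 0]]

    def test_umi_scoped_per_cell(self):
        cm = snpipe.count_umis([("bc1", "U1", "g1"), ("bc2", "U1", "g1")], self.GENES)
        assert cm.to_dense().sum() == 2

    def test_distinct_umis_counted(self):
        triples = [("bc1", f"U{i}", "g2") for i in range(3)]
        cm = snpipe.count_umis(triples, self.GENES)
        assert cm.to_dense().tolist() == [[0, 3]]


class TestDemux:
    def test_error_free_matches_truth_exactly(self, tiny_reads, tiny_transcriptome, tiny_sim_config):
        outdir, truth = tiny_reads
        genes, seqs = tiny_transcriptome
        matrix, stats = snpipe.demux(
            outdir / "R1.fastq.gz", outdir / "R2.fastq.gz", tiny_sim_config.layout,
            truth.preindex_whitelist, truth.droplet_whitelist, genes, seqs,
        )
        expect = truth.umi_count_matrix([g.gene_id for g in genes])
        assert matrix.barcodes == expect.barcodes
        assert (matrix.matrix != expect.matrix).nnz == 0

    def test_read_accounting_conserves(self, tmp_path, tiny_sim_config, tiny_transcriptome):
        cfg = tiny_sim_config.replace(substitution_error_rate=0.02, seed=12)
        genes, seqs = tiny_transcriptome
        truth = snpipe.simulate_reads(cfg, genes, seqs, tmp_path)
        _, stats = snpipe.demux(
            tmp_path / "R1.fastq.gz", tmp_path / "R2.fastq.gz", cfg.layout,
            truth.preindex_whitelist, truth.droplet_whitelist, genes, seqs,
        )
        discard = ["too_short", "unmatched", "ambiguous", "unmapped", "multimapped"]
        assert stats["reads_in"] == stats.get("assigned", 0) + sum(stats.get(c, 0) for c in discard)

    def test_single_segment_mode_agrees_on_clean_reads(self, tiny_reads, tiny_transcriptome):
        outdir, truth = tiny_reads
        genes, seqs = tiny_transcriptome
        layout = snpipe.BarcodeLayout(two_segment=False)
        matrix, stats = snpipe.demux(
            outdir / "R1.fastq.gz", outdir / "R2.fastq.gz", layout,
            truth.preindex_whitelist, truth.droplet_whitelist, genes, seqs,
        )
        expect = truth.umi_count_matrix([g.gene_id for g in genes])
        assert (matrix.matrix != expect.matrix).nnz == 0
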