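import numpy as np
import pytest
from Bio.Seq import Seq

from glnreg.motif import (IUPAC, PWM, RELAXED_CONSENSUS, STRICT_CONSENSUS,
                          WIDE_CONSENSUS, BipartiteConsensus,
                          annotate_regions_with_sites, build_pwm,
                          dedupe_palindromic, genome_background,
                          infer_spacer, promoter_windows, pwm_scan,
                          scan_bipartite)
from glnreg.peaks import BindingRegion
from glnreg.simulate import load_fixture


def iupac_match(pattern, text):
    return len(pattern) == len(text) and all(
        t in IUPAC[p] for p, t in zip(pattern, text))


def exhaustive_scan(seq, consensus):
    """Independent oracle: test every offset / spacer / strand explicitly."""
    found = set()
    for strand in "+-":
        subject = seq if strand == "+" else \
            str(Seq(seq).reverse_complement())
        for spacer in range(consensus.spacer_min, consensus.spacer_max + 1):
            full = consensus.full_length(spacer)
            for off in range(len(subject) - full + 1):
                a = subject[off:off + len(consensus.half_site_a)]
                b = subject[off + len(consensus.half_site_a) + spacer:
                            off + full]
                mid = subject[off + len(consensus.half_site_a):
                              off + len(consensus.half_site_a) + spacer]
                if iupac_match(consensus.half_site_a, a) and \
                        iupac_match(consensus.half_site_b, b) and \
                        all(c in "ACGT" for c in mid):
                    fwd_off = off if strand == "+" else \
                        len(seq) - off - full
                    found.add((fwd_off, strand, spacer))
    return found


def random_seq(rng, n, gc=0.6):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestScanBipartite:
    def test_known_site_has_one_distinct_hit(self):
        hits = scan_bipartite("GTCACGCCCTGGTAAC")
        assert len(dedupe_palindromic(hits)) == 1
        (h,) = dedupe_palindromic(hits)
        assert h.offset == 0 and h.spacer == 6
        assert h.matched == "GTCACGCCCTGGTAAC"

    def test_poly_t_has_no_hits(self):
        assert scan_bipartite("T" * 16) == []

    def test_relaxed_mode_recovers_variant_half_sites(self):
        glnA_site = "TTAACTTCGACGAAAC"
        assert scan_bipartite(glnA_site, STRICT_CONSENSUS) == []
        hits = dedupe_palindromic(scan_bipartite(glnA_site,
                                                 RELAXED_CONSENSUS))
        assert len(hits) == 1 and hits[0].offset == 0

    def test_matched_text_has_full_site_length(self, rng):
        seq = random_seq(rng, 500)
        for h in scan_bipartite(seq, RELAXED_CONSENSUS):
            assert len(h.matched) == 5 + h.spacer + 5

    def test_non_iupac_pattern_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            BipartiteConsensus(half_site_a="GTXAC")

    def test_ambiguity_codes_in_subject_never_match(self):
        assert scan_bipartite("GTNACGCCCTGGTNAC") == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 2000)
        for consensus in (STRICT_CONSENSUS, RELAXED_CONSENSUS):
            got = {(h.offset, h.strand, h.spacer)
                   for h in scan_bipartite(seq, consensus)}
            assert got == exhaustive_scan(seq, consensus)

    def test_strand_symmetry(self, rng):
        seq = random_seq(rng, 1500)
        rc = str(Seq(seq).reverse_complement())
        fwd = {(h.offset, h.strand, h.spacer)
               for h in scan_bipartite(seq, RELAXED_CONSENSUS)}
        mirrored = {(len(seq) - h.offset - (10 + h.spacer),
                     "+" if h.strand == "-" else "-", h.spacer)
                    for h in scan_bipartite(rc, RELAXED_CONSENSUS)}
        assert fwd == mirrored

    def test_tandem_boxes_yield_multiple_full_sites(self):
        # two tandem copies of the minimal site: a-n6-a-n6-a-n6-a
        seq = "GTAAC" + "GCGCGC" + "GTCAC" + "GCGCGC" + "GTAAC" \
            + "GCGCGC" + "GTCAC"
        hits = dedupe_palindromic(scan_bipartite(seq))
        assert len(hits) >= 2
        assert {h.offset for h in hits} >= {0, 22}

    def test_widely_spaced_arrangement_found(self):
        seq = "CC" + "GTAAC" + "T" * 0 + "GCATGCATGCATGCATGC" + "GTAAC" + "CC"
        assert len(seq) == 2 + 5 + 18 + 5 + 2
        hits = [h for h in scan_bipartite(seq, WIDE_CONSENSUS)
                if h.spacer == 18]
        assert any(h.offset == 2 for h in hits)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=120))
def test_scanner_equals_oracle_on_arbitrary_sequences(seq):
    for consensus in (STRICT_CONSENSUS, RELAXED_CONSENSUS):
        got = {(h.offset, h.strand, h.spacer)
               for h in scan_bipartite(seq, consensus)}
        assert got == exhaustive_scan(seq, consensus)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=16, max_size=120))
def test_reverse_complementing_the_subject_mirrors_all_hits(seq):
    rc = str(Seq(seq).reverse_complement())
    fwd = {(h.offset, h.strand, h.spacer)
           for h in scan_bipartite(seq, RELAXED_CONSENSUS)}
    mirrored = {(len(seq) - h.offset - (10 + h.spacer),
                 "+" if h.strand == "-" else "-", h.spacer)
                for h in scan_bipartite(rc, RELAXED_CONSENSUS)}
    assert fwd == mirrored


class TestPromoterWindows:
    def _region(self, start, end, rid="BR001"):
        return BindingRegion(replicon="chr", start=start, end=end,
                             supporting_replicates=frozenset({"rep1",
                                                              "rep2"}),
                             timepoints=frozenset({"T30"}), region_id=rid,
                             target_gene_ids=["gX"])

    def test_window_centred_on_midpoint(self):
        seqs = {"chr": "A" * 10_000}
        (rec,) = promoter_windows([self._region(400, 600)], seqs, width=250)
        assert rec.description.split()[0] == "chr:375-625"
        assert len(rec.seq) == 250

    def test_window_clipped_at_replicon_start(self):
        seqs = {"chr": "A" * 10_000}
        (rec,) = promoter_windows([self._region(0, 100)], seqs, width=250)
        assert len(rec.seq) == 175
        assert "clipped" in rec.description

    def test_missing_replicon_sequence_rejected(self):
        with pytest.raises(ValueError, match="no sequence"):
            promoter_windows([self._region(0, 10)], {"other": "ACGT"})


class TestPWM:
    def test_identical_sites_dominate_columns(self):
        pwm = build_pwm(["GTAAC", "GTAAC"])
        for j, base in enumerate("GTAAC"):
            assert pwm.freqs["ACGT".index(base), j] > 0.5
        assert pwm.information_content.max() <= 2.0
        assert (pwm.information_content >= 0).all()

    def test_pseudocount_closed_form_for_pure_column(self):
        pwm = build_pwm(["A", "A", "A", "A"], pseudocount=0.5)
        eps = 0.5 / (4 + 2.0)
        assert pwm.freqs[0, 0] == pytest.approx(1 - 3 * eps)
        assert pwm.freqs[1, 0] == pytest.approx(eps)

    def test_unequal_site_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_pwm(["GTAAC", "GTAACT"])

    def test_half_sites_carry_more_information_than_spacer(self):
        sites = [s for row in load_fixture("table3")["site_list"]
                 for s in row]
        pwm = build_pwm(sites)
        ic = pwm.information_content
        flanks = np.r_[ic[0:5], ic[11:16]].mean()
        spacer = ic[5:11].mean()
        assert flanks > spacer

    def test_scanning_consensus_scores_maximum_at_offset_zero(self):
        pwm = build_pwm(["GTAAC", "GTAAC", "GTCAC"])
        hits = pwm_scan("GTAACTTTTT", pwm, score_threshold=-np.inf)
        assert hits.iloc[0]["offset"] == 0
        assert hits.iloc[0]["strand"] == "+"

    def test_score_is_sum_of_column_log_odds(self):
        pwm = build_pwm(["GTAAC", "GTCAC"])
        lo = pwm.log_odds
        expected = sum(lo["ACGT".index(b), j]
                       for j, b in enumerate("GTAAC"))
        assert pwm.score("GTAAC") == pytest.approx(expected)

    def test_threshold_minus_inf_returns_all_offsets_both_strands(self):
        pwm = build_pwm(["GTAAC", "GTCAC"])
        seq = "ACGTACGTACGT"
        hits = pwm_scan(seq, pwm, score_threshold=-np.inf)
        assert len(hits) == 2 * (len(seq) - pwm.length + 1)

    def test_background_from_gc_rich_genome(self):
        bg = genome_background({"chr": "GGGCCCGA"})
        assert bg[1] + bg[2] == pytest.approx(7 / 8)
        assert bg.sum() == pytest.approx(1.0)


class TestRegionAnnotation:
    def test_counts_regions_with_and_without_sites(self):
        from Bio.Seq import Seq as BSeq
        from Bio.SeqRecord import SeqRecord
        regions = [BindingRegion(replicon="chr", start=0, end=100,
                                 supporting_replicates=frozenset({"r1",
                                                                  "r2"}),
                                 timepoints=frozenset({"T30"}),
                                 region_id=f"BR{i}") for i in range(2)]
        windows = [SeqRecord(BSeq("AAA" + "GTCACGCCCTGGTAAC" + "AAA"),
                             id="BR0"),
                   SeqRecord(BSeq("A" * 30), id="BR1")]
        table = annotate_regions_with_sites(regions, windows)
        assert table.attrs["n_with_sites"] == 1
        assert table.attrs["n_without_sites"] == 1
        assert table.loc[1, "sites"] == "n/a"

    def test_empty_region_list(self):
        table = annotate_regions_with_sites([], [])
        assert table.empty


class TestInferSpacer:
    def test_published_full_sites_decompose_five_six_five(self):
        sites = [s for row in load_fixture("table3")["site_list"]
                 for s in row]
        assert infer_spacer(sites, half_len=5) == 6

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed lengths"):
            infer_spacer(["GTAAC", "GTAACT"])
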