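"""Variant filters, flank checks, SSR scanning and primer screening."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weevilpop.geno_io import MISSING, MarkerKind
from weevilpop.marker_discovery import (
    DEFAULT_MIN_REPEATS,
    PrimerConstraints,
    check_flanks,
    evaluate_primer_pair,
    filter_call_rate,
    filter_variants,
    gc_fraction_tm,
    scan_ssr_motifs,
)
from weevilpop.synthetic_data import make_contig_fixtures

from conftest import build_matrix


def regex_oracle(seq, mins=DEFAULT_MIN_REPEATS):
    """Brute-force maximal perfect repeats via re, with containment pruning."""
    found = []
    for unit, min_rep in mins.items():
        pat = re.compile(r"([ACGT]{%d})\1{%d,}" % (unit, min_rep - 1))
        for m in pat.finditer(seq.upper()):
            length = (m.end() - m.start()) // unit * unit
            found.append((m.start(), m.start() + length, unit))
    kept = [
        (s, e, u)
        for (s, e, u) in found
        if not any(u2 < u and s2 <= s and e <= e2 for (s2, e2, u2) in found)
    ]
    return sorted(kept)


class TestFilterVariants:
    def _panel_48(self, n_called):
        genos = [[("A", "T")] if i < n_called else [None] for i in range(48)]
        # keep minor allele frequency high: alternate hom/het among called
        genos = [
            [("A", "T") if i % 2 == 0 else ("A", "A")] if i < n_called else [None]
            for i in range(48)
        ]
        return build_matrix(genos)

    def test_locus_called_in_31_of_48_removed(self):
        m = self._panel_48(31)
        out, rep = filter_variants(m, min_depth=0, min_called=32, total=48)
        assert out.n_loci == 0
        assert "31/48" in rep.removed["loc1"]

    def test_locus_called_in_32_of_48_retained(self):
        m = self._panel_48(32)
        out, _ = filter_variants(m, min_depth=0, min_called=32, total=48)
        assert out.n_loci == 1

    def test_maf_exactly_at_threshold_removed(self):
        # 20 genotypes, 2 copies of T / 40 alleles = MAF 0.05 exactly
        genos = [[("A", "T")], [("A", "T")]] + [[("A", "A")]] * 18
        m = build_matrix(genos)
        out, rep = filter_variants(m, min_depth=0, min_called=1, total=20)
        assert out.n_loci == 0 and "frequency" in rep.removed["loc1"]
        # one more T copy crosses the strict threshold
        genos[2] = [("A", "T")]
        m2 = build_matrix(genos)
        out2, _ = filter_variants(m2, min_depth=0, min_called=1, total=20)
        assert out2.n_loci == 1

    def test_depth_gate_runs_before_locus_criteria(self):
        # 5x1 toy: all depths 7 -> all calls blanked -> removed on call count
        genos = [[("A", "T")]] * 5
        depths = [[7]] * 5
        m = build_matrix(genos, depths=depths)
        out, rep = filter_variants(m, min_depth=8, min_called=3, total=5)
        assert out.n_loci == 0
        assert "0/5" in rep.removed["loc1"]

    def test_depthless_matrix_warns_and_skips_depth(self):
        m = self._panel_48(48)
        with pytest.warns(UserWarning, match="no per-call depths"):
            out, _ = filter_variants(m, min_depth=8, min_called=32, total=48)
        assert out.n_loci == 1

    def test_min_called_above_total_rejected(self):
        m = self._panel_48(48)
        with pytest.raises(ValueError):
            filter_variants(m, min_called=49, total=48)

    def test_idempotent(self):
        genos = [
            [("A", "T"), ("A", "A"), None],
            [("A", "A"), ("A", "A"), ("G", "G")],
            [("A", "T"), ("A", "A"), ("G", "G")],
            [("T", "T"), ("A", "A"), ("G", "C")],
        ]
        m = build_matrix(genos)
        once, rep1 = filter_variants(m, min_depth=0, min_called=3, total=4)
        twice, rep2 = filter_variants(once, min_depth=0, min_called=3, total=4)
        assert [l.name for l in once.loci] == [l.name for l in twice.loci]
        assert np.array_equal(once.codes, twice.codes)
        assert rep1.n_in - rep1.n_out == len(rep1.removed)


class TestFilterCallRate:
    def _panel_180(self, n_called):
        genos = [
            [("A", "T") if i % 2 else ("A", "A")] if i < n_called else [None]
            for i in range(180)
        ]
        return build_matrix(genos)

    @pytest.mark.parametrize("called,kept", [(171, False), (172, True)])
    def test_strict_95_percent_boundary(self, called, kept):
        out, _ = filter_call_rate(self._panel_180(called), 0.95)
        assert (out.n_loci == 1) is kept

    def test_stage_composition_equals_tighter_stage(self):
        for called in (160, 165, 171, 172, 178):
            m = self._panel_180(called)
            via_90, _ = filter_call_rate(m, 0.90)
            composed, _ = filter_call_rate(via_90, 0.95)
            direct, _ = filter_call_rate(m, 0.95)
            assert [l.name for l in composed.loci] == [l.name for l in direct.loci]

    def test_report_reconciles(self, demo_panel):
        matrix, _, _ = demo_panel
        out, rep = filter_call_rate(matrix, 0.95)
        assert rep.n_in == matrix.n_loci
        assert rep.n_out == out.n_loci == rep.n_in - len(rep.removed)


class TestCheckFlanks:
    @pytest.mark.parametrize(
        "length,pos,expected",
        [(151, 76, True), (150, 76, False), (300, 150, True), (151, 75, False)],
    )
    def test_boundaries(self, length, pos, expected):
        assert check_flanks(length, pos) is expected

    def test_position_outside_tag_rejected(self):
        with pytest.raises(ValueError):
            check_flanks(100, 0)

    @given(
        length=st.integers(1, 400),
        pos=st.integers(1, 400),
        min_flank=st.integers(0, 100),
    )
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_under_reversal(self, length, pos, min_flank):
        if pos > length:
            return
        mirrored = length - pos + 1
        assert check_flanks(length, pos, min_flank) == check_flanks(
            length, mirrored, min_flank
        )


class TestScanSsrMotifs:
    def test_table_style_trinucleotide(self):
        seq = "GATTACCGA" + "AAC" * 6 + "GGTTACGA"
        hits = scan_ssr_motifs(seq)
        assert len(hits) == 1
        h = hits[0]
        assert (h.motif, h.repeats) == ("AAC", 6)
        assert h.start == 10 and h.end == 27
        assert h.left_flank == 9 and h.right_flank == 8

    def test_mononucleotide_below_threshold_ignored(self):
        assert scan_ssr_motifs("GCA" + "T" * 9 + "GCA") == []
        assert len(scan_ssr_motifs("GCA" + "T" * 10 + "GCA")) == 1

    def test_homopolymer_not_double_reported_as_dimer(self):
        hits = scan_ssr_motifs("GCA" + "T" * 12 + "GCA")
        assert len(hits) == 1
        assert hits[0].motif == "T" and hits[0].repeats == 12

    def test_leftmost_phase_reported(self):
        # C then (AC)5: maximal run starts at the C of "CACACACACA"? No -
        # leftmost full-unit phase is "CA" starting at index 3 (0-based 3)
        seq = "GGT" + "CACACACACAC" + "GGT"
        hits = scan_ssr_motifs(seq)
        assert len(hits) == 1
        h = hits[0]
        assert h.repeats == 5
        assert seq[h.start - 1 : h.end] == h.motif * h.repeats

    def test_n_never_inside_hit(self):
        seq = "A" * 6 + "N" + "A" * 6
        assert scan_ssr_motifs(seq) == []

    def test_empty_sequence(self):
        assert scan_ssr_motifs("") == []

    def test_matches_regex_oracle_on_random_contigs(self):
        rng = np.random.default_rng(123)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            length = int(rng.integers(150, 321))
            seq = "".join(bases[rng.integers(0, 4, size=length)])
            # salt some sequences with planted repeats so hits are common
            if rng.random() < 0.5:
                motif = "".join(bases[rng.integers(0, 4, size=int(rng.integers(1, 7)))])
                reps = int(rng.integers(3, 14))
                pos = int(rng.integers(0, length - len(motif) * reps)) if length > len(motif) * reps else 0
                seq = seq[:pos] + motif * reps + seq[pos + len(motif) * reps:]
            got = [(h.start - 1, h.end, len(h.motif)) for h in scan_ssr_motifs(seq)]
            assert got == regex_oracle(seq), seq

    def test_planted_fixture_truth_recovered_exactly(self):
        planted = [
            ("AAC", 6, (80, 80)), ("AG", 6, (40, 40)), ("CTGCA", 4, (75, 75)),
            ("T", 10, (75, 75)), ("AT", 5, (60, 90)), ("ATG", 5, (80, 80)),
        ]
        records, truth = make_contig_fixtures(len(planted) + 4, planted, seed=77)
        expected = {
            (t.contig, t.motif, t.repeats, t.start, t.end) for t in truth
        }
        got = set()
        for name, seq in records:
            for h in scan_ssr_motifs(seq, contig=name):
                got.add((h.contig, h.motif, h.repeats, h.start, h.end))
        assert got == expected


class TestPrimerScreen:
    def test_tm_formula_hand_value(self):
        # 20-mer with 9 G/C: 64.9 + 41*(9-16.4)/20 = 49.73
        tm = gc_fraction_tm("GCCTATAATAGACCGTTTGG")
        assert tm == pytest.approx(49.73)

    def test_published_style_primer_fails_tm_only_under_gc_model(self):
        a = evaluate_primer_pair(
            "GCCTATAATAGACCGTTTGG", "GTGAAGAACATTGTAACATCTC", 130
        )
        assert a.verdict == "fail"
        assert not any("length" in v for v in a.violations)
        assert any("Tm" in v and "forward" in v for v in a.violations)

    def test_short_primer_fails_length(self):
        a = evaluate_primer_pair("ACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGT", 150)
        assert any("length 17" in v for v in a.violations)

    @pytest.mark.parametrize("product,ok", [(100, True), (280, True), (281, False), (99, False)])
    def test_product_range_inclusive(self, product, ok):
        a = evaluate_primer_pair("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT", product)
        assert (not any("product" in v for v in a.violations)) is ok

    def test_tm_delta_constraint(self):
        # same length, different GC -> Tm differ by 41/20 = 2.05 per GC
        a = evaluate_primer_pair(
            "ACGTACGTACGTACGTACGT", "ATGTACGTACGTACGTACGT", 150
        )
        assert a.tm_delta == pytest.approx(2.05)
        assert any("difference" in v for v in a.violations)

    def test_verdict_iff_violations(self):
        # a primer pair satisfying every window under the GC model:
        # need Tm in [54, 60] -> GC ~ 11 on a 20-mer gives 53.83; 12 -> 55.88
        p = "GCGCGCGCGCGCATATATAT"  # 12 GC
        a = evaluate_primer_pair(p, p, 150)
        assert a.violations == ()
        assert a.verdict == "pass"
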