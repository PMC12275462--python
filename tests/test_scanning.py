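"""Element/window orchestration, PWM scanning, and motif enrichment."""
import io as stdio

import numpy as np
import pytest

from phyloshift import SimSpec, foreground_branches, simulate_alignment
from phyloshift.io import Region, ScoreRecord
from phyloshift.likelihood import Alignment
from phyloshift.scanning import (
    EnrichmentRecord,
    Pwm,
    ScanConfig,
    fasta_extractor,
    motif_global_enrichment,
    pwm_scan,
    read_pwms,
    score_elements,
    score_windows,
    tile_windows,
)
from oracles import hypergeom_tail_p


@pytest.fixture(scope="module")
def panel(model10, tree10):
    """Three elements: neutral, 5x accelerated foreground, neutral."""
    fg = foreground_branches(tree10, {"A", "E", "G"})
    chunks = [
        simulate_alignment(SimSpec(model10, 150, seed=800)),
        simulate_alignment(SimSpec(model10, 150, fg=fg, lam=5.0, seed=801)),
        simulate_alignment(SimSpec(model10, 150, seed=802)),
    ]
    aln = Alignment(chunks[0].species, np.hstack([c.data for c in chunks]))
    regions = [Region("chrS", i * 150, (i + 1) * 150, f"e{i}") for i in range(3)]
    return aln, regions


class TestScoreElements:
    def test_planted_element_detected(self, panel, model10):
        aln, regions = panel
        cfg = ScanConfig(n_permulations=150, seed=5, leave_one_out=False)
        recs = score_elements(
            fasta_extractor(aln), regions, model10, ["A", "E", "G"], cfg
        )
        assert len(recs) == 3
        assert recs[1].lambda_hat > 2 and recs[1].scorr <= 0
        assert abs(recs[0].scorr) < abs(recs[1].scorr) or recs[1].pcorr < recs[0].pcorr
        for r in (recs[0], recs[2]):
            assert r.pcorr > 0.05

    def test_row_count_includes_na_records(self, panel, model10):
        aln, regions = panel
        regions = regions + [Region("chrS", 5000, 5100, "off_the_end")]
        cfg = ScanConfig(calibrate=False)
        recs = score_elements(
            fasta_extractor(aln), regions, model10, ["A", "E", "G"], cfg
        )
        assert len(recs) == 4
        assert recs[3].reason == "no_alignment"
        assert recs[3].rho0 is None

    def test_min_species_filter(self, model10):
        aln = Alignment.from_strings(
            {"A": "ACGTACGTAC", "B": "NNNNNNNNNN", "C": "NNNNNNNNNN",
             "D": "ACGTACGTAC"}
        )
        cfg = ScanConfig(min_species=3, calibrate=False)
        recs = score_elements(
            fasta_extractor(aln), [Region("chrS", 0, 10, "x")], model10, ["A"], cfg
        )
        assert recs[0].reason == "insufficient_species"

    def test_region_order_invariance(self, panel, model10):
        """Per-element seeding makes outputs identical under permuted
        input order."""
        aln, regions = panel
        cfg = ScanConfig(n_permulations=60, seed=9, leave_one_out=False)
        fwd = score_elements(
            fasta_extractor(aln), regions, model10, ["A", "E", "G"], cfg
        )
        rev = score_elements(
            fasta_extractor(aln), regions[::-1], model10, ["A", "E", "G"], cfg
        )
        by_name_fwd = {r.region.name: (r.pcorr, r.scorr, r.n_permulations_used)
                       for r in fwd}
        by_name_rev = {r.region.name: (r.pcorr, r.scorr, r.n_permulations_used)
                       for r in rev}
        assert by_name_fwd == by_name_rev


class TestScoreWindows:
    def test_tiling_arithmetic(self):
        wins = tile_windows("c", 0, 100, 25, 25)
        assert [(w.start, w.end) for w in wins] == [
            (0, 25), (25, 50), (50, 75), (75, 100)
        ]
        # non-overlapping and covering exactly once when step == window
        assert sum(len(w) for w in wins) == 100

    def test_track_over_embedded_shift(self, model10, tree10):
        """Parametric-only windows over a planted accelerated segment
        show negative signed scores there."""
        fg = foreground_branches(tree10, {"A", "B"})
        left = simulate_alignment(SimSpec(model10, 200, seed=900))
        mid = simulate_alignment(SimSpec(model10, 200, fg=fg, lam=5.0, seed=901))
        right = simulate_alignment(SimSpec(model10, 200, seed=902))
        aln = Alignment(left.species, np.hstack([left.data, mid.data, right.data]))
        # write a single-block MAF
        rows = "".join(
            f"s {sp}.chrW 0 600 + 600 {seq}\n"
            for sp, seq in aln.to_strings().items()
        )
        maf = stdio.StringIO(f"##maf version=1\na score=0\n{rows}\n")
        from phyloshift.io import read_maf

        blocks = list(read_maf(maf))
        cfg = ScanConfig(calibrate=False, seed=1)
        recs = score_windows(blocks, 100, 100, model10, ["A", "B"], cfg)
        assert len(recs) == 6
        inside = [r.scorr for r in recs[2:4]]
        outside = [r.scorr for r in recs[:2] + recs[4:]]
        assert max(inside) < 0
        assert min(inside) < min(outside)


CONSENSUS = "ACGGA"


def consensus_pwm(motif_id="m1"):
    counts = np.zeros((5, 4))
    for i, c in enumerate(CONSENSUS):
        counts[i, "ACGT".index(c)] = 10
    return Pwm.from_counts(motif_id, counts)


class TestPwmScan:
    def test_consensus_always_hit_at_max_score(self):
        pwm = consensus_pwm()
        hits = pwm_scan("TT" + CONSENSUS + "TT", [pwm], threshold_frac=1.0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.region.start, h.region.end, h.region.strand) == (2, 7, "+")
        assert h.pwm_score == pytest.approx(pwm.max_score)

    def test_reverse_complement_hit_on_minus_strand(self):
        pwm = consensus_pwm()
        rc = "TCCGT"  # reverse complement of ACGGA
        hits = pwm_scan("GG" + rc + "GG", [pwm], threshold_frac=1.0)
        assert len(hits) == 1
        assert hits[0].region.strand == "-"
        assert hits[0].pwm_score == pytest.approx(pwm.max_score)

    def test_matches_brute_force_enumeration(self):
        """Hand enumeration of all windows/strands on a 10-bp sequence."""
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 20, size=(4, 4)).astype(float)
        pwm = Pwm.from_counts("m2", counts)
        seq = "ACGGTACGTT"
        code = [("ACGT").index(c) for c in seq]
        rc = pwm.matrix[::-1, ::-1]
        best = {}
        for start in range(len(seq) - 4 + 1):
            w = code[start : start + 4]
            for strand, mat in (("+", pwm.matrix), ("-", rc)):
                s = sum(mat[i, w[i]] for i in range(4))
                best[(start, strand)] = s
        threshold = 0.5 * pwm.max_score
        expected = {k for k, v in best.items() if v >= threshold}
        hits = pwm_scan(seq, [pwm], threshold_frac=0.5)
        got = {(h.region.start, h.region.strand) for h in hits}
        # greedy overlap resolution only removes overlapping same-motif
        # hits, so every reported hit must be in the expected set and the
        # best-scoring expected hit must be reported
        assert got <= expected
        top = max(best, key=lambda k: best[k])
        assert top in got

    def test_windows_with_n_skipped(self):
        pwm = consensus_pwm()
        hits = pwm_scan("ACNTA", [pwm], threshold_frac=0.1)
        assert hits == []

    def test_pwm_longer_than_sequence(self):
        assert pwm_scan("ACG", [consensus_pwm()]) == []

    def test_read_pwms_four_column(self, tmp_path):
        text = ">M1\n10 0 0 0\n0 10 0 0\n0 0 10 0\n0 0 0 10\n10 0 0 0\n"
        p = tmp_path / "m.pcm"
        p.write_text(text)
        pwms = read_pwms(p)
        assert len(pwms) == 1
        assert pwms[0].motif_id == "M1"
        assert pwms[0].length == 5
        assert pwms[0].matrix[0].argmax() == 0


def fake_record(name, pcorr, scorr, robust=True):
    return ScoreRecord(
        Region("c", 0, 10, name), rho0=1, rho1=1, lambda_hat=2 if scorr < 0 else 0.5,
        lrt_p=0.01, pcorr=pcorr, scorr=scorr, robust=robust,
    )


class TestEnrichment:
    def test_hand_built_table_matches_hypergeometric(self):
        """2x2 table (8,2,20,70): exact test equals the direct
        hypergeometric tail sum."""
        hits = (
            [("mA", fake_record(f"a{i}", 0.01, -2)) for i in range(8)]
            + [("mA", fake_record(f"a{i+8}", 0.5, -0.1)) for i in range(20)]
            + [("mB", fake_record(f"b{i}", 0.01, -2)) for i in range(2)]
            + [("mB", fake_record(f"b{i+2}", 0.5, -0.1)) for i in range(70)]
        )
        recs = motif_global_enrichment(hits, "accel")
        rec_a = [r for r in recs if r.motif_id == "mA"][0]
        assert (rec_a.n_sig_with_motif, rec_a.n_sig_without,
                rec_a.n_nonsig_with, rec_a.n_nonsig_without) == (8, 2, 20, 70)
        assert rec_a.p == pytest.approx(hypergeom_tail_p(8, 2, 20, 70), rel=1e-9)

    def test_extreme_table_flagged(self):
        hits = (
            [("mA", fake_record(f"a{i}", 0.01, -3)) for i in range(10)]
            + [("mB", fake_record(f"b{i}", 0.9, -0.1)) for i in range(40)]
        )
        recs = motif_global_enrichment(hits, "accel")
        rec_a = [r for r in recs if r.motif_id == "mA"][0]
        assert rec_a.significant and rec_a.fdr_q < 0.05
        assert rec_a.odds_ratio == np.inf

    def test_homogeneous_null_not_flagged(self):
        hits = []
        for m in ("m1", "m2", "m3", "m4"):
            hits += [(m, fake_record(f"{m}_{i}", 0.01, -2)) for i in range(3)]
            hits += [(m, fake_record(f"{m}_{i+3}", 0.9, -0.1)) for i in range(9)]
        recs = motif_global_enrichment(hits, "accel")
        assert all(not r.significant for r in recs)
        assert all(r.p > 0.3 for r in recs)

    def test_direction_and_robustness_filters(self):
        hits = [
            ("mA", fake_record("x", 0.01, +2)),        # decelerated
            ("mA", fake_record("y", 0.01, -2, robust=False)),
            ("mB", fake_record("z", 0.01, -2)),
        ]
        recs = motif_global_enrichment(hits, "accel")
        rec_a = [r for r in recs if r.motif_id == "mA"][0]
        assert rec_a.n_sig_with_motif == 0  # wrong direction / not robust
        rec_b = [r for r in recs if r.motif_id == "mB"][0]
        assert rec_b.n_sig_with_motif == 1

    def test_bh_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        hits = []
        for m in range(6):
            for i in range(12):
                sig = rng.random() < (0.8 if m == 0 else 0.2)
                hits.append(
                    (f"m{m}", fake_record(f"{m}_{i}", 0.01 if sig else 0.9,
                                          -2 if sig else -0.1))
                )
        recs1 = motif_global_enrichment(hits, "accel")
        rng.shuffle(hits)
        recs2 = motif_global_enrichment(hits, "accel")
        flags1 = {r.motif_id: r.significant for r in recs1}
        flags2 = {r.motif_id: r.significant for r in recs2}
        assert flags1 == flags2
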