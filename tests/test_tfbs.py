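"""PWM scanning, cross-species site mapping, and conservation classing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wfkit.alignment import PromoterAlignment, align_promoters
from wfkit.promoter import reverse_complement
from wfkit.synthetic import PlantedMotif, simulate_promoter_trio
from wfkit.tfbs import (
    CLASSES,
    ConservationCall,
    PositionFrequencyMatrix,
    TFBSHit,
    call_conservation,
    classify_conservation,
    map_and_score,
    read_jaspar,
    scan_pwm,
    summarize_conservation,
)

BASES = "ACGT"


def point_mass_pfm(kmer: str, name: str = "pm") -> PositionFrequencyMatrix:
    mat = np.zeros((4, len(kmer)))
    for j, base in enumerate(kmer):
        mat[BASES.index(base), j] = 9.0
    return PositionFrequencyMatrix(tf_name=name, matrix=mat, pseudocount=1e-3)


class TestReadJaspar:
    def test_two_record_fixture(self, jaspar_file):
        pfms = read_jaspar(jaspar_file)
        assert [p.tf_name for p in pfms] == ["MA0001.1 ALPHA", "MA0002.1 BETA"]
        assert pfms[0].length == 4
        assert pfms[1].length == 3
        # rows are ordered A, C, G, T
        assert pfms[0].matrix[0].tolist() == [9, 0, 0, 9]

    def test_unequal_row_lengths_rejected(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">MA0009.9 BAD\nA [1 2 3]\nC [1 2]\nG [1 2 3]\nT [1 2 3]\n")
        with pytest.raises(ValueError):
            read_jaspar(path)


class TestScanPwm:
    def test_point_mass_hit(self):
        # non-palindromic motif: exactly one perfect hit per strand meaning
        pfm = point_mass_pfm("ACGG")
        hits = scan_pwm("TTACGGTT", pfm, min_rel_score=1.0)
        assert [(h.start, h.end, h.strand) for h in hits] == [(3, 6, "+")]
        rc_hits = scan_pwm(reverse_complement("TTACGGTT"), pfm, min_rel_score=1.0)
        assert [(h.start, h.end, h.strand) for h in rc_hits] == [(3, 6, "-")]

    def test_threshold_free_count(self):
        pfm = point_mass_pfm("ACG")
        seq = "ACGTACGT"
        hits = scan_pwm(seq, pfm, min_rel_score=0.0)
        assert len(hits) == 2 * (len(seq) - pfm.length + 1)

    def test_motif_longer_than_sequence(self):
        assert scan_pwm("ACG", point_mass_pfm("ACGTACGT"), 0.0) == []

    def test_rel_scores_match_brute_force(self, jaspar_file):
        pfm = read_jaspar(jaspar_file)[1]  # 3-column matrix
        seq = "ACCAGTCG"
        lod = pfm.log_odds()
        lo = lod.min(axis=0).sum()
        hi = lod.max(axis=0).sum()

        def brute(sub: str) -> float:
            s = sum(lod[BASES.index(b), j] for j, b in enumerate(sub))
            return (s - lo) / (hi - lo)

        expected = {}
        for i in range(len(seq) - pfm.length + 1):
            window = seq[i : i + pfm.length]
            expected[(i + 1, "+")] = brute(window)
            expected[(i + 1, "-")] = brute(reverse_complement(window))
        hits = scan_pwm(seq, pfm, min_rel_score=0.0)
        assert len(hits) == len(expected)
        for h in hits:
            assert h.rel_score == pytest.approx(expected[(h.start, h.strand)], abs=1e-12)

    def test_best_kmer_scores_exactly_one(self, jaspar_file):
        for pfm in read_jaspar(jaspar_file):
            best = "".join(BASES[i] for i in pfm.log_odds().argmax(axis=0))
            hits = scan_pwm(best, pfm, min_rel_score=0.0)
            assert max(h.rel_score for h in hits) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_symmetry(self, seed, jaspar_file):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(BASES), size=40))
        for pfm in read_jaspar(jaspar_file):
            fwd = scan_pwm(seq, pfm, min_rel_score=0.0)
            rev = scan_pwm(reverse_complement(seq), pfm, min_rel_score=0.0)
            n = len(seq)
            mirrored = {
                (n - h.end + 1, n - h.start + 1, "+-"["+-".index(h.strand) - 1], round(h.rel_score, 10))
                for h in rev
            }
            assert {
                (h.start, h.end, h.strand, round(h.rel_score, 10)) for h in fwd
            } == mirrored

    def test_rel_scores_bounded(self, jaspar_file, rng):
        seq = "".join(rng.choice(list(BASES), size=60))
        for pfm in read_jaspar(jaspar_file):
            for h in scan_pwm(seq, pfm, min_rel_score=0.0):
                assert 0.0 <= h.rel_score <= 1.0


class TestMapAndScore:
    def make_aln(self, ts_row: str, ms_row: str | None = None, human_row: str = "ACGTAC"):
        rows = [human_row, ts_row, ms_row or ts_row]
        return PromoterAlignment(["human", "treeshrew", "mouse"], rows)

    def test_identical_site_scores_one(self):
        aln = self.make_aln("ACGTAC")
        hit = TFBSHit("x", 1, 6, "+", 1.0)
        assert map_and_score(hit, aln, "treeshrew") == 1.0

    def test_two_substitutions_in_ten(self):
        aln = PromoterAlignment(
            ["human", "treeshrew", "mouse"],
            ["ACGTACGTAC", "ACGTACGTGG", "ACGTACGTAC"],
        )
        hit = TFBSHit("x", 1, 10, "+", 1.0)
        assert map_and_score(hit, aln, "treeshrew") == pytest.approx(0.8)

    def test_gap_counts_as_mismatch(self):
        aln = self.make_aln("AC-TAC")
        hit = TFBSHit("x", 1, 6, "+", 1.0)
        assert map_and_score(hit, aln, "treeshrew") == pytest.approx(5 / 6)

    def test_minus_strand_similarity_unchanged(self):
        aln = self.make_aln("ACCTAC")
        plus = map_and_score(TFBSHit("x", 1, 6, "+", 1.0), aln, "treeshrew")
        minus = map_and_score(TFBSHit("x", 1, 6, "-", 1.0), aln, "treeshrew")
        assert plus == minus == pytest.approx(5 / 6)

    def test_site_maps_through_gapped_human_row(self):
        aln = PromoterAlignment(
            ["human", "treeshrew", "mouse"],
            ["AC--GTAC", "ACTTGTAC", "ACTTGAAC"],
        )
        hit = TFBSHit("x", 3, 6, "+", 1.0)  # human ungapped GTAC
        assert map_and_score(hit, aln, "treeshrew") == 1.0
        assert map_and_score(hit, aln, "mouse") == pytest.approx(3 / 4)


class TestClassify:
    @pytest.mark.parametrize(
        "ts,ms,expected",
        [
            (0.9, 0.9, "shared_both"),
            (0.70, 0.69, "shared_ts"),
            (0.69, 0.70, "shared_ms"),
            (0.5, 0.5, "human_specific"),
        ],
    )
    def test_boundary_rule(self, ts, ms, expected):
        assert classify_conservation(ts, ms) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_conservation(1.2, 0.5)

    @given(
        ts=st.floats(0, 1), ms=st.floats(0, 1),
        bump=st.floats(0, 0.5),
    )
    def test_monotone_in_similarity(self, ts, ms, bump):
        """Raising a similarity never moves a call away from shared."""
        rank = {"human_specific": 0, "shared_ts": 1, "shared_ms": 1, "shared_both": 2}
        before = classify_conservation(ts, ms)
        after = classify_conservation(min(1.0, ts + bump), ms)
        assert rank[after] >= rank[before]


class TestSummarize:
    def make_call(self, cls, start=1):
        return ConservationCall(
            hit=TFBSHit("x", start, start + 3, "+", 0.9),
            similarity_ts=0.9,
            similarity_ms=0.9,
            conservation_class=cls,
        )

    def test_one_call_per_class(self):
        calls = [self.make_call(c, start=1 + 5 * i) for i, c in enumerate(CLASSES)]
        summary = summarize_conservation(calls)
        assert all(v == 25.0 for v in summary.percents.values())

    def test_all_shared_both(self):
        summary = summarize_conservation([self.make_call("shared_both")] * 4)
        assert summary.percents["shared_both"] == 100.0

    def test_empty_input_all_zero(self):
        summary = summarize_conservation([])
        assert sum(summary.counts.values()) == 0
        assert all(v == 0.0 for v in summary.percents.values())


class TestEndToEndPlantedRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_classes_recovered(self, seed):
        """Intact/scrambled planted sites receive their planted class (>=95%)."""
        rng = np.random.default_rng(seed + 1000)
        motifs = []
        statuses = []
        for i in range(12):
            kmer = "".join(rng.choice(list(BASES), size=10))
            status_ts = ["intact", "scrambled"][i % 2]
            status_ms = ["intact", "scrambled"][(i // 2) % 2]
            motifs.append(
                PlantedMotif(
                    name=f"m{i}", consensus=kmer, position=30 + 40 * i,
                    status_ts=status_ts, status_ms=status_ms,
                )
            )
            statuses.append((status_ts, status_ms))
        trio = simulate_promoter_trio(
            length=600, identities=(0.85, 0.75), indel_rate=0.0,
            motifs=motifs, seed=seed,
        )
        aln = align_promoters([trio.sequences[s] for s in ("human", "treeshrew", "mouse")])
        correct = detected = 0
        for motif, (status_ts, status_ms) in zip(motifs, statuses):
            pfm = point_mass_pfm(motif.consensus, motif.name)
            hits = [
                h for h in scan_pwm(trio.sequences["human"], pfm, min_rel_score=1.0)
                if h.start == motif.position and h.strand == "+"
            ]
            if not hits:
                continue
            detected += 1
            call = call_conservation(hits, aln)[0]
            want_ts = status_ts == "intact"
            want_ms = status_ms == "intact"
            got_ts = call.conservation_class in ("shared_ts", "shared_both")
            got_ms = call.conservation_class in ("shared_ms", "shared_both")
            correct += (got_ts, got_ms) == (want_ts, want_ms)
        assert detected >= 10
        assert correct / detected >= 0.95
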