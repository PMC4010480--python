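import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcsrscan.promoter_scan import (
    PromoterSet,
    PWMModel,
    best_hit_relative_score,
    common_regulators,
    common_regulators_enrichment,
    parse_jaspar_pfm,
    pfm_to_pwm,
    pscan_ztest,
    scan_threshold,
)
from pcsrscan.synthetic import SimulationConfig, demo_pwm, generate_promoters

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_best(seq: str, pwm: PWMModel) -> float:
    """Exhaustive two-strand sliding-window maximum, written independently."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(pwm)
    best = None
    for strand_seq in (seq, revcomp(seq)):
        for off in range(len(strand_seq) - L + 1):
            window = strand_seq[off : off + L]
            if "N" in window:
                continue
            s = sum(pwm.matrix[i, idx[b]] for i, b in enumerate(window))
            best = s if best is None else max(best, s)
    if best is None:
        return 0.0
    return (best - pwm.s_min) / (pwm.s_max - pwm.s_min)


class TestPfmToPwm:
    def test_uniform_pfm_is_zero(self):
        pwm = pfm_to_pwm(np.full((4, 5), 10.0))
        assert np.allclose(pwm.matrix, 0)
        assert pwm.s_min == pwm.s_max == 0

    def test_single_position_hand_formula(self):
        pwm = pfm_to_pwm(np.array([[10.0], [0.0], [0.0], [0.0]]), pseudocount=1.0)
        expected_a = math.log2(((10 + 0.25) / 11) / 0.25)
        expected_other = math.log2(((0 + 0.25) / 11) / 0.25)
        assert pwm.matrix[0, 0] == pytest.approx(expected_a)
        assert pwm.matrix[0, 1] == pytest.approx(expected_other)
        assert pwm.s_max == pytest.approx(expected_a)

    def test_max_cell_tracks_max_count(self, rng):
        pfm = rng.integers(0, 50, size=(4, 8)).astype(float)
        pwm = pfm_to_pwm(pfm)
        assert (pwm.matrix.argmax(axis=1) == pfm.T.argmax(axis=1)).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(np.empty((4, 0)))

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(np.ones((4, 3)), background=(0.5, 0.5, 0.5, 0.5))


class TestBestHitRelativeScore:
    def test_consensus_scores_one(self):
        pwm = demo_pwm()
        assert best_hit_relative_score("TT" + pwm.consensus + "AC", pwm) == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self):
        # palindromic log-odds matrix: worst window is worst on both strands
        matrix = np.array([[0.0, 1.0, 2.0, 3.0], [3.0, 2.0, 1.0, 0.0]])
        pwm = PWMModel(name="pal", matrix=matrix, s_min=0.0, s_max=6.0)
        assert np.array_equal(matrix, pwm.reverse_complement_matrix())
        assert best_hit_relative_score("AT", pwm) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(20):
            pfm = rng.integers(0, 30, size=(4, 6)).astype(float)
            pfm[:, 0] += 1  # avoid all-zero columns
            pwm = pfm_to_pwm(pfm)
            seq = "".join(rng.choice(list("ACGT"), size=200))
            assert best_hit_relative_score(seq, pwm) == pytest.approx(
                brute_force_best(seq, pwm), abs=1e-12
            )

    @given(st.text(alphabet="ACGT", min_size=12, max_size=40))
    def test_reverse_complement_invariance(self, seq):
        pwm = demo_pwm()
        assert best_hit_relative_score(seq, pwm) == pytest.approx(
            best_hit_relative_score(revcomp(seq), pwm), abs=1e-12
        )

    def test_n_windows_skipped(self):
        pwm = demo_pwm()
        spiked = "N".join(pwm.consensus)  # every window hits an N
        padded = spiked + "ACGTACGTAC"
        scored = best_hit_relative_score(padded, pwm)
        assert scored < 1.0

    def test_all_n_scores_zero(self):
        assert best_hit_relative_score("N" * 30, demo_pwm()) == 0.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            best_hit_relative_score("ACG", demo_pwm())

    def test_degenerate_matrix_scores_one(self):
        pwm = PWMModel(name="flat", matrix=np.zeros((3, 4)), s_min=0.0, s_max=0.0)
        assert best_hit_relative_score("ACGTACG", pwm) == 1.0


class TestScanThreshold:
    def test_consensus_promoter_included(self):
        pwm = demo_pwm()
        promoters = PromoterSet({"hit": "AC" + pwm.consensus + "GT" * 10,
                                 "miss": "ACGT" * 8})
        assert scan_threshold(promoters, pwm, threshold=0.99) == {"hit"}

    def test_empty_set(self):
        assert scan_threshold(PromoterSet({}), demo_pwm()) == set()

    def test_anti_monotone_in_threshold(self, rng):
        pwm = demo_pwm()
        promoters = PromoterSet(
            {f"s{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(30)}
        )
        sets = [scan_threshold(promoters, pwm, threshold=t)
                for t in (0.5, 0.7, 0.9, 0.99)]
        for lo, hi in zip(sets, sets[1:]):
            assert hi <= lo

    def test_planted_sites_fully_recalled(self):
        pwm = demo_pwm()
        cfg = SimulationConfig(seed=11, prom_planted_fraction=0.5)
        inp, _, truth = generate_promoters(cfg, pwm)
        hits = scan_threshold(inp, pwm, threshold=1.0)
        assert set(truth["promoter_id"]) <= hits


class TestPscanZtest:
    def test_input_equals_background(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=80)) for i in range(40)}
        promoters = PromoterSet(seqs)
        enr = pscan_ztest(promoters, promoters, demo_pwm())
        assert enr.z == pytest.approx(0.0, abs=1e-12)
        assert enr.p_value == pytest.approx(0.5)

    def test_planted_motif_detected(self):
        pwm = demo_pwm()
        inp, bg, _ = generate_promoters(SimulationConfig(seed=3), pwm)
        assert pscan_ztest(inp, bg, pwm).p_value < 0.1

    def test_degenerate_background_rejected(self):
        same = PromoterSet({f"s{i}": "ACGTACGTACGT" for i in range(5)})
        with pytest.raises(ValueError, match="degenerate"):
            pscan_ztest(same, same, demo_pwm())

    def test_empty_input_rejected(self):
        bg = PromoterSet({"a": "ACGTACGTACGT"})
        with pytest.raises(ValueError):
            pscan_ztest(PromoterSet({}), bg, demo_pwm())


class TestCommonRegulators:
    def test_shared_tf_in_intersection(self):
        hits = {"cl1": {"TF1": {"a", "b"}, "TF2": {"a"}},
                "cl2": {"TF1": {"x", "y"}, "TF2": {"x", "y"}}}
        members = {"cl1": ["a", "b"], "cl2": ["x", "y"]}
        per_group, shared = common_regulators(hits, members)
        assert per_group == {"cl1": {"TF1"}, "cl2": {"TF1", "TF2"}}
        assert shared == {"TF1"}

    def test_partial_hit_excluded_under_all_members(self):
        per_group, _ = common_regulators(
            {"cl": {"TF": {"a"}}}, {"cl": ["a", "b"]}, mode="all_members"
        )
        assert per_group["cl"] == set()

    def test_threshold_mode_relaxes(self):
        per_group, _ = common_regulators(
            {"cl": {"TF": {"a"}}}, {"cl": ["a", "b"]}, mode="threshold", min_fraction=0.5
        )
        assert per_group["cl"] == {"TF"}

    def test_enrichment_mode_requires_every_group(self):
        pvals = {"g1": {"TF1": 0.01, "TF2": 0.5}, "g2": {"TF1": 0.05, "TF2": 0.01}}
        assert common_regulators_enrichment(pvals, alpha=0.1) == {"TF1"}

    def test_planted_shared_tf_recovered(self):
        pwm = demo_pwm("SHARED")
        groups, hits = {}, {}
        for gi, seed in enumerate((21, 22)):
            inp, _, _ = generate_promoters(
                SimulationConfig(seed=seed, prom_n_input=4, prom_planted_fraction=1.0), pwm
            )
            name = f"cluster{gi}"
            groups[name] = list(inp.sequences)
            hits[name] = {"SHARED": scan_threshold(inp, pwm, threshold=0.99)}
        per_group, shared = common_regulators(hits, groups)
        assert shared == {"SHARED"}


def test_parse_jaspar_flat_format():
    text = ">MA0001.1 DEMO\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
    models = parse_jaspar_pfm(io.StringIO(text))
    assert len(models) == 1
    assert models[0].name == "MA0001.1 DEMO"
    assert models[0].consensus == "AC"
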