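import numpy as np
import pytest
from hypothesis import given, strategies as st

import ladkit as lk
from ladkit.align import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_D_GRID,
    DEFAULT_GAP_PENALTY,
    DEFAULT_MATCH_OFFSET,
    DEFAULT_MATCH_SCALE,
)

from conftest import random_profile
from oracles import sw_bruteforce


def profile_from(values, metric="ED", window=9, sid="p"):
    return lk.LADProfile(
        structure_id=sid, metric=metric, window=window,
        entries=[(i + 1, float(v)) for i, v in enumerate(values)],
    )


class TestAlignProfiles:
    def test_self_alignment_is_perfect(self):
        rng = np.random.default_rng(1)
        p = random_profile(40, rng)
        aln = lk.align_profiles(p, p)
        assert aln.Ne == len(p)
        assert aln.lad_rmsd == pytest.approx(0.0, abs=1e-12)
        assert aln.lad_div <= 1e-6

    def test_small_perturbation_keeps_pairing(self):
        q = profile_from([1.0, 2.0, 3.0])
        s = profile_from([1.0, 2.1, 3.0])
        aln = lk.align_profiles(q, s)
        assert aln.pairs == [(0, 0), (1, 1), (2, 2)]
        assert aln.lad_rmsd == pytest.approx(np.sqrt(0.01 / 3))

    def test_metric_and_window_mismatch_error(self):
        q = profile_from([1, 2, 3], metric="ED")
        s = profile_from([1, 2, 3], metric="GD")
        with pytest.raises(ValueError, match="metric mismatch"):
            lk.align_profiles(q, s)
        s2 = profile_from([1, 2, 3], window=5)
        with pytest.raises(ValueError, match="window mismatch"):
            lk.align_profiles(q, s2)

    def test_hopeless_profiles_align_empty(self):
        q = profile_from([1.0, 1.0, 1.0])
        s = profile_from([50.0, 60.0, 70.0])
        aln = lk.align_profiles(q, s)
        assert aln.Ne == 0
        assert aln.lad_div == 1.0

    def test_pairs_strictly_increasing(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            q = random_profile(int(rng.integers(5, 30)), rng)
            s = random_profile(int(rng.integers(5, 30)), rng)
            aln = lk.align_profiles(q, s)
            for (a0, b0), (a1, b1) in zip(aln.pairs, aln.pairs[1:]):
                assert a1 > a0 and b1 > b0

    def test_matches_bruteforce_oracle_on_short_profiles(self):
        """Optimal-score agreement with exhaustive alignment enumeration."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            nq = int(rng.integers(1, 7))
            ns = int(rng.integers(1, 7))
            qv = rng.uniform(0.0, 4.0, nq)
            sv = rng.uniform(0.0, 4.0, ns)
            aln = lk.align_profiles(profile_from(qv), profile_from(sv))
            ref_score, _ = sw_bruteforce(
                qv, sv, DEFAULT_MATCH_OFFSET, DEFAULT_MATCH_SCALE, DEFAULT_GAP_PENALTY
            )
            assert aln.score == pytest.approx(ref_score, abs=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_lad_div_symmetric_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        q = random_profile(int(rng.integers(3, 25)), rng, structure_id="q")
        s = random_profile(int(rng.integers(3, 25)), rng, structure_id="s")
        a = lk.align_profiles(q, s)
        b = lk.align_profiles(s, q)
        assert a.lad_div == pytest.approx(b.lad_div, abs=1e-9)


class TestLadDiv:
    P_ED = lk.DiversityParams(1.0, 4.5)

    def test_no_aligned_residues_gives_one(self):
        assert lk.lad_div(0, 5.0, 100, 100, self.P_ED) == 1.0

    def test_perfect_match_gives_zero(self):
        assert lk.lad_div(100, 0.0, 100, 100, self.P_ED) == 0.0

    def test_published_worked_value(self):
        """Full-coverage pair at LAD-RMSD 0.173 scores 0.0004 (4 d.p.)."""
        assert round(lk.lad_div(100, 0.173, 100, 100, self.P_ED), 4) == 0.0004

    def test_dissimilar_pair_implies_low_coverage(self):
        # a pair at (RMSD, LAD_div) = (1.601, 0.955) implies Ne/mean ~ 0.42
        implied = (1 - 0.955) * (1 + (1.601 / 1.0) ** 4.5)
        assert implied == pytest.approx(0.42, abs=0.01)
        assert lk.lad_div(42, 1.601, 100, 100, self.P_ED) == pytest.approx(0.955, abs=0.001)

    def test_bounds_and_errors(self):
        with pytest.raises(ValueError):
            lk.lad_div(1, 0.5, 0, 0, self.P_ED)
        assert 0.0 <= lk.lad_div(10, 0.9, 30, 50, self.P_ED) <= 1.0

    def test_monotonicity_sweeps(self):
        """LAD_div rises with RMSD and falls with coverage over a fine grid."""
        params = self.P_ED
        rmsds = np.linspace(0.0, 5.0, 1000)
        divs = [lk.lad_div(80, r, 100, 100, params) for r in rmsds]
        assert all(b >= a - 1e-12 for a, b in zip(divs, divs[1:]))
        nes = np.arange(0, 101)
        divs_ne = [lk.lad_div(int(ne), 1.0, 100, 100, params) for ne in nes]
        assert all(b <= a + 1e-12 for a, b in zip(divs_ne, divs_ne[1:]))


class TestStructDiv:
    def test_zero_rmsd(self):
        assert lk.struct_div(0.0, 10, 20, 20) == 0.0

    def test_hand_value(self):
        assert lk.struct_div(2.0, 50, 100, 100) == pytest.approx(5.6569, abs=1e-4)

    def test_full_coverage_reduces_to_rmsd(self):
        assert lk.struct_div(1.37, 100, 100, 100) == pytest.approx(1.37)

    def test_empty_alignment_is_worst(self):
        assert lk.struct_div(1.0, 0, 100, 100) == float("inf")


class TestTuneDiversityParams:
    def test_default_grid_has_1800_combinations(self):
        assert len(DEFAULT_D_GRID) * len(DEFAULT_ALPHA_GRID) == 1800
        assert DEFAULT_D_GRID[0] == pytest.approx(0.1)
        assert DEFAULT_D_GRID[-1] == pytest.approx(20.0)
        assert list(DEFAULT_ALPHA_GRID) == pytest.approx([1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5])

    def test_perfectly_separated_pairs_hit_tie_rule(self):
        # positives/negatives separated at every grid point -> first point
        pos = [(100, 0.0, 100, 100)] * 5
        neg = [(0, 3.0, 100, 100)] * 5
        best = lk.tune_diversity_params(pos, neg)
        assert best.D == pytest.approx(0.1)
        assert best.alpha == pytest.approx(1.0)

    def test_degenerate_identical_sets_return_first_grid_point(self):
        same = [(50, 1.0, 100, 100)] * 4
        best = lk.tune_diversity_params(same, same)
        assert best.D == pytest.approx(0.1)
        assert best.alpha == pytest.approx(1.0)

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            lk.tune_diversity_params([], [(0, 3.0, 100, 100)])

    def test_parameter_recovery_on_synthetic_pairs(self):
        """The tuned optimum separates a held-out synthetic set >= 95%."""
        train = lk.make_labeled_pairs(200, 200, seed=7)
        held = lk.make_labeled_pairs(200, 200, seed=8)
        pos = [tuple(p) for p in train if p.label == "pos"]
        neg = [tuple(p) for p in train if p.label == "neg"]
        best = lk.tune_diversity_params(pos, neg)
        correct = 0
        for p in held:
            div = lk.lad_div(p.Ne, p.lad_rmsd, p.NQ, p.NS, best)
            ok = div < 0.5 if p.label == "pos" else div >= 0.5
            correct += ok
        assert correct / len(held) >= 0.95
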