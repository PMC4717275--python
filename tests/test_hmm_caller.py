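import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from cnvsurv.core import SampleSignal
from cnvsurv.hmm_caller import (
    HMMParams,
    compute_pfb,
    emission_loglik,
    emission_matrix,
    extract_calls,
    transition_matrix,
    viterbi_decode,
)
from cnvsurv.synthetic_data import TruthCNV, simulate_signals

from conftest import make_map
from _oracles import enumerate_best_path, path_score

PARAMS = HMMParams()


class TestEmission:
    def test_heterozygous_marker_favors_diploid_over_deletion(self):
        mu2 = PARAMS.lrr_means[2]
        ll2 = emission_loglik(mu2, 0.5, 0.5, 2, PARAMS)
        ll1 = emission_loglik(mu2, 0.5, 0.5, 1, PARAMS)
        assert ll2 > ll1

    @pytest.mark.parametrize("state", [1, 2, 3, 4])
    def test_baf_density_integrates_to_one_at_pfb_zero(self, state):
        from cnvsurv.hmm_caller import _baf_density
        total, _ = quad(lambda b: float(_baf_density(b, 0.0, state, PARAMS.baf_noise_sd)),
                        0.0, 1.0)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("state", [0, 1, 2, 3, 4])
    def test_allele_label_symmetry(self, state):
        for baf, pfb in [(0.2, 0.3), (0.0, 0.9), (0.47, 0.5), (0.8, 0.05)]:
            a = emission_loglik(0.1, baf, pfb, state, PARAMS)
            b = emission_loglik(0.1, 1 - baf, 1 - pfb, state, PARAMS)
            assert a == pytest.approx(b, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            emission_loglik(np.nan, 0.5, 0.5, 2, PARAMS)
        with pytest.raises(ValueError):
            emission_loglik(0.0, 0.5, 1.5, 2, PARAMS)
        with pytest.raises(ValueError):
            emission_loglik(0.0, 0.5, 0.5, 7, PARAMS)


class TestTransitions:
    @pytest.mark.parametrize("d", [0, 100, 5_000, 100_000, 5_000_000])
    def test_rows_sum_to_one(self, d):
        A = transition_matrix(d, PARAMS)
        assert np.allclose(A.sum(axis=1), 1.0)
        assert (A > 0).all() or d == 0

    def test_zero_distance_is_identity(self):
        assert np.allclose(transition_matrix(0, PARAMS), np.eye(5))

    def test_self_transition_decays_with_distance(self):
        a = transition_matrix(1_000, PARAMS)[2, 2]
        b = transition_matrix(1_000_000, PARAMS)[2, 2]
        assert a > b


class TestViterbi:
    def test_null_signal_decodes_all_diploid(self, small_map):
        rng = np.random.default_rng(0)
        n = len(small_map)
        lrr = rng.normal(0.0, 0.02, n)
        baf = np.clip(rng.binomial(2, small_map.pfb) / 2.0
                      + rng.normal(0, 0.01, n), 0, 1)
        sig = SampleSignal("A", lrr, baf)
        path = viterbi_decode(sig, small_map, PARAMS)
        assert np.all(path == 2)
        assert extract_calls(path, small_map, "A") == []

    def test_matches_exhaustive_enumeration(self):
        """Viterbi equals brute-force argmax over all 5^n paths (50 instances)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            mm = make_map(np.cumsum(rng.integers(500, 50_000, n)),
                          pfb=rng.uniform(0.05, 0.95, n))
            sig = SampleSignal("A",
                               rng.normal(-0.2, 1.0, n),
                               rng.uniform(0, 1, n))
            path = viterbi_decode(sig, mm, PARAMS)
            emis = emission_matrix(sig, mm, PARAMS)
            log_trans = [np.log(transition_matrix(mm.pos[i + 1] - mm.pos[i], PARAMS))
                         for i in range(n - 1)]
            log_init = np.full(5, np.log(0.2))
            best, best_score = enumerate_best_path(emis, log_trans, log_init)
            assert path_score(path, emis, log_trans, log_init) == \
                pytest.approx(best_score, abs=1e-9)
            assert np.array_equal(path, best)

    def test_implanted_deletion_recovered(self, small_map):
        pos = small_map.pos
        truth = [TruthCNV(f"S{i}", "1", int(pos[100]), int(pos[119]), 1)
                 for i in range(10)]
        sigs = simulate_signals(small_map, truth, noise=(0.15, 0.03, 0.0), seed=5)
        recalls = []
        for sid, sig in sigs.items():
            path = viterbi_decode(sig, small_map, PARAMS)
            recalls.append((path[100:120] == 1).mean())
        assert np.mean(recalls) >= 0.95

    def test_chromosome_block_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 40
        import pandas as pd
        from cnvsurv.core import MarkerMap
        blocks = {}
        for c in ("1", "2"):
            blocks[c] = pd.DataFrame({
                "marker_id": [f"m{c}_{i}" for i in range(n)],
                "chrom": c,
                "pos": np.cumsum(rng.integers(1000, 5000, n)),
                "pfb": rng.uniform(0, 1, n),
                "gc": rng.uniform(0.3, 0.7, n),
            })
        lrr = {c: rng.normal(0, 0.3, n) for c in blocks}
        baf = {c: rng.uniform(0, 1, n) for c in blocks}
        paths = {}
        for order in (("1", "2"), ("2", "1")):
            mm = MarkerMap(pd.concat([blocks[c] for c in order], ignore_index=True))
            sig = SampleSignal("A", np.concatenate([lrr[c] for c in order]),
                               np.concatenate([baf[c] for c in order]))
            p = viterbi_decode(sig, mm, PARAMS)
            paths[order] = {c: p[mm.chrom_slice(c)] for c in order}
        for c in ("1", "2"):
            assert np.array_equal(paths[("1", "2")][c], paths[("2", "1")][c])

    def test_single_marker_chromosome_errors(self):
        mm = make_map([1000])
        sig = SampleSignal("A", np.zeros(1), np.full(1, 0.5))
        with pytest.raises(ValueError, match="< 2 markers"):
            viterbi_decode(sig, mm, PARAMS)

    def test_truth_path_loglik_degrades_with_noise(self):
        """Larger emission noise never raises the truth path's likelihood."""
        rng = np.random.default_rng(8)
        n = 30
        mm = make_map(np.cumsum(rng.integers(1000, 4000, n)))
        truth_path = np.full(n, 2)
        truth_path[10:20] = 1
        eps = rng.normal(0, 1.0, n)  # fixed standardized residuals
        means = np.array(PARAMS.lrr_means)
        lls = []
        for sd in (0.05, 0.10, 0.20, 0.40):
            lrr = means[truth_path] + sd * eps
            params = HMMParams(lrr_sds=(sd,) * 5)
            sig = SampleSignal("A", lrr, np.full(n, 0.5))
            emis = emission_matrix(sig, mm, params)
            log_trans = [np.log(transition_matrix(mm.pos[i + 1] - mm.pos[i], params))
                         for i in range(n - 1)]
            lls.append(path_score(truth_path, emis, log_trans, np.full(5, np.log(0.2))))
        assert all(a >= b for a, b in zip(lls, lls[1:]))


class TestExtractCalls:
    def _path(self, n, runs):
        p = np.full(n, 2)
        for start, stop, s in runs:
            p[start:stop] = s
        return p

    def test_two_marker_run_is_dropped(self):
        mm = make_map(range(1000, 11000, 1000))
        calls = extract_calls(self._path(10, [(3, 5, 1)]), mm, "A")
        assert calls == []

    def test_sub_kb_run_is_dropped(self):
        mm = make_map([1000, 1300, 1600, 1800, 5000, 9000])
        # 3 markers spanning 1000..1600 = 800 bp < 1 kb
        calls = extract_calls(self._path(6, [(0, 3, 1)]), mm, "A")
        assert calls == []

    def test_five_marker_duplication_call(self):
        mm = make_map([1000, 4000, 7000, 10000, 12999, 20000, 30000])
        calls = extract_calls(self._path(7, [(0, 5, 3)]), mm, "A")
        assert len(calls) == 1
        c = calls[0]
        assert (c.state, c.n_snps, c.length_bp, c.cnv_type) == (3, 5, 12000, "duplication")
        assert (c.start_pos, c.end_pos) == (1000, 12999)

    def test_mixed_state_runs_split_by_state(self):
        mm = make_map(range(1000, 16000, 1000))
        path = self._path(15, [(2, 6, 1), (6, 10, 0)])
        calls = extract_calls(path, mm, "A")
        assert [c.state for c in calls] == [1, 0]

    def test_calls_sorted_and_non_overlapping(self, small_map):
        rng = np.random.default_rng(17)
        path = rng.choice([0, 1, 2, 3, 4], size=len(small_map), p=[.05, .15, .6, .15, .05])
        calls = extract_calls(path, small_map, "A")
        for a, b in zip(calls, calls[1:]):
            if a.chrom == b.chrom:
                assert a.end_pos < b.start_pos


def test_compute_pfb_is_per_marker_median(small_map):
    rng = np.random.default_rng(2)
    sigs = [SampleSignal(f"S{i}", np.zeros(len(small_map)),
                         rng.uniform(0, 1, len(small_map))) for i in range(7)]
    pfb = compute_pfb(sigs, small_map)
    expected = np.median(np.stack([s.baf for s in sigs]), axis=0)
    assert np.array_equal(pfb, expected)
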