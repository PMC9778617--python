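"""Sequential extraction: centers, radii, pruning, and whole-fit behavior."""

import numpy as np
import pytest

from mixedclust.cluster import (
    FitConfig,
    _dv_from,
    extract_cluster,
    find_center,
    fit,
    prune_memberships,
    radius_categorical,
    radius_quantized,
)
from mixedclust.datatypes import MixedDataset
from mixedclust.localtest import LocalTestResult, cutoff
from mixedclust.metrics import classification_rate
from mixedclust.quantize import quantize_dataset
from mixedclust.simulate import (
    SimulationConfig,
    generate,
    generate_null,
    make_categorical_centers,
)


def _make_test(chi_c, chi_q, df_c, df_q, r_q=1):
    return LocalTestResult(
        r_c=1, r_q=r_q, chi_c=chi_c, chi_q=chi_q, chi_w=(chi_c + chi_q) / 2,
        df=df_c + df_q, crit=0.0, significant=True, df_c=df_c, df_q=df_q,
    )


class TestRadii:
    def test_first_local_minimum_rule(self):
        assert radius_categorical(np.array([10, 6, 2, 7, 1, 0]), fallback=9) == 1

    def test_strictly_decreasing_uses_fallback(self):
        assert radius_categorical(np.array([9, 7, 5, 3, 1, 0]), fallback=4) == 4

    def test_immediate_valley_gives_singleton_radius(self):
        assert radius_categorical(np.array([5, 0, 9, 2]), fallback=3) == 0

    def test_quantized_radius_is_the_cutoff(self):
        assert radius_quantized(_make_test(1, 1, 1, 1, r_q=3)) == 3

    def test_quantized_radius_matches_recomputed_cutoff(self, three_cluster_data):
        data, _ = three_cluster_data
        cfg = FitConfig()
        qd = quantize_dataset(data, 9)
        _, _, _, test, _, dq = find_center(qd, np.ones(data.n, bool), cfg)
        from mixedclust.distances import uniform_dv_quantized

        udv_q = uniform_dv_quantized(data.n, qd.l).expected
        assert radius_quantized(test) == cutoff(_dv_from(dq, data.q), udv_q, start=2)


class TestFindCenter:
    def test_degenerate_single_row_cluster(self):
        X = np.tile([1, 0, 2], (20, 1))
        Z = np.tile([0.3], (20, 1)) + np.linspace(0, 0.01, 20)[:, None]
        data = MixedDataset(X=X, levels=[np.arange(3)] * 3, Z=Z)
        qd = quantize_dataset(data, 4)
        _, S, T, test, _, _ = find_center(qd, np.ones(20, bool), FitConfig())
        np.testing.assert_array_equal(S, [1, 0, 2])
        assert test.chi_w > 0

    def test_center_lands_near_a_true_center(self):
        for seed in (1, 2, 3):
            data, _ = generate(SimulationConfig(seed=seed))
            rng = np.random.default_rng(seed)  # replay the generator's draws
            m = rng.choice(np.asarray((4, 5, 6)), size=10)
            true_centers = make_categorical_centers(3, 10, m, 5, rng)
            qd = quantize_dataset(data, 9)
            _, S, _, _, _, _ = find_center(qd, np.ones(data.n, bool), FitConfig())
            assert min((S != c).sum() for c in true_centers) <= 2


class TestExtract:
    def test_whole_space_radii_remove_everything(self):
        dist_c = np.array([0, 1, 3, 2])
        dist_q = np.array([2, 0, 1, 3])
        _, _, removed = extract_cluster(dist_c, dist_q, R_C=3, R_Q=3)
        assert removed.all()

    def test_zero_radii_keep_only_center_matches(self):
        dist_c = np.array([0, 1, 0, 2])
        dist_q = np.array([0, 0, 1, 2])
        mem_c, mem_q, removed = extract_cluster(dist_c, dist_q, R_C=0, R_Q=0)
        assert mem_c.tolist() == [True, False, True, False]
        assert mem_q.tolist() == [True, True, False, False]
        assert removed.tolist() == [True, True, True, False]

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            extract_cluster(np.array([0]), np.array([0]), -1, 0)

    def test_first_extraction_is_dominated_by_largest_cluster(self, three_cluster_data):
        data, labels = three_cluster_data
        cfg = FitConfig()
        qd = quantize_dataset(data, 9)
        _, _, _, test, dc, dq = find_center(qd, np.ones(data.n, bool), cfg)
        R_C = radius_categorical(_dv_from(dc, data.p), fallback=test.r_c)
        _, _, removed = extract_cluster(dc, dq, R_C, test.r_q)
        assert (labels[removed] == 1).mean() >= 0.9


class TestPrune:
    def test_agreeing_portions_decide_directly(self):
        X = np.array([[0, 0], [2, 2], [0, 0], [2, 2]])
        Q = np.array([[1, 1], [3, 3], [1, 1], [3, 3]])
        data = MixedDataset(X=X, levels=[np.arange(3)] * 2, Z=Q.astype(float))
        from mixedclust.datatypes import QuantizedDataset

        qd = QuantizedDataset(base=data, Q=Q, M=3)
        centers = [(np.array([0, 0]), np.array([1, 1])), (np.array([2, 2]), np.array([3, 3]))]
        tests = [_make_test(50, 50, 1, 1), _make_test(50, 50, 1, 1)]
        member = prune_memberships(centers, tests, qd)
        assert member.tolist() == [1, 2, 1, 2]

    def test_single_cluster_takes_everything(self):
        X = np.array([[0, 1], [1, 0], [2, 2]])
        Q = np.array([[1, 1], [2, 2], [3, 3]])
        data = MixedDataset(X=X, levels=[np.arange(3)] * 2, Z=Q.astype(float))
        from mixedclust.datatypes import QuantizedDataset

        qd = QuantizedDataset(base=data, Q=Q, M=3)
        member = prune_memberships(
            [(np.array([0, 1]), np.array([1, 1]))], [_make_test(10, 10, 1, 1)], qd
        )
        assert member.tolist() == [1, 1, 1]

    def test_conflict_goes_to_stronger_evidence(self):
        # record 0: categorically nearest cluster A, quantized nearest cluster B
        X = np.array([[0, 0], [0, 0], [2, 2]])
        Q = np.array([[3, 3], [1, 1], [3, 3]])
        data = MixedDataset(X=X, levels=[np.arange(3)] * 2, Z=Q.astype(float))
        from mixedclust.datatypes import QuantizedDataset

        qd = QuantizedDataset(base=data, Q=Q, M=3)
        centers = [(np.array([0, 0]), np.array([1, 1])), (np.array([2, 2]), np.array([3, 3]))]
        # A's categorical evidence (chi 25, df 1) beats B's quantized (chi 2, df 1)
        tests = [_make_test(25.0, 25.0, 1, 1), _make_test(2.0, 2.0, 1, 1)]
        member = prune_memberships(centers, tests, qd, conflict_rule="stronger_evidence")
        assert member[0] == 1
        member = prune_memberships(centers, tests, qd, conflict_rule="weaker_evidence")
        assert member[0] == 2


class TestFit:
    def test_recovers_three_clusters_with_high_accuracy(self, three_cluster_data):
        data, labels = three_cluster_data
        model = fit(data)
        assert model.K == 3
        cr, _ = classification_rate(labels, model.membership)
        assert cr > 0.9
        assert model.membership.min() >= 1 and model.membership.max() <= model.K

    def test_deterministic_bitwise(self, three_cluster_data):
        data, _ = three_cluster_data
        cfg = FitConfig(fixed_M=8)
        a = fit(data, cfg)
        b = fit(data, cfg)
        np.testing.assert_array_equal(a.membership, b.membership)
        assert a.radii_c == b.radii_c and a.radii_q == b.radii_q

    def test_record_duplication_invariance(self, three_cluster_data):
        data, _ = three_cluster_data
        cfg = FitConfig(fixed_M=8)
        base = fit(data, cfg)
        dup = MixedDataset(
            X=np.vstack([data.X] * 2), levels=data.levels, Z=np.vstack([data.Z] * 2)
        )
        doubled = fit(dup, cfg)
        assert doubled.K == base.K
        np.testing.assert_array_equal(np.tile(base.membership, 2), doubled.membership)

    def test_record_permutation_stability(self, three_cluster_data):
        data, _ = three_cluster_data
        cfg = FitConfig(fixed_M=8)
        base = fit(data, cfg)
        perm = np.random.default_rng(0).permutation(data.n)
        permuted = MixedDataset(X=data.X[perm], levels=data.levels, Z=data.Z[perm])
        model = fit(permuted, cfg)
        np.testing.assert_array_equal(base.membership[perm], model.membership)

    def test_uniform_data_reports_no_structure(self):
        data = generate_null(200, (3, 3, 3), 3, seed=0)
        model = fit(data, FitConfig(fixed_M=3))
        assert model.no_structure
        assert model.K == 0
        assert (model.membership == 1).all()  # single-cluster fallback

    def test_too_few_records_rejected(self):
        data = generate_null(20, (3, 3), 2, seed=0)
        with pytest.raises(ValueError):
            fit(data, FitConfig(min_n=50))

    def test_extraction_trace_is_recorded(self, three_cluster_data):
        data, _ = three_cluster_data
        model = fit(data, FitConfig(fixed_M=8))
        extracts = [e for e in model.trace if e["event"] == "extract"]
        assert len(extracts) == model.K
        assert all(e["n_removed"] >= 1 for e in extracts)
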