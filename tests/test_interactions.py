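"""Pair regression, distance correlation, mode rules, pair counting,
imputation bookkeeping — with brute-force oracles where the spec of the
operation admits one."""

import itertools

import numpy as np
import pytest

from cpax.interactions import (
    DeltaProfiles,
    InteractionMetrics,
    classify_mode,
    compute_deltas,
    count_missing_pairs,
    distance_correlation,
    fit_pair_regression,
    impute_all_pairs,
    interaction_metrics,
)
from conftest import tiny_dataset


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _grid_refine_regression(da, db, dab, lo=-10.0, hi=10.0, rounds=12, steps=21):
    """Brute-force 2-parameter least squares by iterative grid refinement."""
    best = (np.inf, 0.0, 0.0)
    c1_lo, c1_hi, c2_lo, c2_hi = lo, hi, lo, hi
    for _ in range(rounds):
        c1s = np.linspace(c1_lo, c1_hi, steps)
        c2s = np.linspace(c2_lo, c2_hi, steps)
        for c1 in c1s:
            res = dab - c1 * da
            for c2 in c2s:
                sse = float(np.sum((res - c2 * db) ** 2))
                if sse < best[0]:
                    best = (sse, c1, c2)
        span1 = (c1_hi - c1_lo) / (steps - 1)
        span2 = (c2_hi - c2_lo) / (steps - 1)
        c1_lo, c1_hi = best[1] - span1, best[1] + span1
        c2_lo, c2_hi = best[2] - span2, best[2] + span2
    return best[1], best[2]


def _dcor_bruteforce(x, y):
    """Direct O(n^2) double-loop distance correlation."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    n = x.shape[0]
    a = np.array([[np.linalg.norm(x[i] - x[j]) for j in range(n)] for i in range(n)])
    b = np.array([[np.linalg.norm(y[i] - y[j]) for j in range(n)] for i in range(n)])
    A = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    B = b - b.mean(0) - b.mean(1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvx, dvy = (A * A).mean(), (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


class TestPairRegression:
    def test_orthogonal_projection(self):
        da = np.array([1.0, 0.0, 0.0, 2.0])
        db = np.array([0.0, 3.0, -1.0, 0.0])
        da, db = da - 0, db - 0
        c1, c2, fit = fit_pair_regression(DeltaProfiles(da, db, da.copy()))
        assert c1 == pytest.approx(1.0, abs=1e-12)
        assert c2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_normal_equations(self):
        d = DeltaProfiles(np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([2.0, 3.0]))
        c1, c2, _ = fit_pair_regression(d)
        assert (c1, c2) == (pytest.approx(2.0), pytest.approx(3.0))

    def test_collinear_minimal_norm(self):
        d = DeltaProfiles(np.array([1.0, 1.0]), np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        c1, c2, _ = fit_pair_regression(d)
        assert c1 == pytest.approx(1.0, abs=1e-10)
        assert c2 == pytest.approx(1.0, abs=1e-10)

    def test_recovers_planted_coefficients_vs_grid_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            da = rng.standard_normal(60)
            db = rng.standard_normal(60)
            c1_true, c2_true = rng.uniform(-3, 3, size=2)
            dab = c1_true * da + c2_true * db  # noise-free construction
            c1, c2, _ = fit_pair_regression(DeltaProfiles(da, db, dab))
            assert c1 == pytest.approx(c1_true, abs=1e-6)
            assert c2 == pytest.approx(c2_true, abs=1e-6)
            g1, g2 = _grid_refine_regression(da, db, dab)
            assert c1 == pytest.approx(g1, abs=1e-4)
            assert c2 == pytest.approx(g2, abs=1e-4)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_pair_regression(DeltaProfiles(np.zeros(4), np.zeros(4), np.ones(4)))


class TestDistanceCorrelation:
    def test_self_and_affine_are_one(self):
        x = np.random.default_rng(0).standard_normal(80)
        assert distance_correlation(x, x) == pytest.approx(1.0)
        assert distance_correlation(x, 3.0 - 2.0 * x) == pytest.approx(1.0)

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        assert distance_correlation(x, y) < 0.1

    def test_constant_input_defined_as_zero(self):
        x = np.random.default_rng(2).standard_normal(30)
        assert distance_correlation(np.ones(30), x) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = x**2 + 0.3 * rng.standard_normal(40)
        assert distance_correlation(x, y) == pytest.approx(_dcor_bruteforce(x, y), abs=1e-10)
        m = rng.standard_normal((40, 2))
        assert distance_correlation(m, y) == pytest.approx(_dcor_bruteforce(m, y), abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            v = distance_correlation(rng.standard_normal(25), rng.standard_normal(25))
            assert 0.0 <= v <= 1.0


class TestMetricsAndModes:
    def test_magnitude_and_dominance(self):
        d = DeltaProfiles(np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([2.0, 3.0]))
        m = interaction_metrics(d)
        assert m.magnitude == pytest.approx(np.sqrt(13.0))
        assert m.magnitude == pytest.approx(np.sqrt(m.c1**2 + m.c2**2))
        assert m.dominance == pytest.approx(np.log10(2.0 / 3.0))

    def test_dominance_zero_when_equal_and_clipped_when_degenerate(self):
        rng = np.random.default_rng(0)
        da = rng.standard_normal(30)
        db = rng.standard_normal(30)
        m = interaction_metrics(DeltaProfiles(da, db, da + db))
        assert abs(m.dominance) < 0.2
        m0 = interaction_metrics(DeltaProfiles(da, db, 2.0 * da))
        assert m0.dominance == 6.0  # c2 == 0 -> clipped +inf

    def test_equal_contrib_symmetric_construction(self):
        # orthogonal singles with mirrored profiles: the double relates to each
        # single identically, so min/max of the single-double dcors is 1
        da = np.array([1.0, 2.0, 0.0, 0.0])
        db = np.array([0.0, 0.0, 1.0, 2.0])
        m = interaction_metrics(DeltaProfiles(da, db, da + db))
        assert m.equal_contrib == pytest.approx(1.0)

    def _metrics(self, **kw):
        base = dict(c1=1.0, c2=1.0, fit_dcor=0.9, magnitude=np.sqrt(2.0), dominance=0.0,
                    dcor_ab_singles=0.5, dcor_joint_double=0.95, equal_contrib=0.9)
        base.update(kw)
        return InteractionMetrics(**base)

    def test_epistatic_rule_arithmetic(self):
        # min(|1.0|, |0.3|) > 0.2 and |c1| > 2|c2|: the epistatic rule fires
        m = self._metrics(c1=1.0, c2=0.3, magnitude=np.sqrt(1.09), dcor_ab_singles=0.5,
                          dcor_joint_double=0.5)
        assert "epistatic" in classify_mode(m).matched_rules

    def test_epistatic_fires_alone_below_unit_magnitude(self):
        m = self._metrics(c1=0.6, c2=0.25, magnitude=np.hypot(0.6, 0.25),
                          dcor_ab_singles=0.5, dcor_joint_double=0.5)
        out = classify_mode(m)
        assert out.mode == "epistatic"
        assert out.matched_rules == ["epistatic"]

    def test_overlapping_rules_yield_unassigned(self):
        # magnitude exactly 1 with all dcors ~ 1: additive and redundant both fire
        m = self._metrics(c1=0.6, c2=0.8, magnitude=1.0, dcor_ab_singles=0.99,
                          dcor_joint_double=0.99)
        out = classify_mode(m)
        assert out.mode == "unassigned"
        assert set(out.matched_rules) == {"additive", "redundant"}

    def test_additive_band_two_sided(self):
        # |1.05 - 1| < 0.1: the additive rule fires
        m = self._metrics(c1=0.74, c2=0.74, magnitude=1.05, dcor_ab_singles=0.85,
                          dcor_joint_double=0.95)
        assert "additive" in classify_mode(m).matched_rules
        # sole match requires magnitude <= 1 (else potentiation/synergy compete)
        alone = self._metrics(c1=0.67, c2=0.67, magnitude=0.95, dcor_ab_singles=0.5,
                              dcor_joint_double=0.95)
        assert classify_mode(alone).mode == "additive"
        low = self._metrics(c1=0.5, c2=0.5, magnitude=0.707, dcor_ab_singles=0.5,
                            dcor_joint_double=0.5)
        assert "additive" not in classify_mode(low).matched_rules

    def test_non_finite_metrics_rejected(self):
        with pytest.raises(ValueError):
            classify_mode(self._metrics(magnitude=np.nan))


class TestPairCounting:
    def test_printed_genetic_screen_numbers(self):
        missing, percent = count_missing_pairs(105, 131)
        assert missing == 5329
        assert percent == 97.6

    def test_boundaries(self):
        assert count_missing_pairs(3, 0) == (3, 100.0)
        assert count_missing_pairs(105, 105 * 104 // 2) == (0, 0.0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for n in [2, 5, 13, 27, 50]:
            all_pairs = list(itertools.combinations(range(n), 2))
            k = int(rng.integers(0, len(all_pairs) + 1))
            measured = set(rng.choice(len(all_pairs), size=k, replace=False).tolist())
            expected_missing = sum(1 for i in range(len(all_pairs)) if i not in measured)
            missing, percent = count_missing_pairs(n, k)
            assert missing == expected_missing
            assert percent == round(100.0 * expected_missing / len(all_pairs), 1)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            count_missing_pairs(4, 7)


class TestDeltasAndImputation:
    def test_deltas_zero_for_control_and_shift_invariant(self):
        ds, _ = tiny_dataset(0)
        cids = sorted(set(ds.condition_ids))
        ctrl = next(c for c in cids if c.startswith("ctrl@") and c.endswith("line0"))
        a = next(c for c in cids if c.startswith("A@") and c.endswith("line0"))
        b = next(c for c in cids if c.startswith("B@") and c.endswith("line0"))
        d = compute_deltas(ds, a, b, ctrl)
        ds_shifted = ds.subset(np.arange(ds.n_cells))
        ds_shifted.X = ds.X + 7.5
        d2 = compute_deltas(ds_shifted, a, b, ctrl)
        np.testing.assert_allclose(d.delta_a, d2.delta_a, atol=1e-9)
        np.testing.assert_allclose(d.delta_ab, d2.delta_ab, atol=1e-9)
        d_null = compute_deltas(ds, ctrl, b, ctrl, double=b)
        np.testing.assert_allclose(d_null.delta_a, 0.0, atol=1e-12)

    def test_missing_condition_named_in_error(self):
        ds, _ = tiny_dataset(0)
        with pytest.raises(ValueError, match="nope"):
            compute_deltas(ds, "nope", "alsonope", "ctrl@0|line0", double="x")

    def test_impute_counts_and_uncertainty(self, tiny_trained):
        model, ds, _ = tiny_trained
        # M=3 with one measured pair (A,B) -> C(3,2) - 1 = 2 imputed rows
        table = impute_all_pairs(model, ds, n_cells_per_pair=10)
        assert len(table) == 2
        assert set(table["pair_id"]) == {"A+C", "B+C"}
        assert (table["u_euclidean"] > 0).all()
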