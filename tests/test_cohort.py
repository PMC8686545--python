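"""Differential PSI, overlap/direction tests, BH and survival machinery."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicemap.cohort import (
    CohortMatrix,
    _km_curve,
    bh_fdr,
    differential_psi,
    direction_agreement_test,
    km_stratify,
    overlap_test,
)


# --- overlap / hypergeometric ----------------------------------------------

def test_worked_overlap_example():
    universe = set(range(10))
    a = set(range(5))
    b = {0, 1, 2, 3}
    k, p = overlap_test(a, b, universe)
    assert k == 4
    assert p == pytest.approx(5 / 210)


def test_zero_overlap_and_full_overlap_have_p_one():
    universe = set(range(10))
    assert overlap_test({0, 1}, {5, 6}, universe)[1] == pytest.approx(1.0)
    assert overlap_test(universe, universe, universe)[1] == pytest.approx(1.0)


def test_ids_outside_universe_rejected():
    with pytest.raises(ValueError, match="outside the universe"):
        overlap_test({"x"}, {"y"}, {"y"})


def _enum_hypergeom_upper(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by enumeration."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def test_hypergeometric_matches_enumeration_up_to_n12():
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                lo = max(0, K + n - N)
                hi = min(K, n)
                for k in range(lo, hi + 1):
                    universe = set(range(N))
                    a = set(range(K))
                    # choose b with overlap exactly k
                    b = set(range(k)) | set(range(K, K + (n - k)))
                    got = overlap_test(a, b, universe)[1]
                    assert got == pytest.approx(
                        _enum_hypergeom_upper(k, N, K, n), abs=1e-12)


def _enum_fisher_two_sided(table):
    """Two-sided Fisher p by enumeration over tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    total = comb(N, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / total

    obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= obs + 1e-12)


def test_direction_agreement_matches_enumeration():
    table, p, frac = direction_agreement_test(
        [("up", "up")] * 3 + [("down", "down")] * 3)
    assert p == pytest.approx(0.1)
    assert frac == 1.0
    table, p, _ = direction_agreement_test(
        [("up", "up"), ("up", "down"), ("down", "up"), ("down", "down")])
    assert p == pytest.approx(1.0)


def test_fisher_two_sided_matches_enumeration_small_tables():
    for a, b, c, d in itertools.product(range(4), repeat=4):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        pairs = ([("up", "up")] * a + [("up", "down")] * b
                 + [("down", "up")] * c + [("down", "down")] * d)
        _, p, _ = direction_agreement_test(pairs)
        assert p == pytest.approx(_enum_fisher_two_sided([[a, b], [c, d]]),
                                  abs=1e-9)


def test_agreement_fraction_and_polarity():
    pairs = [("up", "down")] * 27
    _, _, frac = direction_agreement_test(pairs)
    assert frac == 0.0
    _, _, frac = direction_agreement_test(pairs, polarity="opposite")
    assert frac == 1.0


# --- BH ---------------------------------------------------------------------

def test_bh_step_up_examples():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_is_monotone_and_permutation_invariant():
    rng = np.random.default_rng(3)
    p = rng.random(40)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    perm = rng.permutation(40)
    assert bh_fdr(p[perm]) == pytest.approx(q[perm])


# --- differential PSI -------------------------------------------------------

def _psi_frame(a_vals, b_vals, n_events=1):
    samples = [f"A{i}" for i in range(len(a_vals))] + \
              [f"B{i}" for i in range(len(b_vals))]
    data = np.tile(np.concatenate([a_vals, b_vals]), (n_events, 1))
    psi = pd.DataFrame(data, columns=samples,
                       index=[f"e{i}" for i in range(n_events)])
    labels = pd.Series(["ga"] * len(a_vals) + ["gb"] * len(b_vals),
                       index=samples)
    return psi, labels


def test_identical_groups_not_significant():
    vals = np.linspace(0.1, 0.9, 10)
    psi, labels = _psi_frame(vals, vals, n_events=3)
    results = differential_psi(psi, labels)
    assert all(r.delta_median_psi == 0 for r in results)
    assert not any(r.significant for r in results)


def test_shifted_group_detected():
    rng = np.random.default_rng(0)
    a = rng.beta(5, 5, size=40)
    b = np.clip(a + 0.3, 0, 1)
    psi, labels = _psi_frame(a, b)
    (res,) = differential_psi(psi, labels)
    assert res.significant
    assert res.delta_median_psi == pytest.approx(-0.3, abs=0.05)


def test_sparse_events_reported_untested():
    psi, labels = _psi_frame(np.array([0.1, 0.2]), np.array([0.5, 0.6, 0.7]))
    (res,) = differential_psi(psi, labels)
    assert not res.tested and not res.significant


def test_one_group_empty_is_error():
    psi, labels = _psi_frame(np.array([0.1, 0.2, 0.3]), np.array([]))
    with pytest.raises(ValueError):
        differential_psi(psi, labels)


def test_null_type_i_control_small():
    rng = np.random.default_rng(1)
    n_events, n = 400, 30
    psi = pd.DataFrame(rng.beta(5, 5, size=(n_events, 2 * n)),
                       columns=[f"S{i}" for i in range(2 * n)],
                       index=[f"e{i}" for i in range(n_events)])
    labels = pd.Series(["a"] * n + ["b"] * n, index=psi.columns)
    results = differential_psi(psi, labels)
    assert sum(r.significant for r in results) / n_events < 0.01


# --- survival ---------------------------------------------------------------

def test_product_limit_matches_hand_worked_example():
    time = np.array([1.0, 2.0, 2.5, 3.0, 3.5])
    observed = np.array([1, 1, 0, 1, 0])
    curve = _km_curve(time, observed)
    surv = dict(zip(curve.time, curve.survival))
    assert surv[1.0] == pytest.approx(0.8)
    assert surv[2.0] == pytest.approx(0.6)
    assert surv[3.0] == pytest.approx(0.3)


def test_identical_groups_logrank_null():
    time = np.tile(np.arange(1.0, 11.0), 2)
    obs = np.ones(20)
    psi = np.array([0.2] * 10 + [0.8] * 10)
    res = km_stratify(psi, time, obs, cutoff_mode="fixed", fixed_cutoff=0.5)
    assert res.logrank_stat == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_invariant_under_label_exchange():
    rng = np.random.default_rng(2)
    psi = rng.random(40)
    time = rng.exponential(100, size=40)
    obs = np.ones(40)
    a = km_stratify(psi, time, obs, cutoff_mode="fixed", fixed_cutoff=0.5)
    b = km_stratify(1 - psi, time, obs, cutoff_mode="fixed", fixed_cutoff=0.5)
    assert a.logrank_stat == pytest.approx(b.logrank_stat)
    assert a.p_value == pytest.approx(b.p_value)
    assert (a.n_high, a.n_low) == (b.n_low, b.n_high)


def test_optimal_cutoff_respects_group_floor():
    rng = np.random.default_rng(4)
    psi = rng.random(50)
    time = rng.exponential(100, size=50)
    obs = np.ones(50)
    with pytest.warns(UserWarning, match="nominal"):
        res = km_stratify(psi, time, obs, cutoff_mode="optimal",
                          min_group_frac=0.2)
    assert min(res.n_high, res.n_low) >= 10
    assert res.km_curves["high"].survival.iloc[-1] <= 1.0


def test_km_curves_start_at_one_and_decrease():
    rng = np.random.default_rng(5)
    time = rng.exponential(50, size=30)
    obs = rng.integers(0, 2, size=30)
    curve = _km_curve(time, obs)
    assert curve.survival.iloc[0] <= 1.0 + 1e-12
    assert (np.diff(curve.survival) <= 1e-12).all()


def test_cohort_matrix_validates_samples_and_times():
    psi = pd.DataFrame([[0.5]], index=["e"], columns=["S1"])
    expr = pd.DataFrame([[1.0]], index=["g"], columns=["S1"])
    meta = pd.DataFrame({"subtype": ["TNBC"], "survival_time": [10.0],
                         "event_indicator": [1]}, index=["S1"])
    CohortMatrix(psi, expr, meta)  # valid
    bad_meta = meta.copy()
    bad_meta["survival_time"] = [-1.0]
    with pytest.raises(ValueError, match="survival_time"):
        CohortMatrix(psi, expr, bad_meta)
    with pytest.raises(ValueError, match="missing from metadata"):
        CohortMatrix(psi.rename(columns={"S1": "S2"}), expr, meta)
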