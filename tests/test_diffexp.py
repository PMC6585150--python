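"""The count-comparison statistic, FDR, and pairwise group comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circdiff.diffexp import (ACInputs, ComparisonGroup, ComparisonSummary,
                              ac_p_value, ac_point_probability, bh_fdr,
                              compare_group, log2_ratio, read_results,
                              scatter_data, tpm, write_results)

from conftest import ac_point_exact, ac_two_sided_exact, make_table


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("reads, total, expected", [
    (50, 1_000_000, 50.0),
    (0, 123, 0.001),           # undetected -> floor
    (34_101, 34_101, 1_000_000.0),
    (1, 1_000_000, 1.0),       # detected-but-low is NOT floored
])
def test_tpm(reads, total, expected):
    assert tpm(reads, total) == pytest.approx(expected, rel=1e-12)


def test_tpm_rejects_bad_inputs():
    with pytest.raises(ValueError):
        tpm(1, 0)
    with pytest.raises(ValueError):
        tpm(-1, 10)


@pytest.mark.parametrize("b, c, expected", [
    (1.0, 2.0, 1.0),
    (0.001, 1.024, 10.0),  # undetected baseline: log2(1024)
    (3.7, 3.7, 0.0),
])
def test_log2_ratio(b, c, expected):
    assert log2_ratio(b, c) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        log2_ratio(0.0, 1.0)


# ---------------------------------------------------------------------------
# Point probability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, y, n1, n2, expected", [
    (0, 0, 100, 100, 0.5),
    (0, 0, 100, 300, 0.25),
    (1, 2, 100, 100, 3 / 16),
])
def test_point_probability_closed_forms(x, y, n1, n2, expected):
    assert ac_point_probability(ACInputs(x, y, n1, n2)) == pytest.approx(
        expected, rel=1e-12)


def test_point_probability_matches_exact_rational():
    for n1, n2 in [(100, 100), (1000, 100), (100, 1000), (97, 311)]:
        for x in range(0, 31, 5):
            for y in range(0, 31, 3):
                got = ac_point_probability(ACInputs(x, y, n1, n2))
                want = float(ac_point_exact(x, y, n1, n2))
                assert got == pytest.approx(want, rel=1e-10), (x, y, n1, n2)


def test_point_probability_is_negative_binomial():
    """p(y|x) equals the NB pmf with size x+1, success prob 1/(1+N2/N1)."""
    for ratio_n in [(1000, 100), (200, 100), (100, 100), (100, 200), (100, 1000)]:
        n1, n2 = ratio_n
        p = 1.0 / (1.0 + n2 / n1)
        for x in range(0, 51, 10):
            y = np.arange(0, 80)
            ours = np.array([ac_point_probability(ACInputs(x, int(k), n1, n2))
                             for k in y])
            ref = stats.nbinom.pmf(y, x + 1, p)
            np.testing.assert_allclose(ours, ref, rtol=1e-10)


def test_point_probability_sums_to_one():
    """Σ_y p(y|x) = 1; the truncated sum must reach 1 - 1e-9."""
    for n1, n2 in [(100, 100), (1000, 100), (100, 1000)]:
        for x in [0, 3, 25]:
            total, y = 0.0, 0
            # scale both libraries up (ratio preserved) so y never hits N2
            while total < 1 - 1e-9 and y < 500_000:
                total += ac_point_probability(ACInputs(x, y, n1 * 10**4, n2 * 10**4))
                y += 1
            assert total >= 1 - 1e-9


def test_point_probability_symmetric_at_equal_libraries():
    for x, y in [(0, 5), (3, 7), (12, 1), (20, 20)]:
        assert ac_point_probability(ACInputs(x, y, 500, 500)) == pytest.approx(
            ac_point_probability(ACInputs(y, x, 500, 500)), rel=1e-12)


def test_point_probability_large_counts_do_not_overflow():
    p = ac_point_probability(ACInputs(10**6, 10**6, 10**7, 10**7))
    assert 0 < p < 1
    assert math.isfinite(p)


# ---------------------------------------------------------------------------
# Two-sided p-value
# ---------------------------------------------------------------------------

def test_two_sided_trivial_and_point_delegation():
    assert ac_p_value(ACInputs(0, 0, 100, 100)) == 1.0
    for x, y in [(2, 10), (7, 0), (5, 5)]:
        assert ac_p_value(ACInputs(x, y, 300, 700), mode="point") == \
            ac_point_probability(ACInputs(x, y, 300, 700))
    with pytest.raises(ValueError):
        ac_p_value(ACInputs(0, 0, 100, 100), mode="bogus")


def test_two_sided_matches_exact_rational_tail_sum():
    for x, y, n1, n2 in [(2, 10, 100, 100), (0, 4, 100, 100), (10, 2, 500, 300),
                         (6, 6, 100, 400), (1, 0, 100, 100)]:
        got = ac_p_value(ACInputs(x, y, n1, n2))
        want = float(ac_two_sided_exact(x, y, n1, n2))
        assert got == pytest.approx(want, abs=1e-10), (x, y, n1, n2)


def test_two_sided_monotone_beyond_the_mode():
    """At equal library sizes the p-value decays as y moves away from x."""
    for x in [0, 5, 20]:
        ps_up = [ac_p_value(ACInputs(x, y, 10**5, 10**5))
                 for y in range(x + 1, x + 30)]
        assert all(b <= a + 1e-12 for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [ac_p_value(ACInputs(x, y, 10**5, 10**5))
                   for y in range(x, -1, -1)]
        assert all(b <= a + 1e-12 for a, b in zip(ps_down, ps_down[1:]))


@settings(derandomize=True, max_examples=150)
@given(x=st.integers(0, 60), y=st.integers(0, 60),
       n1=st.integers(100, 10**6), n2=st.integers(100, 10**6))
def test_two_sided_is_a_probability(x, y, n1, n2):
    p = ac_p_value(ACInputs(min(x, n1), min(y, n2), n1, n2))
    assert 0.0 < p <= 1.0


def test_ac_inputs_validation():
    with pytest.raises(ValueError):
        ACInputs(5, 0, 4, 100)   # x > N1
    with pytest.raises(ValueError):
        ACInputs(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ACInputs(0, 0, 0, 10)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_bh_fdr_hand_computed():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.42]) == [0.42]
    assert bh_fdr([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)
    assert bh_fdr([]) == []
    # classic staircase: adjusted = p * m / rank with step-up monotonicity
    assert bh_fdr([0.001, 0.008, 0.039, 0.041]) == pytest.approx(
        [0.004, 0.016, 0.041, 0.041])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_fdr_dominates_p_and_preserves_order(ps):
    qs = bh_fdr(ps)
    assert all(0 <= q <= 1 for q in qs)
    assert all(q >= p - 1e-15 for p, q in zip(ps, qs))
    # adjustment is monotone: sorting by p sorts q identically
    order = sorted(range(len(ps)), key=lambda i: ps[i])
    sorted_q = [qs[i] for i in order]
    assert all(b >= a - 1e-15 for a, b in zip(sorted_q, sorted_q[1:]))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def test_compare_group_union_and_floors(toy_pair):
    b, c = toy_pair
    results, summary = compare_group(ComparisonGroup("t", b, c))
    by_id = {r.circ_id: r for r in results}
    union = set(b.circ_ids()) | set(c.circ_ids())
    assert set(by_id) == union
    only_b = by_id["chr2:10|90"]
    assert only_b.c_expression == 0 and only_b.c_tpm == 0.001
    assert only_b.direction == "Down"
    only_c = by_id["chr2:500|900"]
    assert only_c.b_expression == 0 and only_c.b_tpm == 0.001
    assert only_c.direction == "Up"
    strong = by_id["chr1:300|400"]
    assert strong.direction == "Down" and strong.significant
    assert summary.n_sig >= 1
    assert summary.n_diff == len(union) - 1  # one circRNA has equal TPMs


def test_compare_group_self_comparison_is_null(toy_pair):
    b, _ = toy_pair
    results, summary = compare_group(ComparisonGroup("self", b, b))
    assert summary.n_sig == 0 and summary.n_diff == 0
    assert all(r.log2_ratio == 0.0 and not r.significant for r in results)


def test_compare_group_swap_antisymmetry(toy_pair):
    b, c = toy_pair
    fwd, _ = compare_group(ComparisonGroup("f", b, c))
    rev, _ = compare_group(ComparisonGroup("r", c, b))
    rev_by_id = {r.circ_id: r for r in rev}
    for r in fwd:
        s = rev_by_id[r.circ_id]
        assert s.p_value == r.p_value  # identical, not merely close
        assert s.fdr == r.fdr
        assert s.log2_ratio == pytest.approx(-r.log2_ratio, abs=1e-12)
        if r.b_tpm != r.c_tpm:
            assert {r.direction, s.direction} == {"Up", "Down"}


def test_compare_group_rejects_empty_samples():
    filled = make_table("a", {"chr1:1|2": 5})
    with pytest.raises(ValueError):
        compare_group(ComparisonGroup("g", filled, make_table("b", {})))


def test_comparison_summary_percentile():
    assert ComparisonSummary("1B & 1C", 6808, 111).percentile == 1.63
    assert ComparisonSummary("2B & 2C", 4652, 44).percentile == 0.95
    with pytest.raises(ValueError):
        ComparisonSummary("bad", 5, 6)


def test_results_tsv_roundtrip(tmp_path, toy_pair):
    b, c = toy_pair
    results, _ = compare_group(ComparisonGroup("g1", b, c))
    path = tmp_path / "results.tsv"
    write_results("g1", results, path)
    gid, back = read_results(path)
    assert gid == "g1"
    assert len(back) == len(results)
    for orig, rec in zip(results, back):
        assert rec.circ_id == orig.circ_id
        assert rec.p_value == orig.p_value
        assert rec.fdr == orig.fdr
        assert rec.log2_ratio == orig.log2_ratio
        assert rec.significant == orig.significant


def test_scatter_categories(toy_pair):
    b, c = toy_pair
    results, _ = compare_group(ComparisonGroup("g1", b, c))
    frame = scatter_data(results)
    by_id = frame.set_index("circ_id")["category"]
    assert by_id["chr1:300|400"] == "down_significant"
    assert by_id["chr1:100|200"] == "not_significant"
    up = [r for r in results if r.significant and r.direction == "Up"]
    for r in up:
        assert by_id[r.circ_id] == "up_significant"


def test_null_calibration_poisson_pairs():
    """Under equal true rates the two-sided test is conservative: the
    fraction of p < 0.05 stays at or below nominal (discrete statistic)."""
    rng = np.random.default_rng(2024)
    n, reps, n_lib = 400, 25, 10**5
    rates = rng.lognormal(0, 1.5, n)
    rates /= rates.sum()
    hits, total = 0, 0
    for _ in range(reps):
        xs = rng.poisson(rates * n_lib)
        ys = rng.poisson(rates * n_lib)
        for x, y in zip(xs, ys):
            p = ac_p_value(ACInputs(int(min(x, y)), int(max(x, y)), n_lib, n_lib))
            hits += p < 0.05
            total += 1
    assert 0.0 <= hits / total <= 0.08
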