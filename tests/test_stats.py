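import numpy as np
import pytest
from hypothesis import given, strategies as st

from sproutscreen.stats import (
    ChipMeasurement,
    PlateStats,
    classify_inhibition,
    control_cv,
    d10,
    integrity_concordance,
    plate_stats,
    replicate_spearman,
    robust_z,
    z_prime,
)


# ------------------------------------------------------------------------ d10

def test_d10_examples():
    assert d10(list(range(1, 21))) == pytest.approx(15.5)   # mean of 11..20
    assert d10([]) == 0.0
    assert d10([10.0, 20.0, 30.0]) == pytest.approx(20.0)   # fewer than ten


@given(st.lists(st.floats(min_value=0, max_value=1000), max_size=40))
def test_d10_matches_sort_oracle(ys):
    oracle = float(np.mean(sorted(ys)[-10:])) if ys else 0.0
    assert d10(ys) == pytest.approx(oracle)


# ----------------------------------------------------------------- plate stats

def test_plate_stats_hand_computation():
    ps = plate_stats([300.0, 350.0, 400.0, 350.0], "P01")
    assert ps.vehicle_median_d10 == pytest.approx(350.0)
    assert ps.vehicle_mad_d10 == pytest.approx(25.0)  # median{50,0,50,0}
    assert not ps.degenerate


def test_plate_stats_degenerate_flagged():
    ps = plate_stats([350.0, 350.0, 350.0], "P01")
    assert ps.vehicle_mad_d10 == 0.0
    assert ps.degenerate


def test_plate_stats_requires_two_vehicles():
    with pytest.raises(ValueError):
        plate_stats([350.0], "P01")


# ------------------------------------------------------------------- robust Z*

def test_robust_z_examples():
    ps = plate_stats([300.0, 350.0, 400.0, 350.0], "P01")
    assert robust_z(350.0, ps) == pytest.approx(0.0)
    assert robust_z(300.0, ps) == pytest.approx(-2.0)


def test_robust_z_scale_invariance_and_shift_equivariance():
    vals = [300.0, 350.0, 400.0, 330.0]
    ps = plate_stats(vals, "P")
    z = robust_z(310.0, ps)
    for c in (0.5, 3.0):
        ps_scaled = plate_stats([v * c for v in vals], "P")
        assert robust_z(310.0 * c, ps_scaled) == pytest.approx(z)
    ps_shift = plate_stats([v + 40 for v in vals], "P")
    assert robust_z(310.0 + 40, ps_shift) == pytest.approx(z)


def test_robust_z_mad_zero_raises():
    ps = plate_stats([350.0, 350.0], "P")
    with pytest.raises(ZeroDivisionError):
        robust_z(300.0, ps)


def test_robust_z_consistency_scaling():
    ps = plate_stats([300.0, 350.0, 400.0, 350.0], "P")
    assert robust_z(300.0, ps, consistency=True) == pytest.approx(-2.0 / 1.4826)


# -------------------------------------------------------------- classification

@pytest.mark.parametrize(
    "z,expected",
    [
        (-17.9, "high"),       # strong MEK-inhibitor-like score
        (-11.9, "moderate"),   # Raf-inhibitor-like score
        (-7.2, "mild"),
        (-5.9, "mild"),
        (-4.9, "mild"),
        (0.0, "none"),
        (-2.99, "none"),
        (-3.0, "mild"),        # boundary takes the more severe level
        (-9.0, "moderate"),
        (-15.0, "high"),
    ],
)
def test_classify_inhibition_mapping(z, expected):
    assert classify_inhibition(z) == expected


@given(st.floats(min_value=-50, max_value=10), st.floats(min_value=-50, max_value=10))
def test_classification_is_monotone(z1, z2):
    severity = {"none": 0, "mild": 1, "moderate": 2, "high": 3}
    lo, hi = min(z1, z2), max(z1, z2)
    assert severity[classify_inhibition(lo)] >= severity[classify_inhibition(hi)]


def test_classify_rejects_nonfinite():
    with pytest.raises(ValueError):
        classify_inhibition(float("nan"))


# ------------------------------------------------------------------- Z' factor

def test_z_prime_zero_spread_limit():
    assert z_prime([100.0, 100.0], [10.0, 10.0]) == pytest.approx(1.0)


def test_z_prime_default_calibration_arithmetic():
    rng = np.random.default_rng(0)
    a = rng.normal(352.1, 42.6, 4000)
    b = rng.normal(62.2, 12.4, 4000)
    expected = 1 - 3 * (42.6 + 12.4) / (352.1 - 62.2)  # ~0.431
    assert z_prime(a, b) == pytest.approx(expected, abs=0.02)


def test_z_prime_symmetric_and_bounded():
    rng = np.random.default_rng(1)
    a, b = rng.normal(300, 20, 50), rng.normal(100, 15, 50)
    assert z_prime(a, b) == pytest.approx(z_prime(b, a))
    assert z_prime(a, b) <= 1.0


def test_z_prime_grows_with_separation():
    rng = np.random.default_rng(2)
    noise_a, noise_b = rng.normal(0, 10, 40), rng.normal(0, 10, 40)
    zs = [z_prime(noise_a + 300, noise_b + 300 - sep) for sep in (80, 150, 280)]
    assert zs[0] < zs[1] < zs[2]


def test_z_prime_equal_means_undefined():
    with pytest.raises(ZeroDivisionError):
        z_prime([5.0, 5.0], [5.0, 5.0])


# ------------------------------------------------------------------ control CV

def test_control_cv_examples():
    assert control_cv([100.0, 100.0, 100.0]) == 0.0
    assert control_cv([90.0, 100.0, 110.0]) == pytest.approx(10.0)


def test_control_cv_zero_mean_rejected():
    with pytest.raises(ValueError):
        control_cv([0.0, 0.0])


# ---------------------------------------------------------- replicate Spearman

def test_spearman_perfect_and_inverted():
    pairs = [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0), (4.0, 4.0)]
    assert replicate_spearman(pairs) == pytest.approx(1.0)
    inv = [(x, -x) for x, _ in pairs]
    assert replicate_spearman(inv) == pytest.approx(-1.0)


def test_spearman_with_tie_matches_rank_pearson_oracle():
    pairs = [(1.0, 2.0), (2.0, 2.0), (3.0, 1.0), (4.0, 5.0), (5.0, 4.0)]
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])

    def ranks(v):  # average ranks, the brute-force way
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return r

    ra, rb = ranks(a), ranks(b)
    oracle = np.corrcoef(ra, rb)[0, 1]
    assert replicate_spearman(pairs) == pytest.approx(oracle)


def test_spearman_drops_excluded_replicates():
    pairs = [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0), (float("nan"), 4.0)]
    assert replicate_spearman(pairs) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        replicate_spearman([(1.0, 1.0), (2.0, 2.0)])


# ------------------------------------------------------- integrity concordance

def test_concordance_examples():
    assert integrity_concordance([(3, 3), (4, 4)]) == (100.0, 0.0, 0.0)
    same, adj, disc = integrity_concordance([(4, 3), (2, 2), (1, 3)])
    assert same == pytest.approx(100 / 3)
    assert adj == pytest.approx(100 / 3)
    assert disc == pytest.approx(100 / 3)


@given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=1, max_size=30))
def test_concordance_partitions_to_hundred(pairs):
    assert sum(integrity_concordance(pairs)) == pytest.approx(100.0)


# ------------------------------------------------------------- measurement type

def test_measurement_validation():
    with pytest.raises(ValueError):
        ChipMeasurement("c", "p", "sample", -1.0, 10, 4, 4)
    with pytest.raises(ValueError):
        ChipMeasurement("c", "p", "sample", 10.0, 10, 0, 4)
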