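"""LD statistics: closed-form examples, exhaustive oracle equivalence, and
pair-enumeration completeness."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldrepulsion import (
    compute_D,
    compute_Dprime,
    compute_r2,
    enumerate_matched_pairs,
    two_locus_counts,
)
from ldrepulsion.ld import (
    TwoLocusCounts,
    complete_repulsion_fraction,
    normalized_difference_in_D,
    summarize_decay,
)

from conftest import doubleton_sample, make_sample


# ------------------------- closed-form examples ------------------------- #
def test_counts_from_shared_doubletons():
    H = np.zeros((100, 2), dtype=np.uint8)
    H[:2, 0] = H[:2, 1] = 1
    c = two_locus_counts(H[:, 0], H[:, 1])
    assert (c.pA, c.pB, c.pAB) == (0.02, 0.02, 0.02)
    assert compute_D(c) == pytest.approx(0.0196)
    assert compute_r2(c) == pytest.approx(1.0)
    assert compute_Dprime(c) == pytest.approx(1.0)


def test_independent_loci_have_zero_D():
    c = TwoLocusCounts(pA=0.5, pB=0.5, pAB=0.25, n_chrom=100)
    assert compute_D(c) == 0.0
    assert compute_r2(c) == 0.0
    assert compute_Dprime(c) == 0.0


def test_maximal_coupling_at_half_frequency():
    c = TwoLocusCounts(pA=0.5, pB=0.5, pAB=0.5, n_chrom=100)
    assert compute_D(c) == pytest.approx(0.25)
    assert compute_Dprime(c) == pytest.approx(1.0)


def test_worked_negative_D_example():
    # constructed 100-chromosome sample: pA=0.3, pB=0.4, pAB=0.06
    H = np.zeros((100, 2), dtype=np.uint8)
    H[:30, 0] = 1
    H[:6, 1] = 1
    H[30:64, 1] = 1  # 6 + 34 = 40 derived at B, 6 shared
    c = two_locus_counts(H[:, 0], H[:, 1])
    assert (c.pA, c.pB, c.pAB) == (0.3, 0.4, 0.06)
    assert compute_r2(c) == pytest.approx(0.06**2 / (0.3 * 0.7 * 0.4 * 0.6))
    assert compute_Dprime(c) == pytest.approx(-0.06 / min(0.12, 0.42))
    assert compute_Dprime(c) == pytest.approx(-0.5)


def test_monomorphic_column_rejected():
    a = np.zeros(10, dtype=np.uint8)
    b = np.zeros(10, dtype=np.uint8)
    b[0] = 1
    with pytest.raises(ValueError):
        two_locus_counts(a, b)


@pytest.mark.parametrize("coupled,expected", [(True, 1.0), (False, -1.0)])
def test_doubleton_pairs_hit_dprime_bounds(coupled, expected):
    samp = doubleton_sample(coupled=coupled)
    df = enumerate_matched_pairs(samp)
    assert len(df) == 1
    assert df["Dprime"].iloc[0] == pytest.approx(expected)


# ---------------------- exhaustive oracle equivalence -------------------- #
def _oracle_stats(a, b):
    """Independent route: covariance-based D, Pearson r^2, and D' normalized
    by the most extreme feasible haplotype count given the margins."""
    n = len(a)
    D = float(np.cov(a, b, ddof=0)[0, 1])
    r2 = float(np.corrcoef(a, b)[0, 1]) ** 2
    cA, cB, cAB = int(a.sum()), int(b.sum()), int(np.sum(a & b))
    feasible = range(max(0, cA + cB - n), min(cA, cB) + 1)
    indep = cA * cB / n  # expected count under independence
    if cAB == indep:
        dprime = 0.0
    elif cAB > indep:
        dprime = D / ((max(feasible) - indep) / n)
    else:
        dprime = D / ((indep - min(feasible)) / n)
    return D, dprime, r2


def test_formulas_agree_with_oracle_on_all_small_configurations():
    """All two-site haplotype configurations with 8 chromosomes."""
    n = 8
    checked = 0
    for bits_a in range(1, 2**n - 1):
        a = np.array([(bits_a >> i) & 1 for i in range(n)], dtype=np.uint8)
        ca = a.sum()
        for bits_b in range(1, 2**n - 1):
            b = np.array([(bits_b >> i) & 1 for i in range(n)], dtype=np.uint8)
            c = two_locus_counts(a, b)
            D_o, Dp_o, r2_o = _oracle_stats(a, b)
            assert compute_D(c) == pytest.approx(D_o, abs=1e-12)
            assert compute_r2(c) == pytest.approx(r2_o, abs=1e-9)
            assert compute_Dprime(c) == pytest.approx(Dp_o, abs=1e-9)
            checked += 1
    assert checked == (2**n - 2) ** 2


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_invariants_on_random_columns(seed):
    """D' in [-1,1], r2 in [0,1], sign(D')=sign(D), exchange symmetry."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 60)) * 2
    a = (rng.random(n) < rng.uniform(0.05, 0.95)).astype(np.uint8)
    b = (rng.random(n) < rng.uniform(0.05, 0.95)).astype(np.uint8)
    if a.sum() in (0, n) or b.sum() in (0, n):
        return
    c = two_locus_counts(a, b)
    c_swapped = two_locus_counts(b, a)
    D, Dp, r2 = compute_D(c), compute_Dprime(c), compute_r2(c)
    assert -1 - 1e-12 <= Dp <= 1 + 1e-12
    assert -0.25 - 1e-12 <= D <= 0.25 + 1e-12
    assert 0 <= r2 <= 1 + 1e-12
    assert np.sign(Dp) == np.sign(D)
    assert compute_D(c_swapped) == pytest.approx(D)
    assert compute_Dprime(c_swapped) == pytest.approx(Dp)
    assert compute_r2(c_swapped) == pytest.approx(r2)


# ------------------------- pair enumeration ------------------------------ #
def _reference_pairs(sample, max_bp=10_000, allele_counts=None):
    """O(m^2) reference enumerator."""
    sites = sample.sites
    out = []
    m = len(sites)
    for i in range(m):
        for k in range(i + 1, m):
            si, sk = sites.iloc[i], sites.iloc[k]
            if si["annotation"] != sk["annotation"]:
                continue
            if si["annotation"] not in ("NS", "S"):
                continue
            if si["derived_count"] != sk["derived_count"]:
                continue
            if allele_counts and si["derived_count"] not in allele_counts:
                continue
            d = abs(int(sk["position"]) - int(si["position"]))
            if d == 0 or d > max_bp:
                continue
            lo, hi = sorted([int(si["position"]), int(sk["position"])])
            out.append((lo, hi, int(si["derived_count"]), si["annotation"]))
    return sorted(out)


def test_enumeration_matches_reference_on_simulated_sample(small_dfe_sample):
    got = enumerate_matched_pairs(small_dfe_sample, allele_counts=range(1, 6))
    expected = _reference_pairs(small_dfe_sample, allele_counts=set(range(1, 6)))
    got_keys = sorted(
        zip(got["pos_a"], got["pos_b"], got["allele_count"], got["annotation"])
    )
    assert got_keys == expected


def test_enumeration_distance_threshold_inclusive():
    H = np.zeros((100, 3), dtype=np.uint8)
    H[:2, :] = 1
    samp = make_sample(H, [100, 10_100, 20_301], ["NS"] * 3)
    df = enumerate_matched_pairs(samp)
    pairs = set(zip(df["pos_a"], df["pos_b"]))
    assert (100, 10_100) in pairs  # exactly 10,000 apart: included
    assert (10_100, 20_301) not in pairs  # 10,201 apart: excluded


def test_enumeration_requires_identical_count_and_annotation():
    H = np.zeros((100, 4), dtype=np.uint8)
    H[:2, 0] = 1  # NS doubleton
    H[:3, 1] = 1  # NS tripleton
    H[:2, 2] = 1  # S doubleton
    H[:2, 3] = 1  # NS doubleton
    samp = make_sample(H, [100, 200, 300, 400], ["NS", "NS", "S", "NS"])
    df = enumerate_matched_pairs(samp)
    assert len(df) == 1
    assert (df["pos_a"].iloc[0], df["pos_b"].iloc[0]) == (100, 400)


# ------------------------- decay summaries ------------------------------- #
def test_decay_single_and_two_record_bins():
    rec = pd.DataFrame(
        {"bp_distance": [500.0, 700.0], "Dprime": [1.0, -1.0]}
    )
    one = summarize_decay(rec.iloc[:1], stat="Dprime", bins=[0, 1500])
    assert one["mean"].iloc[0] == 1.0
    assert one["se"].iloc[0] == 0.0  # single-pair bin: SE reported as 0
    assert one["n_pairs"].iloc[0] == 1
    two = summarize_decay(rec, stat="Dprime", bins=[0, 1500])
    assert two["mean"].iloc[0] == 0.0
    assert two["se"].iloc[0] == pytest.approx(1.0)  # sd/sqrt(n) = sqrt(2)/sqrt(2)


def test_decay_empty_bin_reported():
    rec = pd.DataFrame({"bp_distance": [500.0], "Dprime": [1.0]})
    out = summarize_decay(rec, stat="Dprime", bins=[0, 1000, 2000])
    assert out["n_pairs"].tolist() == [1, 0]
    assert np.isnan(out["mean"].iloc[1])


def test_normalized_difference_examples():
    ns = pd.DataFrame({"bp_distance": [100.0] * 4, "D": [0.01] * 4})
    s = pd.DataFrame({"bp_distance": [100.0] * 4, "D": [0.01] * 4})
    out = normalized_difference_in_D(ns, s, n_quantile_bins=1)
    assert out["normalized_difference"].iloc[0] == pytest.approx(0.0)
    ns["D"] = 0.005  # NS mean is half the S mean
    out = normalized_difference_in_D(ns, s, n_quantile_bins=1)
    assert out["normalized_difference"].iloc[0] == pytest.approx(-0.5)
    s["D"] = 0.0  # undefined when mean D_S = 0
    out = normalized_difference_in_D(ns, s, n_quantile_bins=1)
    assert np.isnan(out["normalized_difference"].iloc[0])


def test_complete_repulsion_fraction_bounds():
    rec = pd.DataFrame({"Dprime": [-1.0, -1.0, -1.0]})
    assert complete_repulsion_fraction(rec) == 1.0
    rec = pd.DataFrame({"Dprime": [0.5, 1.0, -0.999999999999]})
    assert complete_repulsion_fraction(rec) == pytest.approx(1 / 3)
    rec = pd.DataFrame({"Dprime": [0.5, 1.0]})
    assert complete_repulsion_fraction(rec) == 0.0
    with pytest.raises(ValueError):
        complete_repulsion_fraction(pd.DataFrame({"Dprime": []}))
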