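"""Diversity statistics against brute-force and direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selsweep.diversity import (
    WindowScheme, ld_decay, ld_r2, per_site_pi, population_summary,
    site_pi, tajima_constants, tajimas_d, windowed_pi,
)
from selsweep.io import MISSING, PopulationMap

from conftest import make_matrix


# ---------------------------------------------------------------------------
# oracles


def brute_force_site_pi(dosages):
    """Mean pairwise haplotype difference by explicit pair enumeration.

    Each called diploid contributes two haplotypes (dosage 1 -> one ref +
    one alt haplotype; the unordered expansion is exact for the biallelic
    count statistic).
    """
    haps = []
    for d in dosages:
        if d == MISSING:
            continue
        haps.extend({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(d)])
    n = len(haps)
    if n < 2:
        return float("nan")
    diffs = sum(
        haps[i] != haps[j] for i in range(n) for j in range(i + 1, n)
    )
    return diffs / (n * (n - 1) / 2)


def brute_force_windowed_pi(matrix, idx, scheme, lengths):
    """Loop-based recomputation of per-window per-bp diversity."""
    rows = []
    for chrom in sorted(lengths):
        start = 0
        while start < lengths[chrom]:
            end = min(start + scheme.size, lengths[chrom])
            total = 0.0
            for i in range(matrix.n_sites):
                if (matrix.chrom[i] == chrom
                        and start <= matrix.pos[i] - 1 < end):
                    v = brute_force_site_pi(matrix.dosage[i, idx])
                    if np.isfinite(v):
                        total += v
            rows.append((chrom, start, end, total / (end - start)))
            start += scheme.step
    return rows


def direct_tajima_d(S, pi, n):
    """Second, independent implementation of the D normalization."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# site pi


@pytest.mark.parametrize("k,n,expected", [
    (0, 4, 0.0),          # monomorphic
    (2, 4, 2 / 3),        # {0/0, 1/1}: 4 of 6 haplotype pairs differ
    (1, 2, 1.0),          # single het individual
    (4, 4, 0.0),          # fixed alt
])
def test_site_pi_examples(k, n, expected):
    assert site_pi(k, n) == pytest.approx(expected, abs=1e-15)


def test_site_pi_matches_pair_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(50):
        dos = rng.integers(-1, 3, size=8)
        called = dos[dos != MISSING]
        n = 2 * len(called)
        if n < 2:
            continue
        k = int(called.sum())
        assert site_pi(k, n) == pytest.approx(
            brute_force_site_pi(dos), abs=1e-12
        )


def test_site_pi_undefined_below_two_alleles():
    assert np.isnan(site_pi(0, 0))


@settings(deadline=None, derandomize=True)
@given(n=st.integers(2, 200), k=st.data())
def test_site_pi_bounds_and_allele_symmetry(n, k):
    kk = k.draw(st.integers(0, n))
    v = site_pi(kk, n)
    assert 0.0 <= v <= 1.0 + 1e-12
    assert v == pytest.approx(site_pi(n - kk, n), abs=1e-15)


@settings(deadline=None, derandomize=True)
@given(size=st.integers(1, 10_000), step=st.data(), length=st.integers(1, 50_000))
def test_window_enumeration_tiles_chromosome(size, step, length):
    s = step.draw(st.integers(1, size))
    ws = WindowScheme(size, s).windows(length)
    assert ws[0][0] == 0
    assert all(b - a == s for (a, _), (b, _) in zip(ws, ws[1:]))
    assert all(0 <= a < b <= length for a, b in ws)
    assert ws[-1][0] + s >= length  # no further window would start


# ---------------------------------------------------------------------------
# windows


def test_window_enumeration_policy():
    # 30 kb chromosome, 20 kb / 5 kb -> 6 windows starting 0..25000
    ws = WindowScheme(20_000, 5_000).windows(30_000)
    assert [w[0] for w in ws] == [0, 5_000, 10_000, 15_000, 20_000, 25_000]
    assert ws[0] == (0, 20_000)
    assert ws[-1] == (25_000, 30_000)  # truncated at chromosome end


def test_window_scheme_rejects_bad_step():
    with pytest.raises(ValueError):
        WindowScheme(10_000, 20_000)


def test_windowed_pi_empty_window_is_zero():
    m = make_matrix([[0, 1], [1, 2]], pos=[5, 8])
    df = windowed_pi(m, {"all": np.arange(2)}, WindowScheme(10, 10),
                     {"chr1": 30})
    far = df[df.start == 20].iloc[0]
    assert far.n_sites == 0 and far.pi == 0.0


def test_windowed_pi_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(42)
    scheme = WindowScheme(200, 100)
    lengths = {"chr1": 1_000}
    for _ in range(10):
        dos = rng.integers(-1, 3, size=(50, 20))
        pos = np.sort(rng.choice(1_000, size=50, replace=False)) + 1
        m = make_matrix(dos, pos=pos)
        idx = np.arange(20)
        got = windowed_pi(m, {"all": idx}, scheme, lengths)
        expected = brute_force_windowed_pi(m, idx, scheme, lengths)
        assert len(got) == len(expected)
        for row, (chrom, s, e, pi) in zip(got.itertuples(), expected):
            assert row.chrom == chrom and row.start == s and row.end == e
            assert row.pi == pytest.approx(pi, abs=1e-12)


def test_windowed_pi_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    dos = rng.integers(0, 3, size=(30, 10))
    pos = np.sort(rng.choice(500, size=30, replace=False)) + 1
    m = make_matrix(dos, pos=pos)
    scheme = WindowScheme(100, 50)
    a = windowed_pi(m, {"g": np.arange(10)}, scheme, {"chr1": 500})
    perm = rng.permutation(10)
    b = windowed_pi(m, {"g": perm}, scheme, {"chr1": 500})
    assert np.allclose(a.pi, b.pi)


def test_statistic_invariant_to_input_record_shuffle():
    rng = np.random.default_rng(9)
    dos = rng.integers(0, 3, size=(40, 6))
    pos = np.sort(rng.choice(2_000, size=40, replace=False)) + 1
    m = make_matrix(dos, pos=pos)
    order = rng.permutation(40)
    m_shuf = make_matrix(dos[order], pos=pos[order])  # re-sorts internally
    a = windowed_pi(m, {"g": np.arange(6)}, WindowScheme(500, 250),
                    {"chr1": 2_000})
    b = windowed_pi(m_shuf, {"g": np.arange(6)}, WindowScheme(500, 250),
                    {"chr1": 2_000})
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Tajima's D


def test_tajima_a1_for_n4():
    assert tajima_constants(4).a1 == pytest.approx(1 + 0.5 + 1 / 3, abs=1e-12)


def test_tajima_d_zero_when_pi_equals_watterson():
    n, S = 10, 5
    a1 = tajima_constants(n).a1
    assert tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)


def test_tajima_d_matches_direct_formula():
    assert tajimas_d(5, 1.8, 10) == pytest.approx(
        direct_tajima_d(5, 1.8, 10), abs=1e-12
    )


def test_tajima_d_undefined_without_segregating_sites():
    assert np.isnan(tajimas_d(0, 0.0, 10))


def test_neutral_coalescent_tajima_d_near_zero():
    from selsweep.diversity import tajimas_d_from_dosage  # noqa: F401
    from selsweep.simulate import simulate_neutral_coalescent

    ds = []
    n = 20
    for rep in range(100):
        G = simulate_neutral_coalescent(n, 5.0, seed=500 + rep)
        k = G.sum(axis=1)
        S = len(k)
        pi = float(np.sum(2.0 * k * (n - k) / (n * (n - 1))))
        d = tajimas_d(S, pi, n)
        if np.isfinite(d):
            ds.append(d)
    assert -0.3 <= np.mean(ds) <= 0.3


# ---------------------------------------------------------------------------
# population summary


def test_population_summary_all_het_site():
    # one site, 4 samples all 0/1
    m = make_matrix([[1, 1, 1, 1]])
    pm = PopulationMap({f"s{i}": "p" for i in range(4)})
    row = population_summary(m, pm).iloc[0]
    assert row.obs_het == pytest.approx(1.0)
    assert row.exp_het == pytest.approx((8 / 7) * 0.5, abs=1e-12)
    assert row.fis == pytest.approx(1 - 1 / ((8 / 7) * 0.5), abs=1e-12)
    assert row.num_indv == 4 and row.num_sam == 4


def test_population_summary_no_variant_sites_warns():
    m = make_matrix([[0, 0, 0]])
    pm = PopulationMap({f"s{i}": "p" for i in range(3)})
    with pytest.warns(UserWarning):
        row = population_summary(m, pm).iloc[0]
    assert np.isnan(row.obs_het)


def test_population_summary_num_indv_counts_called_only():
    m = make_matrix([[1, MISSING, 1, 0], [1, 1, MISSING, MISSING]])
    pm = PopulationMap({f"s{i}": "p" for i in range(4)})
    row = population_summary(m, pm).iloc[0]
    assert row.num_indv == pytest.approx((3 + 2) / 2)


def test_exp_het_exceeds_obs_het_under_inbreeding(demo):
    """Heterozygote deficit (positive Fis) on island-model data: pooled
    sampling across HWE subgroups plus drift yields Exp Het > Obs Het."""
    summ = population_summary(demo["matrix"], demo["popmap"])
    assert (summ.exp_het > summ.obs_het).all()
    assert (summ.fis > 0).all()


# ---------------------------------------------------------------------------
# LD


def test_ld_r2_identical_and_repulsion_vectors():
    a = np.array([0, 1, 2, 1, 0, 2], dtype=np.int8)
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, (2 - a).astype(np.int8)) == pytest.approx(1.0)


def test_ld_r2_zero_variance_is_nan():
    a = np.array([1, 1, 1, 1], dtype=np.int8)
    b = np.array([0, 1, 2, 0], dtype=np.int8)
    assert np.isnan(ld_r2(a, b))


def test_ld_decay_under_independence_hits_bias_floor():
    """Unlinked sites: mean r^2 ~ 1/(n-1), far below meaningful LD."""
    rng = np.random.default_rng(1)
    n = 41
    dos = rng.binomial(2, 0.5, size=(120, n)).astype(np.int8)
    pos = np.sort(rng.choice(50_000, size=120, replace=False)) + 1
    m = make_matrix(dos, pos=pos)
    df = ld_decay(m, max_dist=50_000, bin_size=50_000)
    assert df.n_pairs.sum() >= 1_000
    assert df.mean_r2.iloc[0] == pytest.approx(1 / (n - 1), rel=0.3)
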