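import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admixscan.sweep import (
    NslScan,
    normalize_nsl,
    nsl_scan,
    overlap_report,
    site_sl,
    smooth_and_call,
)
from admixscan.ciwi import IntrogressedRegion

from conftest import make_hap_panel


# ---------------------------------------------------------------- oracles


def sl_oracle(haps, focal):
    """Direct pair enumeration with explicit interval extension."""
    haps = np.asarray(haps)
    n, m = haps.shape
    if n < 2:
        return float("nan"), False
    lengths, trunc = [], False
    for i in range(n):
        for j in range(i + 1, n):
            if haps[i, focal] != haps[j, focal]:
                lengths.append(0)
                continue
            lo = focal
            while lo - 1 >= 0 and haps[i, lo - 1] == haps[j, lo - 1]:
                lo -= 1
            hi = focal
            while hi + 1 < m and haps[i, hi + 1] == haps[j, hi + 1]:
                hi += 1
            lengths.append(hi - lo + 1)
            if lo == 0 or hi == m - 1:
                trunc = True
    return float(np.mean(lengths)), trunc


def nsl_oracle(haps, ancestral, maf_min=0.05):
    """Brute-force raw nSL per site: SL by pair enumeration per allele class."""
    haps = np.asarray(haps)
    n, m = haps.shape
    out = np.full(m, np.nan)
    for s in range(m):
        anc = ancestral[s]
        if anc not in (0, 1):
            continue
        der = 1 - anc
        der_freq = (haps[:, s] == der).mean()
        if not maf_min <= der_freq <= 1 - maf_min:
            continue
        anc_rows = haps[haps[:, s] == anc]
        der_rows = haps[haps[:, s] == der]
        if len(anc_rows) < 2 or len(der_rows) < 2:
            continue
        sl_a, _ = sl_oracle(anc_rows, s)
        sl_d, _ = sl_oracle(der_rows, s)
        if sl_a > 0 and sl_d > 0:
            out[s] = math.log(sl_a / sl_d)
    return out


panels = st.integers(2, 8).flatmap(
    lambda n: st.integers(5, 30).flatmap(
        lambda m: st.lists(
            st.lists(st.integers(0, 1), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
)


# ---------------------------------------------------------------- site_sl


class TestSiteSL:
    def test_identical_haplotypes_full_span_truncated(self):
        haps = np.tile(np.array([0, 1, 0, 0, 1, 1, 0, 1, 0, 1, 1]), (2, 1))
        sl, trunc = site_sl(haps, focal=5)
        assert sl == 11.0 and trunc

    def test_mismatch_adjacent_both_sides(self):
        a = np.array([0, 1, 0, 1, 0])
        b = np.array([0, 0, 0, 0, 0])
        sl, trunc = site_sl(np.vstack([a, b]), focal=2)
        assert sl == 1.0 and not trunc

    def test_single_haplotype_sentinel(self):
        sl, _ = site_sl(np.zeros((1, 5), dtype=np.int8), focal=2)
        assert math.isnan(sl)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(panels, st.data())
    def test_matches_bruteforce_oracle(self, rows, data):
        haps = np.array(rows, dtype=np.int8)
        focal = data.draw(st.integers(0, haps.shape[1] - 1))
        sl, trunc = site_sl(haps, focal)
        sl_ref, trunc_ref = sl_oracle(haps, focal)
        assert sl == pytest.approx(sl_ref, abs=0)
        assert trunc == trunc_ref


# ---------------------------------------------------------------- raw nSL


class TestRawNsl:
    def test_symmetric_classes_give_zero(self):
        # ancestral and derived carriers with mirror-image internal structure
        haps = np.array(
            [
                [0, 0, 0, 1, 1],
                [1, 1, 0, 0, 0],
                [0, 0, 1, 1, 1],
                [1, 1, 1, 0, 0],
            ],
            dtype=np.int8,
        )
        panel = make_hap_panel(haps, aa=0)
        raw = nsl_scan(panel)["raw_nsl"].to_numpy()
        assert raw[2] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_derived_sweep_negative(self):
        rng = np.random.default_rng(0)
        m = 21
        derived = np.tile(rng.integers(0, 2, m), (4, 1))  # identical carriers
        derived[:, 10] = 1
        ancestral = rng.integers(0, 2, size=(4, m))
        ancestral[:, 10] = 0
        panel = make_hap_panel(np.vstack([derived, ancestral]).astype(np.int8), aa=0)
        raw = nsl_scan(panel)["raw_nsl"].to_numpy()
        assert raw[10] < 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(panels.filter(lambda rows: len(rows) % 2 == 0))
    def test_matches_bruteforce_oracle(self, rows):
        haps = np.array(rows, dtype=np.int8)
        panel = make_hap_panel(haps, aa=0)
        got = nsl_scan(panel)["raw_nsl"].to_numpy()
        want = nsl_oracle(haps, np.zeros(haps.shape[1], dtype=int))
        np.testing.assert_array_equal(np.isnan(got), np.isnan(want))
        np.testing.assert_allclose(got[~np.isnan(got)], want[~np.isnan(want)], rtol=0, atol=1e-12)

    def test_polarity_flip_negates_exactly(self, default_study):
        panel = default_study.target
        raw0 = nsl_scan(panel)["raw_nsl"].to_numpy()
        flipped = make_hap_panel(
            panel.alleles, pops=list(panel.pop_labels), aa=np.ones(panel.n_markers, dtype=np.int8)
        )
        raw1 = nsl_scan(flipped)["raw_nsl"].to_numpy()
        both = np.isfinite(raw0) & np.isfinite(raw1)
        np.testing.assert_allclose(raw1[both], -raw0[both], atol=1e-12)
        # a site scanned under one polarity is scanned under the other
        np.testing.assert_array_equal(np.isfinite(raw0), np.isfinite(raw1))

    def test_no_ancestral_information_rejected(self):
        panel = make_hap_panel(np.eye(4, 8, dtype=np.int8))
        with pytest.raises(ValueError, match="ancestral"):
            nsl_scan(panel)


# ---------------------------------------------------------------- normalisation


class TestNormalize:
    def test_single_bin_z_identity(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=200)
        freq = np.full(200, 0.42)
        z = normalize_nsl(raw, freq)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_two_bins_centred_separately(self):
        rng = np.random.default_rng(1)
        raw = np.concatenate([rng.normal(5, 1, 100), rng.normal(-3, 2, 100)])
        freq = np.concatenate([np.full(100, 0.1), np.full(100, 0.9)])
        z = normalize_nsl(raw, freq)
        assert z[:100].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[100:].mean() == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=500)
        freq = rng.uniform(0.05, 0.95, 500)
        z1 = normalize_nsl(raw, freq)
        z2 = normalize_nsl(z1, freq)
        np.testing.assert_allclose(z2, z1, atol=1e-9)

    def test_underfull_bins_merged(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=25)
        freq = np.concatenate([np.full(20, 0.3), np.full(5, 0.7)])  # 5 < 10 merged
        z = normalize_nsl(raw, freq)
        assert np.isfinite(z).all()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_bin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_nsl(np.full(50, 1.23), np.full(50, 0.5))


# ---------------------------------------------------------------- smoothing


class TestSmoothAndCall:
    def test_constant_zero_curve_no_intervals(self):
        x = np.arange(100) * 1000.0
        smoothed, intervals = smooth_and_call(x, np.zeros(100))
        np.testing.assert_allclose(smoothed, 0.0)
        assert intervals == []

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10"):
            smooth_and_call(np.arange(5) * 1000.0, np.ones(5))

    def test_region_without_sweep_reported_with_zero_fraction(self):
        region = IntrogressedRegion("1", 100, 200, [0], 0.9, 9)
        rep = overlap_report([region], [])
        assert len(rep) == 1 and rep.iloc[0]["overlap_fraction"] == 0.0

    def test_injected_sweep_detected_end_to_end(self, sweep_study):
        res = NslScan(sweep_study.panel, pop="TGT").fit().smooth()
        t = res.table.dropna(subset=["smoothed"])
        peak = t.loc[t["smoothed"].abs().idxmax()]
        assert 49.6e6 <= peak["pos_bp"] <= 50.8e6
        region = IntrogressedRegion("1", 49_600_000, 50_800_000, [], 0.9, 9)
        rep = res.overlap_report([region])
        assert rep.iloc[0]["overlap_fraction"] >= 0.5
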