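"""Sweep-spectrum model against Monte-Carlo oracles and scan behaviour."""

import numpy as np
import pandas as pd
import pytest

from sweepscape.clr import (
    SFSpectrum, ScanResult, clr_scan, empirical_sfs, fold_vector,
    project_sfs, sweep_site_spectrum,
)
from sweepscape.simulate import simulate_neutral_panel
from sweepscape.types import MISSING

from conftest import make_matrix, make_panel


def neutral_spectrum(n, folded=False):
    counts = 1.0 / np.arange(1, n)
    if folded:
        sym = 0.5 * (counts + counts[::-1])
        counts = sym
    return SFSpectrum(n_background=n, counts=counts, folded=folded)


class TestEmpiricalSFS:
    def test_tally(self):
        # alt counts 1, 1, 3 at n=6 -> c_1 = 2, c_3 = 1
        gm = make_matrix([[1, 0, 0], [0, 0, 1], [1, 1, 1]])
        panel = make_panel(gm.sample_ids, ["c1"] * 3)
        spec = empirical_sfs(gm, panel, "c1", folded=False)
        assert spec.n_background == 6
        np.testing.assert_allclose(spec.counts, [2, 0, 1, 0, 0])

    def test_folding_maps_high_to_low(self):
        gm = make_matrix([[2, 2, 1]])  # count 5 of 6
        panel = make_panel(gm.sample_ids, ["c1"] * 3)
        spec = empirical_sfs(gm, panel, "c1", folded=True)
        # symmetrised: half mass at class 1, half at class 5
        assert spec.counts[0] == pytest.approx(0.5)
        assert spec.counts[4] == pytest.approx(0.5)

    def test_fully_called_projection_identity(self):
        gm, panel, _ = simulate_neutral_panel(1, 6, 30_000, 0.01, seed=0)
        spec = empirical_sfs(gm, panel, "cohort1", folded=False)
        x, n = gm.alt_counts()
        seg = (x > 0) & (x < n)
        expect = np.bincount(x[seg], minlength=13)[1:12]
        np.testing.assert_allclose(spec.counts, expect)

    def test_no_segregating_errors(self):
        gm = make_matrix([[0, 0, 0]])
        panel = make_panel(gm.sample_ids, ["c1"] * 3)
        with pytest.raises(ValueError):
            empirical_sfs(gm, panel, "c1")

    def test_missing_projected_down(self):
        gm = make_matrix([[1, 1, MISSING], [0, 1, 0]])
        panel = make_panel(gm.sample_ids, ["c1"] * 3)
        spec = empirical_sfs(gm, panel, "c1", folded=False)
        assert spec.n_background == 4
        # site 1: x=2 of n=4 (identity); site 2: x=1 of n=6 projected to 4
        assert spec.counts.sum() < 2.0  # projection loses monomorphic mass
        assert spec.counts[1] == pytest.approx(1.0)


class TestProjection:
    def test_identity_at_full_size(self):
        spec = neutral_spectrum(10)
        q = project_sfs(spec, 10)
        np.testing.assert_allclose(q[1:10], spec.probs(), atol=1e-12)
        assert q[0] == pytest.approx(0.0, abs=1e-12)
        assert q[10] == pytest.approx(0.0, abs=1e-12)

    def test_m_one_gives_mean_frequency(self):
        spec = neutral_spectrum(12)
        q = project_sfs(spec, 1)
        p = spec.probs()
        k = np.arange(1, 12)
        assert q[1] == pytest.approx(float((p * k / 12).sum()))

    def test_sums_to_one(self):
        spec = neutral_spectrum(20)
        for m in (1, 5, 19, 20):
            assert project_sfs(spec, m).sum() == pytest.approx(1.0)

    def test_against_sampling_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.uniform(0.5, 3.0, size=14)
        spec = SFSpectrum(n_background=15, counts=counts)
        m = 7
        q = project_sfs(spec, m)
        # Monte-Carlo: draw class k, then hypergeometric subsample
        draws = 200_000
        ks = rng.choice(np.arange(1, 15), size=draws, p=spec.probs())
        js = rng.hypergeometric(ks, 15 - ks, m)
        mc = np.bincount(js, minlength=m + 1) / draws
        assert np.abs(q - mc).sum() / 2 < 0.005

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            project_sfs(neutral_spectrum(10), 11)


def star_like_oracle(spec, n, p_e, draws, seed=0):
    """Independent Monte-Carlo sampler of the star-like sweep genealogy."""
    rng = np.random.default_rng(seed)
    p = spec.probs()
    nb = spec.n_background
    out = np.zeros(n + 1)
    got = 0
    while got < draws:
        e = rng.binomial(n, p_e)
        if e == n:
            k = rng.choice(np.arange(1, nb), p=p)
            b = rng.hypergeometric(k, nb - k, n)
        else:
            k = rng.choice(np.arange(1, nb), p=p)
            j = rng.hypergeometric(k, nb - k, e + 1)
            if rng.random() < j / (e + 1):
                b = j - 1 + n - e
            else:
                b = j
        out[b] += 1
        got += 1
    poly = out[1:n]
    return poly / poly.sum()


class TestSweepSpectrum:
    def test_neutral_limit_exact(self):
        spec = neutral_spectrum(20)
        got = sweep_site_spectrum(spec, 12, 1.0)
        q = project_sfs(spec, 12)
        expect = q[1:12] / q[1:12].sum()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_matches_monte_carlo_oracle(self):
        spec = neutral_spectrum(25)
        n, p_e = 10, 0.3
        model = sweep_site_spectrum(spec, n, p_e)
        mc = star_like_oracle(spec, n, p_e, draws=100_000, seed=2)
        tv = 0.5 * np.abs(model - mc).sum()
        assert tv < 0.01

    def test_monotone_distortion_in_pe(self):
        spec = neutral_spectrum(30)
        n = 12
        base = sweep_site_spectrum(spec, n, 1.0)
        tvs = []
        for pe in (0.05, 0.2, 0.4, 0.6, 0.8, 1.0):
            v = sweep_site_spectrum(spec, n, pe)
            tvs.append(0.5 * np.abs(v - base).sum())
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))

    def test_folding_commutes(self):
        spec = neutral_spectrum(20)
        n, pe = 10, 0.4
        unfolded = sweep_site_spectrum(spec, n, pe)
        folded_after = fold_vector(unfolded)
        folded_after = folded_after / folded_after.sum()
        sym = neutral_spectrum(20, folded=True)
        folded_model = fold_vector(sweep_site_spectrum(sym, n, pe))
        folded_model = folded_model / folded_model.sum()
        # folding the symmetric model equals symmetrising the folded one
        np.testing.assert_allclose(
            folded_after, fold_vector(
                sweep_site_spectrum(
                    SFSpectrum(20, 0.5 * (spec.counts + spec.counts[::-1])),
                    n, pe))
            / fold_vector(sweep_site_spectrum(
                SFSpectrum(20, 0.5 * (spec.counts + spec.counts[::-1])),
                n, pe)).sum(),
            atol=1e-9)
        np.testing.assert_allclose(folded_model,
                                   fold_vector(sweep_site_spectrum(sym, n, pe))
                                   / fold_vector(
                                       sweep_site_spectrum(sym, n, pe)).sum(),
                                   atol=1e-12)

    def test_zero_pe_fully_swept(self):
        spec = neutral_spectrum(20)
        with pytest.raises(FloatingPointError, match="fully swept"):
            sweep_site_spectrum(spec, 10, 0.0)

    def test_invalid_inputs(self):
        spec = neutral_spectrum(10)
        with pytest.raises(ValueError):
            sweep_site_spectrum(spec, 10, 1.5)
        with pytest.raises(ValueError):
            sweep_site_spectrum(spec, 1, 0.5)


class TestScan:
    def _toy(self, seed=0, S=300):
        rng = np.random.default_rng(seed)
        n_samp = 10
        x = rng.integers(1, 2 * n_samp, size=S)
        # construct dosages hitting those counts exactly
        d = np.zeros((S, n_samp), dtype=np.int8)
        for i, xi in enumerate(x):
            alleles = np.zeros(2 * n_samp, dtype=np.int8)
            alleles[rng.choice(2 * n_samp, size=xi, replace=False)] = 1
            d[i] = alleles[0::2] + alleles[1::2]
        gm = make_matrix(d, pos=np.sort(rng.choice(
            np.arange(1, 100_000), size=S, replace=False)))
        panel = make_panel(gm.sample_ids, ["c1"] * n_samp)
        return gm, panel

    def test_clr_nonnegative_and_site_order_invariant(self):
        gm, panel = self._toy()
        spec = empirical_sfs(gm, panel, "c1", folded=True)
        scan = clr_scan(gm, panel, "c1", spec, grid_spacing=5000)
        assert (scan.clr >= 0).all()

    def test_neutral_input_gives_low_clr(self):
        # dosages drawn straight from the background: no sweep signal
        gm, panel = self._toy(seed=3)
        spec = empirical_sfs(gm, panel, "c1", folded=True)
        scan = clr_scan(gm, panel, "c1", spec, grid_spacing=5000)
        assert np.nanmax(scan.clr) < 10

    def test_empty_lambda_grid_errors(self):
        gm, panel = self._toy(seed=4, S=50)
        spec = empirical_sfs(gm, panel, "c1", folded=True)
        with pytest.raises(ValueError, match="Lambda"):
            clr_scan(gm, panel, "c1", spec, lambda_grid=np.array([]))

    def test_grid_positions_strictly_increasing(self):
        gm, panel = self._toy(seed=5)
        spec = empirical_sfs(gm, panel, "c1", folded=True)
        scan = clr_scan(gm, panel, "c1", spec, grid_spacing=2000)
        assert np.all(np.diff(scan.positions) > 0)


def test_scan_result_rejects_negative_clr():
    with pytest.raises(ValueError):
        ScanResult(chrom=np.array(["1"], dtype=object), positions=[1],
                   clr=[-0.5], lambda_hat=[np.nan])
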