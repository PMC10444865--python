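"""Forward optical model: defaults, Born physics, Sigma statistics."""

import numpy as np
import pytest

from cspws import dmap
from cspws.instrument import (
    GridSpec,
    SpectralCube,
    compute_sigma_image,
    density_to_ri,
    interior_mask,
    make_default_instrument,
    make_reference_cube,
    reference_normalize,
    sample_chromatin_density,
    simulate_interference_cube,
)

from conftest import simulate_cell_sigma


def test_default_instrument_matches_published_acquisition():
    cfg = make_default_instrument()
    assert cfg.na_illumination == 0.6
    assert cfg.na_collection == 0.8
    assert cfg.wavelength_min_nm == 450 and cfg.wavelength_max_nm == 700
    assert cfg.transverse_coherence_nm == 458
    assert cfg.depth_of_field_nm == 2874
    lam = cfg.wavelengths_nm
    assert lam[0] == 450 and np.all(np.diff(lam) == 3)


def test_instrument_invariants_enforced():
    with pytest.raises(ValueError):
        make_default_instrument().__class__(na_illumination=0.9, na_collection=0.8)
    with pytest.raises(ValueError):
        make_default_instrument().__class__(wavelength_min_nm=700, wavelength_max_nm=450)


class TestDensityToRi:
    def test_zero_density_gives_media_index(self, instrument, small_grid):
        model = dmap.AcfModel(d_b=2.0, amplitude=0.0)
        real = sample_chromatin_density(model, small_grid, seed=0,
                                        mean_crowding_g_ml=0.0)
        assert np.allclose(density_to_ri(real, instrument), instrument.n_media)

    def test_unit_density_arithmetic(self, instrument, small_grid):
        # rho = 1 g/mL, alpha = 0.18 mL/g, n_media = 1.364 -> n = 1.544
        model = dmap.AcfModel(d_b=2.0, amplitude=0.0)
        real = sample_chromatin_density(model, small_grid, seed=0,
                                        mean_crowding_g_ml=1.0)
        assert np.allclose(density_to_ri(real, instrument), 1.544)

    def test_affine_in_density(self, instrument, small_grid):
        model = dmap.AcfModel(d_b=2.3)
        r1 = sample_chromatin_density(model, small_grid, seed=1)
        n1 = density_to_ri(r1, instrument) - instrument.n_media
        r1.density = 2.0 * r1.density
        n2 = density_to_ri(r1, instrument) - instrument.n_media
        assert np.allclose(n2, 2.0 * n1, atol=1e-9)


class TestChromatinSampler:
    def test_zero_amplitude_gives_zero_fluctuation(self, small_grid):
        model = dmap.AcfModel(d_b=2.5, amplitude=0.0)
        real = sample_chromatin_density(model, small_grid, seed=3)
        assert np.all(real.density == np.float32(real.mean_crowding_g_ml))

    def test_seeded_determinism_bit_identical(self, small_grid):
        model = dmap.AcfModel(d_b=2.2)
        a = sample_chromatin_density(model, small_grid, seed=11)
        b = sample_chromatin_density(model, small_grid, seed=11)
        assert np.array_equal(a.density, b.density)

    def test_grid_too_small_raises(self):
        model = dmap.AcfModel(d_b=2.0)  # r_max 334 nm
        with pytest.raises(ValueError, match="extent"):
            sample_chromatin_density(model, GridSpec(16, 16, 16, 11.0), seed=0)
        with pytest.raises(ValueError, match="voxel"):
            sample_chromatin_density(model, GridSpec(32, 32, 32, 20.0), seed=0)

    def test_empirical_acf_slope_matches_model(self):
        """Radially averaged ACF of sampled fields recovers d_b - 3 within
        +-0.15 over the fractal regime (128^3 voxels, 5 seeds)."""
        model = dmap.AcfModel(d_b=2.5)
        grid = GridSpec(128, 128, 128, 11.0)
        slopes = []
        for seed in range(5):
            f = sample_chromatin_density(model, grid, seed).density.astype(np.float64)
            f -= f.mean()
            spec = np.abs(np.fft.fftn(f)) ** 2
            acf = np.fft.ifftn(spec).real / f.size
            idx = np.arange(128)
            d = np.minimum(idx, 128 - idx) * grid.voxel_nm
            r = np.sqrt(d[:, None, None] ** 2 + d[None, :, None] ** 2
                        + d[None, None, :] ** 2)
            lo, hi = 1.5 * model.r_min_nm, 0.6 * model.r_max_nm
            sel = (r >= lo) & (r <= hi)
            bins = np.geomspace(lo, hi, 12)
            which = np.digitize(r[sel], bins)
            vals, rads = [], []
            for b in range(1, len(bins)):
                m = which == b
                if m.sum() > 10:
                    vals.append(acf[sel][m].mean())
                    rads.append(r[sel][m].mean())
            coef = np.polyfit(np.log(rads), np.log(vals), 1)
            slopes.append(coef[0])
        assert abs(np.mean(slopes) - (model.d_b - 3.0)) <= 0.15


class TestInterference:
    def test_homogeneous_cell_is_wavelength_flat(self, instrument):
        grid = GridSpec(8, 8, 448, 11.0)
        ri = np.full(grid.shape, instrument.n_media + 0.036)
        cube = simulate_interference_cube(ri, grid, instrument)
        assert np.allclose(np.ptp(cube.values, axis=2), 0.0, atol=1e-12)
        ref = make_reference_cube(instrument, (8, 8))
        sig = compute_sigma_image(reference_normalize(cube, ref),
                                  np.ones((8, 8), bool))
        assert np.nanmax(sig.sigma) < 1e-9

    def test_thin_layer_oscillation_period(self, instrument):
        """A single high-density layer at depth z interferes with the
        reference at k-space period pi / z."""
        grid = GridSpec(4, 4, 512, 11.0)
        ri = np.full(grid.shape, 1.4)
        iz = 150
        ri[:, :, iz] += 0.01
        cube = simulate_interference_cube(ri, grid, instrument)
        n0 = 1.4 + 0.01 / 512  # mean of the field
        k = 2 * np.pi * n0 / cube.wavelengths_nm  # descending in wavelength
        spec = cube.values[0, 0, :]
        fluct = spec - spec.mean()
        # fit oscillation frequency in k by scanning candidate depths
        depths = np.linspace(500, 3500, 1201)
        amps = [abs(np.sum(fluct * np.exp(2j * k * z))) for z in depths]
        z_est = depths[int(np.argmax(amps))]
        z_true = (iz + 0.5) * grid.voxel_nm
        assert abs(z_est - z_true) < 60  # within the k-grid resolution

    def test_born_linearity_in_fluctuation_amplitude(self, instrument, small_grid):
        """Doubling the density fluctuation doubles the spectral fluctuation
        about the reference, to first order."""
        model = dmap.AcfModel(d_b=2.3, amplitude=1e-5)  # deep Born regime
        real = sample_chromatin_density(model, small_grid, seed=2)
        ri1 = density_to_ri(real, instrument)
        real.density = real.mean_crowding_g_ml + 2.0 * (
            real.density - np.float32(real.mean_crowding_g_ml)
        )
        ri2 = density_to_ri(real, instrument)
        c1 = simulate_interference_cube(ri1, small_grid, instrument)
        c2 = simulate_interference_cube(ri2, small_grid, instrument)
        f1 = c1.values - c1.values.mean(axis=2, keepdims=True)
        f2 = c2.values - c2.values.mean(axis=2, keepdims=True)
        ratio = np.linalg.norm(f2) / np.linalg.norm(f1)
        assert abs(ratio - 2.0) < 0.02

    def test_nonfinite_ri_rejected(self, instrument):
        grid = GridSpec(4, 4, 448, 11.0)
        ri = np.full(grid.shape, 1.4)
        ri[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            simulate_interference_cube(ri, grid, instrument)


class TestReferenceNormalize:
    def test_identity_and_scalar_division(self, instrument):
        raw = make_reference_cube(instrument, (3, 3))
        out = reference_normalize(raw, raw)
        assert np.allclose(out.values, 1.0)
        lam = np.array([500.0, 550.0, 600.0])
        raw2 = SpectralCube(np.array([[[1.8, 2.0, 2.2]]]), lam)
        ref2 = SpectralCube(np.full((1, 1, 3), 2.0), lam)
        assert np.allclose(reference_normalize(raw2, ref2).values,
                           [[[0.9, 1.0, 1.1]]])
        ones = SpectralCube(np.ones((1, 1, 3)), lam)
        again = reference_normalize(reference_normalize(raw2, ref2), ones)
        assert np.allclose(again.values, reference_normalize(raw2, ref2).values)

    def test_errors(self, instrument):
        lam = np.array([500.0, 550.0, 600.0])
        raw = SpectralCube(np.ones((1, 1, 3)), lam)
        bad_ref = SpectralCube(np.zeros((1, 1, 3)), lam)
        with pytest.raises(ValueError, match="positive"):
            reference_normalize(raw, bad_ref)
        ref_other = SpectralCube(np.ones((1, 1, 3)), lam + 1)
        with pytest.raises(ValueError, match="wavelength"):
            reference_normalize(raw, ref_other)


class TestSigmaImage:
    def test_sample_std_value_and_mask(self):
        lam = np.array([500.0, 550.0, 600.0])
        cube = SpectralCube(np.array([[[0.9, 1.0, 1.1], [1.0, 1.0, 1.0]]]), lam)
        mask = np.array([[True, False]])
        sig = compute_sigma_image(cube, mask)
        assert sig.sigma[0, 0] == pytest.approx(0.1)
        assert np.isnan(sig.sigma[0, 1])

    def test_wavelength_reversal_invariance(self):
        lam = np.array([500.0, 550.0, 600.0, 650.0])
        rng = np.random.default_rng(0)
        vals = rng.random((2, 2, 4))
        a = compute_sigma_image(SpectralCube(vals, lam), np.ones((2, 2), bool))
        b = compute_sigma_image(SpectralCube(vals[:, :, ::-1], lam),
                                np.ones((2, 2), bool))
        assert np.allclose(a.sigma, b.sigma)

    def test_too_few_wavelengths(self):
        lam = np.array([500.0, 550.0])
        cube = SpectralCube(np.ones((1, 1, 2)), lam)
        with pytest.raises(ValueError, match="3 wavelengths"):
            compute_sigma_image(cube, np.ones((1, 1), bool))


def test_monotone_sigma_response_matches_analytic_map(
    instrument, kernel, acf_template, small_grid
):
    """Mean in-mask Sigma from end-to-end simulation is strictly monotone
    over D_b in {1.8, 2.1, 2.4, 2.7} (decreasing for this forward model) and
    matches the analytic map within 10 % relative error."""
    sims, analytic = [], []
    for db in (1.8, 2.1, 2.4, 2.7):
        model = dmap.domain_pinned_model(acf_template, db)
        sig = simulate_cell_sigma(model, small_grid, instrument, seed=1)
        sims.append(float(np.nanmean(sig.sigma)))
        analytic.append(dmap.sigma_from_db(model, kernel, instrument))
    assert np.all(np.diff(sims) < 0), sims
    assert np.all(np.diff(analytic) < 0)
    rel = np.abs(np.array(sims) / np.array(analytic) - 1.0)
    assert rel.max() < 0.10, rel
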