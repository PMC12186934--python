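"""Complex image formation, echo-phase correction, and IDEAL decomposition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import magdensity as md
from magdensity.errors import ConditioningError, DomainError, SizingError
from magdensity.phantom import signal_amplitudes
from magdensity.recon import swap_ambiguity_radius_hz

from conftest import voxel_series


class TestCombineMagPhase:
    def test_unit_identities(self):
        te = (1.0, 2.0, 3.0)
        s = md.combine_mag_phase(
            np.full((1, 1, 1, 3), 2.0), np.full((1, 1, 1, 3), np.pi / 2), te
        )
        np.testing.assert_allclose(s.data, 2j, atol=1e-12)
        m = np.random.default_rng(0).uniform(0, 5, (2, 2, 2, 3))
        s = md.combine_mag_phase(m, np.zeros_like(m), te)
        np.testing.assert_allclose(s.data, m)

    def test_round_trip_on_random_volumes(self):
        rng = np.random.default_rng(42)
        mag = rng.uniform(0, 3, (4, 5, 2, 4))
        phase = rng.uniform(-np.pi, np.pi, (4, 5, 2, 4))
        s = md.combine_mag_phase(mag, phase, (1.0, 2.0, 3.0, 4.0))
        np.testing.assert_allclose(np.abs(s.data), mag, atol=1e-12)
        np.testing.assert_allclose(
            np.angle(s.data * np.exp(-1j * phase)), 0.0, atol=1e-9
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            md.combine_mag_phase(
                -np.ones((1, 1, 1, 3)), np.zeros((1, 1, 1, 3)), (1, 2, 3)
            )
        with pytest.raises(SizingError):
            md.combine_mag_phase(
                np.ones((1, 1, 1, 3)), np.zeros((1, 1, 2, 3)), (1, 2, 3)
            )


class TestEchoPhase:
    def test_injection_recovery_noiseless(self, phantom, presets):
        prof = presets["prisma"].with_(phase0=0.3, phase1=0.05)
        series = md.simulate_echoes(phantom, prof, seed=0)
        p0, p1 = md.estimate_echo_phase(series, profile=prof)
        assert p0 == pytest.approx(0.3, abs=1e-6)
        assert p1 == pytest.approx(0.05, abs=1e-6)

    def test_null_case(self, phantom, presets):
        prof = presets["prisma"].with_(phase0=0.0, phase1=0.0)
        series = md.simulate_echoes(phantom, prof, seed=0)
        p0, p1 = md.estimate_echo_phase(series, profile=prof)
        assert abs(p0) < 1e-8 and abs(p1) < 1e-8

    def test_noise_robustness_nonuniform_echoes(self, phantom, presets):
        # identifiability needs non-uniform echo spacing; the Siemens
        # protocol provides it
        errs = []
        for seed in range(20):
            prof = presets["prisma"].with_(noise_sd=0.01)
            series = md.simulate_echoes(phantom, prof, seed=seed)
            p0, p1 = md.estimate_echo_phase(series, profile=prof)
            errs.append(max(abs(p0 - prof.phase0), abs(p1 - prof.phase1)))
        assert max(errs) < 0.02

    def test_correction_magnitude_preserving_and_idempotent(
        self, phantom, presets
    ):
        prof = presets["mmr"]
        series = md.simulate_echoes(phantom, prof, seed=0)
        ident = md.apply_phase_correction(series, 0.0, 0.0)
        np.testing.assert_array_equal(ident.data, series.data)
        corr = md.apply_phase_correction(series, 0.2, -0.04)
        np.testing.assert_allclose(
            np.abs(corr.data), np.abs(series.data), atol=1e-12
        )
        p0, p1 = md.estimate_echo_phase(
            md.apply_phase_correction(series, prof.phase0, prof.phase1),
            profile=prof,
        )
        assert abs(p0) < 1e-9 and abs(p1) < 1e-9

    def test_empty_mask_rejected(self, phantom, presets):
        series = md.simulate_echoes(phantom, presets["mmr"], seed=0)
        with pytest.raises(DomainError):
            md.estimate_echo_phase(
                series, mask=np.zeros(phantom.shape, bool), profile=presets["mmr"]
            )


class TestIdealDecompose:
    def test_pure_water_voxel(self, presets):
        prof = presets["prisma"]
        maps = md.ideal_decompose(voxel_series(prof, 1.0, 0.0, 0.0), prof)
        assert maps.water[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
        assert maps.fat[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert maps.fat_fraction[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert maps.field_map[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_mixed_voxel_with_field_offset(self, presets):
        prof = presets["prisma"]
        maps = md.ideal_decompose(voxel_series(prof, 0.3, 0.7, 20.0), prof)
        assert maps.fat_fraction[0, 0, 0] == pytest.approx(0.700, abs=1e-6)
        assert maps.field_map[0, 0, 0] == pytest.approx(20.0, abs=1e-4)

    @pytest.mark.parametrize("name", ["prisma", "mmr", "signa"])
    def test_field_convergence_sweep(self, presets, name):
        # initialization at 0 must recover |psi| <= 60 Hz with the study
        # echo spacings
        prof = presets[name]
        for psi in (-60.0, -35.0, -10.0, 15.0, 40.0, 60.0):
            maps = md.ideal_decompose(voxel_series(prof, 0.4, 0.6, psi), prof)
            assert maps.field_map[0, 0, 0] == pytest.approx(psi, abs=1e-3)
            assert maps.fat_fraction[0, 0, 0] == pytest.approx(0.6, abs=1e-6)

    def test_echo_order_invariance(self, presets):
        prof = presets["prisma"]
        s = voxel_series(prof, 0.25, 0.75, 12.0)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = md.EchoSeries(
            data=s.data[..., perm],
            echo_times=tuple(np.asarray(prof.echo_times)[perm]),
        )
        # solver only needs (TE, value) pairs; sort back inside a profile copy
        order = np.argsort(permuted.echo_times)
        restored = md.EchoSeries(
            data=permuted.data[..., order],
            echo_times=tuple(np.asarray(permuted.echo_times)[order]),
        )
        a = md.ideal_decompose(s, prof)
        b = md.ideal_decompose(restored, prof)
        np.testing.assert_allclose(a.fat_fraction, b.fat_fraction, atol=1e-12)
        np.testing.assert_allclose(a.field_map, b.field_map, atol=1e-9)

    def test_matches_dense_grid_search(self, presets):
        # brute-force oracle: exhaustive psi grid + exact least squares
        prof = presets["prisma"]
        te = prof.echo_times_s
        c = np.exp(2j * np.pi * prof.fat_offset_hz * te)
        a_mat = np.stack([np.ones_like(c), c], axis=1)
        pinv = np.linalg.pinv(a_mat)
        rng = np.random.default_rng(3)
        for _ in range(10):
            aw, af = rng.uniform(0.1, 1.0, 2)
            psi_true = rng.uniform(-40, 40)
            s = voxel_series(prof, aw, af, psi_true)
            grid = np.arange(-100.0, 100.0 + 1e-9, 0.1)
            d = s.data.reshape(1, -1) * np.exp(
                -2j * np.pi * grid[:, None] * te
            )
            x = d @ pinv.T
            res = np.linalg.norm(d - x @ a_mat.T, axis=1)
            psi_grid = grid[np.argmin(res)]
            maps = md.ideal_decompose(s, prof)
            assert abs(maps.field_map[0, 0, 0] - psi_grid) <= 0.1

    def test_noisy_fat_fraction_bias(self, presets):
        # mean FF bias over mixed voxels stays below 0.01 at noise sd 0.02
        prof = presets["prisma"]
        te = prof.echo_times_s
        biases = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ff_true = rng.uniform(0.2, 0.8, 200)
            aw, af = 1.0 - ff_true, ff_true
            psi = rng.uniform(-30, 30, 200)
            s = (
                aw[:, None]
                + af[:, None] * np.exp(2j * np.pi * prof.fat_offset_hz * te)
            ) * np.exp(2j * np.pi * psi[:, None] * te)
            s = s + rng.normal(0, 0.02, s.shape) + 1j * rng.normal(0, 0.02, s.shape)
            series = md.EchoSeries(
                data=s.reshape(200, 1, 1, -1), echo_times=prof.echo_times
            )
            maps = md.ideal_decompose(series, prof)
            biases.append(np.mean(maps.fat_fraction.ravel() - ff_true))
        assert abs(np.mean(biases)) < 0.01

    def test_forward_inverse_consistency_on_phantom(
        self, phantom, presets, noiseless_series
    ):
        # noiseless end-to-end: per-voxel FF equals the forward-model signal
        # fat fraction to 1e-6
        prof = presets["mmr"]
        series = noiseless_series["mmr"]
        p0, p1 = md.estimate_echo_phase(series, profile=prof)
        maps = md.ideal_decompose(
            md.apply_phase_correction(series, p0, p1), prof
        )
        a_w, a_f = signal_amplitudes(phantom, prof)
        total = a_w + a_f
        tissue = total > 0
        ff_true = a_f[tissue] / total[tissue]
        assert np.nanmax(np.abs(maps.fat_fraction[tissue] - ff_true)) < 1e-6

    def test_degenerate_configurations_rejected(self, presets):
        prof = presets["prisma"]
        with pytest.raises(DomainError):
            md.ideal_decompose(
                md.EchoSeries(
                    data=np.ones((1, 1, 1, 2), complex), echo_times=(1.0, 2.0)
                ),
                prof,
            )
        # all echoes at in-phase times: design matrix singular
        df = abs(md.fat_frequency_offset_hz(3.0))
        in_phase = tuple(k / df * 1e3 for k in (1, 2, 3))
        with pytest.raises(ConditioningError):
            md.ideal_decompose(
                md.EchoSeries(
                    data=np.ones((1, 1, 1, 3), complex), echo_times=in_phase
                ),
                prof.with_(echo_times=in_phase),
            )

    def test_swap_window_radius(self, presets):
        # half the distance to the nearest swap alias; near-uniform GE
        # spacing pulls the alias close to the passband
        signa = presets["signa"]
        r = swap_ambiguity_radius_hz(signa.echo_times_s, signa.fat_offset_hz)
        assert 45.0 < r < 55.0
        prisma = presets["prisma"]
        r3 = swap_ambiguity_radius_hz(prisma.echo_times_s, prisma.fat_offset_hz)
        assert r3 > 100.0


class TestFatFractionMap:
    def test_basic_values_and_degenerate_voxel(self):
        maps = md.FatWaterMaps(
            water=np.array([[[1.0, 0.0, 0.0]]]),
            fat=np.array([[[1.0, 1.0, 0.0]]]),
            field_map=np.zeros((1, 1, 3)),
            fat_fraction=np.zeros((1, 1, 3)),
            iterations_used=np.zeros((1, 1, 3), int),
        )
        ff = md.fat_fraction_map(maps)
        assert ff[0, 0, 0] == pytest.approx(0.5)
        assert ff[0, 0, 1] == pytest.approx(1.0)
        assert np.isnan(ff[0, 0, 2])

    @given(
        w=st.floats(min_value=0.0, max_value=10.0),
        f=st.floats(min_value=1e-6, max_value=10.0),
    )
    def test_range_property(self, w, f):
        maps = md.FatWaterMaps(
            water=np.full((1, 1, 1), w),
            fat=np.full((1, 1, 1), f),
            field_map=np.zeros((1, 1, 1)),
            fat_fraction=np.zeros((1, 1, 1)),
            iterations_used=np.zeros((1, 1, 1), int),
        )
        ff = md.fat_fraction_map(maps)[0, 0, 0]
        assert 0.0 <= ff <= 1.0
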