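"""Monte Carlo forward model: absorption composition, transport, training set."""

import numpy as np
import pytest

from camvitals import spectra
from camvitals.forward_model import (
    ChromophoreRanges,
    ChromophoreState,
    LayerOptics,
    ReflectanceSpectrum,
    SkinModel,
    absorption_from_chromophores,
    build_training_set,
    sample_states,
    simulate_reflectance,
    skin_layers,
)

WL = spectra.WAVELENGTHS


class TestAbsorption:
    def test_zero_concentrations_give_baseline(self):
        st = ChromophoreState(0.0, 0.0, 0.0)
        for role in ("epidermis", "dermis"):
            mu_a = absorption_from_chromophores(st, role, WL)
            np.testing.assert_allclose(mu_a, spectra.baseline_absorption(WL))

    def test_linear_in_each_concentration(self):
        st1 = ChromophoreState(0.02, 0.004, 0.002)
        st2 = ChromophoreState(0.02, 0.008, 0.002)
        base = absorption_from_chromophores(ChromophoreState(0.02, 0.0, 0.002), "dermis", WL)
        d1 = absorption_from_chromophores(st1, "dermis", WL) - base
        d2 = absorption_from_chromophores(st2, "dermis", WL) - base
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-12)

    def test_melanin_only_in_epidermis_hemoglobin_only_in_dermis(self):
        st = ChromophoreState(0.05, 0.01, 0.01)
        epi = absorption_from_chromophores(st, "epidermis", WL)
        derm = absorption_from_chromophores(st, "dermis", WL)
        base = spectra.baseline_absorption(WL)
        np.testing.assert_allclose(
            epi - base, st.cm * spectra.melanin_absorption(WL)
        )
        assert np.all(derm - base > 0)

    def test_isosbestic_swap_invariance(self):
        # brute-force scan of the bundled table for the crossing wavelength
        tab = spectra.hemoglobin_extinction()
        diff = np.abs(tab["eps_hbo2_cm1_M"] - tab["eps_hbr_cm1_M"]).to_numpy()
        wl_iso = tab["wavelength_nm"].iloc[int(np.argmin(diff))]
        assert wl_iso == spectra.isosbestic_wavelength()
        st = ChromophoreState(0.02, 0.012, 0.003)
        swapped = ChromophoreState(0.02, 0.003, 0.012)
        wl = np.array([wl_iso])
        a = absorption_from_chromophores(st, "dermis", wl)[0]
        b = absorption_from_chromophores(swapped, "dermis", wl)[0]
        assert abs(a - b) / a < 0.01  # table crossing is not exactly on-grid

    def test_out_of_support_wavelength_raises(self):
        st = ChromophoreState(0.02, 0.004, 0.002)
        with pytest.raises(ValueError, match="wavelength"):
            absorption_from_chromophores(st, "dermis", np.array([350.0]))


class TestTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(thickness=-1.0),
            dict(mu_a=-np.ones(3)),
            dict(g=1.5),
            dict(n=0.5),
        ],
    )
    def test_layer_validation(self, kwargs):
        base = dict(thickness=1.0, mu_a=np.ones(3), mu_s=np.ones(3), g=0.0, n=1.4)
        base.update(kwargs)
        with pytest.raises(ValueError):
            LayerOptics(**base)

    def test_state_derived_quantities(self):
        st = ChromophoreState(0.02, 0.006, 0.002)
        assert st.chbt == pytest.approx(0.008)
        assert st.sto2 == pytest.approx(75.0)
        assert np.isnan(ChromophoreState(0.02, 0.0, 0.0).sto2)

    def test_reflectance_spectrum_invariants(self):
        with pytest.raises(ValueError):
            ReflectanceSpectrum(np.array([500.0, 500.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            ReflectanceSpectrum(np.array([500.0, 510.0]), np.array([0.5, 1.5]))


class TestTransport:
    def test_no_absorption_matched_boundary_conserves_weight(self):
        wl = np.array([550.0])
        layers = [
            LayerOptics(50.0, np.zeros(1), np.full(1, 2.0), g=0.0, n=1.0)
        ]
        skin = SkinModel(n_ambient=1.0)
        spec = simulate_reflectance(layers, photons=20_000, seed=3, wavelengths=wl, skin=skin)
        # all launched weight leaves through one face or the other
        assert spec.reflectance[0] > 0
        # energy check inside simulate_reflectance enforces R+T+A == 1;
        # with mu_a = 0 nothing can be absorbed
        layers_a = [
            LayerOptics(50.0, np.zeros(1), np.full(1, 2.0), g=0.0, n=1.0, semi_infinite=True)
        ]
        spec2 = simulate_reflectance(layers_a, photons=20_000, seed=3, wavelengths=wl, skin=skin)
        assert 0 < spec2.reflectance[0] < 1

    def test_seeded_runs_are_bit_identical(self):
        st = ChromophoreState(0.03, 0.005, 0.002)
        layers = skin_layers(st)
        a = simulate_reflectance(layers, photons=2000, seed=42)
        b = simulate_reflectance(layers, photons=2000, seed=42)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        c = simulate_reflectance(layers, photons=2000, seed=43)
        assert np.any(c.reflectance != a.reflectance)

    def test_diffusion_approximation_oracle(self):
        # semi-infinite homogeneous medium, matched boundary, mu_s'/mu_a = 100
        mu_a, mu_sp = 0.01, 1.0
        layers = [
            LayerOptics(
                80.0, np.array([mu_a]), np.array([mu_sp]), g=0.0, n=1.0,
                semi_infinite=True,
            )
        ]
        spec = simulate_reflectance(
            layers, photons=50_000, seed=4, wavelengths=np.array([550.0]),
            skin=SkinModel(n_ambient=1.0),
        )
        a_prime = mu_sp / (mu_a + mu_sp)
        s3 = np.sqrt(3.0 * (1.0 - a_prime))
        r_diffusion = a_prime / 2.0 * np.exp(-s3) * (1.0 + np.exp(-4.0 / 3.0 * s3))
        assert abs(spec.reflectance[0] - r_diffusion) / r_diffusion < 0.03

    def test_reflectance_decreases_with_total_hemoglobin_at_550(self):
        # 5-point CHbT ladder at fixed StO2, single wavelength
        wl = np.array([550.0])
        sk = SkinModel()
        vals = []
        for chbt in np.linspace(0.002, 0.02, 5):
            st = ChromophoreState(0.03, 0.7 * chbt, 0.3 * chbt)
            mu_s = spectra.reduced_scattering(wl) / (1 - sk.g)
            layers = [
                LayerOptics(sk.epidermis_thickness,
                            absorption_from_chromophores(st, "epidermis", wl),
                            mu_s, g=sk.g, n=sk.n),
                LayerOptics(sk.dermis_thickness,
                            absorption_from_chromophores(st, "dermis", wl),
                            mu_s, g=sk.g, n=sk.n, semi_infinite=True),
            ]
            spec = simulate_reflectance(layers, photons=30_000, seed=5, wavelengths=wl)
            vals.append((spec.reflectance[0], spec.mc_stderr[0]))
        for (r1, s1), (r2, s2) in zip(vals, vals[1:]):
            assert r2 + 3 * s2 < r1 - 3 * s1  # strict decrease beyond MC error

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="photons"):
            simulate_reflectance(skin_layers(ChromophoreState(0.02, 0.004, 0.002)), photons=10)
        with pytest.raises(ValueError, match="layer"):
            simulate_reflectance([], photons=2000)


class TestTrainingSet:
    def test_small_set_has_valid_states_and_metadata(self, training_small):
        assert len(training_small) == 60
        df = training_small.table
        sto2 = 100.0 * df["CHbO"] / (df["CHbO"] + df["CHbR"])
        assert ((sto2 >= 0) & (sto2 <= 100)).all()
        assert (df[["X", "Y", "Z"]] > 0).all().all()
        assert training_small.metadata["photons"] == 3000

    def test_same_seed_reproduces_training_set(self):
        a = build_training_set(n=20, photons=1000, seed=5)
        b = build_training_set(n=20, photons=1000, seed=5)
        np.testing.assert_array_equal(a.table.to_numpy(), b.table.to_numpy())

    def test_latin_hypercube_covers_ranges(self):
        ranges = ChromophoreRanges()
        states = sample_states(ranges, n=300, seed=9)
        cm = np.array([s.cm for s in states])
        span = cm.max() - cm.min()
        assert span >= 0.95 * (ranges.cm[1] - ranges.cm[0])

    def test_too_few_samples_refused(self):
        with pytest.raises(ValueError, match="n must be >= 20"):
            build_training_set(n=10, photons=1000, seed=0)

    def test_degenerate_range_refused(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            ChromophoreRanges(cm=(0.05, 0.05))

    def test_csv_round_trip(self, training_small, tmp_path):
        path = tmp_path / "train.csv"
        training_small.to_csv(path)
        back = type(training_small).from_csv(path)
        np.testing.assert_allclose(
            back.table.to_numpy(), training_small.table.to_numpy(), rtol=1e-12
        )
        assert back.metadata["seed"] == training_small.metadata["seed"]
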