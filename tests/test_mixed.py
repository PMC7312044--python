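"""TDRA mixing, iso-effect doses, RBE, and the voxel profile pipeline."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from ionrbe.errors import ConfigurationError, MissingSpeciesError
from ionrbe.mixed import (
    FractionationScheme,
    SpectrumEntry,
    VoxelSpectrum,
    lookup_LQ,
    mix_alpha_beta,
    profile,
    rbe,
    rbe_monochromatic,
    rbe_weighted_dose,
    read_spectra_csv,
    survival_mixed,
    write_spectra_csv,
)
from ionrbe.survival import LQParameters, RadiobiologicalTable

PHOTON = LQParameters(0.159, 0.065)


def table_from(rows):
    return RadiobiologicalTable(
        pd.DataFrame(rows, columns=["particle", "Z", "A", "energy_mev_u", "let_kev_um", "alpha", "beta"])
    )


TABLE = table_from(
    [
        ("C", 6, 12, 10.0, 165.0, 3.2, 0.02),
        ("C", 6, 12, 100.0, 29.0, 0.55, 0.08),
        ("C", 6, 12, 400.0, 10.5, 0.30, 0.17),
        ("H", 1, 1, 10.0, 4.6, 0.23, 0.10),
        ("H", 1, 1, 100.0, 0.82, 0.18, 0.08),
    ]
)


def entry(particle="C", z=6, a=12, e=100.0, let=29.0, dose=1.0):
    return SpectrumEntry(particle, z, a, e, let, dose)


class TestLookupLQ:
    def test_grid_energy_exact(self):
        assert lookup_LQ(TABLE, "C", 100.0) == pytest.approx((0.55, 0.08))

    def test_log_midpoint_linear(self):
        t = table_from(
            [("C", 6, 12, 10.0, 100.0, 0.2, 0.01), ("C", 6, 12, 40.0, 50.0, 0.4, 0.03)]
        )
        e_mid = np.sqrt(10.0 * 40.0)  # midway in log energy
        a, b = lookup_LQ(t, "C", e_mid)
        assert a == pytest.approx(0.3, abs=1e-12)
        assert b == pytest.approx(0.02, abs=1e-12)

    def test_clamped_outside_grid(self):
        assert lookup_LQ(TABLE, "C", 1e-3) == pytest.approx((3.2, 0.02))
        assert lookup_LQ(TABLE, "C", 1e4) == pytest.approx((0.30, 0.17))

    def test_matches_independent_piecewise_evaluator(self, rng):
        sub = TABLE.df[TABLE.df["particle"] == "C"]
        e = sub["energy_mev_u"].to_numpy()
        for _ in range(100):
            q = float(rng.uniform(e[0], e[-1]))
            # manual bracket-and-lerp in log energy
            i = int(np.searchsorted(e, q) - 1)
            i = min(max(i, 0), len(e) - 2)
            w = (np.log(q) - np.log(e[i])) / (np.log(e[i + 1]) - np.log(e[i]))
            ea = (1 - w) * sub["alpha"].iloc[i] + w * sub["alpha"].iloc[i + 1]
            eb = (1 - w) * sub["beta"].iloc[i] + w * sub["beta"].iloc[i + 1]
            a, b = lookup_LQ(TABLE, "C", q)
            assert a == pytest.approx(ea, abs=1e-12)
            assert b == pytest.approx(eb, abs=1e-12)

    def test_missing_species(self):
        with pytest.raises(MissingSpeciesError):
            lookup_LQ(TABLE, "Ne", 100.0)


class TestMixAlphaBeta:
    def test_single_component_passthrough(self):
        sp = VoxelSpectrum(0, 0.0, (entry(dose=2.0),))
        assert mix_alpha_beta(sp, TABLE) == pytest.approx((0.55, 0.08))

    def test_dose_weighted_alpha(self):
        t = table_from(
            [("C", 6, 12, 10.0, 165.0, 0.1, 0.04), ("H", 1, 1, 10.0, 4.6, 0.3, 0.04)]
        )
        sp = VoxelSpectrum(
            0, 0.0, (entry(e=10.0, dose=1.0), entry("H", 1, 1, 10.0, 4.6, 3.0))
        )
        a, b = mix_alpha_beta(sp, t)
        assert a == pytest.approx(0.25)  # (0.1*1 + 0.3*3) / 4
        assert b == pytest.approx(0.04)

    def test_brute_force_loop_oracle(self, rng):
        for _ in range(100):
            picks = TABLE.df.sample(5, replace=True, random_state=int(rng.integers(1e9)))
            doses = rng.uniform(0.1, 2.0, size=5)
            entries = tuple(
                SpectrumEntry(r["particle"], int(r["Z"]), int(r["A"]), r["energy_mev_u"], r["let_kev_um"], d)
                for (_, r), d in zip(picks.iterrows(), doses)
            )
            sp = VoxelSpectrum(0, 0.0, entries)
            a, b = mix_alpha_beta(sp, TABLE)
            num_a = num_sb = 0.0
            for en in entries:
                ai, bi = lookup_LQ(TABLE, en.particle, en.energy_mev_u)
                num_a += ai * en.dose_gy
                num_sb += np.sqrt(bi) * en.dose_gy
            D = doses.sum()
            assert a == pytest.approx(num_a / D, abs=1e-12)
            assert b == pytest.approx((num_sb / D) ** 2, abs=1e-12)
            # mixing bounds on alpha
            alphas = [lookup_LQ(TABLE, en.particle, en.energy_mev_u)[0] for en in entries]
            assert min(alphas) - 1e-12 <= a <= max(alphas) + 1e-12

    def test_linear_beta_variant(self):
        sp = VoxelSpectrum(0, 0.0, (entry(e=10.0, dose=1.0), entry(e=400.0, dose=1.0)))
        _, b = mix_alpha_beta(sp, TABLE, beta_mixing="linear")
        assert b == pytest.approx((0.02 + 0.17) / 2)

    def test_zero_dose_undefined(self):
        with pytest.raises(ConfigurationError):
            mix_alpha_beta(VoxelSpectrum(0, 0.0, ()), TABLE)


class TestSurvivalAndIsoEffect:
    def test_zero_dose_full_survival(self):
        assert survival_mixed(0.3, 0.05, FractionationScheme(1), 0.0) == 1.0

    def test_single_fraction_arithmetic(self):
        s = survival_mixed(0.159, 0.065, FractionationScheme(1), 2.0)
        assert -np.log(s) == pytest.approx(0.578)

    def test_fractionation_sparing(self):
        d = 4.0
        s1 = survival_mixed(0.2, 0.05, FractionationScheme(1), d)
        s2 = survival_mixed(0.2, 0.05, FractionationScheme(2), d)
        assert s2 > s1

    def test_rbe_weighted_dose_identity_field(self):
        for n in (1, 2, 6):
            for d in (1.0, 4.0, 14.0):
                s = survival_mixed(PHOTON.alpha, PHOTON.beta, FractionationScheme(n), d)
                assert rbe_weighted_dose(s, PHOTON, FractionationScheme(n)) == pytest.approx(d, abs=1e-9)

    def test_full_survival_gives_zero_dose(self):
        assert rbe_weighted_dose(1.0, PHOTON) == 0.0

    def test_quadratic_root_oracle(self):
        # -ln S = 2.3026 under (0.159, 0.065): numeric root of the LQ equation
        s = np.exp(-2.3026)
        d = rbe_weighted_dose(s, PHOTON, FractionationScheme(1))
        root = scipy.optimize.brentq(
            lambda x: PHOTON.alpha * x + PHOTON.beta * x * x - 2.3026, 0, 100
        )
        assert d == pytest.approx(root, abs=1e-9)
        assert d == pytest.approx(4.853, abs=2e-3)

    def test_iso_effect_property_random_fields(self, rng):
        # photon survival at D_RBE reproduces the mixed survival to 1e-10
        for _ in range(100):
            a = rng.uniform(0.05, 3.0)
            b = rng.uniform(0.0, 0.3)
            d = rng.uniform(0.1, 10.0)
            n = int(rng.integers(1, 7))
            scheme = FractionationScheme(n)
            s = survival_mixed(a, b, scheme, d)
            d_rbe = rbe_weighted_dose(s, PHOTON, scheme)
            s_ph = survival_mixed(PHOTON.alpha, PHOTON.beta, scheme, d_rbe)
            assert abs(s_ph - s) < 1e-10

    def test_beta_zero_photon_limit(self):
        ph = LQParameters(0.2, 0.0)
        s = 0.5
        assert rbe_weighted_dose(s, ph) == pytest.approx(-np.log(s) / 0.2)


class TestRBE:
    def test_ratio_and_errors(self):
        assert rbe(4.853, 3.429) == pytest.approx(1.415, abs=2e-3)
        with pytest.raises(ConfigurationError):
            rbe(1.0, 0.0)

    def test_monochromatic_identity(self):
        for s in (0.9, 0.5, 0.1):
            assert rbe_monochromatic(PHOTON, PHOTON, survival_level=s) == pytest.approx(1.0)

    def test_monochromatic_example_with_root_oracle(self):
        ion = LQParameters(0.5, 0.05)
        got = rbe_monochromatic(ion, PHOTON, survival_level=0.1)
        dx = scipy.optimize.brentq(lambda x: 0.159 * x + 0.065 * x * x + np.log(0.1), 0, 100)
        di = scipy.optimize.brentq(lambda x: 0.5 * x + 0.05 * x * x + np.log(0.1), 0, 100)
        assert got == pytest.approx(dx / di, abs=1e-9)
        assert got == pytest.approx(1.415, abs=2e-3)

    def test_rbe_decreases_with_ion_dose_for_high_ratio(self):
        # alpha_i/alpha_X exceeding sqrt(beta_i/beta_X): RBE falls with dose
        ion = LQParameters(0.5, 0.05)
        r1 = rbe_monochromatic(ion, PHOTON, ion_dose_gy=1.0)
        r2 = rbe_monochromatic(ion, PHOTON, ion_dose_gy=2.0)
        assert r1 > r2

    def test_rbe_nonincreasing_in_fractional_dose(self):
        # the analytic fractionation trend behind the dose-dependence figures
        ion = LQParameters(1.0, 0.05)
        doses = [0.5, 1.0, 2.0, 4.0, 8.0]
        rbes = [rbe_monochromatic(ion, PHOTON, ion_dose_gy=d) for d in doses]
        assert all(x >= y for x, y in zip(rbes, rbes[1:]))


class TestProfile:
    def test_single_voxel_matches_scalar_pipeline(self):
        sp = VoxelSpectrum(3, 80.0, (entry(dose=2.0),))
        scheme = FractionationScheme(2)
        prof = profile([sp], TABLE, PHOTON, scheme).df
        a, b = mix_alpha_beta(sp, TABLE)
        s = survival_mixed(a, b, scheme, 2.0)
        d_rbe = rbe_weighted_dose(s, PHOTON, scheme)
        row = prof.iloc[0]
        assert row["alpha"] == pytest.approx(a)
        assert row["beta"] == pytest.approx(b)
        assert row["survival"] == pytest.approx(s)
        assert row["d_rbe_gy"] == pytest.approx(d_rbe)
        assert row["rbe"] == pytest.approx(d_rbe / 2.0)

    def test_pure_photon_field_rbe_one(self):
        # a field whose every component carries the photon pair is RBE = 1
        t = table_from(
            [
                ("X", 0, 0, 1.0, 1.0, PHOTON.alpha, PHOTON.beta),
                ("X", 0, 0, 100.0, 1.0, PHOTON.alpha, PHOTON.beta),
            ]
        )
        spectra = [
            VoxelSpectrum(i, 10.0 * i, (SpectrumEntry("X", 0, 0, 10.0, 1.0, d),))
            for i, d in enumerate([0.5, 1.0, 2.0, 5.0])
        ]
        for n in (1, 3):
            prof = profile(spectra, t, PHOTON, FractionationScheme(n)).df
            assert np.allclose(prof["rbe"], 1.0, atol=1e-9)

    def test_zero_dose_voxel_reported_null(self):
        spectra = [VoxelSpectrum(0, 0.0, ()), VoxelSpectrum(1, 5.0, (entry(dose=1.0),))]
        prof = profile(spectra, TABLE, PHOTON).df
        assert np.isnan(prof.iloc[0]["rbe"])
        assert prof.iloc[0]["survival"] == 1.0
        assert np.isfinite(prof.iloc[1]["rbe"])

    def test_missing_species_names_voxel(self):
        spectra = [VoxelSpectrum(7, 5.0, (entry("Ne", 10, 20, 100.0, 30.0, 1.0),))]
        with pytest.raises(MissingSpeciesError, match="voxel 7"):
            profile(spectra, TABLE, PHOTON)


class TestSpectraCSV:
    def test_round_trip(self, tmp_path):
        spectra = [
            VoxelSpectrum(0, 10.0, (entry(dose=1.0), entry("H", 1, 1, 100.0, 0.82, 0.1))),
            VoxelSpectrum(1, 20.0, (entry(dose=2.0),)),
        ]
        p = tmp_path / "spec.csv"
        write_spectra_csv(spectra, p)
        back = read_spectra_csv(p)
        assert len(back) == 2
        assert back[0].entries == spectra[0].entries
        assert back[1].total_dose_gy == pytest.approx(2.0)
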