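"""Tests for the synthetic experiment generator and its closure properties."""

import numpy as np
import pandas as pd
import pytest

from phycovoc.differential import classify_compound
from phycovoc.quantify import compute_ppbv
from phycovoc.spectral import locate_peak, process_series
from phycovoc.synthetic import (
    ANCHOR_COMPOUNDS,
    CompoundSpec,
    ExperimentDesign,
    InstrumentParams,
    make_compound_library,
    render_spectrum_series,
    simulate_cell_counts,
    simulate_gcp_dataset,
    simulate_liquid_concentrations,
)


class TestCompoundLibrary:
    def test_anchor_only_library(self, anchor_library):
        assert len(anchor_library) == 9
        names = {s.label for s in anchor_library}
        assert names == {n for n, _, _ in ANCHOR_COMPOUNDS}
        n_hc = sum(
            1 for s in anchor_library if classify_compound(s.formula) == "hydrocarbon"
        )
        assert n_hc == 4  # C11H16 + the three BTEX signals

    def test_full_library_masses_in_acquisition_range(self, full_library):
        assert len(full_library) == 72
        for s in full_library:
            assert 30.0 <= s.mz <= 240.0

    def test_same_seed_identical(self):
        a = make_compound_library(40, 20, seed=5)
        b = make_compound_library(40, 20, seed=5)
        for x, y in zip(a, b):
            assert x.label == y.label
            assert x.neutral_mass == y.neutral_mass
            assert x.production_exp == y.production_exp
            assert x.depletion_factor == y.depletion_factor

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            make_compound_library(5, 2, seed=0)

    def test_unidentified_fraction(self, full_library):
        n_unid = sum(1 for s in full_library if s.formula is None)
        assert 0.10 <= n_unid / len(full_library) <= 0.20

    def test_methanol_and_acetone_never_depleted(self, full_library):
        for s in full_library:
            if s.label in ("methanol", "acetone"):
                assert s.depletion_factor == {}

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            CompoundSpec("too_heavy", None, 260.0, 0.1, 0.01)
        with pytest.raises(ValueError, match="inconsistent"):
            CompoundSpec("bad_mass", {"C": 6, "H": 6}, 90.0, 0.1, 0.01)
        with pytest.raises(ValueError, match="depletion"):
            CompoundSpec("bad_dep", None, 100.0, 0.1, 0.01, {"X": 1.5})


class TestLiquidConcentrations:
    def test_no_depletion_means_equal_expectation(self, default_design):
        lib = make_compound_library(12, 6, seed=2)
        for s in lib:
            s.depletion_factor.clear()
        truth, _ = simulate_liquid_concentrations(lib, default_design)
        exp = truth.true_liquid_conc
        for phase in default_design.phases:
            for coc in default_design.cocultures:
                assert np.allclose(exp[(coc, phase)], exp[("Axenic", phase)])

    def test_full_depletion_zeroes_coculture(self, default_design):
        lib = make_compound_library(9, 4, seed=2)
        for s in lib:
            s.depletion_factor = {c: 1.0 for c in default_design.cocultures}
        truth, conc = simulate_liquid_concentrations(lib, default_design)
        coc_cols = [c for c in conc.columns if c.startswith("Marinobacter")]
        assert np.allclose(conc[coc_cols].values, 0.0)

    def test_unit_conversion_oracle(self):
        # independent arithmetic: fmol/cell * (cells/ml * 1e3 ml/l)
        # * 1e-15 mol/fmol * 1e9 nM/M
        lib = [CompoundSpec("x", None, 100.0, 84.9, 8.49)]
        design = ExperimentDesign(
            treatments=("Axenic",),
            diatom_density={"exponential": 2.18e5, "stationary": 2.18e5},
            seed=0,
        )
        truth, _ = simulate_liquid_concentrations(lib, design)
        expected_nM = 84.9 * 1e-15 * 2.18e5 * 1e3 * 1e9
        got = truth.true_liquid_conc[("Axenic", "exponential")].iloc[0]
        assert got == pytest.approx(expected_nM, rel=1e-12)

    def test_default_total_pool_near_reported_concentration(self, full_library):
        # the exponential-phase pool should total ~18.5 nM at the default
        # exponential diatom density
        design = ExperimentDesign(seed=1)
        truth, _ = simulate_liquid_concentrations(full_library, design)
        total = truth.true_liquid_conc[("Axenic", "exponential")].sum()
        assert total == pytest.approx(18.5, rel=0.02)

    def test_stationary_percell_scaling(self, full_library):
        tot_exp = sum(s.production_exp for s in full_library)
        tot_stat = sum(s.production_stat for s in full_library)
        assert tot_stat / tot_exp == pytest.approx(0.1, rel=1e-9)

    def test_replicate_noise_mean_preserving(self, full_library):
        design = ExperimentDesign(n_replicates=6, seed=9)
        truth, conc = simulate_liquid_concentrations(
            full_library, design, cv=0.2, seed=77
        )
        ax = [c for c in conc.columns if c.startswith("Axenic-exponential")]
        expect = truth.true_liquid_conc[("Axenic", "exponential")]
        ratio = conc[ax].mean(axis=1) / expect
        # averaged across 72 signals x 6 replicates the bias is small
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_determinism(self, full_library, default_design):
        _, a = simulate_liquid_concentrations(full_library, default_design, seed=3)
        _, b = simulate_liquid_concentrations(full_library, default_design, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRenderSpectra:
    def test_blank_contains_only_reference_and_background(self, anchor_library,
                                                          clean_instrument):
        zero = {s.signal_label: 0.0 for s in anchor_library}
        series = render_spectrum_series(zero, anchor_library, clean_instrument, seed=0)
        peaks = process_series(series)
        centers = sorted(c for c, _ in peaks)
        expected = sorted(
            [29.998, 203.943]
            + list(clean_instrument.background_peaks)
        )
        assert centers == pytest.approx(expected, abs=0.005)

    def test_drift_shifts_uncalibrated_peak(self, anchor_library, clean_instrument):
        from dataclasses import replace

        drifted = replace(clean_instrument, mass_drift=(1.0002, 0.01))
        benzene = next(s for s in anchor_library if s.label == "benzene")
        conc = {s.signal_label: 0.0 for s in anchor_library}
        conc[benzene.signal_label] = 2.0
        series = render_spectrum_series(conc, anchor_library, drifted, seed=0)
        pos = locate_peak(series, benzene.mz)
        # affine map: 79.055 * 1.0002 + 0.01 moves the center > 0.01 Da
        assert abs(pos - benzene.mz) > 0.01
        assert pos == pytest.approx(benzene.mz * 1.0002 + 0.01, abs=0.002)

    def test_noise_free_closure_within_one_percent(self, anchor_library,
                                                   clean_instrument, stripping):
        benzene = next(s for s in anchor_library if s.label == "benzene")
        conc = {s.signal_label: 0.0 for s in anchor_library}
        conc[benzene.signal_label] = 5.0
        series = render_spectrum_series(
            conc, anchor_library, clean_instrument, stripping, seed=0
        )
        peaks = process_series(series)
        total_ncps = sum(
            v for c, v in peaks if abs(c - benzene.mz) < 0.01 or
            abs(c - benzene.mz - 1.003) < 0.01
        )
        recovered_nM = compute_ppbv(total_ncps, clean_instrument.kinetics) \
            * stripping.liquid_per_gas_factor
        assert recovered_nM == pytest.approx(5.0, rel=0.01)

    def test_forward_model_linearity(self, anchor_library, clean_instrument):
        conc1 = {s.signal_label: 1.0 for s in anchor_library}
        conc2 = {s.signal_label: 2.0 for s in anchor_library}
        s1 = render_spectrum_series(conc1, anchor_library, clean_instrument, seed=0)
        s2 = render_spectrum_series(conc2, anchor_library, clean_instrument, seed=0)
        # subtract the shared reference/background signal, then compare
        zero = render_spectrum_series(
            {s.signal_label: 0.0 for s in anchor_library},
            anchor_library, clean_instrument, seed=0,
        )
        net1 = s1.intensity - zero.intensity
        net2 = s2.intensity - zero.intensity
        assert net2.sum() == pytest.approx(2 * net1.sum(), rel=1e-9)

    def test_seed_determinism(self, anchor_library):
        inst = InstrumentParams(noise_sd=2.0)
        conc = {s.signal_label: 1.0 for s in anchor_library}
        a = render_spectrum_series(conc, anchor_library, inst, seed=42)
        b = render_spectrum_series(conc, anchor_library, inst, seed=42)
        assert np.array_equal(a.intensity, b.intensity)

    def test_out_of_range_compound_warns_and_omits(self, clean_instrument):
        from dataclasses import replace

        narrow = replace(clean_instrument, mz_max=60.0)
        spec = CompoundSpec("benzene", {"C": 6, "H": 6}, 78.04695, 0.01, 0.001)
        with pytest.warns(UserWarning, match="outside acquisition"):
            series = render_spectrum_series(
                {spec.signal_label: 5.0}, [spec], narrow, seed=0
            )
        assert locate_peak(series, spec.mz) is None


class TestCellCounts:
    def test_zero_attached_mean_gives_zero_counts(self):
        design = ExperimentDesign(
            attached_per_diatom={c: 0.0 for c in
                                 ("Marinobacter", "Roseibium", "Yoonia",
                                  "Rhodophyticola", "Stappia")},
            seed=0,
        )
        cells = simulate_cell_counts(design, seed=1)
        assert all(c.attached_per_diatom == 0.0 for c in cells)

    def test_attached_mean_within_poisson_error(self):
        design = ExperimentDesign(seed=0, n_replicates=6)
        cells = simulate_cell_counts(design, seed=2, n_diatoms_imaged=50)
        marino = [
            c.attached_per_diatom for c in cells if c.treatment == "Marinobacter"
        ]
        # mean of 50 Poisson(5) draws: SE = sqrt(5/50); pooled over samples
        pooled = np.mean(marino)
        se = np.sqrt(5.0 / 50 / len(marino))
        assert abs(pooled - 5.0) < 3 * se + 0.05

    def test_reproducible(self, default_design):
        a = simulate_cell_counts(default_design, seed=3)
        b = simulate_cell_counts(default_design, seed=3)
        assert [c.diatom_density for c in a] == [c.diatom_density for c in b]


class TestGcpDataset:
    def test_zero_stimulation_equal_expected_rates(self):
        from phycovoc.gcp import compute_gcp

        design = ExperimentDesign(seed=0, n_replicates=6)
        samples = simulate_gcp_dataset(design, {"Marinobacter": 0.0}, seed=4, cv=0.0)
        rates = {}
        for s in samples:
            rates.setdefault(s.treatment, []).append(compute_gcp(s))
        assert np.mean(rates["Marinobacter"]) == pytest.approx(
            np.mean(rates["Axenic"]), rel=1e-9
        )

    def test_planted_stimulation_recovered(self):
        from phycovoc.gcp import compute_gcp, stimulation

        design = ExperimentDesign(seed=0, n_replicates=6)
        estimates = []
        for rep in range(40):
            samples = simulate_gcp_dataset(design, {"Trap": 24.9}, seed=100 + rep)
            rates = {}
            for s in samples:
                rates.setdefault(s.treatment, []).append(compute_gcp(s))
            pct, _ = stimulation(rates["Trap"], rates["Axenic"])
            estimates.append(pct)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 24.9) < 3 * se + 0.5

    def test_invalid_stimulation_rejected(self, default_design):
        with pytest.raises(ValueError):
            simulate_gcp_dataset(default_design, {"X": -150.0}, seed=0)
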