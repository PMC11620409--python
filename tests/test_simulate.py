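"""Generator contracts: expectation oracles, design grid, determinism,
and the physical-effect properties the downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest

from pxrfkit import simulate
from pxrfkit.lines import ATOMIC_NUMBER, default_line_table
from pxrfkit.simulate import (
    ScanCondition,
    SimulationConfig,
    SpecimenProfile,
    default_config,
    expected_beam_spectra,
    select_beam,
    simulate_concentration_table,
    simulate_study,
)
from pxrfkit.spectra import fwhm_kev

LINES = default_line_table()


def _bare_config(profiles, **kw):
    kw.setdefault("tube_lines", {"La1": 0.0, "Lb1": 0.0})
    kw.setdefault("continuum_amplitude", 0.0)
    kw.setdefault("state_effect", {})
    return SimulationConfig(profiles=profiles, **kw)


def _fe_profile(conc=2.0):
    return SpecimenProfile("fish", "f1", {"Fe": conc}, individual_sd_log=0.0)


class TestSpectrumExpectation:
    def test_zero_sources_give_zero_spectra(self):
        prof = SpecimenProfile("fish", "f1", {"Fe": 0.0}, individual_sd_log=0.0)
        cfg = _bare_config((prof,))
        cond = ScanCondition("dried", "body", 40.0, backed=False)
        for beam in expected_beam_spectra(prof, cond, cfg):
            assert np.all(beam == 0)

    def test_expectation_linear_in_dwell_time(self):
        prof = _fe_profile()
        cfg = default_config(profiles=(prof,), taxa=("fish",))
        e20 = expected_beam_spectra(prof, ScanCondition("dried", "body", 20.0, False), cfg)
        e40 = expected_beam_spectra(prof, ScanCondition("dried", "body", 40.0, False), cfg)
        for a, b in zip(e20, e40):
            assert np.allclose(b, 2.0 * a, rtol=1e-12)

    def test_poisson_mean_oracle_fe_window(self):
        # Fe 2%, 50 counts/pct/s, 40 s, no attenuation -> 4000 expected
        # counts under the Ka1 peak; mean of 200 seeded window sums within
        # 3 SE of 4000.
        prof = _fe_profile(2.0)
        cfg = _bare_config((prof,), counts_per_pct_per_s={"Fe": 50.0},
                           panel=("Fe",))
        cond = ScanCondition("dried", "body", 40.0, backed=False)
        expected_total = 50.0 * 2.0 * 40.0
        ka = LINES.get("Fe", "Ka1")
        sigma = float(fwhm_kev(ka.energy_kev)) / 2.355
        axis = cfg.energy_axis
        window = np.abs(axis - ka.energy_kev) <= 4 * sigma
        beam_idx = cfg.beam_energies.index(select_beam(ka.energy_kev))
        rng = np.random.default_rng(7)
        sums = [
            simulate.simulate_spectrum(prof, cond, cfg, rng)[beam_idx][window].sum()
            for _ in range(200)
        ]
        se = np.sqrt(expected_total / 200)
        # the +/-4 sigma window holds >99.99% of the peak mass
        assert abs(np.mean(sums) - expected_total) < 3 * se + 0.0002 * expected_total

    def test_unknown_element_rejected(self):
        prof = SpecimenProfile("fish", "f1", {"Xx": 1.0})
        cfg = default_config(n_specimens=1, taxa=("fish",))
        with pytest.raises(ValueError, match="Xx"):
            expected_beam_spectra(prof, ScanCondition("dried", "body", 20.0, False), cfg)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            ScanCondition("dried", "body", 0.0, backed=False)


class TestStudyGrid:
    def test_single_taxon_design_has_960_exports(self):
        cfg = default_config(n_specimens=10, taxa=("fish",))
        grid = list(simulate._design_grid(cfg))
        # 10 specimens x 2 states x 3 locations x 4 dwells x 2 backings x 2 reps
        assert len(grid) == 960

    def test_same_seed_reproduces_study_byte_identically(self, tmp_path):
        cfg = default_config(n_specimens=1, taxa=("bird",), seed=9,
                             dwell_times=(20.0,))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg, out_dir=d1)
        simulate_study(cfg, out_dir=d2)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_null_state_effect_gives_unit_truth_ratio(self):
        cfg = default_config(n_specimens=2, taxa=("fish",), seed=3,
                             state_effect={}, dwell_times=(20.0,))
        table = simulate_concentration_table(cfg)
        piv = table.pivot_table(index=["specimen_id", "location", "element"],
                                columns="state", values="true_pct")
        ratio = piv["dried"] / piv["thawed"]
        assert np.allclose(ratio.dropna(), 1.0)

    def test_empty_profiles_rejected(self):
        cfg = default_config(n_specimens=1, taxa=("fish",))
        cfg = simulate.replace(cfg, profiles=())
        with pytest.raises(ValueError):
            simulate_study(cfg)


class TestPhysicalProperties:
    def test_relative_sd_increases_with_atomic_number(self):
        # equal concentrations; counts/pct/s decreasing in Z => precision
        # degrades with Z (monotone trend over >= 5 elements, 100 replicates)
        elements = ("Ca", "Fe", "Zn", "Sr", "Mo")
        prof = SpecimenProfile("fish", "f1", {e: 0.1 for e in elements},
                               individual_sd_log=0.0)
        cfg = default_config(profiles=(prof,), taxa=("fish",), seed=0,
                             state_effect={}, dwell_times=(40.0,), panel=elements,
                             backings=(False,), n_replicates=100)
        table = simulate_concentration_table(cfg)
        sub = table[(table.location == "body") & (table.state == "dried")]
        rel_sd = sub.groupby("element")["concentration_pct"].agg(
            lambda x: np.nanstd(x) / np.nanmean(x)
        )
        ordered = [rel_sd[e] for e in elements]  # elements in Z order
        assert all(b > a for a, b in zip(ordered, ordered[1:]))

    def test_thawed_characteristic_counts_below_dried(self):
        # moisture attenuates the characteristic lines at fixed truth
        prof = _fe_profile(1.0)
        cfg = default_config(profiles=(prof,), taxa=("fish",), state_effect={})
        ka = LINES.get("Fe", "Ka1")
        axis = cfg.energy_axis
        sigma = float(fwhm_kev(ka.energy_kev)) / 2.355
        window = np.abs(axis - ka.energy_kev) <= 4 * sigma
        beam = cfg.beam_energies.index(select_beam(ka.energy_kev))
        rng = np.random.default_rng(5)
        thawed, dried = [], []
        for _ in range(100):
            t = simulate.simulate_spectrum(
                prof, ScanCondition("thawed", "body", 20.0, False), cfg, rng)
            d = simulate.simulate_spectrum(
                prof, ScanCondition("dried", "body", 20.0, False), cfg, rng)
            thawed.append(t[beam][window].sum())
            dried.append(d[beam][window].sum())
        assert np.mean(thawed) < np.mean(dried)

    @pytest.mark.parametrize("thick,backed,expect_gain", [
        (False, True, True), (True, True, False), (False, False, False),
    ])
    def test_backing_gain_only_for_thin_backed(self, thick, backed, expect_gain):
        prof = _fe_profile(0.0)
        cfg = default_config(profiles=(prof,), taxa=("fish",), state_effect={})
        la1 = LINES.get("W", "La1")
        axis = cfg.energy_axis
        window = np.abs(axis - la1.energy_kev) <= 0.3
        cond = ScanCondition("dried", "body", 20.0, backed=backed, thick=thick)
        ref = ScanCondition("dried", "body", 20.0, backed=False, thick=True)
        exp = expected_beam_spectra(prof, cond, cfg)[2][window].sum()
        base = expected_beam_spectra(prof, ref, cfg)[2][window].sum()
        if expect_gain:
            assert exp > 1.4 * base
        else:
            assert exp == pytest.approx(base)


class TestConcentrationModel:
    def test_below_lod_has_no_value(self):
        cfg = default_config(n_specimens=1, taxa=("fish",), seed=1,
                             dwell_times=(20.0,))
        records, _ = simulate_study(cfg, spectra=False)
        recs = records[0].concentrations
        assert len(recs) == 42
        for c in recs:
            if c.below_lod:
                assert c.concentration_pct is None
            else:
                assert c.concentration_pct >= 0

    def test_fast_path_matches_export_concentrations(self):
        cfg = default_config(n_specimens=1, taxa=("fish",), seed=8,
                             dwell_times=(20.0,))
        records, _ = simulate_study(cfg, spectra=False)
        table = simulate_concentration_table(cfg)
        rec = records[0]
        sub = table[table.export_id == rec.metadata.export_id].set_index("element")
        for c in rec.concentrations:
            if c.below_lod:
                assert bool(sub.loc[c.element, "below_lod"])
            else:
                assert sub.loc[c.element, "concentration_pct"] == pytest.approx(
                    c.concentration_pct
                )
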