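import numpy as np
import pytest

from sightkit.compounds import MediumSpec, STYRENE
from sightkit.errors import DomainError, LayoutError, StepSizeError
from sightkit.oxygen_budget import oxygen_supply
from sightkit.partition import VialSystem, dose_for_target
from sightkit.vial_simulator import (
    SimulationParams,
    WellSpec,
    simulate,
    simulate_plate,
    write_plate,
)


class TestSingleVial:
    def test_no_solvent_consumes_all_glucose(self, noiseless_params):
        vial = simulate(noiseless_params, dose=0.0)
        assert vial.glucose[-1] == pytest.approx(0.0, abs=0.2)
        assert vial.od[-1] > 3.0

    def test_second_phase_leaves_residual_glucose(self, noiseless_params):
        vial = simulate(noiseless_params, dose=6.0)
        assert vial.solvent_c_medium == pytest.approx(2.8)
        assert vial.glucose[-1] > 1.0  # oxygen ran out first

    def test_no_growth_when_mu_max_is_zero(self):
        params = SimulationParams(mu_max=0.0, noise_sd=0.0)
        vial = simulate(params)
        assert np.all(vial.od == vial.od[0])
        assert np.all(vial.glucose == vial.glucose[0])
        assert np.ptp(vial.gv) == pytest.approx(0.0, abs=1e-9)

    def test_oxygen_conservation_and_supply_bound(self, noiseless_params):
        for dose in (0.0, 0.2, 6.0):
            vial = simulate(noiseless_params, dose=dose)
            supply = vial.o2_supply_total
            remaining = vial.o2_headspace[-1] + vial.o2_dissolved[-1]
            assert vial.o2_consumed + remaining == pytest.approx(
                supply, rel=1e-6
            )
            assert vial.o2_consumed <= supply * (1 + 1e-6)

    def test_trajectories_monotone_and_nonnegative(self, noiseless_params):
        vial = simulate(noiseless_params, dose=0.2)
        assert np.all(vial.od >= 0) and np.all(vial.glucose >= -1e-12)
        assert np.all(np.diff(vial.glucose) <= 1e-12)
        assert np.all(np.diff(vial.o2_headspace) <= 1e-9)

    def test_halving_dt_barely_changes_final_od(self, noiseless_params):
        from dataclasses import replace

        coarse = simulate(noiseless_params, dose=0.1)
        fine = simulate(replace(noiseless_params, dt=0.025), dose=0.1)
        assert abs(fine.od[-1] - coarse.od[-1]) / coarse.od[-1] < 0.005

    def test_lower_fill_improves_glucose_use_under_second_phase(
        self, noiseless_params
    ):
        """Less medium means more headspace oxygen per unit biomass, so the
        residual glucose left behind under a 1% v/v second phase shrinks as
        the fill volume drops."""
        residuals = []
        for v_medium in (1.0, 0.6, 0.3):
            system = VialSystem(v_medium=v_medium)
            vial = simulate(
                noiseless_params, system=system, dose=v_medium * 1e3 * 0.01
            )
            residuals.append(vial.glucose[-1])
            supply = oxygen_supply(system, MediumSpec()).n_o2_total
            assert vial.o2_consumed <= supply * (1 + 1e-6)
        assert residuals[0] > residuals[1] > residuals[2]
        assert residuals[0] > 1.0  # stress leaves glucose behind at high fill

    def test_unstable_step_size_rejected(self):
        with pytest.raises(StepSizeError):
            simulate(SimulationParams(mu_max=0.6, dt=0.2, noise_sd=0.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            SimulationParams(yield_biomass=1.2)
        with pytest.raises(DomainError):
            SimulationParams(dt=-0.1)


class TestPlate:
    def test_replicates_share_latent_curve_with_distinct_noise(self):
        layout = [
            WellSpec("A1", condition="rep"),
            WellSpec("A2", condition="rep"),
        ]
        ts, frame = simulate_plate(layout, SimulationParams(noise_sd=0.5), seed=3)
        a1, a2 = ts["A1"].to_numpy(), ts["A2"].to_numpy()
        assert not np.array_equal(a1, a2)  # distinct noise draws
        # identical latent trajectory: difference is pure noise around zero
        diff = a1 - a2
        assert abs(diff.mean()) < 0.2
        assert diff.std() == pytest.approx(0.5 * np.sqrt(2), rel=0.25)

    def test_fixed_seed_is_deterministic(self):
        layout = [WellSpec("A1"), WellSpec("B2", dose_ul=0.2)]
        ts1, _ = simulate_plate(layout, seed=11)
        ts2, _ = simulate_plate(layout, seed=11)
        assert ts1.equals(ts2)

    def test_dose_series_gives_monotone_final_od(self, default_system, styrene):
        doses = [0.0] + [
            dose_for_target(c, default_system, styrene) for c in (0.7, 1.4, 2.8)
        ] + [6.0]
        layout = [
            WellSpec(f"A{i+1}", dose_ul=d, condition=f"dose{i}")
            for i, d in enumerate(doses)
        ]
        ts, _ = simulate_plate(layout, SimulationParams(noise_sd=0.0), seed=0)
        finals = ts.iloc[-1].to_numpy()
        assert all(b <= a + 1e-9 for a, b in zip(finals, finals[1:]))

    def test_blank_wells_stay_at_background(self):
        ts, frame = simulate_plate(
            [WellSpec("A1", blank=True)], SimulationParams(noise_sd=0.0), seed=0
        )
        assert np.ptp(ts["A1"].to_numpy()) == pytest.approx(0.0, abs=1e-9)
        assert frame.loc["A1", "condition"] == "blank"

    def test_empty_layout_yields_header_only_frames(self):
        ts, frame = simulate_plate([], seed=0)
        assert ts.empty and frame.empty

    @pytest.mark.parametrize(
        "layout",
        [
            [WellSpec("A1"), WellSpec("A1")],  # duplicate
            [WellSpec("E1")],  # bad row
            [WellSpec("A7")],  # bad column
        ],
    )
    def test_invalid_layouts_rejected(self, layout):
        with pytest.raises(LayoutError):
            simulate_plate(layout, seed=0)

    def test_write_plate_round_trips_through_readers(self, tmp_path):
        from sightkit.growth_analysis import read_layout, read_timeseries

        layout = [WellSpec("A1"), WellSpec("A2", blank=True)]
        ts, frame = simulate_plate(layout, SimulationParams(noise_sd=0.1), seed=5)
        gv_path, layout_path = write_plate(ts, frame, tmp_path)
        ts_back = read_timeseries(gv_path)
        frame_back = read_layout(layout_path)
        assert np.allclose(ts_back.to_numpy(), ts.to_numpy())
        assert list(frame_back.index) == ["A1", "A2"]
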