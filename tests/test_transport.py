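"""Solver verification: analytic oracles, conservation, events, convergence."""

import numpy as np
import pytest

from bbbchip.geometry import build_default_layout
from bbbchip.transport import (
    ConcentrationField,
    ConfigurationError,
    DiffusionOperator,
    Grid,
    NumericalFailureError,
    ReplacementSchedule,
    SimulationConfig,
    SimulationHistory,
    SourceSpec,
    apply_replacement,
    discretize,
    profile_along_axis,
    run,
    stable_dt,
    step,
    total_mass,
)
from bbbchip.units import S_PER_DAY


def abeta_config(layout, **overrides):
    base = dict(
        layout=layout,
        solute="abeta",
        dx_um=25.0,
        dt_s=600.0,
        t_end_s=7 * S_PER_DAY,
        initial_values={"ren_3d_mc": 1.65e-7},
        sources=(SourceSpec("ren_3d_mc", 1.4e-12),),
        schedule=(ReplacementSchedule("bec_barrier_mc", S_PER_DAY, 0.0),),
        snapshot_interval_s=21600.0,
        scheme="implicit",
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestDiscretize:
    def test_single_region_cell_counts(self):
        g = Grid.uniform(100.0, 100.0, dx_um=10.0)
        assert (g.ny, g.nx) == (10, 10)
        assert len(g.material_names) == 1

    def test_halving_dx_doubles_counts(self):
        lay = build_default_layout(length_um=100.0)
        g1 = discretize(lay, 25.0)
        g2 = discretize(lay, 12.5)
        assert abs(g2.nx - 2 * g1.nx) <= 1
        assert abs(g2.ny - 2 * g1.ny) <= 1

    def test_material_map_matches_regions(self):
        lay = build_default_layout(length_um=100.0)
        g = discretize(lay, 25.0)
        for role in ("ren_media_mc", "ren_3d_mc", "barrier_mc",
                     "collagen_scaffold_mc", "bec_barrier_mc"):
            mask = g.region_mask(role)
            mat = lay.region(role).material
            assert all(
                g.material_names[i] == mat
                for i in np.unique(g.material_map[mask])
            )

    def test_membrane_face_at_interface(self):
        lay = build_default_layout(length_um=100.0)
        g = discretize(lay, 25.0)
        assert g.membrane_cols == (int(lay.barrier_interface_x_um / 25.0),)

    def test_thin_region_mode_needs_fine_grid(self):
        lay = build_default_layout(length_um=100.0)
        with pytest.raises(ConfigurationError, match="thin-region"):
            discretize(lay, 5.0, barrier_mode="thin_region")

    def test_thin_region_mode_marks_barrier_cells(self):
        lay = build_default_layout(
            widths_um={k: 20.0 for k in
                       ("ren_media_mc", "ren_3d_mc", "barrier_mc",
                        "collagen_scaffold_mc", "bec_barrier_mc")},
            length_um=10.0,
            barrier_thickness_um=2.0,
        )
        g = discretize(lay, 2.0, barrier_mode="thin_region")
        assert "barrier" in g.material_names
        col = g.material_map[0]
        barrier_cols = np.flatnonzero(col == g.material_names.index("barrier"))
        assert len(barrier_cols) == 1  # one 2-um strip against the interface

    def test_dx_exceeding_channel_width_rejected(self):
        lay = build_default_layout(length_um=100.0)
        with pytest.raises(ConfigurationError):
            discretize(lay, 600.0)  # wider than barrier_mc


class TestStep:
    def test_uniform_field_is_equilibrium(self):
        g = Grid.uniform(200.0, 100.0, dx_um=10.0)
        f = ConcentrationField(g, np.full((g.ny, g.nx), 3.3))
        dt = stable_dt(g, "abeta")
        for _ in range(20):
            f = step(f, dt, solute="abeta")
        assert np.allclose(f.values, 3.3, rtol=1e-12)

    def test_gaussian_variance_grows_as_2dt(self):
        # heat-kernel oracle: sigma^2(t) = sigma0^2 + 2 D t
        g = Grid.uniform(4000.0, 40.0, dx_um=10.0, material="medium")
        D = 1.8e-10
        op = DiffusionOperator(g, g.diffusivity_array("abeta"))
        x = g.x_centers_um() * 1e-6
        sigma0 = 100e-6
        values = np.tile(np.exp(-((x - 2000e-6) ** 2) / (2 * sigma0**2)), (g.ny, 1))
        t_end = 750.0
        n = int(np.ceil(t_end / (0.9 * stable_dt(g, "abeta"))))
        dt = t_end / n
        for _ in range(n):
            values = op.explicit_step(values, dt, None)
        w = values.mean(axis=0)
        w = w / w.sum()
        mu = (x * w).sum()
        var = (((x - mu) ** 2) * w).sum()
        assert var == pytest.approx(sigma0**2 + 2 * D * t_end, rel=0.01)

    def test_two_material_slab_steady_state(self):
        # series-resistance oracle: piecewise-linear profile, interface value
        # from flux continuity q = dC / (L1/D1 + L2/D2)
        g = Grid.slab([200.0, 300.0], ["medium", "collagen_scaffold"],
                      length_um=30.0, dx_um=5.0)
        d1, d2 = 1.8e-10, 0.62e-10
        fixed_mask = np.zeros((g.ny, g.nx), dtype=bool)
        fixed_mask[:, 0] = True
        fixed_mask[:, -1] = True
        fixed_values = np.zeros((g.ny, g.nx))
        fixed_values[:, 0] = 1.0
        op = DiffusionOperator(g, g.diffusivity_array("abeta"),
                               fixed_mask=fixed_mask, fixed_values=fixed_values)
        values = fixed_values.copy()
        for _ in range(200):
            values = op.implicit_step(values, 2000.0, None)
        x = g.x_centers_um()
        x_left, x_right, x_if = x[0], x[-1], 200.0
        q = 1.0 / ((x_if - x_left) * 1e-6 / d1 + (x_right - x_if) * 1e-6 / d2)
        c_if = 1.0 - q * (x_if - x_left) * 1e-6 / d1
        analytic = np.where(
            x <= x_if,
            1.0 - q * (x - x_left) * 1e-6 / d1,
            c_if - q * (x - x_if) * 1e-6 / d2,
        )
        assert np.max(np.abs(values.mean(axis=0) - analytic)) < 0.01

    def test_explicit_dt_bound_enforced(self):
        g = Grid.uniform(200.0, 100.0, dx_um=10.0)
        f = ConcentrationField(g, np.zeros((g.ny, g.nx)))
        with pytest.raises(ConfigurationError, match="stability"):
            step(f, 10 * stable_dt(g, "abeta"), solute="abeta")

    def test_maximum_principle_without_sources(self):
        g = Grid.uniform(300.0, 100.0, dx_um=10.0)
        rng = np.random.default_rng(7)
        values = rng.uniform(0.0, 1.0, size=(g.ny, g.nx))
        op = DiffusionOperator(g, g.diffusivity_array("abeta"))
        dt = 0.9 * stable_dt(g, "abeta")
        for _ in range(50):
            new = op.explicit_step(values, dt, None)
            assert new.max() <= values.max() + 1e-12
            assert new.min() >= values.min() - 1e-12
            values = new


class TestReplacement:
    def test_reset_zeroes_region_only(self, short_layout):
        g = discretize(short_layout, 25.0)
        f = ConcentrationField(g, np.ones((g.ny, g.nx)))
        out, removed = apply_replacement(f, "bec_barrier_mc", 0.0)
        lum = g.region_mask("bec_barrier_mc")
        assert out.values[lum].sum() == 0.0
        assert np.all(out.values[~lum] == 1.0)
        assert out.time == f.time

    def test_removed_mass_equals_region_content(self, short_layout):
        g = discretize(short_layout, 25.0)
        rng = np.random.default_rng(3)
        f = ConcentrationField(g, rng.uniform(size=(g.ny, g.nx)))
        lum = g.region_mask("bec_barrier_mc")
        expected = f.values[lum].sum() * g.cell_volume_m3
        _, removed = apply_replacement(f, "bec_barrier_mc", 0.0)
        assert removed == pytest.approx(expected, rel=1e-12)

    def test_unknown_region_raises(self, short_layout):
        g = discretize(short_layout, 25.0)
        f = ConcentrationField(g, np.zeros((g.ny, g.nx)))
        with pytest.raises(KeyError):
            apply_replacement(f, "no_such_region", 0.0)


class TestRun:
    def test_zero_everything_stays_zero(self, short_layout):
        cfg = abeta_config(short_layout, initial_values={}, sources=(),
                           t_end_s=S_PER_DAY)
        h = run(cfg)
        assert np.all(h.snapshots == 0.0)

    def test_sealed_source_mass_balance(self, short_layout):
        # M(t) = M0 + S * V_source * t on a sealed domain without events
        cfg = abeta_config(short_layout, schedule=(), t_end_s=2 * S_PER_DAY)
        h = run(cfg)
        m = h.total_mass_series()
        expected = m[0] + h.source_mass_rate_mol_s * h.times_s[-1]
        assert m[-1] == pytest.approx(expected, rel=1e-3)

    def test_seven_day_mass_conservation_with_events(self, short_layout):
        h = run(abeta_config(short_layout))
        m = h.total_mass_series()
        expected = (
            m[0] + h.source_mass_rate_mol_s * h.times_s[-1] - h.removed_mass_total()
        )
        assert abs(m[-1] - expected) / m[-1] < 1e-3

    def test_lumen_zero_after_each_replacement(self, short_layout):
        h = run(abeta_config(short_layout))
        lum = h.grid.region_mask("bec_barrier_mc")
        for day in range(1, 8):
            snap = h.snapshot_at(day * S_PER_DAY)
            assert snap.values[lum].max() == 0.0

    def test_event_log_times_are_period_multiples(self, short_layout):
        h = run(abeta_config(short_layout))
        times = [e["time_s"] for e in h.events]
        assert times == [day * S_PER_DAY for day in range(1, 8)]

    def test_explicit_and_implicit_agree(self, short_layout):
        # 40 kDa dextran influx over 10 min, both schemes
        common = dict(
            layout=short_layout,
            solute="dextran_40kda",
            dx_um=25.0,
            t_end_s=600.0,
            initial_values={"bec_barrier_mc": 1e-2},
            snapshot_interval_s=300.0,
            membrane_conductance_m_s=6.45e-8,
        )
        h_imp = run(SimulationConfig(dt_s=5.0, scheme="implicit", **common))
        h_exp = run(SimulationConfig(dt_s=2.0, scheme="explicit", **common))
        gel = h_imp.grid.region_mask("collagen_scaffold_mc")
        m_imp = h_imp.snapshots[-1][gel].sum()
        m_exp = h_exp.snapshots[-1][gel].sum()
        assert m_imp == pytest.approx(m_exp, rel=0.01)

    def test_grid_convergence_day3(self, short_layout):
        vals = []
        for dx in (25.0, 12.5):
            h = run(abeta_config(short_layout, dx_um=dx, t_end_s=3 * S_PER_DAY))
            face = h.grid.membrane_cols[0]
            vals.append(h.snapshot_at(3 * S_PER_DAY).values[:, face - 1].mean())
        assert vals[1] == pytest.approx(vals[0], rel=0.02)

    def test_barrier_conductance_monotonicity(self, short_layout):
        # leakier barrier -> more mass reaches the lumen before replacement
        masses = []
        for k in (1e-9, 1e-8):
            cfg = abeta_config(short_layout, t_end_s=S_PER_DAY, schedule=(),
                               membrane_conductance_m_s=k)
            h = run(cfg)
            lum = h.grid.region_mask("bec_barrier_mc")
            masses.append(h.snapshots[-1][lum].sum())
        assert masses[1] > masses[0]

    def test_lumen_stays_far_below_tissue(self, short_layout):
        # the tight barrier keeps luminal amyloid-beta well below the 3D
        # culture channel at all times (>= 10-fold for default geometry)
        h = run(abeta_config(short_layout))
        _, lum = h.region_mean_series("bec_barrier_mc")
        _, ren = h.region_mean_series("ren_3d_mc")
        ratio = ren[1:] / np.maximum(lum[1:], 1e-300)
        assert ratio.min() >= 10.0


class TestProfileAndMass:
    def test_uniform_field_flat_profile(self, short_layout):
        cfg = abeta_config(short_layout, sources=(), schedule=(),
                           initial_values={}, t_end_s=3600.0,
                           snapshot_interval_s=3600.0)
        h = run(cfg)
        prof = profile_along_axis(h, 0.0)
        assert len(prof.position_um) == h.grid.nx
        assert np.all(prof.concentration_mol_m3 == 0.0)
        assert [r for r, _ in prof.region_boundaries] == list(
            r.role for r in short_layout.regions
        )

    def test_profile_monotone_across_barrier_day3(self, short_layout):
        h = run(abeta_config(short_layout, t_end_s=3 * S_PER_DAY))
        prof = profile_along_axis(h, 3 * S_PER_DAY)
        x = prof.position_um
        c = prof.concentration_mol_m3
        # from the source channel outward through the gels into the lumen
        src_right = short_layout.region("ren_3d_mc").x_range[1]
        sel = x >= src_right
        assert np.all(np.diff(c[sel]) <= 1e-15)

    def test_profile_time_out_of_range(self, short_layout):
        h = run(abeta_config(short_layout, t_end_s=S_PER_DAY))
        with pytest.raises(KeyError):
            profile_along_axis(h, 9 * S_PER_DAY)

    def test_total_mass_uniform_field(self):
        g = Grid.uniform(100.0, 200.0, dx_um=10.0, height_um=150.0)
        f = ConcentrationField(g, np.ones((g.ny, g.nx)))
        vol = 100e-6 * 200e-6 * 150e-6
        assert total_mass(f) == pytest.approx(vol, rel=1e-12)
        assert total_mass(ConcentrationField(g, np.zeros((g.ny, g.nx)))) == 0.0

    def test_total_mass_additive_over_regions(self, short_layout):
        g = discretize(short_layout, 25.0)
        rng = np.random.default_rng(11)
        f = ConcentrationField(g, rng.uniform(size=(g.ny, g.nx)))
        parts = 0.0
        for role in (r.role for r in short_layout.regions):
            masked = f.values.copy()
            masked[~g.region_mask(role)] = 0.0
            parts += total_mass(ConcentrationField(g, masked))
        assert parts == pytest.approx(total_mass(f), rel=1e-12)


class TestHistoryPersistence:
    def test_hdf5_roundtrip(self, short_layout, tmp_path):
        h = run(abeta_config(short_layout, t_end_s=S_PER_DAY))
        path = tmp_path / "history.h5"
        h.to_hdf5(path)
        back = SimulationHistory.from_hdf5(path)
        assert np.array_equal(back.times_s, h.times_s)
        assert np.array_equal(back.snapshots, h.snapshots)
        assert back.events == h.events
        assert back.grid.membrane_cols == h.grid.membrane_cols
        assert back.config.solute == "abeta"
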