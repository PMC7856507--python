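"""Phantom generation, placement sampling and the electrode dose gain."""

import numpy as np
import pytest

from scalpdose.dvh import cumulative_dvh
from scalpdose.grids import build_shells
from scalpdose.radiobiology import SKIN_EMAMI_BURMAN, geud, lyman_ntcp
from scalpdose.synthetic import (
    DEFAULT_SCENARIO_FACTORS,
    ElectrodeArrayLayout,
    EnhancementModel,
    PhantomSpec,
    apply_enhancement,
    generate_phantom,
    placement_nearest_average,
    sample_placements,
    simulate_log_ntcp_table,
)

SMALL = PhantomSpec(head_radius_mm=60.0, voxel_mm=2.0)


class TestGeneratePhantom:
    def test_dose_near_prescription_in_ptv(self):
        body, ptv, grid = generate_phantom(SMALL)
        ptv_doses = grid.values[ptv.voxels]
        # deep PTV voxels reach the prescription (up to the plan hot spot)
        assert ptv_doses.max() >= SMALL.prescription_gy
        assert np.median(ptv_doses) > 0.9 * SMALL.prescription_gy

    def test_no_dose_outside_body(self):
        body, _, grid = generate_phantom(SMALL)
        assert np.all(grid.values[~body.voxels] == 0)

    def test_ptv_outside_head_rejected(self):
        with pytest.raises(ValueError, match="fit|outside"):
            PhantomSpec(head_radius_mm=50.0, ptv_radius_mm=45.0, ptv_depth_mm=30.0)

    def test_zero_prescription_gives_negligible_ntcp(self):
        spec = PhantomSpec(head_radius_mm=60.0, voxel_mm=2.0, prescription_gy=0.0)
        body, _, grid = generate_phantom(spec)
        shells = build_shells(body)
        dvh = cumulative_dvh(grid, shells.shell_0_2)
        assert lyman_ntcp(geud(dvh, SKIN_EMAMI_BURMAN), SKIN_EMAMI_BURMAN) < 1e-12

    def test_superficial_target_hotter_than_deep(self):
        hot = PhantomSpec(head_radius_mm=60.0, voxel_mm=2.0,
                          ptv_radius_mm=45.0, ptv_depth_mm=1.0)
        cold = PhantomSpec(head_radius_mm=60.0, voxel_mm=2.0,
                           ptv_radius_mm=30.0, ptv_depth_mm=14.0)
        geuds = {}
        for name, spec in (("hot", hot), ("cold", cold)):
            body, _, grid = generate_phantom(spec)
            shells = build_shells(body)
            geuds[name] = geud(
                cumulative_dvh(grid, shells.shell_0_2), SKIN_EMAMI_BURMAN
            )
        assert geuds["hot"] > geuds["cold"] + 5.0
        # deep small target: clinically negligible skin risk
        assert lyman_ntcp(geuds["cold"], SKIN_EMAMI_BURMAN) < 1e-3


class TestSamplePlacements:
    def test_empirical_sds_match_specification(self):
        layout = ElectrodeArrayLayout()
        placements = sample_placements(layout, 10_000, rng=123)
        offsets = np.array([p["anterior"] for p in placements])
        sds_cm = offsets.std(axis=0, ddof=1) / 10.0
        assert sds_cm[0] == pytest.approx(1.1, rel=0.03)
        assert sds_cm[1] == pytest.approx(0.7, rel=0.03)

    def test_confidence_ellipse_half_axes(self):
        # 95% ellipse half-axes are sqrt(chi2_2,0.95) ~ 2.448 times the SDs
        layout = ElectrodeArrayLayout()
        half_major = np.sqrt(5.991) * layout.placement_sd_major_cm
        half_minor = np.sqrt(5.991) * layout.placement_sd_minor_cm
        assert half_major == pytest.approx(2.7, abs=0.05)
        assert half_minor == pytest.approx(1.7, abs=0.05)

    def test_seed_reproducibility(self):
        layout = ElectrodeArrayLayout()
        a = sample_placements(layout, 5, rng=7)
        b = sample_placements(layout, 5, rng=7)
        for pa, pb in zip(a, b):
            for k in pa:
                assert np.array_equal(pa[k], pb[k])

    def test_nearest_average_minimizes_cost(self):
        layout = ElectrodeArrayLayout()
        placements = sample_placements(layout, 20, rng=9)
        chosen = placement_nearest_average(placements)
        means = {k: np.mean([p[k] for p in placements], axis=0)
                 for k in placements[0]}
        cost = lambda p: sum(np.sum((p[k] - means[k]) ** 2) for k in p)
        assert cost(chosen) == min(cost(p) for p in placements)


@pytest.fixture(scope="module")
def phantom():
    body, ptv, grid = generate_phantom(SMALL)
    return body, grid


class TestApplyEnhancement:
    def test_zero_gain_is_identity(self, phantom):
        body, grid = phantom
        model = EnhancementModel(buildup_gain=0.0, halo_gain=0.0)
        placements = sample_placements(ElectrodeArrayLayout(), 1, rng=0)
        out = apply_enhancement(grid, placements[0], model, body=body)
        assert np.array_equal(out.values, grid.values)

    def test_enhancement_confined_to_superficial_depth(self, phantom):
        body, grid = phantom
        model = EnhancementModel()
        placements = sample_placements(ElectrodeArrayLayout(), 1, rng=1)
        out = apply_enhancement(grid, placements[0], model, body=body)
        from scalpdose.grids import surface_depth_mm

        depth = surface_depth_mm(body)
        deep = body.voxels & (depth > model.max_depth_mm)
        assert np.array_equal(out.values[deep], grid.values[deep])
        changed = out.values != grid.values
        assert changed.any()
        assert np.all(depth[changed] <= model.max_depth_mm)

    def test_enhancement_is_a_bounded_multiplicative_gain(self, phantom):
        body, grid = phantom
        model = EnhancementModel()
        placements = sample_placements(ElectrodeArrayLayout(), 1, rng=2)
        out = apply_enhancement(grid, placements[0], model, body=body)
        ratio = np.divide(out.values, grid.values,
                          out=np.ones_like(grid.values),
                          where=grid.values > 0)
        assert ratio.min() >= 1.0 - 1e-12
        assert ratio.max() <= 1.0 + model.buildup_gain + 1e-12

    def test_deeper_shell_gain_smaller_than_superficial(self, phantom):
        body, grid = phantom
        model = EnhancementModel()
        placements = sample_placements(ElectrodeArrayLayout(), 1, rng=3)
        out = apply_enhancement(grid, placements[0], model, body=body)
        shells = build_shells(body)
        gain = lambda shell: np.mean(
            out.values[shell.voxels] / grid.values[shell.voxels]
        ) - 1.0
        assert gain(shells.shell_0_2) > gain(shells.shell_2_4) > 0

    def test_shell_average_increase_within_reported_bound(self, phantom):
        # under-array shell dose increase stays below 8.5%
        body, grid = phantom
        model = EnhancementModel()
        placements = sample_placements(ElectrodeArrayLayout(), 1, rng=4)
        out = apply_enhancement(grid, placements[0], model, body=body)
        shells = build_shells(body)
        sup = shells.shell_0_2.voxels
        changed = sup & (out.values > grid.values)
        mean_gain = np.mean(out.values[changed] / grid.values[changed]) - 1.0
        assert 0 < mean_gain <= 0.085


class TestCohortTables:
    def test_cohort_is_balanced_and_deterministic(self, small_cohort):
        t = small_cohort
        assert len(t) == 7 * 5
        assert set(t["scenario"]) == {1, 2, 3, 4, 5}
        assert t.groupby("patient").size().eq(5).all()
        # hot-spot ordering: the 0.05 cm^2 dose can never be below the
        # 25 cm^2 dose of the same layer
        assert (t["d005cm2_gy"] >= t["d25cm2_gy"] - 1e-9).all()

    def test_scenario_ordering_in_expectation(self, small_cohort):
        m = small_cohort.groupby("scenario")["d25cm2_gy"].mean()
        assert m[1] <= m[5] <= m[2]
        assert m[4] <= m[3]
        g = small_cohort.groupby("scenario")["geud_0_2_gy"].mean()
        assert g[1] < g[5] < g[2] <= g[3] + 0.5
        assert g[1] < g[4] < g[3]

    def test_mixing_convexity_per_patient(self, small_cohort):
        for _, grp in small_cohort.groupby("patient"):
            by = grp.set_index("scenario")
            assert (by.loc[4, "geud_0_2_gy"]
                    <= 0.4 * by.loc[1, "geud_0_2_gy"]
                    + 0.6 * by.loc[3, "geud_0_2_gy"] + 1e-9)
            lo = min(by.loc[1, "ntcp_fraction"], by.loc[3, "ntcp_fraction"])
            hi = max(by.loc[1, "ntcp_fraction"], by.loc[3, "ntcp_fraction"])
            assert lo - 1e-12 <= by.loc[4, "ntcp_fraction"] <= hi + 1e-12

    def test_depth_gradient_positive(self, small_cohort):
        assert (small_cohort["geud_2_4_gy"] > small_cohort["geud_0_2_gy"]).all()


class TestLogNtcpSimulator:
    def test_balanced_and_reproducible(self):
        a = simulate_log_ntcp_table(rng=5)
        b = simulate_log_ntcp_table(rng=5)
        assert a.equals(b)
        assert len(a) == 7 * len(DEFAULT_SCENARIO_FACTORS)

    def test_scenario_effects_recovered_on_average(self):
        rng = np.random.default_rng(6)
        logratios = []
        for _ in range(300):
            t = simulate_log_ntcp_table(rng=rng)
            by = t.pivot_table(index="patient", columns="scenario",
                               values="ntcp_fraction")
            logratios.append(np.log(by[3] / by[1]).mean())
        assert np.exp(np.mean(logratios)) == pytest.approx(
            DEFAULT_SCENARIO_FACTORS[3], rel=0.05
        )
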