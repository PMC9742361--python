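import numpy as np
import pytest

from flashox import (BoundarySupply, Geometry1D, GridSpec,
                     IrradiationProtocol, ScenarioPair, TissueParameters,
                     cuboid_reproduction_pair, midpoint_value, run_pair,
                     run_transient_bc_study, sweep)
from flashox.experiments import _pair_1d, REFERENCE_SUITE, reproduce
from flashox.solver import STAGE_IRRADIATION


def quick_pair(spacing=50.0, supply=10.1, dose=15.0, uhdr=125.0, let=1.2):
    geom = Geometry1D(spacing, BoundarySupply(supply), BoundarySupply(supply))
    return ScenarioPair.standard(geom, dose, uhdr_rate=uhdr, let_d=let)


class TestScenarioPair:
    def test_rejects_mismatched_doses(self):
        geom = Geometry1D(50.0)
        with pytest.raises(ValueError):
            ScenarioPair(geom, IrradiationProtocol(15.0, 0.5),
                         IrradiationProtocol(8.0, 125.0))

    def test_rejects_inverted_dose_rates(self):
        geom = Geometry1D(50.0)
        with pytest.raises(ValueError):
            ScenarioPair(geom, IrradiationProtocol(15.0, 125.0),
                         IrradiationProtocol(15.0, 0.5))


@pytest.fixture(scope="module")
def pair_50_10():
    return run_pair(quick_pair(), include_recovery=False)


class TestRunPair:
    def test_fedmf_at_least_one_and_cned_below_dose(self, pair_50_10):
        r = pair_50_10
        assert np.all(r.fields.fedmf >= 1.0 - 1e-6)
        for field in (r.fields.cned_conv, r.fields.cned_uhdr):
            assert np.all(field > 0.0)
            assert np.all(field <= 15.0 + 1e-9)
        assert np.all(r.fields.cned_uhdr <= r.fields.cned_conv + 1e-9)

    def test_zero_dose_pair_has_unit_fedmf(self):
        pair = ScenarioPair(Geometry1D(50.0, BoundarySupply(10.1),
                                       BoundarySupply(10.1)),
                            IrradiationProtocol(0.0, 0.5),
                            IrradiationProtocol(0.0, 125.0))
        r = run_pair(pair, include_recovery=False)
        assert r.fields.fedmf == pytest.approx(np.ones(r.domain.n_nodes))

    def test_conv_delivery_barely_perturbs_the_field(self):
        """The conventional delivery is quasi-static: the end field stays
        within 5% (or 0.25 μM where oxygen is nearly exhausted) of
        equilibrium."""
        for spacing, supply in ((50.0, 10.1), (175.0, 18.9), (250.0, 50.4)):
            r = run_pair(quick_pair(spacing, supply), include_recovery=False)
            end = r.conv_history.stage(STAGE_IRRADIATION).final.values
            diff = np.abs(end - r.equilibrium.values)
            limit = np.maximum(0.05 * r.equilibrium.values, 0.25)
            assert np.all(diff <= limit), (spacing, supply)

    def test_summary_metrics_are_consistent(self, pair_50_10):
        s = pair_50_10.summary()
        assert 0.0 <= s.hypoxic_fraction <= 1.0
        assert 0.0 <= s.fedmf_fraction <= 1.0
        assert s.mean_o > 0.0


class TestTransientSupply:
    def test_zero_alpha_reproduces_constant_bc(self):
        study = run_transient_bc_study(quick_pair(175.0, 18.9), 0.0, 10.0)
        assert study["delta"] == pytest.approx(0.0, abs=1e-12)

    def test_recruitment_raises_the_flash_fraction(self):
        study = run_transient_bc_study(quick_pair(175.0, 18.9), 0.2, 10.0)
        assert study["fedmf_fraction"] > study["baseline_fraction"]

    def test_uhdr_barely_sees_the_transient(self):
        """The UHDR delivery (0.12 s) ends long before the ~10 s
        recruitment: its end-of-irradiation midpoint moves < 1%."""
        base = run_pair(quick_pair(175.0, 18.9), include_recovery=False)
        tr = run_pair(quick_pair(175.0, 18.9).with_transient_supplies(
            0.2, 10.0), equilibrium=base.equilibrium, include_recovery=False)
        m0 = midpoint_value(base.uhdr_history.stage(STAGE_IRRADIATION).final,
                            base.domain)
        m1 = midpoint_value(tr.uhdr_history.stage(STAGE_IRRADIATION).final,
                            tr.domain)
        assert m1 == pytest.approx(m0, rel=0.01)

    def test_validates_arguments(self):
        with pytest.raises(ValueError):
            run_transient_bc_study(quick_pair(), -0.1, 10.0)
        with pytest.raises(ValueError):
            run_transient_bc_study(quick_pair(), 0.2, 0.0)


class TestMonotonicitySurfaces:
    def test_flash_fraction_nondecreasing_in_dose(self):
        fracs = [run_pair(_pair_1d(175, 18.9, d),
                          include_recovery=False).fedmf_fraction()
                 for d in (2.0, 8.0, 15.0)]
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_flash_fraction_nondecreasing_in_uhdr_rate(self):
        fracs = [run_pair(_pair_1d(175, 18.9, 15, uhdr_rate=r),
                          include_recovery=False).fedmf_fraction()
                 for r in (125.0, 285.0)]
        assert fracs[0] <= fracs[1]

    def test_proton_let_range_is_inert(self):
        base = run_pair(_pair_1d(175, 18.9, 15), include_recovery=False)
        fracs = [base.fedmf_fraction()]
        for let in (10.0, 20.0):
            fracs.append(run_pair(
                _pair_1d(175, 18.9, 15, let_d=let),
                equilibrium=base.equilibrium,
                include_recovery=False).fedmf_fraction())
        assert max(fracs) - min(fracs) <= 0.01


class TestSweep:
    def test_small_sweep_layout_and_determinism(self):
        kwargs = dict(spacings=[50.0], supplies=[10.1], doses=[2.0, 15.0],
                      uhdr_rates=[125.0], lets=[1.2],
                      grid=GridSpec(dx=1.0, steps_per_stage=300))
        a = sweep(**kwargs)
        b = sweep(**kwargs)
        assert list(a.columns)[0:3] == ["spacing_um", "supply_uM", "dose_Gy"]
        assert len(a) == 2
        assert a.to_csv(index=False) == b.to_csv(index=False)
        assert (a["fedmf_fraction_1p20"].iloc[0]
                <= a["fedmf_fraction_1p20"].iloc[1])

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            sweep([], [10.1], [15.0], [125.0], [1.2])


class TestCuboid:
    def test_solution_is_invariant_along_the_vessel_axis(self):
        """Vertical vessels + zero-flux top/bottom make every z-layer
        identical, so the FLASH fraction cannot depend on cuboid height."""
        fracs = {}
        for h in (5.0, 12.5):
            pair = cuboid_reproduction_pair(center_to_edge=50.0, dx=2.5,
                                            height=h)
            r = run_pair(pair, include_recovery=False)
            shaped = r.equilibrium.values.reshape(r.domain.shape)
            assert np.allclose(shaped, shaped[:, :, :1], rtol=0, atol=1e-12)
            fracs[h] = r.fedmf_fraction()
        assert fracs[5.0] == pytest.approx(fracs[12.5], abs=1e-12)


class TestReproduce:
    def test_subset_excludes_the_volume_scenario(self, tmp_path):
        table = reproduce(tmp_path, subset="1d")
        assert len(table) == len([s for s in REFERENCE_SUITE
                                  if s["kind"] == "1d"])
        assert (tmp_path / "report.csv").exists()
        assert (tmp_path / "report.json").exists()
        assert set(table["kind"]) == {"1d"}

    def test_rejects_unknown_subset(self):
        with pytest.raises(ValueError):
            reproduce(subset="4d")
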