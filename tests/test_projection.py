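"""Scenario specification, back-transform, and Monte-Carlo projection."""

import numpy as np
import pandas as pd
import pytest

import birdtrade as bt
from birdtrade.ordinal import CLMFit
from birdtrade.projection import DEFAULT_SCENARIOS
from birdtrade.scores import ROLE_DEMANDER, ROLE_SUPPLIER, RoleAssignment, VolumeBinCalibration


def make_fit(beta, theta=(-1.5, -0.5, 0.5, 1.5)):
    theta = np.asarray(theta, float)
    return CLMFit(
        beta=beta, theta=theta, se_beta=0.1, z=beta / 0.1, p_value=0.01,
        loglik=-10.0, loglik_null=-20.0, nagelkerke_r2=0.2, mcfadden_r2=0.1,
        n=100, converged=True,
    )


def degenerate_fit():
    """A fit whose predicted distribution is ~point mass on category 3."""
    return make_fit(0.0, theta=(-30.0, -20.0, 20.0, 30.0))


def make_roles(spec):
    df = pd.DataFrame(
        {"role": list(spec.values()), "total_exported": 1.0, "total_imported": 1.0},
        index=pd.Index(list(spec.keys()), name="country"),
    )
    return RoleAssignment(roles=df)


CALIB = VolumeBinCalibration(edges=np.linspace(1.0, 5.0, 6))


class TestScenarioSpecs:
    def test_default_scenario_ranges(self):
        assert DEFAULT_SCENARIOS["A"].supplier_range == (0, 2)
        assert DEFAULT_SCENARIOS["A"].demander_range == (0, 2)
        assert DEFAULT_SCENARIOS["B"].demander_range == (6, 8)
        assert DEFAULT_SCENARIOS["C"].supplier_range == (6, 8)
        assert DEFAULT_SCENARIOS["D"].supplier_range == (6, 8)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bt.ScenarioSpec("X", (0, 9), (0, 2))


class TestScoreToVolume:
    def test_midpoint_arithmetic(self):
        assert bt.score_to_volume(1, CALIB) == pytest.approx(10**1.4)
        assert bt.score_to_volume(5, CALIB) == pytest.approx(10**4.6)

    def test_round_trip_fixes_midpoints(self):
        for T in range(1, 6):
            v = bt.score_to_volume(T, CALIB)
            assert bt.real_trade_score(v, CALIB) == T
            assert bt.score_to_volume(bt.real_trade_score(v, CALIB), CALIB) == v

    def test_category_out_of_range(self):
        with pytest.raises(ValueError):
            bt.score_to_volume(0, CALIB)


class TestProjectScenario:
    def test_deterministic_channel_hits_bin_midpoint(self):
        roles = make_roles({"SAA": ROLE_SUPPLIER})
        proj = bt.project_scenario(
            degenerate_fit(), None, roles, DEFAULT_SCENARIOS["A"], CALIB, None,
            n_reps=50, seed=1,
        )
        row = proj.country_summary.iloc[0]
        assert row["modal_category"] == 3
        assert row["mean_volume"] == pytest.approx(10**3.0)
        assert row["count_3"] == 50

    def test_seeded_runs_reproduce(self):
        roles = make_roles({"SAA": ROLE_SUPPLIER, "DAA": ROLE_DEMANDER})
        kwargs = dict(n_reps=25, seed=7)
        p1 = bt.project_scenario(
            make_fit(0.5), make_fit(-0.5), roles, DEFAULT_SCENARIOS["C"], CALIB, CALIB, **kwargs
        )
        p2 = bt.project_scenario(
            make_fit(0.5), make_fit(-0.5), roles, DEFAULT_SCENARIOS["C"], CALIB, CALIB, **kwargs
        )
        pd.testing.assert_frame_equal(p1.country_summary, p2.country_summary)
        pd.testing.assert_frame_equal(p1.rep_totals, p2.rep_totals)

    def test_category_counts_sum_to_reps(self):
        roles = make_roles({"SAA": ROLE_SUPPLIER, "DAA": ROLE_DEMANDER})
        proj = bt.project_scenario(
            make_fit(0.5), make_fit(-0.5), roles, DEFAULT_SCENARIOS["B"], CALIB, CALIB,
            n_reps=200, seed=2,
        )
        counts = proj.country_summary[[f"count_{k}" for k in range(1, 6)]].sum(axis=1)
        assert (counts == 200).all()

    def test_positive_slope_orders_supplier_volumes_by_range(self):
        roles = make_roles({f"S{i:02d}": ROLE_SUPPLIER for i in range(10)})
        fit = make_fit(0.5)
        low = bt.project_scenario(
            fit, None, roles, DEFAULT_SCENARIOS["A"], CALIB, None, n_reps=2000, seed=3
        )
        high = bt.project_scenario(
            fit, None, roles, DEFAULT_SCENARIOS["D"], CALIB, None, n_reps=2000, seed=3
        )
        assert high.rep_totals["supplier"].mean() > low.rep_totals["supplier"].mean()

    def test_missing_fit_for_present_role_rejected(self):
        roles = make_roles({"DAA": ROLE_DEMANDER})
        with pytest.raises(ValueError):
            bt.project_scenario(
                make_fit(0.5), None, roles, DEFAULT_SCENARIOS["A"], CALIB, None
            )

    def test_modal_mode_is_deterministic_in_category(self):
        roles = make_roles({"SAA": ROLE_SUPPLIER})
        proj = bt.project_scenario(
            degenerate_fit(), None, roles, DEFAULT_SCENARIOS["A"], CALIB, None,
            n_reps=10, seed=4, mode="modal",
        )
        assert proj.country_summary.iloc[0]["count_3"] == 10


class TestGlobalTotals:
    def test_single_country_deterministic_total(self):
        roles = make_roles({"SAA": ROLE_SUPPLIER})
        proj = bt.project_scenario(
            degenerate_fit(), None, roles, DEFAULT_SCENARIOS["A"], CALIB, None,
            n_reps=20, seed=5,
        )
        totals = bt.global_totals(proj)
        sup = totals[totals["role"] == ROLE_SUPPLIER].iloc[0]
        assert sup["mean_total"] == pytest.approx(10**3.0)
        assert sup["total_lo"] == pytest.approx(sup["total_hi"])

    def test_two_identical_countries_double_the_total(self):
        one = bt.project_scenario(
            degenerate_fit(), None, make_roles({"SAA": ROLE_SUPPLIER}),
            DEFAULT_SCENARIOS["A"], CALIB, None, n_reps=20, seed=6,
        )
        two = bt.project_scenario(
            degenerate_fit(), None,
            make_roles({"SAA": ROLE_SUPPLIER, "SAB": ROLE_SUPPLIER}),
            DEFAULT_SCENARIOS["A"], CALIB, None, n_reps=20, seed=6,
        )
        assert bt.global_totals(two).iloc[0]["mean_total"] == pytest.approx(
            2 * bt.global_totals(one).iloc[0]["mean_total"]
        )

    def test_interval_width_shrinks_with_more_replicates(self):
        roles = make_roles({f"S{i:02d}": ROLE_SUPPLIER for i in range(5)})
        fit = make_fit(0.3)

        def se_of_mean(n_reps):
            proj = bt.project_scenario(
                fit, None, roles, DEFAULT_SCENARIOS["D"], CALIB, None,
                n_reps=n_reps, seed=8,
            )
            reps = proj.rep_totals["supplier"]
            return reps.std() / np.sqrt(len(reps))

        assert se_of_mean(4000) < se_of_mean(100) / 3.0
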