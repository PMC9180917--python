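"""Ground-truth structure and determinism of the synthetic world generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency, skew

import birdtrade as bt
from birdtrade.scores import ROLE_DEMANDER, ROLE_SUPPLIER


class TestGenerateWorld:
    def test_deterministic_given_seed(self):
        cfg = bt.SyntheticWorldConfig(seed=99)
        w1, w2 = bt.generate_world(cfg), bt.generate_world(cfg)
        pd.testing.assert_frame_equal(w1.countries, w2.countries)

    def test_invalid_config_rejected(self):
        with pytest.raises(bt.ConfigurationError):
            bt.generate_world(bt.SyntheticWorldConfig(n_suppliers=1))
        with pytest.raises(bt.ConfigurationError):
            bt.generate_world(bt.SyntheticWorldConfig(thresholds=(1, 0.5, 2, 3)))
        with pytest.raises(bt.ConfigurationError):
            bt.generate_world(bt.SyntheticWorldConfig(volume_log_sd=-1))

    def test_scores_are_sums_of_bins_and_volumes_in_bins(self, small_world):
        df = small_world.countries
        assert (
            df["expected_score"]
            == df["law_weakness_bin"] + df["barrier_weakness_bin"]
        ).all()
        assert df["expected_score"].between(0, 8).all()
        logs = np.log10(df["volume"])
        edges = small_world.log_edges
        T = df["trade_category"].to_numpy()
        assert (logs > edges[T - 1]).all() and (logs <= edges[T]).all()

    def test_zero_slope_makes_categories_independent_of_score(self):
        cfg = bt.SyntheticWorldConfig(
            n_suppliers=5000, n_demanders=2, beta_supplier=0.0, seed=13
        )
        df = bt.generate_world(cfg).countries
        sup = df[df["role"] == ROLE_SUPPLIER]
        contingency = pd.crosstab(sup["expected_score"], sup["trade_category"])
        _, p, _, _ = chi2_contingency(contingency)
        assert p > 0.01

    def test_category_frequencies_match_closed_form_clm(self):
        cfg = bt.SyntheticWorldConfig(
            n_suppliers=100_000, n_demanders=2, beta_supplier=0.5, seed=14
        )
        world = bt.generate_world(cfg)
        sup = world.countries[world.countries["role"] == ROLE_SUPPLIER]
        theta = np.asarray(cfg.thresholds)
        checked = 0
        for E in range(9):
            grp = sup[sup["expected_score"] == E]
            if len(grp) < 8000:  # cells large enough that +/-0.02 is ~4 sigma
                continue
            checked += 1
            emp_cum = np.array([(grp["trade_category"] <= k).mean() for k in (1, 2, 3, 4)])
            np.testing.assert_allclose(emp_cum, expit(theta - 0.5 * E), atol=0.02)
        assert checked >= 4

    def test_volume_skewness_profile(self):
        cfg = bt.SyntheticWorldConfig(n_suppliers=500, n_demanders=500, seed=15)
        vols = bt.generate_world(cfg).countries["volume"].to_numpy()
        assert skew(vols) > 0
        assert abs(skew(np.log10(vols))) < 0.3


class TestEmitTradeRecords:
    def test_quantities_conserve_true_volumes(self, small_world):
        records = bt.emit_trade_records(small_world, "preban")
        df = records.records
        for _, ctry in small_world.countries.iterrows():
            if ctry["role"] == ROLE_SUPPLIER:
                got = df.loc[df["exporter"] == ctry["country"], "exporter_qty"].sum()
            else:
                got = df.loc[df["importer"] == ctry["country"], "importer_qty"].sum()
            assert got == ctry["volume"]

    def test_period_year_windows(self, small_world):
        pre = bt.emit_trade_records(small_world, "preban").records["year"]
        post = bt.emit_trade_records(small_world, "postban").records["year"]
        assert pre.between(1995, 2005).all()
        assert post.between(2006, 2017).all()
        with pytest.raises(ValueError):
            bt.emit_trade_records(small_world, "duringban")

    def test_records_pass_the_wild_live_bird_filter(self, small_world):
        records = bt.emit_trade_records(small_world, "preban")
        kept = bt.filter_wild_live_birds(records, (1995, 2005))
        assert len(kept) == len(records)

    def test_csv_round_trip_recovers_every_volume_exactly(self, small_world, tmp_path):
        records = bt.emit_trade_records(small_world, "postban")
        path = tmp_path / "trade.csv"
        bt.write_trade_csv(records, path)
        totals = bt.aggregate_totals(bt.filter_wild_live_birds(bt.read_trade_csv(path), (2006, 2017))).totals
        for _, ctry in small_world.countries.iterrows():
            col = "total_exported" if ctry["role"] == ROLE_SUPPLIER else "total_imported"
            assert totals.loc[ctry["country"], col] == ctry["volume"]


class TestEmitCovariates:
    def test_noiseless_covariates_recover_true_bins(self):
        cfg = bt.SyntheticWorldConfig(covariate_noise_sd=0.0, seed=21)
        world = bt.generate_world(cfg)
        cov = bt.emit_covariates(world, "preban").table.set_index("country")
        for role in (ROLE_SUPPLIER, ROLE_DEMANDER):
            grp = world.countries[world.countries["role"] == role]
            barrier_col = "export_cost" if role == ROLE_SUPPLIER else "import_tariff"
            law_bins = bt.bin_axis_weakness(
                cov.loc[grp["country"], "rule_of_law"], higher_is_stronger=True
            )
            barrier_bins = bt.bin_axis_weakness(
                cov.loc[grp["country"], barrier_col], higher_is_stronger=True
            )
            assert (law_bins == grp["law_weakness_bin"].to_numpy()).all()
            assert (barrier_bins == grp["barrier_weakness_bin"].to_numpy()).all()

    def test_ban_shift_translates_demander_tariffs_uniformly(self):
        # noiseless so the period-specific noise streams cannot mask the shift
        cfg0 = bt.SyntheticWorldConfig(ban_shift=0.2, covariate_noise_sd=0.0, seed=22)
        world0 = bt.generate_world(cfg0)
        pre0 = bt.emit_covariates(world0, "preban").table.set_index("country")
        post0 = bt.emit_covariates(world0, "postban").table.set_index("country")
        d0 = world0.countries.loc[world0.countries["role"] == ROLE_DEMANDER, "country"]
        shift = (
            post0.loc[d0, "import_tariff"].to_numpy()
            - pre0.loc[d0, "import_tariff"].to_numpy()
        )
        np.testing.assert_allclose(shift, 0.2, atol=1e-12)

    def test_noisy_covariates_recover_most_expected_scores(self):
        cfg = bt.SyntheticWorldConfig(
            n_suppliers=100, n_demanders=100, covariate_noise_sd=0.05, seed=23
        )
        world = bt.generate_world(cfg)
        cov = bt.emit_covariates(world, "preban").table.set_index("country")
        hits = total = 0
        for role in (ROLE_SUPPLIER, ROLE_DEMANDER):
            grp = world.countries[world.countries["role"] == role]
            barrier_col = "export_cost" if role == ROLE_SUPPLIER else "import_tariff"
            E_hat = bt.bin_axis_weakness(
                cov.loc[grp["country"], "rule_of_law"], True
            ) + bt.bin_axis_weakness(cov.loc[grp["country"], barrier_col], True)
            hits += (np.abs(E_hat - grp["expected_score"].to_numpy()) <= 1).sum()
            total += len(grp)
        assert hits / total >= 0.90
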