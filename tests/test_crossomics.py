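"""Activity ratios, fold-change concordance, time series, limitation calls."""

import numpy as np
import pandas as pd
import pytest

from uccomics.capability_engine import evaluate_capabilities
from uccomics.crossomics import (
    activity_ratio,
    aggregate_subsystem,
    concordance_regression,
    limitation_signatures,
    marker_timeseries,
    pair_fold_changes,
    sequential_fold_changes,
)
from uccomics.transcript_quant import RPKMMatrix, rpkm_per_organism
from uccomics.synthetic_community import sample_read_counts, simulate_foldchange_records

from conftest import make_genome


def samples_frame(days=(7, 14), reps=3):
    rows = [
        {"sample_id": f"d{d:02d}r{r}", "day": d, "replicate": r}
        for d in days
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


class TestActivityRatio:
    def test_elementwise_ratio(self):
        t = pd.DataFrame({"s1": [0.5, 0.5]}, index=["a", "b"])
        p = pd.DataFrame({"s1": [0.5, 0.25]}, index=["a", "b"])
        rho = activity_ratio(t, p)
        assert rho.loc["a", "s1"] == pytest.approx(1.0)
        assert rho.loc["b", "s1"] == pytest.approx(2.0)

    def test_zero_protein_share_is_nan(self):
        t = pd.DataFrame({"s1": [0.6, 0.4]}, index=["a", "b"])
        p = pd.DataFrame({"s1": [1.0, 0.0]}, index=["a", "b"])
        rho = activity_ratio(t, p)
        assert np.isnan(rho.loc["b", "s1"])

    def test_mismatched_samples_rejected(self):
        t = pd.DataFrame({"s1": [1.0]}, index=["a"])
        p = pd.DataFrame({"s2": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            activity_ratio(t, p)

    def test_renormalization_preserves_rho_ordering(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"s1": rng.dirichlet(np.ones(5))}, index=list("abcde"))
        p = pd.DataFrame({"s1": rng.dirichlet(np.ones(5))}, index=list("abcde"))
        base = activity_ratio(t, p)["s1"]
        scaled = activity_ratio(t * 0.37 / t.sum(), p)["s1"]
        assert list(base.sort_values().index) == list(scaled.sort_values().index)


class TestFoldChanges:
    def test_share_doubling(self):
        meta = samples_frame()
        shares = pd.DataFrame(
            {s: [0.1 if meta.loc[s, "day"] == 7 else 0.2] for s in meta.index}, index=["org"]
        )
        records = sequential_fold_changes(shares, meta)
        assert records.loc[0, "fc"] == pytest.approx(2.0)

    def test_constant_shares_give_unit_fc(self):
        meta = samples_frame(days=(7, 14, 21))
        shares = pd.DataFrame({s: [0.3] for s in meta.index}, index=["org"])
        records = sequential_fold_changes(shares, meta)
        assert np.allclose(records["fc"], 1.0)

    def test_planted_dynamics_match_hand_ratios(self, default_sim):
        truth = default_sim.truth.read_shares
        records = sequential_fold_changes(truth, default_sim.samples)
        days = sorted(default_sim.samples["day"].unique())
        col = {d: default_sim.samples.index[default_sim.samples["day"] == d][0] for d in days}
        for _, row in records.iterrows():
            expected = truth.loc[row["genome_id"], col[row["day_to"]]] / truth.loc[
                row["genome_id"], col[row["day_from"]]
            ]
            assert row["fc"] == pytest.approx(expected)

    def test_single_time_point_rejected(self):
        meta = samples_frame(days=(7,))
        shares = pd.DataFrame({s: [1.0] for s in meta.index}, index=["org"])
        with pytest.raises(ValueError):
            sequential_fold_changes(shares, meta)


class TestConcordanceRegression:
    def test_perfect_concordance(self):
        fc = [0.5, 1.0, 2.0, 4.0]
        fit = concordance_regression(fc, fc)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_linear_scale_closed_form(self):
        fit = concordance_regression([1, 2, 3], [1, 2, 4], scale="linear")
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-2 / 3)
        assert fit.r_squared == pytest.approx(81 / 84)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            concordance_regression([1, 2], [1, 2])

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            concordance_regression([2, 2, 2], [1, 2, 3])

    def test_noise_degrades_r_squared_monotonically(self, default_sim):
        fits = []
        for sigma in (0.05, 0.25, 0.6):
            rec = simulate_foldchange_records(default_sim, noise_sigma=sigma, seed=11)
            fits.append(concordance_regression(rec["fc_t"], rec["fc_p"]))
        assert fits[0].slope == pytest.approx(1.0, abs=0.05)
        assert fits[0].r_squared >= 0.99
        assert fits[0].r_squared > fits[1].r_squared > fits[2].r_squared


class TestMarkerTimeseriesAndSubsystems:
    def _fixture(self):
        meta = samples_frame(days=(7, 14), reps=3)
        cat = [
            make_genome(
                "org",
                {"c1": 1500},
                [("org_pstS", "c1", 1, 600, ["pstS"]), ("org_rpoC", "c1", 701, 1400, ["rpoC"])],
                seed=5,
            )
        ]
        values = pd.DataFrame(
            {
                "d07r1": [100.0, 50.0], "d07r2": [110.0, 55.0], "d07r3": [90.0, 45.0],
                "d14r1": [400.0, 50.0], "d14r2": [380.0, 52.0], "d14r3": [420.0, 48.0],
            },
            index=["org_pstS", "org_rpoC"],
        )
        return values, meta, cat

    def test_series_matches_groupby_oracle(self):
        values, meta, cat = self._fixture()
        series = marker_timeseries(values, meta, cat, "org", ["pstS"])["pstS"]
        oracle = values.loc["org_pstS"].groupby(meta["day"]).mean()
        assert np.allclose(series["mean"].values, oracle.values)
        assert (series["ci_low"] <= series["mean"]).all()
        assert (series["mean"] <= series["ci_high"]).all()

    def test_planted_fourfold_rise_in_log2(self):
        values, meta, cat = self._fixture()
        series = marker_timeseries(values, meta, cat, "org", ["pstS"])["pstS"]
        assert series["log2_mean"].iloc[-1] - series["log2_mean"].iloc[0] == pytest.approx(
            2.0, abs=0.1
        )

    def test_unknown_marker_lists_available(self):
        values, meta, cat = self._fixture()
        with pytest.raises(KeyError, match="pstS"):
            marker_timeseries(values, meta, cat, "org", ["phoA"])

    def test_subsystem_sum_and_errors(self):
        values, meta, cat = self._fixture()
        total = aggregate_subsystem(values, ["org_pstS", "org_rpoC"], cat)
        assert total["d07r1"] == pytest.approx(150.0)
        assert aggregate_subsystem(values, ["org_rpoC"], cat)["d07r1"] == pytest.approx(50.0)
        with pytest.raises(ValueError):
            aggregate_subsystem(values, [], cat)


class TestLimitationSignatures:
    def _rpkm_fixture(self, pst_series, amt_series, glnA_series, reps=3, noise=0.0, seed=0):
        days = (7, 14, 21, 28)
        meta = samples_frame(days=days, reps=reps)
        cat = [
            make_genome(
                "org",
                {"c1": 3000},
                [
                    ("org_pstS", "c1", 1, 600, ["pstS"]),
                    ("org_amt", "c1", 701, 1300, ["amt"]),
                    ("org_glnA", "c1", 1401, 2000, ["glnA"]),
                ],
                seed=6,
            )
        ]
        rng = np.random.default_rng(seed)
        rows = {}
        for gene, series in (
            ("org_pstS", pst_series), ("org_amt", amt_series), ("org_glnA", glnA_series)
        ):
            rows[gene] = {
                s: series[days.index(meta.loc[s, "day"])] * (1 + noise * rng.normal())
                for s in meta.index
            }
        values = pd.DataFrame(rows).T
        rpkm = RPKMMatrix(values=values, basis=None, samples=meta)
        caps = evaluate_capabilities(cat)
        return rpkm, caps, cat

    def test_fourfold_pst_rise_scores_two(self):
        rpkm, caps, cat = self._rpkm_fixture(
            (100, 160, 250, 400), (10, 10, 10, 10), (10, 10, 10, 10)
        )
        sig = limitation_signatures(rpkm, caps, cat)
        assert sig.loc["org", "p_score"] == pytest.approx(2.0)
        assert bool(sig.loc["org", "p_limited"])
        assert sig.loc["org", "p_transporter"] == "pstS"

    def test_identical_amt_glnA_series_are_coupled(self):
        traj = (100, 55, 130, 50)
        rpkm, caps, cat = self._rpkm_fixture((10, 10, 10, 10), traj, traj)
        sig = limitation_signatures(rpkm, caps, cat)
        assert sig.loc["org", "n_coupling"] == "coupled"
        assert sig.loc["org", "n_correlation"] == pytest.approx(1.0)

    def test_flat_glnA_with_declining_amt_is_decoupled(self):
        rpkm, caps, cat = self._rpkm_fixture(
            (10, 10, 10, 10), (400, 250, 160, 100), (200, 200, 200, 200)
        )
        sig = limitation_signatures(rpkm, caps, cat)
        assert sig.loc["org", "n_coupling"] == "decoupled"

    def test_low_expression_class(self):
        rpkm, caps, cat = self._rpkm_fixture(
            (10, 10, 10, 10), (0.01, 0.01, 0.01, 0.01), (0.2, 0.2, 0.2, 0.2)
        )
        sig = limitation_signatures(rpkm, caps, cat)
        assert sig.loc["org", "n_coupling"] == "low_expression"

    def test_p_score_invariant_to_organism_depth_rescaling(self, default_sim):
        gcm = sample_read_counts(default_sim, seed=13)
        caps = evaluate_capabilities(default_sim.catalog, proteins=default_sim.proteins)
        rpkm1 = rpkm_per_organism(gcm, default_sim.catalog)
        # double one organism's counts everywhere: P scores unchanged
        boosted = gcm.counts.copy()
        mask = boosted.index.str.startswith("gamma05_")
        boosted.loc[mask] *= 2
        gcm2 = type(gcm)(counts=boosted, samples=gcm.samples, unassigned=gcm.unassigned)
        rpkm2 = rpkm_per_organism(gcm2, default_sim.catalog)
        s1 = limitation_signatures(rpkm1, caps, default_sim.catalog)
        s2 = limitation_signatures(rpkm2, caps, default_sim.catalog)
        assert s1.loc["gamma05", "p_score"] == pytest.approx(s2.loc["gamma05", "p_score"])


def test_pair_fold_changes_merges_on_interval(default_sim):
    t = sequential_fold_changes(default_sim.truth.read_shares, default_sim.samples).rename(
        columns={"fc": "fc_t"}
    )
    p = sequential_fold_changes(default_sim.truth.protein_shares, default_sim.samples).rename(
        columns={"fc": "fc_p"}
    )
    paired = pair_fold_changes(t.drop(columns="omic"), p.drop(columns="omic"))
    assert len(paired) == 19 * 3
    assert {"fc_t", "fc_p"} <= set(paired.columns)
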