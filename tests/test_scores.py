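import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phiscore.rank import gaussianize_plate
from phiscore.scores import (
    NullCalibration,
    estimate_null_calibration,
    k_scores,
    phi_scores,
    phi_scores_normalized,
    sampling_variance,
    score_plate,
    score_screen,
    score_to_pvalue,
    ssmd_scores,
    summarize_perturbations,
    z_scores,
)


def _summaries(plate):
    return summarize_perturbations(gaussianize_plate(plate))


class TestSummaries:
    def test_cell_counts_pool_wells(self, small_plate):
        summ = _summaries(small_plate)
        by_pert = summ.set_index("perturbation_id")["n_cells"]
        assert by_pert["si00"] == 60  # 2 wells x 30 cells
        assert by_pert["neg"] == 300  # 10 control wells pooled

    def test_counts_partition_plate(self, small_plate):
        summ = _summaries(small_plate)
        assert summ["n_cells"].sum() == len(small_plate)

    def test_mean_cell_score(self):
        g = pd.DataFrame(
            {
                "plate_id": "P1",
                "well_id": ["W1"] * 3 + ["W2"] * 2,
                "perturbation_id": ["a"] * 3 + ["b"] * 2,
                "role": "sample",
                "value": [1.0, 2.0, 3.0, 4.0, 5.0],
                "cell_score": [-1.0, 0.0, 1.0, 0.5, 1.5],
            }
        )
        summ = summarize_perturbations(g)
        assert summ.set_index("perturbation_id").loc["a", "mean_cell_score"] == 0.0


class TestNullCalibration:
    N = 72_000
    n = np.full(10_000, 600)

    def test_pure_sampling_noise_gives_tiny_tau2(self):
        v = sampling_variance(self.n, self.N)
        xbar = np.random.default_rng(11).normal(0.0, np.sqrt(v))
        cal = estimate_null_calibration(xbar, self.n, self.N)
        assert abs(cal.tau2) < 0.001

    def test_recovers_overdispersion(self):
        v = sampling_variance(self.n, self.N)
        xbar = np.random.default_rng(12).normal(0.0, np.sqrt(v + 0.04))
        cal = estimate_null_calibration(xbar, self.n, self.N)
        assert cal.tau2 == pytest.approx(0.04, abs=0.01)

    def test_robust_to_strong_actives(self):
        """30% of perturbations shifted far out of the null must not inflate
        the calibrated extra-variance (outlier-rejection regime)."""
        v = sampling_variance(self.n, self.N)
        rng = np.random.default_rng(13)
        xbar = rng.normal(0.0, np.sqrt(v + 0.04))
        clean = estimate_null_calibration(xbar, self.n, self.N).tau2
        xbar[:3000] += 1.0
        contaminated = estimate_null_calibration(xbar, self.n, self.N).tau2
        assert contaminated == pytest.approx(clean, rel=0.25)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            estimate_null_calibration(np.zeros(5), np.full(5, 10), 100)


class TestPhi:
    def test_arithmetic(self):
        """N=40, n=10, mean score 0.5, tau2=0: v = (1/10)(30/39) = 0.076923,
        so phi = 0.5 / sqrt(v) = 1.80278."""
        summ = pd.DataFrame({"n_cells": [10], "mean_cell_score": [0.5]})
        cal = NullCalibration(tau2=0.0, N=40)
        assert phi_scores(summ, cal).iloc[0] == pytest.approx(1.8027756377, rel=1e-9)

    def test_zero_mean_is_zero(self):
        summ = pd.DataFrame({"n_cells": [10, 200], "mean_cell_score": [0.0, 0.0]})
        assert (phi_scores(summ, NullCalibration(0.1, 1000)) == 0).all()

    def test_cell_number_penalty(self):
        """At fixed mean score, |phi| strictly increases with cell count."""
        ns = np.array([5, 20, 100, 400, 900])
        summ = pd.DataFrame({"n_cells": ns, "mean_cell_score": 0.3})
        phi = phi_scores(summ, NullCalibration(0.01, 1000)).to_numpy()
        assert np.all(np.diff(phi) > 0)

    def test_whole_plate_perturbation_rejected(self):
        summ = pd.DataFrame({"n_cells": [100], "mean_cell_score": [0.1]})
        with pytest.raises(ValueError, match="whole plate"):
            phi_scores(summ, NullCalibration(0.0, 100))


class TestPhiNormalized:
    def test_matches_phi_on_exchangeable_plate(self, small_plate):
        """With controls drawn from the same distribution as samples, the
        control-normalized score agrees with the whole-plate score up to the
        sampling noise of the control-well center (10 wells here)."""
        table = score_plate(small_plate, methods=("phi", "phin"))
        samples = table[table["role"] == "sample"]
        assert np.corrcoef(samples["phin"], samples["phi"])[0, 1] > 0.995
        assert abs((samples["phin"] - samples["phi"]).mean()) < 1.2

    def test_controls_at_plate_median_reduce_to_phi(self, small_plate):
        """Control cells pinned at the plate median give a zero center, so
        the control-normalized score collapses onto the whole-plate score."""
        plate = small_plate.copy()
        neg = plate["role"] == "neg_control"
        plate.loc[neg, "value"] = plate.loc[~neg, "value"].median()
        table = score_plate(plate, methods=("phi", "phin"))
        samples = table[table["role"] == "sample"]
        np.testing.assert_allclose(samples["phin"], samples["phi"], atol=0.25)

    def test_resists_active_fraction_drift(self):
        """With 40% strong actives, inactive perturbations keep median phin
        near 0 while whole-plate phi drifts."""
        rng = np.random.default_rng(5)
        rows = []
        well = 0
        for p in range(40):
            active = p < 16
            for _ in range(2):
                well += 1
                vals = rng.lognormal(5, 1, 40)
                if active:
                    vals = vals * 0.4
                rows.append(pd.DataFrame({
                    "plate_id": "P1", "well_id": f"W{well:03d}",
                    "perturbation_id": f"si{p:02d}", "role": "sample", "value": vals,
                }))
        for c in range(10):
            well += 1
            rows.append(pd.DataFrame({
                "plate_id": "P1", "well_id": f"W{well:03d}",
                "perturbation_id": "neg", "role": "neg_control",
                "value": rng.lognormal(5, 1, 40),
            }))
        plate = pd.concat(rows, ignore_index=True)
        table = score_plate(plate, methods=("phi", "phin"))
        inactive = table[table["perturbation_id"].str.match(r"si(1[6-9]|[23][0-9])")]
        med_phi = inactive["phi"].median()
        med_phin = inactive["phin"].median()
        assert abs(med_phin) < 0.5
        assert med_phi > med_phin + 0.5  # actives pushed the plate reference down

    def test_needs_enough_control_wells(self, small_plate):
        few = small_plate[~small_plate["well_id"].isin([f"W{w:02d}" for w in range(25, 32)])]
        with pytest.raises(ValueError, match="negative-control wells"):
            score_plate(few, methods=("phin",))


class TestZ:
    def test_arithmetic(self):
        """Aggregates (1..5): z of a=5 is (5-3)/1.5811 = 1.2649."""
        summ = pd.DataFrame({
            "mean_value": [1.0, 2.0, 3.0, 4.0, 5.0],
            "role": ["sample"] * 5,
        })
        z = z_scores(summ, reference_aggregates=np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert z.iloc[4] == pytest.approx(1.2649110641, rel=1e-9)
        assert z.iloc[2] == 0.0

    def test_robust_resists_outlier(self):
        rng = np.random.default_rng(3)
        agg = rng.normal(10, 2, 40)
        summ = pd.DataFrame({"mean_value": agg, "role": "sample"})
        z0 = z_scores(summ, robust=False)
        r0 = z_scores(summ, robust=True)
        summ2 = summ.copy()
        summ2.loc[0, "mean_value"] = 1e6
        z1 = z_scores(summ2, robust=False)
        r1 = z_scores(summ2, robust=True)
        rel_robust = np.abs((r1[1:] - r0[1:]) / r0[1:]).median()
        rel_plain = np.abs((z1[1:] - z0[1:]) / z0[1:]).median()
        assert rel_robust < 0.05
        assert rel_plain > 0.5

    def test_degenerate_plate_rejected(self):
        summ = pd.DataFrame({"mean_value": np.full(10, 2.0), "role": "sample"})
        with pytest.raises(ValueError, match="degenerate"):
            z_scores(summ)


class TestSSMD:
    def _plate(self, a_vals, b_vals):
        df = pd.DataFrame({
            "plate_id": "P1",
            "well_id": ["W1"] * len(a_vals) + ["W2"] * len(b_vals),
            "perturbation_id": ["a"] * len(a_vals) + ["b"] * len(b_vals),
            "role": "sample",
            "value": list(a_vals) + list(b_vals),
        })
        df["cell_score"] = 0.0
        return df

    def test_closed_form(self):
        """mu=1, s=1 against mu=0, s=1 gives 1/sqrt(2)."""
        a = 1 / np.sqrt(2)
        plate = self._plate([1 - a, 1 + a], [-a, a])  # exact sample moments
        summ = summarize_perturbations(plate)
        ssmd = ssmd_scores(plate, summ).set_axis(summ["perturbation_id"])
        assert ssmd["a"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=400)
        plate = self._plate(vals[:200], vals[200:])
        summ = summarize_perturbations(plate)
        assert abs(ssmd_scores(plate, summ).iloc[0]) < 0.2

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        p1 = self._plate(a, b)
        p2 = self._plate(2 * a, 2 * b)
        s1 = ssmd_scores(p1, summarize_perturbations(p1))
        s2 = ssmd_scores(p2, summarize_perturbations(p2))
        np.testing.assert_allclose(s1, s2, rtol=1e-12)


class TestKScore:
    def _gauss(self, plate):
        return gaussianize_plate(plate)

    def test_full_separation_downward(self):
        plate = pd.DataFrame({
            "plate_id": "P1", "well_id": ["W1", "W1", "W2", "W2"],
            "perturbation_id": ["a", "a", "b", "b"], "role": "sample",
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        g = self._gauss(plate)
        summ = summarize_perturbations(g)
        k = k_scores(g, summ).set_axis(summ["perturbation_id"])
        assert k["a"] == pytest.approx(-1.0)
        assert k["b"] == pytest.approx(1.0)

    def test_null_subsample_small(self):
        rng = np.random.default_rng(6)
        n = 2000
        plate = pd.DataFrame({
            "plate_id": "P1", "well_id": "W1",
            "perturbation_id": np.where(rng.random(n) < 0.1, "a", "rest"),
            "role": "sample", "value": rng.normal(size=n),
        })
        g = self._gauss(plate)
        summ = summarize_perturbations(g)
        k = k_scores(g, summ).set_axis(summ["perturbation_id"])
        n_a = summ.set_index("perturbation_id").loc["a", "n_cells"]
        n_r = n - n_a
        n_eff = n_a * n_r / (n_a + n_r)
        assert abs(k["a"]) < 1.63 / np.sqrt(n_eff)

    def test_matches_bruteforce_oracle(self):
        """Fast merged-ECDF K equals the O(n^2) sup over all sample points."""
        rng = np.random.default_rng(7)
        for trial in range(200):
            n_a = rng.integers(2, 12)
            n_r = rng.integers(2, 20)
            values = np.round(rng.normal(size=n_a + n_r), 1)  # force ties
            plate = pd.DataFrame({
                "plate_id": "P1", "well_id": "W1",
                "perturbation_id": ["a"] * n_a + ["r"] * n_r,
                "role": "sample", "value": values,
            })
            g = self._gauss(plate)
            summ = summarize_perturbations(g)
            k = k_scores(g, summ).set_axis(summ["perturbation_id"])["a"]
            own = g.loc[g["perturbation_id"] == "a", "cell_score"].to_numpy()
            rest = g.loc[g["perturbation_id"] == "r", "cell_score"].to_numpy()
            pts = np.unique(np.concatenate([own, rest]))  # ascending
            diffs = np.array([(rest <= x).mean() - (own <= x).mean() for x in pts])
            brute = diffs[np.argmax(np.abs(diffs))]  # smallest point wins ties
            assert k == pytest.approx(brute, abs=1e-12), f"trial {trial}"


class TestPValues:
    def test_tail_at_three(self):
        assert score_to_pvalue(3.0, sided="upper") == pytest.approx(1.3499e-3, rel=1e-4)

    def test_zero_is_half(self):
        assert score_to_pvalue(0.0, sided="upper") == 0.5

    def test_quantile_roundtrip(self):
        assert score_to_pvalue(1.95996, sided="upper") == pytest.approx(0.025, rel=1e-4)

    def test_two_sided_doubles(self):
        np.testing.assert_allclose(
            score_to_pvalue(np.array([-2.0, 2.0]), sided="two"),
            2 * stats.norm.sf(2.0),
        )


class TestInvariance:
    def test_phi_k_invariant_z_ssmd_not(self, small_plate):
        base = score_plate(small_plate, methods=("phi", "z", "ssmd", "k"))
        warped = small_plate.copy()
        warped["value"] = np.exp(warped["value"] / warped["value"].max() * 5)
        other = score_plate(warped, methods=("phi", "z", "ssmd", "k"))
        np.testing.assert_allclose(other["phi"], base["phi"], atol=1e-10)
        np.testing.assert_allclose(other["k"], base["k"], atol=1e-10)
        assert not np.allclose(other["z"], base["z"], atol=1e-3)
        assert not np.allclose(other["ssmd"], base["ssmd"], atol=1e-3)

    def test_plate_order_permutation(self, small_plate):
        p2 = small_plate.copy()
        p2["plate_id"] = "P2"
        p2["value"] = p2["value"].sample(frac=1, random_state=1).to_numpy()
        screen = pd.concat([small_plate, p2], ignore_index=True)
        flipped = pd.concat([p2, small_plate], ignore_index=True)
        a = score_screen(screen, methods=("phi",)).sort_values(
            ["plate_id", "perturbation_id"]).reset_index(drop=True)
        b = score_screen(flipped, methods=("phi",)).sort_values(
            ["plate_id", "perturbation_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


def test_score_screen_stouffer_combination(small_plate):
    p2 = small_plate.copy()
    p2["plate_id"] = "P2"
    screen = pd.concat([small_plate, p2], ignore_index=True)
    per_plate = score_screen(screen, methods=("phi",))
    combined = score_screen(screen, methods=("phi",), combine_plates=True)
    one = per_plate[per_plate["perturbation_id"] == "si03"]["phi"]
    merged = combined.set_index("perturbation_id").loc["si03", "phi"]
    assert merged == pytest.approx(one.sum() / np.sqrt(2), rel=1e-9)
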