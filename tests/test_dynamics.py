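"""Condition-pair dynamics: segmentation, change profiles, enrichment, patches."""

import numpy as np
import pandas as pd
import pytest

from methylib.design import load_rest_pwm
from methylib.dynamics import (
    change_percentile_profile,
    composite_profile,
    constitutive_patches,
    dhs_change_association,
    motif_enrichment,
    segment_methylome,
)
from methylib.synthetic import generate_condition_variant, generate_ground_truth


def _methylome(truth: pd.DataFrame) -> pd.DataFrame:
    return truth.rename(columns={"true_methylation": "methylation"})[
        ["contig", "pos", "methylation"]
    ]


def _predictions(truth: pd.DataFrame, model) -> pd.DataFrame:
    out = truth[["contig", "pos"]].copy()
    out["predicted"] = model.predict(truth["cg_density"].to_numpy())
    return out


@pytest.fixture(scope="module")
def condition_pair(dynamics_genome, model):
    genome, islands, sites, truth, cuts = dynamics_genome
    diff = generate_condition_variant(
        truth, "differentiation", model=model, lost_factors={"Oct4"}, seed=31
    )
    cancer = generate_condition_variant(truth, "cancer", epsilon=30.0, islands=islands, seed=32)
    return genome, islands, sites, truth, diff, cancer


class TestSegmentation:
    def _calls(self, meths, contig="c"):
        return pd.DataFrame(
            {"contig": contig, "pos": np.arange(len(meths)) * 20, "methylation": meths}
        )

    def test_uniformly_methylated_contig_is_one_fmr(self):
        segs = segment_methylome(self._calls([90.0] * 50))
        assert len(segs) == 1
        assert segs.iloc[0]["class"] == "FMR"
        assert segs.iloc[0]["n_cgs"] == 50

    def test_long_hypo_run_is_umr(self):
        meths = [90.0] * 10 + [5.0] * 35 + [90.0] * 10
        segs = segment_methylome(self._calls(meths))
        assert list(segs["class"]) == ["FMR", "UMR", "FMR"]
        assert segs[segs["class"] == "UMR"].iloc[0]["n_cgs"] == 35

    def test_short_hypo_run_is_lmr(self):
        meths = [90.0] * 10 + [20.0] * 8 + [90.0] * 10
        segs = segment_methylome(self._calls(meths))
        assert list(segs["class"]) == ["FMR", "LMR", "FMR"]

    def test_runs_below_min_length_absorbed_into_fmr(self):
        meths = [90.0] * 10 + [10.0] * 2 + [90.0] * 10
        segs = segment_methylome(self._calls(meths), min_run=3)
        assert list(segs["class"]) == ["FMR"]

    def test_partition_every_cg_in_exactly_one_segment(self, pipeline):
        calls = pipeline.calls.copy()
        # pipeline calls are per fragment; treat fragments as contigs
        calls["contig"] = calls["fragment"]
        segs = segment_methylome(calls[["contig", "pos", "methylation"]])
        counted = 0
        for _, seg in segs.iterrows():
            sel = calls[
                (calls["contig"] == seg["contig"])
                & (calls["pos"] >= seg["start"])
                & (calls["pos"] < seg["end"])
            ]
            assert len(sel) == seg["n_cgs"]
            counted += seg["n_cgs"]
        assert counted == len(calls)


class TestChangeProfile:
    def test_identical_methylomes_give_zero_profile(self, condition_pair, model):
        *_, truth, _, _ = condition_pair
        prof = change_percentile_profile(_methylome(truth), _methylome(truth), _predictions(truth, model))
        occupied = prof[prof["n"] > 0]
        assert (occupied["percentile_change"] == 0).all()
        assert (occupied["median_change"] == 0).all()

    def test_differentiation_gain_tracks_prediction(self, condition_pair, model):
        _, _, _, truth, diff, _ = condition_pair
        prof = change_percentile_profile(_methylome(truth), _methylome(diff), _predictions(truth, model))
        solid = prof[prof["n"] >= 50]
        assert len(solid) >= 5
        dev = (solid["percentile_change"] - solid["bin_mid"]).abs()
        assert dev.max() <= 10.0

    def test_differentiation_gain_bounded_by_prediction(self, condition_pair, model):
        # the central claim: factor loss moves methylation up toward, but
        # not beyond, what CG density alone predicts
        _, _, _, truth, diff, _ = condition_pair
        prof = change_percentile_profile(_methylome(truth), _methylome(diff), _predictions(truth, model))
        occupied = prof[prof["n"] > 0]
        assert (occupied["percentile_change"] <= occupied["bin_hi"] + 5.0).all()

    def test_cancer_gain_positive_in_low_prediction_bins(self, condition_pair, model):
        _, _, _, truth, _, cancer = condition_pair
        prof = change_percentile_profile(_methylome(truth), _methylome(cancer), _predictions(truth, model))
        low = prof[(prof["bin_hi"] <= 20) & (prof["n"] > 0)]
        assert len(low) >= 1
        assert (low["percentile_change"] > 0).all()

    def test_cancer_dominates_differentiation_below_twenty_percent(self, condition_pair, model):
        _, _, _, truth, diff, cancer = condition_pair
        preds = _predictions(truth, model)
        pd_diff = change_percentile_profile(_methylome(truth), _methylome(diff), preds)
        pd_canc = change_percentile_profile(_methylome(truth), _methylome(cancer), preds)
        low = pd_diff["bin_hi"] <= 20
        occupied = low & (pd_diff["n"] > 0)
        assert (
            pd_canc.loc[occupied, "percentile_change"].to_numpy()
            > pd_diff.loc[occupied, "percentile_change"].to_numpy()
        ).all()

    def test_disjoint_methylomes_rejected(self, condition_pair, model):
        *_, truth, _, _ = condition_pair
        other = _methylome(truth).copy()
        other["pos"] += 1  # CG coordinates no longer shared
        with pytest.raises(ValueError, match="share no CG"):
            change_percentile_profile(_methylome(truth), other, _predictions(truth, model))


class TestDhsChangeAssociation:
    def test_two_condition_association(self, condition_pair, model):
        genome, islands, sites, truth, _, _ = condition_pair
        # independently measured second condition: same genome, Oct4 gone
        sites_b = sites[sites["factor"] != "Oct4"]
        truth_b, _ = generate_ground_truth(genome, sites_b, seed=77)
        dhs_a = truth[["contig", "pos", "dhs_cuts"]].rename(columns={"dhs_cuts": "cuts"})
        dhs_b = truth_b[["contig", "pos", "dhs_cuts"]].rename(columns={"dhs_cuts": "cuts"})
        tab = dhs_change_association(
            _methylome(truth), _methylome(truth_b), dhs_a, dhs_b,
            truth[["contig", "pos", "cg_density"]],
            density_bins=[0, 4, 8, 12, 50],
            dhs_delta_bins=[-60, -10, -4, 4, 60],
        )
        # at CG-poor sites, strong DHS loss goes with strong methylation
        # gain, larger than in the noise-only central bin
        low = tab[tab["density_lo"] == 0]
        loss_cell = low[low["dhs_delta_lo"] == -60].iloc[0]
        center_cell = low[low["dhs_delta_lo"] == -4].iloc[0]
        assert loss_cell["median_change"] > center_cell["median_change"] + 30
        # at very CG rich stretches the association disappears
        rich = tab[(tab["density_lo"] == 12) & (tab["n"] > 0)]
        assert (rich["median_change"].abs() < 5).all()

    def test_identical_dhs_changes_center_on_zero(self, condition_pair):
        *_, truth, _, _ = condition_pair
        dhs = truth[["contig", "pos", "dhs_cuts"]].rename(columns={"dhs_cuts": "cuts"})
        tab = dhs_change_association(
            _methylome(truth), _methylome(truth), dhs, dhs,
            truth[["contig", "pos", "cg_density"]],
            density_bins=[0, 10, 50], dhs_delta_bins=[-10, 0, 10],
        )
        occupied = tab[tab["n"] > 0]
        assert (occupied["median_change"] == 0).all()

    def test_empty_cells_retained(self, condition_pair):
        *_, truth, _, _ = condition_pair
        dhs = truth[["contig", "pos", "dhs_cuts"]].rename(columns={"dhs_cuts": "cuts"})
        tab = dhs_change_association(
            _methylome(truth), _methylome(truth), dhs, dhs,
            truth[["contig", "pos", "cg_density"]],
            density_bins=[0, 25, 50], dhs_delta_bins=[-2000, -1000, 1000],
        )
        assert (tab["n"] == 0).any()
        assert len(tab) == 4


class TestMotifEnrichment:
    def test_planted_motif_enriched_at_changing_cgs(self, condition_pair, model):
        genome, islands, sites, truth, diff, _ = condition_pair
        changed = (diff["true_methylation"] - truth["true_methylation"]).abs() > 5
        pwm = load_rest_pwm()  # the planted site motif is this consensus
        table = motif_enrichment(
            truth.loc[changed, ["contig", "pos"]],
            truth.loc[~changed, ["contig", "pos"]],
            genome,
            {"REST_synthetic": pwm},
            n_permutations=100,
            seed=1,
        )
        row = table.iloc[0]
        assert row["n_changing_hits"] > row["n_control_hits"]
        assert row["log2_ratio"] > 1.0
        assert row["p_value"] < 0.05

    def test_identical_sets_give_zero_ratio(self, condition_pair):
        genome, *_ , truth, _, _ = condition_pair
        subset = truth.iloc[:200][["contig", "pos"]]
        pwm = load_rest_pwm()
        table = motif_enrichment(
            subset, subset, genome, {"REST_synthetic": pwm}, n_permutations=20, seed=2
        )
        assert table.iloc[0]["log2_ratio"] == pytest.approx(0.0)

    def test_absent_pwm_flagged(self, condition_pair):
        genome, *_, truth, _, _ = condition_pair
        from methylib.design import PWM

        # a motif that cannot occur: the generator never writes poly-G runs
        counts = np.zeros((4, 30))
        counts[2] = 10.0
        pwm = PWM("polyG", counts)
        table = motif_enrichment(
            truth.iloc[:100][["contig", "pos"]],
            truth.iloc[100:300][["contig", "pos"]],
            genome,
            {"polyG": pwm},
            n_permutations=20,
            seed=3,
        )
        row = table.iloc[0]
        assert row["absent"] and row["n_changing_hits"] == 0

    def test_empty_set_rejected(self, condition_pair):
        genome, *_, truth, _, _ = condition_pair
        with pytest.raises(ValueError, match="non-empty"):
            motif_enrichment(
                truth.iloc[:0][["contig", "pos"]], truth[["contig", "pos"]], genome, {}
            )


class TestConstitutivePatches:
    def test_dense_island_is_one_patch(self, model):
        # uniform density 12 -> prediction ~15.3% < 20%: the whole island
        preds = pd.DataFrame(
            {"contig": "c", "pos": np.arange(30) * 8, "predicted": model.predict(12.0)}
        )
        islands = pd.DataFrame({"contig": ["c"], "start": [0], "end": [240]})
        patches, summary = constitutive_patches(preds, islands)
        assert len(patches) == 1
        assert patches.iloc[0]["n_cgs"] == 30
        assert summary["fraction_islands_with_patch"] == 1.0
        assert summary["fraction_island_cgs_in_patches"] == 1.0

    def test_sparse_island_has_no_patch(self, model):
        # density 5 -> prediction ~66% > 20%
        preds = pd.DataFrame(
            {"contig": "c", "pos": np.arange(20) * 20, "predicted": model.predict(5.0)}
        )
        islands = pd.DataFrame({"contig": ["c"], "start": [0], "end": [400]})
        patches, summary = constitutive_patches(preds, islands)
        assert patches.empty
        assert summary["fraction_islands_with_patch"] == 0.0

    def test_single_low_cg_not_a_patch(self, model):
        pred = np.full(10, 60.0)
        pred[4] = 10.0
        preds = pd.DataFrame({"contig": "c", "pos": np.arange(10) * 10, "predicted": pred})
        islands = pd.DataFrame({"contig": ["c"], "start": [0], "end": [100]})
        patches, _ = constitutive_patches(preds, islands, min_run=2)
        assert patches.empty

    def test_empty_island_list(self, model):
        preds = pd.DataFrame({"contig": [], "pos": [], "predicted": []})
        islands = pd.DataFrame(columns=["contig", "start", "end"])
        patches, summary = constitutive_patches(preds, islands)
        assert patches.empty
        assert np.isnan(summary["fraction_islands_with_patch"])


class TestCompositeProfile:
    def test_methylation_dips_at_bound_sites(self, condition_pair):
        genome, islands, sites, truth, _, _ = condition_pair
        prof = composite_profile(_methylome(truth), sites, max_dist=1000, bin_width=50)
        near = prof[prof["dist_bin_mid"].abs() <= 100]["mean_methylation"].mean()
        far = prof[prof["dist_bin_mid"].abs() >= 600]["mean_methylation"].mean()
        assert near < far - 10
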