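"""The synthetic genome / ground-truth / read generator."""

import numpy as np
import pandas as pd
import pytest

from methylib.cg_model import SigmoidModel, cg_density, cg_positions
from methylib.library_design import Fragment
from methylib.synthetic import (
    SyntheticGenomeSpec,
    generate_condition_variant,
    generate_genome,
    generate_ground_truth,
    simulate_bisulfite_reads,
)


class TestGenerateGenome:
    def test_determinism(self):
        spec = SyntheticGenomeSpec(n_contigs=2, contig_length=20_000, seed=42)
        out1 = generate_genome(spec)
        out2 = generate_genome(spec)
        assert out1[0] == out2[0]
        pd.testing.assert_frame_equal(out1[1], out2[1])
        pd.testing.assert_frame_equal(out1[2], out2[2])

    def test_no_islands_gives_background_density_everywhere(self):
        spec = SyntheticGenomeSpec(
            n_contigs=1, contig_length=30_000, n_islands=0, background_density=2.0,
            n_tf_sites=0, seed=1,
        )
        genome, islands, _ = generate_genome(spec)
        assert islands.empty
        seq = genome["chr1"]
        dens = [cg_density(seq[i : i + 300]) for i in range(0, len(seq) - 300, 300)]
        assert np.all(np.abs(np.array(dens) - 2.0) <= 2.0)

    def test_island_realized_density_within_two_counts(self):
        spec = SyntheticGenomeSpec(
            n_contigs=1, contig_length=30_000, n_islands=5,
            island_density_range=(15.0, 15.0), n_tf_sites=4, seed=3,
        )
        genome, islands, _ = generate_genome(spec)
        for _, isl in islands.iterrows():
            seq = genome[isl["contig"]][int(isl["start"]) : int(isl["end"])]
            assert 13.0 <= cg_density(seq) <= 17.0

    def test_islands_non_overlapping_and_motifs_planted(self):
        spec = SyntheticGenomeSpec(n_contigs=1, contig_length=40_000, seed=4)
        genome, islands, sites = generate_genome(spec)
        isl = islands.sort_values("start")
        assert (isl["start"].to_numpy()[1:] >= isl["end"].to_numpy()[:-1]).all()
        for _, site in sites.iterrows():
            planted = genome[site["contig"]][int(site["start"]) : int(site["end"])]
            assert planted == spec.tf_motif

    def test_oversized_islands_error_names_contig(self):
        spec = SyntheticGenomeSpec(
            n_contigs=1, contig_length=5_000, n_islands=4,
            island_length_range=(2000, 2000), seed=0,
        )
        with pytest.raises(ValueError, match="chr1"):
            generate_genome(spec)

    def test_density_out_of_range_rejected(self):
        spec = SyntheticGenomeSpec(island_density_range=(10.0, 60.0))
        with pytest.raises(ValueError, match=r"\[0, 50\]"):
            spec.validate()


class TestGroundTruth:
    def test_unbound_cgs_follow_sigmoid_exactly(self, small_genome, model):
        _, genome, _, sites = small_genome
        truth, _ = generate_ground_truth(genome, sites, seed=9)
        unbound = truth[truth["bound_factors"] == ""]
        expected = model.predict(unbound["cg_density"].to_numpy())
        np.testing.assert_allclose(unbound["true_methylation"].to_numpy(), expected)

    def test_zero_tf_effect_is_pure_sigmoid(self, small_genome, model):
        _, genome, _, sites = small_genome
        truth, _ = generate_ground_truth(genome, sites, tf_effect=0.0, seed=9)
        expected = model.predict(truth["cg_density"].to_numpy())
        np.testing.assert_allclose(truth["true_methylation"].to_numpy(), expected)

    def test_bound_strictly_lower_than_sigmoid(self, small_genome, model):
        _, genome, _, sites = small_genome
        truth, _ = generate_ground_truth(genome, sites, tf_effect=90.0, seed=9)
        bound = truth[truth["bound_factors"] != ""]
        assert len(bound) > 0
        expected = model.predict(bound["cg_density"].to_numpy())
        assert (bound["true_methylation"].to_numpy() < expected).all()

    def test_every_truth_position_is_a_cg(self, small_genome):
        _, genome, _, sites = small_genome
        truth, _ = generate_ground_truth(genome, sites, seed=9)
        for contig, grp in truth.groupby("contig"):
            seq = genome[contig]
            assert all(seq[p : p + 2] == "CG" for p in grp["pos"])

    def test_dhs_cuts_elevated_at_bound_sites(self, small_genome):
        _, genome, _, sites = small_genome
        truth, _ = generate_ground_truth(
            genome, sites, dhs_rate_bound=15.0, dhs_rate_unbound=15.0, seed=9
        )
        bound = truth["bound_factors"] != ""
        assert truth.loc[bound, "dhs_cuts"].mean() > truth.loc[~bound, "dhs_cuts"].mean() + 5

    def test_cg_free_genome_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no CG"):
            truth, _ = generate_ground_truth({"chr1": "ATAT" * 100}, None, seed=0)
        assert truth.empty

    def test_positive_slope_rejected(self, small_genome):
        _, genome, _, sites = small_genome
        with pytest.raises(ValueError):
            generate_ground_truth(genome, sites, b=0.3, seed=0)


def _fragment_with_uniform_truth(meth_value):
    """A fragment whose CGs all carry one methylation value."""
    seq = "TT" + "ACGTTTAT" * 12 + "TT"
    genome = {"chrT": seq}
    frag = Fragment("chrT", 0, len(seq))
    pos = cg_positions(seq)
    truth = pd.DataFrame(
        {
            "contig": "chrT",
            "pos": pos,
            "cg_density": 10.0,
            "true_methylation": float(meth_value),
            "bound_factors": "",
            "dhs_cuts": 0.0,
        }
    )
    return genome, [frag], truth, pos


class TestBisulfiteReads:
    def test_unmethylated_full_conversion_reads_tg(self):
        genome, frags, truth, pos = _fragment_with_uniform_truth(0.0)
        reads = simulate_bisulfite_reads(
            genome, frags, truth, reads_per_fragment=20, read_length=100, seed=1
        )
        fwd = [r for r in reads if "|+|" in r.name]
        assert fwd
        for r in fwd:
            for p in pos:
                assert r.sequence[p : p + 2] == "TG"

    def test_fully_methylated_reads_cg(self):
        genome, frags, truth, pos = _fragment_with_uniform_truth(100.0)
        reads = simulate_bisulfite_reads(
            genome, frags, truth, reads_per_fragment=20, read_length=100, seed=2
        )
        for r in reads:
            if "|+|" in r.name:
                assert all(r.sequence[p : p + 2] == "CG" for p in pos)
            else:  # reverse-strand reads keep the CG on their own frame
                assert "TG" not in {r.sequence[p : p + 2] for p in pos}

    def test_half_methylated_fraction_within_binomial_interval(self):
        genome, frags, truth, pos = _fragment_with_uniform_truth(50.0)
        reads = simulate_bisulfite_reads(
            genome, frags, truth, reads_per_fragment=1000, read_length=100, seed=3
        )
        n_meth = n_tot = 0
        flen = len(genome["chrT"])
        for r in reads:
            fwd = "|+|" in r.name
            seq = r.sequence
            for p in pos:
                q = p if fwd else flen - p - 2
                ch = seq[q]
                if (fwd and ch == "C") or (not fwd and ch == "C"):
                    n_meth += 1
                n_tot += 1
        frac = 100.0 * n_meth / n_tot
        assert abs(frac - 50.0) < 5.0

    def test_non_cpg_cytosines_fully_converted(self):
        genome, frags, truth, pos = _fragment_with_uniform_truth(100.0)
        reads = simulate_bisulfite_reads(
            genome, frags, truth, reads_per_fragment=10, read_length=100,
            conversion_rate=1.0, seed=4,
        )
        cg_cs = set(pos)
        for r in reads:
            if "|+|" not in r.name:
                continue
            for i, ch in enumerate(r.sequence):
                if i not in cg_cs:
                    assert ch != "C" or genome["chrT"][i] != "C"

    def test_long_reads_truncated_to_fragment(self):
        genome, frags, truth, _ = _fragment_with_uniform_truth(0.0)
        reads = simulate_bisulfite_reads(
            genome, frags, truth, reads_per_fragment=2, read_length=5000, seed=5
        )
        assert all(len(r.sequence) == len(genome["chrT"]) for r in reads)

    def test_determinism(self):
        genome, frags, truth, _ = _fragment_with_uniform_truth(50.0)
        r1 = simulate_bisulfite_reads(genome, frags, truth, reads_per_fragment=5, seed=7)
        r2 = simulate_bisulfite_reads(genome, frags, truth, reads_per_fragment=5, seed=7)
        assert r1 == r2


class TestConditionVariants:
    def test_empty_lost_factor_set_is_identity(self, dynamics_genome):
        *_, truth, _ = dynamics_genome
        out = generate_condition_variant(truth, "differentiation", lost_factors=set(), seed=1)
        pd.testing.assert_frame_equal(out, truth)

    def test_lost_factor_cgs_reset_to_sigmoid(self, dynamics_genome, model):
        *_, truth, _ = dynamics_genome
        out = generate_condition_variant(
            truth, "differentiation", model=model, lost_factors={"Oct4"}, seed=2
        )
        lost = truth["bound_factors"] == "Oct4"
        assert lost.any()
        np.testing.assert_allclose(
            out.loc[lost, "true_methylation"].to_numpy(),
            model.predict(truth.loc[lost, "cg_density"].to_numpy()),
        )
        kept = truth["bound_factors"].str.contains("REST")
        pd.testing.assert_series_equal(
            out.loc[kept, "true_methylation"], truth.loc[kept, "true_methylation"]
        )

    def test_reset_value_at_density_eight(self, model):
        # bound CG at density 8 reverts to 100 / (1 + e^{0.337 (8 - 6.917)})
        truth = pd.DataFrame(
            {
                "contig": ["chr1"],
                "pos": [10],
                "cg_density": [8.0],
                "true_methylation": [4.0],
                "bound_factors": ["Oct4"],
                "dhs_cuts": [20.0],
            }
        )
        out = generate_condition_variant(
            truth, "differentiation", model=model, lost_factors={"Oct4"}, seed=0
        )
        assert out.loc[0, "true_methylation"] == pytest.approx(41.0, abs=0.05)

    def test_differentiation_never_decreases_methylation(self, dynamics_genome, model):
        *_, truth, _ = dynamics_genome
        out = generate_condition_variant(
            truth, "differentiation", model=model, lost_factors={"Oct4", "REST"}, seed=3
        )
        assert (
            out["true_methylation"].to_numpy() >= truth["true_methylation"].to_numpy() - 1e-9
        ).all()

    def test_unknown_factor_rejected(self, dynamics_genome):
        *_, truth, _ = dynamics_genome
        with pytest.raises(ValueError, match="unknown factor"):
            generate_condition_variant(truth, "differentiation", lost_factors={"Nanog"}, seed=0)

    def test_cancer_gains_epsilon_in_islands_only(self, dynamics_genome, model):
        _, islands, _, truth, _ = dynamics_genome
        out = generate_condition_variant(truth, "cancer", epsilon=30.0, islands=islands, seed=4)
        in_island = np.zeros(len(truth), dtype=bool)
        for _, isl in islands.iterrows():
            in_island |= (
                (truth["contig"] == isl["contig"])
                & (truth["pos"] >= isl["start"])
                & (truth["pos"] < isl["end"])
            ).to_numpy()
        gain = out["true_methylation"].to_numpy() - truth["true_methylation"].to_numpy()
        assert (gain[~in_island] == 0).all()
        expected = np.minimum(truth["true_methylation"].to_numpy()[in_island] + 30.0, 100.0)
        np.testing.assert_allclose(out["true_methylation"].to_numpy()[in_island], expected)
        # gain happens even where density alone predicts < 20% methylation
        low_pred = in_island & (model.predict(truth["cg_density"].to_numpy()) < 20.0)
        assert gain[low_pred].min() > 0

    def test_cancer_leaves_dhs_unchanged(self, dynamics_genome):
        _, islands, _, truth, _ = dynamics_genome
        out = generate_condition_variant(truth, "cancer", epsilon=10.0, islands=islands, seed=5)
        np.testing.assert_array_equal(out["dhs_cuts"].to_numpy(), truth["dhs_cuts"].to_numpy())
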