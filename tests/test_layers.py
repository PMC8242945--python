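"""Layer calling, immune-median comparison, and individuality clustering."""

import numpy as np
import pandas as pd
import pytest

from prrlayers import simulate as sim
from prrlayers.layers import (
    call_layers,
    immune_median_ratio,
    individuality_analysis,
    layer_summary,
    linkage_to_newick,
    presence_matrix,
)


def frame(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


class TestCallLayers:
    def test_partition_is_exhaustive_and_exclusive(self, small_experiment):
        _, exp = small_experiment
        assignment = call_layers(exp.counts)
        assert set(assignment.layer.unique()) <= {
            "constitutive", "individual_specific", "not_expressed"
        }
        n = exp.counts.shape[1]
        const = assignment.layer == "constitutive"
        assert (assignment.n_samples_present[const] == n).all()
        absent = assignment.layer == "not_expressed"
        assert (assignment.n_samples_present[absent] == 0).all()
        mid = assignment.layer == "individual_specific"
        assert assignment.n_samples_present[mid].between(1, n - 1).all()

    def test_all_positive_gene_is_constitutive(self):
        counts = frame([[1, 2, 3], [0, 0, 0], [5, 0, 1]])
        out = call_layers(counts)
        assert out.loc["g0", "layer"] == "constitutive"
        assert out.loc["g1", "layer"] == "not_expressed"
        assert out.loc["g2", "layer"] == "individual_specific"

    def test_fractional_expected_counts_count_as_present(self):
        # RSEM expected counts in (0, 1) still mark presence
        counts = frame([[0.3, 0.7, 0.1]])
        assert call_layers(counts).loc["g0", "layer"] == "constitutive"

    def test_high_tier_requires_constitutive(self):
        counts = frame([[1, 1], [5, 0]])
        norm = frame([[50.0, 50.0], [500.0, 0.0]])
        out = call_layers(counts, norm, high_threshold=10)
        assert bool(out.loc["g0", "constitutive_high"])
        assert not bool(out.loc["g1", "constitutive_high"])  # not constitutive

    def test_high_tier_all_samples_mode(self):
        counts = frame([[1, 1]])
        norm = frame([[100.0, 2.0]])
        assert bool(
            call_layers(counts, norm, high_mode="mean").constitutive_high.iloc[0]
        )
        assert not bool(
            call_layers(counts, norm, high_mode="all").constitutive_high.iloc[0]
        )

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimensions"):
            call_layers(frame([[1, 2]]), frame([[1.0]]))

    def test_truth_recovery_errors_one_directional(self, small_experiment):
        """Sampling zeros may demote constitutive genes, never the reverse."""
        _, exp = small_experiment
        assignment = call_layers(exp.counts)
        truth_layer = exp.truth.layer.replace({"never": "not_expressed"})
        mismatch = assignment.layer != truth_layer
        assert mismatch.mean() < 0.05
        wrong = pd.DataFrame(
            {"truth": truth_layer[mismatch], "called": assignment.layer[mismatch]}
        )
        assert (
            (wrong.truth == "constitutive")
            & (wrong.called == "individual_specific")
        ).all()


class TestLayerSummary:
    def test_half_and_half(self):
        assignment = pd.DataFrame(
            {
                "layer": ["constitutive"] * 2 + ["individual_specific"] * 2,
                "n_samples_present": [3, 3, 1, 2],
                "constitutive_high": [False] * 4,
            },
            index=list("abcd"),
        )
        s = layer_summary(assignment)
        assert s["frac_of_expressed"]["constitutive"] == pytest.approx(0.5)
        assert s["frac_of_expressed"]["individual_specific"] == pytest.approx(0.5)

    def test_single_constitutive_gene(self):
        assignment = pd.DataFrame(
            {
                "layer": ["constitutive"],
                "n_samples_present": [4],
                "constitutive_high": [True],
            },
            index=["a"],
        )
        s = layer_summary(assignment, ["a"])
        assert s["frac_of_expressed"]["constitutive"] == 1.0
        assert s["frac_of_expressed"]["individual_specific"] == 0.0

    def test_fractions_sum_to_one_and_order_invariant(self, small_experiment):
        _, exp = small_experiment
        assignment = call_layers(exp.counts)
        s = layer_summary(assignment)
        assert sum(s["frac_of_expressed"].values()) == pytest.approx(1.0)
        shuffled = assignment.sample(frac=1.0, random_state=0)
        assert layer_summary(shuffled) == s

    def test_planted_fractions_recovered(self, small_experiment):
        cfg, exp = small_experiment
        s = layer_summary(call_layers(exp.counts))
        assert s["frac_of_all"]["constitutive"] == pytest.approx(
            cfg.frac_constitutive, abs=0.05
        )
        assert s["frac_of_all"]["not_expressed"] == pytest.approx(
            cfg.frac_never_expressed, abs=0.05
        )

    def test_empty_subset_raises(self, small_experiment):
        _, exp = small_experiment
        with pytest.raises(ValueError, match="empty"):
            layer_summary(call_layers(exp.counts), [])


class TestImmuneMedianRatio:
    def test_symmetric_sets_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        norm = frame(rng.uniform(10, 100, size=(400, 4)))
        counts = frame(np.ones((400, 4)))
        assignment = call_layers(counts)
        flags = pd.Series(
            [True, False] * 200, index=norm.index
        )
        out = immune_median_ratio(norm, assignment, flags)
        assert out["ratio"] == pytest.approx(1.0, rel=0.15)

    def test_single_pair_of_genes(self):
        norm = frame([[20.0, 20.0], [10.0, 10.0]])
        counts = frame(np.ones((2, 2)))
        assignment = call_layers(counts)
        flags = pd.Series([True, False], index=norm.index)
        assert immune_median_ratio(norm, assignment, flags)["ratio"] == 2.0

    def test_planted_boost_recovered(self):
        cfg = sim.SimulationConfig(n_genes=20_000, seed=21, n_responsive=0)
        design = sim.simulate_design(cfg.n_individuals, cfg.dropout_samples)
        exp = sim.simulate_counts(cfg, design)
        from prrlayers.normalization import tmm_normalized_tpm

        norm, _ = tmm_normalized_tpm(exp.counts, exp.lengths)
        assignment = call_layers(exp.counts, norm)
        out = immune_median_ratio(norm, assignment, exp.truth.is_immune)
        assert out["ratio"] == pytest.approx(
            cfg.immune_median_boost, rel=0.10
        )

    def test_missing_group_raises(self):
        norm = frame([[20.0, 20.0]])
        assignment = call_layers(frame(np.ones((1, 2))))
        with pytest.raises(ValueError, match="constitutive"):
            immune_median_ratio(norm, assignment, pd.Series([True], index=norm.index))


def paired_design(n_individuals, prefix="IND"):
    rows = []
    for i in range(n_individuals):
        for tp in ("t1h", "t6h"):
            rows.append(
                {
                    "sample_id": f"{prefix}{i}_{tp}",
                    "individual_id": f"{prefix}{i}",
                    "treatment": "LPS",
                    "timepoint": tp,
                }
            )
    return pd.DataFrame(rows)


class TestIndividuality:
    def test_identical_clone_vectors_score_one(self):
        design = paired_design(6)
        rng = np.random.default_rng(1)
        per_ind = rng.random((100, 6)) < 0.5
        presence = pd.DataFrame(
            np.repeat(per_ind, 2, axis=1),
            index=[f"g{i}" for i in range(100)],
            columns=design.sample_id,
        )
        res = individuality_analysis(
            presence, design, presence.index, n_permutations=999, seed=0
        )
        assert res.pairing_score == 1.0
        assert res.p_value < 0.01

    def test_all_identical_vectors_flagged_tied(self):
        design = paired_design(3)
        presence = pd.DataFrame(
            True, index=[f"g{i}" for i in range(10)], columns=design.sample_id
        )
        res = individuality_analysis(
            presence, design, presence.index, n_permutations=99, seed=0
        )
        assert res.tied
        assert res.p_value == 1.0

    def test_planted_carriage_is_significant(self, small_experiment):
        _, exp = small_experiment
        assignment = call_layers(exp.counts)
        spec = assignment.index[assignment.layer == "individual_specific"]
        lps = exp.design[exp.design.treatment == "LPS"]
        lps = lps[lps.groupby("individual_id")["sample_id"].transform("size") == 2]
        res = individuality_analysis(
            presence_matrix(exp.counts), lps, spec,
            n_permutations=499, seed=5,
        )
        assert res.p_value < 0.01

    def test_permutation_p_reproducible_and_bounded(self):
        design = paired_design(4)
        rng = np.random.default_rng(2)
        presence = pd.DataFrame(
            rng.random((60, 8)) < 0.5,
            index=[f"g{i}" for i in range(60)],
            columns=design.sample_id,
        )
        r1 = individuality_analysis(presence, design, presence.index, 99, seed=7)
        r2 = individuality_analysis(presence, design, presence.index, 99, seed=7)
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_too_few_pairs_raise(self):
        design = paired_design(1)
        presence = pd.DataFrame(
            True, index=["g0"], columns=design.sample_id
        )
        with pytest.raises(ValueError, match="individuals"):
            individuality_analysis(presence, design, ["g0"], 10, 0)

    def test_newick_serialization_has_all_leaves(self):
        design = paired_design(3)
        rng = np.random.default_rng(3)
        presence = pd.DataFrame(
            rng.random((40, 6)) < 0.5,
            index=[f"g{i}" for i in range(40)],
            columns=design.sample_id,
        )
        res = individuality_analysis(presence, design, presence.index, 19, 0)
        nwk = linkage_to_newick(res.linkage, res.sample_ids)
        assert nwk.endswith(";")
        for s in design.sample_id:
            assert s in nwk
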