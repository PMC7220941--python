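"""Quantile normalisation, co-expression, clustering and sample structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import rand_score

import refpattern as rp
from refpattern.compendium import cluster_genes, gene_coexpression

from _oracles import oracle_pca_percent_variance, oracle_quantile_normalize


class TestQuantileNormalize:
    def test_two_column_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = rp.quantile_normalize(df)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = [5.0, 1.0, 3.0, 2.0]
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        out = rp.quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy())

    def test_ties_receive_mean_of_tied_rank_targets(self):
        # 5x4 with a tie in column a: matches the literal rank-mean oracle
        df = pd.DataFrame(
            {
                "a": [2.0, 2.0, 5.0, 1.0, 9.0],
                "b": [1.0, 4.0, 2.0, 8.0, 3.0],
                "c": [7.0, 6.0, 5.0, 4.0, 3.0],
                "d": [1.0, 1.0, 1.0, 2.0, 3.0],
            }
        )
        out = rp.quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), oracle_quantile_normalize(df))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(1, 100, size=(12, 4)))
        once = rp.quantile_normalize(df)
        twice = rp.quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), rtol=1e-12)

    def test_needs_at_least_two_arrays(self):
        with pytest.raises(rp.PipelineError, match=">= 2"):
            rp.quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestBuildCompendium:
    def _source(self, genes, prefix, condition="cond"):
        rng = np.random.default_rng(hash(prefix) % 2**31)
        cols = [f"{prefix}{i}" for i in range(3)]
        values = pd.DataFrame(
            rng.uniform(10, 100, size=(len(genes), 3)), index=genes, columns=cols
        )
        meta = pd.DataFrame(
            {
                "array_id": cols,
                "dataset_id": prefix,
                "condition": condition,
                "cell_class": "x",
                "control_of": "",
            }
        )
        groups = pd.Series([condition] * 3, index=cols)
        return rp.ExpressionMatrix(values, groups), meta

    def test_merges_on_shared_probe_sets_only(self):
        a = self._source(["g1", "g2", "g3"], "A")
        b = self._source(["g2", "g3", "g4"], "B", condition="other")
        comp = rp.build_compendium([a, b])
        assert list(comp.expr.probe_sets) == ["g2", "g3"]
        assert comp.normalized

    def test_empty_intersection_is_an_error(self):
        a = self._source(["g1"], "A")
        b = self._source(["g9"], "B")
        with pytest.raises(rp.PipelineError, match="empty intersection"):
            rp.build_compendium([a, b])


class TestCoexpression:
    def test_self_correlation_is_one_and_negation_minus_one(self, default_compendium):
        comp = default_compendium
        genes = list(comp.expr.probe_sets[:5])
        cm = rp.gene_coexpression(comp, genes)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert cm.r.equals(cm.r.T)

    def test_anticorrelated_pair_reaches_minus_one(self):
        values = pd.DataFrame(
            {
                "a1": [1.0, 8.0, 5.0],
                "a2": [2.0, 7.0, 5.0],
                "a3": [3.0, 6.0, 5.0],
                "a4": [4.0, 5.0, 5.0],
            },
            index=["up", "down", "flat"],
        )
        meta = pd.DataFrame(
            {
                "array_id": values.columns,
                "dataset_id": "t",
                "condition": "c",
                "cell_class": "x",
                "control_of": "",
            }
        )
        comp = rp.Compendium(
            rp.ExpressionMatrix(values, pd.Series("c", index=values.columns)), meta
        )
        with pytest.warns(UserWarning, match="constant"):
            cm = rp.gene_coexpression(comp, ["up", "down", "flat"])
        assert cm.r.at["up", "down"] == pytest.approx(-1.0)
        assert cm.constant_genes == ["flat"]
        assert (cm.r.loc["flat", ["up", "down"]] == 0).all()
        assert cm.r.at["flat", "flat"] == 1.0

    def test_matches_textbook_pearson(self, default_compendium):
        comp = default_compendium
        genes = list(comp.expr.probe_sets[:3])
        cm = rp.gene_coexpression(comp, genes)
        X = comp.expr.values.loc[genes].to_numpy()
        for i in range(3):
            for j in range(3):
                x, y = X[i], X[j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert cm.r.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_invariant_under_common_linear_rescaling(self, default_compendium):
        comp = default_compendium
        genes = list(comp.expr.probe_sets[:6])
        cm1 = rp.gene_coexpression(comp, genes)
        scaled = rp.Compendium(
            rp.ExpressionMatrix(
                comp.expr.values * 3.0 + 0.0, comp.expr.groups.copy()
            ),
            comp.metadata,
        )
        cm2 = rp.gene_coexpression(scaled, genes)
        np.testing.assert_allclose(cm1.r.to_numpy(), cm2.r.to_numpy(), atol=1e-12)


class TestClustering:
    def test_identical_rows_merge_at_distance_zero(self):
        r = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=["a", "b", "c"],
            columns=["a", "b", "c"],
        )
        cm = rp.CoexpressionMatrix(r)
        clustering = rp.cluster_genes(cm)
        assert clustering.linkage[0, 2] == 0.0  # first merge: the identical pair

    def test_three_point_average_linkage_merge_order(self):
        # points 0, 1, 5 on a line: merge (0,1) at d=1, then join 5 at mean(5,4)=4.5
        r = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]], index=["p0", "p1", "p5"]
        )
        cm = rp.CoexpressionMatrix(
            pd.DataFrame(r.to_numpy(), index=r.index, columns=["x", "y"])
        )
        # feed coordinates directly as feature rows
        clustering = cluster_genes(cm)
        Z = clustering.linkage
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(4.5)

    def test_leaf_order_deterministic_across_runs(self, default_compendium):
        genes = list(default_compendium.expr.probe_sets[:30])
        cm = rp.gene_coexpression(default_compendium, genes)
        a = rp.cluster_genes(cm, rp.ClusteringParams(k=3))
        b = rp.cluster_genes(cm, rp.ClusteringParams(k=3))
        assert a.leaf_order == b.leaf_order
        assert a.labels.equals(b.labels)

    def test_single_gene_rejected(self):
        cm = rp.CoexpressionMatrix(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))
        with pytest.raises(rp.PipelineError, match=">= 2"):
            rp.cluster_genes(cm)

    def test_marker_blocks_recovered_at_default_noise(self, default_compendium):
        """Tree cut at k = #blocks reproduces the marker blocks (Rand >= 0.95)."""
        sig = rp.example_signature()
        marker_genes = [g for ct in sig.cell_type_names for g in sig.marker_blocks[ct]]
        truth = {
            g: i for i, ct in enumerate(sig.cell_type_names)
            for g in sig.marker_blocks[ct]
        }
        norm = rp.Compendium(
            rp.ExpressionMatrix(
                rp.quantile_normalize(default_compendium.expr.values),
                default_compendium.expr.groups.copy(),
            ),
            default_compendium.metadata,
            normalized=True,
        )
        cm = rp.gene_coexpression(norm, marker_genes)
        clustering = rp.cluster_genes(
            cm, rp.ClusteringParams(k=len(sig.cell_type_names))
        )
        labels = clustering.labels.loc[marker_genes].to_numpy()
        truth_labels = np.array([truth[g] for g in marker_genes])
        assert rand_score(truth_labels, labels) >= 0.95


class TestAssignPatterns:
    def test_marker_cluster_assigned_to_its_cell_type(self):
        sig = rp.example_signature(n_cell_types=2, markers_per_type=4, n_background=2,
                                   noise_sd=0.0)
        expr, meta = rp.generate_reference_compendium(sig, [], seed=1)
        comp = rp.Compendium(expr, meta)
        ct1, ct2 = sig.cell_type_names
        labels = pd.Series(
            {**{g: 1 for g in sig.marker_blocks[ct1]},
             **{g: 2 for g in sig.marker_blocks[ct2]}}
        )
        patterns = rp.assign_patterns(comp, labels)
        assert patterns.at[1, "assigned_condition"] == f"{ct1}_ctrl"
        assert patterns.at[2, "assigned_condition"] == f"{ct2}_ctrl"

    def test_stimulus_cluster_assigned_to_stimulated_arm(self):
        sig = rp.example_signature(n_cell_types=2, markers_per_type=6, n_background=2,
                                   noise_sd=0.0)
        stimuli = rp.example_stimuli(sig, genes_per_stimulus=3)
        expr, meta = rp.generate_reference_compendium(sig, stimuli, seed=2)
        comp = rp.Compendium(expr, meta)
        stim = stimuli[0]
        up_genes = [g for g, e in stim.response.items() if e > 0]
        labels = pd.Series({g: 1 for g in up_genes})
        patterns = rp.assign_patterns(comp, labels)
        assert patterns.at[1, "assigned_condition"] == stim.name

    def test_flat_expression_is_unassigned(self):
        values = pd.DataFrame(
            np.full((3, 4), 8.0), index=["a", "b", "c"],
            columns=["s1", "s2", "s3", "s4"],
        )
        meta = pd.DataFrame(
            {"array_id": values.columns, "dataset_id": "t",
             "condition": ["c1", "c1", "c2", "c2"], "cell_class": "x",
             "control_of": ""}
        )
        comp = rp.Compendium(
            rp.ExpressionMatrix(values, pd.Series(meta["condition"].values,
                                                  index=values.columns)), meta
        )
        patterns = rp.assign_patterns(comp, pd.Series({"a": 1, "b": 1, "c": 1}))
        assert patterns.at[1, "assigned_condition"] == "unassigned"
        assert patterns.at[1, "c1"] == 0.0 and patterns.at[1, "c2"] == 0.0


class TestSampleStructure:
    def test_duplicated_samples_get_identical_scores(self, default_study):
        cohort = default_study["cohort"]
        sub = cohort.values.iloc[:, :4]
        dup = pd.concat(
            [sub, sub.rename(columns={c: f"{c}_copy" for c in sub.columns})], axis=1
        )
        groups = pd.Series("g", index=dup.columns)
        structure = rp.sample_structure(rp.ExpressionMatrix(dup, groups), n_components=2)
        for c in sub.columns:
            np.testing.assert_allclose(
                structure.scores.loc[c].to_numpy(),
                structure.scores.loc[f"{c}_copy"].to_numpy(),
                atol=1e-8,
            )

    def test_percent_variance_nonincreasing_and_bounded(self, default_study):
        structure = rp.sample_structure(default_study["cohort"], n_components=3)
        pct = structure.percent_variance
        assert (np.diff(pct) <= 1e-9).all()
        assert pct.sum() <= 100.0 + 1e-9

    def test_percent_variance_matches_eigenvalue_oracle(self, default_study):
        cohort = default_study["cohort"]
        genes = list(cohort.probe_sets[:20])
        sub = rp.ExpressionMatrix(
            cohort.values.loc[genes].iloc[:, :12],
            cohort.groups.iloc[:12].copy(),
        )
        structure = rp.sample_structure(sub, n_components=5)
        z = rp.zscore_log2(sub.values).to_numpy().T
        expected = oracle_pca_percent_variance(z)
        np.testing.assert_allclose(structure.percent_variance, expected[:5], atol=1e-8)

    def test_group_effect_lands_on_first_component(self, default_study):
        cohort = default_study["cohort"]
        structure = rp.sample_structure(cohort, n_components=3)
        pct = structure.percent_variance
        assert pct[0] > pct[1]
        pc1 = structure.scores["PC1"]
        disease = pc1[cohort.groups == "disease"]
        control = pc1[cohort.groups == "control"]
        assert disease.max() < control.min() or control.max() < disease.min()

    def test_overlong_component_request_truncates_with_warning(self, default_study):
        cohort = default_study["cohort"]
        sub = rp.ExpressionMatrix(
            cohort.values.iloc[:5, :4], cohort.groups.iloc[:4].copy()
        )
        with pytest.warns(UserWarning, match="rank"):
            structure = rp.sample_structure(sub, n_components=10)
        assert structure.scores.shape[1] <= 4
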