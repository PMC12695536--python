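"""Contamination partitioning, batch adjustment, clustering and flagging."""

import numpy as np
import pandas as pd
import pytest

from pitdeconv import (
    LineageMap,
    batch_adjust,
    bulk_cpm,
    contamination_score,
    contamination_report,
    flag_discordant,
    hcluster,
    hvg_select,
)


class TestContaminationScore:
    def test_partition_arithmetic(self):
        """GH histotype: somatotroph is tumor, lactotroph same-lineage (PIT1),
        gonadotroph residual (SF1), T cell TME."""
        p = pd.Series(
            {"somatotroph": 0.6, "lactotroph": 0.1, "gonadotroph": 0.2, "t_cell": 0.1}
        )
        row = contamination_score(p, "GH")
        assert row["tumor_fraction"] == pytest.approx(0.6)
        assert row["same_lineage_fraction"] == pytest.approx(0.1)
        assert row["residual_normal_fraction"] == pytest.approx(0.2)
        assert row["tme_fraction"] == pytest.approx(0.1)
        assert row["contaminated"]  # 0.2 >= default threshold 0.2

    def test_pure_tumor_has_zero_residual(self):
        p = pd.Series({"somatotroph": 1.0, "lactotroph": 0.0, "gonadotroph": 0.0})
        row = contamination_score(p, "GH")
        assert row["residual_normal_fraction"] == 0.0
        assert not row["contaminated"]

    def test_fractions_partition_the_total(self):
        rng = np.random.default_rng(1)
        types = ["somatotroph", "lactotroph", "thyrotroph", "gonadotroph",
                 "corticotroph", "stem_cell", "endothelial", "t_cell"]
        for _ in range(10):
            p = pd.Series(rng.dirichlet(np.ones(len(types))), index=types)
            row = contamination_score(p, "GH")
            total = (
                row["tumor_fraction"] + row["same_lineage_fraction"]
                + row["residual_normal_fraction"] + row["tme_fraction"]
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_stem_counts_same_lineage_for_pit1_only(self):
        p = pd.Series({"somatotroph": 0.7, "stem_cell": 0.3})
        assert contamination_score(p, "GH")["same_lineage_fraction"] == pytest.approx(0.3)
        p2 = pd.Series({"gonadotroph": 0.7, "stem_cell": 0.3})
        assert contamination_score(p2, "FSH/LH")["residual_normal_fraction"] == pytest.approx(0.3)
        lm = LineageMap(stem_as_same_lineage=False)
        assert contamination_score(p, "GH", lm)["residual_normal_fraction"] == pytest.approx(0.3)

    def test_unknown_labels_are_errors(self):
        with pytest.raises(ValueError, match="histotype"):
            contamination_score(pd.Series({"somatotroph": 1.0}), "melanoma")
        with pytest.raises(ValueError, match="missing from lineage map"):
            contamination_score(pd.Series({"mystery_cell": 1.0}), "GH")

    def test_cohort_summary(self):
        props = pd.DataFrame(
            {"somatotroph": [0.9, 0.5], "gonadotroph": [0.1, 0.5]},
            index=["clean", "dirty"],
        )
        rep, summary = contamination_report(
            props, pd.Series({"clean": "GH", "dirty": "GH"}), flag_threshold=0.2
        )
        assert summary["n_contaminated"] == 1
        assert summary["mean_residual_flagged"] == pytest.approx(0.5)


class TestBulkCPM:
    def test_arithmetic(self):
        m = pd.DataFrame({"s": [10.0, 30.0]})
        assert np.allclose(bulk_cpm(m)["s"], [250000, 750000])

    def test_zero_column_error(self):
        with pytest.raises(ValueError, match="zero"):
            bulk_cpm(pd.DataFrame({"s": [0.0, 0.0]}))


class TestBatchAdjust:
    def test_single_batch_is_near_identity(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(5, 1, (30, 8)),
                         index=[f"g{i}" for i in range(30)])
        out = batch_adjust([m], ["b0"])
        assert np.allclose(out.to_numpy(), m.to_numpy(), atol=1e-9)

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5, 1, (40, 6))
        m1 = pd.DataFrame(base, index=[f"g{i}" for i in range(40)],
                          columns=[f"a{i}" for i in range(6)])
        m2 = pd.DataFrame(base + 2.0, index=m1.index,
                          columns=[f"b{i}" for i in range(6)])
        out = batch_adjust([m1, m2], ["b1", "b2"])
        mean1 = out[[c for c in out if c.startswith("a")]].mean(axis=1)
        mean2 = out[[c for c in out if c.startswith("b")]].mean(axis=1)
        assert np.allclose(mean1, mean2, atol=1e-9)

    def test_non_shared_genes_dropped(self):
        m1 = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        m2 = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                          columns=[3, 4, 5])
        out = batch_adjust([m1, m2], ["x", "y"])
        assert list(out.index) == list("abc")

    def test_single_sample_batch_centered_only(self):
        rng = np.random.default_rng(4)
        m1 = pd.DataFrame(rng.normal(0, 1, (10, 5)), index=[f"g{i}" for i in range(10)],
                          columns=[f"a{i}" for i in range(5)])
        m2 = pd.DataFrame(rng.normal(9, 1, (10, 1)), index=m1.index, columns=["lonely"])
        out = batch_adjust([m1, m2], ["big", "tiny"])
        # the lonely sample lands at the pooled per-gene mean
        pooled = pd.concat([m1, m2], axis=1).mean(axis=1)
        assert np.allclose(out["lonely"], pooled, atol=1e-9)


class TestHVGSelect:
    def test_constant_genes_never_beat_variable_ones(self):
        m = pd.DataFrame(
            {"s1": [1.0, 5.0, 1.0], "s2": [1.0, 0.0, 1.0], "s3": [1.0, 9.0, 1.0]},
            index=["flat1", "hv", "flat2"],
        )
        assert list(hvg_select(m, 1)) == ["hv"]

    def test_full_selection_is_identity_set(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"g{i}" for i in range(6)])
        assert set(hvg_select(m, 6)) == set(m.index)

    def test_planted_bimodal_genes_all_selected(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(0, 0.01, (50, 20)), index=[f"g{i}" for i in range(50)])
        planted = [f"g{i}" for i in range(5)]
        m.loc[planted, m.columns[:10]] += 10.0
        assert set(planted) <= set(hvg_select(m, 8))

    def test_n_too_large_is_error(self):
        with pytest.raises(ValueError):
            hvg_select(pd.DataFrame(np.ones((3, 2))), 4)


class TestHCluster:
    def test_complete_linkage_hand_example(self):
        """Points at 0, 1, 10 on a line: first merge {0,1} at height 1, final
        merge at the complete-linkage distance 10."""
        m = pd.DataFrame([[0.0, 1.0, 10.0]], index=["g"], columns=["p0", "p1", "p2"])
        link = hcluster(m)
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(10.0)

    def test_duplicate_samples_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]], index=["g1", "g2"],
            columns=["dup1", "dup2", "far"],
        )
        link = hcluster(m)
        assert link[0, 2] == pytest.approx(0.0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            hcluster(pd.DataFrame({"only": [1.0, 2.0]}))


class TestFlagDiscordant:
    @staticmethod
    def _cohort(rng, n_per=6, contaminated=0):
        """Three lineage centroids along orthogonal marker-block axes;
        optionally some PIT1 samples displaced halfway toward SF1."""
        genes = [f"g{i}" for i in range(30)]
        centers = {
            "PIT1": np.repeat([20.0, 0.0, 0.0], 10),
            "TPIT": np.repeat([0.0, 20.0, 0.0], 10),
            "SF1": np.repeat([0.0, 0.0, 20.0], 10),
        }
        cols, lineages = {}, {}
        for lin, c in centers.items():
            for i in range(n_per):
                name = f"{lin}_{i}"
                cols[name] = c + rng.normal(0, 0.5, len(genes))
                lineages[name] = lin
        for i in range(contaminated):
            name = f"mixed_{i}"
            cols[name] = 0.5 * centers["PIT1"] + 0.5 * centers["SF1"] + rng.normal(
                0, 0.5, len(genes)
            )
            lineages[name] = "PIT1"
        m = pd.DataFrame(cols, index=genes)
        return m, pd.Series(lineages)[m.columns]

    def test_separated_cohort_has_no_flags(self):
        m, lin = self._cohort(np.random.default_rng(7))
        flags = flag_discordant(hcluster(m), lin, k=3)
        assert not flags.any()

    def test_displaced_samples_flagged(self):
        m, lin = self._cohort(np.random.default_rng(8), contaminated=3)
        flags = flag_discordant(hcluster(m), lin, k=4)
        assert flags[[s for s in flags.index if s.startswith("mixed")]].all()
        assert not flags[[s for s in flags.index if not s.startswith("mixed")]].any()

    def test_flags_invariant_to_sample_order(self):
        m, lin = self._cohort(np.random.default_rng(9), contaminated=2)
        flags1 = flag_discordant(hcluster(m), lin, k=4)
        order = np.random.default_rng(0).permutation(m.columns)
        m2 = m[order]
        flags2 = flag_discordant(hcluster(m2), lin[order], k=4)
        assert flags1.sort_index().equals(flags2.sort_index())

    def test_k_below_lineage_count_rejected(self):
        m, lin = self._cohort(np.random.default_rng(10))
        with pytest.raises(ValueError, match="k="):
            flag_discordant(hcluster(m), lin, k=2)

    def test_mixed_single_cluster_flags_minority(self):
        """All samples identical: one cluster; flags only where lineage is
        not the majority."""
        genes = [f"g{i}" for i in range(5)]
        m = pd.DataFrame(np.ones((5, 4)), index=genes,
                         columns=["a", "b", "c", "d"])
        lin = pd.Series({"a": "PIT1", "b": "PIT1", "c": "PIT1", "d": "SF1"})
        flags = flag_discordant(hcluster(m), lin, k=2)
        assert bool(flags["d"]) and not flags[["a", "b", "c"]].any()
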