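import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degscan import (
    CountMatrix,
    GeneSubset,
    RelativeExpression,
    compare_subsets,
    define_subsets,
    estimate_size_factors,
    group_correlation,
    histone_fraction,
    simulate_study,
)
from degscan.compare import CompareError
from degscan.simulate import SimulationConfig, generate_annotation


def rel_from_values(values: pd.DataFrame, groups: dict) -> RelativeExpression:
    return RelativeExpression(values, "ref", 1.0, pd.Series(groups))


class TestDefineSubsets:
    def test_planted_fixture_gives_five_subsets_with_expected_sizes(self, default_study):
        _, annotation, _, _ = default_study
        subsets = {s.name: s for s in define_subsets(annotation, "HIST1", (47, 57))}
        assert len(subsets["cluster_histone"].gene_ids) == 47
        assert len(subsets["cluster_nonhistone"].gene_ids) == 26
        assert len(subsets["upstream_flank"].gene_ids) == 47
        assert len(subsets["downstream_flank"].gene_ids) == 57
        assert len(subsets["nonHIST1_histone"].gene_ids) == 100

    def test_flanks_are_nearest_genes_outside_cluster(self, default_study):
        _, annotation, _, _ = default_study
        subsets = {s.name: s for s in define_subsets(annotation, "HIST1", (5, 5))}
        cluster = [g for g in annotation if g.cluster_tag == "HIST1"]
        lo = min(g.start for g in cluster)
        up = sorted((annotation[g] for g in subsets["upstream_flank"].gene_ids),
                    key=lambda g: g.start)
        assert all(g.end <= lo for g in up)
        # the five nearest: no non-cluster gene lies between flank and cluster
        gap_genes = [g for g in annotation.genes_on(up[0].chrom)
                     if up[-1].end <= g.start and g.end <= lo
                     and g.gene_id not in subsets["upstream_flank"].gene_ids]
        assert not gap_genes

    def test_oversized_flank_truncates(self, default_study, caplog):
        _, annotation, _, _ = default_study
        subsets = {s.name: s for s in define_subsets(annotation, "HIST1", (10_000, 5))}
        assert len(subsets["upstream_flank"].gene_ids) < 10_000

    def test_pure_histone_cluster_drops_nonhistone_subset(self):
        cfg = SimulationConfig(seed=2, n_cluster_nonhistone=0, n_chroms=2,
                               genes_per_chrom=50, n_noncluster_histone=10)
        annotation, _ = generate_annotation(cfg)
        names = {s.name for s in define_subsets(annotation, "HIST1", (5, 5))}
        assert "cluster_nonhistone" not in names
        assert "cluster_histone" in names

    def test_missing_cluster_tag_rejected(self, default_study):
        _, annotation, _, _ = default_study
        with pytest.raises(CompareError):
            define_subsets(annotation, "NOPE")


class TestCompareSubsets:
    def test_identical_values_give_t_zero_p_one(self):
        values = pd.DataFrame(
            np.ones((10, 2)) * 2.0,
            index=[f"g{i}" for i in range(10)],
            columns=["s1", "s2"],
        )
        rel = rel_from_values(values, {"s1": "alt", "s2": "alt"})
        subsets = [
            GeneSubset("a", frozenset(f"g{i}" for i in range(5))),
            GeneSubset("b", frozenset(f"g{i}" for i in range(5, 10))),
        ]
        comp = compare_subsets(rel, subsets, "alt")
        assert comp.tests["t"].iloc[0] == 0.0
        assert comp.tests["pvalue"].iloc[0] == 1.0

    def test_single_gene_subset_flagged_undefined(self):
        values = pd.DataFrame(np.ones((3, 1)), index=["g0", "g1", "g2"], columns=["s"])
        rel = rel_from_values(values, {"s": "alt"})
        comp = compare_subsets(
            rel,
            [GeneSubset("a", frozenset(["g0"])), GeneSubset("b", frozenset(["g1", "g2"]))],
            "alt",
        )
        assert comp.tests["undefined"].iloc[0]
        assert np.isnan(comp.tests["pvalue"].iloc[0])

    def test_overlapping_subsets_rejected(self):
        values = pd.DataFrame(np.ones((2, 1)), index=["g0", "g1"], columns=["s"])
        rel = rel_from_values(values, {"s": "alt"})
        with pytest.raises(CompareError, match="disjoint"):
            compare_subsets(
                rel,
                [GeneSubset("a", frozenset(["g0", "g1"])), GeneSubset("b", frozenset(["g1"]))],
                "alt",
            )

    def test_null_pvalues_uniform(self):
        # two subsets drawn from one distribution: p-values over replicates
        # should be uniform (KS test)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            values = pd.DataFrame(
                2.0 ** rng.normal(0, 1, size=(40, 3)),
                index=[f"g{i}" for i in range(40)],
                columns=["s1", "s2", "s3"],
            )
            rel = rel_from_values(values, {s: "alt" for s in ("s1", "s2", "s3")})
            subsets = [
                GeneSubset("a", frozenset(f"g{i}" for i in range(20))),
                GeneSubset("b", frozenset(f"g{i}" for i in range(20, 40))),
            ]
            pvals.append(compare_subsets(rel, subsets, "alt").tests["pvalue"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_shift_detected_only_on_shifted_subset(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        base = 2.0 ** rng.normal(0, 0.5, size=(60, 3))
        base[:20] *= 2.0 ** -2  # -2 log2 shift on subset "hit"
        values = pd.DataFrame(base, index=genes, columns=["s1", "s2", "s3"])
        rel = rel_from_values(values, {s: "alt" for s in ("s1", "s2", "s3")})
        subsets = [
            GeneSubset("hit", frozenset(genes[:20])),
            GeneSubset("ctrl1", frozenset(genes[20:40])),
            GeneSubset("ctrl2", frozenset(genes[40:])),
        ]
        comp = compare_subsets(rel, subsets, "alt")
        assert comp.test_p("hit", "ctrl1") < 0.01
        assert comp.test_p("hit", "ctrl2") < 0.01
        assert comp.test_p("ctrl1", "ctrl2") >= 0.01

    def test_invariant_to_gene_order(self, default_study):
        _, annotation, _, cm = default_study
        from degscan import relative_to_group_mean
        estimate_size_factors(cm)
        rel = relative_to_group_mean(cm, "IVF")
        subsets = define_subsets(annotation, "HIST1")
        a = compare_subsets(rel, subsets, "fSCNT")
        shuffled = RelativeExpression(
            rel.values.sample(frac=1.0, random_state=0), rel.reference_group,
            rel.pseudocount, rel.groups,
        )
        b = compare_subsets(shuffled, subsets, "fSCNT")
        assert np.allclose(
            a.tests.sort_values(["subset_a", "subset_b"])["pvalue"].to_numpy(),
            b.tests.sort_values(["subset_a", "subset_b"])["pvalue"].to_numpy(),
        )


def build_cm(counts, groups):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    df.columns = list(groups)
    cm = CountMatrix(df, groups)
    cm.size_factors = pd.Series(1.0, index=df.columns)
    return cm


class TestHistoneFraction:
    def test_cluster_equal_to_all_histone_gives_fraction_one(self):
        cm = build_cm(np.array([[10, 20], [30, 40]]), {"a": "X", "b": "Y"})
        rep = histone_fraction(cm, {"g0", "g1"}, {"g0", "g1"}, "X", "Y")
        assert (rep.per_group["cluster_fraction"] == 1.0).all()

    def test_identical_groups_give_unit_ratios(self):
        cm = build_cm(np.array([[10, 10], [30, 30]]), {"a": "X", "b": "Y"})
        rep = histone_fraction(cm, {"g0"}, {"g0", "g1"}, "X", "Y")
        assert rep.total_ratio == pytest.approx(1.0)
        assert rep.fraction_ratio == pytest.approx(1.0)

    def test_conservation_is_exact(self, default_study):
        _, annotation, _, cm = default_study
        estimate_size_factors(cm)
        all_hist = {g.gene_id for g in annotation if g.gene_class == "histone"}
        cluster = {g.gene_id for g in annotation
                   if g.cluster_tag == "HIST1" and g.gene_class == "histone"}
        rep = histone_fraction(cm, cluster, all_hist, "IVF", "fSCNT")
        pg = rep.per_group
        assert np.allclose(pg["cluster_sum"] + pg["noncluster_sum"], pg["total"])

    def test_cluster_not_subset_rejected(self):
        cm = build_cm(np.array([[10, 10]]), {"a": "X", "b": "Y"})
        with pytest.raises(CompareError, match="subset"):
            histone_fraction(cm, {"g0", "zz"}, {"g0"}, "X", "Y")

    def test_zero_total_histone_rejected(self):
        cm = build_cm(np.array([[0, 10], [0, 10]]), {"a": "X", "b": "Y"})
        with pytest.raises(CompareError, match="zero total"):
            histone_fraction(cm, {"g0"}, {"g0", "g1"}, "X", "Y")


class TestGroupCorrelation:
    def test_duplicated_sample_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, 500)
        cm = build_cm(np.column_stack([col, col, rng.poisson(100, 500)]),
                      {"a": "X", "b": "Y", "c": "Z"})
        corr = group_correlation(cm, level="sample")
        assert corr[("a", "b")] == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(
            np.exp(rng.normal(3, 1.5, size=(2000, 2))), size=(2000, 2)
        )
        cm = build_cm(counts, {"a": "X", "b": "Y"})
        corr = group_correlation(cm)
        assert abs(corr[("X", "Y")]) < 0.1

    def test_symmetric_with_unit_diagonal(self, default_study):
        _, _, _, cm = default_study
        estimate_size_factors(cm)
        corr = group_correlation(cm)
        r = corr.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_constant_profile_flagged_undefined(self):
        cm = build_cm(np.column_stack([np.full(10, 5), np.arange(10)]),
                      {"a": "X", "b": "Y"})
        corr = group_correlation(cm)
        assert ("X", "Y") in corr.undefined
        assert np.isnan(corr[("X", "Y")])
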