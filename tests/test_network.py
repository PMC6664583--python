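import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pluriscreen as ps
from pluriscreen.network import MIN_P, correlation_pvalue
from tests.conftest import make_log_matrix


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return ps.AdjacencyMatrix(
        pd.DataFrame(a, index=[f"g{i}" for i in range(n)], columns=[f"g{i}" for i in range(n)]),
        beta=1.0,
    )


class TestPairwiseCorrelation:
    def test_self_correlation_is_one(self):
        m = make_log_matrix(np.array([[1.0, 2.0, 3.0], [0.0, 5.0, 1.0]]))
        c = ps.pairwise_correlation(m)
        assert np.allclose(np.diag(c), 1.0)

    def test_negated_profile_gives_minus_one(self):
        x = np.array([1.0, 2.0, 4.0])
        c = ps.pairwise_correlation(make_log_matrix(np.stack([x, -x])))
        assert c.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        c = ps.pairwise_correlation(
            make_log_matrix(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]))
        )
        assert c.iloc[0, 1] == pytest.approx(0.9819805060619659, abs=1e-12)
        ref = stats.pearsonr([1, 2, 3], [1, 2, 4]).statistic
        assert c.iloc[0, 1] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_gene_named(self):
        m = make_log_matrix(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]),
                            genes=["flat", "ok"])
        with pytest.raises(ps.ValidationError, match="flat"):
            ps.pairwise_correlation(m)


class TestSoftThresholdAdjacency:
    def cor(self, r):
        return pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])

    def test_signed_extremes(self):
        assert ps.soft_threshold_adjacency(self.cor(1.0), 20).values.iloc[0, 1] == 1.0
        assert ps.soft_threshold_adjacency(self.cor(-1.0), 7).values.iloc[0, 1] == 0.0

    def test_signed_spot_value(self):
        a = ps.soft_threshold_adjacency(self.cor(0.6), 20).values.iloc[0, 1]
        assert a == pytest.approx(0.8**20, rel=1e-12)
        assert a == pytest.approx(1.15292150460684698e-2, rel=1e-10)

    def test_unsigned_uses_absolute_value(self):
        a = ps.soft_threshold_adjacency(self.cor(-0.5), 2, "unsigned").values.iloc[0, 1]
        assert a == pytest.approx(0.25)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.soft_threshold_adjacency(self.cor(0.5), 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(0.5, 30))
    def test_signed_transform_monotone_in_r(self, r1, r2, beta):
        a1 = ps.soft_threshold_adjacency(self.cor(r1), beta).values.iloc[0, 1]
        a2 = ps.soft_threshold_adjacency(self.cor(r2), beta).values.iloc[0, 1]
        assert 0.0 <= a1 <= 1.0
        if r1 < r2:
            assert a1 <= a2


class TestTopologicalOverlap:
    def test_two_gene_network_equals_adjacency(self):
        adj = ps.AdjacencyMatrix(
            pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=["a", "b"], columns=["a", "b"]),
            beta=1.0,
        )
        tom = ps.topological_overlap(adj)
        assert tom.values.iloc[0, 1] == pytest.approx(0.7, abs=1e-12)

    def test_three_gene_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        adj = ps.AdjacencyMatrix(pd.DataFrame(a, index=list("abc"), columns=list("abc")), 1.0)
        tom = ps.topological_overlap(adj)
        # l_12 = 0.25, k = 1.0 -> (0.25 + 0.5) / (1.0 + 1 - 0.5) = 0.5
        assert tom.values.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_empty_network_stays_empty(self):
        a = np.eye(4)
        adj = ps.AdjacencyMatrix(pd.DataFrame(a, index=list("abcd"), columns=list("abcd")), 1.0)
        tom = ps.topological_overlap(adj).values.to_numpy()
        assert np.allclose(tom - np.eye(4), 0.0)

    def test_non_symmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ps.ValidationError):
            ps.AdjacencyMatrix(pd.DataFrame(a, index=list("abc"), columns=list("abc")), 1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            adj = random_adjacency(rng, 12)
            fast = ps.topological_overlap(adj).values.to_numpy()
            slow = ps.topological_overlap_bruteforce(adj)
            assert np.abs(fast - slow).max() < 1e-10

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 15))
    def test_tom_bounded_with_unit_diagonal(self, seed, n):
        adj = random_adjacency(np.random.default_rng(seed), n)
        tom = ps.topological_overlap(adj).values.to_numpy()
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(np.diag(tom), 1.0)


def block_tom(sizes, within=0.9, between=0.1):
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return ps.TomMatrix(pd.DataFrame(t, index=genes, columns=genes))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        tom = block_tom([4, 3])
        out = ps.detect_modules(tom, cut_height=0.5, min_module_size=2)
        assert out.module_names == ["module_1", "module_2"]
        assert out.genes_in("module_1") == [f"g{i}" for i in range(4)]
        assert out.genes_in("module_2") == [f"g{i}" for i in range(4, 7)]

    def test_everything_grey_when_no_structure(self):
        tom = block_tom([6], within=0.1)  # all dissimilarity 0.9
        out = ps.detect_modules(tom, cut_height=0.5, min_module_size=2)
        assert out.module_names == []
        assert (out.labels == "grey").all()

    def test_single_root_cluster(self):
        tom = block_tom([3, 3])
        out = ps.detect_modules(tom, cut_height=1 - 1e-9, min_module_size=1)
        assert out.module_names == ["module_1"]
        assert (out.labels == "module_1").all()

    def test_min_size_below_one_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.detect_modules(block_tom([4]), cut_height=0.5, min_module_size=0)

    def test_small_clusters_relabelled_grey(self):
        tom = block_tom([5, 2])
        out = ps.detect_modules(tom, cut_height=0.5, min_module_size=3)
        assert out.module_names == ["module_1"]
        assert (out.labels.iloc[5:] == "grey").all()


class TestModuleEigengene:
    def test_single_gene_module_is_zscore(self):
        x = np.array([[3.0, 1.0, 4.0, 1.0, 5.0]])
        m = make_log_matrix(x, genes=["g"])
        eg = ps.module_eigengene(m, ["g"])
        z = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        assert eg.values.to_numpy() == pytest.approx(z, abs=1e-12)
        assert eg.explained_variance == pytest.approx(1.0)

    def test_perfectly_correlated_pair(self):
        base = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        m = make_log_matrix(np.stack([base, 2 * base + 1]))
        eg = ps.module_eigengene(m, ["g0", "g1"])
        z = (base - base.mean()) / base.std(ddof=1)
        assert eg.values.to_numpy() == pytest.approx(z, abs=1e-9)
        assert eg.explained_variance == pytest.approx(1.0)

    def test_planted_factor_recovered(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=55)
        f = (f - f.mean()) / f.std()
        x = rng.normal(5, 1.5, (50, 1)) + 0.9 * f + rng.normal(0, 0.5, (50, 55))
        eg = ps.module_eigengene(make_log_matrix(x), [f"g{i}" for i in range(50)])
        assert abs(np.corrcoef(eg.values, f)[0, 1]) >= 0.99

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 20)) + rng.normal(size=(1, 20))
        m = make_log_matrix(x)
        eg = ps.module_eigengene(m, m.gene_ids)
        c = np.corrcoef(x)
        w = np.linalg.eigvalsh(c)
        assert eg.explained_variance == pytest.approx(w[-1] / w.sum(), abs=1e-10)

    def test_unit_variance_zero_mean_convention(self, default_screen):
        res, _ = default_screen
        for eg in res.network.eigengenes:
            assert eg.values.std(ddof=1) == pytest.approx(1.0)
            assert abs(eg.values.mean()) < 1e-10
            assert 0.0 <= eg.explained_variance <= 1.0

    def test_zero_variance_module_rejected(self):
        m = make_log_matrix(np.ones((2, 4)))
        with pytest.raises(ps.ValidationError):
            ps.module_eigengene(m, ["g0", "g1"])


class TestModuleTraitCorrelation:
    def _set(self, e, samples):
        eg = ps.Eigengene("m", pd.Series(e, index=samples), 1.0)
        s = ps.EigengeneSet()
        s.eigengenes["m"] = eg
        return s

    def test_proportional_indicator_gives_min_p(self):
        samples = list("abcde")
        md = ps.make_sample_metadata(samples, ["hiPSC"] * 2 + ["liver"] * 3)
        design = ps.build_trait_design(md)
        e = design.indicators["PSC"].astype(float)
        e = (e - e.mean()) / e.std(ddof=1)
        res = ps.module_trait_correlation(self._set(e.to_numpy(), samples), design)
        row = res[res["trait"] == "PSC"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-30
        assert correlation_pvalue(1.0, 5) == MIN_P
        assert correlation_pvalue(-1.0, 5) == MIN_P

    def test_orthogonal_indicator_gives_p_one(self):
        samples = list("abcd")
        md = ps.make_sample_metadata(samples, ["hiPSC", "hiPSC", "liver", "liver"])
        design = ps.build_trait_design(md)
        e = np.array([1.0, -1.0, 1.0, -1.0])
        res = ps.module_trait_correlation(self._set(e, samples), design)
        row = res[res["trait"] == "PSC"].iloc[0]
        assert row["r"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_closed_form_t_transform(self):
        # E = standardized (1..5) vs indicator (0,0,0,1,1): r = 3/sqrt(12), t = 3, df = 3
        samples = list("abcde")
        md = ps.make_sample_metadata(samples, ["liver"] * 3 + ["hiPSC"] * 2)
        design = ps.build_trait_design(md)
        e = np.arange(1.0, 6.0)
        e = (e - e.mean()) / e.std(ddof=1)
        res = ps.module_trait_correlation(self._set(e, samples), design)
        row = res[res["trait"] == "PSC"].iloc[0]
        assert row["r"] == pytest.approx(3 / np.sqrt(12), abs=1e-12)
        expected_p = 2 * stats.t.sf(3.0, 3)
        assert row["p"] == pytest.approx(expected_p, abs=1e-12)
        assert row["p"] == pytest.approx(0.0577, abs=2e-4)

    def test_p_agrees_with_t_distribution_everywhere(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            r = float(rng.uniform(-0.999, 0.999))
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert correlation_pvalue(r, n) == pytest.approx(
                2 * stats.t.sf(abs(t), n - 2), abs=1e-12
            )

    def test_bonferroni_option_scales_p(self):
        samples = list("abcde")
        md = ps.make_sample_metadata(samples, ["liver"] * 3 + ["hiPSC"] * 2)
        design = ps.build_trait_design(md)
        e = np.array([0.3, -1.1, 0.2, 1.9, -0.8])
        raw = ps.module_trait_correlation(self._set(e, samples), design)
        adj = ps.module_trait_correlation(self._set(e, samples), design, bonferroni=True)
        assert np.allclose(adj["p"], np.minimum(raw["p"] * len(raw), 1.0))

    def test_constant_indicator_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.TraitDesign(pd.DataFrame({"t": [1, 1, 1]}, index=list("abc")))


class TestSelectTopModules:
    def result(self):
        return pd.DataFrame(
            {
                "module": ["m1", "m2", "m3", "m4"],
                "trait": ["PSC"] * 4,
                "r": [0.9, 0.95, -0.8, 0.5],
                "p": [1e-8, 1e-9, 1e-6, 0.2],
            }
        )

    def test_ranked_by_descending_r_with_alpha(self):
        top = ps.select_top_trait_modules(self.result(), "PSC", k=3, alpha=0.05)
        assert top == ["m2", "m1", "m3"]

    def test_k_larger_than_passing_count(self):
        top = ps.select_top_trait_modules(self.result(), "PSC", k=10, alpha=0.05)
        assert top == ["m2", "m1", "m3"]

    def test_none_passing_returns_empty(self):
        top = ps.select_top_trait_modules(self.result(), "PSC", k=3, alpha=1e-20)
        assert top == []


class TestGeneMembership:
    def test_gene_equal_to_eigengene(self):
        e = np.array([1.0, -1.0, 2.0, 0.0])
        m = make_log_matrix(np.stack([e, -e]))
        eg = ps.Eigengene("m", pd.Series(e, index=m.sample_ids), 1.0)
        k = ps.gene_membership_kme(m, eg)
        assert k.loc["g0", "kme"] == pytest.approx(1.0)
        assert k.loc["g1", "kme"] == pytest.approx(-1.0)

    def test_zero_variance_gene_flagged_not_dropped(self):
        m = make_log_matrix(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        eg = ps.Eigengene("m", pd.Series([1.0, 0.0, -1.0], index=m.sample_ids), 1.0)
        k = ps.gene_membership_kme(m, eg)
        assert bool(k.loc["g0", "undefined"])
        assert np.isnan(k.loc["g0", "kme"])
        assert not k.loc["g1", "undefined"]


class TestBuildNetwork:
    def test_default_network_on_synthetic_data(self, default_screen):
        res, truth = default_screen
        sizes = res.network.assignment.sizes()
        assert len(sizes) == 4  # three tissue modules + pluripotency module
        assert set(res.network.module_trait["trait"]) == {
            "PSC", "hiPSC", "hESC", "liver", "heart", "brain"
        }

    def test_planted_pluripotency_module_ranks_first_for_psc(self, default_screen):
        res, truth = default_screen
        top = ps.select_top_trait_modules(res.network.module_trait, "PSC", k=3)
        genes = set(res.network.assignment.genes_in(top[0]))
        assert set(ps.pgm_gene_set(truth).gene_ids) <= genes
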