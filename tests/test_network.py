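"""Gene mapping, correlation, module detection, annotation and topology."""

import numpy as np
import pandas as pd
import pytest

from epihetkit import (
    GREY,
    EpihetError,
    LocusKey,
    correlation_matrix,
    detect_modules,
    enrich_hypergeometric,
    gene_level_matrix,
    hypergeometric_tail,
    map_loci_to_genes,
    module_eigengenes,
    module_pc1,
    module_topology,
    module_trait_correlation,
    read_bed,
    read_gmt,
)
from epihetkit.network import pearson_with_p


def annotation(*rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene", "region_class"]
    )


class TestGeneMapping:
    def test_overlap_one_bp(self):
        locus = LocusKey("chr1", (100, 110, 120, 130))
        ann = annotation(("chr1", 120, 200, "+", "G1", "promoter"))
        df = map_loci_to_genes([locus], ann)
        assert df["gene"].tolist() == ["G1"]

    def test_half_open_boundary_not_mapped(self):
        locus = LocusKey("chr1", (100, 110, 120, 130))
        # locus span is [100, 131); interval [131, 200) shares no base
        ann = annotation(("chr1", 131, 200, "+", "G1", "promoter"))
        df = map_loci_to_genes([locus], ann)
        assert df["gene"].isna().all()

    def test_last_cpg_base_counts(self):
        locus = LocusKey("chr1", (100, 110, 120, 130))
        ann = annotation(("chr1", 130, 200, "+", "G1", "exon"))
        assert map_loci_to_genes([locus], ann)["gene"].tolist() == ["G1"]

    def test_multi_gene_assignment(self):
        locus = LocusKey("chr1", (100, 110, 120, 130))
        ann = annotation(
            ("chr1", 90, 115, "+", "G1", "promoter"),
            ("chr1", 115, 200, "-", "G2", "promoter"),
        )
        assert sorted(map_loci_to_genes([locus], ann)["gene"]) == ["G1", "G2"]

    def test_bed_reader_rejects_malformed(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\n")
        with pytest.raises(EpihetError, match="1"):
            read_bed(str(bad))

    def test_bed_reader_round_trip(self, tmp_path):
        bed = tmp_path / "ann.bed"
        bed.write_text("chr1\t100\t200\tG1\t0\t+\tpromoter\nchr2\t5\t50\tG2\n")
        df = read_bed(str(bed))
        assert df.loc[0, "region_class"] == "promoter"
        assert df.loc[1, "region_class"] == "custom"
        assert df.loc[1, "strand"] == "."


class TestGeneLevelMatrix:
    def test_mean_over_gene_loci(self):
        values = pd.DataFrame(
            {"s1": [0.2, 0.4], "s2": [0.6, np.nan]}, index=["l1", "l2"]
        )
        assignments = pd.DataFrame({"locus": ["l1", "l2"], "gene": ["G", "G"],
                                    "region_class": ["promoter"] * 2})
        out = gene_level_matrix(values, assignments)
        assert out.loc["G", "s1"] == pytest.approx(0.3)
        assert out.loc["G", "s2"] == pytest.approx(0.6)  # mean over non-missing

    def test_single_locus_gene_equals_locus_row(self):
        values = pd.DataFrame({"s1": [0.2], "s2": [0.7]}, index=["l1"])
        assignments = pd.DataFrame({"locus": ["l1"], "gene": ["G"],
                                    "region_class": ["intron"]})
        out = gene_level_matrix(values, assignments)
        pd.testing.assert_series_equal(
            out.loc["G"], values.loc["l1"], check_names=False
        )

    def test_all_missing_cell_stays_missing(self):
        values = pd.DataFrame({"s1": [np.nan], "s2": [0.7]}, index=["l1"])
        assignments = pd.DataFrame({"locus": ["l1"], "gene": ["G"],
                                    "region_class": ["cgi"]})
        assert np.isnan(gene_level_matrix(values, assignments).loc["G", "s1"])


class TestCorrelationMatrix:
    def _values(self, rows, samples=8, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.random((rows, samples)),
                            index=[f"n{i}" for i in range(rows)])

    def test_perfect_linear(self):
        x = np.arange(8, dtype=float)
        values = pd.DataFrame([x, 2 * x + 1, -x], index=["x", "y", "z"])
        for method in ("pearson", "bicor"):
            C = correlation_matrix(values, method)
            assert C.loc["x", "y"] == pytest.approx(1.0)
            assert C.loc["x", "z"] == pytest.approx(-1.0)
            assert np.allclose(np.diag(C), 1.0)

    def test_bicor_matches_direct_formula_with_outlier(self):
        rng = np.random.default_rng(5)
        x = rng.random(8)
        y = 0.8 * x + 0.1 * rng.random(8)
        y[3] = 25.0  # gross outlier
        values = pd.DataFrame([x, y], index=["x", "y"])
        C = correlation_matrix(values, "bicor")

        def bicor_oracle(x, y):
            def prep(v):
                med = np.median(v)
                mad = np.median(np.abs(v - med))
                u = (v - med) / (9 * mad)
                w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
                t = (v - med) * w
                return t / np.sqrt((t ** 2).sum())

            return float(prep(x) @ prep(y))

        assert C.loc["x", "y"] == pytest.approx(bicor_oracle(x, y), abs=1e-10)

    def test_constant_row_excluded(self):
        values = self._values(3)
        values.loc["n0"] = 0.5
        C = correlation_matrix(values, "pearson")
        assert "n0" not in C.index and C.shape == (2, 2)

    def test_symmetry(self):
        C = correlation_matrix(self._values(6), "bicor")
        np.testing.assert_allclose(C.to_numpy(), C.to_numpy().T, atol=1e-12)

    def test_needs_three_samples(self):
        with pytest.raises(EpihetError):
            correlation_matrix(self._values(4, samples=2))


class TestDetectModules:
    def test_planted_blocks_recovered(self, module_cohort):
        from sklearn.metrics import adjusted_rand_score

        C = correlation_matrix(module_cohort.values)
        modules = detect_modules(C)
        assert len(modules.modules) == 2
        pred = [modules.labels[n] for n in module_cohort.values.index]
        ari = adjusted_rand_score(module_cohort.partition.tolist(), pred)
        assert ari >= 0.9

    def test_small_input_all_grey(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.random((10, 8)), index=[f"n{i}" for i in range(10)])
        modules = detect_modules(correlation_matrix(values), min_module_size=30)
        assert set(modules.labels.values()) == {GREY}

    def test_node_order_invariance(self, module_cohort):
        C = correlation_matrix(module_cohort.values)
        m1 = detect_modules(C)
        rng = np.random.default_rng(0)
        perm = rng.permutation(C.index)
        m2 = detect_modules(C.loc[perm, perm])
        # same partition: members grouped identically regardless of input order
        part1 = {frozenset(v) for v in m1.modules.values()}
        part2 = {frozenset(v) for v in m2.modules.values()}
        assert part1 == part2

    def test_grey_nodes_never_in_member_lists(self, module_cohort):
        C = correlation_matrix(module_cohort.values)
        modules = detect_modules(C)
        greys = {n for n, c in modules.labels.items() if c == GREY}
        for members in modules.modules.values():
            assert not (greys & set(members))


class TestModulePc1:
    def test_identical_rows(self):
        values = pd.DataFrame(
            np.tile(np.array([0.1, 0.5, 0.3, 0.8, 0.2, 0.6]), (5, 1)),
            index=[f"n{i}" for i in range(5)],
        )
        score, ve = module_pc1(values, values.index)
        assert ve == pytest.approx(1.0)
        mean_profile = values.mean(axis=0)
        r = np.corrcoef(score, mean_profile)[0, 1]
        assert abs(r) == pytest.approx(1.0) and r > 0

    def test_orientation_rule_fixes_sign(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.random((30, 8)), index=[f"n{i}" for i in range(30)])
        score, _ = module_pc1(values, values.index)
        centered = (values - values.values.mean(axis=1, keepdims=True)) / values.values.std(
            axis=1, ddof=1, keepdims=True
        )
        assert np.dot(score, centered.mean(axis=0) - centered.mean(axis=0).mean()) >= 0

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.random((30, 8)), index=[f"n{i}" for i in range(30)])
        score, ve = module_pc1(values, values.index)
        X = values.to_numpy()
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(X.T @ X)
        v = evecs[:, -1]
        scale = np.linalg.norm(score.to_numpy())
        oracle = v / np.linalg.norm(v) * scale
        diff = min(np.abs(score - oracle).max(), np.abs(score + oracle).max())
        assert diff < 1e-8
        assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_degenerate_module_error(self):
        values = pd.DataFrame(np.full((4, 6), 0.2), index=list("abcd"))
        with pytest.raises(EpihetError):
            module_pc1(values, values.index)


class TestModuleTraitCorrelation:
    def test_trait_equal_to_pc1(self):
        rng = np.random.default_rng(9)
        pc1 = pd.DataFrame(rng.random((2, 8)), index=["blue", "turquoise"],
                           columns=[f"s{i}" for i in range(8)])
        traits = pd.DataFrame({"age": pc1.loc["blue"]})
        r, p = module_trait_correlation(pc1, traits)
        assert r.loc["blue", "age"] == pytest.approx(1.0)
        assert p.loc["blue", "age"] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_closed_form(self):
        rng = np.random.default_rng(10)
        pc1 = pd.DataFrame(rng.random((1, 8)), index=["m"],
                           columns=[f"s{i}" for i in range(8)])
        traits = pd.DataFrame(
            {"t": rng.random(8)}, index=pc1.columns
        )
        r, p = module_trait_correlation(pc1, traits)
        from scipy.stats import pearsonr

        r_o, p_o = pearsonr(pc1.loc["m"], traits["t"])
        assert r.loc["m", "t"] == pytest.approx(r_o, abs=1e-12)
        assert p.loc["m", "t"] == pytest.approx(p_o, abs=1e-10)

    def test_null_p_values_roughly_uniform(self):
        """Independent trait: p-values uniform within a 99% KS band."""
        rng = np.random.default_rng(11)
        n = 1000
        ps = np.empty(n)
        for i in range(n):
            x, y = rng.random(10), rng.random(10)
            _, ps[i] = pearson_with_p(x, y)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_trait_flagged_nan(self):
        pc1 = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["m"],
                           columns=list("abcd"))
        traits = pd.DataFrame({"t": [1.0] * 4}, index=list("abcd"))
        r, p = module_trait_correlation(pc1, traits)
        assert np.isnan(r.loc["m", "t"])


class TestEnrichment:
    def test_exact_tail_summation(self):
        from math import comb

        N, K, n, k = 100, 10, 20, 5
        oracle = sum(
            comb(K, j) * comb(N - K, n - j) for j in range(k, K + 1)
        ) / comb(N, n)
        assert hypergeometric_tail(k, N, K, n) == pytest.approx(oracle, abs=1e-12)

    def test_zero_overlap_p_one(self):
        assert hypergeometric_tail(0, 100, 10, 20) == 1.0

    def test_module_equal_to_set_is_minimal_p(self):
        universe = [f"g{i}" for i in range(50)]
        gene_set = set(universe[:10])
        df = enrich_hypergeometric({"blue": gene_set}, {"S": gene_set}, universe)
        k, n = df.loc[0, "k"], df.loc[0, "module_size"]
        assert k == n == 10
        worse = hypergeometric_tail(9, 50, 10, 10)
        assert df.loc[0, "p"] <= worse

    def test_relabeling_invariance(self):
        universe = [f"g{i}" for i in range(40)]
        relabel = {g: f"x_{g}" for g in universe}
        mod, gs = set(universe[:15]), set(universe[10:20])
        p1 = enrich_hypergeometric({"m": mod}, {"s": gs}, universe).loc[0, "p"]
        p2 = enrich_hypergeometric(
            {"m": {relabel[g] for g in mod}},
            {"s": {relabel[g] for g in gs}},
            [relabel[g] for g in universe],
        ).loc[0, "p"]
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_set_outside_universe_error(self):
        with pytest.raises(EpihetError):
            enrich_hypergeometric({"m": {"g1", "zzz"}}, {"s": {"g1"}}, ["g1", "g2"])

    def test_deg_fallback_flags_containing_modules(self):
        universe = [f"g{i}" for i in range(1000)]
        df = enrich_hypergeometric(
            {"m1": set(universe[:30]), "m2": set(universe[30:60])},
            {"degs": {universe[0], universe[999]}},
            universe,
            deg_fallback=True,
        )
        assert not df["significant"].any()
        assert df.set_index("module")["contains_genes"].to_dict() == {
            "m1": True, "m2": False
        }

    def test_gmt_reader(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("S1\tdesc\tg1\tg2\nS2\tdesc\tg3\n")
        sets = read_gmt(str(gmt))
        assert sets == {"S1": {"g1", "g2"}, "S2": {"g3"}}


class TestTopology:
    def _cor(self, edges, nodes):
        C = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
        for a, b, w in edges:
            C.loc[a, b] = C.loc[b, a] = w
        return C

    def test_complete_module_degrees(self):
        nodes = list("abcd")
        edges = [(x, y, 0.9) for i, x in enumerate(nodes) for y in nodes[i + 1:]]
        topo = module_topology(nodes, self._cor(edges, nodes), edge_cutoff=0.2)
        assert (topo["degree"] == 3).all()

    def test_path_graph_betweenness(self):
        nodes = list("abc")
        C = self._cor([("a", "b", 0.8), ("b", "c", 0.8)], nodes)
        topo = module_topology(nodes, C, edge_cutoff=0.2)
        assert topo.loc["b", "betweenness"] > topo.loc["a", "betweenness"]

    def test_star_graph_hand_computed(self):
        """Hub vs leaf closeness and eigenvector centrality on a 5-node star."""
        nodes = ["hub", "l1", "l2", "l3", "l4"]
        C = self._cor([("hub", l, 0.9) for l in nodes[1:]], nodes)
        topo = module_topology(nodes, C, edge_cutoff=0.2)
        # brute-force all-pairs shortest paths: hub distance sum 4, leaves 1+2*3=7
        assert topo.loc["hub", "closeness"] == pytest.approx(1.0)
        assert topo.loc["l1", "closeness"] == pytest.approx(4 / 7)
        # power-iteration oracle on the adjacency (identity shift: the star
        # is bipartite, so plain iteration would oscillate)
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1
        v = np.ones(5)
        for _ in range(200):
            v = (A + np.eye(5)) @ v
            v /= np.linalg.norm(v)
        v = np.abs(v) / np.abs(v).sum()
        assert topo.loc["hub", "eigenvector"] == pytest.approx(v[0], abs=1e-8)
        assert topo.loc["l1", "eigenvector"] == pytest.approx(v[1], abs=1e-8)

    def test_isolated_nodes_zeroed(self):
        nodes = list("abc")
        C = self._cor([("a", "b", 0.9)], nodes)
        topo = module_topology(nodes, C, edge_cutoff=0.5)
        assert topo.loc["c", ["degree", "eigenvector", "betweenness", "closeness"]].eq(0).all()

    def test_edge_cutoff_uses_absolute_correlation(self):
        nodes = list("ab")
        C = self._cor([("a", "b", -0.9)], nodes)
        topo = module_topology(nodes, C, edge_cutoff=0.2)
        assert topo.loc["a", "degree"] == 1


class TestEndToEndModuleTrait:
    def test_planted_module_trait_association(self, module_cohort):
        """Pipeline recovers the generating factor: |r(PC1, factor)| >= 0.9."""
        C = correlation_matrix(module_cohort.values)
        modules = detect_modules(C)
        pc1 = module_eigengenes(module_cohort.values, modules)
        r, p = module_trait_correlation(pc1, module_cohort.traits)
        best = r["trait"].abs().max()
        assert best >= 0.9
        # the associated module is (mostly) the planted trait-driving one
        top = r["trait"].abs().idxmax()
        members = set(modules.members(top))
        planted = set(
            module_cohort.partition.index[module_cohort.partition == "module1"]
        )
        assert len(members & planted) / len(planted) >= 0.9
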