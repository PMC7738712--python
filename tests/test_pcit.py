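"""PCIT network inference: closed forms, naive-oracle equivalence,
permutation invariance and planted-pair retention."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pubernet import (
    ExpressionMatrix,
    SimulationConfig,
    build_input_list,
    correlation_matrix,
    export_network,
    generate_expression,
    partial_correlation,
    pcit_filter,
)
from pubernet.pcit import read_sif, write_edge_list


def naive_pcit_edges(r: np.ndarray) -> set[tuple[int, int]]:
    """Independent reference: explicit three-level loop over all trios,
    scalar arithmetic only."""
    n = r.shape[0]
    keep = {(i, j): True for i, j in itertools.combinations(range(n), 2)}
    if n <= 2:
        return {p for p, k in keep.items() if k}

    def usable(v):
        return 0.0 < abs(v) < 1.0

    for i, j in itertools.combinations(range(n), 2):
        for z in range(n):
            if z in (i, j):
                continue
            rij, riz, rjz = r[i, j], r[i, z], r[j, z]
            if not (usable(rij) and usable(riz) and usable(rjz)):
                continue  # degenerate trio: no tolerance computed
            pij = (rij - riz * rjz) / math.sqrt((1 - riz**2) * (1 - rjz**2))
            piz = (riz - rij * rjz) / math.sqrt((1 - rij**2) * (1 - rjz**2))
            pjz = (rjz - rij * riz) / math.sqrt((1 - rij**2) * (1 - riz**2))
            eps = (pij / rij + piz / riz + pjz / rjz) / 3.0
            if abs(rij) <= abs(eps * riz) and abs(rij) <= abs(eps * rjz):
                keep[(i, j)] = False
                break
    return {p for p, k in keep.items() if k}


def corr_from_data(rng, n, m=12):
    x = rng.standard_normal((n, m))
    r = np.corrcoef(x)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(r, index=ids, columns=ids)


class TestBuildInputList:
    def make_de(self, flags):
        return pd.DataFrame(
            {"dex_flag": list(flags.values())}, index=list(flags.keys())
        )

    def test_union_and_order(self):
        de = self.make_de({"g3": True, "g1": True, "g2": False})
        out = build_input_list(de, ["t2", "t1", "g1"], ["g1", "g2", "g3", "t1", "t2"])
        assert out == ["g1", "g3", "t1", "t2"]  # DE first, TFs after, no dupes

    def test_disjoint_sizes_add(self):
        de = self.make_de({"a": True, "b": True, "c": True})
        out = build_input_list(de, ["x", "y", "z", "w"],
                               ["a", "b", "c", "x", "y", "z", "w"])
        assert len(out) == 7

    def test_empty_union_rejected(self):
        de = self.make_de({"a": False})
        with pytest.raises(ValueError, match="empty input list"):
            build_input_list(de, [], ["a"])


class TestCorrelationMatrix:
    def test_definitional_oracle(self, rng):
        x = rng.standard_normal((10, 8))
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=[f"g{i}" for i in range(10)],
                         columns=[f"s{j}" for j in range(8)]),
            scale="log2",
        )
        r = correlation_matrix(expr)
        for i in range(0, 10, 3):
            for j in range(0, 10, 3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
                assert r.iloc[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(r, r.T, atol=1e-12)
        assert np.allclose(np.diag(r), 1.0)

    def test_anticorrelated_pair(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [-1.0, -2.0, -3.0, -4.0]])
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=["a", "b"], columns=list("wxyz")), scale="log2"
        )
        assert correlation_matrix(expr).loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_gene_named(self):
        x = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=["flat", "ok"], columns=list("wxyz")),
            scale="log2",
        )
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(expr)


class TestPartialCorrelation:
    def test_closed_form(self):
        assert partial_correlation(0.9, 0.8, 0.8) == pytest.approx(0.26 / 0.36)
        # conditioning on an independent gene changes nothing
        assert partial_correlation(0.42, 0.0, 0.0) == pytest.approx(0.42)

    def test_symmetry_in_x_and_y(self, rng):
        for _ in range(20):
            rxy, rxz, ryz = rng.uniform(-0.9, 0.9, size=3)
            assert partial_correlation(rxy, rxz, ryz) == pytest.approx(
                partial_correlation(rxy, ryz, rxz)
            )

    def test_collinear_trio_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(0.5, 1.0, 0.3)


class TestPcitFilter:
    def test_two_genes_always_connected(self):
        c = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        net = pcit_filter(c)
        assert net.number_of_edges() == 1
        assert net["a"]["b"]["weight"] == pytest.approx(0.5)

    def test_mediated_trio_behavior(self):
        """Exact mediation r_xy = r_xz * r_yz: at moderate correlation the
        indirect edge falls below the trio tolerance and is removed; at
        strong correlation (0.8) the indirect 0.64 edge survives because
        the tolerance-scaled comparison 0.64 > eps*0.8 keeps it — both
        verified against the naive reference loop."""
        for rho in (0.5, 0.8):
            c = np.array([[1, rho**2, rho], [rho**2, 1, rho], [rho, rho, 1.0]])
            cdf = pd.DataFrame(c, index=list("xyz"), columns=list("xyz"))
            got = {tuple(sorted(e)) for e in pcit_filter(cdf).edges()}
            ids = list("xyz")
            expected = {
                tuple(sorted((ids[i], ids[j])))
                for i, j in naive_pcit_edges(c)
            }
            assert got == expected
            assert ("x", "z") in got and ("y", "z") in got
            if rho == 0.5:
                assert ("x", "y") not in got

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 26))
        corr = corr_from_data(rng, n)
        got = {tuple(sorted(e)) for e in pcit_filter(corr).edges()}
        ids = list(corr.index)
        expected = {
            tuple(sorted((ids[i], ids[j])))
            for i, j in naive_pcit_edges(corr.to_numpy())
        }
        assert got == expected

    def test_permutation_invariance(self, rng):
        corr = corr_from_data(rng, 15)
        perm = list(rng.permutation(corr.index))
        net = pcit_filter(corr)
        net_p = pcit_filter(corr.loc[perm, perm])
        assert {tuple(sorted(e)) for e in net.edges()} == {
            tuple(sorted(e)) for e in net_p.edges()
        }

    def test_all_nodes_present_including_isolated(self, rng):
        corr = corr_from_data(rng, 10)
        net = pcit_filter(corr)
        assert set(net.nodes()) == set(corr.index)

    def test_degenerate_unit_correlation_skipped_not_fatal(self):
        # duplicated gene: correlation exactly 1 with its copy
        c = np.array(
            [[1.0, 1.0, 0.3], [1.0, 1.0, 0.3], [0.3, 0.3, 1.0]]
        )
        cdf = pd.DataFrame(c, index=list("abc"), columns=list("abc"))
        from pubernet.pcit import pcit_filter as pf

        res = pf(cdf, with_diagnostics=True)
        assert res.n_degenerate_trios > 0
        assert res.network.number_of_nodes() == 3

    def test_planted_pairs_retained_above_background(self):
        """Pairs co-expressed at |rho| = 0.8 in both groups survive the
        filter at >= 90%, far above the retention of independent pairs.
        (Differentially wired pairs are deliberately excluded: their
        pooled correlation cancels between groups by construction.)"""
        planted_kept = indep_kept = planted_tot = indep_tot = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_regulators=0, wiring_targets_per_regulator=0,
                n_hubs=1, hub_degree=10, hub_rho=0.8, frac_silent=0.0,
            )
            expr, _, truth = generate_expression(cfg)
            hub = truth.hub_ids[0]
            partners = truth.hub_partners[hub]
            free = [g for g in truth.gene_ids
                    if g not in set(partners) | {hub}
                    | set(truth.de_gene_ids)][:40]
            sub_ids = [hub] + partners + free
            sub = ExpressionMatrix(expr.data.loc[sub_ids], scale="log2")
            net = pcit_filter(correlation_matrix(sub))
            for p in partners:
                planted_tot += 1
                planted_kept += net.has_edge(hub, p)
            for i in range(0, 38, 2):
                indep_tot += 1
                indep_kept += net.has_edge(free[i], free[i + 1])
        planted_rate = planted_kept / planted_tot
        assert planted_rate >= 0.9
        assert indep_kept / indep_tot < planted_rate


class TestExport:
    def test_sif_round_trip_with_singleton(self, tmp_path):
        net = nx.Graph()
        net.add_weighted_edges_from([("a", "b", 0.7)])
        net.add_node("lonely")
        p = tmp_path / "net.sif"
        export_network(net, str(p), fmt="sif")
        lines = p.read_text().splitlines()
        assert "a\tco\tb" in lines and "lonely" in lines
        back = read_sif(str(p))
        assert set(back.nodes()) == {"a", "b", "lonely"}
        assert back.has_edge("a", "b")

    def test_graphml_round_trip_preserves_weights(self, tmp_path):
        net = nx.Graph()
        net.add_weighted_edges_from([("a", "b", 0.7), ("b", "c", -0.4)])
        p = tmp_path / "net.graphml"
        export_network(net, str(p), fmt="graphml")
        back = nx.read_graphml(str(p))
        assert back["a"]["b"]["weight"] == pytest.approx(0.7)
        assert back["b"]["c"]["weight"] == pytest.approx(-0.4)

    def test_unknown_format_rejected(self):
        net = nx.Graph()
        net.add_edge("a", "b")
        with pytest.raises(ValueError, match="unknown network format"):
            export_network(net, "out.xyz", fmt="xyz")

    def test_edge_list_tsv(self, tmp_path):
        net = nx.Graph()
        net.add_weighted_edges_from([("a", "b", 0.5)])
        p = tmp_path / "edges.tsv"
        write_edge_list(net, str(p))
        df = pd.read_csv(p, sep="\t")
        assert list(df.columns) == ["idA", "idB", "weight"]
        assert df.loc[0, "weight"] == pytest.approx(0.5)
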