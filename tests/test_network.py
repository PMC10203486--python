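"""Mass-difference transformation networks."""

import numpy as np
import pytest

from phenolstress.formulas import monoisotopic_mass, parse_formula
from phenolstress.network import (Transformation, build_network,
                                  default_transformations, hetero_group_of,
                                  load_transformations, summarize_network,
                                  to_networkx, write_network_tables,
                                  write_transformations)


def brute_force_edges(mzs, transformations, tol_ppm):
    """O(n^2 * |T|) double-loop oracle for build_network (ppm mode)."""
    out = set()
    for i, a in enumerate(mzs):
        for b in mzs[i + 1:] + mzs[:i]:
            lo, hi = min(a, b), max(a, b)
            if lo == hi:
                continue
            for t in transformations:
                if abs((hi - lo) - t.exact_mass) <= tol_ppm * 1e-6 * hi:
                    out.add((lo, hi, t.name))
    return out


@pytest.fixture
def glycine() -> Transformation:
    return Transformation(name="glycine residue", exact_mass=57.02146)


class TestBuildNetwork:
    def test_exact_difference_yields_one_edge(self, glycine):
        nodes, edges = build_network([300.00000, 357.02146], [glycine])
        assert len(edges) == 1
        assert edges[0].match_error_ppm == pytest.approx(0.0, abs=1e-6)
        assert edges[0].node_hi > edges[0].node_lo

    def test_off_by_ten_ppm_yields_none(self, glycine):
        _, edges = build_network([300.0, 357.0250], [glycine])
        assert edges == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        mzs = list(rng.uniform(150, 900, 60))
        trans = default_transformations()
        _, edges = build_network(mzs, trans, tol_ppm=2)
        got = {(e.node_lo, e.node_hi, e.transformation) for e in edges}
        assert got == brute_force_edges(mzs, trans, 2)

    def test_node_order_invariance(self):
        rng = np.random.default_rng(5)
        mzs = list(rng.uniform(150, 900, 40))
        trans = default_transformations()
        _, e1 = build_network(mzs, trans)
        _, e2 = build_network(mzs[::-1], trans)
        key = lambda es: {(e.node_lo, e.node_hi, e.transformation) for e in es}
        assert key(e1) == key(e2)

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(11)
        mzs = list(rng.uniform(150, 900, 50))
        trans = default_transformations()
        key = lambda es: {(e.node_lo, e.node_hi, e.transformation) for e in es}
        _, narrow = build_network(mzs, trans, tol_ppm=1)
        _, wide = build_network(mzs, trans, tol_ppm=2)
        assert key(narrow) <= key(wide)

    def test_no_self_edges_positive_deltas(self):
        rng = np.random.default_rng(13)
        mzs = list(rng.uniform(150, 900, 40))
        _, edges = build_network(mzs, default_transformations())
        for e in edges:
            assert e.delta_observed > 0
            assert e.node_hi > e.node_lo

    def test_multi_edges_retained(self):
        # two transformations with masses within tolerance of each other
        t1 = Transformation(name="a", exact_mass=57.02146)
        t2 = Transformation(name="b", exact_mass=57.02149)
        _, edges = build_network([300.0, 357.02146], [t1, t2], tol_ppm=2)
        assert {e.transformation for e in edges} == {"a", "b"}

    def test_mda_mode(self, glycine):
        _, edges = build_network([300.0, 357.0219], [glycine],
                                 tol_mode="mda", tol_mda=0.5)
        assert len(edges) == 1
        _, edges = build_network([300.0, 357.0226], [glycine],
                                 tol_mode="mda", tol_mda=0.5)
        assert edges == []

    def test_fewer_than_two_nodes_raises(self, glycine):
        with pytest.raises(ValueError):
            build_network([300.0], [glycine])


class TestSummarize:
    def test_edge_counting(self, glycine):
        # plant three differences: two glycine, one adenine
        ade = Transformation(name="adenine", exact_mass=135.0545, hetero_group=2)
        mzs = [300.0, 357.02146, 414.04292, 635.0545, 500.0]
        _, edges = build_network(mzs, [glycine, ade], tol_ppm=2)
        s = summarize_network(edges, [glycine, ade], n_nodes=5)
        assert s.n_edges == 3
        assert s.abundance["glycine residue"] == pytest.approx(2 / 3)
        assert s.abundance["adenine"] == pytest.approx(1 / 3)
        assert sum(s.abundance.values()) == pytest.approx(1.0)
        assert s.group_totals[2] == pytest.approx(1 / 3)

    def test_planted_transformations_recovered(self):
        trans = default_transformations()[:10]
        base = 300.0
        mzs = [base] + [base + t.exact_mass for t in trans]
        _, edges = build_network(mzs, trans, tol_ppm=2)
        found = {e.transformation for e in edges}
        assert found >= {t.name for t in trans}

    def test_empty_edge_set_is_not_a_crash(self, glycine):
        s = summarize_network([], [glycine], n_nodes=2)
        assert s.n_edges == 0
        assert s.abundance == {}


class TestTransformationTables:
    def test_default_table_masses_match_formulas(self):
        for t in default_transformations():
            assert t.exact_mass == pytest.approx(
                monoisotopic_mass(t.formula), abs=1e-9)

    def test_default_table_group_taxonomy(self):
        by_name = {t.name: t for t in default_transformations()}
        assert by_name["cysteine residue"].hetero_group == 1      # sulfur
        assert by_name["adenine"].hetero_group == 2               # N only
        assert by_name["glycine residue"].hetero_group == 3       # N and O
        assert by_name["hexose residue"].hetero_group == 4        # O only
        assert by_name["methylation"].hetero_group == 0           # ungrouped

    def test_hetero_group_of(self):
        assert hetero_group_of(parse_formula("SO3")) == 1
        assert hetero_group_of(parse_formula("C5H5N5")) == 2
        assert hetero_group_of(parse_formula("CH4N2O")) == 3
        assert hetero_group_of(parse_formula("CO2")) == 4
        assert hetero_group_of(parse_formula("C2H4")) == 0

    def test_round_trip_through_csv(self, tmp_path):
        path = tmp_path / "trans.csv"
        write_transformations(default_transformations(), path)
        back = load_transformations(path)
        assert [t.name for t in back] == [t.name for t in default_transformations()]
        assert all(b.hetero_group == d.hetero_group
                   for b, d in zip(back, default_transformations()))

    def test_glycine_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,exact_mass\nglycine_residue,57.02146\n")
        (t,) = load_transformations(p)
        assert t.exact_mass == pytest.approx(57.02146)

    def test_mass_formula_mismatch_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,exact_mass,formula\nbad,57.0250,C2H3NO\n")
        with pytest.raises(ValueError, match="differs from"):
            load_transformations(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,exact_mass\nx,57.02146\nx,71.03711\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_transformations(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,exact_mass\n")
        with pytest.raises(ValueError):
            load_transformations(p)


class TestExport:
    def test_tables_round_trip_counts(self, tmp_path, glycine):
        nodes, edges = build_network([300.0, 357.02146], [glycine])
        npath, epath = write_network_tables(nodes, edges, tmp_path / "net")
        import pandas as pd
        assert len(pd.read_csv(npath)) == 2
        assert len(pd.read_csv(epath)) == 1

    def test_networkx_graph(self, glycine):
        nodes, edges = build_network([300.0, 357.02146, 500.0], [glycine])
        g = to_networkx(nodes, edges)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 1
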