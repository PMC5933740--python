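import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cscnet import data_io
from cscnet.errors import FormatError, UsageError
from cscnet.types import (
    CoreNetwork,
    DrugTargetTable,
    ExpressionProfile,
    PathwayGraph,
    RegulatoryNetwork,
)
from conftest import make_pathway


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


# ---------------------------------------------------------------------------
# expression


class TestExpression:
    def test_reads_values_and_missing(self, tmp_path):
        p = _write(tmp_path, "e.tsv",
                   "gene\tlog2fc\nELK1\t0.48\nNRF1\t1.59\nTAL1_TCF4\tNA\n")
        prof = data_io.read_expression(p, "d1")
        assert prof.values == {"ELK1": 0.48, "NRF1": 1.59}
        assert "TAL1_TCF4" in prof.universe and prof.get("TAL1_TCF4") is None

    def test_duplicates_keep_max_abs(self, tmp_path):
        p = _write(tmp_path, "e.tsv",
                   "gene\tlog2fc\nG\t1.0\nG\t3.0\nH\t-2.5\nH\t2.0\n")
        prof = data_io.read_expression(p, "d1")
        assert prof.get("G") == 3.0
        assert prof.get("H") == -2.5

    def test_symbols_normalized(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "gene\tlog2fc\n elk1 \t1.0\n")
        assert data_io.read_expression(p, "d").get("ELK1") == 1.0

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "gene\tfc\nA\t1.0\n")
        with pytest.raises(FormatError, match="log2fc"):
            data_io.read_expression(p, "d1")

    def test_non_numeric_names_line(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "gene\tlog2fc\nA\t1.0\nB\txyz\n")
        with pytest.raises(FormatError, match=":3"):
            data_io.read_expression(p, "d1")


# ---------------------------------------------------------------------------
# regulatory network / drugs


class TestNetworkAndDrugs:
    def test_duplicate_rows_collapse(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "tf\ttarget\nT\tA\nT\tA\nT\tB\n")
        net = data_io.read_regulatory_network(p)
        assert net.edges == frozenset([("T", "A"), ("T", "B")])

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "tf\ttarget\n")
        with pytest.raises(FormatError):
            data_io.read_regulatory_network(p)

    def test_empty_target_rejected_with_line(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "tf\ttarget\nT\tA\nT\t\n")
        with pytest.raises(FormatError, match=":3"):
            data_io.read_regulatory_network(p)

    def test_drug_table_dedupes(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "drug\ttarget\nAspirin\tptgs1\nAspirin\tPTGS1\n")
        table = data_io.read_drug_table(p)
        assert table.rows == frozenset([("Aspirin", "PTGS1")])


# ---------------------------------------------------------------------------
# pathway TSV


class TestPathwayTsv:
    def test_groups_by_pathway_and_entries(self, tmp_path):
        p = _write(
            tmp_path, "p.tsv",
            "pathway_id\tsource\ttarget\tinteraction\tis_entry\n"
            "pw1\tE\t\t\t1\n"
            "pw1\tE\tA\tactivation\t\n"
            "pw2\tX\tY\t\t\n",
        )
        graphs = {g.pathway_id: g for g in data_io.read_pathway_tsv(p)}
        assert set(graphs) == {"pw1", "pw2"}
        assert graphs["pw1"].entry_nodes == frozenset({"E"})
        assert graphs["pw1"].edge_labels[("E", "A")] == "activation"

    def test_blank_pathway_id_rejected(self, tmp_path):
        p = _write(tmp_path, "p.tsv", "pathway_id\tsource\ttarget\n\tA\tB\n")
        with pytest.raises(FormatError, match=":2"):
            data_io.read_pathway_tsv(p)


# ---------------------------------------------------------------------------
# KGML subset


KGML = """<?xml version="1.0"?>
<pathway name="path:test01" title="demo">
  <entry id="1" type="gene"><graphics name="A, ALIAS1"/></entry>
  <entry id="2" type="gene"><graphics name="B"/></entry>
  <entry id="3" type="gene"><graphics name="C..."/></entry>
  <entry id="9" type="map"><graphics name="another map"/></entry>
  <relation entry1="1" entry2="2" type="PPrel"><subtype name="activation"/></relation>
  <relation entry1="2" entry2="3" type="PPrel"/>
  <relation entry1="9" entry2="2" type="maplink"/>
</pathway>
"""


class TestKgml:
    def test_parses_gene_entries_and_relations(self, tmp_path, caplog):
        p = _write(tmp_path, "t.xml", KGML)
        with caplog.at_level("WARNING"):
            g = data_io.read_pathway_kgml(p)
        assert g.nodes == frozenset({"A", "B", "C"})
        assert g.edges == frozenset({("A", "B"), ("B", "C")})
        assert g.edge_labels[("A", "B")] == "activation"
        assert g.entry_nodes == frozenset()
        assert any("type 'map'" in m for m in caplog.messages)

    def test_undeclared_relation_id_is_located_error(self, tmp_path):
        bad = KGML.replace('entry1="2" entry2="3"', 'entry1="2" entry2="42"')
        p = _write(tmp_path, "t.xml", bad)
        with pytest.raises(FormatError, match="'42'"):
            data_io.read_pathway_kgml(p)

    def test_malformed_xml_rejected(self, tmp_path):
        p = _write(tmp_path, "t.xml", "<pathway><entry id=1></pathway>")
        with pytest.raises(FormatError, match="malformed"):
            data_io.read_pathway_kgml(p)


# ---------------------------------------------------------------------------
# core network exports


def _demo_core():
    core = CoreNetwork()
    core.nodes = {"E": "start", "S": "transduction", "T": "tf", "G": "target",
                  "DrugX": "drug"}
    core.edges = {("E", "S", "signals"), ("S", "T", "signals"),
                  ("T", "G", "regulates"), ("DrugX", "S", "targets")}
    core.provenance = {("E", "S", "signals"): frozenset({"pw1"})}
    return core


class TestCoreNetworkExport:
    def test_graphml_roundtrips_roles(self, tmp_path):
        import networkx as nx

        core = _demo_core()
        path = tmp_path / "core.graphml"
        data_io.write_core_network(core, path, "graphml")
        g = nx.read_graphml(path)
        assert {n: d["role"] for n, d in g.nodes(data=True)} == core.nodes
        assert g.edges["E", "S"]["kind"] == "signals"

    def test_sif_edge_labels_and_role_sidecar(self, tmp_path):
        core = _demo_core()
        path = tmp_path / "core.sif"
        data_io.write_core_network(core, path, "sif")
        lines = path.read_text().splitlines()
        assert "DrugX\ttargets\tS" in lines
        assert "T\tregulates\tG" in lines
        sidecar = (tmp_path / "core.sif.nodes.tsv").read_text()
        assert "T\ttf" in sidecar

    def test_json_roundtrip(self, tmp_path):
        core = _demo_core()
        path = tmp_path / "core.json"
        data_io.write_core_network(core, path, "json")
        back = data_io.read_core_network(path)
        assert back.nodes == core.nodes and back.edges == core.edges

    def test_empty_network_and_determinism(self, tmp_path):
        empty = CoreNetwork()
        for fmt in ("graphml", "sif", "json"):
            p1, p2 = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
            data_io.write_core_network(empty, p1, fmt)
            data_io.write_core_network(empty, p2, fmt)
            assert p1.read_bytes() == p2.read_bytes()
        c1, c2 = tmp_path / "c1.json", tmp_path / "c2.json"
        data_io.write_core_network(_demo_core(), c1, "json")
        data_io.write_core_network(_demo_core(), c2, "json")
        assert c1.read_bytes() == c2.read_bytes()

    def test_unknown_format_is_usage_error(self, tmp_path):
        with pytest.raises(UsageError):
            data_io.write_core_network(_demo_core(), tmp_path / "x", "xlsx")


# ---------------------------------------------------------------------------
# round-trip property tests


symbols = st.text(alphabet="ABCDEFGH123_", min_size=1, max_size=6).map(
    lambda s: s.upper()
)
fcs = st.floats(min_value=-8, max_value=8, allow_nan=False).map(
    lambda v: float(np.float64(v))
)


@settings(max_examples=50, deadline=None)
@given(st.dictionaries(symbols, st.one_of(st.none(), fcs), min_size=0, max_size=20),
       st.sets(symbols, max_size=5))
def test_expression_roundtrip(tmp_path_factory, table, extra):
    prof = ExpressionProfile(
        "d1",
        {g: v for g, v in table.items() if v is not None},
        frozenset(table) | frozenset(extra),
    )
    p = tmp_path_factory.mktemp("rt") / "e.tsv"
    data_io.write_expression(prof, p)
    assert data_io.read_expression(p, "d1") == prof


@settings(max_examples=50, deadline=None)
@given(st.sets(st.tuples(symbols, symbols), min_size=1, max_size=30))
def test_network_roundtrip(tmp_path_factory, edges):
    net = RegulatoryNetwork(frozenset(edges))
    p = tmp_path_factory.mktemp("rt") / "n.tsv"
    data_io.write_regulatory_network(net, p)
    assert data_io.read_regulatory_network(p) == net


@settings(max_examples=50, deadline=None)
@given(
    st.sets(st.tuples(symbols, symbols), min_size=1, max_size=15),
    st.sets(symbols, max_size=4),
)
def test_pathway_tsv_roundtrip(tmp_path_factory, edges, entries):
    g = make_pathway("PW1", sorted(edges), entries=sorted(entries))
    p = tmp_path_factory.mktemp("rt") / "p.tsv"
    data_io.write_pathway_tsv([g], p)
    (back,) = data_io.read_pathway_tsv(p)
    assert back == g


@settings(max_examples=50, deadline=None)
@given(st.sets(st.tuples(st.text("DrugXYZ09", min_size=1, max_size=8), symbols),
               min_size=1, max_size=20))
def test_drug_table_roundtrip(tmp_path_factory, rows):
    table = DrugTargetTable(frozenset(rows))
    p = tmp_path_factory.mktemp("rt") / "d.tsv"
    data_io.write_drug_table(table, p)
    assert data_io.read_drug_table(p) == table
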