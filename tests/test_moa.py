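"""Mechanism-of-action models, pathway extraction, agreement, DOT export."""

import re

import networkx as nx
import numpy as np
import pytest

import triggernet as tn
from triggernet.knowledge_base import ValidationError

import oracles
from conftest import full_weight_params, make_ensemble


@pytest.fixture
def moa_net() -> tn.Interactome:
    """Eight proteins: two drug targets feeding two effectors."""
    edges = [
        ("T1", "M1", 1), ("M1", "E1", -1),
        ("T2", "M2", -1), ("M2", "E2", 1),
        ("T1", "M2", 1), ("M1", "M2", 1),
        ("X1", "E1", 1), ("X2", "M1", -1),
    ]
    return tn.Interactome({"T1", "T2", "M1", "M2", "E1", "E2", "X1", "X2"}, edges)


@pytest.fixture
def moa_drug() -> tn.DrugProfile:
    return tn.DrugProfile("drug", [
        tn.DrugTarget("T1", "inhibit", 10.0, "primary_target"),
        tn.DrugTarget("T2", "inhibit", 120.0, "off_target"),
    ])


@pytest.fixture
def moa_effs() -> tn.EffectorSet:
    return tn.EffectorSet("proc", {"E1": 1, "E2": -1})


class TestBuildMoA:
    def test_flagged_must_be_drug_targets(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 2)
        with pytest.raises(ValidationError, match="not targets"):
            tn.build_moa(moa_net, ens, moa_drug, ["X1"], moa_effs)

    def test_all_targets_clamped_inhibited(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 3)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T2"], moa_effs)
        assert set(model.stimulus) == {("T1", -1), ("T2", -1)}
        assert model.mean_activity["T1"] == -1.0
        assert model.mean_activity["T2"] == -1.0

    def test_single_solution_mean_is_that_solution(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 1, seed=5)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1"], moa_effs)
        y = tn.propagate(moa_net, ens.solutions[0].params, dict(model.stimulus))
        for p in moa_net.proteins:
            assert model.mean_activity[p] == pytest.approx(y[p])

    def test_mean_equals_hand_average_over_solutions(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 3, seed=9)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1", "T2"], moa_effs)
        for p in moa_net.proteins:
            hand = np.mean([
                oracles.naive_propagate(moa_net, s.params.weights, s.params.steps,
                                        {"T1": -1, "T2": -1})[p]
                for s in ens.solutions
            ])
            assert model.mean_activity[p] == pytest.approx(hand, abs=1e-12)


class TestExtractPathways:
    def test_unanimous_chain_has_support_one(self):
        net = tn.Interactome({"T", "M", "E"}, [("T", "M", 1), ("M", "E", -1)])
        # strong weights keep the whole chain suprathreshold in every solution
        sols = [
            tn.Solution(params=full_weight_params(net, magnitude=m), accuracy=1.0, seed=i)
            for i, m in enumerate((0.6, 0.7, 0.8, 1.0))
        ]
        ens = tn.SolutionEnsemble(sols, 0.0, [1.0] * 4)
        drug = tn.DrugProfile("d", [tn.DrugTarget("T")])
        effs = tn.EffectorSet("p", {"E": 1})
        model = tn.build_moa(net, ens, drug, ["T"], effs)
        paths = tn.extract_pathways(net, ens, model, max_len=3, min_support=1.0)
        assert len(paths) == 1
        assert paths[0].nodes == ("T", "M", "E")
        assert paths[0].edge_signs == (1, -1)
        assert paths[0].support == 1.0

    def test_effector_beyond_max_len_absent(self):
        net = tn.Interactome(
            {"T", "A", "B", "C", "E"},
            [("T", "A", 1), ("A", "B", 1), ("B", "C", 1), ("C", "E", 1)],
        )
        ens = make_ensemble(net, 2)
        drug = tn.DrugProfile("d", [tn.DrugTarget("T")])
        model = tn.build_moa(net, ens, drug, ["T"], tn.EffectorSet("p", {"E": 1}))
        assert tn.extract_pathways(net, ens, model, max_len=3, min_support=0.0) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_supports_match_brute_force(self, moa_net, moa_drug, moa_effs, seed):
        ens = make_ensemble(moa_net, 5, seed=seed)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1", "T2"], moa_effs)
        got = tn.extract_pathways(moa_net, ens, model, max_len=4, min_support=1e-9)
        want = oracles.brute_pathway_supports(
            moa_net, ens, dict(model.stimulus), ["T1", "T2"], ["E1", "E2"], max_len=4,
        )
        got_map = {r.nodes: r.support for r in got}
        positive = {p: s for p, s in want.items() if s > 0}
        assert got_map == pytest.approx(positive, abs=1e-12)

    def test_every_pathway_exists_edge_by_edge(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 4, seed=2)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1", "T2"], moa_effs)
        g = moa_net.graph
        for r in tn.extract_pathways(moa_net, ens, model, max_len=4, min_support=0.1):
            for k in range(len(r.nodes) - 1):
                assert g.has_edge(r.nodes[k], r.nodes[k + 1])
                assert g.edges[r.nodes[k], r.nodes[k + 1]]["sign"] == r.edge_signs[k]

    def test_sorted_by_support_then_length(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 5, seed=3)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1", "T2"], moa_effs)
        paths = tn.extract_pathways(moa_net, ens, model, max_len=4, min_support=1e-9)
        keys = [(-r.support, len(r.nodes), r.nodes) for r in paths]
        assert keys == sorted(keys)


class TestLiteratureAgreement:
    def _model(self, net, ens, drug, effs, flagged=("T1",)):
        return tn.build_moa(net, ens, drug, list(flagged), effs)

    def test_all_matching_is_hundred_percent(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 3, seed=1)
        model = self._model(moa_net, ens, moa_drug, moa_effs)
        lit = tn.LiteratureResponseSet("drug", {
            p: (1 if y > 0 else -1)
            for p, y in model.mean_activity.items()
            if p not in model.clamped and abs(y) >= 0.05
        })
        assert tn.literature_agreement([model], lit) == 100.0

    def test_half_matching_is_fifty_percent(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 3, seed=1)
        model = self._model(moa_net, ens, moa_drug, moa_effs)
        present = [
            (p, y) for p, y in model.mean_activity.items()
            if p not in model.clamped and abs(y) >= 0.05
        ][:2]
        assert len(present) == 2
        lit = tn.LiteratureResponseSet("drug", {
            present[0][0]: (1 if present[0][1] > 0 else -1),
            present[1][0]: (-1 if present[1][1] > 0 else 1),
        })
        assert tn.literature_agreement([model], lit) == 50.0

    def test_no_present_protein_is_undefined_not_zero(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 2, seed=1)
        model = self._model(moa_net, ens, moa_drug, moa_effs)
        lit = tn.LiteratureResponseSet("drug", {"T1": 1})  # clamped -> never present
        assert tn.literature_agreement([model], lit) is None

    def test_planted_literature_set_scores_hundred(self, ref_benchmark):
        """A response set recorded from the planted model's own signs
        must agree perfectly with the planted model."""
        b = ref_benchmark
        ens = b.planted_ensemble()
        drug = b.drugs["drug_A"]
        effs = b.processes[0]
        flagged = [p for (p, proc) in b.planted.inducers
                   if proc == effs.process_name and p in drug]
        model = tn.build_moa(b.net, ens, drug, flagged, effs)
        lit = tn.LiteratureResponseSet("drug_A", {
            p: (1 if y > 0 else -1)
            for p, y in model.mean_activity.items()
            if p not in model.clamped and abs(y) >= 0.05
        })
        assert tn.literature_agreement([model], lit) == 100.0


def parse_dot(text: str) -> nx.DiGraph:
    """Minimal DOT reader sufficient for the exporter's output."""
    g = nx.DiGraph()
    for m in re.finditer(r'^\s*"([^"]+)"\s*\[', text, flags=re.M):
        g.add_node(m.group(1))
    for m in re.finditer(r'"([^"]+)"\s*->\s*"([^"]+)"\s*\[([^\]]*)\]', text):
        sign = -1 if "tee" in m.group(3) else 1
        g.add_edge(m.group(1), m.group(2), sign=sign)
    return g


class TestDotExport:
    def test_empty_pathways_still_draw_stimulus_and_effectors(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 2)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1"], moa_effs)
        g = parse_dot(tn.export_dot(model, []))
        assert {"T1", "E1", "E2"} <= set(g.nodes)
        assert g.number_of_edges() == 0

    def test_three_step_path_emits_three_edges_in_order(self):
        net = tn.Interactome({"T", "A", "B", "E"},
                             [("T", "A", 1), ("A", "B", -1), ("B", "E", 1)])
        ens = make_ensemble(net, 2)
        drug = tn.DrugProfile("d", [tn.DrugTarget("T")])
        model = tn.build_moa(net, ens, drug, ["T"], tn.EffectorSet("p", {"E": 1}))
        path = tn.PathwayRecord(("T", "A", "B", "E"), (1, -1, 1), 1.0)
        dot = tn.export_dot(model, [path])
        g = parse_dot(dot)
        assert list(nx.topological_sort(g.subgraph({"T", "A", "B", "E"})))
        assert set(g.edges) == {("T", "A"), ("A", "B"), ("B", "E")}
        assert g.edges["A", "B"]["sign"] == -1

    def test_export_parses_back_to_pathway_union(self, moa_net, moa_drug, moa_effs):
        ens = make_ensemble(moa_net, 4, seed=6)
        model = tn.build_moa(moa_net, ens, moa_drug, ["T1", "T2"], moa_effs)
        paths = tn.extract_pathways(moa_net, ens, model, max_len=4, min_support=1e-9)
        g = parse_dot(tn.export_dot(model, paths))
        union = nx.DiGraph()
        for r in paths:
            for k in range(len(r.nodes) - 1):
                union.add_edge(r.nodes[k], r.nodes[k + 1], sign=r.edge_signs[k])
        assert set(g.edges) == set(union.edges)
        for u, v in union.edges:
            assert g.edges[u, v]["sign"] == union.edges[u, v]["sign"]


def test_superset_drug_modulates_superset_of_effectors(ref_benchmark):
    """Drug A carries every off-target of drug B plus its own: over the
    process effectors (where the planted wiring isolates each drug's
    reach), A's model must modulate a superset of B's suprathreshold
    effectors, and strictly more overall."""
    b = ref_benchmark
    ens = b.planted_ensemble()
    tau = 0.05
    supra = {"drug_A": set(), "drug_B": set()}
    for name in supra:
        drug = b.drugs[name]
        for effs in b.processes:
            flagged = [p for (p, proc) in b.planted.inducers
                       if proc == effs.process_name and p in drug] or [drug.proteins[0]]
            model = tn.build_moa(b.net, ens, drug, flagged, effs)
            mean = model.mean_activity
            supra[name] |= {(effs.process_name, p) for p in effs.effectors
                            if abs(mean[p]) >= tau}
    assert supra["drug_B"] <= supra["drug_A"]
    assert supra["drug_B"] < supra["drug_A"]  # A-specific inducers add reach
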