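"""Synthetic benchmarks with planted ground truth.

Real inputs to this kind of analysis are literature-curated (interactome,
target profiles, effector sets) and cannot be redistributed, so every
pipeline stage is exercised on generated data instead. The generator
emulates the curated inputs structurally:

* a scale-free signed directed interactome (preferential attachment,
  random edge orientation, inhibition edges with probability 0.3);
* two drug profiles sharing a primary target and some off-targets, with
  additional drug-A-specific off-targets (the asymmetry between a
  first-generation and a more selective second-generation inhibitor);
* per process, designated *inducer* off-targets wired to dedicated
  effector chains at distances 1-3 whose expected signs are exactly what
  inhibiting the inducer produces — so the triggering decision rule
  recovers the inducers by construction;
* an *antagonist* cotreatment protein wired to push every effector
  against its expected sign, guaranteeing a negative Diff Effect, plus
  null cotreatments with no path to any effector;
* a truth table recorded from propagation under the planted parameters,
  guaranteeing a perfectly compliant solution exists.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .knowledge_base import (
    Constraint,
    DrugProfile,
    DrugTarget,
    EffectorSet,
    Interactome,
    TruthTable,
    ValidationError,
    save_drug_profile,
    save_effector_set,
    save_interactome,
    save_truth_table,
)
from .network_model import (
    DEFAULT_STEPS,
    DEFAULT_TAU_ACT,
    ModelParameters,
    SolutionEnsemble,
    Solution,
    accuracy,
    propagate,
)

INDUCERS_PER_PROCESS = 2
#: required propagated margin (2 x tau_act) for truth-table responses
RESPONSE_MARGIN = 2 * DEFAULT_TAU_ACT


class GenerationError(RuntimeError):
    """The spec is infeasible or a planted guarantee failed to verify."""


@dataclass
class BenchmarkSpec:
    """Study conditions for one synthetic benchmark.

    Defaults are the reference conditions: a 200-protein scale-free
    network and a 30-constraint training set, two processes with six
    effectors each, and an ibrutinib/acalabrutinib-like pair of profiles
    (two shared off-targets, three drug-A-specific ones).
    """

    n_proteins: int = 200
    attachment: int = 3
    p_inhibition: float = 0.3
    n_processes: int = 2
    effectors_per_process: int = 6
    n_shared_offtargets: int = 2
    n_specific_offtargets: int = 3
    n_constraints: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "attachment", "n_processes", "effectors_per_process",
                     "n_shared_offtargets", "n_specific_offtargets", "n_constraints"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 <= self.p_inhibition <= 1:
            raise ValidationError(f"p_inhibition must be in [0, 1], got {self.p_inhibition}")
        if self.effectors_per_process < 2 * INDUCERS_PER_PROCESS:
            raise ValidationError(
                "effectors_per_process must allow >= 2 effectors per designated inducer "
                f"({2 * INDUCERS_PER_PROCESS} minimum)"
            )
        if self.n_processes > self.n_shared_offtargets + self.n_specific_offtargets:
            raise ValidationError("not enough off-targets to designate inducers for every process")

    @property
    def n_planted_nodes(self) -> int:
        # one fresh node per step of every effector chain, plus the antagonist
        per_process = sum(
            1 + (j // INDUCERS_PER_PROCESS) % 3 for j in range(self.effectors_per_process)
        )
        return self.n_processes * per_process + 1

    @property
    def n_core(self) -> int:
        return self.n_proteins - self.n_planted_nodes


@dataclass
class PlantedTruth:
    """Ground truth the benchmark plants and downstream stages must recover."""

    params: ModelParameters
    inducers: set[tuple[str, str]]  # (off-target protein, process name)
    antagonist_classes: list[str]
    evaluated_proteins: list[str]

    def non_inducers(self, processes: list[str]) -> set[tuple[str, str]]:
        all_pairs = {(p, proc) for p in self.evaluated_proteins for proc in processes}
        return all_pairs - self.inducers


@dataclass
class Benchmark:
    """Everything one pipeline run needs, plus the planted ground truth."""

    spec: BenchmarkSpec
    net: Interactome
    processes: list[EffectorSet]
    drugs: dict[str, DrugProfile]
    cotreatments: dict[str, DrugProfile]
    truth: TruthTable
    planted: PlantedTruth

    def planted_ensemble(self) -> SolutionEnsemble:
        """Single-solution ensemble holding the planted parameters."""
        acc = accuracy(self.net, self.planted.params, self.truth)
        return SolutionEnsemble(
            solutions=[Solution(params=self.planted.params, accuracy=acc, seed=self.spec.seed)],
            acceptance_threshold=0.0,
            all_accuracies=[acc],
        )

    def save(self, directory: str | Path) -> None:
        """Write all artifacts in the standard formats plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_interactome(self.net, directory / "interactome.tsv")
        for e in self.processes:
            save_effector_set(e, directory / f"process_{e.process_name}.json")
        for name, d in self.drugs.items():
            save_drug_profile(d, directory / f"drug_{name}.json")
        for name, c in self.cotreatments.items():
            save_drug_profile(c, directory / f"cotreatment_{name}.json")
        save_truth_table(self.truth, directory / "truth_table.json")
        manifest = {
            "schema_version": 1,
            "type": "benchmark_manifest",
            "spec": asdict(self.spec),
            "planted": {
                "inducers": sorted(self.planted.inducers),
                "antagonist_classes": self.planted.antagonist_classes,
                "evaluated_proteins": self.planted.evaluated_proteins,
                "steps": self.planted.params.steps,
                "tau_act": self.planted.params.tau_act,
            },
            "files": {
                "interactome": "interactome.tsv",
                "processes": [f"process_{e.process_name}.json" for e in self.processes],
                "drugs": {n: f"drug_{n}.json" for n in self.drugs},
                "cotreatments": {n: f"cotreatment_{n}.json" for n in self.cotreatments},
                "truth_table": "truth_table.json",
            },
        }
        (directory / "benchmark.json").write_text(json.dumps(manifest, indent=1) + "\n")


def _separated_sample(
    g: nx.DiGraph, rng: np.random.Generator, pool: list[str], k: int
) -> list[str]:
    """Pick k nodes pairwise far apart in directed distance (both
    directions), so no pick sits on another's scoring horizon.

    Greedy with reshuffles at separation 3; dense small networks may
    only admit separation 2, in which case the post-generation
    verification still guards the planted decision-rule guarantee."""
    for min_sep in (3, 3, 3, 2, 2):
        order = list(pool)
        rng.shuffle(order)
        chosen: list[str] = []
        for cand in order:
            near = nx.single_source_shortest_path_length(g, cand, cutoff=min_sep - 1)
            if any(c in near for c in chosen):
                continue
            rnear = nx.single_source_shortest_path_length(
                g.reverse(copy=False), cand, cutoff=min_sep - 1)
            if any(c in rnear for c in chosen):
                continue
            chosen.append(cand)
            if len(chosen) == k:
                return chosen
    raise GenerationError(
        f"could not place {k} sufficiently separated proteins; use a larger network"
    )


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Build the full planted benchmark; deterministic given ``spec.seed``."""
    n_core = spec.n_core
    if n_core < max(20, spec.attachment + 2):
        raise GenerationError(
            f"spec infeasible: only {n_core} core proteins remain after planting "
            f"{spec.n_planted_nodes} dedicated nodes"
        )
    n_targets = 1 + spec.n_shared_offtargets + spec.n_specific_offtargets + 1  # + weak decoy
    if n_core < 3 * n_targets:
        raise GenerationError("spec infeasible: more drug targets than the core network can host")

    rng = np.random.default_rng(spec.seed)

    # --- core scale-free interactome -------------------------------------
    base = nx.barabasi_albert_graph(n_core, spec.attachment, seed=int(rng.integers(2**31)))
    width = len(str(spec.n_proteins))
    name = lambda i: f"P{i:0{width}d}"
    core_nodes = [name(i) for i in range(n_core)]
    edges: list[tuple[str, str, int]] = []
    weights: dict[tuple[str, str], float] = {}
    for u, v in sorted(base.edges()):
        if rng.random() < 0.5:
            u, v = v, u
        sign = -1 if rng.random() < spec.p_inhibition else 1
        e = (name(u), name(v))
        edges.append((*e, sign))
        weights[e] = sign * float(rng.uniform(0.3, 0.9))

    g_core = nx.DiGraph()
    g_core.add_nodes_from(core_nodes)
    g_core.add_edges_from((u, v) for u, v, _ in edges)

    # --- drug profiles ----------------------------------------------------
    n_real = 1 + spec.n_shared_offtargets + spec.n_specific_offtargets
    picks = _separated_sample(g_core, rng, core_nodes, n_real + 1)
    primary = picks[0]
    shared = picks[1:1 + spec.n_shared_offtargets]
    specific = picks[1 + spec.n_shared_offtargets:n_real]
    weak = picks[n_real]  # above the potency cutoff; removed by the IC50 filter

    def _offtarget(p: str, regulatory: bool = False) -> DrugTarget:
        return DrugTarget(
            protein=p, action="inhibit",
            ic50_nm=None if regulatory else float(rng.uniform(10, 450)),
            role="off_target", regulatory_source=regulatory,
        )

    drug_a_targets = [DrugTarget(primary, "inhibit", float(rng.uniform(1, 10)), "primary_target")]
    drug_a_targets += [_offtarget(p) for p in shared]
    drug_a_targets += [
        _offtarget(p, regulatory=(i == 0)) for i, p in enumerate(specific)
    ]
    drug_a_targets.append(DrugTarget(weak, "inhibit", float(rng.uniform(600, 2000)), "off_target"))
    drug_a = DrugProfile(name="drug_A", targets=drug_a_targets)
    drug_b = DrugProfile(
        name="drug_B",
        targets=[DrugTarget(primary, "inhibit", float(rng.uniform(1, 10)), "primary_target")]
        + [_offtarget(p) for p in shared],
    )

    # --- planted effector chains ------------------------------------------
    next_id = n_core
    processes: list[EffectorSet] = []
    inducers: set[tuple[str, str]] = set()
    # interleave drug-A-specific and shared off-targets so each process gets
    # (where counts allow) one specific and one shared designated inducer
    all_inducer_pool = [
        p for pair in zip(specific, shared) for p in pair
    ] + list(specific[len(shared):]) + list(shared[len(specific):])
    effector_nodes: list[str] = []
    for k in range(spec.n_processes):
        proc = f"process_{k}"
        proc_inducers = [
            all_inducer_pool[(INDUCERS_PER_PROCESS * k + j) % len(all_inducer_pool)]
            for j in range(INDUCERS_PER_PROCESS)
        ]
        # keep designations unique within the process
        proc_inducers = list(dict.fromkeys(proc_inducers))
        effectors: dict[str, int] = {}
        for j in range(spec.effectors_per_process):
            u = proc_inducers[j % len(proc_inducers)]
            depth = 1 + (j // INDUCERS_PER_PROCESS) % 3
            sign_product = 1
            parent = u
            for _ in range(depth):
                node = name(next_id)
                next_id += 1
                s = -1 if rng.random() < spec.p_inhibition else 1
                edges.append((parent, node, s))
                weights[(parent, node)] = s * float(rng.uniform(0.6, 0.95))
                sign_product *= s
                parent = node
            # expected sign = what inhibiting the inducer produces
            effectors[parent] = -sign_product
            effector_nodes.append(parent)
        processes.append(EffectorSet(process_name=proc, effectors=effectors))
        inducers.update((u, proc) for u in proc_inducers)

    # --- antagonist cotreatment -------------------------------------------
    antagonist = name(next_id)
    next_id += 1
    for e in processes:
        for p, v in e.effectors.items():
            if (antagonist, p) in weights:
                continue
            edges.append((antagonist, p, v))
            weights[(antagonist, p)] = v * 0.9  # clamped at -1 -> pushes toward -v
    cotx_antagonist = DrugProfile(
        name="antagonist_class",
        targets=[DrugTarget(antagonist, "inhibit", float(rng.uniform(10, 450)), "off_target")],
    )

    proteins = [name(i) for i in range(next_id)]
    if len(proteins) != spec.n_proteins:  # arithmetic guard, not a runtime path
        raise GenerationError("internal node accounting error")
    net = Interactome(proteins, edges)
    params = ModelParameters(weights=weights, steps=DEFAULT_STEPS, tau_act=DEFAULT_TAU_ACT)

    # --- truth table from planted propagation ------------------------------
    stimulus_pool = [p for p in core_nodes if p != antagonist]
    constraints: list[Constraint] = []
    attempts = 0
    while len(constraints) < spec.n_constraints:
        attempts += 1
        if attempts > 50 * spec.n_constraints:
            raise GenerationError("could not place the requested number of constraints")
        k = int(rng.integers(1, 3))
        stim_proteins = list(rng.choice(stimulus_pool, size=k, replace=False))
        stimulus = tuple((p, int(rng.choice([-1, 1]))) for p in stim_proteins)
        y = propagate(net, params, stimulus)
        candidates = sorted(
            p for p in core_nodes
            if p not in stim_proteins and abs(y[p]) >= RESPONSE_MARGIN
        )
        if not candidates:
            continue
        response = str(rng.choice(candidates))
        constraints.append(Constraint(
            stimulus=stimulus, response=response,
            required_sign=1 if y[response] > 0 else -1,
        ))
    truth = TruthTable(constraints=constraints)

    evaluated = sorted(set(drug_a.proteins) | set(drug_b.proteins))
    planted = PlantedTruth(
        params=params,
        inducers=inducers,
        antagonist_classes=[cotx_antagonist.name],
        evaluated_proteins=evaluated,
    )
    bench = Benchmark(
        spec=spec, net=net, processes=processes,
        drugs={drug_a.name: drug_a, drug_b.name: drug_b},
        cotreatments={cotx_antagonist.name: cotx_antagonist},
        truth=truth, planted=planted,
    )
    _verify_planted(bench)
    return bench


def _verify_planted(bench: Benchmark) -> None:
    """Check the planted guarantees before handing the benchmark out."""
    from .triggering import classify_triggers, compute_triggering_table

    acc = accuracy(bench.net, bench.planted.params, bench.truth)
    if acc != 1.0:
        raise GenerationError(f"planted parameters only reach accuracy {acc} on their own truth table")
    ensemble = bench.planted_ensemble()
    table = compute_triggering_table(
        bench.net, ensemble, bench.planted.evaluated_proteins, bench.processes
    )
    recovered = classify_triggers(table)
    if recovered != bench.planted.inducers:
        raise GenerationError(
            "triggering under the planted parameters does not recover the designated "
            f"inducers exactly: expected {sorted(bench.planted.inducers)}, got {sorted(recovered)}"
        )


def generate_null_cotreatment(
    net: Interactome,
    effector_sets: list[EffectorSet],
    seed: int = 0,
    n_targets: int = 2,
) -> DrugProfile:
    """A cotreatment whose targets have no directed path to any effector,
    so its Diff Effect is exactly zero under any parameters."""
    rng = np.random.default_rng(seed)
    g = net.graph
    effectors = {p for e in effector_sets for p in e.effectors}
    upstream: set[str] = set(effectors)
    for p in effectors:
        if p in g:
            upstream |= nx.ancestors(g, p)
    eligible = sorted(net.proteins - upstream)
    if len(eligible) < n_targets:
        raise GenerationError(
            "no proteins are disconnected from the effectors; use a larger network"
        )
    picks = list(rng.choice(eligible, size=n_targets, replace=False))
    return DrugProfile(
        name="null_cotreatment",
        targets=[DrugTarget(str(p), "inhibit", float(rng.uniform(10, 450)), "off_target")
                 for p in picks],
    )
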