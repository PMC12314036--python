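"""Shared fixtures: tiny hand-built networks, small trained ensembles,
and the session-scoped reference benchmark."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import triggernet as tn
from triggernet.network_model import TrainConfig

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def chain_net() -> tn.Interactome:
    """A -> B -> C with an inhibiting second edge."""
    return tn.Interactome({"A", "B", "C"}, [("A", "B", 1), ("B", "C", -1)])


@pytest.fixture
def small_net() -> tn.Interactome:
    """Six proteins, mixed signs, effectors reachable at distances 1-3."""
    edges = [
        ("S", "E1", 1),
        ("S", "M1", 1), ("M1", "M2", -1), ("M2", "E3", 1),
        ("M1", "E2", 1),
        ("X", "E1", -1),
    ]
    return tn.Interactome({"S", "E1", "M1", "M2", "E3", "E2", "X"}, edges)


def full_weight_params(net: tn.Interactome, magnitude: float = 1.0,
                       steps: int = 5, tau_act: float = 0.05) -> tn.ModelParameters:
    return tn.ModelParameters(
        weights={(u, v): s * magnitude for u, v, s in net.edges},
        steps=steps, tau_act=tau_act,
    )


def random_params(net: tn.Interactome, rng: np.random.Generator,
                  steps: int = 5, tau_act: float = 0.05) -> tn.ModelParameters:
    return tn.ModelParameters(
        weights={(u, v): s * float(rng.uniform(0.2, 1.0)) for u, v, s in net.edges},
        steps=steps, tau_act=tau_act,
    )


def make_ensemble(net: tn.Interactome, n_solutions: int, seed: int = 0,
                  steps: int = 5, tau_act: float = 0.05) -> tn.SolutionEnsemble:
    """Ensemble of random sign-constrained parameterizations (no training),
    for exercising ensemble-summary code paths."""
    rng = np.random.default_rng(seed)
    sols = [
        tn.Solution(params=random_params(net, rng, steps, tau_act), accuracy=1.0, seed=seed + i)
        for i in range(n_solutions)
    ]
    return tn.SolutionEnsemble(sols, acceptance_threshold=0.0,
                               all_accuracies=[s.accuracy for s in sols])


@pytest.fixture(scope="session")
def ref_benchmark() -> tn.Benchmark:
    """The reference synthetic benchmark (200 proteins, 30 constraints)."""
    return tn.generate_benchmark(tn.BenchmarkSpec(seed=0))


@pytest.fixture(scope="session")
def ref_trained_ensemble(ref_benchmark: tn.Benchmark) -> tn.SolutionEnsemble:
    """Ten solutions trained on the reference benchmark with default
    annealing settings (threshold 0: keep all, record all accuracies)."""
    return tn.sample_ensemble(
        ref_benchmark.net, ref_benchmark.truth, n_solutions=10,
        acceptance_threshold=0.0, base_seed=1000,
    )


@pytest.fixture(scope="session")
def small_trained_benchmark() -> tuple[tn.Benchmark, tn.SolutionEnsemble]:
    """A 30-protein planted benchmark and an ensemble trained on it."""
    spec = tn.BenchmarkSpec(
        n_proteins=30, n_processes=1, effectors_per_process=4,
        n_shared_offtargets=1, n_specific_offtargets=1, n_constraints=8, seed=3,
    )
    bench = tn.generate_benchmark(spec)
    ens = tn.sample_ensemble(bench.net, bench.truth, n_solutions=4,
                             acceptance_threshold=0.0, base_seed=42,
                             config=TrainConfig(n_proposals=800))
    return bench, ens
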