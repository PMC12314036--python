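"""Signal propagation over the signed interactome and ensemble training.

The model treats the network like a recurrent perceptron layered on the
interactome: proteins are units with activity in [-1, 1], signed edges
carry real weights whose sign must match the curated interaction sign,
and a stimulus is a set of clamped units. Activity spreads by synchronous
updates y <- tanh(W^T y) for a fixed number of steps, with clamped units
held at their clamp value.

Training is a stochastic search: simulated annealing over edge-weight
magnitudes (signs are fixed by curation) maximizing compliance with a
stimulus->response truth table. Repeating the search from many seeds
yields a "universe of solutions" — an ensemble of parameterizations all
compatible with the training data — and every downstream prediction is
an ensemble summary. Retained solutions are weighted uniformly; no
density over the solution space is assumed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .knowledge_base import Constraint, Interactome, TruthTable, ValidationError

DEFAULT_STEPS = 5
DEFAULT_TAU_ACT = 0.05


class EnsembleEmptyError(RuntimeError):
    """Raised when no trained solution meets the acceptance threshold."""


# ---------------------------------------------------------------------------
# Parameters and stimuli
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """One parameterization of the propagation model.

    weights maps each directed edge (u, v) to a real weight in [-1, 1]
    whose sign matches the edge sign (zero is allowed). ``steps`` is the
    synchronous update count T; ``tau_act`` the activity threshold below
    which a protein does not count as stimulated.
    """

    weights: dict[tuple[str, str], float]
    steps: int = DEFAULT_STEPS
    tau_act: float = DEFAULT_TAU_ACT

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValidationError(f"steps must be >= 1, got {self.steps}")
        if not 0 < self.tau_act < 1:
            raise ValidationError(f"tau_act must be in (0, 1), got {self.tau_act}")
        for e, w in self.weights.items():
            if abs(w) > 1:
                raise ValidationError(f"weight for edge {e} out of [-1, 1]: {w}")

    def validate_for(self, net: Interactome) -> None:
        """Check the sign constraint against a network's edge signs."""
        for u, v, s in net.edges:
            w = self.weights.get((u, v), 0.0)
            if w != 0.0 and math.copysign(1.0, w) != s:
                raise ValidationError(f"weight sign for edge {u} -> {v} contradicts edge sign {s:+d}")


def default_steps(net: Interactome, cap: int = DEFAULT_STEPS) -> int:
    """Propagation depth: the directed diameter of the largest weakly
    connected component, capped at ``cap`` (signal beyond that is deeply
    attenuated by the squashing anyway)."""
    import networkx as nx

    g = net.graph
    try:
        diam = max(
            (max(lengths.values()) for _, lengths in nx.shortest_path_length(g)),
            default=1,
        )
    except Exception:  # pragma: no cover - disconnected oddities
        diam = cap
    return max(1, min(cap, diam))


def _norm_stimulus(stimulus) -> list[tuple[str, int]]:
    if isinstance(stimulus, Mapping):
        items = list(stimulus.items())
    else:
        items = [(p, c) for p, c in stimulus]
    seen: set[str] = set()
    for p, c in items:
        if c not in (1, -1):
            raise ValidationError(f"clamp value for {p!r} must be +1 or -1, got {c!r}")
        if p in seen:
            raise ValidationError(f"protein {p!r} clamped twice")
        seen.add(p)
    return items


# ---------------------------------------------------------------------------
# Compiled arrays (internal)
# ---------------------------------------------------------------------------

@dataclass
class _Compiled:
    nodes: list[str]
    index: dict[str, int]
    src: np.ndarray
    dst: np.ndarray
    sign: np.ndarray
    edge_keys: list[tuple[str, str]]


def _compile(net: Interactome) -> _Compiled:
    nodes = sorted(net.proteins)
    index = {p: i for i, p in enumerate(nodes)}
    src = np.fromiter((index[u] for u, _, _ in net.edges), dtype=np.int64, count=net.n_edges)
    dst = np.fromiter((index[v] for _, v, _ in net.edges), dtype=np.int64, count=net.n_edges)
    sign = np.fromiter((s for _, _, s in net.edges), dtype=np.float64, count=net.n_edges)
    return _Compiled(nodes, index, src, dst, sign, [(u, v) for u, v, _ in net.edges])


def _weight_vector(comp: _Compiled, params: ModelParameters) -> np.ndarray:
    w = np.fromiter((params.weights.get(e, 0.0) for e in comp.edge_keys),
                    dtype=np.float64, count=len(comp.edge_keys))
    if np.any(w * comp.sign < 0):
        bad = comp.edge_keys[int(np.argmax(w * comp.sign < 0))]
        raise ValidationError(f"weight sign for edge {bad[0]} -> {bad[1]} contradicts the edge sign")
    return w


def _propagate_batch(
    comp: _Compiled,
    w: np.ndarray,
    clamp_idx: Sequence[np.ndarray],
    clamp_val: Sequence[np.ndarray],
    steps: int,
) -> np.ndarray:
    """Synchronously propagate several stimuli at once.

    Returns an (n_nodes, n_stimuli) activity matrix."""
    n = len(comp.nodes)
    k = len(clamp_idx)
    mat = sparse.csr_matrix((w, (comp.dst, comp.src)), shape=(n, n))
    y = np.zeros((n, k))
    for j in range(k):
        y[clamp_idx[j], j] = clamp_val[j]
    for _ in range(steps):
        y = np.tanh(mat @ y)
        for j in range(k):
            y[clamp_idx[j], j] = clamp_val[j]
    return y


# ---------------------------------------------------------------------------
# Public propagation and accuracy
# ---------------------------------------------------------------------------

def propagate(net: Interactome, params: ModelParameters, stimulus) -> dict[str, float]:
    """Propagate a clamped stimulus through the network.

    All activities start at 0 except the clamps; ``params.steps``
    synchronous tanh updates follow, with clamps re-imposed after each.
    Returns protein -> activity in [-1, 1].
    """
    comp = _compile(net)
    items = _norm_stimulus(stimulus)
    unknown = [p for p, _ in items if p not in comp.index]
    if unknown:
        raise ValidationError(f"stimulus proteins not in network: {unknown}")
    w = _weight_vector(comp, params)
    idx = np.array([comp.index[p] for p, _ in items], dtype=np.int64)
    val = np.array([c for _, c in items], dtype=np.float64)
    y = _propagate_batch(comp, w, [idx], [val], params.steps)[:, 0]
    return {p: float(y[i]) for i, p in enumerate(comp.nodes)}


def _constraint_clamps(comp: _Compiled, truth: TruthTable):
    clamp_idx, clamp_val, resp_idx, req = [], [], [], []
    for c in truth.constraints:
        for p, _ in c.stimulus:
            if p not in comp.index:
                raise ValidationError(f"stimulus protein {p!r} not in network")
        if c.response not in comp.index:
            raise ValidationError(f"response protein {c.response!r} not in network")
        clamp_idx.append(np.array([comp.index[p] for p, _ in c.stimulus], dtype=np.int64))
        clamp_val.append(np.array([v for _, v in c.stimulus], dtype=np.float64))
        resp_idx.append(comp.index[c.response])
        req.append(c.required_sign)
    return clamp_idx, clamp_val, np.array(resp_idx, dtype=np.int64), np.array(req, dtype=np.float64)


def _batch_scores(y: np.ndarray, resp_idx: np.ndarray, req: np.ndarray, tau_act: float):
    resp = y[resp_idx, np.arange(len(resp_idx))]
    satisfied = (np.sign(resp) == req) & (np.abs(resp) >= tau_act)
    acc = float(np.mean(satisfied))
    margin = float(np.mean(req * resp))
    return acc, margin


def accuracy(net: Interactome, params: ModelParameters, truth: TruthTable) -> float:
    """Fraction of truth-table constraints the model satisfies.

    A constraint holds when the propagated response activity has the
    required sign and magnitude >= tau_act.
    """
    if not truth.constraints:
        raise ValidationError("truth table is empty")
    comp = _compile(net)
    w = _weight_vector(comp, params)
    clamp_idx, clamp_val, resp_idx, req = _constraint_clamps(comp, truth)
    y = _propagate_batch(comp, w, clamp_idx, clamp_val, params.steps)
    acc, _ = _batch_scores(y, resp_idx, req, params.tau_act)
    return acc


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Simulated-annealing settings for one solution.

    6,000 single-weight proposals with geometric cooling reliably
    polishes a sign-constrained weight vector on benchmark-sized
    networks; the continuous margin term breaks ties between weight
    settings that satisfy the same constraint count, giving the annealer
    a gradient between accuracy plateaus. The initial temperature is
    scaled to the objective's step size (one constraint flipping changes
    accuracy by 1/n_constraints, a few hundredths on typical training
    sets); a much hotter start just wastes proposals on random-walk
    acceptance.
    """

    n_proposals: int = 6000
    t_initial: float = 0.05
    t_final: float = 1e-3
    steps: int = DEFAULT_STEPS
    tau_act: float = DEFAULT_TAU_ACT
    init_magnitude: tuple[float, float] = (0.1, 1.0)
    margin_weight: float = 0.01


def train_solution(
    net: Interactome,
    truth: TruthTable,
    seed: int,
    config: TrainConfig | None = None,
) -> tuple[ModelParameters, float]:
    """Train one solution by simulated annealing over weight magnitudes.

    Deterministic given ``seed``. Returns the best-found parameters and
    their training accuracy (low accuracy is a result, not an error).
    """
    cfg = config or TrainConfig()
    comp = _compile(net)
    clamp_idx, clamp_val, resp_idx, req = _constraint_clamps(comp, truth)
    rng = np.random.default_rng(seed)
    m = len(comp.edge_keys)

    lo, hi = cfg.init_magnitude
    w = rng.uniform(lo, hi, size=m) * comp.sign

    def evaluate(wv: np.ndarray) -> tuple[float, float]:
        y = _propagate_batch(comp, wv, clamp_idx, clamp_val, cfg.steps)
        return _batch_scores(y, resp_idx, req, cfg.tau_act)

    acc, margin = evaluate(w)
    score = acc + cfg.margin_weight * margin
    best_w, best_acc, best_score = w.copy(), acc, score

    if m > 0 and cfg.n_proposals > 0:
        cool = (cfg.t_final / cfg.t_initial) ** (1.0 / cfg.n_proposals)
        temp = cfg.t_initial
        for _ in range(cfg.n_proposals):
            i = int(rng.integers(m))
            old = w[i]
            if rng.random() < 0.5:
                w[i] = rng.uniform(0.05, 1.0) * comp.sign[i]
            else:
                mag = abs(old) + rng.normal(0.0, 0.15)
                w[i] = float(np.clip(mag, 0.0, 1.0)) * comp.sign[i]
            new_acc, new_margin = evaluate(w)
            new_score = new_acc + cfg.margin_weight * new_margin
            delta = new_score - score
            if delta >= 0 or rng.random() < math.exp(delta / temp):
                acc, score = new_acc, new_score
                if score > best_score:
                    best_w, best_acc, best_score = w.copy(), acc, score
            else:
                w[i] = old
            temp *= cool
    params = ModelParameters(
        weights={e: float(best_w[i]) for i, e in enumerate(comp.edge_keys)},
        steps=cfg.steps,
        tau_act=cfg.tau_act,
    )
    return params, best_acc


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    params: ModelParameters
    accuracy: float
    seed: int


@dataclass
class SolutionEnsemble:
    """Retained trained solutions plus the acceptance record.

    ``all_accuracies`` keeps every trained solution's accuracy, including
    those rejected by the threshold, so training compliance can be
    reported over the whole sampling run.
    """

    solutions: list[Solution]
    acceptance_threshold: float
    all_accuracies: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.solutions:
            raise EnsembleEmptyError(
                f"ensemble empty: no solution reached acceptance threshold {self.acceptance_threshold}"
            )
        for s in self.solutions:
            if s.accuracy < self.acceptance_threshold:
                raise ValidationError("retained solution below the acceptance threshold")

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([s.accuracy for s in self.solutions]))

    @property
    def tau_act(self) -> float:
        return self.solutions[0].params.tau_act


def sample_ensemble(
    net: Interactome,
    truth: TruthTable,
    n_solutions: int,
    acceptance_threshold: float = 0.9,
    base_seed: int = 0,
    config: TrainConfig | None = None,
) -> SolutionEnsemble:
    """Train ``n_solutions`` independent solutions (seeds base_seed + i)
    and retain those with accuracy >= the acceptance threshold."""
    if n_solutions < 1:
        raise ValidationError(f"n_solutions must be >= 1, got {n_solutions}")
    solutions: list[Solution] = []
    all_acc: list[float] = []
    for i in range(n_solutions):
        seed = base_seed + i
        params, acc = train_solution(net, truth, seed, config)
        all_acc.append(acc)
        if acc >= acceptance_threshold:
            solutions.append(Solution(params=params, accuracy=acc, seed=seed))
    if not solutions:
        raise EnsembleEmptyError(
            f"ensemble empty: none of {n_solutions} solutions reached "
            f"acceptance threshold {acceptance_threshold}"
        )
    return SolutionEnsemble(solutions, acceptance_threshold, all_acc)


def save_ensemble(ensemble: SolutionEnsemble, directory: str | Path) -> None:
    """Serialize an ensemble: one JSON header plus one weight TSV per
    solution (full float precision, so reloads are bit-exact)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "schema_version": 1,
        "type": "solution_ensemble",
        "acceptance_threshold": ensemble.acceptance_threshold,
        "all_accuracies": ensemble.all_accuracies,
        "solutions": [],
    }
    for i, s in enumerate(ensemble.solutions):
        fname = f"solution_{i:03d}.tsv"
        with open(directory / fname, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for (u, v), w in sorted(s.params.weights.items()):
                fh.write(f"{u}\t{v}\t{w!r}\n")
        header["solutions"].append({
            "weights_file": fname,
            "accuracy": s.accuracy,
            "seed": s.seed,
            "steps": s.params.steps,
            "tau_act": s.params.tau_act,
        })
    (directory / "ensemble.json").write_text(json.dumps(header, indent=1) + "\n")


def load_ensemble(directory: str | Path) -> SolutionEnsemble:
    directory = Path(directory)
    header = json.loads((directory / "ensemble.json").read_text())
    solutions = []
    for rec in header["solutions"]:
        weights: dict[tuple[str, str], float] = {}
        with open(directory / rec["weights_file"]) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                u, v, w = line.rstrip("\n").split("\t")
                weights[(u, v)] = float(w)
        params = ModelParameters(weights=weights, steps=rec["steps"], tau_act=rec["tau_act"])
        solutions.append(Solution(params=params, accuracy=rec["accuracy"], seed=rec["seed"]))
    return SolutionEnsemble(solutions, header["acceptance_threshold"], header["all_accuracies"])
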