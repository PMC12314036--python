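"""Mechanism-of-action (MoA) models.

A MoA model simulates administering the drug with attention on the
off-targets flagged by the triggering analysis: *every* drug target is
clamped inhibited (-1) — the flagged off-targets act as the stimulus of
interest, the remaining targets are held inhibited to reproduce the
drug's full effect — and activity is propagated through each ensemble
solution. Downstream of the model we extract the most frequent
sign-consistent pathways from the flagged off-targets to the process
effectors, score agreement with literature-described drug responses, and
export schematic pathway graphs as DOT text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .knowledge_base import (
    DrugProfile,
    EffectorSet,
    Interactome,
    LiteratureResponseSet,
    ValidationError,
)
from .network_model import SolutionEnsemble, _compile, _propagate_batch, _weight_vector


@dataclass
class MoAModel:
    """Ensemble propagation of a drug's inhibited target profile.

    ``activities`` holds one row per ensemble solution over ``nodes``;
    ``stimulus`` is the applied clamp set (all drug targets at -1);
    ``flagged`` are the triggering-positive off-targets whose downstream
    pathways the model is built to expose.
    """

    drug: str
    process: str
    stimulus: tuple[tuple[str, int], ...]
    flagged: tuple[str, ...]
    effectors: dict[str, int]
    nodes: list[str]
    activities: np.ndarray  # (n_solutions, n_nodes)

    @property
    def clamped(self) -> set[str]:
        return {p for p, _ in self.stimulus}

    @property
    def mean_activity(self) -> dict[str, float]:
        mean = self.activities.mean(axis=0)
        return {p: float(mean[i]) for i, p in enumerate(self.nodes)}

    def solution_activity(self, i: int) -> dict[str, float]:
        return {p: float(self.activities[i, j]) for j, p in enumerate(self.nodes)}


@dataclass(frozen=True)
class PathwayRecord:
    """A simple directed path from a flagged off-target to an effector,
    with per-step interaction signs and the fraction of ensemble
    solutions in which the whole path is active and sign-consistent."""

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]
    support: float

    def __post_init__(self) -> None:
        if len(self.edge_signs) != len(self.nodes) - 1:
            raise ValidationError("pathway must carry one sign per step")
        if not 0 < self.support <= 1:
            raise ValidationError(f"pathway support must be in (0, 1], got {self.support}")


def build_moa(
    net: Interactome,
    ensemble: SolutionEnsemble,
    drug: DrugProfile,
    flagged: Iterable[str],
    effs: EffectorSet,
) -> MoAModel:
    """Clamp every drug target at -1, propagate through each ensemble
    solution, and record the per-solution activity matrix."""
    flagged = tuple(dict.fromkeys(flagged))
    targets = set(drug.proteins)
    outside = [p for p in flagged if p not in targets]
    if outside:
        raise ValidationError(f"flagged proteins are not targets of {drug.name!r}: {outside}")
    comp = _compile(net)
    missing = [p for p in drug.proteins if p not in comp.index]
    if missing:
        raise ValidationError(f"drug targets not in network: {missing}")
    stimulus = tuple((p, -1) for p in drug.proteins)
    idx = np.array([comp.index[p] for p, _ in stimulus], dtype=np.int64)
    val = np.array([c for _, c in stimulus], dtype=np.float64)
    rows = []
    for sol in ensemble.solutions:
        w = _weight_vector(comp, sol.params)
        rows.append(_propagate_batch(comp, w, [idx], [val], sol.params.steps)[:, 0])
    return MoAModel(
        drug=drug.name,
        process=effs.process_name,
        stimulus=stimulus,
        flagged=flagged,
        effectors=dict(effs.effectors),
        nodes=comp.nodes,
        activities=np.vstack(rows),
    )


def _path_active(
    path: Sequence[str],
    y: dict[str, float] | np.ndarray,
    index: dict[str, int],
    signs: Sequence[int],
    tau_act: float,
) -> bool:
    def val(p: str) -> float:
        return y[index[p]] if not isinstance(y, dict) else y[p]

    for p in path:
        if abs(val(p)) < tau_act:
            return False
    for k in range(len(path) - 1):
        if np.sign(val(path[k + 1])) != signs[k] * np.sign(val(path[k])):
            return False
    return True


def extract_pathways(
    net: Interactome,
    ensemble: SolutionEnsemble,
    moa: MoAModel,
    max_len: int = 4,
    min_support: float = 0.5,
) -> list[PathwayRecord]:
    """Most frequent pathways from the flagged off-targets to the
    process effectors.

    Simple directed paths up to ``max_len`` edges are enumerated; a path
    is active in a solution when every node on it is suprathreshold
    (|y| >= tau_act) and every step is sign-consistent (child sign =
    edge sign x parent sign). Paths with support >= ``min_support`` are
    returned sorted by support descending, then length, then node order.
    """
    if max_len < 1:
        raise ValidationError(f"max_len must be >= 1, got {max_len}")
    g = net.graph
    index = {p: i for i, p in enumerate(moa.nodes)}
    tau = ensemble.tau_act
    candidates: list[tuple[tuple[str, ...], tuple[int, ...]]] = []
    seen: set[tuple[str, ...]] = set()
    for src in moa.flagged:
        for eff in moa.effectors:
            if src == eff or src not in g or eff not in g:
                continue
            for path in nx.all_simple_paths(g, src, eff, cutoff=max_len):
                tpath = tuple(path)
                if tpath in seen:
                    continue
                seen.add(tpath)
                signs = tuple(g.edges[tpath[k], tpath[k + 1]]["sign"] for k in range(len(tpath) - 1))
                candidates.append((tpath, signs))
    records = []
    n_sol = moa.activities.shape[0]
    for tpath, signs in candidates:
        active = sum(
            _path_active(tpath, moa.activities[i], index, signs, tau) for i in range(n_sol)
        )
        support = active / n_sol
        if support >= min_support and support > 0:
            records.append(PathwayRecord(nodes=tpath, edge_signs=signs, support=support))
    records.sort(key=lambda r: (-r.support, len(r.nodes), r.nodes))
    return records


def literature_agreement(
    models: Sequence[MoAModel],
    lit: LiteratureResponseSet,
    tau_act: float = 0.05,
    require_all_models: bool = True,
) -> float | None:
    """Percentage of literature proteins predicted in the described
    direction.

    A literature protein is *present* in a model when it is not clamped
    there and its ensemble-mean activity is suprathreshold. Proteins
    present in no model yield ``None`` (undefined agreement, not 0). With
    ``require_all_models`` (default) a protein counts as matching only
    when its sign agrees in every model where it is present; otherwise a
    single agreeing model suffices.
    """
    if not models:
        raise ValidationError("at least one MoA model is required")
    present_any: dict[str, list[int]] = {}
    for p, direction in lit.entries.items():
        signs = []
        for m in models:
            if p in m.clamped:
                continue
            y = m.mean_activity.get(p)
            if y is not None and abs(y) >= tau_act:
                signs.append(1 if y > 0 else -1)
        if signs:
            present_any[p] = signs
    if not present_any:
        return None
    matches = 0
    for p, signs in present_any.items():
        direction = lit.entries[p]
        ok = all(s == direction for s in signs) if require_all_models else any(
            s == direction for s in signs
        )
        matches += ok
    return 100.0 * matches / len(present_any)


def export_dot(moa: MoAModel, pathways: Sequence[PathwayRecord]) -> str:
    """Render the MoA model as a DOT digraph.

    Nodes are colored by ensemble-mean activity sign (activated red,
    inhibited blue, subthreshold grey); activating steps are solid with
    normal arrowheads, inhibiting steps dashed with tee arrowheads.
    Flagged off-targets and effectors appear even when no pathway was
    retained. Output ordering is deterministic.
    """
    mean = moa.mean_activity
    node_set = set(moa.flagged) | set(moa.effectors)
    edges: dict[tuple[str, str], int] = {}
    for r in pathways:
        node_set.update(r.nodes)
        for k in range(len(r.nodes) - 1):
            edges[(r.nodes[k], r.nodes[k + 1])] = r.edge_signs[k]

    def color(p: str) -> str:
        y = mean.get(p, 0.0)
        if y >= 0.05:
            return "indianred1"
        if y <= -0.05:
            return "lightblue"
        return "grey90"

    lines = [f'digraph "{moa.drug} :: {moa.process}" {{', "  rankdir=LR;"]
    for p in sorted(node_set):
        shape = "box" if p in moa.flagged else ("doublecircle" if p in moa.effectors else "ellipse")
        lines.append(
            f'  "{p}" [shape={shape}, style=filled, fillcolor={color(p)}, '
            f'label="{p}\\n{mean.get(p, 0.0):+.2f}"];'
        )
    for (u, v), s in sorted(edges.items()):
        style = 'style=solid, arrowhead=normal' if s > 0 else 'style=dashed, arrowhead=tee'
        lines.append(f'  "{u}" -> "{v}" [{style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
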