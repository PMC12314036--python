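"""Triggering analysis.

Scores each evaluated protein's capacity, when inhibited versus
activated, to evoke a pathophysiological process. A protein is clamped
at -1 (inhibited) or +1 (activated), activity is propagated through
every solution of the ensemble, and process effectors reached within
three directed network steps that carry their expected activity sign are
counted with proximity weights (closer effectors count more). The
ensemble mean of that weighted count is the raw score; scores are
normalized per process by the maximum over all evaluated proteins and
both modes, and the difference

    D = score(inhibited) - score(activated)

classifies a trigger when strictly above the decision threshold
(default 0.2): the protein's *inhibition*, rather than its overall
modulation, leads to the process.

Note on scales: normalized scores here lie in [0, 1], so D is confined
to [-1, 1]. Published tables produced with other normalizations can
carry |D| > 1; the classification rule itself is normalization-agnostic
and is applied to whatever difference column it is given.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .knowledge_base import EffectorSet, Interactome, ValidationError
from .network_model import SolutionEnsemble, _compile, _propagate_batch, _weight_vector

#: proximity weights w_d for effector distances 1, 2, 3
DEFAULT_DISTANCE_WEIGHTS = (1.0, 0.5, 1.0 / 3.0)
TRIGGER_THRESHOLD = 0.2
MAX_DISTANCE = 3

INHIBITED = "inhibited"
ACTIVATED = "activated"


def effector_distances(net: Interactome, source: str, effs: EffectorSet) -> dict[str, int]:
    """Shortest directed path lengths (edge counts) from ``source`` to
    each effector, following edge direction; unreachable effectors are
    omitted. The source itself appears at distance 0 when it is an
    effector (scoring tiers use distances 1-3 only)."""
    if source not in net.proteins:
        raise ValidationError(f"source protein {source!r} not in network")
    lengths = nx.single_source_shortest_path_length(net.graph, source)
    return {p: lengths[p] for p in effs.effectors if p in lengths}


def _mode_clamp(mode: str) -> int:
    if mode == INHIBITED:
        return -1
    if mode == ACTIVATED:
        return 1
    raise ValidationError(f"mode must be '{INHIBITED}' or '{ACTIVATED}', got {mode!r}")


def _solution_score(
    y: dict[str, float] | np.ndarray,
    node_index: dict[str, int],
    dist: dict[str, int],
    effs: EffectorSet,
    tau_act: float,
    weights: Sequence[float],
) -> float:
    """Distance-weighted count of matching effectors for one solution."""
    score = 0.0
    for p, d in dist.items():
        if not 1 <= d <= MAX_DISTANCE:
            continue
        yi = y[node_index[p]] if not isinstance(y, dict) else y[p]
        if abs(yi) >= tau_act and np.sign(yi) == effs.effectors[p]:
            score += weights[d - 1]
    return score


def raw_triggering_score(
    net: Interactome,
    ensemble: SolutionEnsemble,
    source: str,
    mode: str,
    effs: EffectorSet,
    distance_weights: Sequence[float] = DEFAULT_DISTANCE_WEIGHTS,
) -> float:
    """Ensemble-mean distance-weighted count of effectors stimulated with
    their expected sign when ``source`` is clamped per ``mode``."""
    if not effs.effectors:
        raise ValidationError("effector set is empty")
    clamp = _mode_clamp(mode)
    dist = effector_distances(net, source, effs)
    comp = _compile(net)
    idx = np.array([comp.index[source]], dtype=np.int64)
    val = np.array([clamp], dtype=np.float64)
    scores = []
    for sol in ensemble.solutions:
        w = _weight_vector(comp, sol.params)
        y = _propagate_batch(comp, w, [idx], [val], sol.params.steps)[:, 0]
        scores.append(_solution_score(y, comp.index, dist, effs, sol.params.tau_act, distance_weights))
    return float(np.mean(scores))


def compute_triggering_table(
    net: Interactome,
    ensemble: SolutionEnsemble,
    proteins: Iterable[str],
    processes: Sequence[EffectorSet],
    distance_weights: Sequence[float] = DEFAULT_DISTANCE_WEIGHTS,
    trigger_threshold: float = TRIGGER_THRESHOLD,
) -> pd.DataFrame:
    """Raw + normalized triggering scores for every (protein, process).

    One propagation per (protein, mode, solution), shared across
    processes. Columns: protein, process, raw_inhibited, raw_activated,
    score_inhibited, score_activated, difference, triggered.
    """
    proteins = list(dict.fromkeys(proteins))
    if not proteins:
        raise ValidationError("no proteins to evaluate")
    if not processes:
        raise ValidationError("no processes to evaluate")
    comp = _compile(net)
    for p in proteins:
        if p not in comp.index:
            raise ValidationError(f"evaluated protein {p!r} not in network")

    dists = {(p, e.process_name): effector_distances(net, p, e) for p in proteins for e in processes}

    raw: dict[tuple[str, str, str], float] = {}
    modes = (INHIBITED, ACTIVATED)
    clamp_idx = [np.array([comp.index[p]], dtype=np.int64) for p in proteins for _ in modes]
    clamp_val = [np.array([_mode_clamp(m)], dtype=np.float64) for _ in proteins for m in modes]
    acc: dict[tuple[str, str, str], float] = {
        (p, m, e.process_name): 0.0 for p in proteins for m in modes for e in processes
    }
    for sol in ensemble.solutions:
        w = _weight_vector(comp, sol.params)
        y = _propagate_batch(comp, w, clamp_idx, clamp_val, sol.params.steps)
        col = 0
        for p in proteins:
            for m in modes:
                yv = y[:, col]
                for e in processes:
                    acc[(p, m, e.process_name)] += _solution_score(
                        yv, comp.index, dists[(p, e.process_name)], e,
                        sol.params.tau_act, distance_weights,
                    )
                col += 1
    n_sol = len(ensemble.solutions)
    raw = {k: v / n_sol for k, v in acc.items()}

    rows = []
    for e in processes:
        for p in proteins:
            rows.append({
                "protein": p,
                "process": e.process_name,
                "raw_inhibited": raw[(p, INHIBITED, e.process_name)],
                "raw_activated": raw[(p, ACTIVATED, e.process_name)],
            })
    table = pd.DataFrame(rows)
    table = normalize_scores(table)
    table["triggered"] = table["difference"] > trigger_threshold
    return table


def normalize_scores(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Divide each process's raw scores (both modes) by the maximum raw
    score observed for that process across all evaluated proteins; an
    all-zero process column passes through unchanged."""
    table = raw_table.copy().reset_index(drop=True)
    norm_inh = np.empty(len(table))
    norm_act = np.empty(len(table))
    for proc, grp in table.groupby("process", sort=False):
        peak = max(grp["raw_inhibited"].max(), grp["raw_activated"].max())
        scale = peak if peak > 0 else 1.0
        norm_inh[grp.index] = grp["raw_inhibited"] / scale
        norm_act[grp.index] = grp["raw_activated"] / scale
    table["score_inhibited"] = norm_inh
    table["score_activated"] = norm_act
    table["difference"] = table["score_inhibited"] - table["score_activated"]
    return table


def classify_triggers(table: pd.DataFrame, threshold: float = TRIGGER_THRESHOLD) -> set[tuple[str, str]]:
    """(protein, process) pairs whose difference column strictly exceeds
    the threshold. Works on any table carrying protein / process /
    difference columns, including externally produced difference
    matrices."""
    needed = {"protein", "process", "difference"}
    missing = needed - set(table.columns)
    if missing:
        raise ValidationError(f"triggering table lacks columns: {sorted(missing)}")
    flagged = table[table["difference"] > threshold]
    return {(r.protein, r.process) for r in flagged.itertuples()}


def write_triggering_tsv(
    table: pd.DataFrame,
    path,
    drug_tags: dict[str, str] | None = None,
) -> None:
    """Write the triggering table as TSV, optionally with a per-protein
    drug tag column (e.g. I, A, I/A) mirroring the published layout."""
    out = table.copy()
    if drug_tags is not None:
        out["drugs"] = out["protein"].map(lambda p: drug_tags.get(p, ""))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
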