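"""tSignal, cotreatment interference, and the statistical layer.

The tSignal of a stimulus against a process definition is

    tSignal = -(1/n) * sum_i v_i * y_i

over the n process effectors, where v_i is the expected activity sign
of effector i and y_i its propagated activity. On this raw scale a
stimulus that drives the effectors in their disease-expected directions
scores *negative*. Because the narrative convention in the field reads
"more signal over the process" as positive, interference is reported on
the negated ("induction") scale as well: inductionSignal = -tSignal.

Cotreatment interference (Diff Effect) compares, per ensemble solution,
the tSignal with the kinase inhibitor's targets clamped alone versus
combined with a cotreatment class's targets. The headline Diff Effect
is the induction-scale difference

    DiffEffect = induction(combined) - induction(alone)
               = tSignal(alone) - tSignal(combined)

so a cotreatment that damps the drug-evoked process signal gets a
negative Diff Effect (the published convention); both raw tSignal
samples are kept and printed alongside. Significance is a two-sided
Wilcoxon rank-sum over the combined-vs-alone tSignal samples, with
Benjamini-Hochberg FDR across the whole screen; an interference flag
requires q <= alpha AND |mean Diff Effect| > a minimum effect size
(default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .knowledge_base import DrugProfile, EffectorSet, Interactome, ValidationError
from .network_model import SolutionEnsemble, _compile, _propagate_batch, _weight_vector

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_DIFF_THRESHOLD = 0.05


def tsignal(y: Mapping[str, float], effs: EffectorSet) -> float:
    """Eq.-style alignment score -(1/n) * sum v_i y_i over the effectors.

    Effectors missing from ``y`` contribute 0 (logged at debug level).
    """
    if not effs.effectors:
        raise ValidationError("effector set is empty")
    total = 0.0
    for p, v in effs.effectors.items():
        if p not in y:
            logger.debug("effector %s has no activity value; treated as 0", p)
            continue
        total += v * y[p]
    return -total / len(effs.effectors)


def _merge_clamps(btki: DrugProfile, cotx: DrugProfile) -> list[tuple[str, int]]:
    merged: dict[str, int] = dict(btki.clamps())
    for p, c in cotx.clamps():
        if p in merged and merged[p] != c:
            raise ValidationError(
                f"protein {p!r} is clamped in opposite directions by "
                f"{btki.name!r} and {cotx.name!r}"
            )
        merged[p] = c
    return list(merged.items())


@dataclass
class InterferenceResult:
    """Per (cotreatment class, process) interference record.

    ``mean_diff_effect`` is on the induction scale (negative = the
    cotreatment damps the drug-evoked process signal); the raw Eq.-scale
    tSignal samples are in ``tsignal_alone`` / ``tsignal_combined``.
    p/q/flag are filled in by :func:`interference_screen`.
    """

    cotx_class: str
    process: str
    tsignal_alone: np.ndarray
    tsignal_combined: np.ndarray
    p_value: float | None = None
    q_value: float | None = None
    flagged: bool | None = None

    @property
    def mean_tsignal_alone(self) -> float:
        return float(np.mean(self.tsignal_alone))

    @property
    def mean_tsignal_combined(self) -> float:
        return float(np.mean(self.tsignal_combined))

    @property
    def per_solution_diff(self) -> np.ndarray:
        """Induction-scale Diff Effect per ensemble solution."""
        return self.tsignal_alone - self.tsignal_combined

    @property
    def mean_diff_effect(self) -> float:
        return float(np.mean(self.per_solution_diff))


def diff_effect(
    net: Interactome,
    ensemble: SolutionEnsemble,
    btki: DrugProfile,
    cotx: DrugProfile,
    effs: EffectorSet,
) -> InterferenceResult:
    """Per-solution tSignal with the drug alone and combined with the
    cotreatment's targets (each clamped per its action)."""
    comp = _compile(net)
    for prof in (btki, cotx):
        missing = [p for p in prof.proteins if p not in comp.index]
        if missing:
            raise ValidationError(f"targets of {prof.name!r} not in network: {missing}")
    alone = btki.clamps()
    combined = _merge_clamps(btki, cotx)
    stims = []
    for clampset in (alone, combined):
        stims.append((
            np.array([comp.index[p] for p, _ in clampset], dtype=np.int64),
            np.array([c for _, c in clampset], dtype=np.float64),
        ))
    eff_idx = np.array([comp.index[p] for p in effs.effectors if p in comp.index], dtype=np.int64)
    eff_sign = np.array([v for p, v in effs.effectors.items() if p in comp.index], dtype=np.float64)
    n_eff = len(effs.effectors)
    ts_alone, ts_comb = [], []
    for sol in ensemble.solutions:
        w = _weight_vector(comp, sol.params)
        y = _propagate_batch(comp, w, [s[0] for s in stims], [s[1] for s in stims], sol.params.steps)
        ts_alone.append(-float(eff_sign @ y[eff_idx, 0]) / n_eff)
        ts_comb.append(-float(eff_sign @ y[eff_idx, 1]) / n_eff)
    return InterferenceResult(
        cotx_class=cotx.name,
        process=effs.process_name,
        tsignal_alone=np.array(ts_alone),
        tsignal_combined=np.array(ts_comb),
    )


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples (both n <= 20), normal
    approximation with tie correction otherwise; two identical constant
    samples give p = 1.0 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("rank-sum test needs at least 2 values per sample")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def paired_sign_test(diffs: Sequence[float]) -> float:
    """Alternative paired test: two-sided Wilcoxon signed-rank of the
    per-solution differences against zero (all-zero differences -> 1.0)."""
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValidationError("paired test needs at least 2 differences")
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d, alternative="two-sided", zero_method="wilcox").pvalue)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at
    1), returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def interference_screen(
    net: Interactome,
    ensemble: SolutionEnsemble,
    btki: DrugProfile,
    cotx_classes: Sequence[DrugProfile],
    processes: Sequence[EffectorSet],
    alpha: float = DEFAULT_ALPHA,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    paired: bool = False,
) -> list[InterferenceResult]:
    """Screen every (cotreatment class, process) pair for interference.

    Diff Effects are computed per pair, p-values come from the rank-sum
    of combined-vs-alone tSignal samples (or the paired signed-rank of
    per-solution differences with ``paired=True``), BH correction spans
    the whole screen, and a pair is flagged when q <= alpha and
    |mean Diff Effect| > diff_threshold. Sorted by q then effect size.
    """
    if not cotx_classes:
        raise ValidationError("at least one cotreatment class is required")
    if not processes:
        raise ValidationError("at least one process is required")
    results = [
        diff_effect(net, ensemble, btki, cotx, effs)
        for cotx in cotx_classes
        for effs in processes
    ]
    for r in results:
        if paired:
            r.p_value = paired_sign_test(r.per_solution_diff)
        else:
            r.p_value = rank_sum_test(r.tsignal_combined, r.tsignal_alone)
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.flagged = bool(r.q_value <= alpha and abs(r.mean_diff_effect) > diff_threshold)
    results.sort(key=lambda r: (r.q_value, -abs(r.mean_diff_effect)))
    return results


def write_interference_tsv(results: Sequence[InterferenceResult], path, drug: str) -> None:
    """Interference table: drug, class, process, mean tSignals (raw
    scale), Diff Effect (induction scale), p, q, flag."""
    with open(path, "w") as fh:
        fh.write(
            "drug\tcotreatment_class\tprocess\tmean_tsignal_alone\t"
            "mean_tsignal_combined\tdiff_effect\tp_value\tq_value\tflagged\n"
        )
        for r in results:
            fh.write(
                f"{drug}\t{r.cotx_class}\t{r.process}\t"
                f"{r.mean_tsignal_alone:.6g}\t{r.mean_tsignal_combined:.6g}\t"
                f"{r.mean_diff_effect:.6g}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{int(bool(r.flagged))}\n"
            )
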