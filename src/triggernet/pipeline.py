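"""End-to-end orchestration: characterize -> train -> trigger -> MoA -> interfere.

A run is driven by a :class:`RunConfig` (a flat JSON file on disk) and
writes a self-contained bundle: the serialized config (provenance), the
trained ensemble, the triggering table, per-drug MoA summaries with DOT
pathway graphs, the interference table, literature-agreement
percentages, and a machine-readable run manifest. Reruns with the same
config and seeds reproduce the numeric tables byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import cotreatment as ct
from . import moa as moa_mod
from . import triggering as trig
from .knowledge_base import (
    DrugProfile,
    EffectorSet,
    KnowledgeBaseError,
    filter_offtargets,
    load_drug_profile,
    load_effector_set,
    load_interactome,
    load_literature_set,
    load_truth_table,
)
from .network_model import TrainConfig, sample_ensemble, save_ensemble

logger = logging.getLogger("triggernet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def configure_logging(output_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Structured logs to stderr and, when a run directory is given, to
    ``run.log`` inside it."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if output_dir is not None:
        handlers.append(logging.FileHandler(Path(output_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """All inputs and thresholds of one full analysis run."""

    network: str
    truth_table: str
    drugs: list[str] = field(default_factory=list)
    processes: list[str] = field(default_factory=list)
    cotreatments: list[str] = field(default_factory=list)
    literature_sets: list[str] = field(default_factory=list)
    output_dir: str = "triggernet_run"
    # thresholds
    ic50_threshold_nm: float = 500.0
    trigger_threshold: float = 0.2
    tau_act: float = 0.05
    min_support: float = 0.5
    max_path_len: int = 4
    alpha: float = 0.05
    diff_threshold: float = 0.05
    # ensemble
    n_solutions: int = 10
    acceptance_threshold: float = 0.9
    base_seed: int = 0
    n_proposals: int = 6000

    def __post_init__(self) -> None:
        for name in ("ic50_threshold_nm", "trigger_threshold", "tau_act", "min_support",
                     "alpha", "diff_threshold"):
            if getattr(self, name) <= 0:
                raise KnowledgeBaseError(f"threshold {name} must be positive")
        if not self.drugs:
            raise KnowledgeBaseError("at least one drug profile is required")
        if not self.processes:
            raise KnowledgeBaseError("at least one process definition is required")

    def validate_paths(self) -> None:
        missing = [
            p for p in [self.network, self.truth_table, *self.drugs, *self.processes,
                        *self.cotreatments, *self.literature_sets]
            if not Path(p).exists()
        ]
        if missing:
            raise KnowledgeBaseError(f"input paths do not exist: {missing}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc.pop("schema_version", None)
        return cls(**doc)

    def to_json(self, path: str | Path) -> None:
        doc = {"schema_version": 1, **asdict(self)}
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest: dict = {"stages": {}, "outputs": {}}

    stage = "load"
    try:
        logger.info("stage=load network=%s", config.network)
        net = load_interactome(config.network)
        raw_drugs = [load_drug_profile(p) for p in config.drugs]
        drugs = [filter_offtargets(d, config.ic50_threshold_nm) for d in raw_drugs]
        processes = [load_effector_set(p) for p in config.processes]
        cotx = [load_drug_profile(p) for p in config.cotreatments]
        lits = [load_literature_set(p) for p in config.literature_sets]
        truth = load_truth_table(config.truth_table)
        manifest["stages"]["load"] = {
            "n_proteins": net.n_proteins, "n_edges": net.n_edges,
            "n_constraints": len(truth),
            "drugs": {d.name: len(d.targets) for d in drugs},
        }
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "train"
    try:
        logger.info("stage=train n_solutions=%d base_seed=%d", config.n_solutions, config.base_seed)
        ensemble = sample_ensemble(
            net, truth, config.n_solutions,
            acceptance_threshold=config.acceptance_threshold,
            base_seed=config.base_seed,
            config=TrainConfig(n_proposals=config.n_proposals, tau_act=config.tau_act),
        )
        save_ensemble(ensemble, out / "ensemble")
        manifest["stages"]["train"] = {
            "n_retained": len(ensemble),
            "mean_accuracy": ensemble.mean_accuracy,
            "all_accuracies": ensemble.all_accuracies,
        }
        manifest["outputs"]["ensemble"] = "ensemble"
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "trigger"
    try:
        evaluated = sorted({p for d in drugs for p in d.proteins})
        logger.info("stage=trigger n_evaluated=%d n_processes=%d", len(evaluated), len(processes))
        table = trig.compute_triggering_table(
            net, ensemble, evaluated, processes,
            trigger_threshold=config.trigger_threshold,
        )
        tags = {
            p: "/".join(d.name for d in drugs if p in d)
            for p in evaluated
        }
        trig.write_triggering_tsv(table, out / "triggering.tsv", drug_tags=tags)
        flagged = trig.classify_triggers(table, config.trigger_threshold)
        manifest["stages"]["trigger"] = {"n_flagged": len(flagged),
                                         "flagged": sorted(map(list, flagged))}
        manifest["outputs"]["triggering"] = "triggering.tsv"
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "moa"
    try:
        moa_models: dict[str, list[moa_mod.MoAModel]] = {d.name: [] for d in drugs}
        moa_outputs = []
        for drug in drugs:
            for effs in processes:
                drug_flagged = [p for (p, proc) in flagged
                                if proc == effs.process_name and p in drug]
                if not drug_flagged:
                    continue
                logger.info("stage=moa drug=%s process=%s flagged=%s",
                            drug.name, effs.process_name, drug_flagged)
                model = moa_mod.build_moa(net, ensemble, drug, drug_flagged, effs)
                moa_models[drug.name].append(model)
                pathways = moa_mod.extract_pathways(
                    net, ensemble, model,
                    max_len=config.max_path_len, min_support=config.min_support,
                )
                base = f"moa_{drug.name}_{effs.process_name}"
                (out / f"{base}.dot").write_text(moa_mod.export_dot(model, pathways))
                with open(out / f"{base}.tsv", "w") as fh:
                    fh.write("protein\tmean_activity\tn_solutions_present\n")
                    tau = ensemble.tau_act
                    acts = model.activities
                    for j, p in enumerate(model.nodes):
                        n_present = int((abs(acts[:, j]) >= tau).sum())
                        if n_present == 0:
                            continue
                        fh.write(f"{p}\t{model.mean_activity[p]:.6g}\t{n_present}\n")
                with open(out / f"{base}_pathways.tsv", "w") as fh:
                    fh.write("pathway\tedge_signs\tsupport\n")
                    for r in pathways:
                        signs = ",".join(f"{s:+d}" for s in r.edge_signs)
                        fh.write(f"{'->'.join(r.nodes)}\t{signs}\t{r.support:.6g}\n")
                moa_outputs.append({"drug": drug.name, "process": effs.process_name,
                                    "n_pathways": len(pathways), "files": base})
        agreement = {}
        for lit in lits:
            models = moa_models.get(lit.drug, [])
            if models:
                agreement[lit.drug] = moa_mod.literature_agreement(
                    models, lit, tau_act=config.tau_act
                )
        manifest["stages"]["moa"] = {"models": moa_outputs, "literature_agreement": agreement}
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "interfere"
    try:
        interference = {}
        for drug in drugs:
            if not cotx:
                continue
            logger.info("stage=interfere drug=%s n_classes=%d", drug.name, len(cotx))
            results = ct.interference_screen(
                net, ensemble, drug, cotx, processes,
                alpha=config.alpha, diff_threshold=config.diff_threshold,
            )
            fname = f"interference_{drug.name}.tsv"
            ct.write_interference_tsv(results, out / fname, drug.name)
            interference[drug.name] = {
                "file": fname,
                "n_flagged": sum(bool(r.flagged) for r in results),
                "flagged": [[r.cotx_class, r.process, r.mean_diff_effect]
                            for r in results if r.flagged],
            }
        manifest["stages"]["interfere"] = interference
    except Exception as e:
        raise PipelineError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("run complete: %s", out)
    return manifest
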