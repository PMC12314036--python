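"""Domain data model and file I/O.

Holds the five curated inputs the analysis runs on: the signed directed
protein-interaction network (interactome), drug target profiles, effector
sets defining pathophysiological processes, literature response sets used
for post-hoc agreement scoring, and stimulus->response truth tables used
for model training.

Protein identifiers are case-sensitive gene symbols throughout; no
identifier mapping is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx

SCHEMA_VERSION = 1

#: accepted edge-sign spellings, normalized internally to +1 / -1
_SIGN_TOKENS = {
    "1": 1, "+1": 1, "+": 1,
    "activation": 1, "activates": 1, "activate": 1,
    "-1": -1, "−1": -1, "-": -1,
    "inhibition": -1, "inhibits": -1, "inhibit": -1,
}

ACTIONS = ("inhibit", "activate")
ROLES = ("primary_target", "off_target")


class KnowledgeBaseError(ValueError):
    """Base class for validation and parse failures in this module."""


class ParseError(KnowledgeBaseError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(KnowledgeBaseError):
    """An object violates a structural invariant."""


def _norm_sign(token: Union[str, int, float], *, where: str = "") -> int:
    key = str(token).strip().lower()
    if key in _SIGN_TOKENS:
        return _SIGN_TOKENS[key]
    raise ParseError(f"malformed sign token {token!r}{where}")


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

class Interactome:
    """Signed, directed protein-interaction network.

    Edges carry a sign: +1 for activation, -1 for inhibition. Self-edges
    and duplicate (source, target) pairs are rejected; a duplicate pair
    with conflicting signs is reported as conflicting curation.
    """

    def __init__(
        self,
        proteins: Iterable[str],
        edges: Iterable[tuple[str, str, int]],
        annotations: Mapping[tuple[str, str], str] | None = None,
    ) -> None:
        self.proteins: set[str] = {str(p) for p in proteins}
        self.edges: list[tuple[str, str, int]] = []
        seen: dict[tuple[str, str], int] = {}
        for u, v, s in edges:
            u, v = str(u), str(v)
            if s not in (1, -1):
                raise ValidationError(f"edge ({u}, {v}) has sign {s!r}; must be +1 or -1")
            if u == v:
                raise ValidationError(f"self-edge on {u!r} is not allowed")
            if u not in self.proteins or v not in self.proteins:
                missing = u if u not in self.proteins else v
                raise ValidationError(f"edge endpoint {missing!r} is not in the protein set")
            key = (u, v)
            if key in seen:
                if seen[key] != s:
                    raise ValidationError(
                        f"conflicting signs for duplicate edge {u} -> {v}; "
                        "resolve the curation upstream"
                    )
                raise ValidationError(f"duplicate edge {u} -> {v}")
            seen[key] = s
            self.edges.append((u, v, int(s)))
        self.annotations = dict(annotations or {})
        self._graph: nx.DiGraph | None = None

    @property
    def graph(self) -> nx.DiGraph:
        """The network as a networkx DiGraph with a 'sign' edge attribute."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(sorted(self.proteins))
            for u, v, s in self.edges:
                g.add_edge(u, v, sign=s)
            self._graph = g
        return self._graph

    def edge_sign(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["sign"]

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.proteins == other.proteins and set(self.edges) == set(other.edges)

    def __repr__(self) -> str:
        return f"Interactome({self.n_proteins} proteins, {self.n_edges} edges)"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "sif", "graphml"):
        return suffix
    raise KnowledgeBaseError(f"cannot infer network format from {path.name!r}; pass format=")


def load_interactome(path: str | Path, format: str | None = None) -> Interactome:
    """Load a signed directed network from TSV, SIF or GraphML.

    TSV rows are ``source<TAB>sign<TAB>target``; SIF rows are
    ``source<TAB>relation<TAB>target`` with relation in {activates,
    inhibits}. GraphML must carry a ``sign`` edge attribute.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    edges: list[tuple[str, str, int]] = []
    if fmt in ("tsv", "sif"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path.name}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
                u, token, v = (p.strip() for p in parts)
                sign = _norm_sign(token, where=f" at {path.name}:{lineno}")
                edges.append((u, v, sign))
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        for u, v, data in g.edges(data=True):
            if "sign" not in data:
                raise ParseError(f"{path.name}: edge {u} -> {v} lacks a 'sign' attribute")
            edges.append((str(u), str(v), _norm_sign(data["sign"], where=f" on edge {u} -> {v}")))
    else:
        raise KnowledgeBaseError(f"unsupported network format {fmt!r}")
    if not edges:
        raise ParseError(f"{path.name}: no edges")
    proteins = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    if fmt == "graphml":
        proteins |= {str(n) for n in g.nodes}
    return Interactome(proteins, edges)


def save_interactome(net: Interactome, path: str | Path, format: str | None = None) -> None:
    """Write a network in TSV, SIF or GraphML; inverse of :func:`load_interactome`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        with open(path, "w") as fh:
            for u, v, s in net.edges:
                fh.write(f"{u}\t{'+1' if s > 0 else '-1'}\t{v}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, s in net.edges:
                fh.write(f"{u}\t{'activates' if s > 0 else 'inhibits'}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise KnowledgeBaseError(f"unsupported network format {fmt!r}")


# ---------------------------------------------------------------------------
# Drug profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugTarget:
    """One (protein, action) entry of a drug's target profile.

    ``ic50_nm`` is the reported half-maximal inhibitory concentration in
    nanomolar; ``regulatory_source`` marks targets taken from a regulatory
    assessment report, which are kept by the potency filter even without
    an IC50 value.
    """

    protein: str
    action: str = "inhibit"
    ic50_nm: float | None = None
    role: str = "off_target"
    regulatory_source: bool = False

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValidationError(f"target action must be one of {ACTIONS}, got {self.action!r}")
        if self.role not in ROLES:
            raise ValidationError(f"target role must be one of {ROLES}, got {self.role!r}")
        if self.ic50_nm is not None and not self.ic50_nm > 0:
            raise ValidationError(f"ic50_nm must be positive, got {self.ic50_nm}")

    @property
    def clamp_value(self) -> int:
        """Clamp applied when the drug acts on this target: inhibit -> -1."""
        return -1 if self.action == "inhibit" else 1


@dataclass
class DrugProfile:
    """A drug (or drug class) as its set of protein targets with actions."""

    name: str
    targets: list[DrugTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.targets:
            if t.protein in seen:
                raise ValidationError(f"protein {t.protein!r} appears twice in profile {self.name!r}")
            seen.add(t.protein)

    @property
    def proteins(self) -> list[str]:
        return [t.protein for t in self.targets]

    def clamps(self) -> list[tuple[str, int]]:
        """Clamp set implied by administering the drug (one entry per target)."""
        return [(t.protein, t.clamp_value) for t in self.targets]

    def __contains__(self, protein: str) -> bool:
        return protein in set(self.proteins)


def filter_offtargets(profile: DrugProfile, threshold_nm: float = 500.0) -> DrugProfile:
    """Keep targets with IC50 strictly below ``threshold_nm``, or with no
    recorded IC50 but sourced from a regulatory document. Order preserved.
    """
    if not threshold_nm > 0:
        raise ValidationError(f"threshold_nM must be positive, got {threshold_nm}")
    kept = [
        t for t in profile.targets
        if (t.ic50_nm is not None and t.ic50_nm < threshold_nm)
        or (t.ic50_nm is None and t.regulatory_source)
    ]
    return DrugProfile(name=profile.name, targets=kept)


# ---------------------------------------------------------------------------
# Effector sets, literature response sets
# ---------------------------------------------------------------------------

@dataclass
class EffectorSet:
    """A pathophysiological process as proteins with expected activity signs.

    ``effectors`` maps protein -> expected sign v_i: +1 if the process
    involves the protein being active, -1 if inactive.
    """

    process_name: str
    effectors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.effectors:
            raise ValidationError(f"effector set {self.process_name!r} is empty")
        for p, v in self.effectors.items():
            if v not in (1, -1):
                raise ValidationError(f"expected sign for {p!r} must be +1 or -1, got {v!r}")

    @property
    def proteins(self) -> list[str]:
        return list(self.effectors)

    def __len__(self) -> int:
        return len(self.effectors)


@dataclass
class LiteratureResponseSet:
    """Literature-described directions of proteins indirectly modulated by
    a drug; used only for post-hoc agreement scoring, never for training."""

    drug: str
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, v in self.entries.items():
            if v not in (1, -1):
                raise ValidationError(f"described direction for {p!r} must be +1 or -1, got {v!r}")


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    """One training datum: clamping ``stimulus`` must drive ``response``
    to ``required_sign`` (with suprathreshold magnitude)."""

    stimulus: tuple[tuple[str, int], ...]
    response: str
    required_sign: int

    def __post_init__(self) -> None:
        if self.required_sign not in (1, -1):
            raise ValidationError(f"required_sign must be +1 or -1, got {self.required_sign!r}")
        seen = set()
        for p, c in self.stimulus:
            if c not in (1, -1):
                raise ValidationError(f"clamp value for {p!r} must be +1 or -1, got {c!r}")
            if p in seen:
                raise ValidationError(f"protein {p!r} clamped twice in one stimulus")
            seen.add(p)


@dataclass
class TruthTable:
    """The training set: a list of stimulus -> required response constraints."""

    constraints: list[Constraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValidationError("truth table must contain at least one constraint")

    def __len__(self) -> int:
        return len(self.constraints)


# ---------------------------------------------------------------------------
# Cross-validation against a network
# ---------------------------------------------------------------------------

def _referenced_proteins(obj) -> set[str]:
    if isinstance(obj, DrugProfile):
        return set(obj.proteins)
    if isinstance(obj, EffectorSet):
        return set(obj.effectors)
    if isinstance(obj, LiteratureResponseSet):
        return set(obj.entries)
    if isinstance(obj, TruthTable):
        out: set[str] = set()
        for c in obj.constraints:
            out.update(p for p, _ in c.stimulus)
            out.add(c.response)
        return out
    raise TypeError(f"cannot validate object of type {type(obj).__name__}")


def validate_against_network(obj, net: Interactome) -> list[str]:
    """Return the identifiers in ``obj`` that are absent from ``net``
    (sorted); an empty list means the object maps fully."""
    return sorted(_referenced_proteins(obj) - net.proteins)


# ---------------------------------------------------------------------------
# JSON / TSV serialization
# ---------------------------------------------------------------------------

def _check_schema(doc: dict, expected_type: str, path: Path) -> None:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"{path.name}: unsupported schema_version {doc.get('schema_version')!r}")
    if doc.get("type") != expected_type:
        raise ParseError(f"{path.name}: expected type {expected_type!r}, got {doc.get('type')!r}")


def save_drug_profile(profile: DrugProfile, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".tsv":
        with open(path, "w") as fh:
            fh.write("protein\taction\tic50_nM\trole\tregulatory_source\n")
            for t in profile.targets:
                ic50 = "" if t.ic50_nm is None else repr(t.ic50_nm)
                fh.write(f"{t.protein}\t{t.action}\t{ic50}\t{t.role}\t{int(t.regulatory_source)}\n")
        return
    doc = {
        "schema_version": SCHEMA_VERSION,
        "type": "drug_profile",
        "name": profile.name,
        "targets": [
            {"protein": t.protein, "action": t.action, "ic50_nM": t.ic50_nm,
             "role": t.role, "regulatory_source": t.regulatory_source}
            for t in profile.targets
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def load_drug_profile(path: str | Path, name: str | None = None) -> DrugProfile:
    path = Path(path)
    if path.suffix == ".tsv":
        targets = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("protein\t"):
                raise ParseError(f"{path.name}:1: missing drug-profile header")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 5:
                    raise ParseError(f"{path.name}:{lineno}: expected 5 fields, got {len(parts)}")
                p, action, ic50, role, reg = parts
                targets.append(DrugTarget(
                    protein=p, action=action,
                    ic50_nm=float(ic50) if ic50 else None,
                    role=role, regulatory_source=bool(int(reg)),
                ))
        return DrugProfile(name=name or path.stem, targets=targets)
    doc = json.loads(path.read_text())
    _check_schema(doc, "drug_profile", path)
    return DrugProfile(
        name=doc["name"],
        targets=[
            DrugTarget(protein=t["protein"], action=t["action"], ic50_nm=t.get("ic50_nM"),
                       role=t.get("role", "off_target"),
                       regulatory_source=bool(t.get("regulatory_source", False)))
            for t in doc["targets"]
        ],
    )


def save_effector_set(effs: EffectorSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".tsv":
        with open(path, "w") as fh:
            fh.write("protein\texpected_sign\n")
            for p, v in effs.effectors.items():
                fh.write(f"{p}\t{'+1' if v > 0 else '-1'}\n")
        return
    doc = {
        "schema_version": SCHEMA_VERSION,
        "type": "effector_set",
        "process_name": effs.process_name,
        "effectors": [{"protein": p, "expected_sign": v} for p, v in effs.effectors.items()],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def load_effector_set(path: str | Path, process_name: str | None = None) -> EffectorSet:
    path = Path(path)
    if path.suffix == ".tsv":
        effectors: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("protein\t"):
                raise ParseError(f"{path.name}:1: missing effector-set header")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{path.name}:{lineno}: expected 2 fields, got {len(parts)}")
                p, v = parts
                if p in effectors:
                    raise ParseError(f"{path.name}:{lineno}: duplicate effector {p!r}")
                effectors[p] = _norm_sign(v, where=f" at {path.name}:{lineno}")
        return EffectorSet(process_name=process_name or path.stem, effectors=effectors)
    doc = json.loads(path.read_text())
    _check_schema(doc, "effector_set", path)
    effectors = {}
    for e in doc["effectors"]:
        if e["protein"] in effectors:
            raise ParseError(f"{path.name}: duplicate effector {e['protein']!r}")
        effectors[e["protein"]] = int(e["expected_sign"])
    return EffectorSet(process_name=doc["process_name"], effectors=effectors)


def save_literature_set(lit: LiteratureResponseSet, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "type": "literature_response_set",
        "drug": lit.drug,
        "entries": [{"protein": p, "described_direction": v} for p, v in lit.entries.items()],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_literature_set(path: str | Path) -> LiteratureResponseSet:
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_schema(doc, "literature_response_set", path)
    entries: dict[str, int] = {}
    for e in doc["entries"]:
        if e["protein"] in entries:
            raise ParseError(f"{path.name}: duplicate entry {e['protein']!r}")
        entries[e["protein"]] = int(e["described_direction"])
    return LiteratureResponseSet(drug=doc["drug"], entries=entries)


def save_truth_table(truth: TruthTable, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "type": "truth_table",
        "constraints": [
            {"stimulus": [{"protein": p, "clamp": c} for p, c in con.stimulus],
             "response": con.response, "required_sign": con.required_sign}
            for con in truth.constraints
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_truth_table(path: str | Path) -> TruthTable:
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_schema(doc, "truth_table", path)
    constraints = [
        Constraint(
            stimulus=tuple((s["protein"], int(s["clamp"])) for s in c["stimulus"]),
            response=c["response"],
            required_sign=int(c["required_sign"]),
        )
        for c in doc["constraints"]
    ]
    return TruthTable(constraints=constraints)
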