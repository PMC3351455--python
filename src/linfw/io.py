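"""Readers and writers for the file formats.

Graph JSON::

    {"vertices": ["1", "2"],
     "edges": [{"from": "1", "to": "2", "label": "k1*[S]"}, ...]}

Graph TSV: three columns ``from<TAB>to<TAB>label``; symbols in labels
are rate constants unless bracketed as ``[X]``.  Mechanism JSON: a list
of reactions ``{"type": "bind|release|convert", "from": ..., "to": ...,
"k": ..., "species": ...}`` plus the enzyme name.  Partial-graph JSON:
a core graph plus ``{"synthesis": {v: rate}, "degradation": {v: rate}}``.
Reaction-network JSON: ``{"species": [...], "reactions":
[{"reactants": {"A": 1}, "products": {...}, "k": 1.0}]}``.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from pathlib import Path
from typing import Mapping

import sympy
import yaml

from .enzymes import EnzymeReaction, MechanismSpec
from .binding import BindingSystem
from .crnt import ReactionNetwork
from .graph import GraphError, LinGraph, build_graph
from .labels import format_label, parse_label
from .ptm import PTMEnzyme, PTMSystem
from .syndeg import PartialGraph

__all__ = [
    "RunConfig",
    "read_graph",
    "write_graph",
    "read_mechanism",
    "read_partial_graph",
    "read_network",
    "read_ptm_system",
    "write_ptm_system",
    "read_binding_system",
    "write_binding_system",
]


from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class RunConfig:
    """Run-wide defaults: tolerances, ODE settings, solver seeding and
    output format.  Round-trips losslessly through YAML."""

    symbolic_term_cap: int = 2000       # ops before probabilistic equality
    numeric_rtol: float = 1e-10
    numeric_atol: float = 1e-12
    cycle_tolerance: float = 1e-9       # relative, cycle-condition ratios
    ode_deriv_tol: float = 1e-10        # steady-state stopping criterion
    solver_seed: int = 0
    output_format: str = "expr"         # expr | tsv | json

    def save(self, path) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        Path(path).write_text(text)
        return text

    @staticmethod
    def load(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = RunConfig.__dataclass_fields__
        bad = set(data) - set(known)
        if bad:
            raise GraphError(f"unknown config fields: {sorted(bad)}")
        return RunConfig(**data)


def _load(path_or_text, suffix_hint=".json"):
    if isinstance(path_or_text, (str, Path)) and Path(str(path_or_text)).exists():
        p = Path(str(path_or_text))
        return p.read_text(), p.suffix or suffix_hint
    return str(path_or_text), suffix_hint


def read_graph(path) -> LinGraph:
    """Read a graph from a JSON or TSV file."""
    text, suffix = _load(path)
    if suffix == ".tsv":
        rows = list(csv.reader(_stdio.StringIO(text), delimiter="\t"))
        rows = [r for r in rows if r and not r[0].startswith("#")]
        verts: list[str] = []
        triples = []
        for r in rows:
            if len(r) != 3:
                raise GraphError(f"TSV row must have 3 fields, got {r}")
            s, t, lab = r
            for v in (s, t):
                if v not in verts:
                    verts.append(v)
            triples.append((s, t, parse_label(lab)))
        return build_graph(verts, triples)
    data = json.loads(text)
    triples = [
        (e["from"], e["to"], parse_label(str(e["label"])))
        for e in data["edges"]
    ]
    return build_graph(data["vertices"], triples)


def write_graph(G: LinGraph, path=None) -> str:
    """Serialise a graph to the JSON format; returns the text (and
    writes it if ``path`` is given)."""
    data = {
        "vertices": list(G.vertices),
        "edges": [
            {"from": s, "to": t, "label": format_label(l)}
            for (s, t), l in sorted(
                G.edges.items(),
                key=lambda kv: (G.vertices.index(kv[0][0]), G.vertices.index(kv[0][1])),
            )
        ],
    }
    text = json.dumps(data, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_mechanism(path) -> MechanismSpec:
    text, _ = _load(path)
    data = json.loads(text)
    kinds = {"bind", "release", "convert"}
    reactions = []
    for i, r in enumerate(data["reactions"]):
        if r.get("type") not in kinds:
            raise GraphError(f"reactions[{i}].type must be one of {sorted(kinds)}")
        reactions.append(
            EnzymeReaction(
                r["type"], r["from"], r["to"], r["k"], r.get("species")
            )
        )
    return MechanismSpec(
        data["enzyme"], tuple(data["intermediates"]), tuple(reactions)
    )


def read_partial_graph(path) -> PartialGraph:
    text, _ = _load(path)
    data = json.loads(text)
    core = build_graph(
        data["vertices"],
        [(e["from"], e["to"], parse_label(str(e["label"]))) for e in data["edges"]],
    )
    syn = {v: parse_label(str(r)) for v, r in data.get("synthesis", {}).items()}
    deg = {v: parse_label(str(r)) for v, r in data.get("degradation", {}).items()}
    return PartialGraph(core, syn, deg)


def read_network(path) -> ReactionNetwork:
    text, _ = _load(path)
    data = json.loads(text)
    return ReactionNetwork.make(
        data["species"],
        [(r["reactants"], r["products"], float(r["k"])) for r in data["reactions"]],
    )


def _mechanism_from_dict(data: Mapping) -> MechanismSpec:
    reactions = tuple(
        EnzymeReaction(r["type"], r["from"], r["to"], r["k"], r.get("species"))
        for r in data["reactions"]
    )
    return MechanismSpec(data["enzyme"], tuple(data["intermediates"]), reactions)


def read_ptm_system(path):
    """PTM system from YAML/JSON; returns ``(PTMSystem, k_values)``
    where k_values maps rate-constant names to floats (may be empty for
    a purely symbolic system)."""
    text, _ = _load(path, ".yaml")
    data = yaml.safe_load(text)
    enzymes = tuple(
        PTMEnzyme(e["name"], tuple(_mechanism_from_dict(m) for m in e["mechanisms"]))
        for e in data["enzymes"]
    )
    system = PTMSystem(tuple(data["modforms"]), enzymes)
    return system, {k: float(v) for k, v in data.get("rate_constants", {}).items()}


def write_ptm_system(system: PTMSystem, k_values=None, path=None) -> str:
    """Serialise a PTM system (and optional numeric rate constants) to
    the YAML schema accepted by :func:`read_ptm_system`."""
    data = {
        "modforms": list(system.modforms),
        "enzymes": [
            {
                "name": e.name,
                "mechanisms": [
                    {
                        "enzyme": m.enzyme,
                        "intermediates": list(m.intermediates),
                        "reactions": [
                            {"type": rx.kind, "from": rx.source,
                             "to": rx.target, "k": rx.k,
                             "species": rx.species}
                            for rx in m.reactions
                        ],
                    }
                    for m in e.mechanisms
                ],
            }
            for e in system.enzymes
        ],
    }
    if k_values:
        data["rate_constants"] = {k: float(v) for k, v in k_values.items()}
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_binding_system(system: BindingSystem, k_values=None, path=None) -> str:
    """Serialise a binding system to the YAML schema accepted by
    :func:`read_binding_system` (table keys comma-joined)."""

    def table(t):
        return {
            ",".join(map(str, k)): str(v) for k, v in sorted(
                t.items(), key=lambda kv: tuple(map(str, kv[0]))
            )
        }

    data = {
        "conformations": list(system.conformations),
        "site_ligands": list(system.site_ligands),
        "conf_transitions": table(system.conf_transitions),
        "on_constants": table(system.on_constants),
        "off_constants": table(system.off_constants),
    }
    if system.pruned:
        data["pruned"] = sorted(system.pruned)
    if k_values:
        data["rate_constants"] = {k: float(v) for k, v in k_values.items()}
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _tuple_key(k):
    if isinstance(k, str):
        parts = k.split(",")
        return tuple(int(p) if p.lstrip("-").isdigit() else p for p in parts)
    return tuple(k)


def read_binding_system(path):
    """Binding system from YAML/JSON; table keys are comma-joined, e.g.
    ``"C1,0"`` for (conformation C1, site 0).  Returns
    ``(BindingSystem, k_values)``."""
    text, _ = _load(path, ".yaml")
    data = yaml.safe_load(text)
    sym = lambda s: sympy.Symbol(str(s), positive=True) if not _is_number(s) else sympy.Float(s)
    on = {_tuple_key(k): sym(v) for k, v in data.get("on_constants", {}).items()}
    off = {_tuple_key(k): sym(v) for k, v in data.get("off_constants", {}).items()}
    trans = {_tuple_key(k): sym(v) for k, v in data.get("conf_transitions", {}).items()}
    system = BindingSystem(
        tuple(data["conformations"]),
        tuple(data["site_ligands"]),
        trans,
        on,
        off,
        frozenset(data.get("pruned", [])),
    )
    return system, {k: float(v) for k, v in data.get("rate_constants", {}).items()}


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False
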