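"""Minimal HPO-style ontology graph with true-path-rule propagation.

The Human Phenotype Ontology (HPO) is a directed acyclic graph of phenotype
terms connected by ``is_a`` edges.  Annotation follows the *true path rule*:
an individual annotated to a specific term (e.g. *Nuclear cataract*) also
manifests every ancestor term (*Zonular cataract*, *Cataract*, ...).  This
module loads an ontology from OBO-graph JSON (the ``hp.json`` dialect) or a
compact toy dialect, answers ancestor/descendant queries, and propagates
observed/excluded annotations across the hierarchy.

Exclusion propagates *downward*: excluding a general term (no *Cataract*)
logically excludes every specialization of it.  A term reached by both an
upward observed path and a downward excluded path is flagged as conflicting
and dropped from the individual's analyzable set.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx

__all__ = [
    "TermId",
    "ObservationStatus",
    "OntologyGraph",
    "OntologyError",
    "PropagationResult",
    "load_ontology",
    "propagate",
]

_TERM_ID_RE = re.compile(r"^(HP:\d{7}|(?!HP:)[A-Za-z][A-Za-z0-9]*:\d+)$")


class OntologyError(ValueError):
    """Structural or lookup failure in an ontology document or query."""


class TermId(str):
    """A CURIE identifying an ontology term, e.g. ``HP:0001250``.

    Real HPO terms use the ``HP:`` prefix with seven digits; toy ontologies
    may use any alphanumeric prefix (``TOY:``).  Equality is plain string
    equality, so a ``TermId`` can be used interchangeably with a validated
    string.
    """

    def __new__(cls, value: str) -> "TermId":
        if not _TERM_ID_RE.match(value):
            raise OntologyError(f"not a valid term CURIE: {value!r}")
        return super().__new__(cls, value)


class ObservationStatus(enum.Enum):
    """Whether a phenotypic feature was observed or explicitly excluded.

    Absence of a term from an individual's record means *not assayed*,
    never EXCLUDED.
    """

    OBSERVED = "OBSERVED"
    EXCLUDED = "EXCLUDED"


class OntologyGraph:
    """DAG of terms over ``is_a`` edges with a phenotypic-abnormality subroot.

    Edges run child -> parent.  ``ancestors`` walks edges forward (toward
    the root); ``descendants`` walks them backward.
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str]],
        root: str,
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        for tid, label in terms.items():
            g.add_node(TermId(tid), label=label)
        for child, parent in edges:
            if child not in g or parent not in g:
                missing = child if child not in g else parent
                raise OntologyError(f"edge endpoint not declared as a term: {missing}")
            g.add_edge(TermId(child), TermId(parent))
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is_a cycle detected, e.g. edge {cycle[0][0]} -> {cycle[0][1]}")
        if root not in g:
            raise OntologyError(f"declared root {root} is not a member term")
        self._g = g
        self._root = TermId(root)
        self._alt = {TermId(k): TermId(v) for k, v in (alt_ids or {}).items()}
        # the graph is immutable after construction, so closures are cacheable
        self._anc_cache: dict[TermId, frozenset[TermId]] = {}
        self._des_cache: dict[TermId, frozenset[TermId]] = {}

    # -- basic queries ---------------------------------------------------

    @property
    def root(self) -> TermId:
        """The designated *Phenotypic abnormality* subroot."""
        return self._root

    @property
    def terms(self) -> frozenset[TermId]:
        return frozenset(self._g.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._g or term in self._alt

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def primary(self, term: str) -> TermId:
        """Resolve an alternative/obsolete id to its primary id."""
        term = TermId(term)
        if term in self._alt:
            return self._alt[term]
        if term not in self._g:
            raise OntologyError(f"unknown term: {term}")
        return term

    def label(self, term: str) -> str:
        return self._g.nodes[self.primary(term)].get("label", "")

    def parents(self, term: str) -> frozenset[TermId]:
        return frozenset(self._g.successors(self.primary(term)))

    def children(self, term: str) -> frozenset[TermId]:
        return frozenset(self._g.predecessors(self.primary(term)))

    def ancestors(self, term: str, include_self: bool = False) -> frozenset[TermId]:
        """Transitive closure over ``is_a`` edges toward the root."""
        t = self.primary(term)
        if t not in self._anc_cache:
            # graph edges point child -> parent
            self._anc_cache[t] = frozenset(nx.descendants(self._g, t))
        anc = self._anc_cache[t]
        return anc | {t} if include_self else anc

    def descendants(self, term: str, include_self: bool = False) -> frozenset[TermId]:
        t = self.primary(term)
        if t not in self._des_cache:
            self._des_cache[t] = frozenset(nx.ancestors(self._g, t))
        des = self._des_cache[t]
        return des | {t} if include_self else des

    def is_general_level(self, term: str, depth: int = 1) -> bool:
        """True for the subroot itself and terms within ``depth`` levels below it.

        Also true for terms that are not descendants of the subroot at all
        (they carry no phenotype signal of interest).
        """
        t = self.primary(term)
        if t == self._root:
            return True
        if self._root not in self.ancestors(t):
            return True
        frontier = {self._root}
        for _ in range(depth):
            frontier = set().union(*(self.children(x) for x in frontier)) if frontier else set()
            if t in frontier:
                return True
        return False


# -- loading ------------------------------------------------------------


def load_ontology(document: Union[str, Path, Mapping]) -> OntologyGraph:
    """Load an ontology from a toy-dialect or OBO-graph JSON document.

    Toy dialect::

        {"root": "TOY:1", "terms": [{"id": ..., "label": ...}],
         "edges": [[child, parent], ...]}

    OBO-graph dialect (``hp.json``): ``graphs[0].nodes`` / ``graphs[0].edges``
    with ``pred`` of ``is_a``; node IRIs are converted to CURIEs; deprecated
    nodes are skipped and ``hasAlternativeId`` mappings are resolved to the
    primary id.
    """
    if isinstance(document, (str, Path)):
        with open(document) as fh:
            document = json.load(fh)
    if "graphs" in document:
        return _load_obograph(document)
    return _load_toy(document)


def _load_toy(doc: Mapping) -> OntologyGraph:
    terms = {t["id"]: t.get("label", "") for t in doc["terms"]}
    edges = [tuple(e) for e in doc["edges"]]
    return OntologyGraph(terms, edges, doc["root"])


_IRI_RE = re.compile(r".*/([A-Za-z0-9]+)_(\d+)$")

PHENOTYPIC_ABNORMALITY = "HP:0000118"


def _curie(iri: str) -> str:
    m = _IRI_RE.match(iri)
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    return iri


def _load_obograph(doc: Mapping) -> OntologyGraph:
    graph = doc["graphs"][0]
    terms: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node in graph.get("nodes", []):
        if node.get("type") not in (None, "CLASS"):
            continue
        meta = node.get("meta", {}) or {}
        tid = _curie(node["id"])
        if not _TERM_ID_RE.match(tid):
            continue
        if meta.get("deprecated"):
            continue
        terms[tid] = node.get("lbl", "")
        for bpv in meta.get("basicPropertyValues", []):
            if bpv.get("pred", "").endswith("hasAlternativeId"):
                alt_ids[_curie(bpv["val"])] = tid
    edges = []
    for e in graph.get("edges", []):
        if e.get("pred") not in ("is_a", "rdfs:subClassOf"):
            continue
        child, parent = _curie(e["sub"]), _curie(e["obj"])
        if child in terms and parent in terms:
            edges.append((child, parent))
    root = doc.get("root") or PHENOTYPIC_ABNORMALITY
    return OntologyGraph(terms, edges, root, alt_ids=alt_ids)


# -- propagation --------------------------------------------------------


@dataclass(frozen=True)
class PropagationResult:
    """Propagated annotation statuses for one individual.

    ``statuses`` maps each term to OBSERVED or EXCLUDED after rollup;
    ``conflicting`` lists terms reached by both an observed and an excluded
    source annotation — these are dropped from ``statuses`` and from any
    downstream counting.
    """

    statuses: Mapping[TermId, ObservationStatus]
    conflicting: frozenset[TermId] = field(default_factory=frozenset)

    def observed(self) -> frozenset[TermId]:
        return frozenset(
            t for t, s in self.statuses.items() if s is ObservationStatus.OBSERVED
        )

    def excluded(self) -> frozenset[TermId]:
        return frozenset(
            t for t, s in self.statuses.items() if s is ObservationStatus.EXCLUDED
        )


def propagate(
    graph: OntologyGraph,
    observations: Sequence[tuple[str, ObservationStatus]],
) -> PropagationResult:
    """Apply the true path rule to a set of direct annotations.

    Every OBSERVED annotation marks the term and all its ancestors OBSERVED;
    every EXCLUDED annotation marks the term and all its descendants
    EXCLUDED.  Terms touched by both rules are flagged conflicting and
    excluded from the status map.
    """
    observed: set[TermId] = set()
    excluded: set[TermId] = set()
    for term, status in observations:
        t = graph.primary(term)
        if status is ObservationStatus.OBSERVED:
            observed |= graph.ancestors(t, include_self=True)
        elif status is ObservationStatus.EXCLUDED:
            excluded |= graph.descendants(t, include_self=True)
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown status {status}")
    conflicting = frozenset(observed & excluded)
    statuses: dict[TermId, ObservationStatus] = {}
    for t in observed - conflicting:
        statuses[t] = ObservationStatus.OBSERVED
    for t in excluded - conflicting:
        statuses[t] = ObservationStatus.EXCLUDED
    return PropagationResult(statuses=statuses, conflicting=conflicting)
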