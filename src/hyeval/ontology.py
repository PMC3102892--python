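"""Ontology terms and subsumption reasoning.

Biological facts and scoring rules in this package refer to entities through
compact identifiers (CURIEs) drawn from public ontologies — GO for cellular
locations and molecular functions, ChEBI and SO for participant types, ECO
for evidence codes.  A :class:`TermStore` holds the excerpt of those
ontologies a knowledge base needs and answers the one inference the engine
depends on: reflexive-transitive *is-a* subsumption, so that a rule or query
asking for "RNA" also accepts an entity typed "messenger RNA".

Parthood (*part-of*) edges are stored under a separate label and queried via
:func:`has_part_transitive`; they never participate in ``is_a``, because
mixing the two edge semantics would silently change rule outcomes.

Two input dialects are supported by :func:`load_terms`:

* a 3-column TSV — ``id<TAB>label<TAB>parents`` with pipe-separated parent
  CURIEs (an optional 4th column carries pipe-separated part-of parents);
* N-Triples with ``rdfs:subClassOf`` edges (and optionally ``rdfs:label``
  and the local ``hq:partOf`` predicate).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import rdflib

from .errors import DataError

__all__ = [
    "OntologyTerm",
    "TermStore",
    "load_terms",
    "is_a",
    "has_part_transitive",
    "normalize_curie",
    "expand_curie",
    "contract_iri",
    "default_prefix_map",
]

_HQ_PART_OF = "http://example.org/hq/vocab#partOf"


def default_prefix_map() -> dict[str, str]:
    """Return the shipped prefix → namespace-IRI map (sgd, chebi, go, ...)."""
    text = resources.files("hyeval.data").joinpath("prefixes.json").read_text()
    return json.loads(text)


def normalize_curie(curie: str) -> str:
    """Normalize a CURIE: lower-case the prefix, keep the local part intact.

    Local parts are case-significant in Bio2RDF-style identifiers, prefixes
    are not.  Raises :class:`DataError` for strings that are not
    ``prefix:local`` shaped.
    """
    curie = curie.strip()
    prefix, sep, local = curie.partition(":")
    if not sep or not prefix or not local:
        raise DataError(f"not a CURIE: {curie!r}")
    return prefix.lower() + ":" + local


def expand_curie(curie: str, prefix_map: Mapping[str, str]) -> str:
    prefix, _, local = normalize_curie(curie).partition(":")
    try:
        return prefix_map[prefix] + local
    except KeyError:
        raise DataError(f"unknown CURIE prefix {prefix!r} in {curie!r}") from None


def contract_iri(iri: str, prefix_map: Mapping[str, str]) -> str | None:
    """Contract an IRI back to a CURIE, preferring the longest namespace."""
    best: tuple[int, str] | None = None
    for prefix, ns in prefix_map.items():
        if iri.startswith(ns) and len(iri) > len(ns):
            if best is None or len(ns) > best[0]:
                best = (len(ns), prefix + ":" + iri[len(ns):])
    return best[1] if best else None


@dataclass
class OntologyTerm:
    """One ontology class: a CURIE, a human label, and its parent edges."""

    id: str
    label: str = ""
    parents: tuple[str, ...] = ()
    part_of: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.id = normalize_curie(self.id)
        self.parents = tuple(normalize_curie(p) for p in self.parents)
        self.part_of = tuple(normalize_curie(p) for p in self.part_of)


class TermStore:
    """Ontology terms indexed by CURIE, with cached transitive closures.

    The parent (is-a) relation over all terms must form a DAG; this is
    checked eagerly by :func:`load_terms` and can be re-checked with
    :meth:`validate_dag` after programmatic mutation.
    """

    def __init__(self, prefix_map: Mapping[str, str] | None = None) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        self.prefix_map: dict[str, str] = dict(prefix_map or default_prefix_map())
        self._closure: dict[tuple[str, str], frozenset[str]] = {}

    # -- construction -------------------------------------------------

    def add(self, term: OntologyTerm) -> None:
        if term.id in self.terms:
            raise DataError(f"duplicate ontology term id {term.id!r}")
        self.terms[term.id] = term
        self._closure.clear()

    def ensure(self, curie: str, label: str = "") -> OntologyTerm:
        """Return the term for ``curie``, auto-creating a bare root if absent.

        Ontology excerpts are routinely partial; referenced-but-undefined
        terms become parentless roots rather than hard errors.
        """
        curie = normalize_curie(curie)
        if curie not in self.terms:
            self.terms[curie] = OntologyTerm(curie, label)
            self._closure.clear()
        return self.terms[curie]

    # -- lookup --------------------------------------------------------

    def __contains__(self, curie: str) -> bool:
        try:
            return normalize_curie(curie) in self.terms
        except DataError:
            return False

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, curie: str) -> OntologyTerm:
        curie = normalize_curie(curie)
        try:
            return self.terms[curie]
        except KeyError:
            raise DataError(f"unresolvable CURIE {curie!r}") from None

    # -- reasoning -----------------------------------------------------

    def _ancestors(self, curie: str, rel: str) -> frozenset[str]:
        key = (rel, curie)
        cached = self._closure.get(key)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = [curie]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            term = self.terms.get(cur)
            if term is not None:
                stack.extend(getattr(term, rel))
        result = frozenset(seen)
        self._closure[key] = result
        return result

    def is_a(self, term: str, ancestor: str) -> bool:
        """Reflexive-transitive subsumption along is-a parent edges."""
        term = self.resolve(term).id
        ancestor = self.resolve(ancestor).id
        return ancestor in self._ancestors(term, "parents")

    def has_part_transitive(self, whole: str, part: str) -> bool:
        """True iff ``part`` reaches ``whole`` along part-of edges (reflexive)."""
        whole = self.resolve(whole).id
        part = self.resolve(part).id
        return whole in self._ancestors(part, "part_of")

    def validate_dag(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                g.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DataError(f"is-a cycle in ontology involving {cycle[0][0]!r}")

    # -- serialization ---------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["id\tlabel\tparents\tpart_of"]
        for tid in sorted(self.terms):
            t = self.terms[tid]
            lines.append(
                f"{t.id}\t{t.label}\t{'|'.join(t.parents)}\t{'|'.join(t.part_of)}"
            )
        return "\n".join(lines) + "\n"


def _load_terms_tsv(text: str, store: TermStore) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if lineno == 1 and cols[0].strip().lower() == "id":
            continue  # header row
        if len(cols) < 1 or not cols[0].strip():
            raise DataError(f"ontology TSV line {lineno}: missing term id")
        tid = cols[0]
        label = cols[1].strip() if len(cols) > 1 else ""
        parents = [p for p in (cols[2].split("|") if len(cols) > 2 else []) if p.strip()]
        part_of = [p for p in (cols[3].split("|") if len(cols) > 3 else []) if p.strip()]
        store.add(OntologyTerm(tid, label, tuple(parents), tuple(part_of)))


def _load_terms_ntriples(text: str, store: TermStore) -> None:
    graph = rdflib.Graph()
    graph.parse(data=text, format="nt")
    pm = store.prefix_map
    parents: dict[str, list[str]] = {}
    part_of: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    subjects: list[str] = []

    def curie(node: rdflib.term.Node) -> str | None:
        if isinstance(node, rdflib.URIRef):
            return contract_iri(str(node), pm)
        return None

    for s, p, o in graph:
        sc = curie(s)
        if sc is None:
            continue
        if sc not in parents:
            parents[sc] = []
            part_of[sc] = []
            subjects.append(sc)
        if p == rdflib.RDFS.subClassOf:
            oc = curie(o)
            if oc is not None:
                parents[sc].append(oc)
        elif str(p) == _HQ_PART_OF:
            oc = curie(o)
            if oc is not None:
                part_of[sc].append(oc)
        elif p == rdflib.RDFS.label and isinstance(o, rdflib.Literal):
            labels[sc] = str(o)
    for sc in subjects:
        store.add(
            OntologyTerm(
                sc,
                labels.get(sc, ""),
                tuple(sorted(parents[sc])),
                tuple(sorted(part_of[sc])),
            )
        )


def load_terms(
    source: str | Path | io.TextIOBase | Iterable[OntologyTerm],
    fmt: str | None = None,
    prefix_map: Mapping[str, str] | None = None,
) -> TermStore:
    """Load an ontology excerpt into a validated :class:`TermStore`.

    ``source`` may be a path to a ``.tsv``/``.nt`` file, a text stream, or
    an iterable of :class:`OntologyTerm`.  ``fmt`` (``"tsv"``/``"ntriples"``)
    overrides extension/content sniffing.  Parent CURIEs referenced but never
    defined are auto-created as bare roots with a warning.  A cycle in the
    is-a relation is a hard error naming one cycle member.
    """
    store = TermStore(prefix_map)
    if isinstance(source, (str, Path)) and Path(source).exists():
        text = Path(source).read_text()
        if fmt is None:
            fmt = "ntriples" if str(source).endswith(".nt") else "tsv"
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, str):
        text = source
    else:
        for term in source:
            store.add(term)
        text = None  # type: ignore[assignment]
    if text is not None:
        if fmt is None:
            fmt = "ntriples" if text.lstrip().startswith("<") else "tsv"
        if fmt == "ntriples":
            _load_terms_ntriples(text, store)
        elif fmt == "tsv":
            _load_terms_tsv(text, store)
        else:
            raise DataError(f"unknown ontology format {fmt!r}")

    dangling = sorted(
        {p for t in store.terms.values() for p in (*t.parents, *t.part_of)}
        - set(store.terms)
    )
    if dangling:
        warnings.warn(
            f"auto-created {len(dangling)} dangling ontology root(s): "
            + ", ".join(dangling),
            stacklevel=2,
        )
        for curie in dangling:
            store.ensure(curie)
    store.validate_dag()
    return store


def is_a(term: str, ancestor: str, store: TermStore) -> bool:
    """Functional form of :meth:`TermStore.is_a`."""
    return store.is_a(term, ancestor)


def has_part_transitive(whole: str, part: str, store: TermStore) -> bool:
    """Functional form of :meth:`TermStore.has_part_transitive`."""
    return store.has_part_transitive(whole, part)
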