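"""GO-term enrichment of methylation bins: true-path propagation and
Fisher/hypergeometric upper-tail tests.

Annotations are propagated to all ancestors over is_a and part_of edges
(the true-path rule), then each term with at least ``min_node`` annotated
universe genes is tested for over-representation in the study bin with the
upper-tail hypergeometric probability P(X >= k).  Raw p-values are reported
with fixed significance tiers (0.05 / 0.001 / 0.00001); no multiple-testing
correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of")
TIERS = (0.05, 0.001, 0.00001)


@dataclass
class OntologyGraph:
    """Acyclic term graph: parents over is_a/part_of, namespace per term."""

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    K: int  # universe genes annotated with term
    k: int  # study genes annotated with term
    n: int  # study size
    N: int  # universe size
    p_value: float
    study_fraction: float

    @property
    def tier(self) -> str:
        for t in TIERS[::-1]:
            if self.p_value < t:
                return f"p<{t:g}"
        return "ns"


def read_obo(path: str | Path) -> OntologyGraph:
    """Load an OBO ontology, keeping is_a and part_of edges.

    Obsolete terms are dropped; a cyclic graph is rejected.
    """
    graph = obonet.read_obo(str(path))  # skips obsolete stanzas by default
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key in RELATIONS:
            sub.add_edge(child, parent, key=key)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    parents = {
        node: frozenset(sub.successors(node)) for node in sub.nodes
    }
    namespace = {
        node: data.get("namespace", "") for node, data in sub.nodes(data=True)
    }
    return OntologyGraph(parents=parents, namespace=namespace)


def propagate(
    direct: Mapping[str, Iterable[str]], graph: OntologyGraph
) -> dict[str, frozenset[str]]:
    """True-path closure: each gene inherits all ancestors of its terms.

    Terms absent from the graph are logged and kept as direct-only
    annotations.
    """
    known = graph.terms
    unknown: set[str] = set()
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        closure: set[str] = set()
        for t in terms:
            closure.add(t)
            if t in known:
                closure |= graph.ancestors(t)
            else:
                unknown.add(t)
        out[gene] = frozenset(closure)
    if unknown:
        logger.warning("%d annotation term(s) not in ontology: kept direct-only", len(unknown))
    return out


def fisher_enrichment(
    study: Iterable[str],
    universe: Iterable[str],
    propagated: Mapping[str, frozenset[str]],
    min_node: int = 10,
    namespace: str | None = "biological_process",
    graph: OntologyGraph | None = None,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of each term in the study set.

    Terms annotated to fewer than ``min_node`` universe genes are skipped.
    When ``namespace`` and ``graph`` are both given, terms outside that
    namespace are skipped too.  Rows come back sorted by ascending p.
    """
    study_set = set(study)
    universe_set = set(universe)
    if not study_set <= universe_set:
        missing = sorted(study_set - universe_set)[:3]
        raise ValueError(f"study genes outside universe, e.g. {missing}")
    N = len(universe_set)
    n = len(study_set)
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe_set:
        for t in propagated.get(gene, ()):
            term_universe[t] = term_universe.get(t, 0) + 1
    for gene in study_set:
        for t in propagated.get(gene, ()):
            term_study[t] = term_study.get(t, 0) + 1
    rows: list[EnrichmentRow] = []
    for term, K in term_universe.items():
        if K < min_node:
            continue
        if namespace and graph is not None:
            if graph.namespace.get(term, "") not in ("", namespace):
                continue
        k = term_study.get(term, 0)
        # P(X >= k) under Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentRow(
                term=term,
                K=K,
                k=k,
                n=n,
                N=N,
                p_value=min(1.0, p),
                study_fraction=k / n if n else 0.0,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows


def read_gene2go_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO annotation table (gene_id TAB pipe-separated terms)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip()
            terms = set()
            if len(parts) > 1 and parts[1].strip():
                terms = {t.strip() for t in parts[1].split("|") if t.strip()}
            out[gene] = terms
    return out
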