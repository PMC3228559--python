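"""GO Biological Process enrichment with parent-exclusion counting.

Each gene's term set is first reduced to its most specific terms (once a
node is counted, all its ancestors are excluded), then each term is tested
for over-representation in the foreground against the reference with a
one-sided Fisher exact test, Bonferroni-corrected over the terms actually
tested. Only terms with more than ``min_hits`` foreground genes and a
corrected p below ``alpha`` are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
from scipy import stats

__all__ = [
    "GoAnnotation",
    "load_obo",
    "read_gene2terms",
    "most_specific_terms",
    "ancestors",
    "enrich",
    "EnrichmentRow",
]

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class GoAnnotation:
    """A GO DAG plus gene -> BP term assignments.

    ``dag`` edges point child -> parent; ``relations`` restricts which edge
    types count as ancestry (default is_a + part_of).
    """

    dag: nx.MultiDiGraph
    gene2terms: dict[str, set[str]]
    relations: frozenset[str] = DEFAULT_RELATIONS

    def __post_init__(self) -> None:
        sub = self._relation_view()
        if not nx.is_directed_acyclic_graph(sub):
            raise ValueError("GO graph has a cycle under the chosen relations")

    def _relation_view(self) -> nx.DiGraph:
        cached = getattr(self, "_view_cache", None)
        if cached is not None:
            return cached
        g = nx.DiGraph()
        g.add_nodes_from(self.dag.nodes)
        for u, v, k in self.dag.edges(keys=True):
            if k in self.relations:
                g.add_edge(u, v)
        object.__setattr__(self, "_view_cache", g)
        return g


def load_obo(path: str | Path) -> nx.MultiDiGraph:
    """Parse an OBO ontology into a child->parent multigraph."""
    import obonet

    return obonet.read_obo(str(path))


def read_gene2terms(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>term TSV (GAF-like minimal dialect)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "!")):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def ancestors(term: str, ann: GoAnnotation) -> set[str]:
    """All proper ancestors of a term under the annotation's relations."""
    sub = ann._relation_view()
    if term not in sub:
        return set()
    return set(nx.descendants(sub, term))  # edges point child->parent


def most_specific_terms(terms: set[str], ann: GoAnnotation) -> set[str]:
    """Drop every term that is a proper ancestor of another term in the set.

    Terms missing from the DAG are dropped with a warning.
    """
    import warnings

    sub = ann._relation_view()
    present = set()
    for t in terms:
        if t in sub:
            present.add(t)
        else:
            warnings.warn(f"term {t} not in ontology; dropped", stacklevel=2)
    anc: set[str] = set()
    for t in present:
        anc |= nx.descendants(sub, t)
    return present - anc


@dataclass
class EnrichmentRow:
    term: str
    name: str
    foreground_hits: int
    foreground_size: int
    reference_hits: int
    reference_size: int
    p_raw: float
    p_bonferroni: float


def enrich(
    foreground: set[str],
    reference: set[str],
    ann: GoAnnotation,
    min_hits: int = 5,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Over-representation of GO terms in foreground genes vs a reference.

    Requires foreground to be a subset of the reference. Per-gene term sets
    are reduced by parent exclusion before counting. The Fisher table per
    term is (fg with term, fg without, ref-only with, ref-only without); the
    Bonferroni multiplier is the number of terms with at least one
    foreground hit. Rows kept need foreground_hits > min_hits (strict) and
    corrected p < alpha, sorted by p.
    """
    if not foreground or not reference:
        raise ValueError("foreground and reference must be nonempty")
    if not foreground <= reference:
        raise ValueError("foreground must be a subset of the reference")

    reduced = {
        g: most_specific_terms(ts, ann)
        for g, ts in ann.gene2terms.items()
        if g in reference
    }
    fg_count: dict[str, int] = {}
    ref_count: dict[str, int] = {}
    for g, ts in reduced.items():
        for t in ts:
            ref_count[t] = ref_count.get(t, 0) + 1
            if g in foreground:
                fg_count[t] = fg_count.get(t, 0) + 1

    n_fg = len(foreground)
    n_ref = len(reference)
    tested = sorted(fg_count)
    rows = []
    for t in tested:
        a = fg_count[t]
        b = n_fg - a
        c = ref_count[t] - a
        d = (n_ref - n_fg) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            EnrichmentRow(
                term=t,
                name=str(ann.dag.nodes[t].get("name", "")) if t in ann.dag else "",
                foreground_hits=a,
                foreground_size=n_fg,
                reference_hits=ref_count[t],
                reference_size=n_ref,
                p_raw=float(p),
                p_bonferroni=min(1.0, float(p) * len(tested)),
            )
        )
    kept = [r for r in rows if r.foreground_hits > min_hits and r.p_bonferroni < alpha]
    kept.sort(key=lambda r: (r.p_raw, r.term))
    return kept
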