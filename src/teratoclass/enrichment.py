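"""Gene-set comparison and over-representation analysis.

Three layers sit on top of the per-condition differential-expression
tables:

* a Venn partition of the SPS universe into probe sets deregulated only by
  teratogens, only by non-teratogens, or by both;
* a two-level ranking of the probe sets in a partition cell — first by the
  number of compounds that deregulated the probe set, then by the mean
  (absolute) log2 fold change — collapsed to one row per gene;
* over-representation tests: one-sided Fisher (hypergeometric tail) per
  ontology term or pathway, with a topology-aware *elim* variant that walks
  the is-a DAG bottom-up and removes the study genes of already-significant
  child terms from their ancestors' contingency tables, so that generic
  parent terms are not carried by their specific children.

The ontology container is a thin wrapper over a ``networkx`` DiGraph with
child → parent is-a edges, direct gene annotations, and ancestor-propagated
annotation sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust

__all__ = [
    "OntologyDAG",
    "GeneSetPartition",
    "venn_partition",
    "sps_sets_from_tables",
    "rank_top_genes",
    "fisher_overrep",
    "go_elim",
    "pathway_enrich",
]

DEFAULT_ELIM_CUTOFF = 0.01
#: probe-set suffixes retained by the high-specificity display filter
SPECIFIC_SUFFIXES = ("_at", "_a_at", "_s_at")
_SUFFIX_RE = re.compile(r"_(?:([a-z])_)?at$")


# ---------------------------------------------------------------------------
# ontology container
# ---------------------------------------------------------------------------

class OntologyDAG:
    """Acyclic single-root is-a hierarchy with term → gene annotations.

    Parameters
    ----------
    parents
        mapping term → iterable of parent terms (is-a edges).
    annotations
        mapping term → iterable of directly annotated genes.
    names
        optional mapping term → human-readable name.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        annotations: Mapping[str, Iterable[str]] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> None:
        graph = nx.DiGraph()
        for term, ps in parents.items():
            graph.add_node(term)
            for p in ps:
                graph.add_edge(term, p)  # child -> parent
        if graph.number_of_nodes() == 0:
            raise ValueError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology is-a graph contains a cycle: {cycle}")
        roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {sorted(roots)}")
        self.graph = graph
        self.root = roots[0]
        self.names = dict(names or {})
        self.direct_annotations: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for term, genes in (annotations or {}).items():
            if term not in self.direct_annotations:
                raise ValueError(f"annotation references unknown term {term!r}")
            self.direct_annotations[term].update(genes)
        self._propagated: dict[str, set[str]] | None = None

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)  # along child->parent edges

    def reverse_topological_order(self) -> list[str]:
        """Terms ordered children before parents (root last)."""
        return list(nx.topological_sort(self.graph))

    def propagated_annotations(self) -> dict[str, set[str]]:
        """Annotation closure: a gene in a term belongs to all its ancestors."""
        if self._propagated is None:
            prop = {t: set(g) for t, g in self.direct_annotations.items()}
            for term in self.reverse_topological_order():
                for parent in self.graph.successors(term):
                    prop[parent].update(prop[term])
            self._propagated = prop
        return self._propagated

    def annotated_genes(self) -> set[str]:
        return set().union(*self.propagated_annotations().values())

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_obo(cls, path: str | Path, annotations_path: str | Path | None = None) -> "OntologyDAG":
        """Read an OBO(-subset) file (and optionally a gene↔term TSV)."""
        import obonet

        graph = obonet.read_obo(path)
        parents: dict[str, list[str]] = {}
        names: dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            parents[node] = list(graph.successors(node))  # obonet: child -> parent
            if "name" in data:
                names[node] = data["name"]
        ann = read_annotation_tsv(annotations_path) if annotations_path else None
        return cls(parents, annotations=ann, names=names)

    @classmethod
    def from_edgelist(
        cls,
        edges: Iterable[tuple[str, str]],
        annotations: Mapping[str, Iterable[str]] | None = None,
    ) -> "OntologyDAG":
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        return cls(parents, annotations=annotations)

    def write_obo(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.graph.nodes):
                fh.write("\n[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {self.names.get(term, term)}\n")
                for parent in sorted(self.graph.successors(term)):
                    fh.write(f"is_a: {parent}\n")

    def write_annotation_tsv(self, path: str | Path) -> None:
        rows = [
            (gene, term)
            for term, genes in sorted(self.direct_annotations.items())
            for gene in sorted(genes)
        ]
        pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column gene↔term TSV into term → gene sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation file {path!s} needs two columns (gene, term)")
    gene_col, term_col = df.columns[:2]
    ann: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        ann.setdefault(term, set()).add(gene)
    return ann


# ---------------------------------------------------------------------------
# Venn partition and top genes
# ---------------------------------------------------------------------------

@dataclass
class GeneSetPartition:
    """Disjoint split of the SPS universe by compound class."""

    teratogen_only: set[str]
    non_teratogen_only: set[str]
    overlap: set[str]
    direction: str = "all"

    @property
    def teratogen_union(self) -> set[str]:
        return self.teratogen_only | self.overlap

    @property
    def non_teratogen_union(self) -> set[str]:
        return self.non_teratogen_only | self.overlap


def sps_sets_from_tables(
    tables: Mapping[str, pd.DataFrame], direction: str = "all"
) -> dict[str, set[str]]:
    """Per-compound SPS id sets from flagged differential-expression tables."""
    if direction not in ("all", "up", "down"):
        raise ValueError(f"direction must be all/up/down, got {direction!r}")
    out = {}
    for compound, table in tables.items():
        if direction == "all":
            mask = table["significant"].astype(bool)
        else:
            mask = table["direction"] == direction
        out[compound] = set(table.index[mask])
    return out


def venn_partition(
    sps_sets: Mapping[str, set[str]],
    labels: Mapping[str, str],
    direction: str = "all",
) -> GeneSetPartition:
    """Partition the union of per-compound SPS sets by compound class."""
    ter: set[str] = set()
    non: set[str] = set()
    seen_ter = seen_non = False
    for compound, sps in sps_sets.items():
        label = labels[compound]
        if label == "teratogen":
            ter |= sps
            seen_ter = True
        else:
            non |= sps
            seen_non = True
    if not (seen_ter and seen_non):
        raise ValueError("need at least one compound of each class")
    return GeneSetPartition(
        teratogen_only=ter - non,
        non_teratogen_only=non - ter,
        overlap=ter & non,
        direction=direction,
    )


def has_specific_suffix(probe_id: str) -> bool:
    """True for the high-specificity suffixes ``_at``, ``_a_at``, ``_s_at``."""
    m = _SUFFIX_RE.search(probe_id)
    if m is None:
        return False
    qualifier = m.group(1)
    return qualifier in (None, "a", "s")


def rank_top_genes(
    cell: Iterable[str],
    tables: Mapping[str, pd.DataFrame],
    probe_to_gene: Mapping[str, str],
    variant: str = "all",
    suffix_filter: bool = False,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Two-level ranking of a partition cell, collapsed to one row per gene.

    Level 1: number of compounds in which the probe set is significant
    (restricted to the direction ``variant``); level 2: mean log2 fold
    change across those compounds (mean of |log2fc| when ``variant="all"``).
    Only the highest-ranked probe set of each gene is kept.  Probe sets with
    no gene mapping are retained under their own id and flagged.
    """
    if variant not in ("all", "up", "down"):
        raise ValueError(f"variant must be all/up/down, got {variant!r}")
    rows = []
    for probe in cell:
        if suffix_filter and not has_specific_suffix(probe):
            continue
        lfcs = []
        for table in tables.values():
            if probe not in table.index:
                continue
            row = table.loc[probe]
            if variant == "all":
                hit = bool(row["significant"])
            else:
                hit = row["direction"] == variant
            if hit:
                lfcs.append(abs(row["log2fc"]) if variant == "all" else row["log2fc"])
        if not lfcs:
            continue
        gene = probe_to_gene.get(probe)
        rows.append(
            {
                "probe_id": probe,
                "gene_id": gene if gene is not None else probe,
                "unmapped": gene is None,
                "n_compounds": len(lfcs),
                "mean_log2fc": float(np.mean(lfcs)),
            }
        )
    ranked = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "unmapped", "n_compounds", "mean_log2fc"]
    )
    if ranked.empty:
        return ranked
    ranked = ranked.sort_values(
        ["n_compounds", "mean_log2fc", "probe_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    ranked = ranked.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def fisher_overrep(
    study_genes: Iterable[str], universe_genes: Iterable[str], term_genes: Iterable[str]
) -> float:
    """One-sided over-representation p-value (hypergeometric upper tail)."""
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    study = set(study_genes) & universe
    term = set(term_genes) & universe
    k = len(study & term)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, len(universe), len(term), len(study)))


def go_elim(
    dag: OntologyDAG,
    study_genes: Iterable[str],
    universe_genes: Iterable[str],
    elim_cutoff: float = DEFAULT_ELIM_CUTOFF,
    method: str = "elim",
) -> pd.DataFrame:
    """Per-term over-representation with bottom-up elimination.

    Terms are tested children-before-parents; when a term's raw p-value
    falls below ``elim_cutoff``, its study genes are removed from the
    annotation sets of all its ancestors before those are tested
    (``method="classic"`` or ``elim_cutoff=0`` disables elimination and
    reduces to a flat Fisher test per term).  P-values are BH-adjusted
    across terms; ``significant`` flags adjusted p < 0.05.
    """
    if method not in ("elim", "classic"):
        raise ValueError(f"method must be 'elim' or 'classic', got {method!r}")
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    study = set(study_genes) & universe
    prop = dag.propagated_annotations()
    removed: dict[str, set[str]] = {t: set() for t in dag.terms}
    rows = []
    for term in dag.reverse_topological_order():
        ann = (prop[term] & universe) - removed[term]
        k = len(study & ann)
        p = float(hypergeom.sf(k - 1, len(universe), len(ann), len(study))) if k else 1.0
        rows.append(
            {
                "term_id": term,
                "name": dag.names.get(term, term),
                "annotated": len(ann),
                "count": k,
                "hits_percent": 100.0 * k / len(ann) if ann else 0.0,
                "p_raw": p,
            }
        )
        if method == "elim" and p < elim_cutoff:
            confiscated = study & ann
            for ancestor in dag.ancestors(term):
                removed[ancestor] |= confiscated
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_fdr"] < 0.05
    return out.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)


def pathway_enrich(
    study_genes: Iterable[str],
    universe_genes: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Flat Fisher over-representation per pathway.

    ``gene_ratio`` is the fraction of study genes in the pathway relative to
    the study genes mapping to *any* pathway (study genes without a pathway
    assignment do not enter the denominator).
    """
    if not pathway_map:
        raise ValueError("empty pathway map")
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    study = set(study_genes) & universe
    mapped_study = study & set().union(*(set(g) for g in pathway_map.values()))
    rows = []
    for pathway, genes in pathway_map.items():
        genes = set(genes) & universe
        k = len(study & genes)
        p = float(hypergeom.sf(k - 1, len(universe), len(genes), len(study))) if k else 1.0
        rows.append(
            {
                "pathway_id": pathway,
                "annotated": len(genes),
                "count": k,
                "gene_ratio": k / len(mapped_study) if mapped_study else 0.0,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_fdr"] < 0.05
    return out.sort_values(["p_raw", "pathway_id"], kind="mergesort").reset_index(drop=True)
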