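"""Biological priors as genomic features.

A genomic feature is a named group of genes (a GO term with its annotations
up-propagated along the ontology, a co-expression cluster, or a curated
list) translated into the set of markers falling inside the genes' ORF
intervals. Marker membership is positional: chromosome match and
orf_start <= pos <= orf_end (1-based, inclusive on both ends); strand is
ignored. A feature may map to zero markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import OntologyError, ParseError

logger = logging.getLogger(__name__)

#: ontology relations that are traversed during up-propagation
PROPAGATED_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class GeneModel:
    """A gene's ORF interval (1-based, inclusive)."""

    gene_id: str
    chrom: str
    orf_start: int
    orf_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.orf_start > self.orf_end:
            raise ValueError(
                f"gene {self.gene_id}: orf_start > orf_end "
                f"({self.orf_start} > {self.orf_end})"
            )


@dataclass
class FeatureSet:
    """A named gene group with its derived marker-index set."""

    feature_id: str
    source: str  # GO-BP | GO-MF | GO-CC | COEX | CUSTOM
    gene_ids: frozenset
    marker_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.gene_ids = frozenset(self.gene_ids)
        self.marker_indices = np.unique(
            np.asarray(self.marker_indices, dtype=np.int64)
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)


@dataclass
class OntologyDAG:
    """Term graph with child -> parent edges and direct gene annotations."""

    graph: nx.DiGraph  # edge child -> parent
    annotations: dict  # term -> set of gene ids
    namespaces: dict = field(default_factory=dict)  # term -> sub-ontology

    @property
    def terms(self):
        return set(self.graph.nodes)


def load_ontology(obo_path: str) -> OntologyDAG:
    """Read an OBO file, keeping is_a and part_of edges (child -> parent)."""
    import obonet

    raw = obonet.read_obo(obo_path)
    g = nx.DiGraph()
    namespaces = {}
    for term, data in raw.nodes(data=True):
        g.add_node(term)
        ns = data.get("namespace")
        if ns:
            namespaces[term] = ns
    for child, parent, key in raw.edges(keys=True):
        if key in PROPAGATED_RELATIONS:
            g.add_edge(child, parent)
    return OntologyDAG(g, annotations={}, namespaces=namespaces)


def load_annotations(dag: OntologyDAG, path: str) -> OntologyDAG:
    """Attach gene -> term annotations from a GAF-like TSV.

    Columns: gene id, term id, optional evidence code (ignored). Terms not
    present in the ontology are added as isolated nodes.
    """
    annotations: dict = {t: set(s) for t, s in dag.annotations.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"annotation line needs >= 2 columns: {line!r}")
            gene, term = parts[0], parts[1]
            if term not in dag.graph:
                dag.graph.add_node(term)
            annotations.setdefault(term, set()).add(gene)
    return OntologyDAG(dag.graph, annotations, dag.namespaces)


def up_propagate(dag: OntologyDAG) -> dict:
    """Map each term to the union of annotations of itself and all descendants.

    Children are processed before parents (edges point child -> parent), so
    each term's set accumulates every gene annotated at or below it. The
    operation is idempotent: re-running on the propagated sets is a no-op.
    """
    try:
        order = list(nx.topological_sort(dag.graph))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(dag.graph)
        raise OntologyError(f"ontology contains a cycle through edge {cycle[0]}")
    full: dict = {t: set(dag.annotations.get(t, ())) for t in dag.graph.nodes}
    for term in order:  # children first
        for parent in dag.graph.successors(term):
            full[parent] |= full[term]
    return full


def map_genes_to_markers(genes, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Marker indices falling inside any of the genes' ORF intervals.

    ``chrom``/``pos`` form the marker map, sorted by (chrom, pos). A marker
    belongs to a gene iff the chromosome matches and
    orf_start <= pos <= orf_end; the union over genes is returned.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    by_chrom: dict = {}
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        by_chrom[c] = (idx, pos[idx])
    hits: list[np.ndarray] = []
    for gene in genes:
        entry = by_chrom.get(gene.chrom)
        if entry is None:
            continue
        idx, p = entry
        lo = np.searchsorted(p, gene.orf_start, side="left")
        hi = np.searchsorted(p, gene.orf_end, side="right")
        if hi > lo:
            hits.append(idx[lo:hi])
    if not hits:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(hits))


def build_feature_set(
    feature_id: str,
    gene_ids,
    gene_models: dict,
    chrom: np.ndarray,
    pos: np.ndarray,
    source: str = "CUSTOM",
) -> FeatureSet:
    """Assemble a FeatureSet, warning about gene ids without a gene model."""
    gene_ids = frozenset(gene_ids)
    known = [gene_models[g] for g in gene_ids if g in gene_models]
    n_unknown = len(gene_ids) - len(known)
    if n_unknown:
        logger.warning(
            "feature %s: %d gene id(s) not in the gene models contribute no markers",
            feature_id, n_unknown,
        )
    markers = map_genes_to_markers(known, chrom, pos)
    return FeatureSet(feature_id, source, gene_ids, markers)


def load_custom_gene_list(
    path: str,
    gene_models: dict | None = None,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> list:
    """Read gene sets from a GMT file or a plain one-id-per-line list.

    Duplicate ids are removed; unknown ids stay in ``gene_ids`` but map to
    no markers (with a warning). An empty file yields an empty list with a
    warning, not an error.
    """
    sets: list[tuple[str, list]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("gene list %s is empty", path)
        return []
    if any("\t" in ln for ln in lines):  # GMT: name, description, genes...
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ParseError(f"GMT row needs >= 3 columns: {ln!r}")
            sets.append((parts[0], parts[2:]))
    else:
        sets.append((path.rsplit("/", 1)[-1], lines))

    out = []
    for name, genes in sets:
        if gene_models is not None and chrom is not None and pos is not None:
            out.append(
                build_feature_set(name, genes, gene_models, chrom, pos, "CUSTOM")
            )
        else:
            out.append(FeatureSet(name, "CUSTOM", frozenset(genes)))
    return out


def features_from_ontology(
    dag: OntologyDAG,
    gene_models: dict,
    chrom: np.ndarray,
    pos: np.ndarray,
    min_genes: int = 1,
) -> list:
    """One FeatureSet per ontology term, after up-propagation."""
    propagated = up_propagate(dag)
    ns_to_source = {
        "biological_process": "GO-BP",
        "molecular_function": "GO-MF",
        "cellular_component": "GO-CC",
    }
    out = []
    for term, genes in propagated.items():
        if len(genes) < min_genes:
            continue
        source = ns_to_source.get(dag.namespaces.get(term, ""), "GO-BP")
        out.append(
            build_feature_set(term, genes, gene_models, chrom, pos, source)
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 / GMT IO
# ---------------------------------------------------------------------------

def load_gene_models(gff_path: str, feature_type: str = "gene") -> dict:
    """Read gene models from GFF3 (1-based, inclusive coordinates).

    Multiple records for one gene id (isoforms) are merged into the union
    interval. Returns {gene_id: GeneModel}.
    """
    intervals: dict = {}
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"GFF3 line does not have 9 columns: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature_type:
                continue
            gene_id = None
            for kv in attrs.split(";"):
                k, _, v = kv.partition("=")
                if k.strip() == "ID":
                    gene_id = v.strip()
                    break
            if gene_id is None:
                raise ParseError(f"GFF3 record without ID attribute: {line!r}")
            s, e = int(start), int(end)
            if gene_id in intervals:
                prev = intervals[gene_id]
                if prev.chrom != seqid:
                    raise ParseError(
                        f"gene {gene_id} spans chromosomes {prev.chrom}/{seqid}"
                    )
                s, e = min(prev.orf_start, s), max(prev.orf_end, e)
                strand = prev.strand
            intervals[gene_id] = GeneModel(gene_id, seqid, s, e, strand)
    return intervals


def write_gmt(features, path: str) -> None:
    with open(path, "w") as fh:
        for f in features:
            genes = "\t".join(sorted(f.gene_ids))
            fh.write(f"{f.feature_id}\t{f.source}\t{genes}\n")
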