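"""Core record types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based, half-open.  Conversions to and from the
1-based inclusive convention (GFF3) and the strand-relative convention (MAF
``s`` lines) happen only at file boundaries.  Minus-strand alignment rows are
normalised to forward-strand intervals with the strand recorded, so downstream
overlap arithmetic never has to branch on orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "GenomicInterval",
    "MultiAlignmentBlock",
    "GeneModel",
    "HomologyHit",
    "ExpressionMatrix",
    "PhyloOrder",
    "AnnotationSet",
    "read_maf",
    "write_maf",
    "read_gene_models",
    "write_gene_models_gff3",
    "write_gene_models_bed",
    "read_obo",
    "read_annotation_table",
    "write_annotation_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_homology_table",
    "write_homology_table",
    "read_phylo_order",
    "write_phylo_order",
]


class MafParseError(ValueError):
    """Raised when a MAF paragraph cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome or scaffold."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 if on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class MultiAlignmentBlock:
    """One aligned block: a per-species row with its (forward-strand) interval.

    ``rows`` maps species name to ``(interval, aligned_text_or_None)``.  The
    reference species must be present; its projection is what anchor
    extraction uses.
    """

    rows: dict[str, tuple[GenomicInterval, str | None]]
    reference_species: str

    def __post_init__(self) -> None:
        if self.reference_species not in self.rows:
            raise ValueError(
                f"reference species {self.reference_species!r} missing from block rows"
            )

    @property
    def species(self) -> set[str]:
        return set(self.rows)

    @property
    def reference_interval(self) -> GenomicInterval:
        return self.rows[self.reference_species][0]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene used as a genomic marker.

    ``rank`` is the ordinal position of the gene along its chromosome
    (1-based, by start coordinate); collinearity chaining works on ranks,
    not base coordinates.
    """

    gene_id: str
    species: str
    interval: GenomicInterval
    rank: int


@dataclass(frozen=True)
class HomologyHit:
    """One row of an all-vs-all protein similarity search (outfmt-6 subset)."""

    query_gene: str
    subject_gene: str
    e_value: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")


class ExpressionMatrix:
    """A genes x tissues matrix of FPKM values, backed by a DataFrame."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            bad = values.index[np.isnan(arr).any(axis=1)].tolist()
            raise ValueError(f"non-numeric or missing expression values for genes {bad}")
        if (arr < 0).any():
            bad = values.index[(arr < 0).any(axis=1)].tolist()
            raise ValueError(f"negative FPKM values for genes {bad}")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy()

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index


@dataclass
class PhyloOrder:
    """Species listed by increasing divergence from the reference.

    The reference comes first and carries no index; every other species gets
    the divergence index d = 2, 3, ... in list order, mirroring how pairwise
    collinear segments are labelled 2way-d.
    """

    species: list[str]

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("phylo order needs a reference plus at least one species")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in phylo order")

    @property
    def reference(self) -> str:
        return self.species[0]

    @property
    def d_index(self) -> dict[str, int]:
        return {sp: d for d, sp in enumerate(self.species[1:], start=2)}

    def __len__(self) -> int:
        return len(self.species)


class AnnotationSet:
    """An annotation result as its (P, G, GO) triplet.

    P is the set of de-duplicated gene-term pairs; G and GO are the genes and
    terms P covers, always derived (never stored independently).  Provenance
    optionally records, per pair, the orthologs that contributed it.
    """

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]],
        provenance: Mapping[tuple[str, str], list[tuple[str, str, float]]] | None = None,
    ):
        self.pairs: frozenset[tuple[str, str]] = frozenset(pairs)
        self.provenance: dict[tuple[str, str], list[tuple[str, str, float]]] = (
            {k: list(v) for k, v in provenance.items()} if provenance else {}
        )
        extra = set(self.provenance) - set(self.pairs)
        if extra:
            raise ValueError(f"provenance keys not in P: {sorted(extra)[:5]}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def terms_of(self, gene: str) -> frozenset[str]:
        return frozenset(t for g, t in self.pairs if g == gene)

    def genes_of(self, term: str) -> frozenset[str]:
        return frozenset(g for g, t in self.pairs if t == term)

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(self.pairs)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    """Split a MAF ``src`` field 'species.chrom' at the first dot."""
    if "." in src:
        sp, chrom = src.split(".", 1)
    else:
        sp, chrom = src, src
    return sp, chrom


def read_maf(path: str | Path, reference_species: str | None = None) -> list[MultiAlignmentBlock]:
    """Parse a MULTIZ-dialect MAF file into alignment blocks.

    ``s`` line coordinates are strand-relative with an explicit size; they are
    converted to forward-strand half-open intervals here (for a minus-strand
    row, forward start = srcSize - start - size).  If ``reference_species`` is
    None, the species of the first ``s`` row of the first block is used, which
    matches MULTIZ output where the reference row always comes first.
    """
    blocks: list[MultiAlignmentBlock] = []
    rows: dict[str, tuple[GenomicInterval, str | None]] = {}
    first_species: str | None = None
    in_block = False

    def flush() -> None:
        nonlocal rows, in_block
        if in_block and rows:
            ref = reference_species or first_species
            blocks.append(MultiAlignmentBlock(rows=rows, reference_species=ref))
        rows = {}
        in_block = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("a"):
                flush()
                in_block = True
            elif line.startswith("s"):
                parts = line.split()
                if len(parts) < 6:
                    raise MafParseError(f"malformed s-line at line {lineno}: {line!r}")
                try:
                    start, size, srcsize = int(parts[2]), int(parts[3]), int(parts[5])
                except ValueError as exc:
                    raise MafParseError(
                        f"malformed s-line at line {lineno}: {line!r}"
                    ) from exc
                strand = parts[4]
                if strand not in ("+", "-") or size < 1:
                    raise MafParseError(f"malformed s-line at line {lineno}: {line!r}")
                text = parts[6] if len(parts) > 6 else None
                sp, chrom = _split_src(parts[1])
                fwd_start = start if strand == "+" else srcsize - start - size
                interval = GenomicInterval(chrom, fwd_start, fwd_start + size, strand)
                if first_species is None:
                    first_species = sp
                rows[sp] = (interval, text)
    flush()
    return blocks


def write_maf(blocks: Sequence[MultiAlignmentBlock], path: str | Path) -> None:
    """Write blocks as MAF with a srcSize equal to the interval end.

    Forward-strand intervals are emitted directly; minus-strand intervals are
    re-expressed in the strand-relative convention (start counted from the
    source end), so read_maf(write_maf(blocks)) reproduces intervals and
    strands exactly.
    """
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            ref = block.reference_species
            order = [ref] + sorted(sp for sp in block.rows if sp != ref)
            for sp in order:
                iv, text = block.rows[sp]
                srcsize = iv.end
                start = iv.start if iv.strand == "+" else srcsize - iv.end
                fh.write(
                    f"s {sp}.{iv.chrom} {start} {iv.length} {iv.strand} {srcsize} "
                    f"{text if text is not None else '*'}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 / BED6)
# ---------------------------------------------------------------------------

def _assign_ranks(raw: list[tuple[str, str, int, int, str]], species: str) -> list[GeneModel]:
    ids = [g for g, *_ in raw]
    seen: set[str] = set()
    dups = sorted({g for g in ids if g in seen or seen.add(g)})
    if dups:
        raise ValueError(f"duplicate gene ids in {species}: {dups}")
    by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
    for rec in raw:
        by_chrom.setdefault(rec[1], []).append(rec)
    out: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r[2], r[3], r[0]))
        for rank, (gid, chrom_, start, end, strand) in enumerate(recs, start=1):
            out.append(
                GeneModel(gid, species, GenomicInterval(chrom_, start, end, strand), rank)
            )
    return out


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | Path, species: str, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 ('gene'-type rows) or BED6.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Ranks are assigned per chromosome by start order.
    """
    raw: list[tuple[str, str, int, int, str]] = []
    if format == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9 or cols[2] != "gene":
                    continue
                attrs = _parse_gff3_attributes(cols[8])
                gid = attrs.get("ID") or attrs.get("Name")
                if gid is None:
                    raise ValueError(f"gene row without ID attribute: {line!r}")
                raw.append((gid, cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]))
    elif format == "bed":
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                strand = cols[5] if len(cols) > 5 else "+"
                raw.append((cols[3], cols[0], int(cols[1]), int(cols[2]), strand))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return _assign_ranks(raw, species)


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tsynortho\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


def write_gene_models_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# OBO
# ---------------------------------------------------------------------------

def read_obo(path: str | Path):
    """Read an OBO 1.2 ontology into an OntologyDag (is_a / part_of edges only)."""
    from .ontology_compare import OntologyDag

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    dag = nx.DiGraph()
    for term, data in graph.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            continue
        dag.add_node(term, namespace=data.get("namespace", ""), name=data.get("name", ""))
    for child, parent, key in graph.edges(keys=True):
        if key in ("is_a", "part_of") and child in dag and parent in dag:
            dag.add_edge(child, parent, relation=key)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return OntologyDag(dag)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path, dag=None) -> AnnotationSet:
    """Read a (gene, term[, evidence]) TSV into an AnnotationSet.

    Duplicate rows are de-duplicated; if a DAG is supplied, pairs whose term
    is absent from it trigger a warning but are retained.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation table needs >= 2 columns, got {df.shape[1]}")
    pairs = {(g, t) for g, t in zip(df[0], df[1])}
    if dag is not None:
        missing = sorted({t for _, t in pairs if t not in dag})
        if missing:
            warnings.warn(f"terms absent from ontology: {missing}", stacklevel=2)
    return AnnotationSet(pairs)


def write_annotation_table(annset: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, t in sorted(annset.pairs):
            fh.write(f"{g}\t{t}\n")


def read_gaf(path: str | Path) -> AnnotationSet:
    """Read the gene-term projection of a GAF file (columns 2 and 5)."""
    pairs = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 5:
                pairs.add((cols[1], cols[4]))
    return AnnotationSet(pairs)


# ---------------------------------------------------------------------------
# Expression and homology tables
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x tissues FPKM TSV (header row = tissue names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    widths = {len(line.rstrip("\n").split("\t")) for line in open(path) if line.strip()}
    if len(widths) > 1:
        raise ValueError(f"ragged expression table: row widths {sorted(widths)}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression values: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_homology_table(path: str | Path) -> list[HomologyHit]:
    """Read a BLAST outfmt-6 TSV into HomologyHit records."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(_OUTFMT6_COLS):
        raise ValueError(
            f"expected {len(_OUTFMT6_COLS)} outfmt-6 columns, got {df.shape[1]}"
        )
    df.columns = _OUTFMT6_COLS
    return [
        HomologyHit(str(r.qseqid), str(r.sseqid), float(r.evalue), float(r.bitscore))
        for r in df.itertuples()
    ]


def write_homology_table(hits: Sequence[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t100.0\t100\t0\t0\t1\t100\t1\t100\t"
                f"{h.e_value:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# Phylogenetic species order
# ---------------------------------------------------------------------------

def read_phylo_order(path: str | Path) -> PhyloOrder:
    """Read a plain-text species list, reference first, divergence order after."""
    species = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                species.append(line)
    return PhyloOrder(species)


def write_phylo_order(order: PhyloOrder, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in order.species:
            fh.write(sp + "\n")
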