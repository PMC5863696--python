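"""Seeded generator of a synthetic comparative-genomics world with known truth.

The generator emulates every input the pipeline consumes.  An ancestral
genome of ordered gene families is laid out on one chromosome; planted
collinear blocks (runs of consecutive families) are copied into each partner
species in phylogenetic order, with per-gene dropout, optional inversions and
translocations, and species-specific noise genes.  Divergence is modelled
ordinally: dropout and rearrangement probabilities grow with the species'
divergence index, so alignability decays along the order as it does between
real genomes.  Multiple-alignment blocks are emitted for evenly spaced
anchors inside each planted block (a configurable fraction conserved in all
species); homology hits cover true orthologs (strong scores) and decoy
paralogs (borderline scores, never best hits); a small layered ontology with
is_a/part_of edges carries per-family annotations, and an expression matrix
plants co-expressed modules for a subset of terms via a shared latent factor.

Every piece of planted structure is retained as truth, so recovery by the
detection, orthology, transfer and validation stages can be scored exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .formats_io import (
    AnnotationSet,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    HomologyHit,
    MultiAlignmentBlock,
    PhyloOrder,
    write_annotation_table,
    write_expression_matrix,
    write_gene_models_gff3,
    write_homology_table,
    write_maf,
    write_phylo_order,
)

import pandas as pd

__all__ = ["WorldConfig", "SyntheticWorld", "PlantedBlock", "generate_world", "write_world"]

SLOT = 1000  # bp per marker slot
GENE_LEN = 600


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for one synthetic world.

    The default world is small enough for the full pipeline to run in
    seconds: 5 species, 200 genes per genome, 7 planted blocks, mild noise.
    """

    n_species: int = 5
    genes_per_genome: int = 200
    n_planted_blocks: int = 7
    block_size_range: tuple[int, int] = (5, 12)
    inter_block_gap: int = 15  # background genes between blocks (> gap_size)
    noise_marker_rate: float = 0.1
    rearrangement_rate: float = 0.1
    ortholog_dropout_rate: float = 0.05
    decoy_rate: float = 0.1
    maa_per_block_range: tuple[int, int] = (3, 8)
    maa_conserved_fraction: float = 0.8
    background_maas_per_gap: int = 125
    n_terms: int = 30
    term_size_range: tuple[int, int] = (5, 15)
    n_coexpressed_terms: int = 10
    latent_factor_sd: float = 1.0
    noise_sd: float = 0.3
    n_tissues: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_marker_rate", "rearrangement_rate",
                     "ortholog_dropout_rate", "decoy_rate", "maa_conserved_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        lo, hi = self.block_size_range
        if not (2 <= lo <= hi):
            raise ValueError("block_size_range must satisfy 2 <= lo <= hi")
        need = self.n_planted_blocks * (hi + self.inter_block_gap)
        if need > self.genes_per_genome:
            raise ValueError(
                f"infeasible config: {self.n_planted_blocks} blocks of up to {hi} genes "
                f"with gaps of {self.inter_block_gap} exceed {self.genes_per_genome} slots"
            )


@dataclass
class PlantedBlock:
    """One planted collinear block and its realisation in a partner species."""

    block_id: int
    species: str
    pairs: list[tuple[str, str]]  # (reference gene, species gene) in reference order
    orientation: str  # "same" | "inverted"


@dataclass
class SyntheticWorld:
    config: WorldConfig
    order: PhyloOrder
    genes_by_species: dict[str, list[GeneModel]]
    alignment_blocks: list[MultiAlignmentBlock]
    hits: list[HomologyHit]
    truth_orthologs: set[tuple[str, str]]
    truth_decoys: set[tuple[str, str]]
    truth_blocks: list[PlantedBlock]
    ontology_edges: list[tuple[str, str, str]]  # (child, parent, relation)
    term_namespaces: dict[str, str]
    truth_annotations: dict[str, AnnotationSet]
    expression: ExpressionMatrix
    truth_coexpressed_terms: list[str]

    @property
    def reference(self) -> str:
        return self.order.reference

    def ontology(self):
        from .ontology_compare import OntologyDag

        return OntologyDag.from_edges(self.ontology_edges, self.term_namespaces)


def _species_names(n: int) -> list[str]:
    return [f"sp{i:02d}" for i in range(1, n + 1)]


def _slot_interval(slot: int, strand: str = "+") -> GenomicInterval:
    start = slot * SLOT + (SLOT - GENE_LEN) // 2
    return GenomicInterval("chr1", start, start + GENE_LEN, strand)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    rng = np.random.default_rng(config.seed)
    species = _species_names(config.n_species)
    order = PhyloOrder(species)
    ref = species[0]

    # --- reference layout: families 0..N-1 in order, blocks as family runs ---
    n_fam = config.genes_per_genome
    lo, hi = config.block_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_planted_blocks)]
    starts: list[int] = []
    cursor = int(rng.integers(0, config.inter_block_gap + 1))
    for size in sizes:
        starts.append(cursor)
        cursor += size + config.inter_block_gap
    if cursor - config.inter_block_gap > n_fam:
        raise ValueError("infeasible config: planted blocks exceed genome size")
    shift = int(rng.integers(0, n_fam - (cursor - config.inter_block_gap) + 1))
    starts = [s + shift for s in starts]
    block_families = [list(range(s, s + size)) for s, size in zip(starts, sizes)]
    in_block = {f: b for b, fams in enumerate(block_families) for f in fams}

    def ref_gene(fam: int) -> str:
        return f"{ref}_g{fam:04d}"

    genes_by_species: dict[str, list[GeneModel]] = {
        ref: [
            GeneModel(ref_gene(f), ref, _slot_interval(f), f + 1)
            for f in range(n_fam)
        ]
    }

    truth_orthologs: set[tuple[str, str]] = set()
    truth_blocks: list[PlantedBlock] = []
    # per species: block_id -> (slot range, orientation, retained families in slot order)
    block_layout: dict[str, dict[int, tuple[int, int, str, list[int]]]] = {ref: {}}
    for b, fams in enumerate(block_families):
        s0, s1 = fams[0], fams[-1]
        block_layout[ref][b] = (s0, s1, "same", list(fams))

    for d, sp in enumerate(order.species[1:], start=2):
        drop_p = min(0.5, config.ortholog_dropout_rate * (d - 1))
        rearr_p = min(0.9, config.rearrangement_rate * (d - 1) / (config.n_species - 1) * 2)
        # block order: ancestral, with translocations moving a block elsewhere
        block_order = list(range(config.n_planted_blocks))
        orientations = {}
        for b in range(config.n_planted_blocks):
            orientations[b] = "same"
            if rng.random() < rearr_p:
                if rng.random() < 0.5:
                    orientations[b] = "inverted"
                else:
                    block_order.remove(b)
                    block_order.insert(int(rng.integers(0, len(block_order) + 1)), b)
        genome: list[tuple[str, int | None]] = []  # (gene_id, family or None)
        filler_i = 0

        def filler() -> tuple[str, None]:
            nonlocal filler_i
            filler_i += 1
            return (f"{sp}_x{filler_i:04d}", None)

        layout: dict[int, tuple[int, int, str, list[int]]] = {}
        for k, b in enumerate(block_order):
            for _ in range(config.inter_block_gap):
                genome.append(filler())
            fams = list(block_families[b])
            fams = [f for f in fams if rng.random() >= drop_p]
            if orientations[b] == "inverted":
                fams = fams[::-1]
            slot_start = len(genome)
            for i, f in enumerate(fams):
                genome.append((f"{sp}_g{f:04d}", f))
                if i < len(fams) - 1 and rng.random() < config.noise_marker_rate:
                    genome.append(filler())
            layout[b] = (slot_start, len(genome) - 1, orientations[b],
                         fams if orientations[b] == "same" else fams[::-1])
        for _ in range(config.inter_block_gap):
            genome.append(filler())
        while len(genome) < config.genes_per_genome:
            genome.append(filler())
        block_layout[sp] = layout

        genes_by_species[sp] = [
            GeneModel(gid, sp, _slot_interval(slot), slot + 1)
            for slot, (gid, _) in enumerate(genome)
        ]
        for gid, fam in genome:
            if fam is not None:
                truth_orthologs.add((ref_gene(fam), gid))
        for b in range(config.n_planted_blocks):
            _, _, orient, fams_ref_order = layout[b]
            truth_blocks.append(
                PlantedBlock(
                    block_id=b,
                    species=sp,
                    pairs=[(ref_gene(f), f"{sp}_g{f:04d}") for f in fams_ref_order],
                    orientation=orient,
                )
            )

    # --- homology hits: true orthologs strong, decoy paralogs borderline ---
    hits: list[HomologyHit] = []
    truth_decoys: set[tuple[str, str]] = set()
    fam_present: dict[str, set[int]] = {
        sp: {int(g.gene_id[-4:]) for g in genes if "_g" in g.gene_id}
        for sp, genes in genes_by_species.items()
    }
    for ref_id, sp_id in sorted(truth_orthologs):
        e = 10.0 ** -float(rng.uniform(20, 60))
        bits = float(rng.uniform(250, 450))
        hits.append(HomologyHit(ref_id, sp_id, e, bits))
    for sp in order.species[1:]:
        present = sorted(fam_present[sp])
        for fam in sorted(fam_present[ref] if ref in fam_present else set(in_block)):
            if rng.random() >= config.decoy_rate:
                continue
            near = [f for f in present if f != fam and abs(f - fam) <= 3]
            if not near:
                continue
            partner = int(rng.choice(near))
            pair = (ref_gene(fam), f"{sp}_g{partner:04d}")
            e = 10.0 ** -float(rng.uniform(5.5, 9))
            bits = float(rng.uniform(60, 140))
            hits.append(HomologyHit(pair[0], pair[1], e, bits))
            truth_decoys.add(pair)

    # --- alignment blocks (MAAs) inside planted blocks ---
    alignment_blocks: list[MultiAlignmentBlock] = []
    mlo, mhi = config.maa_per_block_range
    for b in range(config.n_planted_blocks):
        k = int(rng.integers(mlo, mhi + 1))
        if rng.random() < config.maa_conserved_fraction:
            subset = set(species)
        else:
            others = [sp for sp in species[1:]]
            keep = max(1, int(rng.integers(1, len(others) + 1)))
            subset = {ref} | set(rng.choice(others, size=keep, replace=False).tolist())
        lengths = rng.integers(50, 200, size=k)
        fracs = np.linspace(0.0, 1.0, k)
        for i, (frac, maa_len) in enumerate(zip(fracs, lengths)):
            rows: dict[str, tuple[GenomicInterval, str | None]] = {}
            for sp in species:
                if sp not in subset or b not in block_layout[sp]:
                    continue
                s0, s1, orient, _ = block_layout[sp][b]
                if s1 < s0:  # every gene of the block was dropped in this species
                    continue
                span_start, span_end = s0 * SLOT, (s1 + 1) * SLOT
                width = span_end - span_start - int(maa_len)
                f = frac if orient == "same" else 1.0 - frac
                start = span_start + int(round(f * width))
                rows[sp] = (
                    GenomicInterval("chr1", start, start + int(maa_len),
                                    "+" if orient == "same" else "-"),
                    None,
                )
            if ref in rows:
                alignment_blocks.append(
                    MultiAlignmentBlock(rows=rows, reference_species=ref)
                )
    # Structural background MAAs: conserved in every species but at scrambled
    # positions confined to inter-block regions.  They emulate the rearranged
    # fraction of the genome between collinear blocks: they set the background
    # homology density against which chain significance is judged, and they
    # keep planted chains separated (each reference gap holds more background
    # markers than any reasonable gap_size tolerates).
    def _interblock_regions(sp: str) -> list[tuple[int, int]]:
        occupied = sorted(
            (s0, s1) for s0, s1, _, _ in block_layout[sp].values() if s1 >= s0
        )
        genome_slots = len(genes_by_species[sp])
        regions, prev = [], 0
        for s0, s1 in occupied:
            if s0 > prev:
                regions.append((prev, s0))
            prev = s1 + 1
        if prev < genome_slots:
            regions.append((prev, genome_slots))
        return regions

    regions_by_sp = {sp: _interblock_regions(sp) for sp in species}
    for region in regions_by_sp[ref]:
        for _ in range(config.background_maas_per_gap):
            maa_len = int(rng.integers(50, 200))
            rows = {}
            for sp in species:
                regs = regions_by_sp[sp] if sp != ref else [region]
                lo_s, hi_s = regs[int(rng.integers(0, len(regs)))]
                lo_bp, hi_bp = lo_s * SLOT, hi_s * SLOT - maa_len
                start = int(rng.integers(lo_bp, max(lo_bp + 1, hi_bp)))
                rows[sp] = (GenomicInterval("chr1", start, start + maa_len, "+"), None)
            alignment_blocks.append(MultiAlignmentBlock(rows=rows, reference_species=ref))

    # noise alignment blocks outside planted blocks, never in all species
    if config.noise_marker_rate > 0 and config.n_species > 2:
        n_noise = int(config.noise_marker_rate * config.n_planted_blocks * (mlo + mhi) / 2)
        for _ in range(n_noise):
            others = [sp for sp in species[1:]]
            keep = int(rng.integers(1, len(others)))
            subset = [ref] + list(rng.choice(others, size=keep, replace=False))
            maa_len = int(rng.integers(50, 200))
            rows = {}
            for sp in subset:
                start = int(rng.integers(0, config.genes_per_genome * SLOT - maa_len))
                rows[sp] = (GenomicInterval("chr1", start, start + maa_len, "+"), None)
            alignment_blocks.append(MultiAlignmentBlock(rows=rows, reference_species=ref))

    # --- ontology: per-namespace layered DAG ---
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    edges: list[tuple[str, str, str]] = []
    term_ns: dict[str, str] = {}
    mids_by_ns: dict[str, list[str]] = {}
    for ns in namespaces:
        root = f"T:{ns[:2].upper()}:root"
        term_ns[root] = ns
        mids = [f"T:{ns[:2].upper()}:mid{i}" for i in range(2)]
        for m in mids:
            term_ns[m] = ns
            edges.append((m, root, "is_a"))
        mids_by_ns[ns] = mids
    leaf_terms: list[str] = []
    for t in range(config.n_terms):
        ns = namespaces[t % len(namespaces)]
        term = f"T:{ns[:2].upper()}:{t:04d}"
        term_ns[term] = ns
        leaf_terms.append(term)
        mids = mids_by_ns[ns]
        parent = mids[int(rng.integers(0, len(mids)))]
        rel = "part_of" if rng.random() < 0.25 else "is_a"
        edges.append((term, parent, rel))

    # --- term membership over families; co-expressed terms get disjoint sets ---
    tlo, thi = config.term_size_range
    coexpressed = leaf_terms[: config.n_coexpressed_terms]
    families = list(range(n_fam))
    rng.shuffle(families)
    cursor = 0
    term_families: dict[str, list[int]] = {}
    for term in coexpressed:
        size = int(rng.integers(tlo, thi + 1))
        term_families[term] = families[cursor : cursor + size]
        cursor += size
    for term in leaf_terms[config.n_coexpressed_terms :]:
        size = int(rng.integers(tlo, thi + 1))
        term_families[term] = [
            int(f) for f in rng.choice(n_fam, size=size, replace=False)
        ]

    truth_annotations: dict[str, AnnotationSet] = {}
    for sp in species:
        pairs = set()
        present = fam_present[sp] if sp != ref else set(range(n_fam))
        gene_of = (lambda f, sp=sp: f"{sp}_g{f:04d}") if sp != ref else ref_gene
        for term, fams in term_families.items():
            for f in fams:
                if f in present:
                    pairs.add((gene_of(f), term))
        truth_annotations[sp] = AnnotationSet(pairs)

    # --- expression: latent-factor co-expression for planted modules ---
    tissues = [f"tissue{i:02d}" for i in range(1, config.n_tissues + 1)]
    base = 5.0
    expr = base + rng.normal(0.0, 1.0, size=(n_fam, config.n_tissues))
    for term in coexpressed:
        factor = rng.normal(0.0, config.latent_factor_sd, size=config.n_tissues)
        for f in term_families[term]:
            expr[f] = base + factor + rng.normal(0.0, config.noise_sd, size=config.n_tissues)
    expr = np.clip(expr, 0.0, None)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=[ref_gene(f) for f in range(n_fam)], columns=tissues)
    )

    return SyntheticWorld(
        config=config,
        order=order,
        genes_by_species=genes_by_species,
        alignment_blocks=alignment_blocks,
        hits=hits,
        truth_orthologs=truth_orthologs,
        truth_decoys=truth_decoys,
        truth_blocks=truth_blocks,
        ontology_edges=edges,
        term_namespaces=term_ns,
        truth_annotations=truth_annotations,
        expression=expression,
        truth_coexpressed_terms=list(coexpressed),
    )


def _write_obo(world: SyntheticWorld, path: Path) -> None:
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in world.ontology_edges:
        parents.setdefault(child, []).append((parent, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(world.term_namespaces):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic {term}\n")
            fh.write(f"namespace: {world.term_namespaces[term]}\n")
            for parent, rel in sorted(parents.get(term, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! synthetic {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! synthetic {parent}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, str]:
    """Write all pipeline inputs under ``inputs/`` and truth under ``truth/``.

    Returns a manifest mapping relative paths to sha256 checksums; the
    manifest itself is written as ``manifest.json``.
    """
    out = Path(out_dir)
    inputs = out / "inputs"
    truth = out / "truth"
    inputs.mkdir(parents=True, exist_ok=True)
    truth.mkdir(parents=True, exist_ok=True)

    write_maf(world.alignment_blocks, inputs / "alignment.maf")
    for sp, genes in world.genes_by_species.items():
        write_gene_models_gff3(genes, inputs / f"genes_{sp}.gff3")
    write_homology_table(world.hits, inputs / "hits.tsv")
    _write_obo(world, inputs / "ontology.obo")
    for sp, annset in world.truth_annotations.items():
        if sp == world.reference:
            write_annotation_table(annset, truth / f"annotations_{sp}.tsv")
        else:
            write_annotation_table(annset, inputs / f"annotations_{sp}.tsv")
    write_expression_matrix(world.expression, inputs / "expression.tsv")
    write_phylo_order(world.order, inputs / "species_order.txt")

    with open(truth / "orthologs.tsv", "w") as fh:
        for a, b in sorted(world.truth_orthologs):
            fh.write(f"{a}\t{b}\n")
    with open(truth / "decoys.tsv", "w") as fh:
        for a, b in sorted(world.truth_decoys):
            fh.write(f"{a}\t{b}\n")
    with open(truth / "blocks.tsv", "w") as fh:
        for blk in world.truth_blocks:
            genes = ",".join(f"{a}|{b}" for a, b in blk.pairs)
            fh.write(f"{blk.block_id}\t{blk.species}\t{blk.orientation}\t{genes}\n")
    with open(truth / "coexpressed_terms.txt", "w") as fh:
        for term in world.truth_coexpressed_terms:
            fh.write(term + "\n")

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
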