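"""Shared fixtures: small synthetic worlds and detection helpers."""

from __future__ import annotations

import numpy as np
import pytest

from synortho import collinearity as C
from synortho.collinearity import GENE_PARAMS, MAA_PARAMS
from synortho.orthology import infer_opps
from synortho.synth import WorldConfig, generate_world


def clean_config(seed: int, **overrides) -> WorldConfig:
    """A noise-free, fully conserved world: no spurious markers, no
    rearrangements, no ortholog dropout, no decoy hits."""
    base = dict(
        seed=seed,
        noise_marker_rate=0.0,
        rearrangement_rate=0.0,
        ortholog_dropout_rate=0.0,
        decoy_rate=0.0,
        maa_conserved_fraction=1.0,
    )
    base.update(overrides)
    return WorldConfig(**base)


def detect_world_segments(world, marker_type: str = "both"):
    """Run pairwise detection between the reference and every partner."""
    ref = world.reference
    maa_segs, gene_segs = [], []
    ref_maa = C.maa_markers(world.alignment_blocks, ref) if marker_type in ("both", "maa") else None
    ref_gen = C.gene_markers(world.genes_by_species[ref]) if marker_type in ("both", "gene") else None
    for sp in world.order.species[1:]:
        if ref_maa is not None:
            spm = C.maa_markers(world.alignment_blocks, sp)
            pairs = C.build_homology_pairs(ref_maa, spm)
            maa_segs += C.detect_pairwise_segments(ref_maa, spm, pairs, MAA_PARAMS, ref, sp)
        if ref_gen is not None:
            spg = C.gene_markers(world.genes_by_species[sp])
            gp = C.build_homology_pairs(ref_gen, spg, world.hits)
            gene_segs += C.detect_pairwise_segments(ref_gen, spg, gp, GENE_PARAMS, ref, sp)
    return maa_segs, gene_segs


def run_orthology(world):
    maa_segs, gene_segs = detect_world_segments(world)
    return infer_opps(world.genes_by_species, maa_segs, gene_segs, world.hits, world.order)


@pytest.fixture(scope="session")
def clean_world():
    return generate_world(clean_config(seed=101))


@pytest.fixture(scope="session")
def default_world():
    return generate_world(WorldConfig(seed=202))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
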