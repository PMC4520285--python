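"""Segregant cross generation with a planted 3'-vs-5' imbalance QTL."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Cross:
    """Genotypes plus per-gene segregant x nucleosome value matrices."""

    genotypes: pd.DataFrame  # segregants x markers, values in {0, 1}
    values: dict[str, np.ndarray]  # gene -> (n_segregants, n_nucleosomes)
    qtl_marker: int
    effect: float
    seed: int


def generate_cross(
    seed: int,
    n_segregants: int,
    n_markers: int,
    qtl_marker: int,
    effect: float,
    n_genes: int,
    nucs_per_gene: int = 8,
    recomb: float = 0.1,
    affected_fraction: float = 1.0,
) -> Cross:
    """Simulate a biallelic cross where segregants carrying the planted
    allele have their nucleosome values tilted toward the 3' half of
    affected genes (+effect/2 on the second half, -effect/2 on the first).
    """
    if n_segregants < 10:
        raise ValueError("need at least 10 segregants")
    if n_markers < 1:
        raise ValueError("need at least one marker")
    if not (0 <= qtl_marker < n_markers):
        raise ValueError(f"qtl_marker {qtl_marker} out of range [0, {n_markers})")

    rng = np.random.default_rng(seed)
    geno = np.empty((n_segregants, n_markers), dtype=np.int8)
    geno[:, 0] = rng.integers(0, 2, size=n_segregants)
    for j in range(1, n_markers):
        flip = rng.random(n_segregants) < recomb
        geno[:, j] = geno[:, j - 1] ^ flip

    allele = geno[:, qtl_marker].astype(float)
    half = nucs_per_gene // 2
    values: dict[str, np.ndarray] = {}
    for g in range(n_genes):
        v = rng.normal(0.0, 1.0, size=(n_segregants, nucs_per_gene))
        if effect != 0 and rng.random() < affected_fraction:
            v[:, half:] += (effect / 2.0) * allele[:, None]
            v[:, :half] -= (effect / 2.0) * allele[:, None]
        values[f"gene{g:04d}"] = v

    genotypes = pd.DataFrame(
        geno,
        index=pd.Index([f"seg{i:03d}" for i in range(n_segregants)], name="segregant"),
        columns=pd.Index([f"m{j:04d}" for j in range(n_markers)], name="marker"),
    )
    return Cross(genotypes, values, qtl_marker, effect, seed)
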