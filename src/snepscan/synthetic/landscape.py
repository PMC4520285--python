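"""Nucleosome landscape generation with planted positional divergence."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..align import CurSet, build_curs
from .genomes import GenomeSet

MAX_PLANTED_SHIFT = 75  # bp; positional shifts never exceed this


@dataclass
class Landscape:
    """True dyad maps per strain plus the planted-divergence bookkeeping.

    ``table`` has one row per ancestral nucleosome: columns ``dyad_<strain>``
    (NaN when absent in that strain), ``cls`` (well/fuzzy), ``shift`` (bp,
    0 when unshifted) and ``evicted``.
    """

    genomes: GenomeSet
    cur_set: CurSet
    table: pd.DataFrame
    seed: int

    @property
    def strains(self) -> list[str]:
        return self.genomes.strains

    @property
    def contig(self) -> str:
        return self.genomes.contig

    def dyads(self, strain: str) -> pd.Series:
        col = self.table[f"dyad_{strain}"]
        return col[col.notna()].astype(int)

    @property
    def shifted_ids(self) -> np.ndarray:
        return self.table.index[self.table["shift"] != 0].to_numpy()

    @property
    def evicted_ids(self) -> np.ndarray:
        return self.table.index[self.table["evicted"]].to_numpy()

    @property
    def fuzzy_ids(self) -> np.ndarray:
        return self.table.index[self.table["cls"] == "fuzzy"].to_numpy()


def generate_landscape(
    seed: int,
    genomes: GenomeSet,
    spacing_mean: int = 165,
    fuzzy_fraction: float = 0.0,
    n_shifted: int = 0,
    shift_range=(15, MAX_PLANTED_SHIFT),
    n_evicted: int = 0,
    occupancy_sd: float = 0.3,
    spacing_jitter: int = 8,
    cur_min_length: int = 4000,
    cur_max_indel: int = 30,
) -> Landscape:
    """Place nucleosomes on the reference strain and lift them to the others.

    The lifted maps are identical to the reference map translated through the
    coordinate map, except at the planted shift/eviction/fuzzy sites, all of
    which are recorded in the returned table.  Shifts and evictions are
    planted on the *second* strain.
    """
    if spacing_mean <= 147:
        raise ValueError("spacing_mean must exceed 147 bp")
    if isinstance(shift_range, (int, np.integer)):
        shift_range = (15, int(shift_range))
    lo, hi = shift_range
    if not (0 < lo <= hi <= MAX_PLANTED_SHIFT):
        raise ValueError(f"shift magnitudes must lie in (0, {MAX_PLANTED_SHIFT}]")

    rng = np.random.default_rng(seed)
    ref = genomes.reference
    length = len(genomes.sequences[ref])

    dyads = []
    pos = 150
    while pos < length - 150:
        dyads.append(pos)
        pos += spacing_mean + int(rng.integers(-spacing_jitter, spacing_jitter + 1))
    dyads = np.asarray(dyads)
    n = len(dyads)
    if n == 0:
        raise ValueError("genome too short for any nucleosome")

    cls = np.where(rng.random(n) < fuzzy_fraction, "fuzzy", "well")
    eligible = np.flatnonzero(cls == "well")
    if n_shifted + n_evicted > len(eligible):
        raise ValueError(
            f"n_shifted + n_evicted = {n_shifted + n_evicted} exceeds the "
            f"{len(eligible)} available well-positioned nucleosomes"
        )
    picked = rng.choice(eligible, size=n_shifted + n_evicted, replace=False)
    shifted_idx, evicted_idx = picked[:n_shifted], picked[n_shifted:]

    shifts = np.zeros(n, dtype=int)
    if n_shifted:
        mags = rng.integers(lo, hi + 1, size=n_shifted)
        signs = rng.choice([-1, 1], size=n_shifted)
        shifts[shifted_idx] = mags * signs
    evicted = np.zeros(n, dtype=bool)
    evicted[evicted_idx] = True

    occupancy = np.exp(rng.normal(0.0, occupancy_sd, size=n))

    blocks = [b for pair, bs in genomes.blocks.items() for b in bs if pair[0] == ref]
    # one CurSet per (ref, other) pair; keep the first pair's for matching
    cur_sets = {
        other: build_curs(genomes.blocks[(ref, other)], cur_min_length, cur_max_indel)
        for other in genomes.strains[1:]
    }

    table = pd.DataFrame(
        {
            f"dyad_{ref}": dyads.astype(float),
            "cls": cls,
            "shift": shifts,
            "evicted": evicted,
            "occupancy": occupancy,
        },
        index=pd.Index([f"nuc{i:05d}" for i in range(n)], name="nuc_id"),
    )
    for j, other in enumerate(genomes.strains[1:]):
        cs = cur_sets[other]
        lifted = cs.translate_array(genomes.contig, dyads, "forward")
        if j == 0:  # planted divergence lives on the second strain
            lifted = lifted + shifts
            lifted[evicted] = np.nan
        table[f"dyad_{other}"] = lifted

    return Landscape(genomes, cur_sets[genomes.strains[1]], table, seed)
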