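"""Read-start simulation: NB-distributed counts, Gaussian positional jitter.

Each read start is drawn at the nucleosome 5' edge (dyad - 73) plus
Normal(0, sigma=10) jitter, forward strand only.  Counts follow a
Gamma-Poisson mixture with a single dispersion parameter; per-sample depth
multipliers are log-uniform in [0.5, 2] so size-factor estimation is
exercised downstream.  Planted SNEPs multiply the ChIP rate of the second
strain by 2**log2FC and leave MNase untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .landscape import Landscape


class SampleId(NamedTuple):
    strain: str
    assay: str  # "MNase" or "ChIP"
    mark: str | None
    replicate: int

    @property
    def label(self) -> str:
        mid = f".{self.mark}" if self.mark else ""
        return f"{self.strain}.{self.assay}{mid}.rep{self.replicate}"


_FIVE_PRIME = [(0.0, 3.0), (0.3, 1.6), (1.0, 0.8)]
_THREE_PRIME = [(0.0, 0.8), (0.7, 1.6), (1.0, 3.0)]


def default_enrichment(mark: str) -> Callable[[float | None], float]:
    """Piecewise-linear gene-body enrichment for a mark.

    Acetylation marks and H3K4me3 are 5'-skewed, H3K4me1 is 3'-skewed,
    anything else is flat.  Outside genes the factor is 1.
    """
    knots = _THREE_PRIME if mark == "H3K4me1" else _FIVE_PRIME
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])

    def profile(relpos: float | None) -> float:
        if relpos is None or np.isnan(relpos):
            return 1.0
        return float(np.interp(relpos, xs, ys))

    return profile


@dataclass
class ReadSet:
    """Per-sample sorted forward read-start arrays (single contig)."""

    contig: str
    samples: dict[SampleId, np.ndarray]
    contig_lengths: dict[str, int]  # per strain
    planted_sneps: dict[tuple[str, str], float]  # (nuc_id, mark) -> log2FC
    seed: int

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.label, s.strain, s.assay, s.mark or "", s.replicate, len(v))
                for s, v in self.samples.items()
            ],
            columns=["sample", "strain", "assay", "mark", "replicate", "n_reads"],
        ).set_index("sample")

    def total(self, sample: SampleId) -> int:
        return len(self.samples[sample])

    def by_group(self):
        """Yield ((strain, assay, mark), {replicate: starts}) groups."""
        groups: dict[tuple, dict[int, np.ndarray]] = {}
        for sid, starts in self.samples.items():
            groups.setdefault((sid.strain, sid.assay, sid.mark), {})[
                sid.replicate
            ] = starts
        return groups

    def write_bed(self, outdir, read_length: int = 50) -> list[str]:
        import os

        paths = []
        for sid, starts in sorted(self.samples.items()):
            path = os.path.join(outdir, f"{sid.label}.bed")
            with open(path, "w") as fh:
                for s in starts:
                    fh.write(
                        f"{self.contig}\t{s}\t{s + read_length}\t{sid.label}\t0\t+\n"
                    )
            paths.append(path)
        return paths


def _gene_relpos(landscape: Landscape, genes: pd.DataFrame | None) -> np.ndarray:
    """Fractional, strand-aware gene-body position of each nucleosome."""
    n = len(landscape.table)
    rel = np.full(n, np.nan)
    if genes is None or genes.empty:
        return rel
    dyads = landscape.table[f"dyad_{landscape.genomes.reference}"].to_numpy()
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    strands = genes["strand"].to_numpy()
    order = np.argsort(starts)
    idx = np.searchsorted(starts[order], dyads, side="right") - 1
    for i, j in enumerate(idx):
        if j < 0:
            continue
        g = order[j]
        if starts[g] <= dyads[i] < ends[g]:
            f = (dyads[i] - starts[g]) / (ends[g] - starts[g])
            rel[i] = f if strands[g] == "+" else 1.0 - f
    return rel


def simulate_reads(
    seed: int,
    landscape: Landscape,
    marks: list[str],
    n_reads_per_sample: int,
    n_replicates: int = 2,
    enrichment_profiles: dict[str, Callable] | None = None,
    genes: pd.DataFrame | None = None,
    planted_sneps=None,
    dispersion: float = 0.05,
    read_jitter_sd: float = 10.0,
    fuzzy_jitter: int = 40,
    depth_range: tuple[float, float] = (0.5, 2.0),
    strains: list[str] | None = None,
) -> ReadSet:
    """Simulate per-sample forward read starts for MNase and ChIP assays."""
    table = landscape.table
    if table.empty:
        raise ValueError("empty landscape: no nucleosomes to sample reads from")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per strain x assay")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    strains = strains or landscape.strains
    snep_strain = strains[1] if len(strains) > 1 else None
    sneps: dict[tuple[str, str], float] = {}
    if planted_sneps:
        items = (
            planted_sneps.items()
            if isinstance(planted_sneps, dict)
            else [((nid, mark), lfc) for nid, mark, lfc in planted_sneps]
        )
        for (nid, mark), lfc in items:
            if nid not in table.index:
                raise ValueError(f"planted SNEP references unknown nucleosome {nid}")
            if mark not in marks:
                raise ValueError(f"planted SNEP references unsimulated mark {mark}")
            sneps[(nid, mark)] = float(lfc)

    profiles = {m: default_enrichment(m) for m in marks}
    if enrichment_profiles:
        profiles.update(enrichment_profiles)
    relpos = _gene_relpos(landscape, genes)
    enrich = {
        m: np.array([profiles[m](r) for r in relpos]) for m in marks
    }

    nuc_ids = table.index.to_numpy()
    occupancy = table["occupancy"].to_numpy()
    fuzzy_mask = (table["cls"] == "fuzzy").to_numpy()

    sample_ids = [
        SampleId(strain, assay, mark, rep)
        for strain in strains
        for assay, mark in [("MNase", None)] + [("ChIP", m) for m in marks]
        for rep in range(1, n_replicates + 1)
    ]
    child_seeds = np.random.SeedSequence(seed).spawn(len(sample_ids))

    samples: dict[SampleId, np.ndarray] = {}
    for sid, ss in zip(sample_ids, child_seeds):
        rng = np.random.default_rng(ss)
        dyads = table[f"dyad_{sid.strain}"].to_numpy()
        present = ~np.isnan(dyads)

        w = occupancy.copy()
        if sid.assay == "ChIP":
            w = w * enrich[sid.mark]
            if sid.strain == snep_strain:
                for (nid, mark), lfc in sneps.items():
                    if mark == sid.mark:
                        w[table.index.get_loc(nid)] *= 2.0**lfc
        w = np.where(present, w, 0.0)

        depth_mult = float(
            np.exp(rng.uniform(np.log(depth_range[0]), np.log(depth_range[1])))
        )
        lam = w / w.sum() * n_reads_per_sample * depth_mult
        if dispersion > 0:
            lam = lam * rng.gamma(1.0 / dispersion, dispersion, size=len(lam))
        counts = rng.poisson(lam)

        centers = dyads.copy()
        if fuzzy_mask.any():
            offs = rng.integers(-fuzzy_jitter, fuzzy_jitter + 1, size=len(centers))
            centers = np.where(fuzzy_mask, centers + offs, centers)

        edges = np.repeat(centers[present] - 73, counts[present])
        starts = np.rint(edges + rng.normal(0.0, read_jitter_sd, size=len(edges)))
        length = landscape_strain_length(landscape, sid.strain)
        starts = np.clip(starts, 0, length - 1).astype(np.int64)
        starts.sort()
        samples[sid] = starts

    contig_lengths = {
        s: landscape_strain_length(landscape, s) for s in strains
    }
    return ReadSet(landscape.contig, samples, contig_lengths, sneps, seed)


def landscape_strain_length(landscape: Landscape, strain: str) -> int:
    return len(landscape.genomes.sequences[strain])
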