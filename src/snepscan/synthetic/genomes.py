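"""Strain genome generation from a common ancestral sequence."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..align import AlignmentBlock, Variant

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GenomeSet:
    """Strain sequences plus the exact ancestor-vs-strain variant lists."""

    contig: str
    strains: list[str]
    sequences: dict[str, str]
    blocks: dict[tuple[str, str], list[AlignmentBlock]]
    variants: dict[str, tuple[Variant, ...]]
    seed: int

    @property
    def reference(self) -> str:
        return self.strains[0]

    def write_fasta(self, path, strain: str) -> None:
        seq = self.sequences[strain]
        with open(path, "w") as fh:
            fh.write(f">{self.contig} strain={strain}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, base: bytes) -> bytes:
    choices = [b for b in (b"A", b"C", b"G", b"T") if b != base]
    return choices[rng.integers(0, 3)]


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def generate_genomes(
    seed: int,
    length: int,
    n_strains: int = 2,
    snp_rate: float = 0.005,
    indel_rate: float = 0.0,
    indel_size_max: int = 10,
    contig: str = "chrI",
    indel_exclude=None,
    strain_names=None,
) -> GenomeSet:
    """Derive ``n_strains`` genomes from one ancestral sequence.

    The first strain *is* the ancestor; every other strain carries SNPs at
    ``snp_rate`` per bp and indels at ``indel_rate`` per bp (size uniform in
    ``1..indel_size_max``).  Indels are kept out of ``indel_exclude``
    intervals so gene binning stays well defined.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if length < 10_000:
        raise ValueError("genome length must be >= 10000 bp")
    for name, rate in (("snp_rate", snp_rate), ("indel_rate", indel_rate)):
        if not (0 <= rate < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    if n_strains < 2:
        raise ValueError("need at least two strains")

    strains = list(strain_names) if strain_names else [f"S{i+1}" for i in range(n_strains)]
    if len(strains) != n_strains:
        raise ValueError("strain_names length must match n_strains")
    indel_exclude = list(indel_exclude or [])

    rng = np.random.default_rng(seed)
    ancestor = _random_sequence(rng, length)
    sequences = {strains[0]: ancestor.tobytes().decode()}
    blocks: dict[tuple[str, str], list[AlignmentBlock]] = {}
    variants: dict[str, tuple[Variant, ...]] = {strains[0]: ()}

    for strain in strains[1:]:
        snp_pos = np.flatnonzero(rng.random(length) < snp_rate)
        indel_pos = np.flatnonzero(rng.random(length) < indel_rate)

        # keep indels apart from each other and outside excluded intervals
        chosen: list[tuple[int, str, int]] = []
        last_end = -(10 * indel_size_max)
        for p in indel_pos:
            p = int(p)
            if p < last_end + 2 * indel_size_max:
                continue
            if p < 200 or p > length - 200:
                continue
            if _in_intervals(p, indel_exclude):
                continue
            vtype = "del" if rng.random() < 0.5 else "ins"
            size = int(rng.integers(1, indel_size_max + 1))
            chosen.append((p, vtype, size))
            last_end = p + size
        del_spans = [(p, p + s) for p, t, s in chosen if t == "del"]
        snp_pos = [int(p) for p in snp_pos if not _in_intervals(int(p), del_spans)]

        var_list = sorted(
            [Variant(p, "snp", 1) for p in snp_pos]
            + [Variant(p, t, s) for p, t, s in chosen],
            key=lambda v: v.offset,
        )

        # build the mutated sequence
        parts: list[bytes] = []
        cursor = 0
        for v in var_list:
            parts.append(ancestor[cursor : v.offset].tobytes())
            if v.type == "snp":
                parts.append(_mutate(rng, ancestor[v.offset].tobytes()))
                cursor = v.offset + 1
            elif v.type == "del":
                cursor = v.offset + v.size
            else:  # ins
                parts.append(_random_sequence(rng, v.size).tobytes())
                cursor = v.offset
        parts.append(ancestor[cursor:].tobytes())
        seq = b"".join(parts).decode()

        sequences[strain] = seq
        variants[strain] = tuple(var_list)
        blocks[(strains[0], strain)] = [
            AlignmentBlock(contig, 0, length, contig, 0, len(seq), tuple(var_list))
        ]

    return GenomeSet(contig, strains, sequences, blocks, variants, seed)
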