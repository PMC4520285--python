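"""Cross-strain coordinate maps built from pairwise alignment blocks.

The central object is the :class:`CurSet`: an ordered collection of common
uninterrupted regions (CURs), i.e. alignable regions that are at least
``min_length`` bp long in *both* strains and contain no indel larger than
``max_indel`` bp.  Within a CUR, positions translate bidirectionally and
monotonically between the two genomes.

All coordinates are 0-based half-open.  "source" denotes the first strain of
the pair (the reference frame of block source intervals) and "target" the
second.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Variant",
    "AlignmentBlock",
    "CUR",
    "CurSet",
    "TranslationResult",
    "build_curs",
    "read_blocks_tsv",
    "write_blocks_tsv",
]

VARIANT_TYPES = ("snp", "ins", "del")


@dataclass(frozen=True)
class Variant:
    """A polymorphism inside an alignment block.

    ``offset`` is relative to the block/CUR source start and refers to a
    source-strain coordinate.  ``ins`` means the target genome carries
    ``size`` extra bases immediately before that source position; ``del``
    means source bases ``[offset, offset + size)`` are absent from the
    target; ``snp`` is a 1-bp mismatch.
    """

    offset: int
    type: str
    size: int = 1

    def __post_init__(self) -> None:
        if self.type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.type!r}")
        if self.offset < 0:
            raise ValueError("variant offset must be >= 0")
        if self.size < 1:
            raise ValueError("variant size must be >= 1")


@dataclass(frozen=True)
class AlignmentBlock:
    """A colinear aligned segment between two genomes, with its variants."""

    source_contig: str
    source_start: int
    source_end: int
    target_contig: str
    target_start: int
    target_end: int
    variants: tuple[Variant, ...] = ()

    def __post_init__(self) -> None:
        if self.source_start < 0 or self.target_start < 0:
            raise ValueError("negative interval coordinates")
        if self.source_end <= self.source_start:
            raise ValueError("source end must exceed start")
        if self.target_end <= self.target_start:
            raise ValueError("target end must exceed start")
        object.__setattr__(
            self, "variants", tuple(sorted(self.variants, key=lambda v: v.offset))
        )
        src_len = self.source_end - self.source_start
        ins = sum(v.size for v in self.variants if v.type == "ins")
        dele = sum(v.size for v in self.variants if v.type == "del")
        if self.target_end - self.target_start != src_len + ins - dele:
            raise ValueError(
                "inconsistent block: target length does not equal source "
                "length adjusted for indels"
            )

    @property
    def source_length(self) -> int:
        return self.source_end - self.source_start

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class TranslationResult:
    """Outcome of a coordinate translation; ``ok`` is False outside CURs."""

    ok: bool
    position: int | None = None
    cur_id: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


UNTRANSLATABLE = TranslationResult(False)


def _build_runs(
    src_start: int, src_end: int, tgt_start: int, variants: Sequence[Variant]
) -> list[tuple[int, int, int]]:
    """Decompose an aligned segment into colinear runs (src_s, src_e, tgt_s)."""
    runs: list[tuple[int, int, int]] = []
    s, t = src_start, tgt_start
    for v in variants:
        if v.type == "snp":
            continue
        pos = src_start + v.offset
        if pos > s:
            runs.append((s, pos, t))
            t += pos - s
            s = pos
        if v.type == "del":
            s = max(s, pos + v.size)
        else:  # ins
            t += v.size
    if src_end > s:
        runs.append((s, src_end, t))
    return runs


class CUR:
    """A common uninterrupted region with bidirectional translation."""

    def __init__(
        self,
        cur_id: str,
        source_contig: str,
        source_start: int,
        source_end: int,
        target_contig: str,
        target_start: int,
        target_end: int,
        variants: Sequence[Variant] = (),
    ):
        self.id = cur_id
        self.source_contig = source_contig
        self.source_start = source_start
        self.source_end = source_end
        self.target_contig = target_contig
        self.target_start = target_start
        self.target_end = target_end
        self.variants = tuple(sorted(variants, key=lambda v: v.offset))
        self._runs = _build_runs(source_start, source_end, target_start, self.variants)
        # inverse runs: (tgt_s, tgt_e, src_s), monotone by construction
        self._inv_runs = [
            (ts, ts + (se - ss), ss) for (ss, se, ts) in self._runs
        ]
        self._run_starts = [r[0] for r in self._runs]
        self._inv_starts = [r[0] for r in self._inv_runs]

    @property
    def source_length(self) -> int:
        return self.source_end - self.source_start

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CUR({self.id}, {self.source_contig}:{self.source_start}-"
            f"{self.source_end} -> {self.target_contig}:{self.target_start}-"
            f"{self.target_end}, {len(self.variants)} variants)"
        )

    @staticmethod
    def _translate(runs, starts, pos) -> int | None:
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        s, e, other = runs[i]
        if pos < e:
            return other + (pos - s)
        # inside a gap (deleted / inserted segment): map to the left flank
        return other + (e - s) - 1

    def translate_forward(self, pos: int) -> int | None:
        if not (self.source_start <= pos < self.source_end):
            return None
        return self._translate(self._runs, self._run_starts, pos)

    def translate_reverse(self, pos: int) -> int | None:
        if not (self.target_start <= pos < self.target_end):
            return None
        return self._translate(self._inv_runs, self._inv_starts, pos)


class CurSet:
    """Sorted, non-overlapping CURs with genome-wide translation queries."""

    def __init__(self, curs: Iterable[CUR]):
        self.curs = sorted(curs, key=lambda c: (c.source_contig, c.source_start))
        self._by_source: dict[str, list[CUR]] = {}
        self._by_target: dict[str, list[CUR]] = {}
        for c in self.curs:
            self._by_source.setdefault(c.source_contig, []).append(c)
            self._by_target.setdefault(c.target_contig, []).append(c)
        for lst in self._by_target.values():
            lst.sort(key=lambda c: c.target_start)
        self._src_starts = {
            ctg: [c.source_start for c in lst] for ctg, lst in self._by_source.items()
        }
        self._tgt_starts = {
            ctg: [c.target_start for c in lst] for ctg, lst in self._by_target.items()
        }

    def __len__(self) -> int:
        return len(self.curs)

    def __iter__(self):
        return iter(self.curs)

    @property
    def total_source_span(self) -> int:
        return sum(c.source_length for c in self.curs)

    @property
    def total_target_span(self) -> int:
        return sum(c.target_length for c in self.curs)

    def find(self, contig: str, pos: int, direction: str = "forward") -> CUR | None:
        """Return the CUR containing ``pos`` on ``contig``, or None."""
        if direction == "forward":
            lst, starts = self._by_source.get(contig), self._src_starts.get(contig)
            lo, hi = "source_start", "source_end"
        else:
            lst, starts = self._by_target.get(contig), self._tgt_starts.get(contig)
            lo, hi = "target_start", "target_end"
        if not lst:
            return None
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        c = lst[i]
        if getattr(c, lo) <= pos < getattr(c, hi):
            return c
        return None

    def translate(
        self, contig: str, pos: int, direction: str = "forward"
    ) -> TranslationResult:
        """Translate ``pos`` to the other strain; typed miss outside CURs."""
        c = self.find(contig, pos, direction)
        if c is None:
            return UNTRANSLATABLE
        if direction == "forward":
            out = c.translate_forward(pos)
        else:
            out = c.translate_reverse(pos)
        if out is None:  # pragma: no cover - guarded by find()
            return UNTRANSLATABLE
        return TranslationResult(True, out, c.id)

    def translate_array(self, contig, positions, direction="forward"):
        """Vectorized translate; returns float array with NaN for misses."""
        import numpy as np

        out = np.full(len(positions), np.nan)
        for i, p in enumerate(positions):
            r = self.translate(contig, int(p), direction)
            if r.ok:
                out[i] = r.position
        return out

    def local_polymorphism(
        self, contig: str, center: int, halfwidth: int = 30, percent: bool = True
    ) -> float | None:
        """SNP+indel rate per bp in ``center +/- halfwidth``; None outside CURs."""
        c = self.find(contig, center, "forward")
        if c is None:
            return None
        lo = max(center - halfwidth, c.source_start)
        hi = min(center + halfwidth + 1, c.source_end)
        if hi <= lo:
            return None
        n = sum(
            1
            for v in c.variants
            if lo <= c.source_start + v.offset < hi
        )
        rate = n / (hi - lo)
        return rate * 100.0 if percent else rate

    # ------------------------------------------------------------------ I/O
    def to_bed(self, which: str = "source") -> str:
        lines = []
        for c in self.curs:
            if which == "source":
                lines.append(f"{c.source_contig}\t{c.source_start}\t{c.source_end}\t{c.id}")
            else:
                lines.append(f"{c.target_contig}\t{c.target_start}\t{c.target_end}\t{c.id}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_offset_table(self) -> str:
        """TSV of per-CUR variants, enough to rebuild translation tables."""
        rows = ["cur_id\tsource_contig\tsource_start\tsource_end\ttarget_contig\ttarget_start\ttarget_end\tvariants"]
        for c in self.curs:
            enc = ",".join(f"{v.offset}:{v.type}:{v.size}" for v in c.variants)
            rows.append(
                f"{c.id}\t{c.source_contig}\t{c.source_start}\t{c.source_end}\t"
                f"{c.target_contig}\t{c.target_start}\t{c.target_end}\t{enc}"
            )
        return "\n".join(rows) + "\n"


def _check_non_overlapping(blocks: Sequence[AlignmentBlock]) -> None:
    for key, lo, hi in (
        ("source", lambda b: (b.source_contig, b.source_start), lambda b: b.source_end),
        ("target", lambda b: (b.target_contig, b.target_start), lambda b: b.target_end),
    ):
        ordered = sorted(blocks, key=lo)
        for a, b in zip(ordered, ordered[1:]):
            if lo(a)[0] == lo(b)[0] and hi(a) > lo(b)[1]:
                raise ValueError(
                    f"overlapping {key} intervals between blocks {a} and {b}"
                )


def _split_block(
    block: AlignmentBlock, max_indel: int
) -> list[tuple[int, int, int, int, list[Variant]]]:
    """Split a block at every indel larger than ``max_indel``.

    Returns (src_s, src_e, tgt_s, tgt_e, variants-with-reoffset) segments.
    """
    segments = []
    src_s, tgt_s = block.source_start, block.target_start
    pending: list[Variant] = []

    def close(src_e: int) -> int:
        nonlocal src_s, tgt_s, pending
        ins = sum(v.size for v in pending if v.type == "ins")
        dele = sum(v.size for v in pending if v.type == "del")
        tgt_e = tgt_s + (src_e - src_s) + ins - dele
        if src_e > src_s:
            reoff = [
                Variant(block.source_start + v.offset - src_s, v.type, v.size)
                for v in pending
            ]
            segments.append((src_s, src_e, tgt_s, tgt_e, reoff))
        pending = []
        return tgt_e

    for v in block.variants:
        if v.type in ("ins", "del") and v.size > max_indel:
            pos = block.source_start + v.offset
            tgt_e = close(pos)
            if v.type == "del":
                src_s, tgt_s = pos + v.size, tgt_e
            else:
                src_s, tgt_s = pos, tgt_e + v.size
        else:
            pending.append(v)
    close(block.source_end)
    return segments


def build_curs(
    blocks: Sequence[AlignmentBlock],
    min_length: int = 4000,
    max_indel: int = 30,
) -> CurSet:
    """Build CURs: split blocks at indels > ``max_indel``, keep segments that
    are at least ``min_length`` bp long in both strains."""
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    _check_non_overlapping(blocks)
    curs = []
    i = 0
    for block in sorted(blocks, key=lambda b: (b.source_contig, b.source_start)):
        for src_s, src_e, tgt_s, tgt_e, variants in _split_block(block, max_indel):
            if src_e - src_s >= min_length and tgt_e - tgt_s >= min_length:
                curs.append(
                    CUR(
                        f"cur{i:04d}",
                        block.source_contig,
                        src_s,
                        src_e,
                        block.target_contig,
                        tgt_s,
                        tgt_e,
                        variants,
                    )
                )
                i += 1
    return CurSet(curs)


# --------------------------------------------------------------------- I/O

BLOCKS_HEADER = [
    "source_contig",
    "source_start",
    "source_end",
    "target_contig",
    "target_start",
    "target_end",
    "variants",
]


def write_blocks_tsv(blocks: Sequence[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BLOCKS_HEADER) + "\n")
        for b in blocks:
            enc = ",".join(f"{v.offset}:{v.type}:{v.size}" for v in b.variants)
            fh.write(
                f"{b.source_contig}\t{b.source_start}\t{b.source_end}\t"
                f"{b.target_contig}\t{b.target_start}\t{b.target_end}\t{enc}\n"
            )


def read_blocks_tsv(path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != BLOCKS_HEADER:
            raise ValueError(f"unexpected blocks header: {header}")
        for line in fh:
            if not line.strip():
                continue
            sc, ss, se, tc, ts, te, enc = line.rstrip("\n").split("\t")
            variants = []
            if enc:
                for item in enc.split(","):
                    off, vt, size = item.split(":")
                    variants.append(Variant(int(off), vt, int(size)))
            blocks.append(
                AlignmentBlock(sc, int(ss), int(se), tc, int(ts), int(te), tuple(variants))
            )
    return blocks
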