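"""Synthetic gene annotations (TSS/TES/strand) on the reference genome."""

from __future__ import annotations

import numpy as np
import pandas as pd


def make_genes(
    seed: int,
    genome_length: int,
    n_genes: int,
    length_range=(600, 2400),
    gap_range=(300, 900),
    contig: str = "chrI",
    start_margin: int = 1000,
) -> pd.DataFrame:
    """Place non-overlapping genes with random strand along one contig.

    Returns a frame with columns contig/start/end/strand/tss/tes (tss and
    tes are strand-aware; 0-based, tes is the last base + 1 boundary).
    """
    rng = np.random.default_rng(seed)
    rows = []
    pos = start_margin
    for i in range(n_genes):
        glen = int(rng.integers(length_range[0], length_range[1] + 1))
        if pos + glen > genome_length - start_margin:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + glen
        tss, tes = (start, end) if strand == "+" else (end - 1, start)
        rows.append((f"gene{i:04d}", contig, start, end, strand, tss, tes))
        pos = end + int(rng.integers(gap_range[0], gap_range[1] + 1))
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "strand", "tss", "tes"]
    ).set_index("gene_id")


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, g in genes.iterrows():
            fh.write(
                f"{g.contig}\tsnepscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ctg, _src, ftype, s1, e1, _score, strand, _phase, attrs = line.rstrip(
                "\n"
            ).split("\t")
            if ftype != "gene":
                continue
            gid = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            ).get("ID", f"{ctg}:{s1}-{e1}")
            start, end = int(s1) - 1, int(e1)
            tss, tes = (start, end) if strand == "+" else (end - 1, start)
            rows.append((gid, ctg, start, end, strand, tss, tes))
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "strand", "tss", "tes"]
    ).set_index("gene_id")
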