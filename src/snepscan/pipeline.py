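"""Configuration-driven orchestration of all analysis stages.

Stages run in dependency order (curs -> coverage -> nucmap -> snep ->
genediv -> covary); each stage reads only declared files or in-memory
artifacts of earlier stages, writes TSV/BED outputs under the output
directory and records itself in a manifest.  All randomness flows from the
single config seed through per-stage derived seeds, so reruns with an
identical config reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, align, coverage as covmod, covary as covarymod
from . import genediv as gdmod, nucmap as nmmod, snep as snepmod
from . import synthetic as syn
from .synthetic.genes import read_gff3, write_gff3
from .synthetic.reads import ReadSet, SampleId

STAGES = ["curs", "coverage", "nucmap", "snep", "genediv", "covary"]

DEFAULT_THRESHOLDS = {
    "chunk": 90,
    "min_cur_length": 4000,
    "max_indel": 30,
    "fdr": 0.0001,
    "p": 0.01,
    "delta_cutoff": 10.0,
    "window": 10,
    "permutations": 3,
    "shift_threshold": 10,
    "qc_threshold": 0.25,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    thresholds: dict = field(default_factory=dict)
    simulate: dict | None = None
    sample_sheet: str | None = None
    blocks: str | None = None
    genes: str | None = None
    contig_lengths: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir", "snepscan_out"),
            thresholds={**DEFAULT_THRESHOLDS, **(raw.get("thresholds") or {})},
            simulate=raw.get("simulate"),
            sample_sheet=raw.get("sample_sheet"),
            blocks=raw.get("blocks"),
            genes=raw.get("genes"),
            contig_lengths=raw.get("contig_lengths"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for k, v in self.thresholds.items():
            if isinstance(v, (int, float)) and v <= 0:
                raise ConfigError(f"threshold {k} must be positive, got {v}")
        if self.simulate is None:
            for name in ("sample_sheet", "blocks", "genes"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"file-mode config requires '{name}'")
                if not os.path.exists(path):
                    raise ConfigError(f"{name} path does not exist: {path}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "thresholds": self.thresholds,
            "simulate": self.simulate,
            "sample_sheet": self.sample_sheet,
            "blocks": self.blocks,
            "genes": self.genes,
            "contig_lengths": self.contig_lengths,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_readset(sample_sheet: str, contig_lengths: dict[str, int]) -> ReadSet:
    """Load per-sample BED files of forward read starts into a ReadSet."""
    sheet = pd.read_csv(sample_sheet, sep="\t")
    required = {"path", "strain", "assay", "mark", "replicate"}
    if not required.issubset(sheet.columns):
        raise ConfigError(f"sample sheet must have columns {sorted(required)}")
    samples = {}
    contig = None
    for _, row in sheet.iterrows():
        if not os.path.exists(row["path"]):
            raise ConfigError(f"sample path does not exist: {row['path']}")
        bed = pd.read_csv(row["path"], sep="\t", header=None, usecols=[0, 1, 5])
        fwd = bed[bed[5] == "+"]
        contig = contig or fwd[0].iloc[0]
        mark = None if pd.isna(row["mark"]) or row["mark"] == "" else str(row["mark"])
        sid = SampleId(str(row["strain"]), str(row["assay"]), mark, int(row["replicate"]))
        samples[sid] = np.sort(fwd[1].to_numpy(dtype=np.int64))
    strains = {sid.strain for sid in samples}
    missing = [s for s in strains if not any(
        sid.strain == s and sid.assay == "MNase" for sid in samples
    )]
    if missing:
        raise ConfigError(f"strain(s) missing an MNase sample: {sorted(missing)}")
    return ReadSet(contig, samples, dict(contig_lengths), {}, 0)


def _simulate_inputs(cfg: PipelineConfig, outdir: str):
    sim = dict(cfg.simulate or {})
    seed = cfg.seed
    length = int(sim.get("genome_length", 120_000))
    genes = syn.make_genes(seed + 11, length, int(sim.get("n_genes", 40)))
    gene_iv = [(int(r["start"]) - 60, int(r["end"]) + 60) for _, r in genes.iterrows()]
    genomes = syn.generate_genomes(
        seed,
        length,
        n_strains=int(sim.get("n_strains", 2)),
        snp_rate=float(sim.get("snp_rate", 0.005)),
        indel_rate=float(sim.get("indel_rate", 0.0002)),
        indel_size_max=int(sim.get("indel_size_max", 10)),
        indel_exclude=gene_iv,
    )
    landscape = syn.generate_landscape(
        seed + 1,
        genomes,
        fuzzy_fraction=float(sim.get("fuzzy_fraction", 0.05)),
        n_shifted=int(sim.get("n_shifted", 0)),
        shift_range=tuple(sim.get("shift_range", (20, 60))),
        n_evicted=int(sim.get("n_evicted", 0)),
        cur_min_length=int(cfg.thresholds["min_cur_length"]),
        cur_max_indel=int(cfg.thresholds["max_indel"]),
    )
    marks = list(sim.get("marks", ["H3K4me3", "H3K14ac"]))
    planted = sim.get("planted_sneps") or []
    readset = syn.simulate_reads(
        seed + 2,
        landscape,
        marks,
        int(sim.get("n_reads_per_sample", 100_000)),
        n_replicates=int(sim.get("n_replicates", 2)),
        genes=genes,
        planted_sneps=[(p[0], p[1], float(p[2])) for p in planted],
        dispersion=float(sim.get("dispersion", 0.05)),
    )
    # persist the simulated inputs so the run is re-doable from files
    for strain in genomes.strains:
        genomes.write_fasta(os.path.join(outdir, f"{strain}.fa"), strain)
    ref = genomes.reference
    align.write_blocks_tsv(
        genomes.blocks[(ref, genomes.strains[1])], os.path.join(outdir, "blocks.tsv")
    )
    write_gff3(genes, os.path.join(outdir, "genes.gff3"))
    blocks = genomes.blocks[(ref, genomes.strains[1])]
    return readset, blocks, genes


def run(cfg: PipelineConfig, until: str | None = None) -> dict:
    """Execute the pipeline; returns the manifest dict (also written to disk)."""
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    th = cfg.thresholds
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": th,
        "stages": {},
        "inputs": {},
    }

    if cfg.simulate is not None:
        readset, blocks, genes = _simulate_inputs(cfg, outdir)
    else:
        blocks = align.read_blocks_tsv(cfg.blocks)
        genes = read_gff3(cfg.genes)
        readset = load_readset(cfg.sample_sheet, cfg.contig_lengths or {})
        for name in ("sample_sheet", "blocks", "genes"):
            manifest["inputs"][name] = _sha256(getattr(cfg, name))

    stop_after = STAGES.index(until) if until else len(STAGES) - 1
    strains = list(readset.contig_lengths)
    marks = sorted({sid.mark for sid in readset.samples if sid.mark})

    # ---- stage: curs
    cur_set = align.build_curs(blocks, int(th["min_cur_length"]), int(th["max_indel"]))
    with open(os.path.join(outdir, "curs.bed"), "w") as fh:
        fh.write(cur_set.to_bed())
    with open(os.path.join(outdir, "curs_offsets.tsv"), "w") as fh:
        fh.write(cur_set.to_offset_table())
    manifest["stages"]["curs"] = {"n_curs": len(cur_set), "span": cur_set.total_source_span}
    if stop_after < 1:
        return _finish(manifest, outdir)

    # ---- stage: coverage
    cov = covmod.chunk_coverage(readset, cur_set, chunk_size=int(th["chunk"]))
    qc = covmod.qc_replicates(cov, threshold=float(th["qc_threshold"]))
    qc.to_csv(os.path.join(outdir, "qc.tsv"), sep="\t")
    bad_groups = [
        g
        for g, grp in qc.groupby(["strain", "assay", "mark"])
        if (grp["verdict"] == "flagged").all() and len(grp) > 1
    ]
    if bad_groups:
        raise RuntimeError(
            f"all replicates flagged in group(s) {bad_groups}; aborting"
        )
    keep = qc.index[qc["verdict"] != "flagged"]
    cov.values.drop(columns=[c for c in cov.values if c not in set(keep)], inplace=True)
    cov.samples.drop(index=[c for c in cov.samples.index if c not in set(keep)], inplace=True)
    pca = covmod.pca_components(
        cov, n_permutations=int(th["permutations"]), seed=cfg.seed + 101
    )
    cov.values.to_csv(os.path.join(outdir, "coverage.tsv"), sep="\t")
    pd.DataFrame(
        {
            "variance_fraction": pca.variance_fraction,
            "significant": pca.significant,
        }
    ).to_csv(os.path.join(outdir, "pca.tsv"), sep="\t")
    manifest["stages"]["coverage"] = {
        "n_chunks": len(cov.chunks),
        "n_samples": cov.values.shape[1],
        "n_significant_components": pca.n_significant,
        "flagged": list(qc.index[qc["verdict"] == "flagged"]),
    }
    if stop_after < 2:
        return _finish(manifest, outdir)

    # ---- stage: nucmap
    maps = {s: nmmod.build_map(readset, s) for s in strains[:2]}
    match = nmmod.match_maps(maps[strains[0]], maps[strains[1]], cur_set)
    div = nmmod.divergence_analysis(
        match,
        maps[strains[0]],
        maps[strains[1]],
        cur_set,
        shift_threshold=int(th["shift_threshold"]),
    )
    ann, slots = nmmod.annotate_calls(maps[strains[0]], genes, cur_set=cur_set)
    for s, nm in maps.items():
        with open(os.path.join(outdir, f"nucmap_{s}.bed"), "w") as fh:
            for cid, row in nm.wells.iterrows():
                d = int(row["dyad"])
                fh.write(f"{nm.contig}\t{d - 73}\t{d + 74}\t{cid}:well\n")
            for cid, row in nm.fuzzy.iterrows():
                fh.write(f"{nm.contig}\t{int(row['start'])}\t{int(row['end'])}\t{cid}:fuzzy\n")
    match.pairs.to_csv(os.path.join(outdir, "pairs.tsv"), sep="\t", index=False)
    match.unrs.to_csv(os.path.join(outdir, "unrs.tsv"), sep="\t")
    ann.to_csv(os.path.join(outdir, "annotations.tsv"), sep="\t")
    manifest["stages"]["nucmap"] = {
        "wells": {s: len(m.wells) for s, m in maps.items()},
        "fuzzy": {s: len(m.fuzzy) for s, m in maps.items()},
        "pairs": len(match.pairs),
        "unrs": len(match.unrs),
        "shifted": len(div.shifted_pairs),
        "diverged_subpopulation": len(div.subpopulation),
    }
    if stop_after < 3:
        return _finish(manifest, outdir)

    # ---- stage: snep
    counts, unit_meta = snepmod.extract_counts(readset, match)
    sf = snepmod.size_factors(counts)
    snep_frames = []
    for mark in marks:
        cols = [
            c
            for c in counts.columns
            if c[1] == "MNase" or (c[1] == "ChIP" and c[2] == mark)
        ]
        sub = counts[cols]
        res = snepmod.test_interaction_table(
            sub, strains=(strains[0], strains[1]), sf=sf[cols]
        )
        res["called"] = snepmod.call_sneps(
            res["p_interaction"].to_numpy(), fdr=float(th["fdr"])
        )
        res.insert(0, "mark", mark)
        snep_frames.append(res)
    snep_table = pd.concat(snep_frames)
    snep_table.to_csv(os.path.join(outdir, "sneps.tsv"), sep="\t")
    manifest["stages"]["snep"] = {
        "n_units": len(counts),
        "n_called": {
            m: int(snep_table[snep_table["mark"] == m]["called"].sum()) for m in marks
        },
    }
    if stop_after < 4:
        return _finish(manifest, outdir)

    # ---- stage: genediv
    sf_by_label = {
        SampleId(s, a, m if m else None, r).label: v
        for (s, a, m, r), v in sf.items()
    }
    profiles = gdmod.bin_genes(readset, genes, cur_set, sf=sf_by_label)
    epidivs = gdmod.epidiv_table(profiles)
    epidivs.to_csv(os.path.join(outdir, "epidiv.tsv"), sep="\t")
    clusters = None
    if len(marks) >= 1 and len(profiles.genes) >= 2:
        patterns = gdmod.differential_patterns(profiles, (strains[0], strains[1]))
        clusters = patterns.cut(min(8, len(patterns.genes)))
        clusters.to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    delta_mark = "H3K14ac" if "H3K14ac" in marks else marks[0]
    d = (
        profiles.log_ratio(strains[1], delta_mark)
        - profiles.log_ratio(strains[0], delta_mark)
    )
    delta, selected = gdmod.delta_select(
        pd.DataFrame(d, index=profiles.genes.index), cutoff=float(th["delta_cutoff"])
    )
    pd.DataFrame({"delta": delta, "selected": selected}).to_csv(
        os.path.join(outdir, "delta.tsv"), sep="\t"
    )
    manifest["stages"]["genediv"] = {
        "n_genes": len(profiles.genes),
        "n_excluded": len(profiles.excluded),
        "median_epidiv": float(np.nanmedian(epidivs)) if len(epidivs) else None,
        "n_delta_selected": int(selected.sum()),
    }
    if stop_after < 5:
        return _finish(manifest, outdir)

    # ---- stage: covary
    pair_units = snep_table.loc[snep_table.index.str.startswith("pair:")]
    cov_stats = {}
    if len(marks) >= 2:
        first = pair_units[pair_units["mark"] == marks[0]]
        second = pair_units[pair_units["mark"] == marks[1]].reindex(first.index)
        res = covarymod.snep_covariation(
            first["called"].to_numpy(),
            first["direction"].to_numpy(),
            second["p_interaction"].to_numpy(),
            second["direction"].to_numpy(),
            p_threshold=float(th["p"]),
        )
        cov_stats["covariation_fraction"] = res.fraction
        cov_stats["covariation_p"] = res.pvalue
    first_mark = pair_units[pair_units["mark"] == marks[0]]
    if first_mark["called"].sum() >= 2:
        reg = covarymod.regionality(
            first_mark["called"].to_numpy(),
            window=int(th["window"]),
            seed=cfg.seed + 77,
        )
        pd.DataFrame(
            {
                "offset": reg.offsets,
                "observed": reg.observed,
                "random_mean": reg.randomized_mean,
            }
        ).to_csv(os.path.join(outdir, "regionality.tsv"), sep="\t", index=False)
        cov_stats["regionality_written"] = True
    manifest["stages"]["covary"] = cov_stats or {"skipped": "insufficient SNEPs"}
    return _finish(manifest, outdir)


def _finish(manifest: dict, outdir: str) -> dict:
    manifest["complete"] = list(manifest["stages"])
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
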