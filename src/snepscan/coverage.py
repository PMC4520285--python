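"""Chunked coverage profiles over CURs, replicate QC, and permutation PCA."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import CurSet

__all__ = [
    "CoverageMatrix",
    "PCAResult",
    "chunk_coverage",
    "qc_replicates",
    "pca_components",
    "mnase_normalize",
]


@dataclass
class CoverageMatrix:
    """Per-chunk, per-sample forward-read-start density.

    ``values[chunk, sample]`` is reads-per-million divided by the chunk's
    effective length in the sample's own genome.  ``chunks`` records the
    source-strain interval; ``strain_intervals[strain]`` the per-strain
    translated intervals and effective lengths.
    """

    values: pd.DataFrame  # chunks x samples
    chunks: pd.DataFrame  # cur_id, contig, start, end
    strain_intervals: dict[str, pd.DataFrame]  # strain -> start/end/length
    samples: pd.DataFrame  # sample -> strain, assay, mark, replicate

    def columns_for(self, strain=None, assay=None, mark=None) -> list[str]:
        m = self.samples
        mask = pd.Series(True, index=m.index)
        if strain is not None:
            mask &= m["strain"] == strain
        if assay is not None:
            mask &= m["assay"] == assay
        if mark is not None:
            mask &= m["mark"] == mark
        return list(m.index[mask])


def _chunk_bounds(cur, chunk_size: int):
    bounds = list(range(cur.source_start, cur.source_end, chunk_size))
    bounds.append(cur.source_end)
    return np.asarray(bounds)


def chunk_coverage(
    readset,
    cur_set: CurSet,
    source_strain: str | None = None,
    target_strain: str | None = None,
    chunk_size: int = 90,
) -> CoverageMatrix:
    """Segment every CUR into ``chunk_size``-bp chunks and count forward
    read starts per chunk, per million reads, per effective bp."""
    strains = list(readset.contig_lengths)
    source_strain = source_strain or strains[0]
    target_strain = target_strain or strains[1]

    rows = []
    src_left, src_right = [], []
    tgt_left, tgt_right = [], []
    for cur in cur_set:
        b = _chunk_bounds(cur, chunk_size)
        for i in range(len(b) - 1):
            lo, hi = int(b[i]), int(b[i + 1])
            t_lo = cur.translate_forward(lo)
            t_hi = cur.translate_forward(hi - 1) + 1
            rows.append((cur.id, cur.source_contig, lo, hi))
            src_left.append(lo)
            src_right.append(hi)
            tgt_left.append(t_lo)
            tgt_right.append(max(t_hi, t_lo + 1))
    chunks = pd.DataFrame(rows, columns=["cur_id", "contig", "start", "end"])
    chunks.index.name = "chunk"
    intervals = {
        source_strain: pd.DataFrame(
            {"start": src_left, "end": src_right}
        ),
        target_strain: pd.DataFrame({"start": tgt_left, "end": tgt_right}),
    }
    for df in intervals.values():
        df["length"] = df["end"] - df["start"]

    values = {}
    meta_rows = []
    for sid, starts in readset.samples.items():
        total = len(starts)
        if total == 0:
            raise ValueError(f"sample {sid.label} has zero forward reads")
        if sid.strain not in intervals:
            continue
        iv = intervals[sid.strain]
        left = np.searchsorted(starts, iv["start"].to_numpy(), side="left")
        right = np.searchsorted(starts, iv["end"].to_numpy(), side="left")
        counts = (right - left).astype(float)
        values[sid.label] = counts / total * 1e6 / iv["length"].to_numpy()
        meta_rows.append((sid.label, sid.strain, sid.assay, sid.mark or "", sid.replicate))

    samples = pd.DataFrame(
        meta_rows, columns=["sample", "strain", "assay", "mark", "replicate"]
    ).set_index("sample")
    return CoverageMatrix(pd.DataFrame(values), chunks, intervals, samples)


def qc_replicates(cov: CoverageMatrix, threshold: float = 0.25) -> pd.DataFrame:
    """Flag replicates whose coverage distribution markedly deviates from
    their group's median profile (distance = 1 - Spearman of log1p values)."""
    verdicts = []
    for (strain, assay, mark), grp in cov.samples.groupby(
        ["strain", "assay", "mark"], sort=False
    ):
        cols = list(grp.index)
        if len(cols) < 2:
            for c in cols:
                verdicts.append((c, strain, assay, mark, np.nan, "unevaluable"))
            continue
        block = np.log1p(cov.values[cols].to_numpy())
        median = np.median(block, axis=1)
        for j, c in enumerate(cols):
            rho = stats.spearmanr(block[:, j], median).statistic
            dist = 1.0 - rho if np.isfinite(rho) else np.nan
            flagged = (not np.isfinite(dist)) or dist > threshold
            verdicts.append(
                (c, strain, assay, mark, dist, "flagged" if flagged else "ok")
            )
    out = pd.DataFrame(
        verdicts, columns=["sample", "strain", "assay", "mark", "distance", "verdict"]
    ).set_index("sample")
    return out


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    variance_fraction: np.ndarray
    significant: np.ndarray  # bool per component
    permuted_max: np.ndarray
    sample_names: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _column_normalize(X: np.ndarray) -> np.ndarray:
    sums = X.sum(axis=0)
    sums[sums == 0] = 1.0
    return X / sums


def _varfracs(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA on samples-as-observations; returns (variance fractions, scores)."""
    Y = X.T - X.T.mean(axis=0)
    u, s, _ = np.linalg.svd(Y, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-12 * max((X**2).sum(), 1e-300):
        return np.zeros(0), np.zeros((X.shape[1], 0))
    k = min(X.shape[1] - 1, len(s))
    return var[:k] / total, (u * s)[:, :k]


def pca_components(
    cov,
    n_permutations: int = 3,
    seed: int = 0,
    log: bool = False,
    normalize: bool = True,
) -> PCAResult:
    """PCA of the column-normalized coverage matrix with permutation-based
    component significance: component k is significant iff its variance
    fraction exceeds the max variance fraction of component k over
    ``n_permutations`` chunk-wise permuted datasets, and every earlier
    component is significant too (sequential stopping)."""
    if isinstance(cov, CoverageMatrix):
        X = cov.values.to_numpy(dtype=float)
        names = list(cov.values.columns)
    else:
        X = np.asarray(cov, dtype=float)
        names = [f"s{i}" for i in range(X.shape[1])]
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    if log:
        X = np.log1p(X)
    if normalize:
        X = _column_normalize(X)

    vf, scores = _varfracs(X)
    if len(vf) == 0:
        return PCAResult(
            np.zeros((X.shape[1], 0)),
            np.zeros(0),
            np.zeros(0, dtype=bool),
            np.zeros(0),
            names,
            degenerate=True,
        )

    rng = np.random.default_rng(seed)
    perm_max = np.zeros(len(vf))
    for _ in range(n_permutations):
        order = np.argsort(rng.random(X.shape), axis=1)
        Xp = np.take_along_axis(X, order, axis=1)
        vfp, _ = _varfracs(Xp)
        k = min(len(vfp), len(perm_max))
        perm_max[:k] = np.maximum(perm_max[:k], vfp[:k])

    # sequential flagging: stop at the first component that fails, so a
    # chance excess at some deep rank never counts as signal
    significant = np.zeros(len(vf), dtype=bool)
    for k in range(len(vf)):
        if vf[k] > perm_max[k]:
            significant[k] = True
        else:
            break
    return PCAResult(scores, vf, significant, perm_max, names)


def mnase_normalize(cov: CoverageMatrix, epsilon: float = 1e-8) -> CoverageMatrix:
    """Divide each ChIP column by its strain's mean MNase profile.

    Columns are first normalized to unit sum (so rescaling raw depth has no
    effect); chunks whose MNase value falls below ``epsilon`` times the mean
    chunk level are masked with NaN instead of divided.
    """
    norm = _column_normalize(cov.values.to_numpy(dtype=float))
    normed = pd.DataFrame(norm, index=cov.values.index, columns=cov.values.columns)

    out = {}
    meta_rows = []
    for strain in cov.samples["strain"].unique():
        mnase_cols = cov.columns_for(strain=strain, assay="MNase")
        if not mnase_cols:
            raise ValueError(f"strain {strain} has no MNase sample")
        mnase = normed[mnase_cols].mean(axis=1).to_numpy()
        floor = epsilon * max(mnase.mean(), 1e-300)
        mask = mnase < floor
        for col in cov.columns_for(strain=strain, assay="ChIP"):
            ratio = np.where(mask, np.nan, normed[col].to_numpy() / np.where(mask, 1.0, mnase))
            out[col] = ratio
            meta_rows.append(col)

    values = pd.DataFrame(out, index=cov.values.index)
    samples = cov.samples.loc[meta_rows]
    return CoverageMatrix(values, cov.chunks, cov.strain_intervals, samples)
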