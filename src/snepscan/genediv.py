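"""Gene-level epigenomic divergence.

600-bin gene profiles (250 upstream 10-bp bins, 100 TSS-to-TES percentile
bins, 250 downstream 10-bp bins), differential-pattern clustering, the
*epidiv* ANOVA statistic, delta-based gene selection, subset distribution
tests, covariate associations and the metaphenotype QTL scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .align import CurSet

N_BODY = 100
N_FLANK = 250
FLANK_BIN = 10
N_BINS = N_FLANK + N_BODY + N_FLANK  # 600; bin 251 abuts the TSS

__all__ = [
    "GeneProfiles",
    "EpidivResult",
    "LinkageScan",
    "bin_genes",
    "differential_patterns",
    "epidiv",
    "epidiv_table",
    "delta_select",
    "subset_shift_test",
    "qtl_scan",
    "covariate_assoc",
]


def body_bin_widths(length: int, n_body: int = N_BODY) -> np.ndarray:
    """Even integer partition of a gene body; remainder goes to 5' bins."""
    base, rem = divmod(length, n_body)
    w = np.full(n_body, base, dtype=int)
    w[:rem] += 1
    return w


def _gene_bin_intervals(start: int, end: int, strand: str) -> np.ndarray:
    """(600, 2) genomic [lo, hi) intervals in 5'->3' bin order."""
    length = end - start
    widths = body_bin_widths(length)
    # oriented offsets from the TSS, bin edges
    edges = np.empty(N_BINS + 1, dtype=int)
    edges[: N_FLANK + 1] = np.arange(-N_FLANK * FLANK_BIN, 1, FLANK_BIN)
    edges[N_FLANK : N_FLANK + N_BODY + 1] = np.concatenate(
        [[0], np.cumsum(widths)]
    )
    edges[N_FLANK + N_BODY :] = length + np.arange(0, (N_FLANK + 1) * FLANK_BIN, FLANK_BIN)
    lo, hi = edges[:-1], edges[1:]
    if strand == "+":
        return np.column_stack([start + lo, start + hi])
    return np.column_stack([end - hi, end - lo])


@dataclass
class GeneProfiles:
    """Replicate-averaged 600-bin coverage per gene x strain x mark."""

    genes: pd.DataFrame  # retained genes (annotation columns)
    data: dict[tuple[str, str], np.ndarray]  # (strain, mark|"MNase") -> (n_genes, 600)
    excluded: pd.DataFrame  # gene_id -> reason
    strains: list[str] = field(default_factory=list)
    marks: list[str] = field(default_factory=list)

    def log_ratio(self, strain: str, mark: str, eps: float = 1e-3) -> np.ndarray:
        chip = self.data[(strain, mark)]
        mnase = self.data[(strain, "MNase")]
        return np.log2((chip + eps) / (mnase + eps))

    def meta_profile(self, strain: str, mark: str) -> np.ndarray:
        return np.nanmean(self.data[(strain, mark)], axis=0)


def bin_genes(
    readset,
    genes: pd.DataFrame,
    cur_set: CurSet,
    sf: dict | pd.Series | None = None,
    min_length: int = 100,
) -> GeneProfiles:
    """Bin per-million read-start coverage into 600 bins per gene.

    Genes shorter than ``min_length`` bp or not fully inside a CUR are
    excluded.  Flank bins falling outside the gene's CUR, or untranslatable
    in a sample's strain, are NaN.  Values are reads per million per bp,
    divided by the sample's size factor, averaged over replicates.
    """
    strains = list(readset.contig_lengths)
    source = strains[0]
    contig = readset.contig

    kept_rows, excl_rows = [], []
    intervals = {}
    for gid, g in genes.iterrows():
        if g["end"] - g["start"] <= min_length:
            excl_rows.append((gid, "too_short"))
            continue
        c1 = cur_set.find(contig, int(g["start"]))
        c2 = cur_set.find(contig, int(g["end"]) - 1)
        if c1 is None or c2 is None or c1.id != c2.id:
            excl_rows.append((gid, "outside_curs"))
            continue
        kept_rows.append(gid)
        intervals[gid] = _gene_bin_intervals(int(g["start"]), int(g["end"]), g["strand"])

    kept = genes.loc[kept_rows]
    excluded = pd.DataFrame(excl_rows, columns=["gene_id", "reason"]).set_index("gene_id")
    n_genes = len(kept)

    if n_genes == 0:
        return GeneProfiles(kept, {}, excluded, strains, [])

    # flatten bin bounds once per strain frame
    all_iv = np.concatenate([intervals[g] for g in kept.index])  # (n*600, 2)
    lo1, hi1 = all_iv[:, 0], all_iv[:, 1]
    strain_bounds = {source: (lo1.astype(float), hi1.astype(float))}
    if len(strains) > 1:
        t_lo = cur_set.translate_array(contig, lo1, "forward")
        t_hi = cur_set.translate_array(contig, hi1 - 1, "forward") + 1
        strain_bounds[strains[1]] = (t_lo, t_hi)

    marks = sorted(
        {sid.mark for sid in readset.samples if sid.mark is not None}
    )
    acc: dict[tuple[str, str], list[np.ndarray]] = {}
    for sid, starts in sorted(readset.samples.items()):
        if sid.strain not in strain_bounds:
            continue
        lo, hi = strain_bounds[sid.strain]
        valid = np.isfinite(lo) & np.isfinite(hi) & (hi > lo)
        vals = np.full(len(lo), np.nan)
        lo_v = lo[valid].astype(np.int64)
        hi_v = hi[valid].astype(np.int64)
        cnt = np.searchsorted(starts, hi_v) - np.searchsorted(starts, lo_v)
        factor = 1.0
        if sf is not None:
            factor = float(sf[sid.label]) if sid.label in sf else 1.0
        vals[valid] = cnt / len(starts) * 1e6 / (hi_v - lo_v) / factor
        key = (sid.strain, sid.mark or "MNase")
        acc.setdefault(key, []).append(vals.reshape(n_genes, N_BINS))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN flank bins
        data = {k: np.nanmean(np.stack(v), axis=0) for k, v in acc.items()}
    return GeneProfiles(kept, data, excluded, strains, marks)


# ----------------------------------------------------- differential patterns

TRUNC_FLANK = 50  # keep only 500 bp (50 bins) on either side of the body


@dataclass
class DiffPatterns:
    genes: pd.Index
    vectors: np.ndarray  # genes x (marks * 200)
    tree: np.ndarray  # scipy linkage matrix
    marks: list[str]

    def cut(self, k: int) -> pd.Series:
        return pd.Series(
            fcluster(self.tree, k, criterion="maxclust"), index=self.genes, name="cluster"
        )


def differential_patterns(
    profiles: GeneProfiles,
    strain_pair: tuple[str, str],
    marks: list[str] | None = None,
    eps: float = 1e-3,
    near_zero: float = 1e-3,
) -> DiffPatterns:
    """Per-gene concatenated strain1 - strain2 log-ratio difference vectors
    (5 marks x 200 bins each), clustered with complete linkage."""
    s1, s2 = strain_pair
    marks = marks or profiles.marks
    sel = np.r_[
        N_FLANK - TRUNC_FLANK : N_FLANK + N_BODY + TRUNC_FLANK
    ]

    # drop genes with near-zero ChIP signal for all marks in all strains
    signal = np.zeros(len(profiles.genes), dtype=bool)
    for s in (s1, s2):
        for m in marks:
            signal |= np.nanmean(profiles.data[(s, m)], axis=1) >= near_zero
    vecs = []
    for m in marks:
        d = profiles.log_ratio(s1, m, eps) - profiles.log_ratio(s2, m, eps)
        vecs.append(d[:, sel])
    V = np.concatenate(vecs, axis=1)[signal]
    genes = profiles.genes.index[signal]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with signal: cannot cluster")
    V = np.nan_to_num(V)
    tree = linkage(V, method="complete", metric="euclidean")
    return DiffPatterns(genes, V, tree, list(marks))


# ----------------------------------------------------------------- epidiv


@dataclass
class EpidivResult:
    epidiv: float
    table: pd.DataFrame  # term -> ss, df, ms


def epidiv(y: np.ndarray) -> EpidivResult:
    """Balanced sequential ANOVA of log-ratio ~ strain + mark + bin +
    strain:mark + strain:bin + strain:mark:bin; the mark:bin stratum is
    absent from the model, so the residual absorbs it.  epidiv is the F
    statistic of strain:mark against that residual.

    ``y`` has shape (strains, marks, bins), one observation per cell.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must be (strains, marks, bins)")
    if np.isnan(y).any():
        raise ValueError("missing cells: gene must be skipped")
    S, M, B = y.shape
    if S < 2 or M < 2 or B < 2:
        raise ValueError("need >= 2 strains, marks and bins")

    grand = y.mean()
    ys = y.mean(axis=(1, 2))
    ym = y.mean(axis=(0, 2))
    yb = y.mean(axis=(0, 1))
    ysm = y.mean(axis=2)
    ysb = y.mean(axis=1)
    ymb = y.mean(axis=0)

    ss_s = M * B * ((ys - grand) ** 2).sum()
    ss_m = S * B * ((ym - grand) ** 2).sum()
    ss_b = S * M * ((yb - grand) ** 2).sum()
    ss_sm = B * ((ysm - ys[:, None] - ym[None, :] + grand) ** 2).sum()
    ss_sb = M * ((ysb - ys[:, None] - yb[None, :] + grand) ** 2).sum()
    ss_mb = S * ((ymb - ym[:, None] - yb[None, :] + grand) ** 2).sum()  # residual
    ss_tot = ((y - grand) ** 2).sum()
    ss_smb = max(ss_tot - (ss_s + ss_m + ss_b + ss_sm + ss_sb + ss_mb), 0.0)

    rows = [
        ("strain", ss_s, S - 1),
        ("mark", ss_m, M - 1),
        ("bin", ss_b, B - 1),
        ("strain:mark", ss_sm, (S - 1) * (M - 1)),
        ("strain:bin", ss_sb, (S - 1) * (B - 1)),
        ("strain:mark:bin", ss_smb, (S - 1) * (M - 1) * (B - 1)),
        ("residual", ss_mb, (M - 1) * (B - 1)),
    ]
    table = pd.DataFrame(rows, columns=["term", "ss", "df"]).set_index("term")
    table["ms"] = table["ss"] / table["df"]
    f = float(table.loc["strain:mark", "ms"] / table.loc["residual", "ms"])
    return EpidivResult(f, table)


def epidiv_table(
    profiles: GeneProfiles,
    strains: list[str] | None = None,
    marks: list[str] | None = None,
    eps: float = 1e-3,
) -> pd.Series:
    """epidiv per gene from ChIP/MNase log ratios; unfit genes are NaN."""
    strains = strains or profiles.strains
    marks = marks or profiles.marks
    out = pd.Series(np.nan, index=profiles.genes.index, name="epidiv")
    ratios = {
        (s, m): profiles.log_ratio(s, m, eps) for s in strains for m in marks
    }
    for i, gid in enumerate(profiles.genes.index):
        y = np.stack(
            [[ratios[(s, m)][i] for m in marks] for s in strains]
        )
        if np.isnan(y).any():
            continue
        out.iloc[i] = epidiv(y).epidiv
    return out


# ----------------------------------------------------------- delta selection


def delta_select(
    d: np.ndarray | pd.DataFrame,
    r1: tuple[int, int] = (251, 266),
    r2: tuple[int, int] = (284, 333),
    cutoff: float = 10.0,
):
    """delta = median(d over R2) - median(d over R1) per gene (segments are
    1-based inclusive); selection is delta > cutoff."""
    arr = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d)
    if arr.ndim == 1:
        arr = arr[None, :]
    m1 = np.median(arr[:, r1[0] - 1 : r1[1]], axis=1)
    m2 = np.median(arr[:, r2[0] - 1 : r2[1]], axis=1)
    delta = m2 - m1
    if isinstance(d, pd.DataFrame):
        delta = pd.Series(delta, index=d.index, name="delta")
    return delta, delta > cutoff


def subset_shift_test(values: np.ndarray, subset_mask: np.ndarray):
    """Two-sample KS test of the subset's values against the complement.

    Comparing against the complement (rather than the full set, which
    contains the subset) keeps the two samples independent, so the null
    p-value is uniform.
    """
    values = np.asarray(values, dtype=float)
    subset_mask = np.asarray(subset_mask, dtype=bool)
    if subset_mask.sum() == 0:
        raise ValueError("subset is empty")
    if subset_mask.all():
        raise ValueError("subset equals the whole set")
    res = stats.ks_2samp(values[subset_mask], values[~subset_mask])
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------- QTL scan


@dataclass
class LinkageScan:
    scores: pd.Series  # per marker, -log10(p); NaN at monomorphic markers
    threshold: float  # max genome-wide score over permuted scans
    metaphenotypes: np.ndarray  # segregants x components used
    variance_fraction: np.ndarray
    n_significant_components: int

    @property
    def significant_markers(self) -> pd.Index:
        return self.scores.index[self.scores > self.threshold]


def _ranksum_scores(pheno: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """-log10 two-sided Wilcoxon rank-sum p per marker (normal approx)."""
    n = len(pheno)
    r = stats.rankdata(pheno)
    n1 = geno.sum(axis=0).astype(float)
    n0 = n - n1
    T = geno.T.astype(float) @ r
    mu = n1 * (n + 1) / 2.0
    _, t_counts = np.unique(pheno, return_counts=True)
    tie = (t_counts**3 - t_counts).sum() / (n * (n - 1.0))
    var = n0 * n1 / 12.0 * ((n + 1.0) - tie)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (T - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    score = -np.log10(np.clip(p, 1e-300, None))
    score[(n1 == 0) | (n0 == 0)] = np.nan
    return score


def qtl_scan(
    values: dict[str, np.ndarray],
    genotypes: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
    n_metaphenotypes: int = 2,
    pca_permutations: int = 3,
) -> LinkageScan:
    """Metaphenotype linkage scan with a permutation-derived threshold.

    Per gene and segregant, nucleosome values are ranked across segregants;
    the phenotype is the mean rank over the second half of the gene-body
    nucleosomes minus the first half.  A PCA across genes yields
    metaphenotypes (components passing the permutation significance rule,
    capped at ``n_metaphenotypes``; PC1 if none pass).  Each marker is
    scored by a Wilcoxon rank-sum of metaphenotype values by genotype; the
    genome-wide threshold is the max score over ``n_permutations``
    genotype-permuted scans.
    """
    from .coverage import pca_components

    n_seg = genotypes.shape[0]
    if n_seg < 10:
        raise ValueError("scan refuses to run with fewer than 10 segregants")
    if not values:
        raise ValueError("no genes selected for the scan")

    phen = np.empty((n_seg, len(values)))
    for j, (_gene, v) in enumerate(sorted(values.items())):
        if v.shape[0] != n_seg:
            raise ValueError("value matrix rows must equal segregants")
        ranks = stats.rankdata(v, axis=0)
        half = v.shape[1] // 2
        phen[:, j] = ranks[:, half:].mean(axis=1) - ranks[:, :half].mean(axis=1)

    pca = pca_components(
        phen.T, n_permutations=pca_permutations, seed=seed, normalize=False
    )
    if pca.degenerate:
        raise ValueError("degenerate phenotype matrix")
    sig = np.flatnonzero(pca.significant)[:n_metaphenotypes]
    comps = sig if len(sig) else np.array([0])
    metas = pca.scores[:, comps]

    geno = genotypes.to_numpy(dtype=np.int8)
    mono = (geno.sum(axis=0) == 0) | (geno.sum(axis=0) == n_seg)

    def scan(g):
        per_meta = np.stack([_ranksum_scores(metas[:, k], g) for k in range(metas.shape[1])])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN markers
            return np.nanmax(per_meta, axis=0)

    with np.errstate(invalid="ignore"):
        obs = scan(geno)
    obs[mono] = np.nan

    rng = np.random.default_rng(seed)
    threshold = 0.0
    for _ in range(n_permutations):
        perm = rng.permutation(n_seg)
        s = scan(geno[perm])
        s[mono] = np.nan
        if np.isfinite(s).any():
            threshold = max(threshold, float(np.nanmax(s)))

    scores = pd.Series(obs, index=genotypes.columns, name="linkage_score")
    return LinkageScan(scores, threshold, metas, pca.variance_fraction, len(sig))


# -------------------------------------------------------------- covariates


@dataclass
class AssocResult:
    kind: str  # "spearman" or "wilcoxon"
    statistic: float
    pvalue: float
    curve: pd.DataFrame | None = None


def covariate_assoc(
    values: pd.Series,
    covariate: pd.Series,
    test: str | None = None,
    smooth_window: int | None = None,
) -> AssocResult:
    """Rank correlation (continuous covariate) or two-group Wilcoxon test
    (binary covariate) of per-gene divergence values, plus a smoothed curve."""
    joined = pd.concat([values, covariate], axis=1, join="inner").dropna()
    if len(joined) < 10:
        raise ValueError("need >= 10 genes with both values")
    v = joined.iloc[:, 0].to_numpy(dtype=float)
    c = joined.iloc[:, 1].to_numpy()
    uniq = pd.unique(c)
    if len(uniq) < 2:
        raise ValueError("constant covariate")
    if test is None:
        test = "two-group" if len(uniq) == 2 else "rank-correlation"

    if test == "two-group":
        g0, g1 = v[c == uniq[0]], v[c == uniq[1]]
        res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        return AssocResult("wilcoxon", float(res.statistic), float(res.pvalue))

    res = stats.spearmanr(c.astype(float), v)
    order = np.argsort(c.astype(float))
    w = smooth_window or max(10, len(v) // 20)
    sm = pd.Series(v[order]).rolling(w, center=True, min_periods=1).mean()
    curve = pd.DataFrame(
        {"covariate": c.astype(float)[order], "smoothed": sm.to_numpy()}
    )
    return AssocResult("spearman", float(res.statistic), float(res.pvalue), curve)
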