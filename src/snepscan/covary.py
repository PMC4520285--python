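"""Co-variation and regionality of per-nucleosome mark differences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mark_correlation",
    "snep_covariation",
    "regionality",
    "class_enrichment",
    "persistence_covariation",
]


def mark_correlation(signal: pd.DataFrame, min_nucleosomes: int = 100) -> pd.DataFrame:
    """Spearman matrix of per-nucleosome ChIP/MNase signal across marks.

    Rows are nucleosomes, columns marks.  Marks with constant signal get a
    masked (NaN) row/column.
    """
    complete = signal.dropna()
    if len(complete) < min_nucleosomes:
        raise ValueError(
            f"need >= {min_nucleosomes} nucleosomes with signal in all marks"
        )
    corr = complete.corr(method="spearman")
    for m in complete.columns:
        if complete[m].nunique() == 1:
            corr.loc[m, :] = np.nan
            corr.loc[:, m] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class CovariationResult:
    fraction: float | None  # None when the SNEP set is empty
    n_covarying: int
    n_sneps: int
    odds_ratio: float
    pvalue: float
    table: np.ndarray  # 2x2 contingency (snep/non-snep x covary/not)


def snep_covariation(
    snep_mask: np.ndarray,
    direction1: np.ndarray,
    p2: np.ndarray,
    direction2: np.ndarray,
    p_threshold: float = 0.01,
) -> CovariationResult:
    """Fraction of mark-1 SNEPs whose mark-2 divergence is significant at
    ``p_threshold`` in the same direction, with a one-sided Fisher exact
    enrichment test against non-SNEP nucleosomes.  Zero directions (exact
    ties) never count as co-varying."""
    snep_mask = np.asarray(snep_mask, dtype=bool)
    covary = (
        (np.asarray(p2) < p_threshold)
        & (np.sign(direction2) == np.sign(direction1))
        & (np.sign(direction1) != 0)
    )
    a = int((covary & snep_mask).sum())
    b = int((~covary & snep_mask).sum())
    c = int((covary & ~snep_mask).sum())
    d = int((~covary & ~snep_mask).sum())
    table = np.array([[a, b], [c, d]])
    if snep_mask.sum() == 0:
        return CovariationResult(None, 0, 0, np.nan, np.nan, table)
    odds, p = stats.fisher_exact(table, alternative="greater")
    return CovariationResult(
        a / snep_mask.sum(), a, int(snep_mask.sum()), float(odds), float(p), table
    )


@dataclass
class RegionalityResult:
    offsets: np.ndarray  # -window..-1, 1..window
    observed: np.ndarray  # fraction of SNEPs whose k-th neighbor is an SNEP
    randomized_mean: np.ndarray
    randomized_low: np.ndarray  # 2.5% envelope
    randomized_high: np.ndarray  # 97.5% envelope


def _neighbor_profile(order_contigs, snep_mask, window):
    """Fraction of SNEPs whose k-th ordinal neighbor is also an SNEP."""
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    hits = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    for idx in order_contigs:
        m = snep_mask[idx]
        s = np.flatnonzero(m)
        n = len(idx)
        for j, k in enumerate(offsets):
            nb = s + k
            ok = (nb >= 0) & (nb < n)
            counts[j] += ok.sum()
            hits[j] += m[nb[ok]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return offsets, np.where(counts > 0, hits / counts, np.nan)


def regionality(
    snep_mask: np.ndarray,
    contigs: np.ndarray | None = None,
    window: int = 10,
    n_randomizations: int = 100,
    seed: int = 0,
    universe_mask: np.ndarray | None = None,
) -> RegionalityResult:
    """Neighbor-frequency profile of SNEPs over ordered nucleosomes, with a
    label-reassignment randomization envelope.

    ``snep_mask`` follows genome order; ``contigs`` delimits contigs
    (windows never cross a boundary).  ``universe_mask`` optionally
    restricts random reassignment to, e.g., nucleosomes with
    above-background ChIP signal.
    """
    snep_mask = np.asarray(snep_mask, dtype=bool)
    n = len(snep_mask)
    if snep_mask.sum() < 2:
        raise ValueError("need at least 2 SNEPs for a regionality profile")
    if contigs is None:
        groups = [np.arange(n)]
    else:
        contigs = np.asarray(contigs)
        groups = [np.flatnonzero(contigs == c) for c in pd.unique(contigs)]
    universe = (
        np.ones(n, dtype=bool) if universe_mask is None else np.asarray(universe_mask, bool)
    )
    if not snep_mask[~universe].sum() == 0:
        raise ValueError("every SNEP must lie inside the randomization universe")

    offsets, observed = _neighbor_profile(groups, snep_mask, window)

    rng = np.random.default_rng(seed)
    k = int(snep_mask.sum())
    pool = np.flatnonzero(universe)
    rand = np.empty((n_randomizations, len(offsets)))
    for r in range(n_randomizations):
        m = np.zeros(n, dtype=bool)
        m[rng.choice(pool, size=k, replace=False)] = True
        _, rand[r] = _neighbor_profile(groups, m, window)
    return RegionalityResult(
        offsets,
        observed,
        np.nanmean(rand, axis=0),
        np.nanquantile(rand, 0.025, axis=0),
        np.nanquantile(rand, 0.975, axis=0),
    )


@dataclass
class EnrichmentResult:
    frequencies: pd.Series  # per-class call frequency
    table: pd.DataFrame  # 2 x k contingency
    statistic: float
    pvalue: float
    method: str  # "chi2" or "exact"


def class_enrichment(
    calls: np.ndarray,
    class_labels: np.ndarray,
    seed: int = 0,
    n_resamples: int = 10000,
) -> EnrichmentResult:
    """Per-class call frequency with a chi-square independence test
    (exact / Monte Carlo fallback when any expected cell is < 5)."""
    calls = np.asarray(calls, dtype=bool)
    labels = pd.Series(class_labels)
    classes = [c for c in labels.unique() if (labels == c).sum() > 0]
    if len(classes) < 2:
        raise ValueError("need at least 2 non-empty classes")
    tab = pd.DataFrame(
        {
            c: [int(calls[(labels == c).to_numpy()].sum()), int((~calls)[(labels == c).to_numpy()].sum())]
            for c in classes
        },
        index=["called", "not_called"],
    )
    freqs = tab.loc["called"] / tab.sum(axis=0)

    obs = tab.to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(obs)
    method = "chi2"
    if (expected < 5).any():
        if obs.shape == (2, 2):
            _, p = stats.fisher_exact(obs)
            method = "exact"
        else:
            res = stats.chi2_contingency(obs)
            rng = np.random.default_rng(seed)
            # Monte Carlo exact test under fixed margins
            flat_calls = calls.to_numpy() if hasattr(calls, "to_numpy") else calls
            count = 0
            lab_arr = labels.to_numpy()
            for _ in range(n_resamples):
                perm = rng.permutation(flat_calls)
                t = np.array(
                    [
                        [perm[lab_arr == c].sum(), (~perm[lab_arr == c]).sum()]
                        for c in classes
                    ]
                ).T
                c2 = stats.chi2_contingency(t)[0]
                count += c2 >= res[0]
            p = (count + 1) / (n_resamples + 1)
            method = "exact"
    return EnrichmentResult(freqs, tab, float(chi2), float(p), method)


def persistence_covariation(
    persistence: np.ndarray,
    covary_flags: np.ndarray,
    strata: np.ndarray | None = None,
) -> pd.DataFrame:
    """Chi-square independence of persistence x co-variation per stratum
    (Fisher exact when a margin is tiny).  Returns one row per stratum."""
    persistence = pd.Series(persistence)
    covary_flags = np.asarray(covary_flags, dtype=bool)
    strata = pd.Series(["all"] * len(persistence) if strata is None else strata)

    rows = []
    for name in strata.unique():
        m = (strata == name).to_numpy()
        pers = persistence[m].to_numpy()
        cov = covary_flags[m]
        tab = np.array(
            [
                [int(cov[pers == "persistent"].sum()), int((~cov)[pers == "persistent"].sum())],
                [int(cov[pers == "labile"].sum()), int((~cov)[pers == "labile"].sum())],
            ]
        )
        if tab.sum(axis=1).min() < 2 or tab.sum(axis=0).min() < 2:
            if tab.sum() == 0:
                rows.append((name, np.nan, np.nan, "unevaluable", tab))
                continue
            _, p = stats.fisher_exact(tab)
            rows.append((name, np.nan, float(p), "exact", tab))
            continue
        try:
            chi2, p, _, expected = stats.chi2_contingency(tab)
            if (expected < 5).any():
                _, p = stats.fisher_exact(tab)
                rows.append((name, float(chi2), float(p), "exact", tab))
            else:
                rows.append((name, float(chi2), float(p), "chi2", tab))
        except ValueError:
            rows.append((name, np.nan, np.nan, "unevaluable", tab))
    return pd.DataFrame(
        rows, columns=["stratum", "statistic", "pvalue", "method", "table"]
    ).set_index("stratum")
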