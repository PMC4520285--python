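"""Single-nucleosome epi-polymorphism detection.

Counts are modeled with a negative-binomial GLM (log link, per-sample
size-factor offsets).  The SNEP test is a 1-df likelihood-ratio test of the
strain x assay interaction: a differential ChIP signal that is *not*
explained by a matching differential MNase (occupancy) signal.  Direction is
the sign of the interaction coefficient; positive means higher
ChIP-per-occupancy in the second strain.  The occupancy-only test is the
same machinery on MNase counts with a strain main effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _glm
from .nucmap import FOOTPRINT_HALF, MatchResult

__all__ = [
    "extract_counts",
    "size_factors",
    "estimate_dispersions",
    "test_interaction",
    "test_occupancy",
    "test_interaction_table",
    "call_sneps",
]


def extract_counts(readset, match: MatchResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count forward read starts per testable unit per sample.

    Pairs are counted in ``[dyad - 73, dyad + 74)`` in each strain's own
    coordinates; UNRs in their per-strain intervals.  UNRs lacking a
    translated interval are excluded (returned in the units frame with
    ``included=False``).
    """
    strain1, strain2 = match.strain1, match.strain2
    units = []
    iv = {strain1: [], strain2: []}
    for _, row in match.pairs.iterrows():
        units.append((f"pair:{row['id1']}|{row['id2']}", "pair", True))
        d1, d2 = int(row["dyad1"]), int(row["dyad2"])
        iv[strain1].append((d1 - FOOTPRINT_HALF, d1 + FOOTPRINT_HALF + 1))
        iv[strain2].append((d2 - FOOTPRINT_HALF, d2 + FOOTPRINT_HALF + 1))
    for uid, row in match.unrs.iterrows():
        ok = row["start2"] >= 0
        units.append((f"unr:{uid}", "unr", bool(ok)))
        iv[strain1].append((int(row["start"]), int(row["end"])))
        iv[strain2].append((int(row["start2"]), int(row["end2"])) if ok else (0, 0))

    unit_meta = pd.DataFrame(units, columns=["unit_id", "kind", "included"]).set_index(
        "unit_id"
    )
    bounds = {
        s: (np.array([a for a, _ in v]), np.array([b for _, b in v]))
        for s, v in iv.items()
    }

    data = {}
    for sid, starts in sorted(readset.samples.items()):
        if sid.strain not in bounds:
            continue
        lo, hi = bounds[sid.strain]
        counts = np.searchsorted(starts, hi, side="left") - np.searchsorted(
            starts, lo, side="left"
        )
        data[(sid.strain, sid.assay, sid.mark or "", sid.replicate)] = counts

    counts = pd.DataFrame(data, index=unit_meta.index)
    counts.columns = pd.MultiIndex.from_tuples(
        counts.columns, names=["strain", "assay", "mark", "replicate"]
    )
    keep = unit_meta["included"].to_numpy()
    return counts.loc[keep], unit_meta


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors (one per sample column)."""
    X = counts.to_numpy(dtype=float)
    if X.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    all_pos = (X > 0).all(axis=1)
    if all_pos.sum() == 0:
        warnings.warn(
            "no unit with positive counts in every sample; "
            "falling back to total-count size factors"
        )
        totals = X.sum(axis=0)
        return pd.Series(totals / np.exp(np.mean(np.log(totals))), index=counts.columns)
    logs = np.log(X[all_pos])
    log_gm = logs.mean(axis=1, keepdims=True)
    return pd.Series(np.exp(np.median(logs - log_gm, axis=0)), index=counts.columns)


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    floor: float = 1e-8,
    shrink: float = 0.5,
) -> np.ndarray:
    """Per-unit method-of-moments NB dispersions, shrunk toward a fitted
    mean-dispersion trend (alpha ~ a0 + a1/mean)."""
    X = counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    q = X / s

    cols = counts.columns
    group_keys = list(zip(cols.get_level_values("strain"), cols.get_level_values("assay")))
    uniq = sorted(set(group_keys))
    num = np.zeros(X.shape[0])
    dof = 0
    for g in uniq:
        idx = [i for i, k in enumerate(group_keys) if k == g]
        if len(idx) < 2:
            continue
        num += q[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
        dof += len(idx) - 1
    if dof == 0:
        return np.full(X.shape[0], floor)
    within_var = num / dof

    mu = q.mean(axis=1)
    xim = np.mean(1.0 / s)
    mu_safe = np.clip(mu, 1e-8, None)
    raw = np.clip((within_var - mu_safe * xim) / mu_safe**2, floor, None)

    # parametric trend alpha(mu) = a0 + a1/mu, non-negative coefficients
    good = mu > 0
    A = np.column_stack([np.ones(good.sum()), 1.0 / mu_safe[good]])
    coef, *_ = np.linalg.lstsq(A, raw[good], rcond=None)
    coef = np.clip(coef, 0.0, None)
    trend = np.clip(coef[0] + coef[1] / mu_safe, floor, None)

    return np.clip((1.0 - shrink) * raw + shrink * trend, floor, None)


@dataclass
class _Design:
    X_full: np.ndarray
    X_reduced: np.ndarray
    cols: list
    chip_idx: np.ndarray
    mnase_idx: np.ndarray


def _build_design(columns: pd.MultiIndex, strains: tuple[str, str]) -> _Design:
    s1, s2 = strains
    rows, chip, mnase = [], [], []
    for i, col in enumerate(columns):
        strain, assay = col[0], col[1]
        s = 1.0 if strain == s2 else 0.0
        a = 1.0 if assay == "ChIP" else 0.0
        rows.append([1.0, s, a, s * a])
        (chip if a else mnase).append(i)
    X = np.array(rows)
    return _Design(X, X[:, :3], list(columns), np.array(chip), np.array(mnase))


def test_interaction_table(
    counts: pd.DataFrame,
    strains: tuple[str, str] | None = None,
    sf: pd.Series | None = None,
    dispersions: np.ndarray | None = None,
    wald: bool = False,
) -> pd.DataFrame:
    """Interaction + occupancy tests for every unit of one mark x strain pair.

    ``counts`` columns must be a (strain, assay, ...) MultiIndex holding one
    mark's ChIP columns and the MNase columns of both strains.
    """
    cols = counts.columns
    strain_level = cols.get_level_values("strain")
    assay_level = cols.get_level_values("assay")
    if strains is None:
        seen = list(dict.fromkeys(strain_level))
        if len(seen) != 2:
            raise ValueError(f"expected exactly 2 strains, got {seen}")
        strains = (seen[0], seen[1])
    for s in strains:
        for a in ("MNase", "ChIP"):
            n = int(((strain_level == s) & (assay_level == a)).sum())
            if n < 2:
                raise ValueError(f"need >= 2 replicates for {s} x {a}, found {n}")

    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, sf)
    design = _build_design(cols, strains)

    Y = counts.to_numpy(dtype=float)
    offset = np.log(sf.to_numpy(dtype=float))

    if wald:
        p_int, _, beta = _glm.wald_batch(Y, design.X_full, offset, dispersions, 3)
    else:
        p_int, _, beta = _glm.lrt_batch(
            Y, design.X_full, design.X_reduced, offset, dispersions
        )
    direction = np.sign(beta[:, 3])

    Ym = Y[:, design.mnase_idx]
    Xm_full = design.X_full[design.mnase_idx][:, :2]
    Xm_red = design.X_full[design.mnase_idx][:, :1]
    p_occ, _, _ = _glm.lrt_batch(
        Ym, Xm_full, Xm_red, offset[design.mnase_idx], dispersions
    )

    chip_zero = Y[:, design.chip_idx].sum(axis=1) == 0
    status = np.where(chip_zero, "insufficient_signal", "ok")
    p_int = np.where(chip_zero, np.nan, p_int)
    direction = np.where(chip_zero, 0.0, direction)

    return pd.DataFrame(
        {
            "p_interaction": p_int,
            "direction": direction,
            "p_occupancy": p_occ,
            "status": status,
        },
        index=counts.index,
    )


def test_interaction(unit_counts: pd.Series, strains=None, sf=None, alpha=None):
    """Single-unit convenience wrapper; returns (p, direction)."""
    df = unit_counts.to_frame().T
    alphas = None if alpha is None else np.array([alpha])
    res = test_interaction_table(df, strains=strains, sf=sf, dispersions=alphas)
    return float(res["p_interaction"].iloc[0]), float(res["direction"].iloc[0])


def test_occupancy(unit_mnase_counts: pd.Series, strains=None, sf=None, alpha=None):
    """Single-unit MNase-only strain-effect LRT; returns the p value."""
    cols = unit_mnase_counts.index
    strain_level = cols.get_level_values("strain")
    seen = list(dict.fromkeys(strain_level))
    if strains is None:
        strains = tuple(seen)
    for s in strains:
        if (strain_level == s).sum() < 2:
            raise ValueError(f"insufficient replicates for strain {s}")
    y = unit_mnase_counts.to_numpy(dtype=float)[None, :]
    X_full = np.column_stack(
        [np.ones(len(cols)), (strain_level == strains[1]).astype(float)]
    )
    X_red = X_full[:, :1]
    offset = np.zeros(len(cols)) if sf is None else np.log(np.asarray(sf, dtype=float))
    alphas = np.array([1e-8 if alpha is None else alpha])
    p, _, _ = _glm.lrt_batch(y, X_full, X_red, offset, alphas)
    return float(p[0])


# keep pytest from collecting the library test functions
test_interaction_table.__test__ = False  # type: ignore[attr-defined]
test_interaction.__test__ = False  # type: ignore[attr-defined]
test_occupancy.__test__ = False  # type: ignore[attr-defined]


def call_sneps(pvalues, fdr: float = 0.0001) -> np.ndarray:
    """Benjamini-Hochberg step-up at the given FDR; NaNs are never called."""
    p = np.asarray(pvalues, dtype=float)
    calls = np.zeros(len(p), dtype=bool)
    tested = np.flatnonzero(np.isfinite(p))
    m = len(tested)
    if m == 0:
        return calls
    ps = p[tested]
    order = np.argsort(ps)
    ranked = ps[order]
    thresh = (np.arange(1, m + 1) / m) * fdr
    passing = np.flatnonzero(ranked <= thresh)
    if len(passing):
        cutoff = ranked[passing[-1]]
        calls[tested] = ps <= cutoff
    return calls
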