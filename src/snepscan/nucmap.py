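"""Nucleosome dyad calling, replicate reproducibility, cross-strain matching
and positional-divergence analysis.

The dyad caller smooths forward-start + 73 bp dyad coverage with a Gaussian
kernel (sigma = 15 bp) and picks peaks greedily, highest score first, with a
120-bp exclusion zone and a score floor at the 25th percentile of nonzero
smoothed coverage.  A consensus nucleosome is well-positioned iff every
replicate contributes exactly one dyad to its 75-bp consensus window and the
replicate dyads' standard deviation is at most sigma_max (default 20 bp);
any other occupied cluster is emitted as a fuzzy region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .align import CurSet

FOOTPRINT_HALF = 73  # dyad +/- half footprint = 147 bp
MATCH_WINDOW = 75


@dataclass
class NucleosomeMap:
    """Per-strain consensus nucleosome calls on one contig."""

    strain: str
    contig: str
    wells: pd.DataFrame  # index call id; columns dyad, score, sd
    fuzzy: pd.DataFrame  # index call id; columns start, end, n_dyads

    @property
    def n_calls(self) -> int:
        return len(self.wells) + len(self.fuzzy)


def call_dyads(
    starts: np.ndarray,
    contig_length: int,
    sigma: float = 15.0,
    min_dist: int = 120,
    score_floor_quantile: float = 0.25,
    score_floor_mean_factor: float = 1.5,
    dyad_offset: int = FOOTPRINT_HALF,
) -> pd.DataFrame:
    """Call dyads from one replicate's forward read starts.

    The score floor is the larger of the ``score_floor_quantile`` quantile
    of nonzero smoothed coverage and ``score_floor_mean_factor`` times the
    mean smoothed coverage; the absolute component suppresses calls on
    unstructured (uniform) input.  Returns a frame with columns ``dyad``
    and ``score`` sorted by position.
    """
    starts = np.asarray(starts)
    if len(starts) == 0:
        warnings.warn("no reads: returning an empty dyad map")
        return pd.DataFrame(columns=["dyad", "score"])
    if len(starts) / (contig_length / 1000.0) < 10:
        warnings.warn("fewer than 10 reads per kb: dyad calls will be unreliable")

    dyads = np.clip(starts + dyad_offset, 0, contig_length - 1)
    cov = np.bincount(dyads, minlength=contig_length).astype(float)
    sm = gaussian_filter1d(cov, sigma)

    nonzero = sm[sm > 1e-12]
    floor = np.quantile(nonzero, score_floor_quantile) if len(nonzero) else np.inf
    floor = max(floor, score_floor_mean_factor * sm.mean())

    interior = sm[1:-1]
    is_peak = (interior >= sm[:-2]) & (interior > sm[2:]) & (interior >= floor)
    cand = np.flatnonzero(is_peak) + 1
    order = cand[np.argsort(sm[cand])[::-1]]

    blocked = np.zeros(contig_length, dtype=bool)
    kept = []
    for i in order:
        if blocked[i]:
            continue
        kept.append(i)
        blocked[max(0, i - min_dist + 1) : i + min_dist] = True
    kept.sort()
    return pd.DataFrame({"dyad": kept, "score": sm[kept]})


def classify_reproducibility(
    replicate_calls: list[pd.DataFrame],
    strain: str,
    contig: str,
    window: int = MATCH_WINDOW,
    sigma_max: float = 20.0,
) -> NucleosomeMap:
    """Build the consensus map from per-replicate dyad calls."""
    if len(replicate_calls) < 2:
        raise ValueError("need at least 2 replicates to assess reproducibility")
    n_reps = len(replicate_calls)

    dyads, scores, reps = [], [], []
    for r, df in enumerate(replicate_calls):
        dyads.append(np.asarray(df["dyad"], dtype=float))
        scores.append(np.asarray(df["score"], dtype=float))
        reps.append(np.full(len(df), r))
    dyads = np.concatenate(dyads) if dyads else np.array([])
    scores = np.concatenate(scores)
    reps = np.concatenate(reps)
    order = np.argsort(dyads, kind="stable")
    dyads, scores, reps = dyads[order], scores[order], reps[order]

    well_rows, fuzzy_rows = [], []
    if len(dyads):
        breaks = np.flatnonzero(np.diff(dyads) > window) + 1
        for seg in np.split(np.arange(len(dyads)), breaks):
            d, r, s = dyads[seg], reps[seg], scores[seg]
            counts = np.bincount(r.astype(int), minlength=n_reps)
            sd = d.std(ddof=1) if len(d) > 1 else 0.0
            if np.all(counts == 1) and sd <= sigma_max:
                well_rows.append((int(round(d.mean())), float(s.mean()), float(sd)))
            else:
                fuzzy_rows.append(
                    (int(d.min()) - FOOTPRINT_HALF, int(d.max()) + FOOTPRINT_HALF + 1, len(d))
                )

    wells = pd.DataFrame(well_rows, columns=["dyad", "score", "sd"])
    wells.index = pd.Index(
        [f"{strain}:w{i:05d}" for i in range(len(wells))], name="call_id"
    )
    fuzzy = pd.DataFrame(fuzzy_rows, columns=["start", "end", "n_dyads"])
    fuzzy.index = pd.Index(
        [f"{strain}:f{i:05d}" for i in range(len(fuzzy))], name="call_id"
    )
    return NucleosomeMap(strain, contig, wells, fuzzy)


def build_map(
    readset,
    strain: str,
    assay: str = "MNase",
    sigma: float = 15.0,
    window: int = MATCH_WINDOW,
    sigma_max: float = 20.0,
) -> NucleosomeMap:
    """Convenience wrapper: call dyads in every replicate, then classify."""
    length = readset.contig_lengths[strain]
    per_rep = [
        call_dyads(starts, length, sigma=sigma)
        for sid, starts in sorted(readset.samples.items())
        if sid.strain == strain and sid.assay == assay
    ]
    return classify_reproducibility(
        per_rep, strain, readset.contig, window=window, sigma_max=sigma_max
    )


# ---------------------------------------------------------------- matching


@dataclass
class MatchResult:
    """Matched well-positioned pairs plus UNRs; an exhaustive partition of
    all in-CUR calls of both strains."""

    pairs: pd.DataFrame  # id1, id2, dyad1, dyad2, dyad2_in_1, shift
    unrs: pd.DataFrame  # start, end (frame-1), start2, end2, n_members
    unr_members: dict[str, list[tuple[str, str]]]  # unr id -> [(strain, call_id)]
    excluded: list[str]  # call ids outside CURs
    strain1: str
    strain2: str

    @property
    def n_in_partition(self) -> int:
        members = sum(len(v) for v in self.unr_members.values())
        return 2 * len(self.pairs) + members


def _nearest(sorted_ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Index of nearest element of sorted_ref for each query value."""
    idx = np.searchsorted(sorted_ref, query)
    idx = np.clip(idx, 0, len(sorted_ref) - 1)
    left = np.clip(idx - 1, 0, len(sorted_ref) - 1)
    use_left = np.abs(query - sorted_ref[left]) <= np.abs(sorted_ref[idx] - query)
    return np.where(use_left, left, idx)


def _merge_intervals(items):
    """Merge overlapping [start, end) items [(start, end, payload)]."""
    items = sorted(items, key=lambda x: x[0])
    merged = []
    for s, e, payload in items:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].append(payload)
        else:
            merged.append([s, e, [payload]])
    return merged


def match_maps(
    map1: NucleosomeMap,
    map2: NucleosomeMap,
    cur_set: CurSet,
    window: int = MATCH_WINDOW,
    orientation: str = "forward",
) -> MatchResult:
    """Mutual-nearest-neighbor pairing of well-positioned nucleosomes after
    coordinate translation; all remaining occupied territory becomes UNRs.

    ``orientation="forward"`` means map1 lives on the CurSet source strain;
    ``"reverse"`` swaps the frames.
    """
    if map1.strain == map2.strain:
        raise ValueError("cannot match a strain's map against itself")
    into1 = "reverse" if orientation == "forward" else "forward"
    from1 = "forward" if orientation == "forward" else "reverse"

    excluded: list[str] = []

    def in_cur_mask(positions, direction):
        return np.array(
            [cur_set.find(map1.contig, int(p), direction) is not None for p in positions]
        )

    w1 = map1.wells
    d1 = w1["dyad"].to_numpy()
    keep1 = in_cur_mask(d1, from1) if len(d1) else np.zeros(0, bool)
    excluded += list(w1.index[~keep1])
    w1 = w1[keep1]
    d1 = w1["dyad"].to_numpy()

    w2 = map2.wells
    d2_native = w2["dyad"].to_numpy()
    t2 = cur_set.translate_array(map2.contig, d2_native, into1)
    keep2 = np.isfinite(t2)
    excluded += list(w2.index[~keep2])
    w2 = w2[keep2]
    d2_native = d2_native[keep2]
    t2 = t2[keep2]

    pairs_rows = []
    paired1: set[str] = set()
    paired2: set[str] = set()
    if len(d1) and len(t2):
        order1 = np.argsort(d1)
        order2 = np.argsort(t2)
        d1s = d1[order1].astype(float)
        t2s = t2[order2]
        nn12 = _nearest(t2s, d1s)
        nn21 = _nearest(d1s, t2s)
        for i, j in enumerate(nn12):
            if int(nn21[j]) != i or abs(d1s[i] - t2s[j]) > window:
                continue
            k1, k2 = order1[i], order2[j]
            id1, id2 = w1.index[k1], w2.index[k2]
            pairs_rows.append(
                (
                    id1,
                    id2,
                    int(d1[k1]),
                    int(d2_native[k2]),
                    int(round(t2[k2])),
                    int(round(t2[k2] - d1[k1])),
                )
            )
            paired1.add(id1)
            paired2.add(id2)
    pairs = pd.DataFrame(
        pairs_rows, columns=["id1", "id2", "dyad1", "dyad2", "dyad2_in_1", "shift"]
    )

    # ---- UNRs: unpaired wells plus all fuzzy regions, in frame-1 coords
    items = []
    for cid, row in w1.iterrows():
        if cid not in paired1:
            d = int(row["dyad"])
            items.append((d - FOOTPRINT_HALF, d + FOOTPRINT_HALF + 1, (map1.strain, cid)))
    for cid, dn, t in zip(w2.index, d2_native, t2):
        if cid not in paired2:
            c = int(round(t))
            items.append((c - FOOTPRINT_HALF, c + FOOTPRINT_HALF + 1, (map2.strain, cid)))
    for cid, row in map1.fuzzy.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if cur_set.find(map1.contig, (s + e) // 2, from1) is None:
            excluded.append(cid)
            continue
        items.append((s, e, (map1.strain, cid)))
    for cid, row in map2.fuzzy.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        r = cur_set.translate(map2.contig, mid, into1)
        if not r.ok:
            excluded.append(cid)
            continue
        half = (int(row["end"]) - int(row["start"])) // 2
        items.append((r.position - half, r.position + half + 1, (map2.strain, cid)))

    unr_rows = []
    unr_members: dict[str, list[tuple[str, str]]] = {}
    for k, (s, e, payloads) in enumerate(_merge_intervals(items)):
        uid = f"unr{k:05d}"
        r_s = cur_set.translate(map1.contig, max(s, 0), from1)
        r_e = cur_set.translate(map1.contig, e - 1, from1)
        s2 = r_s.position if r_s.ok else -1
        e2 = r_e.position + 1 if r_e.ok else -1
        unr_rows.append((uid, s, e, s2, e2, len(payloads)))
        unr_members[uid] = payloads
    unrs = pd.DataFrame(
        unr_rows, columns=["unr_id", "start", "end", "start2", "end2", "n_members"]
    ).set_index("unr_id")

    return MatchResult(pairs, unrs, unr_members, excluded, map1.strain, map2.strain)


# ---------------------------------------------------- positional divergence


@dataclass
class DivergenceResult:
    shifted_pairs: pd.DataFrame  # subset of pairs with |shift| > threshold
    subpopulation: pd.DataFrame  # unmatched strain-1 wells failing both rescues
    unmatched_metrics: pd.DataFrame  # per unmatched well: distance, unr overlap

    @property
    def diverged_ids(self) -> set[str]:
        return set(self.shifted_pairs["id1"]) | set(self.subpopulation.index)


def divergence_analysis(
    match: MatchResult,
    map1: NucleosomeMap,
    map2: NucleosomeMap,
    cur_set: CurSet,
    shift_threshold: int = 10,
    dist_threshold: int = 40,
    overlap_threshold: float = 0.99,
    orientation: str = "forward",
) -> DivergenceResult:
    """Flag matched pairs as shifted (|shift| > ``shift_threshold``) and
    assign unmatched strain-1 wells to the diverged subpopulation unless
    rescued by a nearby strain-2 well-positioned dyad or by (near-)complete
    overlap with strain-2-occupied UNR territory (conserved occupancy)."""
    shifted = match.pairs[match.pairs["shift"].abs() > shift_threshold]

    into1 = "reverse" if orientation == "forward" else "forward"
    t2 = cur_set.translate_array(map2.contig, map2.wells["dyad"].to_numpy(), into1)
    t2 = np.sort(t2[np.isfinite(t2)])

    # UNR intervals containing at least one strain-2 member (occupied in 2)
    occ2 = []
    for uid, members in match.unr_members.items():
        if any(strain == match.strain2 for strain, _ in members):
            row = match.unrs.loc[uid]
            occ2.append((int(row["start"]), int(row["end"])))
    occ2.sort()
    occ2_starts = np.array([s for s, _ in occ2]) if occ2 else np.zeros(0)

    paired1 = set(match.pairs["id1"])
    rows = []
    for cid, row in map1.wells.iterrows():
        if cid in paired1 or cid in match.excluded:
            continue
        d = int(row["dyad"])
        dist = (
            float(np.min(np.abs(t2 - d))) if len(t2) else np.inf
        )
        lo, hi = d - FOOTPRINT_HALF, d + FOOTPRINT_HALF + 1
        best = 0.0
        if occ2:
            i = np.searchsorted(occ2_starts, hi)
            for s, e in occ2[max(0, i - 3) : i + 1]:
                ov = max(0, min(e, hi) - max(s, lo))
                best = max(best, ov / (hi - lo))
        diverged = dist > dist_threshold and best < overlap_threshold
        rows.append((cid, d, dist, best, diverged))
    metrics = pd.DataFrame(
        rows, columns=["call_id", "dyad", "nearest_well_dist", "unr_overlap", "diverged"]
    ).set_index("call_id")
    sub = metrics[metrics["diverged"]]
    return DivergenceResult(shifted, sub, metrics)


# ------------------------------------------------------------- annotation


def annotate_calls(
    nmap: NucleosomeMap,
    genes: pd.DataFrame,
    tf_sites: pd.DataFrame | None = None,
    cur_set: CurSet | None = None,
    plus_one_window: int = 300,
    tf_max_dist: int = 30,
    poly_halfwidth: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate well-positioned calls with genic position, +1/-1 status,
    TFBS proximity (strict <= ``tf_max_dist`` bp) and local polymorphism.

    Returns (per-call annotations, per-gene +1/-1 slot table).  A call may
    be the -1 of one gene and the +1 of a divergently transcribed neighbor;
    both annotations are retained.
    """
    wells = nmap.wells
    dyads = wells["dyad"].to_numpy()
    order = np.argsort(dyads)
    sorted_dyads = dyads[order]
    ids = wells.index.to_numpy()[order]

    plus_one: dict[str, str] = {}
    minus_one: dict[str, str] = {}
    slot_rows = []
    for gid, g in genes.iterrows():
        sgn = 1 if g["strand"] == "+" else -1
        tss = int(g["tss"])
        deltas = (sorted_dyads - tss) * sgn
        down = np.flatnonzero((deltas >= 0) & (deltas <= plus_one_window))
        up = np.flatnonzero((deltas < 0) & (deltas >= -plus_one_window))
        p1 = m1 = None
        if len(down):
            p1 = ids[down[np.argmin(deltas[down])]]
            plus_one[p1] = gid
        if len(up):
            m1 = ids[up[np.argmax(deltas[up])]]
            minus_one[m1] = gid
        slot_rows.append((gid, p1, m1))
    slots = pd.DataFrame(slot_rows, columns=["gene_id", "plus_one", "minus_one"]).set_index(
        "gene_id"
    )

    gs = genes.sort_values("start")
    gstarts = gs["start"].to_numpy()
    gends = gs["end"].to_numpy()
    gstrand = gs["strand"].to_numpy()
    gids = gs.index.to_numpy()

    tf_intervals = None
    if tf_sites is not None and len(tf_sites):
        tf_intervals = tf_sites.sort_values("start")[["start", "end"]].to_numpy()

    rows = []
    for cid, row in wells.iterrows():
        d = int(row["dyad"])
        j = np.searchsorted(gstarts, d, side="right") - 1
        gene_id, relpos = None, np.nan
        if j >= 0 and gstarts[j] <= d < gends[j]:
            gene_id = gids[j]
            f = (d - gstarts[j]) / (gends[j] - gstarts[j])
            relpos = f if gstrand[j] == "+" else 1.0 - f
        tf_prox = False
        if tf_intervals is not None:
            ds = np.where(
                (tf_intervals[:, 0] <= d) & (d < tf_intervals[:, 1]),
                0,
                np.minimum(
                    np.abs(tf_intervals[:, 0] - d), np.abs(tf_intervals[:, 1] - 1 - d)
                ),
            )
            tf_prox = bool(ds.min() <= tf_max_dist)
        poly = (
            cur_set.local_polymorphism(nmap.contig, d, poly_halfwidth)
            if cur_set is not None
            else None
        )
        rows.append(
            (
                cid,
                d,
                gene_id,
                relpos,
                plus_one.get(cid),
                minus_one.get(cid),
                tf_prox,
                np.nan if poly is None else poly,
            )
        )
    ann = pd.DataFrame(
        rows,
        columns=[
            "call_id",
            "dyad",
            "gene_id",
            "genic_relpos",
            "plus_one_of",
            "minus_one_of",
            "tf_proximal",
            "local_polymorphism",
        ],
    ).set_index("call_id")
    return ann, slots
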