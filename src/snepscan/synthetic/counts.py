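"""Direct unit-level count simulation for the differential-mark test.

Bypasses read placement: draws the per-nucleosome count table itself from
the Gamma-Poisson model, which is what the interaction test assumes.  Used
for calibration/power studies where simulating millions of individual reads
would be wasteful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_count_table(
    seed: int,
    n_units: int,
    depth: float = 200.0,
    dispersion: float = 0.05,
    n_replicates: int = 2,
    planted_lfc: dict[int, float] | None = None,
    occupancy_lfc: dict[int, float] | None = None,
    strains: tuple[str, str] = ("S1", "S2"),
    depth_range: tuple[float, float] = (0.5, 2.0),
    mark: str = "markA",
):
    """Simulate a nucleosome x sample count table for one mark.

    ``planted_lfc`` maps unit index -> log2 fold change of the second
    strain's ChIP rate *per occupied nucleosome* (an SNEP).
    ``occupancy_lfc`` maps unit index -> log2 fold change of the second
    strain's occupancy, which scales MNase *and* ChIP alike (not an SNEP).

    Returns (counts, meta, true_depth_factors): ``counts`` is a DataFrame
    with unit rows and MultiIndex columns (strain, assay, replicate).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    planted_lfc = planted_lfc or {}
    occupancy_lfc = occupancy_lfc or {}

    base = np.exp(rng.normal(0.0, 0.25, size=n_units))  # unit-to-unit spread
    occ = {strains[0]: np.ones(n_units), strains[1]: np.ones(n_units)}
    for i, lfc in occupancy_lfc.items():
        occ[strains[1]][i] = 2.0**lfc
    snep = np.ones(n_units)
    for i, lfc in planted_lfc.items():
        snep[i] = 2.0**lfc

    columns = []
    data = {}
    factors = {}
    for strain in strains:
        for assay in ("MNase", "ChIP"):
            for rep in range(1, n_replicates + 1):
                mult = float(
                    np.exp(
                        rng.uniform(np.log(depth_range[0]), np.log(depth_range[1]))
                    )
                )
                mu = depth * mult * base * occ[strain]
                if assay == "ChIP" and strain == strains[1]:
                    mu = mu * snep
                if dispersion > 0:
                    mu = mu * rng.gamma(
                        1.0 / dispersion, dispersion, size=n_units
                    )
                key = (strain, assay, rep)
                data[key] = rng.poisson(mu)
                factors[key] = mult
                columns.append(key)

    counts = pd.DataFrame(
        data,
        index=pd.Index([f"u{i:05d}" for i in range(n_units)], name="unit_id"),
    )
    counts.columns = pd.MultiIndex.from_tuples(
        columns, names=["strain", "assay", "replicate"]
    )
    meta = pd.DataFrame(
        [(s, a, r, mark if a == "ChIP" else "", factors[(s, a, r)]) for s, a, r in columns],
        columns=["strain", "assay", "replicate", "mark", "true_depth"],
    )
    return counts, meta, factors
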