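"""Species x TE incidence and the Muller apparent-competition index.

The Muller (potential-for-apparent-competition) index treats horizontally
transferred TEs as shared interaction partners: the potential d_ij of
species j to influence species i via shared TEs is

    d_ij = sum_k [ (a_ik / sum_l a_il) * (a_jk / sum_m a_mk) ]

where a_ik is how much of TE unit k species i carries through HTT. Each
acting species' row of d sums to 1 (an algebraic identity of the formula),
so d_ij is the share of i's HTT-acquired mobilome "attributable" to j.

Two alpha resolutions are supported, because the construction of a from the
event table is not uniquely determined: family-level (summed per-species
event weights per TE family, the default) and superfamily-level
(superfamily-by-pair counts summed over the pairs involving each species).
Outputs are labelled with the mode used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .htt_events import HTTEvent

logger = logging.getLogger("httflow")


@dataclass
class AlphaMatrix:
    """Non-negative species x TE-unit incidence (DataFrame wrapper)."""

    table: pd.DataFrame  # index: species, columns: TE units
    resolution: str  # "family" | "superfamily"

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("alpha matrix must be non-negative")
        zero_rows = self.table.index[self.table.sum(axis=1) == 0]
        if len(zero_rows):
            logger.warning(
                "alpha matrix: species with all-zero rows retained: %s",
                list(zero_rows),
            )

    @property
    def species(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MullerMatrix:
    """d_ij potential-effects matrix; rows are acting species i."""

    table: pd.DataFrame
    resolution: str

    def row_sums(self) -> pd.Series:
        return self.table.sum(axis=1)


def build_alpha(
    source: list[HTTEvent] | pd.DataFrame,
    resolution: str = "family",
    species_order: list[str] | None = None,
) -> AlphaMatrix:
    """Build the incidence matrix from events or a superfamily-by-pair count table.

    family mode (events input): ``a[i][k]`` = species i's summed event
    weights for family k. superfamily mode: with events, weights are summed
    per superfamily; with a count table (superfamily x pair columns like
    ``BMxBD``), ``a[i][k]`` = sum over the pairs involving i of the pair's
    count for superfamily k.
    """
    if resolution not in {"family", "superfamily"}:
        raise ValueError("resolution must be family|superfamily")
    if isinstance(source, pd.DataFrame):
        if resolution != "superfamily":
            raise ValueError("count-table input implies superfamily resolution")
        df = source.copy()
        if isinstance(df.index, pd.MultiIndex):
            df.index = df.index.get_level_values("superfamily")
        species: list[str] = species_order or sorted(
            {sp for col in df.columns for sp in col.split("x")}
        )
        table = pd.DataFrame(0.0, index=species, columns=list(df.index))
        for col in df.columns:
            a, b = col.split("x")
            for sf, count in df[col].items():
                table.loc[a, sf] += count
                table.loc[b, sf] += count
        return AlphaMatrix(table=table, resolution="superfamily")

    events: list[HTTEvent] = source
    species = species_order or sorted({sp for ev in events for sp in ev.weights})
    unit_of = (
        (lambda ev: ev.family) if resolution == "family" else (lambda ev: ev.superfamily)
    )
    units = sorted({unit_of(ev) for ev in events})
    table = pd.DataFrame(0.0, index=species, columns=units)
    for ev in events:
        for sp, w in ev.weights.items():
            table.loc[sp, unit_of(ev)] += w
    return AlphaMatrix(table=table, resolution=resolution)


def muller_index(alpha: AlphaMatrix) -> MullerMatrix:
    """Compute d_ij for all ordered species pairs (including i = j).

    Species with an all-zero alpha row get an all-NaN row (flagged in the
    log) and are excluded from the row-normalization identity.
    """
    a = alpha.table.to_numpy(dtype=float)
    if a.sum() == 0:
        raise ValueError("alpha matrix is entirely zero")
    row_tot = a.sum(axis=1, keepdims=True)  # sum_l a_il
    col_tot = a.sum(axis=0, keepdims=True)  # sum_m a_mk
    with np.errstate(invalid="ignore", divide="ignore"):
        share_i = np.where(row_tot > 0, a / row_tot, np.nan)
        contrib_j = np.where(col_tot > 0, a / col_tot, 0.0)
    d = share_i @ contrib_j.T
    table = pd.DataFrame(d, index=alpha.species, columns=alpha.species)
    empty = table.index[~np.isfinite(d).all(axis=1)]
    if len(empty):
        logger.warning("muller: species with zero alpha rows undefined: %s", list(empty))
    return MullerMatrix(table=table, resolution=alpha.resolution)


def export_network(
    muller: MullerMatrix,
    path: str | Path,
    include_self: bool = False,
    decimals: int = 6,
) -> pd.DataFrame:
    """Write the d matrix as a TSV edge list (acting, target, dij).

    Edges are ordered by acting then target species (lexicographic); self
    edges are included only on request. Returns the written frame.
    """
    rows = []
    for acting in muller.table.index:
        for target in muller.table.columns:
            if acting == target and not include_self:
                continue
            value = muller.table.loc[acting, target]
            if not np.isfinite(value):
                continue
            rows.append([acting, target, round(float(value), decimals)])
    df = pd.DataFrame(rows, columns=["acting", "target", "dij"])
    df = df.sort_values(["acting", "target"], kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df
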