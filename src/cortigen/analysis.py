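"""Post-run laminar analysis: filtering, counts, thickness, segregation
and apoptosis time courses.

All operations are pure functions of the exported position table
(columns ``cell_id, layer, x_um, y_um, z_um``; the layer label is one
of MZ, L2..L6) or of the event log.  Counts convert back to adult
per-mm^2 equivalents with the inverse of the column conversion, and
layer 2/3 is always reported as a sum because the experimental
reference tables group those layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expected import column_to_mm2
from .grn import LAYER_LABELS

__all__ = [
    "committed_alive",
    "discard_above_mz",
    "layer_counts",
    "cortical_thickness",
    "laminar_profile",
    "adjacent_overlap",
    "adjacent_layer_overlaps",
    "apoptosis_time_series",
    "SPATIAL_ORDER",
]

#: layers ordered from the pia downward (MZ on top in a healthy column)
SPATIAL_ORDER = ("MZ", "L2", "L3", "L4", "L5", "L6")


def pool_position_tables(tables) -> pd.DataFrame:
    """Concatenate replicate position tables with disambiguated cell ids.

    Replicate pooling is the package's standard measurement protocol for
    laminar statistics: single scaled-down runs have small per-layer
    populations, so thickness, ordering and overlap are estimated from
    the pooled cells of a few independent runs.
    """
    parts = []
    for k, t in enumerate(tables):
        t = t.copy()
        t["cell_id"] = t["cell_id"].astype(str) + f"_r{k}"
        parts.append(t)
    if not parts:
        raise ValueError("no tables to pool")
    return pd.concat(parts, ignore_index=True)


def committed_alive(table: pd.DataFrame) -> pd.DataFrame:
    """Keep alive, committed (layer-labelled) cells only."""
    mask = table["layer"].isin(SPATIAL_ORDER)
    if "alive" in table.columns:
        mask &= table["alive"].astype(bool)
    return table[mask].reset_index(drop=True)


def discard_above_mz(table: pd.DataFrame, margin: float = 30.0) -> pd.DataFrame:
    """Drop non-MZ cells that overshot through the marginal zone.

    Cells occasionally migrate through the MZ and park at the top of the
    column; they are removed by thresholding at the MZ median height
    plus a configurable margin (um).
    """
    if table.empty:
        raise ValueError("empty position table")
    mz_z = table.loc[table["layer"] == "MZ", "z_um"]
    if mz_z.empty:
        raise ValueError("no MZ cells in table; cannot set the discard threshold")
    cutoff = float(mz_z.median()) + margin
    keep = (table["layer"] == "MZ") | (table["z_um"] <= cutoff)
    return table[keep].reset_index(drop=True)


def layer_counts(table: pd.DataFrame, column_area_mm2: float = 0.09) -> pd.DataFrame:
    """Per-layer cell counts with adult per-mm^2 equivalents.

    Returns one row per reporting layer (L1=MZ, L2/3 pooled, L4, L5,
    L6) with columns ``layer, count, per_mm2_equivalent``.  The
    equivalent assumes the standard 300 um x 300 um column; pass the
    actual cross-section area for scaled columns.
    """
    counts = table.groupby("layer").size()
    get = lambda l: int(counts.get(l, 0))
    rows = [
        ("L1", get("MZ")),
        ("L2/3", get("L2") + get("L3")),
        ("L4", get("L4")),
        ("L5", get("L5")),
        ("L6", get("L6")),
    ]
    df = pd.DataFrame(rows, columns=["layer", "count"])
    scale = 0.09 / column_area_mm2
    df["per_mm2_equivalent"] = column_to_mm2(df["count"].to_numpy(dtype=float) * scale)
    return df


def cortical_thickness(table: pd.DataFrame, lower_percentile: float = 5.0,
                       upper_percentile: float = 95.0) -> float:
    """Radial extent from the bottom of layer 6 to the top of the MZ.

    Robust percentiles (5th of L6 depths, 95th of MZ depths by default)
    keep the few mislocated stragglers every run produces from defining
    the boundary; the cutoffs are configurable.
    """
    missing = [l for l in ("L6", "MZ") if not (table["layer"] == l).any()]
    if missing:
        raise ValueError(f"cannot measure thickness; missing layers: {missing}")
    bottom = float(np.percentile(table.loc[table["layer"] == "L6", "z_um"], lower_percentile))
    top = float(np.percentile(table.loc[table["layer"] == "MZ", "z_um"], upper_percentile))
    return top - bottom


def laminar_profile(table: pd.DataFrame, min_bins: int = 10) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-layer histogram of radial position.

    Bin counts adapt per layer (Freedman-Diaconis with a floor of
    ``min_bins``); returns ``{layer: (counts, bin_edges)}``.
    """
    out = {}
    for layer in SPATIAL_ORDER:
        z = table.loc[table["layer"] == layer, "z_um"].to_numpy(dtype=float)
        if z.size == 0:
            continue
        iqr = np.subtract(*np.percentile(z, [75, 25]))
        if iqr > 0:
            width = 2.0 * iqr / z.size ** (1.0 / 3.0)
            n_bins = max(min_bins, int(np.ceil((z.max() - z.min()) / width))) if width > 0 else min_bins
        else:
            n_bins = min_bins
        counts, edges = np.histogram(z, bins=n_bins)
        out[layer] = (counts, edges)
    return out


def adjacent_overlap(z_a, z_b, bin_width: float = 15.0) -> float:
    """Overlap coefficient of two radial density profiles.

    Both samples are histogrammed on a common fixed-width grid spanning
    their joint range; the coefficient is sum(min(p_a, p_b)) of the
    normalised densities: 0 for disjoint supports, 1 for identical
    distributions.  Returns NaN when either sample is empty.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.size == 0 or z_b.size == 0:
        return float("nan")
    lo = min(z_a.min(), z_b.min())
    hi = max(z_a.max(), z_b.max())
    if hi <= lo:
        return 1.0  # all mass at one point in both samples
    edges = np.arange(lo, hi + bin_width, bin_width)
    pa, _ = np.histogram(z_a, bins=edges)
    pb, _ = np.histogram(z_b, bins=edges)
    return float(np.minimum(pa / z_a.size, pb / z_b.size).sum())


def adjacent_layer_overlaps(table: pd.DataFrame, bin_width: float = 15.0,
                            pool_l23: bool = True) -> dict[tuple[str, str], float]:
    """Overlap coefficient for every spatially adjacent layer pair.

    By default layers 2 and 3 are pooled into one L2/3 population, as
    in the experimental reference counts (the L2/L3 border is not
    experimentally delineated); pass ``pool_l23=False`` for all six
    populations separately.
    """
    if pool_l23:
        order: list[tuple[str, tuple[str, ...]]] = [
            ("MZ", ("MZ",)), ("L2/3", ("L2", "L3")), ("L4", ("L4",)),
            ("L5", ("L5",)), ("L6", ("L6",))]
    else:
        order = [(l, (l,)) for l in SPATIAL_ORDER]
    out = {}
    for (name_a, members_a), (name_b, members_b) in zip(order[:-1], order[1:]):
        za = table.loc[table["layer"].isin(members_a), "z_um"]
        zb = table.loc[table["layer"].isin(members_b), "z_um"]
        out[(name_a, name_b)] = adjacent_overlap(za, zb, bin_width)
    return out


def apoptosis_time_series(events: pd.DataFrame, n_steps: int | None = None) -> pd.DataFrame:
    """Per-layer alive-count trajectories and cumulative deaths by cause.

    Reconstructed from the event log: a ``commit`` raises a layer's
    count, ``a2_death``/``l1_extra_death`` lower it.  Returns a frame
    indexed by step with one column per layer plus cumulative death
    counts per cause.
    """
    if n_steps is None:
        n_steps = int(events["step"].max()) if len(events) else 0
    steps = np.arange(n_steps + 1)
    out = pd.DataFrame(index=pd.Index(steps, name="step"))
    for code in range(1, 7):
        label = LAYER_LABELS[code]
        births = events[(events["event"] == "commit") & (events["layer"] == code)]
        deaths = events[events["event"].isin(["a2_death", "l1_extra_death"])
                        & (events["layer"] == code)]
        delta = np.zeros(n_steps + 1)
        np.add.at(delta, np.clip(births["step"].to_numpy(), 0, n_steps), 1)
        np.add.at(delta, np.clip(deaths["step"].to_numpy(), 0, n_steps), -1)
        out[label] = np.cumsum(delta)
    for cause in ("a1_death", "a2_death", "l1_extra_death"):
        delta = np.zeros(n_steps + 1)
        sel = events[events["event"] == cause]
        np.add.at(delta, np.clip(sel["step"].to_numpy(), 0, n_steps), 1)
        out[f"cum_{cause}"] = np.cumsum(delta)
    return out
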