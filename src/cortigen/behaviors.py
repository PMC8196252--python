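"""Per-cell behavior rules: growth/division thresholds, layer-specific
migration stop conditions, post-settlement physical transitions, and the
neighborhood rule for A2-type apoptosis.

These are the pure decision rules; the driver applies them to the whole
population each step.  Layers are identified by their anatomical index
(MZ / future layer 1 = 1, L2 = 2, ..., L6 = 6), so the spatial stacking
order of a healthy cortex coincides with the index order, and "adjacent"
vs "more distant" layers in the A2 rule reduce to an index difference of
1 vs >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grn import LAYER_MZ

__all__ = [
    "GROWTH_RATE",
    "DIVISION_DIAMETER",
    "SETTLED_DIAMETER",
    "StopRuleParams",
    "A2Params",
    "earlier_layers",
    "should_stop",
    "a2_should_die",
    "MigrationState",
]

#: diameter growth per time step (um)
GROWTH_RATE = 0.2
#: maximum cell-body diameter during proliferation; reaching it triggers
#: the division / fate decision
DIVISION_DIAMETER = 10.0
#: final diameter of a settled neuron (um)
SETTLED_DIAMETER = 15.0


class MigrationState:
    """Integer codes for the per-cell migration state machine."""

    QUIESCENT = 0   # progenitor, or a stranded (heterotopic) neuron
    WAITING = 1     # committed layer-6 neuron running its waiting clock
    MIGRATING = 2
    SETTLED = 3


@dataclass(frozen=True)
class StopRuleParams:
    """Thresholds of the migration stop conditions.

    Marginal-zone cells stop on the guidance-cue concentration alone;
    layer 6 needs at least one settled MZ contact; layers 2-5 need at
    least two settled MZ contacts and no contact with any earlier-born
    layer.  The sensing radius is the physical-contact range (sum of the
    radii plus the adhesion range), supplied by the caller.
    """

    mz_conc_threshold: float
    mz_neighbor_min_l6: int = 1
    mz_neighbor_min_l2to5: int = 2
    earlier_layer_neighbor_max: int = 0


@dataclass(frozen=True)
class A2Params:
    """Parameters of post-migration, neighborhood-sensing apoptosis."""

    radius: float = 20.0            # sensing radius, um (inclusive)
    adjacent_layer_kill_count: int = 3
    distant_layer_kill_count: int = 1
    layer1_extra_p: float = 0.9     # one-shot Bernoulli for MZ cells at A2 onset

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("A2 radius must be positive")
        if self.adjacent_layer_kill_count < 1 or self.distant_layer_kill_count < 1:
            raise ValueError("kill counts must be >= 1")


def earlier_layers(layer: int) -> frozenset[int]:
    """Layers born before ``layer``, excluding the MZ.

    Birth order is MZ, L6, L5, ..., L2; in anatomical indices the layers
    born before layer ``l`` (for l in 2..5) are those with larger index.
    Layer 6 and the MZ have no earlier cortical-plate layer.
    """
    if not 1 <= layer <= 6:
        raise ValueError(f"invalid layer code {layer}")
    if layer in (LAYER_MZ, 6):
        return frozenset()
    return frozenset(range(layer + 1, 7))


def should_stop(layer: int, n_mz_neighbors: int, n_earlier_neighbors: int,
                concentration: float, params: StopRuleParams) -> bool:
    """Migration stop rule for a committed, migrating cell.

    ``n_mz_neighbors`` counts settled MZ cells inside the contact range,
    ``n_earlier_neighbors`` counts settled cells of earlier-born layers.
    """
    if not 1 <= layer <= 6:
        raise ValueError(f"cell has no committed layer (code {layer}); stop rule undefined")
    if layer == LAYER_MZ:
        return concentration >= params.mz_conc_threshold
    if layer == 6:
        return n_mz_neighbors >= params.mz_neighbor_min_l6
    return (n_mz_neighbors >= params.mz_neighbor_min_l2to5
            and n_earlier_neighbors <= params.earlier_layer_neighbor_max)


def a2_should_die(layer: int, neighbor_layers, params: A2Params = A2Params()) -> bool:
    """Neighborhood condition of A2-type apoptosis.

    ``neighbor_layers`` are the anatomical layer codes of settled
    neurons within the sensing radius.  Neighbors of the cell's own
    layer are ignored.  Death is triggered by at least
    ``adjacent_layer_kill_count`` neighbors belonging to one adjacent
    layer (index distance 1), or ``distant_layer_kill_count`` neighbors
    of more distant layers (index distance >= 2).  Counting the
    adjacent condition per single layer tolerates the two flat
    interfaces every correctly placed cell has, while a cell pushed
    into an adjacent band (many contacts with that one layer) or near
    any distant band is removed.  The extra layer-1 Bernoulli is drawn
    by the caller (it is independent of the neighborhood).
    """
    if not 1 <= layer <= 6:
        raise ValueError(f"invalid layer code {layer}")
    nb = np.asarray(list(neighbor_layers), dtype=int)
    if nb.size == 0:
        return False
    dist = np.abs(nb - layer)
    n_adjacent_max = 0
    for adj in (layer - 1, layer + 1):
        if 1 <= adj <= 6:
            n_adjacent_max = max(n_adjacent_max, int(np.sum(nb == adj)))
    n_distant = int(np.sum(dist >= 2))
    return (n_adjacent_max >= params.adjacent_layer_kill_count
            or n_distant >= params.distant_layer_kill_count)
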