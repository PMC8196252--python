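"""Gene-regulatory state machine for cortical neurogenesis.

The model describes a single progenitor chain: a purely proliferative
state S1 (symmetric amplification, terminated by a decaying intracellular
clock substance), followed by six asymmetric progenitor stages S2..S7.
At each asymmetric stage a cell either commits to a layer-specific
neuronal fate (probability ``C``), undergoes environment-independent
apoptosis ("A1-type", probability ``P`` among the non-committing cells),
or divides once more and both daughters advance to the next stage.

The commit targets follow the birth order of cortical neurons:
S2 decides the marginal-zone (MZ, future layer 1) fate, S3 decides
layer 6, S4 layer 5, S5 layer 4, S6 layer 3 and S7 layer 2.  At S7 the
residual apoptosis probability is ``1 - C_2``, so the outcome space is
exhausted and no cell advances past S7.

The state machine can run embedded in the spatial simulator (per-cell
draws) or as the fast, non-spatial lineage Monte Carlo implemented by
:func:`run_lineage_cascade`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CellStage",
    "FateDecision",
    "GRNParams",
    "LayerCounts",
    "StageTally",
    "clock_steps_to_threshold",
    "decide_stage_fate",
    "symmetric_amplification",
    "run_lineage_cascade",
    "lineage_replicates",
    "list_presets",
]

# Anatomical layer codes used throughout the package: MZ (future layer 1)
# is 1, then L2=2 ... L6=6.  Birth order is MZ, L6, L5, L4, L3, L2.
LAYER_MZ, LAYER_L2, LAYER_L3, LAYER_L4, LAYER_L5, LAYER_L6 = 1, 2, 3, 4, 5, 6
LAYER_LABELS = {1: "MZ", 2: "L2", 3: "L3", 4: "L4", 5: "L5", 6: "L6"}
BIRTH_ORDER = (LAYER_MZ, LAYER_L6, LAYER_L5, LAYER_L4, LAYER_L3, LAYER_L2)

#: committed layer (anatomical code) decided at each asymmetric stage
STAGE_TO_LAYER = {2: LAYER_MZ, 3: LAYER_L6, 4: LAYER_L5, 5: LAYER_L4, 6: LAYER_L3, 7: LAYER_L2}


class CellStage(IntEnum):
    """States of the regulatory cascade.

    ``S1`` is the symmetric-amplification state; ``S2``..``S7`` are the
    asymmetric progenitor stages; the remaining members are absorbing.
    """

    S1 = 1
    S2 = 2
    S3 = 3
    S4 = 4
    S5 = 5
    S6 = 6
    S7 = 7
    MZ = 11
    L6 = 16
    L5 = 15
    L4 = 14
    L3 = 13
    L2 = 12
    DEAD_A1 = 98
    DEAD_A2 = 99

    @property
    def is_asymmetric(self) -> bool:
        return 2 <= int(self) <= 7


class FateDecision(Enum):
    COMMIT = "commit"
    APOPTOSE = "apoptose"
    ADVANCE = "advance"


@dataclass(frozen=True)
class GRNParams:
    """The eleven cascade probabilities plus the amplification clock.

    ``C_k`` is the probability of committing to the layer-k neuronal
    fate at the corresponding stage; ``P_k`` the A1-apoptosis
    probability among non-committing cells.  ``P_2`` is derived as
    ``1 - C_2`` so stage S7 leaves no survivors.  ``T_SYM`` is the clock
    threshold (unitless substance quantity) ending symmetric division.
    """

    C_M: float
    C_6: float
    C_5: float
    C_4: float
    C_3: float
    C_2: float
    P_M: float
    P_6: float
    P_5: float
    P_4: float
    P_3: float
    T_SYM: float = 65.0
    clock_init: float = 100.0
    clock_decay: float = 0.01
    symmetric_rounds: int = 6
    species_label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("C_M", "C_6", "C_5", "C_4", "C_3", "C_2", "P_M", "P_6", "P_5", "P_4", "P_3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.T_SYM < self.clock_init:
            raise ValueError("T_SYM must lie in (0, clock_init)")
        if not 0.0 < self.clock_decay < 1.0:
            raise ValueError("clock_decay must lie in (0, 1)")
        if self.symmetric_rounds < 0:
            raise ValueError("symmetric_rounds must be >= 0")

    @property
    def P_2(self) -> float:
        """Residual apoptosis probability at S7 (derived, = 1 - C_2)."""
        return 1.0 - self.C_2

    def stage_probs(self, stage: int) -> tuple[float, float]:
        """(C, P) pair governing an asymmetric stage (2..7)."""
        table = {
            2: (self.C_M, self.P_M),
            3: (self.C_6, self.P_6),
            4: (self.C_5, self.P_5),
            5: (self.C_4, self.P_4),
            6: (self.C_3, self.P_3),
            7: (self.C_2, self.P_2),
        }
        try:
            return table[int(stage)]
        except KeyError:
            raise ValueError(f"stage {stage} has no (C, P) pair") from None

    def with_apoptosis_scaled(self, factor: float) -> "GRNParams":
        """Scale every A1 probability by ``factor`` (capped at 1)."""
        kw = {k: min(1.0, getattr(self, k) * factor) for k in ("P_M", "P_6", "P_5", "P_4", "P_3")}
        return replace(self, **kw)

    def without_apoptosis(self) -> "GRNParams":
        return replace(self, P_M=0.0, P_6=0.0, P_5=0.0, P_4=0.0, P_3=0.0)

    @classmethod
    def from_preset(cls, species: str, **overrides) -> "GRNParams":
        """Load a species preset bundled with the package."""
        table = _load_presets()
        if species not in table.index:
            raise KeyError(
                f"unknown species preset {species!r}; available: {sorted(table.index)}"
            )
        row = table.loc[species]
        kw = {k: float(row[k]) for k in ("C_M", "C_6", "C_5", "C_4", "C_3", "C_2",
                                         "P_M", "P_6", "P_5", "P_4", "P_3", "T_SYM")}
        kw["species_label"] = species
        kw.update(overrides)
        return cls(**kw)


def _load_presets() -> pd.DataFrame:
    with resources.files("cortigen.data").joinpath("species_presets.csv").open() as fh:
        return pd.read_csv(fh).set_index("species")


def list_presets() -> list[str]:
    return list(_load_presets().index)


def clock_steps_to_threshold(q0: float, decay: float, threshold: float,
                             max_steps: int = 10_000_000) -> int:
    """Smallest ``n >= 1`` with ``q0 * (1 - decay)**n < threshold``.

    Models the intracellular clock substance that decays by a fixed
    fraction per step; the phase it times ends when the quantity first
    drops below the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (clock never reaches it)")
    if q0 <= 0:
        raise ValueError("initial quantity must be positive")
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must lie in (0, 1)")
    if threshold > q0:
        return 1
    # closed-form candidate, then correct for floating point at the boundary
    n = max(1, math.floor(math.log(threshold / q0) / math.log(1.0 - decay)))
    while n > 1 and q0 * (1.0 - decay) ** (n - 1) < threshold:
        n -= 1
    while q0 * (1.0 - decay) ** n >= threshold:
        n += 1
        if n > max_steps:
            raise ValueError(f"threshold {threshold} not reached within {max_steps} steps")
    return n


def decide_stage_fate(stage: int | CellStage, params: GRNParams, rng: np.random.Generator) -> FateDecision:
    """One fate draw for an asymmetric-stage cell.

    The draw is sequential — commit first, then apoptosis among the
    non-committing cells — so the outcome probabilities are
    ``(C, (1-C)*P, (1-C)*(1-P))`` and per-stage survival is
    ``(1-C)(1-P)``.
    """
    stage = int(stage)
    if not 2 <= stage <= 7:
        raise ValueError(f"stage {stage} is not an asymmetric progenitor stage (S2..S7)")
    c, p = params.stage_probs(stage)
    if stage == 7:
        p = 1.0  # terminal stage: no next state, non-committing cells die
    u = rng.random()
    if u < c:
        return FateDecision.COMMIT
    if u < c + (1.0 - c) * p:
        return FateDecision.APOPTOSE
    return FateDecision.ADVANCE


def symmetric_amplification(n_founders: int, rounds: int) -> int:
    """Progenitor pool after ``rounds`` synchronous symmetric divisions."""
    if n_founders < 1:
        raise ValueError("need at least one founder")
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    return n_founders * (1 << rounds)


@dataclass(frozen=True)
class StageTally:
    """Bookkeeping for one asymmetric stage of a cascade realisation."""

    stage: int
    entered: int
    committed: int
    a1_deaths: int
    advanced: int

    def __post_init__(self) -> None:
        if self.committed + self.a1_deaths + self.advanced != self.entered:
            raise ValueError("stage tally does not conserve cells")


@dataclass
class LayerCounts:
    """Committed neurons per layer plus per-stage A1 death counts."""

    n_MZ: int = 0
    n_L6: int = 0
    n_L5: int = 0
    n_L4: int = 0
    n_L3: int = 0
    n_L2: int = 0
    a1_deaths: dict[int, int] = field(default_factory=dict)
    stages: list[StageTally] = field(default_factory=list)

    _ATTR = {LAYER_MZ: "n_MZ", LAYER_L6: "n_L6", LAYER_L5: "n_L5",
             LAYER_L4: "n_L4", LAYER_L3: "n_L3", LAYER_L2: "n_L2"}

    def __getitem__(self, layer: int) -> int:
        return getattr(self, self._ATTR[layer])

    def __setitem__(self, layer: int, value: int) -> None:
        setattr(self, self._ATTR[layer], int(value))

    @property
    def n_L23(self) -> int:
        return self.n_L2 + self.n_L3

    @property
    def total_neurons(self) -> int:
        return self.n_MZ + self.n_L6 + self.n_L5 + self.n_L4 + self.n_L3 + self.n_L2

    @property
    def total_a1_deaths(self) -> int:
        return sum(self.a1_deaths.values())

    def as_array(self) -> np.ndarray:
        """Counts ordered MZ, L6, L5, L4, L3, L2 (birth order)."""
        return np.array([self[k] for k in BIRTH_ORDER], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Per-stage tallies as a table (stage, entered, committed, a1_deaths, advanced)."""
        return pd.DataFrame(
            [(t.stage, t.entered, t.committed, t.a1_deaths, t.advanced) for t in self.stages],
            columns=["stage", "entered", "committed", "a1_deaths", "advanced"],
        )


def run_lineage_cascade(params: GRNParams, n_progenitors: int,
                        rng: np.random.Generator) -> LayerCounts:
    """One stochastic realisation of the full differentiation cascade.

    Each of the ``n_progenitors`` S2-entering progenitors first divides
    once (the proliferative round of S2, the factor 2 in the layer-1
    expectation), then every asymmetric-stage cell draws its fate;
    advancing cells divide once and both daughters enter the next stage.
    Cells are exchangeable within a stage, so the population-level
    outcome is sampled as one multinomial per stage — distributionally
    identical to per-cell draws and orders of magnitude faster.
    """
    if n_progenitors < 1:
        raise ValueError("need at least one progenitor")
    counts = LayerCounts()
    n = 2 * n_progenitors  # S2 pool after the proliferative division
    for stage in range(2, 8):
        c, p = params.stage_probs(stage)
        if stage == 7:
            p = 1.0  # terminal stage exhausts the outcome space
        probs = [c, (1.0 - c) * p, (1.0 - c) * (1.0 - p)]
        committed, died, advanced = rng.multinomial(n, probs)
        counts[STAGE_TO_LAYER[stage]] = committed
        counts.a1_deaths[stage] = int(died)
        counts.stages.append(StageTally(stage, n, int(committed), int(died), int(advanced)))
        n = 2 * int(advanced)
        if n == 0:
            break
    return counts


def lineage_replicates(params: GRNParams, n_progenitors: int, n_replicates: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Stack of per-replicate layer counts, shape (n_replicates, 6).

    Columns are ordered MZ, L6, L5, L4, L3, L2 (birth order).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    return np.stack([
        run_lineage_cascade(params, n_progenitors, rng).as_array()
        for _ in range(n_replicates)
    ])
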