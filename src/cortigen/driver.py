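"""Orchestration of a full cortical-column simulation.

A run proceeds through the phases the regulatory cascade defines:
clocked symmetric amplification of the founder sheet at the ventricular
floor, the stochastic commit/apoptose/advance cascade, radial migration
of committed neurons up the guidance gradient with layer-specific stop
rules, mechanical relaxation (heavy settled neurons pushing the light
marginal zone toward the pia), and finally neighborhood-sensing A2
apoptosis triggered by a substance secreted by settled layer-2 cells.

Sub-step order within one time step is fixed: (1) clock decay,
(2) growth/division/fate/migration/stop/A2 behaviors, (3) extracellular
diffusion, (4) force computation, (5) overdamped integration.  A run is
fully determined by its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviors as bhv
from .behaviors import (A2Params, DIVISION_DIAMETER, GROWTH_RATE, MigrationState,
                        SETTLED_DIAMETER, StopRuleParams, a2_should_die, earlier_layers)
from .fields import DiffusibleSignal, GradientField
from .grn import (GRNParams, LAYER_LABELS, LAYER_MZ, STAGE_TO_LAYER,
                  clock_steps_to_threshold)
from .physics import (Body, Bond, Domain, ForceConstants, SpatialIndex,
                      bond_forces, integrate_step, pairwise_forces)

__all__ = [
    "DiseaseVariant",
    "SimulationConfig",
    "SimulationResult",
    "World",
    "apply_disease_variant",
    "initialize",
    "step",
    "run",
]

_CBRT2 = 2.0 ** (1.0 / 3.0)


class DiseaseVariant(str, Enum):
    CONTROL = "control"
    POLYMICROGYRIA_A1 = "polymicrogyria_a1"
    POLYMICROGYRIA_SHORT = "polymicrogyria_short"
    AUTISM_NO_A2 = "autism_no_a2"
    HETEROTOPIA = "heterotopia"


@dataclass(frozen=True)
class SimulationConfig:
    """Full run configuration (everything a run depends on besides the seed)."""

    species: str = "human_temporal"
    variant: DiseaseVariant = DiseaseVariant.CONTROL
    seed: int = 0
    steps: int = 50_000
    n_founders: int = 175
    symmetric_rounds: int = 6
    founder_jitter_sd: float = 0.3
    domain_x: float = 300.0
    domain_y: float = 300.0
    domain_z: float = 1400.0
    # clocks
    clock_init: float = 100.0
    clock_decay: float = 0.01
    l6_wait_threshold: float = 95.0     # same decaying-substance mechanism as T_SYM
    # migration / stop rules
    v_mig: float = 2.0                  # um/step radial migration speed
    mz_stop_height: float = 1100.0      # height where the guidance cue crosses threshold
    # physics
    k_rep: float = 2.0
    k_adh: float = 1.0
    g_max: float = 1.0
    max_displacement: float = 3.0
    dt: float = 1.0
    division_offset_fraction: float = 0.25
    # A2 apoptosis and its trigger substance
    a2_enabled: bool = True
    a2_trigger: str = "diffusible"      # "diffusible" | "broadcast"
    a2_radius: float = 20.0
    a2_adjacent_kill: int = 3
    a2_distant_kill: int = 1
    layer1_extra_p: float = 0.9
    diffusion_coefficient: float = 60.0
    diffusion_voxel: float = 20.0
    secretion_per_step: float = 10.0
    detect_threshold: float = 2.0
    a2_commit_delay: int = 3000     # signalling latency between sensing and death
    layer1_extra_delay: int = 2500  # latency of the layer-1 Bernoulli death
    stop_exclusion_radius: float = 14.5  # sensing radius for earlier-layer neighbors
    max_arrest_steps: int = 1000    # uninterrupted arrest at the MZ ends migration
    arrest_lateral_sd: float = 1.0  # um/step tangential exploration while arrested
    # disease-variant knobs
    poly_a1_factor: float = 1.5
    poly_short_reduction: int = 2
    migration_failure_p: float = 0.0    # set by the heterotopia variant
    # output
    snapshot_every: int = 0

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        if self.a2_trigger not in ("diffusible", "broadcast"):
            raise ValueError(f"unknown a2_trigger {self.a2_trigger!r}")
        object.__setattr__(self, "variant", DiseaseVariant(self.variant))

    @property
    def domain(self) -> Domain:
        return Domain(self.domain_x, self.domain_y, self.domain_z)

    @property
    def force_constants(self) -> ForceConstants:
        return ForceConstants(self.k_rep, self.k_adh, self.g_max)

    @property
    def a2_params(self) -> A2Params:
        return A2Params(self.a2_radius, self.a2_adjacent_kill,
                        self.a2_distant_kill, self.layer1_extra_p)

    @classmethod
    def scaled(cls, **overrides) -> "SimulationConfig":
        """Scaled-down study conditions preserving the qualitative dynamics.

        44 founders, 4 symmetric rounds and 8000 steps in a 70 um x
        70 um column cross-section (the narrower footprint keeps each
        layer several cell monolayers thick at the reduced cell
        numbers, so radial segregation remains observable).
        """
        kw = dict(n_founders=44, symmetric_rounds=4, steps=8000,
                  domain_x=70.0, domain_y=70.0)
        kw.update(overrides)
        return cls(**kw)

    def to_metadata(self) -> dict:
        d = dataclasses.asdict(self)
        d["variant"] = self.variant.value
        return d


def apply_disease_variant(params: GRNParams, config: SimulationConfig) -> tuple[GRNParams, SimulationConfig]:
    """Translate the selected disease variant into parameter changes.

    CONTROL is the identity; the others modify exactly one mechanism:
    scaled-up A1 probabilities, a shortened amplification phase, a
    disabled A2 module, or a per-neuron migration-failure chance.
    """
    v = config.variant
    if v is DiseaseVariant.CONTROL:
        return params, config
    if v is DiseaseVariant.POLYMICROGYRIA_A1:
        return params.with_apoptosis_scaled(config.poly_a1_factor), config
    if v is DiseaseVariant.POLYMICROGYRIA_SHORT:
        rounds = max(1, config.symmetric_rounds - config.poly_short_reduction)
        return params, dataclasses.replace(config, symmetric_rounds=rounds)
    if v is DiseaseVariant.AUTISM_NO_A2:
        return params, dataclasses.replace(config, a2_enabled=False)
    if v is DiseaseVariant.HETEROTOPIA:
        return params, dataclasses.replace(config, migration_failure_p=0.2)
    raise ValueError(f"unknown disease variant {v!r}")


def founder_grid(n: int, lx: float, ly: float) -> np.ndarray:
    """Regular near-square grid with >= n nodes; first n nodes used."""
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    sx, sy = lx / nx, ly / ny
    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    return pts


class World:
    """Mutable population state, stored as parallel arrays.

    Cells are append-only; ``alive`` masks the dead.  ``stage`` is 1..7
    for progenitors and 0 once committed; ``layer`` uses anatomical
    codes (MZ=1, L2=2, ..., L6=6, 0 = uncommitted).
    """

    def __init__(self, config: SimulationConfig):
        params = GRNParams.from_preset(config.species,
                                       symmetric_rounds=config.symmetric_rounds,
                                       clock_init=config.clock_init,
                                       clock_decay=config.clock_decay)
        params, config = apply_disease_variant(params, config)
        # a variant may change the round count; keep the clock schedule in sync
        params = dataclasses.replace(params, symmetric_rounds=config.symmetric_rounds)
        self.config = config
        self.params = params
        self.domain = config.domain
        self.rng = np.random.default_rng(config.seed)
        self.gradient = GradientField(0.0, 1.0 / config.domain_z)
        self.stop_params = StopRuleParams(
            mz_conc_threshold=self.gradient.threshold_for_height(config.mz_stop_height))
        self.signal = DiffusibleSignal(self.domain, config.diffusion_voxel,
                                       config.diffusion_coefficient, config.dt)
        self.bonds: list[Bond] = []
        self.events: list[tuple] = []
        self.step_no = 0
        self.broadcast_on = False
        self.first_settle_step: dict[int, int] = {}
        self.snapshots: list[tuple[int, dict[str, int]]] = []

        # amplification schedule: `symmetric_rounds` synchronous divisions
        # spread uniformly inside the clock window, then the S1->S2
        # transition division when the clock crosses T_SYM
        self.amplification_window = clock_steps_to_threshold(
            params.clock_init, params.clock_decay, params.T_SYM)
        rounds = params.symmetric_rounds
        sched = [int(round(self.amplification_window * k / (rounds + 1)))
                 for k in range(1, rounds + 1)]
        sched = [max(1, s) for s in sched]
        if len(set(sched)) != rounds:
            raise ValueError("amplification window too short for the requested rounds")
        self.division_schedule = frozenset(sched)

        n = config.n_founders
        pts = founder_grid(n, config.domain_x, config.domain_y)
        pts = pts + self.rng.normal(0.0, config.founder_jitter_sd, size=pts.shape)
        self.pos = np.column_stack([pts, np.zeros(n)])
        np.clip(self.pos[:, 0], 0.0, config.domain_x, out=self.pos[:, 0])
        np.clip(self.pos[:, 1], 0.0, config.domain_y, out=self.pos[:, 1])
        self.diam = np.full(n, DIVISION_DIAMETER)
        self.mass = np.ones(n)
        self.adher = np.ones(n)
        self.fc = np.ones(n)
        self.stage = np.ones(n, dtype=np.int16)
        self.layer = np.zeros(n, dtype=np.int16)
        self.mig = np.full(n, MigrationState.QUIESCENT, dtype=np.int8)
        self.alive = np.ones(n, dtype=bool)
        self.clock = np.full(n, params.clock_init)
        self.a2_done = np.zeros(n, dtype=bool)
        self.a2_onset = np.full(n, -1, dtype=np.int64)
        self.l1_drawn = np.zeros(n, dtype=bool)
        self.arrested = np.zeros(n, dtype=np.int32)
        self.stranded = np.zeros(n, dtype=bool)
        self.escaped = np.zeros(n, dtype=bool)
        self.bond_pending = np.zeros(n, dtype=bool)

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.diam)

    def log(self, cell_ids, event: str, layer=0, stage=0) -> None:
        ids = np.atleast_1d(np.asarray(cell_ids, dtype=int))
        layers = np.broadcast_to(np.atleast_1d(layer), ids.shape)
        stages = np.broadcast_to(np.atleast_1d(stage), ids.shape)
        for i, l, s in zip(ids, layers, stages):
            self.events.append((self.step_no, int(i), event, int(l), int(s)))

    def _append(self, **arrays) -> np.ndarray:
        """Append daughter cells; returns their new global indices."""
        k = len(arrays["pos"])
        start = self.n_cells
        self.pos = np.vstack([self.pos, arrays["pos"]])
        self.diam = np.append(self.diam, arrays["diam"])
        self.mass = np.append(self.mass, arrays["mass"])
        self.adher = np.append(self.adher, arrays["adher"])
        self.fc = np.append(self.fc, arrays["fc"])
        self.stage = np.append(self.stage, arrays["stage"].astype(np.int16))
        self.layer = np.append(self.layer, np.zeros(k, dtype=np.int16))
        self.mig = np.append(self.mig, np.full(k, MigrationState.QUIESCENT, dtype=np.int8))
        self.alive = np.append(self.alive, np.ones(k, dtype=bool))
        self.clock = np.append(self.clock, arrays["clock"])
        self.a2_done = np.append(self.a2_done, np.zeros(k, dtype=bool))
        self.a2_onset = np.append(self.a2_onset, np.full(k, -1, dtype=np.int64))
        self.l1_drawn = np.append(self.l1_drawn, np.zeros(k, dtype=bool))
        self.arrested = np.append(self.arrested, np.zeros(k, dtype=np.int32))
        self.stranded = np.append(self.stranded, np.zeros(k, dtype=bool))
        self.escaped = np.append(self.escaped, np.zeros(k, dtype=bool))
        self.bond_pending = np.append(self.bond_pending, np.zeros(k, dtype=bool))
        return np.arange(start, start + k)

    def _divide(self, idx: np.ndarray, daughter_stage: np.ndarray) -> None:
        """Synchronous division: parents become one daughter in place,
        the second daughter is appended.  Volume is conserved."""
        idx = np.sort(np.asarray(idx, dtype=int))
        if idx.size == 0:
            return
        d_new = self.diam[idx] / _CBRT2
        axes = self.rng.normal(size=(idx.size, 3))
        axes /= np.linalg.norm(axes, axis=1)[:, None]
        offsets = self.config.division_offset_fraction * 0.5 * d_new[:, None] * axes
        pos2 = self.pos[idx] - offsets
        self.pos[idx] += offsets
        self.diam[idx] = d_new
        self.stage[idx] = daughter_stage
        self.clock[idx] = self.clock[idx]  # clock substance copied, not split
        new = self._append(pos=pos2, diam=d_new, mass=self.mass[idx].copy(),
                           adher=self.adher[idx].copy(), fc=self.fc[idx].copy(),
                           stage=np.asarray(daughter_stage), clock=self.clock[idx].copy())
        # keep every body inside the column
        for cells in (idx, new):
            self.pos[cells, 0] = np.clip(self.pos[cells, 0], 0.0, self.domain.lx)
            self.pos[cells, 1] = np.clip(self.pos[cells, 1], 0.0, self.domain.ly)
            self.pos[cells, 2] = np.clip(self.pos[cells, 2], 0.0, self.domain.lz)

    # -- per-step phases ----------------------------------------------

    def _decay_clocks(self) -> None:
        running = self.alive & ((self.stage == 1) | (self.mig == MigrationState.WAITING))
        self.clock[running] *= (1.0 - self.params.clock_decay)

    def _amplification_phase(self) -> None:
        s1 = self.alive & (self.stage == 1)
        if not np.any(s1):
            return
        grow = s1 & (self.diam < DIVISION_DIAMETER)
        self.diam[grow] = np.minimum(self.diam[grow] + GROWTH_RATE, DIVISION_DIAMETER)
        if self.step_no in self.division_schedule:
            idx = np.flatnonzero(s1)
            self._divide(idx, np.ones(idx.size, dtype=np.int16))
        # end of symmetric division: every S1 cell divides once into two
        # S2 cells (the proliferative round of state S2)
        s1 = self.alive & (self.stage == 1)
        ending = s1 & (self.clock < self.params.T_SYM)
        if np.any(ending):
            idx = np.flatnonzero(ending)
            self._divide(idx, np.full(idx.size, 2, dtype=np.int16))

    def _fate_phase(self) -> None:
        prog = self.alive & (self.stage >= 2) & (self.stage <= 7)
        grow = prog & (self.diam < DIVISION_DIAMETER)
        self.diam[grow] = np.minimum(self.diam[grow] + GROWTH_RATE, DIVISION_DIAMETER)
        ready = np.flatnonzero(prog & (self.diam >= DIVISION_DIAMETER - 1e-9))
        if ready.size == 0:
            return
        ready = np.sort(ready)
        stages = self.stage[ready]
        cs = np.empty(ready.size)
        ps = np.empty(ready.size)
        for s in np.unique(stages):
            c, p = self.params.stage_probs(int(s))
            if int(s) == 7:
                p = 1.0  # terminal stage: commit or die, nothing advances
            sel = stages == s
            cs[sel], ps[sel] = c, p
        u = self.rng.random(ready.size)
        commit = u < cs
        apoptose = ~commit & (u < cs + (1.0 - cs) * ps)
        advance = ~commit & ~apoptose

        # A1 apoptosis
        died = ready[apoptose]
        if died.size:
            self.alive[died] = False
            self.log(died, "a1_death", stage=stages[apoptose])

        # commitment to a layer fate
        com = ready[commit]
        if com.size:
            layers = np.array([STAGE_TO_LAYER[int(s)] for s in stages[commit]], dtype=np.int16)
            self.stage[com] = 0
            self.layer[com] = layers
            self.log(com, "commit", layer=layers)
            fail_p = self.config.migration_failure_p
            failed = (self.rng.random(com.size) < fail_p) if fail_p > 0 else np.zeros(com.size, bool)
            ok = ~failed
            if np.any(failed):
                self.mig[com[failed]] = MigrationState.QUIESCENT
                self.stranded[com[failed]] = True
                self.log(com[failed], "stranded", layer=layers[failed])
            waits = ok & (layers == 6)
            goes = ok & (layers != 6)
            self.mig[com[waits]] = MigrationState.WAITING
            self.clock[com[waits]] = self.params.clock_init
            self.mig[com[goes]] = MigrationState.MIGRATING
            self.fc[com[ok]] = 1e-4  # migratory cells barely receive forces

        # advance: one more division, daughters enter the next stage
        adv = ready[advance]
        if adv.size:
            self._divide(adv, (stages[advance] + 1).astype(np.int16))

    def _waiting_phase(self) -> None:
        waiting = self.alive & (self.mig == MigrationState.WAITING)
        release = waiting & (self.clock < self.config.l6_wait_threshold)
        if np.any(release):
            self.mig[release] = MigrationState.MIGRATING

    def _settle(self, idx: np.ndarray) -> None:
        idx = np.sort(np.asarray(idx, dtype=int))
        self.mig[idx] = MigrationState.SETTLED
        self.log(idx, "settle", layer=self.layer[idx])
        mz = self.layer[idx] == LAYER_MZ
        self.mass[idx[mz]] = 1e-4
        self.adher[idx[mz]] = 1e-4
        self.fc[idx[mz]] = 1.0
        self.bond_pending[idx[mz]] = True
        other = ~mz
        self.mass[idx[other]] = 10.0
        self.fc[idx[other]] = 1.0
        for l in np.unique(self.layer[idx]):
            self.first_settle_step.setdefault(int(l), self.step_no)

    def _migration_phase(self) -> None:
        mig = self.alive & (self.mig == MigrationState.MIGRATING)
        if not np.any(mig):
            return

        to_settle: list[int] = []
        # MZ cells ascend and stop on the guidance-cue concentration alone
        mz_mig = np.flatnonzero(mig & (self.layer == LAYER_MZ))
        if mz_mig.size:
            self.pos[mz_mig, 2] = np.minimum(self.pos[mz_mig, 2] + self.config.v_mig,
                                             self.domain.lz)
            conc = self.gradient.concentration_at(self.pos[mz_mig])
            to_settle.extend(mz_mig[conc >= self.stop_params.mz_conc_threshold].tolist())

        # Cortical-plate cells ascend until they contact the settled MZ
        # (the marginal zone / pial membrane arrests radial migration),
        # then trail its underside and settle once the layer-specific
        # neighbor composition is right.  The earlier-layer exclusion
        # counts every earlier-born neuron still in the column, settled
        # or migrating, which is what serialises the waves.
        settled = self.alive & (self.mig == MigrationState.SETTLED)
        cp_mig = np.flatnonzero(mig & (self.layer != LAYER_MZ) & (self.layer > 0))
        ascend = np.ones(self.n_cells, dtype=bool)
        if cp_mig.size and np.any(settled):
            nb_mask = self.alive & (self.layer > 0) & (
                (self.mig == MigrationState.SETTLED) | (self.mig == MigrationState.MIGRATING))
            sidx = np.flatnonzero(nb_mask)
            s_settled_mz = (self.mig[sidx] == MigrationState.SETTLED) & (self.layer[sidx] == LAYER_MZ)
            contact_max = 0.5 * (DIVISION_DIAMETER + SETTLED_DIAMETER) + self.config.g_max
            r_query = max(contact_max, self.config.stop_exclusion_radius)
            # cells still far below the settled plate cannot have contacts
            z_floor = self.pos[settled, 2].min() - r_query
            near = cp_mig[self.pos[cp_mig, 2] >= z_floor]
            if near.size:
                tree = SpatialIndex(self.pos[sidx])
                hits = tree.neighbors_within_many(self.pos[near], r_query)
                s_layer = self.layer[sidx]
                s_diam = self.diam[sidx]
                s_pos = self.pos[sidx]
                for i, hit in zip(near, hits):
                    if hit.size == 0:
                        continue
                    hit = hit[sidx[hit] != i]
                    d = np.linalg.norm(s_pos[hit] - self.pos[i], axis=1)
                    # settled-MZ detection is by physical contact; the
                    # earlier-layer exclusion senses a wider neighborhood
                    contact = d <= 0.5 * (self.diam[i] + s_diam[hit]) + self.config.g_max
                    n_mz = int(np.sum(s_settled_mz[hit] & contact))
                    earlier = earlier_layers(int(self.layer[i]))
                    n_earlier = 0
                    if earlier:
                        within = d <= self.config.stop_exclusion_radius
                        n_earlier = int(np.sum(np.isin(s_layer[hit], list(earlier)) & within))
                    if bhv.should_stop(int(self.layer[i]), n_mz, n_earlier,
                                       0.0, self.stop_params):
                        to_settle.append(int(i))
                        ascend[i] = False
                    elif n_mz >= 1:
                        ascend[i] = False  # arrested at the MZ underside
                        self.arrested[i] += 1
                        if self.arrested[i] >= self.config.max_arrest_steps:
                            # prolonged arrest terminates migration
                            to_settle.append(int(i))
        movers = cp_mig[ascend[cp_mig]]
        self.arrested[movers] = 0  # only uninterrupted arrest ends migration
        self.pos[movers, 2] = np.minimum(self.pos[movers, 2] + self.config.v_mig,
                                         self.domain.lz)
        # arrested cells disperse tangentially, exploring for a free
        # settling pocket at the MZ underside
        parked = cp_mig[~ascend[cp_mig]]
        if parked.size and self.config.arrest_lateral_sd > 0:
            parked = np.sort(parked)
            wander = self.rng.normal(0.0, self.config.arrest_lateral_sd, size=(parked.size, 2))
            self.pos[parked, 0] = np.clip(self.pos[parked, 0] + wander[:, 0], 0.0, self.domain.lx)
            self.pos[parked, 1] = np.clip(self.pos[parked, 1] + wander[:, 1], 0.0, self.domain.ly)
        newly_escaped = mig & ~self.escaped & (self.pos[:, 2] >= self.domain.lz - 1e-9)
        if np.any(newly_escaped):
            self.escaped[newly_escaped] = True
            self.log(np.flatnonzero(newly_escaped), "escaped", layer=self.layer[newly_escaped])
        if to_settle:
            self._settle(np.array(sorted(set(to_settle)), dtype=int))

    def _bond_phase(self) -> None:
        # an MZ cell whose bond broke (or whose partner died) re-bonds,
        # keeping the marginal zone a connected sheet
        for bond in self.bonds:
            if not bond.broken and not (self.alive[bond.i] and self.alive[bond.j]):
                bond.broken = True
            if bond.broken and self.alive[bond.i] and not self.bond_pending[bond.i]:
                if self.mig[bond.i] == MigrationState.SETTLED and self.layer[bond.i] == LAYER_MZ:
                    self.bond_pending[bond.i] = True
        self.bonds = [b for b in self.bonds if not b.broken]
        pending = np.flatnonzero(self.bond_pending & self.alive)
        if pending.size == 0:
            return
        settled_mz = self.alive & (self.mig == MigrationState.SETTLED) & (self.layer == LAYER_MZ)
        cand = np.flatnonzero(settled_mz)
        if cand.size < 2:
            return  # bond deferred until a partner exists
        tree = SpatialIndex(self.pos[cand])
        for i in pending:
            d, j = tree._tree.query(self.pos[i], k=2)
            partner = cand[j[1]] if cand[j[0]] == i else cand[j[0]]
            # touching rest length (floored so a long re-bond starts
            # inside its breaking strain and reels the pair in)
            dist = float(np.linalg.norm(self.pos[partner] - self.pos[i]))
            rest = max(0.5 * (self.diam[i] + self.diam[partner]), dist / 4.0)
            self.bonds.append(Bond(int(i), int(partner), rest))
            self.bond_pending[i] = False

    def _settled_growth_phase(self) -> None:
        settled = self.alive & (self.mig == MigrationState.SETTLED)
        grow = settled & (self.diam < SETTLED_DIAMETER)
        self.diam[grow] = np.minimum(self.diam[grow] + GROWTH_RATE, SETTLED_DIAMETER)

    def _a2_phase(self) -> None:
        if not self.config.a2_enabled:
            return
        cfg = self.config
        a2p = cfg.a2_params
        settled = self.alive & (self.mig == MigrationState.SETTLED)
        l2_settled = settled & (self.layer == 2)
        if not np.any(l2_settled) and not self.broadcast_on:
            return  # A2 cannot start before the first layer-2 cell settles
        if cfg.a2_trigger == "broadcast":
            self.broadcast_on = True
        elif np.any(l2_settled):
            self.signal.secrete(self.pos[l2_settled], cfg.secretion_per_step)

        # trigger onset per cell: a settled cell that senses the
        # substance records the onset and (layer 1 only) draws the extra
        # Bernoulli immediately; the neighborhood-sensing death follows
        # after a short signalling latency, so the heavily pruned
        # marginal zone no longer dominates its neighbors' counts
        cand = np.flatnonzero(settled & (self.a2_onset < 0))
        if cand.size:
            if cfg.a2_trigger == "broadcast":
                newly = np.sort(cand)
            else:
                newly = np.sort(cand[self.signal.sense_many(self.pos[cand], cfg.detect_threshold)])
            if newly.size:
                self.a2_onset[newly] = self.step_no

        # the layer-1 extra Bernoulli, drawn exactly once per cell after
        # its own latency
        mz_due = np.flatnonzero(self.alive & ~self.l1_drawn & (self.layer == LAYER_MZ)
                                & (self.a2_onset >= 0)
                                & (self.step_no - self.a2_onset >= cfg.layer1_extra_delay))
        if mz_due.size and a2p.layer1_extra_p > 0:
            mz_due = np.sort(mz_due)
            self.l1_drawn[mz_due] = True
            draws = self.rng.random(mz_due.size)
            extras = mz_due[draws < a2p.layer1_extra_p]
            if extras.size:
                self.alive[extras] = False
                self.log(extras, "l1_extra_death", layer=self.layer[extras])

        settled = self.alive & (self.mig == MigrationState.SETTLED)
        due = np.flatnonzero(settled & ~self.a2_done & (self.a2_onset >= 0)
                             & (self.step_no - self.a2_onset >= cfg.a2_commit_delay))
        if due.size == 0:
            return
        due = np.sort(due)
        self.a2_done[due] = True
        sidx = np.flatnonzero(settled)
        tree = SpatialIndex(self.pos[sidx])
        pairs = tree.pairs_within(a2p.radius)
        # per-cell neighbor counts by anatomical layer
        by_layer = np.zeros((self.n_cells, 8), dtype=np.int32)
        if len(pairs):
            gi, gj = sidx[pairs[:, 0]], sidx[pairs[:, 1]]
            np.add.at(by_layer, (gi, self.layer[gj]), 1)
            np.add.at(by_layer, (gj, self.layer[gi]), 1)
        own = self.layer[due].astype(int)
        below = np.where(own - 1 >= 1, own - 1, 7)
        above = np.where(own + 1 <= 6, own + 1, 7)
        n_adj_max = np.maximum(by_layer[due, below], by_layer[due, above])
        all_counts = by_layer[due, 1:7]
        dist_mask = np.abs(np.arange(1, 7)[None, :] - own[:, None]) >= 2
        n_dist = np.sum(all_counts * dist_mask, axis=1)
        doomed = due[(n_adj_max >= a2p.adjacent_layer_kill_count)
                     | (n_dist >= a2p.distant_layer_kill_count)]
        if doomed.size:
            self.alive[doomed] = False
            self.log(doomed, "a2_death", layer=self.layer[doomed])

    def _chemistry_phase(self) -> None:
        if self.config.a2_trigger == "diffusible" and self.signal.total_mass > 0:
            self.signal.diffuse_step()

    def _mechanics_phase(self) -> None:
        aidx = np.flatnonzero(self.alive)
        if aidx.size == 0:
            return
        tree = SpatialIndex(self.pos[aidx])
        r_max = float(self.diam[aidx].max()) + self.config.g_max
        pairs = tree.pairs_within(r_max)
        forces_local = pairwise_forces(self.pos[aidx], self.diam[aidx], self.adher[aidx],
                                       self.fc[aidx], pairs, self.config.force_constants)
        forces = np.zeros_like(self.pos)
        forces[aidx] = forces_local
        for bond in self.bonds:
            if not bond.broken and not (self.alive[bond.i] and self.alive[bond.j]):
                bond.broken = True
        forces += bond_forces(self.pos, self.bonds)
        new_pos = integrate_step(self.pos[aidx], self.mass[aidx], forces[aidx],
                                 self.config.dt, self.domain, self.config.max_displacement)
        self.pos[aidx] = new_pos

    def step(self) -> None:
        self.step_no += 1
        self._decay_clocks()
        self._amplification_phase()
        self._fate_phase()
        self._waiting_phase()
        self._migration_phase()
        self._bond_phase()
        self._settled_growth_phase()
        self._a2_phase()
        self._chemistry_phase()
        self._mechanics_phase()
        if self.config.snapshot_every and self.step_no % self.config.snapshot_every == 0:
            counts = {LAYER_LABELS[l]: int(np.sum(self.alive & (self.layer == l)))
                      for l in range(1, 7)}
            counts["progenitors"] = int(np.sum(self.alive & (self.stage > 0)))
            self.snapshots.append((self.step_no, counts))

    # -- export --------------------------------------------------------

    def positions_table(self) -> pd.DataFrame:
        """Exported position table (one record per cell ever created)."""
        labels = np.array(["none"] + [LAYER_LABELS[l] for l in range(1, 7)])
        return pd.DataFrame({
            "cell_id": np.arange(self.n_cells),
            "layer": labels[self.layer],
            "x_um": self.pos[:, 0],
            "y_um": self.pos[:, 1],
            "z_um": self.pos[:, 2],
            "diameter_um": self.diam,
            "alive": self.alive,
            "settled": self.mig == MigrationState.SETTLED,
            "stranded": self.stranded,
            "escaped": self.escaped,
        })

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["step", "cell_id", "event", "layer", "stage"])


def initialize(config: SimulationConfig) -> World:
    """Founder sheet at the ventricular floor, all in state S1."""
    return World(config)


def step(world: World) -> World:
    world.step()
    return world


@dataclass
class SimulationResult:
    positions: pd.DataFrame
    events: pd.DataFrame
    config: SimulationConfig
    first_settle_step: dict[int, int]
    snapshots: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def alive_counts(self) -> dict[str, int]:
        df = self.positions[self.positions["alive"]]
        out = df[df["layer"] != "none"].groupby("layer").size().to_dict()
        out["total_alive"] = int(df.shape[0])
        return out

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.positions.to_csv(out / "positions.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        meta = {
            "config": self.config.to_metadata(),
            "first_settle_step": {LAYER_LABELS[k]: v for k, v in self.first_settle_step.items()},
            "wall_time_s": self.wall_time_s,
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2))
        if self.snapshots:
            pd.DataFrame(
                [{"step": s, **c} for s, c in self.snapshots]
            ).to_csv(out / "snapshots.csv", index=False)
        return out


def run(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulationResult:
    """Execute ``config.steps`` steps from a fresh initial state."""
    t0 = time.perf_counter()
    world = initialize(config)
    for _ in range(config.steps):
        world.step()
    result = SimulationResult(
        positions=world.positions_table(),
        events=world.events_table(),
        config=world.config,
        first_settle_step=dict(world.first_settle_step),
        snapshots=world.snapshots,
        wall_time_s=time.perf_counter() - t0,
    )
    if out_dir is not None:
        result.save(out_dir)
    return result
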