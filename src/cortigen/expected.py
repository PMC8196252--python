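"""Closed-form expected layer counts and the experimental-unit conversion.

The cascade admits simple mean-field expectations.  With ``N_P``
progenitors entering the asymmetric phase, the expected number of
committed neurons per layer is a product of the doubling prefactor
``2^k`` (one division per stage passed), the per-stage survival factors
``(1-C)(1-P)`` of all earlier stages, and the commitment probability of
the deciding stage:

    N_1 = 2   N_P C_M
    N_6 = 2^2 N_P (1-C_M)(1-P_M) C_6
    N_5 = 2^3 N_P (1-C_M)(1-P_M)(1-C_6)(1-P_6) C_5
    ...
    N_2 = 2^6 N_P (1-C_M)(1-P_M) ... (1-C_3)(1-P_3) C_2

Setting every ``P`` to zero gives the no-apoptosis variant, in which
the layers are strictly coupled: raising any earlier commitment
probability necessarily lowers every later expectation.  Apoptosis
breaks that coupling, which is the flexibility argument the model makes.

Experimental reference counts are neurons under 1 mm^2 of adult cortex;
the simulated column covers 300 um x 300 um and precedes the ~25% of
postnatal neuron death, hence the conversion factor 0.3*0.3/0.75.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .grn import BIRTH_ORDER, GRNParams, LAYER_LABELS

__all__ = [
    "ExpectedLayerCounts",
    "expected_with_apoptosis",
    "expected_without_apoptosis",
    "mm2_to_column",
    "column_to_mm2",
    "agreement_test",
    "experimental_targets",
    "MM2_TO_COLUMN_FACTOR",
]

#: 300 um x 300 um column area (mm^2) over the 75% of neurons surviving postnatally
MM2_TO_COLUMN_FACTOR = 0.3 * 0.3 / 0.75


@dataclass(frozen=True)
class ExpectedLayerCounts:
    """Expected neurons per layer (anatomical numbering) for a pool N_P."""

    N_1: float
    N_2: float
    N_3: float
    N_4: float
    N_5: float
    N_6: float
    N_P: float

    @property
    def N_23(self) -> float:
        return self.N_2 + self.N_3

    @property
    def total(self) -> float:
        return self.N_1 + self.N_2 + self.N_3 + self.N_4 + self.N_5 + self.N_6

    def __getitem__(self, layer: int) -> float:
        return getattr(self, f"N_{int(layer)}")

    def as_array(self) -> np.ndarray:
        """Expectations ordered MZ, L6, L5, L4, L3, L2 (birth order)."""
        return np.array([self[k] for k in BIRTH_ORDER], dtype=float)

    def to_series(self) -> pd.Series:
        return pd.Series({LAYER_LABELS[k]: self[k] for k in BIRTH_ORDER})


def expected_with_apoptosis(params: GRNParams, n_progenitors: float) -> ExpectedLayerCounts:
    """Mean-field layer counts with A1 apoptosis active."""
    out = {}
    survival = 1.0
    prefactor = 2.0
    for stage, layer in zip(range(2, 8), (1, 6, 5, 4, 3, 2)):
        c, p = params.stage_probs(stage)
        out[layer] = prefactor * n_progenitors * survival * c
        survival *= (1.0 - c) * (1.0 - p)
        prefactor *= 2.0
    return ExpectedLayerCounts(
        N_1=out[1], N_2=out[2], N_3=out[3], N_4=out[4], N_5=out[5], N_6=out[6],
        N_P=float(n_progenitors),
    )


def expected_without_apoptosis(params: GRNParams, n_progenitors: float) -> ExpectedLayerCounts:
    """Mean-field layer counts of the same cascade with every P set to 0."""
    return expected_with_apoptosis(params.without_apoptosis(), n_progenitors)


def mm2_to_column(count_per_mm2: float) -> float:
    """Adult per-mm^2 count -> expected simulated column count."""
    if np.any(np.asarray(count_per_mm2) < 0):
        raise ValueError("counts must be non-negative")
    return count_per_mm2 * MM2_TO_COLUMN_FACTOR


def column_to_mm2(column_count: float) -> float:
    """Simulated column count -> adult per-mm^2 equivalent (inverse conversion)."""
    if np.any(np.asarray(column_count) < 0):
        raise ValueError("counts must be non-negative")
    return column_count / MM2_TO_COLUMN_FACTOR


def experimental_targets(species: str | None = None) -> pd.DataFrame:
    """Bundled per-mm^2 layer counts, with the derived column targets.

    Returns a frame with columns ``species, layer, neurons_per_mm2,
    column_target``; optionally filtered to one species.
    """
    with resources.files("cortigen.data").joinpath("layer_counts_mm2.csv").open() as fh:
        df = pd.read_csv(fh)
    df["column_target"] = mm2_to_column(df["neurons_per_mm2"].to_numpy(dtype=float))
    if species is not None:
        df = df[df["species"] == species].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"no experimental targets for species {species!r}")
    return df


def agreement_test(sim_replicate_counts, experimental_mean: float,
                   experimental_sd: float, n_exp: int,
                   alpha: float = 0.05) -> tuple[bool, float, bool]:
    """Welch two-sample t-test of simulated replicates against an
    experimental summary, plus a 95% CI containment check.

    Returns ``(not_rejected, p_value, sim_mean_within_exp_ci)`` where
    ``not_rejected`` is True when the equal-means null survives at the
    given significance level.
    """
    sim = np.asarray(sim_replicate_counts, dtype=float)
    if sim.size < 2:
        raise ValueError("need at least two simulated replicates")
    if n_exp < 2:
        raise ValueError("need at least two experimental observations")
    sim_mean = float(sim.mean())
    sim_sd = float(sim.std(ddof=1))
    if sim_sd == 0.0 and experimental_sd == 0.0:
        if sim_mean == experimental_mean:
            return True, 1.0, True
        raise ValueError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind_from_stats(
        sim_mean, sim_sd, sim.size,
        experimental_mean, experimental_sd, n_exp,
        equal_var=False,
    )
    half_width = stats.t.ppf(1.0 - alpha / 2.0, df=n_exp - 1) * experimental_sd / np.sqrt(n_exp)
    within_ci = abs(sim_mean - experimental_mean) <= half_width
    return bool(p > alpha), float(p), bool(within_ci)
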