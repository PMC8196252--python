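"""Extracellular fields: the static radial guidance gradient and the
diffusible substance that triggers post-migration (A2) apoptosis.

The guidance gradient is a fixed linear profile increasing toward the
pia; marginal-zone cells stop migrating when the sensed concentration
reaches a threshold, which places the future layer 1 at a configurable
height and thereby sets the ventricular-zone-to-cortex distance.

The trigger substance lives on a coarse voxel grid and follows an
explicit (FTCS) diffusion scheme with zero-flux boundaries; it is
secreted by settled layer-2 cells and sensed at the nearest voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import Domain

__all__ = ["GradientField", "DiffusibleSignal", "concentration_at", "diffuse_step", "sense"]


@dataclass(frozen=True)
class GradientField:
    """Linear pial guidance cue ``c(z) = c0 + slope * z`` (slope > 0)."""

    c0: float = 0.0
    slope: float = 1.0 / 1400.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("gradient must increase toward the pia (slope > 0)")

    def concentration_at(self, p) -> float:
        z = np.asarray(p, dtype=float)
        z = z[..., 2] if z.ndim and z.shape[-1] == 3 else z
        return self.c0 + self.slope * z

    def crossing_height(self, c_stop: float) -> float:
        """Height z* at which the profile first reaches ``c_stop``."""
        return (c_stop - self.c0) / self.slope

    def threshold_for_height(self, z: float) -> float:
        return self.c0 + self.slope * z


def concentration_at(field: GradientField, p) -> float:
    return field.concentration_at(p)


class DiffusibleSignal:
    """Mass-conserving diffusible substance on a coarse 3D grid.

    Explicit finite differences with zero-flux (reflecting) boundaries;
    the stability criterion ``D*dt/h^2 <= 1/6`` is enforced at
    construction.  There is no decay, so total mass equals total
    secreted mass up to floating-point error.
    """

    def __init__(self, domain: Domain, voxel: float = 20.0,
                 diffusion_coefficient: float = 50.0, dt: float = 1.0):
        if voxel <= 0:
            raise ValueError("voxel size must be positive")
        if diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        stability = diffusion_coefficient * dt / voxel**2
        if stability > 1.0 / 6.0:
            raise ValueError(
                f"explicit diffusion unstable: D*dt/h^2 = {stability:.3g} > 1/6; "
                "coarsen the grid or reduce D or dt"
            )
        self.domain = domain
        self.voxel = float(voxel)
        self.D = float(diffusion_coefficient)
        self.dt = float(dt)
        self.shape = (
            max(1, int(np.ceil(domain.lx / voxel))),
            max(1, int(np.ceil(domain.ly / voxel))),
            max(1, int(np.ceil(domain.lz / voxel))),
        )
        self.concentration = np.zeros(self.shape)

    @property
    def total_mass(self) -> float:
        return float(self.concentration.sum())

    def voxel_index(self, p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        if np.any(p < -1e-9) or np.any(p > [self.domain.lx + 1e-9,
                                            self.domain.ly + 1e-9,
                                            self.domain.lz + 1e-9]):
            raise ValueError("position outside the simulation domain")
        idx = np.floor(p / self.voxel).astype(int)
        idx = np.minimum(idx, np.array(self.shape) - 1)
        idx = np.maximum(idx, 0)
        return idx[:, 0], idx[:, 1], idx[:, 2]

    def secrete(self, positions, amount: float) -> None:
        """Deposit ``amount`` (per position) into the nearest voxels."""
        ix, iy, iz = self.voxel_index(positions)
        np.add.at(self.concentration, (ix, iy, iz), amount)

    def diffuse_step(self) -> None:
        """One explicit diffusion step (zero-flux boundaries)."""
        if self.D == 0.0:
            return
        c = self.concentration
        padded = np.pad(c, 1, mode="edge")
        lap = (
            padded[2:, 1:-1, 1:-1] + padded[:-2, 1:-1, 1:-1]
            + padded[1:-1, 2:, 1:-1] + padded[1:-1, :-2, 1:-1]
            + padded[1:-1, 1:-1, 2:] + padded[1:-1, 1:-1, :-2]
            - 6.0 * c
        )
        self.concentration = c + self.D * self.dt / self.voxel**2 * lap

    def sense(self, p, threshold: float) -> bool:
        """True when the nearest-voxel concentration reaches ``threshold``
        (inclusive)."""
        ix, iy, iz = self.voxel_index(p)
        return bool(self.concentration[ix[0], iy[0], iz[0]] >= threshold)

    def sense_many(self, positions, threshold: float) -> np.ndarray:
        ix, iy, iz = self.voxel_index(positions)
        return self.concentration[ix, iy, iz] >= threshold


def diffuse_step(signal: DiffusibleSignal, dt: float | None = None) -> DiffusibleSignal:
    """Functional wrapper over :meth:`DiffusibleSignal.diffuse_step`."""
    if dt is not None and dt != signal.dt:
        raise ValueError("signal was configured with a different dt")
    signal.diffuse_step()
    return signal


def sense(signal: DiffusibleSignal, p, threshold: float) -> bool:
    return signal.sense(p, threshold)
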