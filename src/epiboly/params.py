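"""Model constants for the three-force epiboly simulation.

Parameter roles
---------------
``U_0``   elastic constant of the EVL vertex springs (min⁻¹ under unit
          mobility: velocity response per μm of spring strain).
``V_0``   constant speed of the free (vegetal) EVL border, μm/min.
``U_1``   DCL–DCL soft-sphere repulsion amplitude (min⁻¹ per μm of overlap).
``U_2``   amplitude of the Gaussian attraction well centred on EVL cell
          borders, in the model's native dimensionless units; the declared
          ``ATTRACTION_SCALE`` converts it to a well depth in μm²/min.
``a_2``   Gaussian length of the border well, μm.
``sigma`` autonomous-noise amplitude in the model's native dimensionless
          units; the declared ``SIGMA_TO_D`` maps it to a tangential
          diffusion coefficient D_n = sigma·SIGMA_TO_D in μm²/min.
``drag``  dimensionless coupling of DCL particles to the local EVL velocity
          field (0 = detached, 1 = fully advected).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

from .geometry import EGG_RADIUS_UM

SIGMA_TO_D = 2.6e-5
"""Declared conversion, μm²/min of autonomous diffusion per unit of sigma.

With sigma = 2×10⁴ (the optimum of the parameter landscape) this gives
D_n = 0.52 μm²/min — an rms autonomous step of ≈4.6 μm per 10-min frame,
the scale seen in the tracked deep cells.
"""

ATTRACTION_SCALE = 15.0
"""Declared conversion, μm²/min of border-well depth per unit of U_2.

With U_2 = 0.3 the well depth is 4.5 μm²/min ≈ 8.7 × D_n at the optimal
noise level, deep enough to concentrate deep cells along EVL cell borders
without freezing their random motility.
"""


@dataclass(frozen=True)
class SimParams:
    """All constants of the three-force model plus integration settings."""

    U_0: float = 0.1            # EVL spring elastic constant, min⁻¹
    V_0: float = 0.25           # free-border speed, μm/min
    U_1: float = 0.2            # DCL-DCL repulsion amplitude, min⁻¹
    U_2: float = 0.3            # border-attraction amplitude, native units
    a_2: float = 15.0           # border-attraction Gaussian length, μm
    sigma: float = 2.0e4        # noise amplitude, native units
    drag: float = 1.0           # EVL-DCL coupling, dimensionless in [0, 1]
    dt: float = 0.5             # integration step, min
    R: float = EGG_RADIUS_UM    # egg sphere radius, μm
    n_frames: int = 60          # output frames
    frame_interval: float = 10.0  # min between output frames
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("U_0", "V_0", "U_1", "U_2", "a_2", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.drag <= 1.0:
            raise ValueError("drag must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.frame_interval < self.dt:
            raise ValueError("frame_interval must be >= dt")

    @property
    def D_noise(self) -> float:
        """Autonomous tangential diffusion coefficient, μm²/min."""
        return self.sigma * SIGMA_TO_D

    @property
    def steps_per_frame(self) -> int:
        n = self.frame_interval / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_interval must be a multiple of dt")
        return int(round(n))

    def replace(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        return cls(**yaml.safe_load(Path(path).read_text()))
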