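"""Tissue material parameters for the deformable model.

Each tissue gets a linear-elastic parameter set: Young's modulus E
(kPa), Poisson ratio, mass density (kg/m^3) and Rayleigh damping
coefficients (mass-proportional alpha in 1/s, stiffness-proportional
beta in s). The defaults are engineering choices in the ranges soft-
tissue simulation commonly uses — parenchyma softest, bronchial wall
stiffest — and every field can be overridden per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Mapping

from .labels import LOBE_LABELS, Label


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear-elastic material with Rayleigh damping."""

    young_modulus: float  # kPa
    poisson_ratio: float  # dimensionless, in (0, 0.5)
    density: float  # kg/m^3
    rayleigh_alpha: float = 8.0  # 1/s, mass-proportional damping
    rayleigh_beta: float = 5e-4  # s, stiffness-proportional damping

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            # nu = 0 (no lateral coupling) is valid and handy for analysis
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.rayleigh_alpha < 0 or self.rayleigh_beta < 0:
            raise ValueError("damping coefficients must be non-negative")


def default_materials(
    overrides: Mapping[int, Mapping[str, Any]] | None = None,
) -> dict[int, MaterialParams]:
    """Default material table keyed by tissue label code.

    All five lobe labels share the parenchyma parameters. ``overrides``
    maps label code -> field updates, e.g. ``{6: {"young_modulus": 80}}``.
    """
    parenchyma = MaterialParams(young_modulus=5.0, poisson_ratio=0.35, density=400.0)
    table: dict[int, MaterialParams] = {int(code): parenchyma for code in LOBE_LABELS}
    table[int(Label.ARTERY)] = MaterialParams(
        young_modulus=100.0, poisson_ratio=0.45, density=1100.0
    )
    table[int(Label.VEIN)] = MaterialParams(
        young_modulus=60.0, poisson_ratio=0.45, density=1100.0
    )
    table[int(Label.BRONCHUS)] = MaterialParams(
        young_modulus=200.0, poisson_ratio=0.40, density=1100.0
    )
    table[int(Label.TUMOR)] = MaterialParams(
        young_modulus=30.0, poisson_ratio=0.40, density=1050.0
    )
    if overrides:
        for code, fields in overrides.items():
            table[int(code)] = replace(table[int(code)], **dict(fields))
    return table


def scale_damping(
    materials: Mapping[int, MaterialParams], factor: float
) -> dict[int, MaterialParams]:
    """Uniformly scale both Rayleigh coefficients of every tissue."""
    return {
        code: replace(
            m, rayleigh_alpha=m.rayleigh_alpha * factor, rayleigh_beta=m.rayleigh_beta * factor
        )
        for code, m in materials.items()
    }
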