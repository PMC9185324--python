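"""Continuum material constants for the brush and tooth solids.

The simulator treats every body as one of two isotropic elastic materials:
the acrylic of the bristle tufts and dental enamel for the simplified tooth
surfaces.  Constants are literature averages for those materials; hardness
enters only through the Archard wear law, the elastic constants through the
Hertz-Mindlin contact law and the tuft beam stiffnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Material:
    """Isotropic material with the constants the contact and wear laws need.

    Parameters
    ----------
    name
        Identifier used to look up pairwise friction coefficients.
    elastic_modulus
        Young's modulus E in Pa.
    poisson_ratio
        Poisson's ratio nu (dimensionless, 0 < nu < 0.5).
    density
        Mass density in kg/m^3.
    hardness
        Indentation hardness H in Pa (used by the Archard wear law).
    restitution
        Coefficient of restitution e in (0, 1] controlling contact damping.
        Not a tabulated property of either material; the default is a
        configuration choice (see docs/methods.md).
    friction
        Map partner-material-name -> Coulomb friction coefficient.
    """

    name: str
    elastic_modulus: float
    poisson_ratio: float
    density: float
    hardness: float
    restitution: float = 0.3
    friction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.elastic_modulus > 0:
            raise ValueError(f"elastic_modulus must be > 0, got {self.elastic_modulus}")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError(f"poisson_ratio must be in (0, 0.5), got {self.poisson_ratio}")
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not self.hardness > 0:
            raise ValueError(f"hardness must be > 0, got {self.hardness}")
        if not 0 < self.restitution <= 1:
            raise ValueError(f"restitution must be in (0, 1], got {self.restitution}")
        for partner, mu in self.friction.items():
            if mu < 0:
                raise ValueError(f"friction[{partner!r}] must be >= 0, got {mu}")

    @property
    def shear_modulus(self) -> float:
        """Shear modulus G = E / (2 (1 + nu)) in Pa."""
        return self.elastic_modulus / (2.0 * (1.0 + self.poisson_ratio))

    def friction_with(self, other: "Material", default: float = 0.18) -> float:
        """Coulomb friction coefficient against ``other`` (default applies
        to every pair unless overridden)."""
        return self.friction.get(other.name, default)

    def with_restitution(self, e: float) -> "Material":
        """Copy of this material with a different restitution coefficient."""
        return Material(
            self.name,
            self.elastic_modulus,
            self.poisson_ratio,
            self.density,
            self.hardness,
            e,
            dict(self.friction),
        )


#: Bulk acrylic of the bristle tufts (42 tufts of ~40 filaments modelled as
#: one solid beam each).
ACRYLIC = Material(
    name="acrylic",
    elastic_modulus=3.4e9,
    poisson_ratio=0.3,
    density=1185.0,
    hardness=0.22e9,
    friction={"acrylic": 0.18, "enamel": 0.18},
)

#: Tooth enamel of the simplified two-plate + groove tooth model.
ENAMEL = Material(
    name="enamel",
    elastic_modulus=60.0e9,
    poisson_ratio=0.3,
    density=3000.0,
    hardness=0.92e9,
    friction={"acrylic": 0.18},
)

PRESETS = {"acrylic": ACRYLIC, "enamel": ENAMEL}
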