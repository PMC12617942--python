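"""Material parameter presets for the skull vibration models.

Two presets mirror the two physical specimens modeled: a *natural*
(denuded bone) skull and a 3D-printed plastic *replica*.  The natural
preset assigns distinct isotropic properties to three tissue classes —
skull/mandible bone, the dense tympanoperiotic complex (TPC), and the
compliant connective tissue of the temporomandibular joint (TMJ),
symphysis, and bulla pedicles.  The replica preset uses a single ASA
thermoplastic for everything.

Each material is isotropic linear elastic with structural (hysteretic)
damping: stiffness enters the harmonic problem as ``(1 + i*eta) * K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Voxel/element labels for the three solid tissue classes.
LABEL_BONE = 1
LABEL_TPC = 2
LABEL_TMJ = 3

#: Pool water properties (temperature- and salinity-adjusted seawater).
WATER_DENSITY = 1026.0  # kg/m^3
WATER_SOUND_SPEED = 1507.0  # m/s

#: Poisson ratio ceiling: constant-strain tetrahedra lock as nu -> 0.5,
#: so near-incompressible tissue is capped just below that regime.
NU_MAX = 0.49


@dataclass(frozen=True)
class Material:
    """Isotropic linear elastic material with structural damping.

    Parameters
    ----------
    rho : float
        Mass density, kg/m^3.
    E : float
        Young's modulus, Pa.
    nu : float
        Poisson ratio, dimensionless, in [0, ``NU_MAX``].
    eta : float
        Loss factor of isotropic structural damping, dimensionless.
    """

    rho: float
    E: float
    nu: float
    eta: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0.0 <= self.nu <= NU_MAX:
            raise ValueError(
                f"Poisson ratio must be in [0, {NU_MAX}] "
                f"(linear tets lock near 0.5), got {self.nu}"
            )
        if self.eta < 0:
            raise ValueError(f"loss factor must be nonnegative, got {self.eta}")

    @property
    def bulk_sound_speed(self) -> float:
        """Equivalent fluid sound speed sqrt(E/rho), m/s.

        Used when the solid is represented acoustically as a
        fluid-equivalent scatterer in the pressure model.
        """
        return (self.E / self.rho) ** 0.5

    def replace(self, **kw) -> "Material":
        d = dict(rho=self.rho, E=self.E, nu=self.nu, eta=self.eta, name=self.name)
        d.update(kw)
        return Material(**d)


MaterialMap = dict  # label -> Material


def natural_preset(skull_loss_factor: float = 0.3) -> MaterialMap:
    """Best-estimate properties of the natural whale skull.

    Bone of the cranium and mandible: trabecular-dominated whale bone
    (rho 1100 kg/m^3, E 8 GPa).  TPC: highly mineralized, exceptionally
    stiff and dense ear bone (rho 2500 kg/m^3, E 35 GPa).  TMJ and
    symphysis: water-saturated fibrous connective tissue, nearly
    incompressible (nu capped at 0.49).

    The skull loss factor is genuinely uncertain: the acoustic-regime
    literature value is 0.3, while a lower 0.1 also circulates for
    prepared bone.  Both are shipped; 0.3 is the default here and 0.1 is
    available via ``skull_loss_factor=0.1`` (see also
    ``NATURAL_SKULL_LOSS_FACTORS``).
    """
    return {
        LABEL_BONE: Material(1100.0, 8.0e9, 0.3, skull_loss_factor, "skull/mandible bone"),
        LABEL_TPC: Material(2500.0, 35.0e9, 0.3, 0.05, "TPC"),
        LABEL_TMJ: Material(1100.0, 0.2e9, NU_MAX, 0.1, "TMJ/symphysis"),
    }


#: Named presets for the skull bone loss factor (both are published
#: estimates; neither is silently preferred — pick explicitly).
NATURAL_SKULL_LOSS_FACTORS = {"acoustic-regime": 0.3, "prepared-bone": 0.1}

#: ASA datasheet tensile moduli for the two print orientations, Pa.
ASA_MODULUS_ON_EDGE = 2.05e9
ASA_MODULUS_UPRIGHT = 2.14e9


def replica_modulus() -> float:
    """Isotropic Young's modulus for the FDM-printed ASA replica, Pa.

    Fused deposition introduces orientation-dependent stiffness; lacking
    the deposition pattern the material is treated as isotropic with the
    mean of the datasheet's "on edge" and "upright" moduli.
    """
    return 0.5 * (ASA_MODULUS_ON_EDGE + ASA_MODULUS_UPRIGHT)


def replica_preset() -> MaterialMap:
    """ASA thermoplastic replica: one material for all three regions.

    Density 1008 kg/m^3 (weighed artifact / known volume, lower than the
    datasheet's 1080 due to residual print porosity); loss tangent 0.05.
    """
    asa = Material(1008.0, replica_modulus(), 0.3, 0.05, "ASA plastic")
    return {LABEL_BONE: asa, LABEL_TPC: asa, LABEL_TMJ: asa}


@dataclass(frozen=True)
class FactorRange:
    """Low/nominal/high physical values of one design factor."""

    name: str
    low: float
    nominal: float
    high: float


#: Two-factor study ranges for the replica skull (modulus and density
#: varied ~10% around nominal).
REPLICA_STUDY_FACTORS = [
    FactorRange("E", 1.885e9, 2.095e9, 2.305e9),
    FactorRange("rho", 907.0, 1008.0, 1109.0),
]

#: Six-factor study ranges for the natural skull.  Moduli and densities
#: vary ~10%; the loss factors span deliberately wider, asymmetric
#: ranges reflecting their much larger uncertainty.
NATURAL_STUDY_FACTORS = [
    FactorRange("Esk", 7.2e9, 8.0e9, 8.8e9),
    FactorRange("Etp", 31.5e9, 35.0e9, 38.5e9),
    FactorRange("rhosk", 990.0, 1100.0, 1210.0),
    FactorRange("rhotp", 2250.0, 2500.0, 2750.0),
    FactorRange("lfs", 0.2, 0.3, 0.45),
    FactorRange("lft", 0.01, 0.05, 0.1),
]


def natural_from_factors(values: dict) -> MaterialMap:
    """Build a natural-skull material map from six-factor study values.

    ``values`` maps factor names (Esk, Etp, rhosk, rhotp, lfs, lft) to
    physical values; missing names fall back to the nominal preset.
    """
    base = natural_preset()
    bone = base[LABEL_BONE].replace(
        E=values.get("Esk", base[LABEL_BONE].E),
        rho=values.get("rhosk", base[LABEL_BONE].rho),
        eta=values.get("lfs", base[LABEL_BONE].eta),
    )
    tpc = base[LABEL_TPC].replace(
        E=values.get("Etp", base[LABEL_TPC].E),
        rho=values.get("rhotp", base[LABEL_TPC].rho),
        eta=values.get("lft", base[LABEL_TPC].eta),
    )
    return {LABEL_BONE: bone, LABEL_TPC: tpc, LABEL_TMJ: base[LABEL_TMJ]}


def replica_from_factors(values: dict) -> MaterialMap:
    """Build a replica material map from two-factor study values."""
    base = replica_preset()[LABEL_BONE]
    asa = base.replace(E=values.get("E", base.E), rho=values.get("rho", base.rho))
    return {LABEL_BONE: asa, LABEL_TPC: asa, LABEL_TMJ: asa}
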