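"""Model parameters, unit normalization and configuration loading.

All quantities are kept in a single internal unit system: micrometre (um)
for length, minute (min) for time and nanonewton (nN) for force.  Energies
are then nN*um, pressures/moduli nN/um^2 (= kPa), adhesion energy densities
nN/um (= mN/m), per-contact-area friction constants nN*min/um^3 and linear
friction constants nN*min/um.  The published parameter table uses mixed SI
units (uN/m, kPa, Ns/m^3, Ns/m, 1/d, ...); :func:`load_parameters` converts
on input and :meth:`ModelParameters.to_table_units` converts back, so a
round trip reproduces the printed values.

The choice keeps every number close to unity -- e.g. the podium retraction
time constant gamma_p/k is about 11.7 min.
"""

from __future__ import annotations

import configparser
import io
import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Tuple

__all__ = [
    "ModelParameters",
    "load_parameters",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


_MIN_PER_DAY = 1440.0

# multiplicative factor: printed table units -> internal units
_PER_AREA_FRICTION = 1e-9 / 60.0   # Ns/m^3 -> nN*min/um^3
_LINEAR_FRICTION = 1e3 / 60.0      # Ns/m   -> nN*min/um
_ENERGY_DENSITY = 1e-3             # uN/m   -> nN/um
_PER_DAY = 1.0 / _MIN_PER_DAY      # 1/d    -> 1/min


def _default_v_max() -> float:
    # volume doubling before division: 2 * (4/3) pi R0^3
    return 2.0 * (4.0 / 3.0) * math.pi * 4.75**3


@dataclass
class ModelParameters:
    """All model constants in internal units (um, min, nN).

    Attributes correspond to the published parameter table plus a small
    number of gap-filling constants (``v_max``, ``lag_frac``,
    ``cone_tip_frac``, ``p_groove``, ``dt``, confinement and frame) that the
    table does not print.
    """

    # -- body mechanics -------------------------------------------------
    eps_cc: float = 600.0 * _ENERGY_DENSITY     # cell-cell adhesion, nN/um
    eps_cs: float = 200.0 * _ENERGY_DENSITY     # cell-substrate adhesion, nN/um
    nu: float = 1.0 / 3.0                       # Poisson ratio
    e_young: float = 1.0                        # Young modulus, nN/um^2 (kPa)
    k_bulk: float = 1.0                         # bulk modulus, nN/um^2 (kPa)
    gamma_cc: float = 2.8e9 * _PER_AREA_FRICTION
    gamma_cs: float = 2.8e9 * _PER_AREA_FRICTION
    gamma_r: float = 173e9 * _PER_AREA_FRICTION
    gamma_v: float = 0.04 * _LINEAR_FRICTION    # viscous drag, nN*min/um
    adhesion_onset: float = 2.0                 # cc-contact maturation depth, um

    # -- podia ----------------------------------------------------------
    lambda_np: float = 1440.0 * _PER_DAY        # podium-count update rate, 1/min
    r_ind_lo: float = 2.0 * _PER_DAY            # independent inactivation, 1/min
    r_ind_hi: float = 0.0
    n_off_lo: float = 3.5                       # number-of-podia offset
    n_off_hi: float = 2.5
    c_a: float = 3.0                            # angle scaling constant, rad
    gen_accept_scale: float = 0.05              # generation acceptance / deficit
    f_p: float = 2.5                            # protrusion force, nN
    gamma_p: float = 0.07 * _LINEAR_FRICTION    # podium-substrate friction
    k_spring: float = 0.1                       # traction spring, nN/um
    cone_tip_frac: float = 0.6                  # tip radius / base radius

    # -- growth and division -------------------------------------------
    r0: float = 4.75                            # initial body radius, um
    dvdt_lo: float = 1200.0 * _PER_DAY          # target-volume rate, um^3/min
    dvdt_hi: float = 0.0
    m_inc: float = 20.0 * _PER_DAY              # increment events, 1/min
    v_max: float = field(default_factory=_default_v_max)  # division volume, um^3
    lag_frac: float = 0.1                       # quiescence lag threshold

    # -- density regulation --------------------------------------------
    d_nn: float = 5.0                           # neighbor classification, um
    n_prolif_lo: float = 4.0
    n_prolif_hi: float = 5.0
    n_podia_lo: float = 1.0
    n_podia_hi: float = 3.0

    # -- substrate / run -----------------------------------------------
    p_groove: float = 0.15                      # groove alignment prob / step
    dt: float = 1.0                             # integration step, min
    boundary_radius: Optional[float] = 450.0    # confinement, um (None = free)
    frame: Optional[Tuple[float, float]] = None  # evaluation rectangle, um

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities --------------------------------------------
    @property
    def v0(self) -> float:
        """Initial (seeding) cell volume, um^3."""
        return (4.0 / 3.0) * math.pi * self.r0**3

    @property
    def l_max(self) -> float:
        """Maximum podium length F_p/k of a resting cell, um."""
        return self.f_p / self.k_spring

    @property
    def tip_speed_max(self) -> float:
        """Maximum podium tip speed F_p/gamma_p, um/min."""
        return self.f_p / self.gamma_p

    def e_star_cc(self) -> float:
        """Effective Hertz modulus for a cell-cell contact."""
        return self.e_young / (2.0 * (1.0 - self.nu**2))

    def e_star_cs(self) -> float:
        """Effective Hertz modulus for a cell against the rigid substrate."""
        return self.e_young / (1.0 - self.nu**2)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        positive = (
            "eps_cc", "eps_cs", "e_young", "k_bulk", "gamma_cc", "gamma_cs",
            "gamma_r", "gamma_v", "lambda_np", "c_a", "f_p", "gamma_p",
            "k_spring", "r0", "m_inc", "d_nn", "dt", "v_max",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"parameter {name!r} must be > 0")
        nonneg = ("r_ind_lo", "r_ind_hi", "n_off_lo", "n_off_hi",
                  "dvdt_lo", "dvdt_hi", "lag_frac")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"parameter {name!r} must be >= 0")
        if not 0.0 <= self.nu < 0.5:
            raise ParameterError("parameter 'nu' must satisfy 0 <= nu < 0.5")
        if not self.adhesion_onset > 0:
            raise ParameterError("parameter 'adhesion_onset' must be > 0")
        if not 0.0 < self.gen_accept_scale <= 1.0:
            raise ParameterError("parameter 'gen_accept_scale' must lie in (0, 1]")
        if not 0.0 <= self.p_groove <= 1.0:
            raise ParameterError("parameter 'p_groove' must lie in [0, 1]")
        if not 0.0 < self.cone_tip_frac <= 1.0:
            raise ParameterError("parameter 'cone_tip_frac' must lie in (0, 1]")
        for lo, hi in (("n_prolif_lo", "n_prolif_hi"), ("n_podia_lo", "n_podia_hi")):
            if getattr(self, lo) > getattr(self, hi):
                raise ParameterError(f"ramp bounds {lo!r} > {hi!r}")
        if self.boundary_radius is not None and not self.boundary_radius > 0:
            raise ParameterError("parameter 'boundary_radius' must be > 0 or none")
        if self.frame is not None and (self.frame[0] <= 0 or self.frame[1] <= 0):
            raise ParameterError("parameter 'frame' extents must be > 0")

    # -- unit round trip -------------------------------------------------
    def to_table_units(self) -> dict:
        """Return the parameters in the published table's mixed units."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            factor = _TABLE_FACTORS.get(f.name)
            out[f.name] = v if (factor is None or v is None) else v / factor
        return out

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


# printed-unit -> internal-unit factor, keyed by field name
_TABLE_FACTORS = {
    "eps_cc": _ENERGY_DENSITY, "eps_cs": _ENERGY_DENSITY,
    "gamma_cc": _PER_AREA_FRICTION, "gamma_cs": _PER_AREA_FRICTION,
    "gamma_r": _PER_AREA_FRICTION,
    "gamma_v": _LINEAR_FRICTION, "gamma_p": _LINEAR_FRICTION,
    "lambda_np": _PER_DAY, "r_ind_lo": _PER_DAY, "r_ind_hi": _PER_DAY,
    "dvdt_lo": _PER_DAY, "dvdt_hi": _PER_DAY, "m_inc": _PER_DAY,
}

# configuration layout: section -> parameter keys (values in table units)
CONFIG_SECTIONS = {
    "mechanics": ("eps_cc", "eps_cs", "nu", "e_young", "k_bulk",
                  "gamma_cc", "gamma_cs", "gamma_r", "gamma_v",
                  "adhesion_onset"),
    "podia": ("lambda_np", "r_ind_lo", "r_ind_hi", "n_off_lo", "n_off_hi",
              "c_a", "gen_accept_scale", "f_p", "gamma_p", "k_spring",
              "cone_tip_frac"),
    "cycle": ("r0", "dvdt_lo", "dvdt_hi", "m_inc", "v_max", "lag_frac"),
    "regulation": ("d_nn", "n_prolif_lo", "n_prolif_hi",
                   "n_podia_lo", "n_podia_hi"),
    "substrate": ("p_groove",),
    "run": ("dt", "boundary_radius", "frame_width", "frame_height"),
}

# keys legal in config files but consumed by other components (substrate
# geometry and run control); load_parameters validates and skips them.
EXTRA_KEYS = {
    "substrate": ("kind", "groove_width", "groove_spacing", "extent",
                  "star_arms", "grooves_per_arm", "unit_radius",
                  "lattice_pitch", "pattern_file"),
    "run": ("days", "seed", "n_init", "seed_radius", "snapshot_every", "out"),
}


def load_parameters(config=None) -> ModelParameters:
    """Load :class:`ModelParameters` from flat ``key = value`` sectioned text.

    ``config`` may be ``None`` (all defaults), a path, a file object or a
    string of INI-style text.  Values are given in the published table's
    units and converted to internal units here.  Unknown keys are rejected;
    a missing key keeps its default.
    """
    if config is None:
        return ModelParameters()
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    if hasattr(config, "read"):
        parser.read_file(config)
    else:
        text = str(config)
        if "\n" in text or "=" in text:
            parser.read_file(io.StringIO(text))
        else:
            read = parser.read(text)
            if not read:
                raise ParameterError(f"config file not found: {text}")

    overrides = {}
    for section in parser.sections():
        if section not in CONFIG_SECTIONS:
            raise ParameterError(f"unknown config section [{section}]")
        known = CONFIG_SECTIONS[section]
        extra = EXTRA_KEYS.get(section, ())
        for key, raw in parser.items(section):
            if key in extra:
                continue
            if key not in known:
                raise ParameterError(f"unknown key {key!r} in section [{section}]")
            if key in ("frame_width", "frame_height"):
                overrides[key] = float(raw)
                continue
            if key == "boundary_radius" and raw.strip().lower() in ("none", ""):
                overrides[key] = None
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise ParameterError(f"key {key!r}: not a number: {raw!r}") from exc
            factor = _TABLE_FACTORS.get(key, 1.0)
            overrides[key] = value * factor

    fw = overrides.pop("frame_width", None)
    fh = overrides.pop("frame_height", None)
    if (fw is None) != (fh is None):
        raise ParameterError("frame_width and frame_height must be given together")
    if fw is not None:
        overrides["frame"] = (fw, fh)
    try:
        return ModelParameters(**overrides)
    except TypeError as exc:  # pragma: no cover - guarded by key check above
        raise ParameterError(str(exc)) from exc
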