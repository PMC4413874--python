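"""Force-field parameters and the in-silico/in-vivo time mapping.

The model represents a nucleosome chain as 10 nm beads joined by harmonic
linker springs (rest length ``c2`` = 15 nm).  Five forces act on every bead:
an entropic kick of fixed magnitude ``c1`` in a random direction, the linker
tension (Hooke, constant ``Ks``), a soft-core excluded-volume repulsion of
magnitude ``c3`` within 15 nm, a weak second-neighbour attraction
(coefficient ``c4``) that shapes the nucleosome entry/exit angle, and a
Hookean condensin bond force (constant ``Kcondensin``, rest length ``c5``)
between condensin binding sites that have come within ``attraction_radius``
of one another.  Bonds dissolve stochastically with probability ``p`` per
unit time.

Forces are expressed in pN and displacements in nm with a bead mobility of
1 nm/pN per unit time; one integration step advances the system by ``dt``
time units.  The stiffest relaxation in the system is the linker spring
(time constant ``1/(2*Ks)`` for the relative coordinate), so the default
``dt`` is half of that, the largest step at which the explicit midpoint
scheme is comfortably stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

__all__ = [
    "SimulationParams",
    "TimeMapping",
    "BOLTZMANN_PN_NM",
    "DEFAULT_DIFFUSION_NM2_S",
    "interphase_params",
    "mitotic_params",
    "step_seconds",
    "ParameterError",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM = 1.380649e-2

#: Nucleosome diffusion coefficient used for the step -> seconds conversion
#: (nm^2/s).  This is the published rounded value for a solvated nucleosome
#: with friction coefficient ~3e-7 g/s at room temperature.
DEFAULT_DIFFUSION_NM2_S = 1.33e7


class ParameterError(ValueError):
    """Raised when simulation parameters violate their invariants."""


@dataclass(frozen=True)
class SimulationParams:
    """Constants of the bead-spring force field.

    Attributes
    ----------
    c1 : float
        Entropic force magnitude (pN); every bead receives a kick of exactly
        this magnitude in an independent uniform random direction each step.
    Ks : float
        Linker spring constant (pN/nm).
    c2 : float
        Linker rest length (nm); also the natural inter-nucleosome spacing.
    c3 : float
        Repulsion magnitude (pN) for bead overlaps closer than the bead
        diameter; decays as ``c3/(d/10nm)^12`` between 10 and 15 nm.
    c4 : float
        Second-neighbour attraction coefficient (pN per nm of i,i+/-2
        separation).  Calibrated so the equilibrium alpha-angle distribution
        peaks near 70 degrees.
    Kcondensin : float
        Condensin bond spring constant (pN/nm).
    c5 : float
        Condensin bond rest length (nm); shorter than ``attraction_radius``
        so a freshly broken pair can re-form while still in range.
    attraction_radius : float
        Condensin capture/interaction radius (nm).
    p : float
        Bond dissociation probability per unit time (per-step probability is
        ``p * dt``).
    mode : str
        ``"type1"`` (each site binds at most one partner) or ``"type2"``
        (at most two partners).
    dt : float, optional
        Integration step in time units.  ``None`` selects
        ``1 / (2 * max(Ks, Kcondensin))``.
    bead_diameter, repulsion_radius : float
        Geometry of the excluded-volume term (nm).
    rebond_window : int
        Number of integration steps during which a freshly dissolved pair
        re-forms automatically if still within ``attraction_radius``.
    """

    c1: float = 24.5
    Ks: float = 50.0
    c2: float = 15.0
    c3: float = 10.0
    c4: float = 0.005
    Kcondensin: float = 50.0
    c5: float = 30.0
    attraction_radius: float = 40.0
    p: float = 1e-3
    mode: str = "type1"
    dt: Optional[float] = None
    bead_diameter: float = 10.0
    repulsion_radius: float = 15.0
    rebond_window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.Ks <= 0:
            errors.append(f"Ks must be positive, got {self.Ks}")
        if self.Kcondensin <= 0:
            errors.append(f"Kcondensin must be positive, got {self.Kcondensin}")
        if self.c2 <= 0:
            errors.append(f"c2 must be positive, got {self.c2}")
        if not 0.0 <= self.p <= 1.0:
            errors.append(f"p must lie in [0, 1], got {self.p}")
        if self.c5 >= self.attraction_radius:
            errors.append(
                f"condensin rest length c5={self.c5} must be below the "
                f"capture radius {self.attraction_radius}"
            )
        if self.mode not in ("type1", "type2"):
            errors.append(f"mode must be 'type1' or 'type2', got {self.mode!r}")
        if self.dt is not None and self.dt <= 0:
            errors.append(f"dt must be positive, got {self.dt}")
        if errors:
            raise ParameterError("; ".join(errors))

    def stable_dt(self, include_condensin: bool = True) -> float:
        """Half the stiffest relaxation time among the springs in play.

        Runs without condensin sites are governed by the linker spring
        alone, which allows a larger step when ``Ks < Kcondensin``.
        """
        stiffest = max(self.Ks, self.Kcondensin) if include_condensin else self.Ks
        return 1.0 / (2.0 * stiffest)

    @property
    def effective_dt(self) -> float:
        """Integration step: explicit value or half the stiffest relaxation time."""
        if self.dt is not None:
            return self.dt
        return self.stable_dt(True)

    @property
    def degree_cap(self) -> int:
        """Maximum number of simultaneous bonds per condensin site."""
        return 1 if self.mode == "type1" else 2

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)


def interphase_params(mode: str = "type1", **kwargs) -> SimulationParams:
    """Default parameters of the G1 (interphase) regime: p = 1e-3."""
    return SimulationParams(p=1e-3, mode=mode, **kwargs)


def mitotic_params(mode: str = "type1", **kwargs) -> SimulationParams:
    """Default parameters of the M-phase regime: p = 1e-4."""
    return SimulationParams(p=1e-4, mode=mode, **kwargs)


@dataclass(frozen=True)
class TimeMapping:
    """Conversion between integration steps and in-vivo seconds.

    One time unit corresponds to ``lambda^2 / D`` seconds, where ``lambda``
    is the natural linker length and ``D`` the diffusion coefficient of a
    solvated nucleosome.  ``D`` defaults to the published rounded constant
    (1.33e7 nm^2/s); passing ``friction_g_per_s`` instead derives it as
    ``kB*T/f``.
    """

    dt: float = 1.0
    linker_nm: float = 15.0
    diffusion_nm2_s: Optional[float] = DEFAULT_DIFFUSION_NM2_S
    friction_g_per_s: Optional[float] = None
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.linker_nm <= 0:
            raise ParameterError(f"linker length must be positive, got {self.linker_nm}")
        if self.temperature_K <= 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature_K}")
        if self.friction_g_per_s is not None and self.friction_g_per_s <= 0:
            raise ParameterError(
                f"friction must be positive, got {self.friction_g_per_s}"
            )
        if self.diffusion_nm2_s is None and self.friction_g_per_s is None:
            raise ParameterError("either a diffusion or a friction coefficient is required")

    @property
    def diffusion(self) -> float:
        """Nucleosome diffusion coefficient (nm^2/s)."""
        if self.friction_g_per_s is not None:
            # kB*T in pN nm; 1 g/s == 1e-3 kg/s == 1 pN s/nm, so f is numerically
            # the same in pN s/nm and the ratio lands in nm^2/s
            return BOLTZMANN_PN_NM * self.temperature_K / self.friction_g_per_s
        return float(self.diffusion_nm2_s)

    @property
    def seconds_per_step(self) -> float:
        """In-vivo seconds advanced by one integration step of size dt."""
        return self.dt * self.linker_nm**2 / self.diffusion

    def steps_to_seconds(self, steps: float) -> float:
        return steps * self.seconds_per_step

    def seconds_to_steps(self, seconds: float) -> float:
        return seconds / self.seconds_per_step


def step_seconds(mapping: TimeMapping) -> float:
    """Seconds of in-vivo time per integration step (``dt * lambda^2 / D``)."""
    return mapping.seconds_per_step
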