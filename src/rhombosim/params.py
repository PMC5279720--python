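"""Parameter containers for the boundary-sharpening simulator.

All lengths are measured in characteristic cell diameters, all times in hours
(the simulation clock reads hours post fertilization, hpf), and concentrations
are on the calibrated dimensionless scale on which the stable expression states
of the two-gene circuit are O(1).

The shipped defaults are calibration outputs (see ``models.calibrate`` and
``docs/methods.md``): the original study's exact force/kinetic tables are not
reproduced here, only the constraints they were chosen to satisfy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import yaml

Mechanism = Literal["sorting", "plasticity"]


@dataclass
class MorsePair:
    """Morse pair potential U(r) = depth*(exp(-2(r-r_eq)/a) - 2 exp(-(r-r_eq)/a))."""

    depth: float
    equilibrium_distance: float
    range: float  # the Morse width parameter a

    def validate(self) -> None:
        if self.depth < 0:
            raise ValueError("Morse depth must be >= 0")
        if self.equilibrium_distance <= 0 or self.range <= 0:
            raise ValueError("Morse equilibrium distance and range must be > 0")


@dataclass
class RepulsionPair:
    """Purely repulsive exponential U(r) = amplitude * exp(-r/range)."""

    amplitude: float
    range: float

    def validate(self) -> None:
        if self.amplitude < 0:
            raise ValueError("repulsion amplitude must be >= 0")
        if self.range <= 0:
            raise ValueError("repulsion range must be > 0")


@dataclass
class ForceParams:
    """Mechanical parameters of the sub-cellular-element model.

    ``morse_intra`` couples element pairs within one cell, ``morse_adhesion``
    couples element pairs of two like-type cells, ``repulsion`` couples element
    pairs of unlike-type cells.  All inter-cellular interactions vanish beyond
    ``cutoff`` (contact-limited forces; the long-range variant uses 3.0).
    ``strength_scale`` multiplies the two *inter*-cellular interactions only,
    leaving cell integrity untouched.
    """

    morse_intra: MorsePair = field(
        default_factory=lambda: MorsePair(depth=1.0, equilibrium_distance=0.50, range=0.80)
    )
    morse_adhesion: MorsePair = field(
        default_factory=lambda: MorsePair(depth=0.30, equilibrium_distance=1.00, range=0.40)
    )
    repulsion: RepulsionPair = field(
        default_factory=lambda: RepulsionPair(amplitude=0.5, range=0.50)
    )
    cutoff: float = 2.0
    drag: float = 1.0  # mobility: dx/dt = drag * force
    element_noise: float = 0.2
    strength_scale: float = 1.0

    def validate(self) -> None:
        self.morse_intra.validate()
        self.morse_adhesion.validate()
        self.repulsion.validate()
        if self.cutoff < max(
            self.morse_intra.equilibrium_distance, self.morse_adhesion.equilibrium_distance
        ):
            raise ValueError("cutoff must be >= the Morse equilibrium distances")
        if self.drag <= 0:
            raise ValueError("drag must be > 0")
        if self.element_noise < 0:
            raise ValueError("element_noise must be >= 0")
        if self.strength_scale <= 0:
            raise ValueError("strength_scale must be > 0")

    def stiffness_bound(self) -> float:
        """Estimate of the maximum force-curve stiffness |dF/dr| (per drag unit).

        Uses the Morse second derivative at the equilibrium distance, 2*depth/a^2,
        and the repulsive curvature evaluated at the intra-cell equilibrium
        spacing (the closest approach elements maintain in practice).
        """

        k_intra = 2.0 * self.morse_intra.depth / self.morse_intra.range**2
        k_adh = (
            2.0
            * self.strength_scale
            * self.morse_adhesion.depth
            / self.morse_adhesion.range**2
        )
        r_min = self.morse_intra.equilibrium_distance
        rep = self.repulsion
        k_rep = (
            self.strength_scale
            * rep.amplitude
            / rep.range**2
            * float(__import__("math").exp(-r_min / rep.range))
        )
        return max(k_intra, k_adh, k_rep)

    def max_stable_dt(self) -> float:
        """Explicit-Euler stability bound dt <= 0.2 / (drag * max stiffness)."""

        return 0.2 / (self.drag * self.stiffness_bound())


@dataclass
class SParams:
    """Saturating Hill sink for intracellular morphogen, S(M) = V*M^h/(K^h+M^h)."""

    V_S: float = 2.0
    K_S: float = 1.0
    h_S: float = 2.0

    def validate(self) -> None:
        if self.V_S < 0 or self.K_S <= 0 or self.h_S < 1:
            raise ValueError("invalid intracellular sink parameters")


@dataclass
class GeneParams:
    """Kinetics of the mutually antagonistic, self-activating A/B circuit.

    Rates are per hour.  ``m_A``/``m_B`` are the Hill exponents of the
    morphogen drive onto each gene; the steeper B drive (m_B > m_A) makes the
    B-dominant state the deeper attractor at posterior (high-M) levels while A
    wins anteriorly, which sets the direction of noise-driven fate switching.
    ``K_A``/``K_B`` are the half-saturation scales of the self-activation Hill
    terms; they set the absolute concentration scale of the stable states
    (A*, B* ~ K) and hence the barrier heights the additive noise amplitudes
    must cross.
    ``tau`` rescales the A/B kinetics only (tau > 1 slows fate switching
    without moving the steady states).  ``kappa_B_low``/``K_low``/``h_low``
    enable an additional low-morphogen activation branch of B used by the
    three-zone scenario; it is off (0) by default.
    """

    C_A: float = 3.30
    C_B: float = 2.52
    n_A: float = 2.0
    n_B: float = 2.0
    m_A: float = 1.0
    m_B: float = 4.0
    K_A: float = 0.10
    K_B: float = 0.10
    chi_A: float = 0.6  # strength of A's inhibition of B (1 = symmetric antagonism)
    chi_B: float = 1.3  # strength of B's inhibition of A
    kappa_A: float = 0.90
    kappa_B: float = 50.0
    d_A: float = 15.0
    d_B: float = 15.0
    k_M: float = 5.0
    S_params: SParams = field(default_factory=SParams)
    eta_in: float = 0.15
    eta_A: float = 0.06
    eta_B: float = 0.06
    tau: float = 1.0
    kappa_B_low: float = 0.0
    K_low: float = 0.4
    h_low: float = 4.0

    def validate(self) -> None:
        if min(self.n_A, self.n_B, self.m_A, self.m_B) < 1:
            raise ValueError("Hill exponents must be >= 1")
        if min(self.C_A, self.C_B, self.d_A, self.d_B, self.k_M) <= 0:
            raise ValueError("rates must be > 0")
        if min(self.K_A, self.K_B) <= 0:
            raise ValueError("half-saturation scales must be > 0")
        if min(self.kappa_A, self.kappa_B, self.kappa_B_low) < 0:
            raise ValueError("morphogen coupling coefficients must be >= 0")
        if min(self.eta_in, self.eta_A, self.eta_B) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        self.S_params.validate()


@dataclass
class ProductionProfile:
    """Graded morphogen source, maximal at the posterior (high-x) domain end."""

    V_max: float = 3.83
    profile: Literal["exponential", "linear", "step"] = "exponential"
    length_scale: float = 9.33

    def validate(self) -> None:
        if self.V_max < 0 or self.length_scale <= 0:
            raise ValueError("invalid production profile parameters")
        if self.profile not in ("exponential", "linear", "step"):
            raise ValueError(f"unknown production profile {self.profile!r}")


@dataclass
class MorphogenParams:
    """Extracellular morphogen field: diffusion, decay, graded noisy source."""

    D: float = 10.0  # cell-diameter^2 / hour
    beta: float = 1.0  # extracellular degradation multiplier of k_M
    k_M: float = 5.0  # intra/extracellular exchange rate (shared with GeneParams)
    production: ProductionProfile = field(default_factory=ProductionProfile)
    eta_out: float = 0.25
    dx: float = 0.5
    plasticity_window: tuple[float, float] = (0.0, 14.0)

    def validate(self) -> None:
        if self.D <= 0 or self.dx <= 0:
            raise ValueError("D and dx must be > 0")
        if self.beta < 0 or self.k_M <= 0 or self.eta_out < 0:
            raise ValueError("invalid morphogen parameters")
        self.production.validate()

    def max_stable_dt(self) -> float:
        """FTCS diffusion stability D*dt/dx^2 <= 0.25 (2-D five-point stencil)."""

        return 0.25 * self.dx**2 / self.D


@dataclass
class ScheduleInterval:
    t_start: float
    t_end: float
    active: tuple[Mechanism, ...]


@dataclass
class RunConfig:
    """Full configuration of a single simulation run.

    ``mode`` selects which subsystems evolve: "S" freezes gene expression
    (fates fixed, sorting only), "P" freezes element positions (plasticity
    only), "SP" runs both with expression-coupled mechanics.  ``schedule``
    optionally restricts which mechanism is active in sub-intervals of
    [t0, t_end] (used for the sequential P-then-S / S-then-P scenarios); it
    must tile the run window exactly.
    """

    mode: Literal["S", "P", "SP"] = "SP"
    scenario: Literal["two_zone_manual", "two_zone_morphogen", "three_zone"] = (
        "two_zone_morphogen"
    )
    ITW: int = 4
    n_columns: int = 14
    n_rows: int = 6
    t0: float = 10.7
    t_end: float = 12.7
    dt: float = 0.005
    snapshot_dt: float = 0.1
    burn_in: float = 1.0
    seed: int = 0
    replicate_count: int = 16
    elements_per_cell: int = 4
    schedule: list[ScheduleInterval] | None = None
    forces: ForceParams = field(default_factory=ForceParams)
    genes: GeneParams = field(default_factory=GeneParams)
    morphogen: MorphogenParams = field(default_factory=MorphogenParams)

    def validate(self) -> None:
        if self.mode not in ("S", "P", "SP"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scenario not in ("two_zone_manual", "two_zone_morphogen", "three_zone"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.ITW < 1:
            raise ValueError("ITW must be >= 1")
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.elements_per_cell < 3:
            raise ValueError("cells need at least 3 elements")
        self.forces.validate()
        self.genes.validate()
        self.morphogen.validate()
        if self.schedule is not None:
            ivs = sorted(self.schedule, key=lambda s: s.t_start)
            t = self.t0
            for iv in ivs:
                if abs(iv.t_start - t) > 1e-9:
                    raise ValueError("schedule intervals must tile [t0, t_end] (gap/overlap)")
                if iv.t_end <= iv.t_start:
                    raise ValueError("schedule interval must have t_end > t_start")
                for mech in iv.active:
                    if mech not in ("sorting", "plasticity"):
                        raise ValueError(f"unknown mechanism {mech!r}")
                t = iv.t_end
            if abs(t - self.t_end) > 1e-9:
                raise ValueError("schedule intervals must tile [t0, t_end] (gap/overlap)")

    def active_mechanisms(self, t: float) -> tuple[Mechanism, ...]:
        base: tuple[Mechanism, ...]
        if self.mode == "S":
            base = ("sorting",)
        elif self.mode == "P":
            base = ("plasticity",)
        else:
            base = ("sorting", "plasticity")
        if self.schedule is None:
            return base
        for iv in self.schedule:
            if iv.t_start - 1e-12 <= t < iv.t_end - 1e-12:
                return tuple(m for m in iv.active if m in base)
        return tuple(m for m in self.schedule[-1].active if m in base)


# ---------------------------------------------------------------------------
# (de)serialisation


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_dict(config)


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(config_to_dict(config), sort_keys=False)


def _build(cls, data: dict):
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in hints:
            raise KeyError(f"unknown configuration key {key!r} for {cls.__name__}")
        kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "morse_intra": MorsePair,
    "morse_adhesion": MorsePair,
    "repulsion": RepulsionPair,
    "S_params": SParams,
    "production": ProductionProfile,
    "forces": ForceParams,
    "genes": GeneParams,
    "morphogen": MorphogenParams,
}


def _from_dict(cls, data: dict):
    kwargs = {}
    names = {f.name for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in names:
            raise KeyError(f"unknown configuration key {key!r} for {cls.__name__}")
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _from_dict(_NESTED[key], value)
        elif key == "schedule" and value is not None:
            kwargs[key] = [
                ScheduleInterval(s["t_start"], s["t_end"], tuple(s["active"])) for s in value
            ]
        elif key == "plasticity_window":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    cfg = _from_dict(RunConfig, data)
    cfg.validate()
    return cfg


def config_from_yaml(text: str) -> RunConfig:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return config_from_dict(data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_yaml(fh.read())


def mild_forces(**overrides) -> ForceParams:
    """The calibrated 'mild' sorting force set (Table-1 baseline)."""

    fp = ForceParams()
    for key, value in overrides.items():
        setattr(fp, key, value)
    return fp


def longrange_forces(**overrides) -> ForceParams:
    """Long-range interaction variant: contact radius extended to ~3 cell
    diameters with a far-reaching adhesion tail (chemoattraction mimic) and
    element-level jitter that frees wall-trapped stragglers."""

    fp = ForceParams(
        morse_adhesion=MorsePair(depth=0.60, equilibrium_distance=1.0, range=1.2),
        repulsion=RepulsionPair(amplitude=0.35, range=0.50),
        cutoff=3.0,
        element_noise=0.25,
    )
    for key, value in overrides.items():
        setattr(fp, key, value)
    return fp


def strong_forces(**overrides) -> ForceParams:
    """'Strong' sorting: same repulsion, adhesion depth doubled."""

    fp = ForceParams()
    fp.morse_adhesion = MorsePair(
        depth=2.0 * fp.morse_adhesion.depth,
        equilibrium_distance=fp.morse_adhesion.equilibrium_distance,
        range=fp.morse_adhesion.range,
    )
    for key, value in overrides.items():
        setattr(fp, key, value)
    return fp
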