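"""Assembly of the three sharpening models and their scenarios.

Model S: mechanical cell sorting only — fates are frozen and cells move under
type-dependent adhesion/repulsion.  Model P: plasticity only — cells are
stationary while the noisy morphogen field and the stochastic gene circuit
drive fate switching.  Model SP: both, with the mechanical like/unlike
classification replaced by a continuous blend of the cells' expression
states, so gene expression and motion feed back on each other.

Initial conditions are either manual checkerboards (a half-half random
transition band of width ITW between pure zones) or generated by the
morphogen system itself (burned-in noisy gradient + relaxed gene states),
in which case the same generated state seeds S, P and SP runs for paired
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import gene_circuit, metrics, morphogen_field, scem_mechanics
from .metrics import Boundary, MetricsSeries
from .morphogen_field import MorphogenGrid
from .params import ForceParams, GeneParams, RunConfig
from .scem_mechanics import CellExpressionState, Fate, Tissue

log = logging.getLogger(__name__)

__all__ = [
    "init_manual",
    "init_morphogen",
    "expression_to_interaction",
    "phi_scores",
    "boundaries_for",
    "deterministic_switch_positions",
    "RunResult",
    "run",
    "run_ensemble",
    "calibrate",
    "CalibrationReport",
]

PHI_EPS = 1e-9
PHI_SATURATION = 0.75  # |phi| at which a cell couples with full Model-S strength
PAIR_REBUILD_EVERY = 10
PAIR_SKIN = 0.4


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-based generator keyed by (seed, stream): order-independent."""

    return np.random.Generator(np.random.Philox(key=np.array([seed, stream], dtype=np.uint64)))


# ---------------------------------------------------------------------------
# initial conditions


def init_manual(
    ITW: int,
    seed: int,
    n_rows: int = 6,
    forces: ForceParams | None = None,
    n_e: int = 4,
    t0: float = 10.7,
) -> Tissue:
    """Manual checkerboard initial condition.

    (6 + ITW) columns x ``n_rows`` rows of equilibrated cells on a unit
    lattice: the leftmost 3 columns are fate A, the rightmost 3 fate B, and
    the ITW middle columns hold an exactly half-half random mixture drawn
    under ``seed``.  No expression state is attached (pure Model S input).
    """

    if ITW < 1:
        raise ValueError("ITW must be >= 1")
    forces = forces or ForceParams()
    n_cols = 6 + ITW
    fates = np.empty(n_cols * n_rows, dtype=np.int8)
    cols = np.arange(n_cols * n_rows) // n_rows
    fates[cols < 3] = int(Fate.A)
    fates[cols >= n_cols - 3] = int(Fate.B)
    trans = np.flatnonzero((cols >= 3) & (cols < n_cols - 3))
    n_trans = len(trans)
    rng = np.random.default_rng(seed)
    n_a = n_trans // 2
    if n_trans % 2:
        extra = int(rng.integers(0, 2))
        n_a += extra
        log.info("odd transition cell count: extra cell assigned to %s", "A" if extra else "B")
    mix = np.full(n_trans, int(Fate.B), dtype=np.int8)
    mix[rng.permutation(n_trans)[:n_a]] = int(Fate.A)
    fates[trans] = mix
    return scem_mechanics.lattice_tissue(fates, n_cols, n_rows, forces, n_e, time=t0)


_steady_cache: dict[tuple, MorphogenGrid] = {}


def _steady_grid(config: RunConfig) -> MorphogenGrid:
    """Cell-coupled deterministic stationary field for the configured lattice."""

    mp = config.morphogen
    sp = config.genes.S_params
    key = (
        mp.D,
        mp.beta,
        mp.k_M,
        mp.production.V_max,
        mp.production.profile,
        mp.production.length_scale,
        mp.dx,
        config.genes.k_M,
        sp.V_S,
        sp.K_S,
        sp.h_S,
        config.n_columns,
        config.n_rows,
    )
    if key not in _steady_cache:
        fates = np.full(config.n_columns * config.n_rows, int(Fate.A), dtype=np.int8)
        tissue = scem_mechanics.lattice_tissue(
            fates, config.n_columns, config.n_rows, config.forces,
            config.elements_per_cell, time=0.0,
        )
        sink = lambda m: gene_circuit._sink(m, config.genes)  # noqa: E731
        _steady_cache[key] = morphogen_field.steady_profile(
            mp, tissue.domain, tissue=tissue, sink=sink
        )
    return _steady_cache[key].copy()


def init_morphogen(config: RunConfig, seed: int | None = None) -> tuple[Tissue, MorphogenGrid]:
    """Morphogen-patterned initial condition.

    Cells on the lattice with expression state; the extracellular field is
    initialised at its deterministic stationary profile and co-evolved with
    the gene circuit (noise on, positions frozen) for ``config.burn_in``
    hours before t0; fates are then read out from the relaxed expression.
    The result has coherent anterior-A and posterior-B zones separated by a
    salt-and-pepper transition region whose width is set by the noise level
    and gradient steepness.
    """

    config.validate()
    seed = config.seed if seed is None else seed
    rng_init = _rng(seed, 0)
    n_cols, n_rows = config.n_columns, config.n_rows
    fates = np.full(n_cols * n_rows, int(Fate.A), dtype=np.int8)
    tissue = scem_mechanics.lattice_tissue(
        fates, n_cols, n_rows, config.forces, config.elements_per_cell, time=config.t0 - config.burn_in
    )
    n_cells = tissue.n_cells
    tissue.A = rng_init.uniform(0.0, 0.05, n_cells)
    tissue.B = rng_init.uniform(0.0, 0.05, n_cells)
    tissue.M_in = np.zeros(n_cells)

    grid = _steady_grid(config)
    dt = config.dt
    # pre-equilibrate the intracellular morphogen pools against the stationary
    # field so the fate-capture race happens at each cell's true local level
    nodes0 = grid.bilinear_stencil(tissue.centers())
    for _ in range(int(round(1.0 / dt))):
        M_out_local = morphogen_field.sample_with_stencil(grid, nodes0)
        tissue.M_in += dt * (
            config.genes.k_M * (M_out_local - tissue.M_in)
            - gene_circuit._sink(tissue.M_in, config.genes)
        )
        np.clip(tissue.M_in, 0.0, None, out=tissue.M_in)
    n_burn = int(round(config.burn_in / dt))
    nodes = grid.bilinear_stencil(tissue.centers())
    clipped = 0
    for _ in range(n_burn):
        M_out_local = morphogen_field.sample_with_stencil(grid, nodes)
        clipped += gene_circuit.step_expression_arrays(
            tissue.M_in, tissue.A, tissue.B, M_out_local, config.genes, dt, rng_init
        )
        morphogen_field.step_field(grid, tissue, config.morphogen, dt, rng_init, cell_nodes=nodes)
        tissue.time += dt
    _warn_clipping(clipped, n_burn * n_cells * 3, "burn-in")
    tissue.time = config.t0
    _update_fates(tissue)
    if len(np.unique(tissue.fate)) < 2:
        raise RuntimeError(
            "morphogen burn-in failed to produce two fate zones; "
            "check gradient scale and circuit calibration"
        )
    return tissue, grid


def _update_fates(tissue: Tissue) -> None:
    """Dominant-gene readout with hysteresis on exact ties."""

    new = np.where(
        tissue.A > tissue.B,
        int(Fate.A),
        np.where(tissue.B > tissue.A, int(Fate.B), tissue.fate),
    )
    tissue.fate = new.astype(np.int8)


def _warn_clipping(clipped: int, total: int, where: str) -> None:
    if total and clipped / total > 0.01:
        log.warning(
            "positivity clipping hit %.2f%% of channel updates during %s",
            100.0 * clipped / total,
            where,
        )


# ---------------------------------------------------------------------------
# expression -> mechanics coupling


def phi_scores(tissue: Tissue) -> np.ndarray:
    """Continuous fate score per cell, in [-1, 1].

    The raw score (A - B)/(A + B + eps) is passed through a saturating ramp
    (full strength at |raw| >= PHI_SATURATION) so that committed cells — whose
    losing gene never decays exactly to zero — recover the discrete Model S
    interaction strength, while genuinely undifferentiated cells still couple
    weakly.
    """

    if not tissue.has_expression:
        return tissue.fate.astype(float)
    raw = (tissue.A - tissue.B) / (tissue.A + tissue.B + PHI_EPS)
    return np.clip(raw / PHI_SATURATION, -1.0, 1.0)


def expression_to_interaction(
    state_i: CellExpressionState, state_j: CellExpressionState
) -> dict[str, float]:
    """Bilinear blend of two cells' expression into mechanical weights.

    attraction_weight = max(0, phi_i*phi_j), repulsion_weight = max(0, -phi_i*phi_j):
    committed like pairs recover Model S adhesion, committed unlike pairs
    recover Model S repulsion, undifferentiated cells interact weakly.
    """

    def phi(s: CellExpressionState) -> float:
        return (s.A - s.B) / (s.A + s.B + PHI_EPS)

    p = phi(state_i) * phi(state_j)
    return {"attraction_weight": max(0.0, p), "repulsion_weight": max(0.0, -p)}


# ---------------------------------------------------------------------------
# boundaries


def deterministic_switch_positions(config: RunConfig) -> list[float]:
    """x positions where the noise-free morphogen readout flips the fate.

    Clamps each lattice column to the deterministic stationary field value at
    its center, relaxes the full (M_in, A, B) kinetics without noise, and
    returns the midpoints between adjacent columns of opposite outcome.
    """

    grid = _steady_grid(config)
    xs = np.arange(config.n_columns) + 0.5
    y_mid = config.n_rows / 2.0
    M_out = np.array(
        [morphogen_field.sample_at(grid, np.array([x, y_mid])) for x in xs]
    )
    p = config.genes
    M_in = np.zeros(len(xs))
    A = np.zeros(len(xs))
    B = np.zeros(len(xs))
    dt = config.dt
    for _ in range(int(round(3.0 / dt))):
        dM, dA, dB = gene_circuit.drift_arrays(M_in, A, B, M_out, p)
        M_in = np.clip(M_in + dt * dM, 0.0, None)
        A = np.clip(A + dt * dA, 0.0, None)
        B = np.clip(B + dt * dB, 0.0, None)
    fate = np.where(A >= B, 1, -1)
    switches = [float((xs[k] + xs[k + 1]) / 2.0) for k in range(len(xs) - 1) if fate[k] != fate[k + 1]]
    return switches


def boundaries_for(config: RunConfig) -> list[Boundary]:
    """The metric boundaries of a scenario.

    Two-zone scenarios have the single anterior-A | posterior-B interface.
    The three-zone scenario has r3/4 (B|A) and r4/5 (A|B); their metric
    sub-domains split at the midpoint between the two deterministic switch
    positions.
    """

    if config.scenario != "three_zone":
        return [metrics.TWO_ZONE_BOUNDARY]
    switches = deterministic_switch_positions(config)
    if len(switches) < 2:
        raise RuntimeError(
            f"three-zone scenario requires two deterministic switches, found {switches}"
        )
    mid = 0.5 * (switches[0] + switches[-1])
    return [
        Boundary("r3/4", Fate.B, Fate.A, (0.0, mid)),
        Boundary("r4/5", Fate.A, Fate.B, (mid, float(config.n_columns))),
    ]


# ---------------------------------------------------------------------------
# the time loop


@dataclass
class RunResult:
    config: RunConfig
    seed: int
    tissue: Tissue  # final state
    grid: MorphogenGrid | None
    metrics: dict[str, MetricsSeries]
    snapshots: list[Tissue] = field(default_factory=list)
    initial: Tissue | None = None

    @property
    def boundary(self) -> MetricsSeries:
        """The single boundary's series (two-zone runs)."""

        if len(self.metrics) != 1:
            raise ValueError("run has multiple boundaries; index metrics by name")
        return next(iter(self.metrics.values()))


def run(
    config: RunConfig,
    seed: int | None = None,
    initial: tuple[Tissue, MorphogenGrid | None] | None = None,
    keep_snapshots: bool = False,
) -> RunResult:
    """Simulate one replicate of the configured model.

    ``initial`` (tissue, grid) allows paired S/P/SP comparisons from one
    generated state; it is copied, never mutated.  Fully reproducible from
    (config, seed).
    """

    config.validate()
    seed = config.seed if seed is None else seed
    if initial is None:
        if config.scenario == "two_zone_manual":
            tissue = init_manual(
                config.ITW,
                seed,
                n_rows=config.n_rows,
                forces=config.forces,
                n_e=config.elements_per_cell,
                t0=config.t0,
            )
            grid = None
        else:
            tissue, grid = init_morphogen(config, seed)
    else:
        tissue = initial[0].copy()
        grid = initial[1].copy() if initial[1] is not None else None
    if config.mode in ("P", "SP") and not tissue.has_expression:
        raise ValueError(f"mode {config.mode} requires an expression state (morphogen scenario)")

    rng = _rng(seed, 1)
    boundaries = boundaries_for(config) if config.scenario == "three_zone" else [
        metrics.TWO_ZONE_BOUNDARY
    ]
    series = {b.name: MetricsSeries(b) for b in boundaries}
    result = RunResult(
        config=config,
        seed=seed,
        tissue=tissue,
        grid=grid,
        metrics=series,
        initial=tissue.copy(),
    )

    dt = config.dt
    n_steps = int(round((config.t_end - config.t0) / dt))
    snap_every = max(1, int(round(config.snapshot_dt / dt)))
    mech_bound = config.forces.max_stable_dt()
    if dt > mech_bound:
        raise ValueError(f"dt={dt} exceeds mechanical stability bound {mech_bound:.3g}")

    for s in series.values():
        s.record(tissue)
    if keep_snapshots:
        result.snapshots.append(tissue.copy())

    pairs = None
    steps_since_rebuild = 0
    nodes = None
    clipped = 0
    gene_updates = 0
    for k in range(n_steps):
        t = config.t0 + k * dt
        active = config.active_mechanisms(t)
        moving = "sorting" in active

        if "plasticity" in active and tissue.has_expression and grid is not None:
            if nodes is None or moving:
                nodes = grid.bilinear_stencil(tissue.centers())
            M_out_local = morphogen_field.sample_with_stencil(grid, nodes)
            clipped += gene_circuit.step_expression_arrays(
                tissue.M_in, tissue.A, tissue.B, M_out_local, config.genes, dt, rng
            )
            gene_updates += tissue.n_cells * 3
            morphogen_field.step_field(
                grid, tissue, config.morphogen, dt, rng, cell_nodes=nodes
            )
            _update_fates(tissue)

        if moving:
            if pairs is None or steps_since_rebuild >= PAIR_REBUILD_EVERY:
                pairs = scem_mechanics.build_pairs(tissue.pos, config.forces.cutoff + PAIR_SKIN)
                steps_since_rebuild = 0
            coupling = phi_scores(tissue) if config.mode == "SP" else None
            scem_mechanics.step_mechanics(
                tissue, config.forces, dt, rng=rng, coupling=coupling, pairs=pairs
            )
            steps_since_rebuild += 1

        tissue.time = config.t0 + (k + 1) * dt
        if (k + 1) % snap_every == 0 or k + 1 == n_steps:
            for s in series.values():
                s.record(tissue)
            if keep_snapshots:
                result.snapshots.append(tissue.copy())

    _warn_clipping(clipped, gene_updates, "run")
    for s in series.values():
        s.finalize(tissue)
    return result


def run_ensemble(
    config: RunConfig,
    base_seed: int,
    modes: tuple[str, ...] = ("SP",),
    n_replicates: int | None = None,
    keep_snapshots: bool = False,
) -> dict[str, list[RunResult]]:
    """Paired replicate ensembles: replicate i of every mode starts from the
    same generated initial state (seed = base_seed XOR i)."""

    import dataclasses as _dc

    n = config.replicate_count if n_replicates is None else n_replicates
    out: dict[str, list[RunResult]] = {m: [] for m in modes}
    for i in range(n):
        seed = (base_seed ^ i) & 0x7FFFFFFF
        if config.scenario == "two_zone_manual":
            initial = (
                init_manual(
                    config.ITW,
                    seed,
                    n_rows=config.n_rows,
                    forces=config.forces,
                    n_e=config.elements_per_cell,
                    t0=config.t0,
                ),
                None,
            )
        else:
            initial = init_morphogen(config, seed)
        for mode in modes:
            cfg = _dc.replace(config, mode=mode)  # shallow copy; params shared read-only
            out[mode].append(
                run(cfg, seed=seed, initial=initial, keep_snapshots=keep_snapshots)
            )
    return out


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationStage:
    name: str
    passed: bool
    details: dict


@dataclass
class CalibrationReport:
    stages: list[CalibrationStage]

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.stages)

    def failures(self) -> list[str]:
        return [s.name for s in self.stages if not s.passed]


def calibrate(
    config: RunConfig | None = None,
    seed: int = 0,
    n_replicates: int = 16,
    heavy: bool = True,
) -> CalibrationReport:
    """Check the staged calibration requirements of the shipped defaults.

    Stages, in order: (1) isolated-cell rounding; (2) bistability of the A/B
    circuit across the transition-region morphogen range with the B basin
    deeper at posterior-half levels; (3) Model P noise response (medium noise
    narrows TW most; strong noise erodes the A zone); (4) Model S narrow-band
    effectiveness (ITW=2 mostly sharpens, ITW=4 mostly fails).  Stages 3-4
    run replicate ensembles and are skipped when ``heavy`` is false.
    The report names any failing stage.
    """

    import dataclasses as _dc

    config = config or RunConfig()
    stages: list[CalibrationStage] = []

    # stage 1: rounding (noise-off relaxation)
    fp = _dc.replace(config.forces, element_noise=0.0)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(5):
        n_e = config.elements_per_cell
        pos = 0.4 * rng.standard_normal((n_e, 2))
        t = Tissue(
            pos=pos,
            cell_of=np.zeros(n_e, dtype=np.int64),
            fate=np.array([1], dtype=np.int8),
            domain=(-100.0, 100.0, -100.0, 100.0),
            time=0.0,
            n_e=n_e,
        )
        dt_rel = 0.5 * fp.max_stable_dt()
        for _ in range(4000):
            scem_mechanics.step_mechanics(t, fp, dt_rel)
        geom = scem_mechanics.cell_geometry(t.cell(0))
        worst = max(worst, geom["asphericity"])
    stages.append(CalibrationStage("rounding", worst < 0.05, {"max_asphericity": worst}))

    # stage 2: bistability and posterior B bias
    switches = deterministic_switch_positions(config)
    grid = _steady_grid(config)
    x_switch = switches[-1] if switches else config.n_columns / 2.0
    y_mid = config.n_rows / 2.0
    M_at = lambda x: float(
        morphogen_field.sample_at(grid, np.array([x, y_mid]))
    )  # noqa: E731
    M_mid = _readout(M_at(x_switch), config.genes)
    fps_mid = [f for f in gene_circuit.steady_states(M_mid, config.genes) if f.stable]
    M_post = _readout(M_at(min(x_switch + 2.0, config.n_columns - 0.5)), config.genes)
    fps_post = [f for f in gene_circuit.steady_states(M_post, config.genes) if f.stable]
    bistable = len(fps_mid) == 2
    bias_ok = False
    if len(fps_post) == 2:
        a_state = max(fps_post, key=lambda f: f.A - f.B)
        b_state = min(fps_post, key=lambda f: f.A - f.B)
        bias_ok = (b_state.depth or 0) > (a_state.depth or 0)
    elif len(fps_post) == 1:
        bias_ok = fps_post[0].B > fps_post[0].A  # monostable B: maximal bias
    stages.append(
        CalibrationStage(
            "bistability",
            bistable and bias_ok,
            {
                "switches": switches,
                "M_mid": M_mid,
                "n_stable_mid": len(fps_mid),
                "M_post": M_post,
                "n_stable_post": len(fps_post),
            },
        )
    )

    if heavy:
        # stage 3: Model P noise response
        tw_end = {}
        a_loss = {}
        for eta in (0.03, 0.06, 0.09):
            genes = _dc.replace(config.genes, eta_A=eta, eta_B=eta)
            cfg = _dc.replace(config, mode="P", genes=genes)
            ens = run_ensemble(cfg, seed, modes=("P",), n_replicates=n_replicates)["P"]
            tw_end[eta] = float(np.nanmean([r.boundary.TW[-1] for r in ens]))
            a0 = np.mean([np.sum(r.initial.fate == 1) for r in ens])
            a1 = np.mean([np.sum(r.tissue.fate == 1) for r in ens])
            a_loss[eta] = float(a1 - a0)
        ok3 = tw_end[0.06] < tw_end[0.03] and a_loss[0.09] < 0
        stages.append(CalibrationStage("plasticity_noise", ok3, {"TW_end": tw_end, "A_change": a_loss}))

        # stage 4: Model S band-width dependence
        succ = {}
        for itw in (2, 4):
            cfg = _dc.replace(config, mode="S", scenario="two_zone_manual", ITW=itw)
            ens = run_ensemble(cfg, seed, modes=("S",), n_replicates=n_replicates)["S"]
            outcomes = [r.boundary.outcome for r in ens]
            succ[itw] = sum(o in ("formed", "nearly_formed") for o in outcomes)
        ok4 = succ[2] >= n_replicates // 2 and succ[4] < succ[2]
        stages.append(CalibrationStage("sorting_bandwidth", ok4, {"formed_or_nearly": succ}))

    return CalibrationReport(stages)


def _readout(M_out: float, genes: GeneParams) -> float:
    """Steady intracellular morphogen level given a clamped extracellular level."""

    from scipy.optimize import brentq

    f = lambda m: genes.k_M * (M_out - m) - gene_circuit._sink(m, genes)  # noqa: E731
    hi = max(M_out, 1e-6)
    return brentq(f, 0.0, hi + 1e-9) if f(0.0) > 0 else 0.0
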