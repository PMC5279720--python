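"""Extracellular morphogen dynamics on the rectangular tissue domain.

The diffusible morphogen M_out obeys a stochastic reaction-diffusion
equation: diffusion, first-order removal at rate (1+beta)*k_M (exchange into
cells plus extracellular degradation), re-release k_M*M_in from each cell,
a graded deterministic source V_M(x) that is maximal at the posterior
(high-x) end, and additive space-time white noise.  Integration is explicit
FTCS on a regular grid with no-flux (mirror) boundaries; cells exchange
morphogen with the single grid node nearest their center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MorphogenParams
from .scem_mechanics import Tissue

__all__ = [
    "MorphogenGrid",
    "production_profile",
    "step_field",
    "sample_at",
    "steady_profile",
]


@dataclass
class MorphogenGrid:
    """Non-negative concentration lattice covering the tissue domain.

    ``values[iy, ix]`` sits at (x0 + ix*dx, y0 + iy*dx).
    """

    values: np.ndarray
    dx: float
    domain: tuple[float, float, float, float]

    @classmethod
    def for_domain(
        cls, domain: tuple[float, float, float, float], dx: float, fill: float = 0.0
    ) -> "MorphogenGrid":
        x0, x1, y0, y1 = domain
        nx = int(round((x1 - x0) / dx)) + 1
        ny = int(round((y1 - y0) / dx)) + 1
        return cls(values=np.full((ny, nx), fill, dtype=float), dx=dx, domain=domain)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def node_x(self) -> np.ndarray:
        return self.domain[0] + self.dx * np.arange(self.shape[1])

    def bilinear_stencil(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Flat indices (n, 4) and weights (n, 4) of the four nodes around
        each point (clamped at the lattice edge); weights sum to 1."""

        x0, _, y0, _ = self.domain
        ny, nx = self.shape
        fx = np.clip((points[:, 0] - x0) / self.dx, 0.0, nx - 1.0)
        fy = np.clip((points[:, 1] - y0) / self.dx, 0.0, ny - 1.0)
        ix = np.minimum(fx.astype(int), max(nx - 2, 0))
        iy = np.minimum(fy.astype(int), max(ny - 2, 0))
        tx = fx - ix
        ty = fy - iy
        ix1 = np.minimum(ix + 1, nx - 1)
        iy1 = np.minimum(iy + 1, ny - 1)
        idx = np.stack(
            [iy * nx + ix, iy * nx + ix1, iy1 * nx + ix, iy1 * nx + ix1], axis=1
        )
        w = np.stack(
            [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty], axis=1
        )
        return idx, w

    def nearest_nodes(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(iy, ix) indices of the node nearest each (x, y) point, clamped."""

        x0, _, y0, _ = self.domain
        ix = np.clip(np.rint((points[:, 0] - x0) / self.dx).astype(int), 0, self.shape[1] - 1)
        iy = np.clip(np.rint((points[:, 1] - y0) / self.dx).astype(int), 0, self.shape[0] - 1)
        return iy, ix

    def copy(self) -> "MorphogenGrid":
        return MorphogenGrid(self.values.copy(), self.dx, self.domain)


def production_profile(x, t: float, params: MorphogenParams, x_max: float):
    """Deterministic source rate V_M(x, t); maximal V_max at the posterior end.

    The exponential profile decays with length scale lambda toward the
    anterior; linear decays to zero over lambda; step is V_max within lambda
    of the posterior end and zero elsewhere.  (Time-independent; ``t`` is kept
    in the signature for source schedules.)
    """

    prod = params.production
    depth = x_max - np.asarray(x, dtype=float)
    if prod.profile == "exponential":
        out = prod.V_max * np.exp(-depth / prod.length_scale)
    elif prod.profile == "linear":
        out = prod.V_max * np.clip(1.0 - depth / prod.length_scale, 0.0, None)
    elif prod.profile == "step":
        out = prod.V_max * (depth <= prod.length_scale).astype(float)
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown production profile {prod.profile!r}")
    return out if np.ndim(x) else float(out)


def _laplacian_noflux(v: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian with mirror (no-flux) boundary nodes."""

    p = np.pad(v, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * v) / dx**2


def step_field(
    grid: MorphogenGrid,
    cells: Tissue | None,
    params: MorphogenParams,
    dt: float,
    rng: np.random.Generator | None = None,
    cell_nodes: tuple[np.ndarray, np.ndarray] | None = None,
) -> MorphogenGrid:
    """One explicit FTCS update of the field (in place; grid returned).

    Removal (1+beta)*k_M*M_out acts everywhere; each cell deposits
    k_M * M_in / dx^2 at the node nearest its center (all of a cell's release
    goes to exactly one node, so the deposited total is conserved); lattice
    white noise is scaled by 1/dx.  Negative excursions are clipped to zero.
    """

    if dt > params.max_stable_dt() * (1 + 1e-9):
        raise ValueError(
            f"dt={dt} violates the diffusion stability bound {params.max_stable_dt():.3g}"
        )
    v = grid.values
    x_max = grid.domain[1]
    source = production_profile(grid.node_x(), 0.0, params, x_max)[None, :]
    dv = params.D * _laplacian_noflux(v, grid.dx) - (1.0 + params.beta) * params.k_M * v + source
    v += dt * dv
    if cells is not None and cells.M_in is not None:
        # bilinear (area-weighted) splatting: each cell's release is shared
        # among the four surrounding nodes so that compressed cell clusters do
        # not create single-node concentration spikes; total deposit conserved
        if cell_nodes is None:
            cell_nodes = grid.bilinear_stencil(cells.centers())
        idx, w = cell_nodes
        deposit = np.bincount(idx.ravel(), weights=(w * cells.M_in[:, None]).ravel(), minlength=v.size)
        v += (dt * params.k_M / grid.dx**2) * deposit.reshape(grid.shape)
    if params.eta_out > 0:
        if rng is None:
            raise ValueError("eta_out > 0 requires an rng")
        v += (params.eta_out * np.sqrt(dt) / grid.dx) * rng.standard_normal(v.shape)
    np.clip(v, 0.0, None, out=v)
    return grid


def sample_with_stencil(grid: MorphogenGrid, stencil: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Field values at precomputed bilinear stencils (one per cell)."""

    idx, w = stencil
    return (grid.values.ravel()[idx] * w).sum(axis=1)


def sample_at(grid: MorphogenGrid, position) -> float | np.ndarray:
    """Bilinear interpolation; positions outside the lattice clamp to the edge."""

    pos = np.atleast_2d(np.asarray(position, dtype=float))
    x0, _, y0, _ = grid.domain
    ny, nx = grid.shape
    fx = np.clip((pos[:, 0] - x0) / grid.dx, 0.0, nx - 1.0)
    fy = np.clip((pos[:, 1] - y0) / grid.dx, 0.0, ny - 1.0)
    ix = np.minimum(fx.astype(int), nx - 2) if nx > 1 else np.zeros(len(fx), int)
    iy = np.minimum(fy.astype(int), ny - 2) if ny > 1 else np.zeros(len(fy), int)
    tx = fx - ix
    ty = fy - iy
    v = grid.values
    out = (
        v[iy, ix] * (1 - tx) * (1 - ty)
        + v[iy, ix + 1] * tx * (1 - ty)
        + v[iy + 1, ix] * (1 - tx) * ty
        + v[iy + 1, ix + 1] * tx * ty
    )
    return float(out[0]) if np.ndim(position) == 1 else out


def steady_profile(
    params: MorphogenParams,
    domain: tuple[float, float, float, float],
    tissue: Tissue | None = None,
    sink=None,
    tol: float = 1e-10,
    max_steps: int = 200_000,
) -> MorphogenGrid:
    """Deterministic stationary field, by relaxation.

    With ``tissue`` supplied the intracellular pools are co-relaxed: each cell
    exchanges with its nearest node and degrades morphogen through the sink S,
    so the result is the operating gradient the gene circuit actually reads
    (the intracellular subsystem is independent of the A/B states).  ``sink``
    is the S(M_in) callable; it defaults to the Hill sink with
    :class:`~rhombosim.params.GeneParams` defaults.
    """

    import dataclasses

    params = dataclasses.replace(params, eta_out=0.0)
    grid = MorphogenGrid.for_domain(domain, params.dx)
    v0 = production_profile(grid.node_x(), 0.0, params, domain[1]) / (
        (1.0 + params.beta) * params.k_M
    )
    grid.values[:] = v0[None, :]
    dt = 0.9 * params.max_stable_dt()
    M_in = None
    nodes = None
    if tissue is not None:
        if sink is None:
            from .gene_circuit import _sink
            from .params import GeneParams

            gp = GeneParams()
            sink = lambda m: _sink(m, gp)  # noqa: E731
        tissue = tissue.copy()
        tissue.M_in = np.zeros(tissue.n_cells) if tissue.M_in is None else tissue.M_in.copy()
        M_in = tissue.M_in
        nodes = grid.bilinear_stencil(tissue.centers())
    for _ in range(max_steps):
        prev = grid.values.copy()
        if M_in is not None:
            M_out_local = sample_with_stencil(grid, nodes)
            M_in += dt * (params.k_M * (M_out_local - M_in) - sink(M_in))
            np.clip(M_in, 0.0, None, out=M_in)
        step_field(grid, tissue, params, dt, cell_nodes=nodes)
        if np.max(np.abs(grid.values - prev)) < tol * max(1.0, grid.values.max()):
            break
    return grid
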