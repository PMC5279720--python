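"""Sub-cellular-element mechanics.

Each cell is a cluster of point elements in 2-D.  Element pairs inside one
cell interact through a Morse potential (short-range repulsion, longer-range
attraction) that makes an isolated cell round up; element pairs in different
cells interact through a like-type Morse adhesion or an unlike-type pure
exponential repulsion, truncated at a contact cutoff of two cell diameters
(three in the long-range variant).  Dynamics are overdamped: element velocity
equals mobility times the summed pair force, integrated with explicit Euler.

Forces are tapered linearly to zero over the last 5% of the cutoff so that
they are continuous at the truncation radius.
"""

from __future__ import annotations

import enum
import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.spatial import cKDTree

from . import _kernels
from .params import ForceParams

log = logging.getLogger(__name__)

__all__ = [
    "Fate",
    "Cell",
    "Tissue",
    "pair_force",
    "pair_potential",
    "total_forces",
    "step_mechanics",
    "cell_geometry",
    "build_cell_template",
    "element_frame",
    "cell_frame",
]


class Fate(enum.IntEnum):
    """Discrete cell identity: A (red/anterior), B (blue/posterior)."""

    A = 1
    B = -1

    @property
    def label(self) -> str:
        return self.name


@dataclass
class Cell:
    """Read-only view of one cell of a :class:`Tissue`."""

    id: int
    elements: np.ndarray  # (n_e, 2) positions
    fate: Fate
    expression: Optional["CellExpressionState"] = None


@dataclass
class CellExpressionState:
    """Per-cell intracellular state (shared with :mod:`rhombosim.gene_circuit`)."""

    M_in: float
    A: float
    B: float


@dataclass
class Tissue:
    """Mechanical + biochemical state of the whole simulated tissue.

    Stored struct-of-arrays: ``pos`` is (E, 2) element positions, ``cell_of``
    maps each element to its cell, ``fate`` holds one ±1 entry per cell
    (:class:`Fate`), and the optional expression arrays ``A``/``B``/``M_in``
    hold one concentration per cell (absent in pure Model S from manual
    initial conditions).
    """

    pos: np.ndarray
    cell_of: np.ndarray
    fate: np.ndarray
    domain: tuple[float, float, float, float]
    time: float
    n_e: int
    A: np.ndarray | None = None
    B: np.ndarray | None = None
    M_in: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.fate)

    @property
    def n_elements(self) -> int:
        return len(self.pos)

    @property
    def has_expression(self) -> bool:
        return self.A is not None

    def centers(self) -> np.ndarray:
        """(C, 2) arithmetic mean of each cell's element positions."""

        cx = np.bincount(self.cell_of, weights=self.pos[:, 0], minlength=self.n_cells)
        cy = np.bincount(self.cell_of, weights=self.pos[:, 1], minlength=self.n_cells)
        counts = np.bincount(self.cell_of, minlength=self.n_cells)
        return np.stack([cx, cy], axis=1) / counts[:, None]

    def cell(self, i: int) -> Cell:
        expr = None
        if self.has_expression:
            expr = CellExpressionState(
                M_in=float(self.M_in[i]), A=float(self.A[i]), B=float(self.B[i])
            )
        return Cell(
            id=i,
            elements=self.pos[self.cell_of == i],
            fate=Fate(int(self.fate[i])),
            expression=expr,
        )

    def copy(self) -> "Tissue":
        return Tissue(
            pos=self.pos.copy(),
            cell_of=self.cell_of.copy(),
            fate=self.fate.copy(),
            domain=self.domain,
            time=self.time,
            n_e=self.n_e,
            A=None if self.A is None else self.A.copy(),
            B=None if self.B is None else self.B.copy(),
            M_in=None if self.M_in is None else self.M_in.copy(),
        )


# ---------------------------------------------------------------------------
# pair interactions

_KINDS = ("intra", "like", "unlike")


def _taper(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Continuous ramp: 1 below 0.95*cutoff, linear to 0 at cutoff, 0 beyond."""

    r_t = 0.95 * cutoff
    return np.clip((cutoff - r) / (cutoff - r_t), 0.0, 1.0)


def _morse_force(r: np.ndarray, depth: float, r_eq: float, a: float) -> np.ndarray:
    s = (r - r_eq) / a
    return (2.0 * depth / a) * (np.exp(-2.0 * s) - np.exp(-s))


def _morse_energy(r: np.ndarray, depth: float, r_eq: float, a: float) -> np.ndarray:
    s = (r - r_eq) / a
    return depth * (np.exp(-2.0 * s) - 2.0 * np.exp(-s))


def _rep_force(r: np.ndarray, amplitude: float, rng_: float) -> np.ndarray:
    return (amplitude / rng_) * np.exp(-r / rng_)


def _rep_energy(r: np.ndarray, amplitude: float, rng_: float) -> np.ndarray:
    return amplitude * np.exp(-r / rng_)


def _raw_force(r: np.ndarray, kind: str, params: ForceParams) -> np.ndarray:
    if kind == "intra":
        mp = params.morse_intra
        return _morse_force(r, mp.depth, mp.equilibrium_distance, mp.range)
    if kind == "like":
        mp = params.morse_adhesion
        return params.strength_scale * _morse_force(
            r, mp.depth, mp.equilibrium_distance, mp.range
        )
    if kind == "unlike":
        rp = params.repulsion
        return params.strength_scale * _rep_force(r, rp.amplitude, rp.range)
    raise ValueError(f"unknown interaction kind {kind!r}; expected one of {_KINDS}")


def pair_force(r, kind: str, params: ForceParams):
    """Signed radial force between two elements at separation ``r``.

    Positive values are repulsive (directed along increasing separation).
    ``kind`` is "intra" (same cell), "like" (different cells, same type) or
    "unlike" (different cells, different type).  Forces vanish continuously
    at ``params.cutoff``.
    """

    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("pair separation must be > 0")
    out = _raw_force(r_arr, kind, params) * _taper(r_arr, params.cutoff)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(out)
    return out


def pair_potential(r, kind: str, params: ForceParams):
    """Pair energy consistent with :func:`pair_force` (U' = -F exactly).

    Inside the taper window the energy is the analytic (numerically
    integrated) antiderivative of the tapered force, so relaxation
    trajectories dissipate this energy monotonically.  Zero at and beyond the
    cutoff.  Diagnostic/oracle use; not called by the integrator.
    """

    cutoff = params.cutoff
    r_t = 0.95 * cutoff

    def tapered_force(s):
        return _raw_force(np.asarray(s, dtype=float), kind, params) * _taper(
            np.asarray(s, dtype=float), cutoff
        )

    tail, _ = quad(tapered_force, r_t, cutoff, limit=200)

    def one(ri: float) -> float:
        if ri <= 0:
            raise ValueError("pair separation must be > 0")
        if ri >= cutoff:
            return 0.0
        if ri >= r_t:
            val, _ = quad(tapered_force, ri, cutoff, limit=200)
            return val
        if kind == "intra":
            mp = params.morse_intra
            u = _morse_energy(ri, mp.depth, mp.equilibrium_distance, mp.range)
            u0 = _morse_energy(r_t, mp.depth, mp.equilibrium_distance, mp.range)
            return float(u - u0) + tail
        if kind == "like":
            mp = params.morse_adhesion
            u = _morse_energy(ri, mp.depth, mp.equilibrium_distance, mp.range)
            u0 = _morse_energy(r_t, mp.depth, mp.equilibrium_distance, mp.range)
            return params.strength_scale * float(u - u0) + tail
        rp = params.repulsion
        u = _rep_energy(ri, rp.amplitude, rp.range)
        u0 = _rep_energy(r_t, rp.amplitude, rp.range)
        return params.strength_scale * float(u - u0) + tail

    r_arr = np.asarray(r, dtype=float)
    if np.isscalar(r) or r_arr.ndim == 0:
        return one(float(r_arr))
    return np.array([one(float(ri)) for ri in r_arr.ravel()]).reshape(r_arr.shape)


# ---------------------------------------------------------------------------
# pair lists and force assembly


def build_pairs(pos: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """All unordered element pairs (i < j) with separation below ``radius``."""

    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return pairs[:, 0], pairs[:, 1]


def _resolve_coincident(tissue: Tissue, i: np.ndarray, j: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Separate exactly coincident elements by a deterministic 1e-6 nudge."""

    bad = np.flatnonzero(r == 0.0)
    for k in bad:
        e = int(j[k])
        h = int.from_bytes(hashlib.blake2b(e.to_bytes(8, "little"), digest_size=8).digest(), "little")
        angle = 2.0 * np.pi * (h % 10**6) / 10**6
        tissue.pos[e] += 1e-6 * np.array([np.cos(angle), np.sin(angle)])
        log.warning("coincident elements %d/%d resolved by deterministic perturbation", int(i[k]), e)
        d = tissue.pos[int(i[k])] - tissue.pos[e]
        r[k] = float(np.hypot(d[0], d[1]))
    return r


def total_forces(
    tissue: Tissue,
    params: ForceParams,
    coupling: np.ndarray | None = None,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-element 2-D force vectors from all pair interactions within cutoff.

    ``coupling`` optionally supplies a continuous per-cell fate score
    φ ∈ [-1, 1] (Model SP): the like/unlike classification is then replaced by
    the bilinear blend attraction = max(0, φ_i φ_j), repulsion = max(0, -φ_i φ_j).
    Without it, φ is the discrete ±1 fate, which reproduces Model S exactly.
    Newton's third law holds pairwise by construction.
    """

    if tissue.n_elements == 0:
        raise ValueError("tissue is empty")
    pos = tissue.pos
    if pairs is None:
        i, j = build_pairs(pos, params.cutoff)
    else:
        i, j = pairs
    forces = np.zeros_like(pos)
    if len(i) == 0:
        return forces

    if _kernels.HAVE_NUMBA:
        phi = tissue.fate.astype(np.float64) if coupling is None else np.asarray(coupling, np.float64)
        mp_i, mp_a, rp = params.morse_intra, params.morse_adhesion, params.repulsion
        for _attempt in range(3):
            n_zero = _kernels.pair_forces_kernel(
                pos,
                i,
                j,
                tissue.cell_of,
                phi,
                mp_i.depth,
                mp_i.equilibrium_distance,
                mp_i.range,
                mp_a.depth,
                mp_a.equilibrium_distance,
                mp_a.range,
                rp.amplitude,
                rp.range,
                params.cutoff,
                params.strength_scale,
                forces,
            )
            if n_zero == 0:
                return forces
            d = pos[i] - pos[j]
            r = np.hypot(d[:, 0], d[:, 1])
            _resolve_coincident(tissue, i, j, r)
            forces[:] = 0.0
        raise RuntimeError("could not separate coincident elements")

    d = pos[i] - pos[j]
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0.0):
        r = _resolve_coincident(tissue, i, j, r)
        d = pos[i] - pos[j]

    ci = tissue.cell_of[i]
    cj = tissue.cell_of[j]
    same = ci == cj
    fmag = np.zeros_like(r)

    if np.any(same):
        mp = params.morse_intra
        rs = r[same]
        fmag[same] = _morse_force(rs, mp.depth, mp.equilibrium_distance, mp.range) * _taper(
            rs, params.cutoff
        )
    cross = ~same
    if np.any(cross):
        phi = tissue.fate.astype(float) if coupling is None else np.asarray(coupling, float)
        p = phi[ci[cross]] * phi[cj[cross]]
        w_att = np.clip(p, 0.0, None)
        w_rep = np.clip(-p, 0.0, None)
        rc = r[cross]
        mp = params.morse_adhesion
        rp = params.repulsion
        f_att = _morse_force(rc, mp.depth, mp.equilibrium_distance, mp.range)
        f_rep = _rep_force(rc, rp.amplitude, rp.range)
        fmag[cross] = (
            params.strength_scale
            * (w_att * f_att + w_rep * f_rep)
            * _taper(rc, params.cutoff)
        )

    scale = fmag / r
    fx = scale * d[:, 0]
    fy = scale * d[:, 1]
    n = tissue.n_elements
    forces[:, 0] = np.bincount(i, weights=fx, minlength=n) - np.bincount(
        j, weights=fx, minlength=n
    )
    forces[:, 1] = np.bincount(i, weights=fy, minlength=n) - np.bincount(
        j, weights=fy, minlength=n
    )
    return forces


def total_energy(
    tissue: Tissue, params: ForceParams, coupling: np.ndarray | None = None
) -> float:
    """Total pair interaction energy (oracle for relaxation tests; slow)."""

    i, j = build_pairs(tissue.pos, params.cutoff)
    if len(i) == 0:
        return 0.0
    d = tissue.pos[i] - tissue.pos[j]
    r = np.hypot(d[:, 0], d[:, 1])
    ci, cj = tissue.cell_of[i], tissue.cell_of[j]
    same = ci == cj
    energy = 0.0
    if np.any(same):
        energy += float(np.sum(pair_potential(r[same], "intra", params)))
    cross = ~same
    if np.any(cross):
        phi = tissue.fate.astype(float) if coupling is None else np.asarray(coupling, float)
        p = phi[ci[cross]] * phi[cj[cross]]
        u_att = np.asarray(pair_potential(r[cross], "like", params))
        u_rep = np.asarray(pair_potential(r[cross], "unlike", params))
        energy += float(np.sum(np.clip(p, 0, None) * u_att + np.clip(-p, 0, None) * u_rep))
    return energy


# ---------------------------------------------------------------------------
# integration


def step_mechanics(
    tissue: Tissue,
    params: ForceParams,
    dt: float,
    rng: np.random.Generator | None = None,
    coupling: np.ndarray | None = None,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
    forces: np.ndarray | None = None,
) -> Tissue:
    """One overdamped explicit-Euler step; reflecting walls; advances the clock.

    ``dt`` above the stability bound ``params.max_stable_dt()`` raises before
    any state change.  The tissue is updated in place and returned.
    """

    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > params.max_stable_dt() * (1 + 1e-9):
        raise ValueError(
            f"dt={dt} exceeds the mechanical stability bound {params.max_stable_dt():.3g}"
        )
    if forces is None:
        forces = total_forces(tissue, params, coupling=coupling, pairs=pairs)
    tissue.pos += params.drag * dt * forces
    if params.element_noise > 0:
        if rng is None:
            raise ValueError("element_noise > 0 requires an rng")
        tissue.pos += params.element_noise * np.sqrt(dt) * rng.standard_normal(tissue.pos.shape)
    reflect_walls(tissue)
    tissue.time += dt
    return tissue


def reflect_walls(tissue: Tissue) -> None:
    x0, x1, y0, y1 = tissue.domain
    pos = tissue.pos
    np.copyto(pos[:, 0], np.where(pos[:, 0] < x0, 2 * x0 - pos[:, 0], pos[:, 0]))
    np.copyto(pos[:, 0], np.where(pos[:, 0] > x1, 2 * x1 - pos[:, 0], pos[:, 0]))
    np.copyto(pos[:, 1], np.where(pos[:, 1] < y0, 2 * y0 - pos[:, 1], pos[:, 1]))
    np.copyto(pos[:, 1], np.where(pos[:, 1] > y1, 2 * y1 - pos[:, 1], pos[:, 1]))


# ---------------------------------------------------------------------------
# geometry and initialisation


def cell_geometry(cell: Cell) -> dict:
    """Center (mean of elements) and asphericity = var(r_i) / mean(r_i)^2.

    Asphericity is 0 for any element arrangement whose distances to the
    center are all equal (e.g. a regular polygon) and grows with radial
    scatter; the intra-cell force calibration requires an isolated relaxed
    cell to reach asphericity < 0.05.
    """

    elems = np.asarray(cell.elements, dtype=float)
    if len(elems) < 3:
        raise ValueError("cell_geometry requires at least 3 elements")
    center = elems.mean(axis=0)
    radii = np.hypot(*(elems - center).T)
    mean_r = radii.mean()
    if mean_r == 0:
        return {"center": center, "asphericity": 0.0}
    return {"center": center, "asphericity": float(radii.var() / mean_r**2)}


_template_cache: dict[tuple, np.ndarray] = {}


def build_cell_template(
    n_e: int, params: ForceParams, n_steps: int = 3000, dt: float | None = None
) -> np.ndarray:
    """Element offsets of one isolated, mechanically relaxed cell.

    Elements start on a deterministic sunflower spiral and relax (noise off,
    intra-cell forces only) until the cluster rounds up.  The result is
    cached per parameter set and re-centered on the origin.
    """

    import dataclasses

    mp = params.morse_intra
    key = (n_e, mp.depth, mp.equilibrium_distance, mp.range, params.cutoff, n_steps)
    if key in _template_cache:
        return _template_cache[key]
    params = dataclasses.replace(params, element_noise=0.0)  # relax deterministically
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_e)
    radius = 0.5 * mp.equilibrium_distance * np.sqrt(k + 0.5) / np.sqrt(n_e) * 2.2
    offsets = np.stack([radius * np.cos(golden * k), radius * np.sin(golden * k)], axis=1)
    tissue = Tissue(
        pos=offsets.copy(),
        cell_of=np.zeros(n_e, dtype=np.int64),
        fate=np.array([1], dtype=np.int8),
        domain=(-100.0, 100.0, -100.0, 100.0),
        time=0.0,
        n_e=n_e,
    )
    dt_rel = dt if dt is not None else 0.5 * params.max_stable_dt()
    for _ in range(n_steps):
        step_mechanics(tissue, params, dt_rel)
    out = tissue.pos - tissue.pos.mean(axis=0)
    _template_cache[key] = out
    return out


def lattice_tissue(
    fates: np.ndarray,
    n_columns: int,
    n_rows: int,
    params: ForceParams,
    n_e: int,
    time: float,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tissue:
    """Stamp equilibrated cells on a unit lattice covering [0, n_columns] x [0, n_rows].

    ``fates`` is column-major with column index varying slowest:
    cell (col, row) has index col * n_rows + row and center (col+0.5, row+0.5).
    """

    template = build_cell_template(n_e, params)
    n_cells = n_columns * n_rows
    if len(fates) != n_cells:
        raise ValueError("fates length must equal n_columns * n_rows")
    cols, rows = np.divmod(np.arange(n_cells), n_rows)
    centers = np.stack([cols + 0.5, rows + 0.5], axis=1).astype(float)
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter > 0 requires an rng")
        centers += jitter * rng.standard_normal(centers.shape)
    pos = (centers[:, None, :] + template[None, :, :]).reshape(-1, 2)
    return Tissue(
        pos=pos,
        cell_of=np.repeat(np.arange(n_cells), n_e),
        fate=np.asarray(fates, dtype=np.int8).copy(),
        domain=(0.0, float(n_columns), 0.0, float(n_rows)),
        time=time,
        n_e=n_e,
    )


# ---------------------------------------------------------------------------
# tabular snapshots


def element_frame(tissue: Tissue):
    """One row per element: time_hpf, cell_id, fate, x, y."""

    import pandas as pd

    return pd.DataFrame(
        {
            "time_hpf": tissue.time,
            "cell_id": tissue.cell_of,
            "fate": np.where(tissue.fate[tissue.cell_of] > 0, "A", "B"),
            "x": tissue.pos[:, 0],
            "y": tissue.pos[:, 1],
        }
    )


def cell_frame(tissue: Tissue):
    """One row per cell: time_hpf, cell_id, fate, center, expression state."""

    import pandas as pd

    centers = tissue.centers()
    data = {
        "time_hpf": tissue.time,
        "cell_id": np.arange(tissue.n_cells),
        "fate": np.where(tissue.fate > 0, "A", "B"),
        "center_x": centers[:, 0],
        "center_y": centers[:, 1],
    }
    for name in ("A", "B", "M_in"):
        arr = getattr(tissue, name)
        data[name] = np.full(tissue.n_cells, np.nan) if arr is None else arr
    return pd.DataFrame(data)
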