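"""Vessel geometries and structured finite-difference domains.

Three geometry families are supported, all bounded by blood vessels that
act as fixed-concentration (Dirichlet) oxygen sources:

* 1D: a segment between two parallel vessels a given spacing apart;
* 2D: a rectangle with vessels along the four borders plus optional
  internal capillary segments;
* 3D: a cuboid with five vertical vessels (one through the center, one
  along each vertical edge) and zero-flux (Neumann) outer faces, so the
  cuboid tiles space periodically.

Grids are node-centered and 0-based: node ``i`` along an axis sits at the
physical coordinate ``i * dx``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .parameters import BoundarySupply


class InvalidGeometryError(ValueError):
    """The requested vessel geometry is degenerate or inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Discretization and stopping-rule settings shared by all solvers.

    Attributes
    ----------
    dx:
        Node spacing, μm.
    steps_per_stage:
        Number of uniform time steps used for the irradiation stage and
        for the recovery stage.
    recovery_duration:
        Length of the post-irradiation replenishment stage, s.  Also sets
        the internal time step of the pre-irradiation equilibration,
        ``recovery_duration / steps_per_stage``.
    equilibration_tolerance:
        Relative per-step change below which the pre-irradiation march is
        considered stationary (max over nodes of ``|ΔO| / max(O, 0.1 μM)``).
    equilibration_residual_tol:
        Additional stop requirement on the steady-state residual
        ``|K3 lap(O) - K2 O/(O+λ)|`` at interior nodes, μM/s.  The bare
        per-step criterion alone can trigger far from steady state when
        the internal time step is small.
    equilibration_max_time:
        Simulated time after which a non-converged equilibration raises.
    irradiation_snapshot_stride / other_snapshot_stride:
        Keep every n-th state in the returned history for the irradiation
        stage and for the other stages.  Dose integrals are accumulated at
        full step resolution regardless of these strides.
    """

    dx: float = 0.5
    steps_per_stage: int = 1500
    recovery_duration: float = 10.0
    equilibration_tolerance: float = 1e-4
    equilibration_residual_tol: float = 1e-3
    equilibration_max_time: float = 600.0
    irradiation_snapshot_stride: int = 1
    other_snapshot_stride: int = 10

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise InvalidGeometryError(f"dx must be > 0, got {self.dx!r}")
        if self.steps_per_stage < 1:
            raise InvalidGeometryError("steps_per_stage must be >= 1")
        if not self.recovery_duration > 0:
            raise InvalidGeometryError("recovery_duration must be > 0")


@dataclass(frozen=True)
class Geometry1D:
    """Two parallel vessels ``spacing`` μm apart bounding a 1D segment."""

    spacing: float
    left_supply: BoundarySupply = field(
        default_factory=lambda: BoundarySupply(50.4))
    right_supply: BoundarySupply = field(
        default_factory=lambda: BoundarySupply(50.4))

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise InvalidGeometryError(
                f"vessel spacing must be > 0, got {self.spacing!r}")


@dataclass(frozen=True)
class VesselSegment2D:
    """A straight capillary segment inside a 2D region."""

    start: tuple[float, float]
    end: tuple[float, float]
    radius: float
    supply: BoundarySupply

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Euclidean distance from grid points to the segment."""
        px, py = self.start
        qx, qy = self.end
        vx, vy = qx - px, qy - py
        denom = vx * vx + vy * vy
        if denom == 0.0:
            return np.hypot(x - px, y - py)
        t = np.clip(((x - px) * vx + (y - py) * vy) / denom, 0.0, 1.0)
        return np.hypot(x - (px + t * vx), y - (py + t * vy))


@dataclass(frozen=True)
class Geometry2D:
    """Rectangle with vessels along all four borders plus internal segments.

    ``border_supplies`` maps side names ``left``, ``right``, ``bottom``,
    ``top`` to their supplies.  Where two sides meet at a corner the side
    listed first in that order claims the node.
    """

    width: float
    height: float
    border_supplies: dict[str, BoundarySupply]
    vessels: tuple[VesselSegment2D, ...] = ()

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidGeometryError("width and height must be > 0")
        unknown = set(self.border_supplies) - {"left", "right", "bottom", "top"}
        if unknown:
            raise InvalidGeometryError(f"unknown border side(s): {unknown}")
        for v in self.vessels:
            for x, y in (v.start, v.end):
                if not (0.0 <= x <= self.width and 0.0 <= y <= self.height):
                    raise InvalidGeometryError(
                        f"vessel endpoint ({x}, {y}) outside the "
                        f"{self.width} x {self.height} rectangle")


@dataclass(frozen=True)
class Geometry3D:
    """Cuboid with one central and four edge vessels, all vertical.

    The square cross-section has side ``cross_section_side``; the center
    vessel is therefore ``cross_section_side / sqrt(2)`` from each edge
    vessel.  All five vessels share one supply and run the full height.
    Because the vessels are vertical, the outer faces are zero-flux and
    the initial state is uniform in z, the solution is exactly invariant
    along z; the height therefore only sets how many identical layers are
    carried.
    """

    cross_section_side: float
    height: float
    vessel_radius: float = 5.0
    supply: BoundarySupply = field(
        default_factory=lambda: BoundarySupply(18.9))

    def __post_init__(self) -> None:
        if not (self.cross_section_side > 0 and self.height > 0):
            raise InvalidGeometryError("cuboid dimensions must be > 0")
        if not 0 < self.vessel_radius < self.cross_section_side / 4:
            raise InvalidGeometryError(
                f"vessel_radius {self.vessel_radius!r} must lie in "
                f"(0, side/4) = (0, {self.cross_section_side / 4})")

    @classmethod
    def from_center_to_edge_distance(cls, distance: float,
                                     height: Optional[float] = None,
                                     **kwargs) -> "Geometry3D":
        """Build from the stated center-vessel-to-edge-vessel distance."""
        side = distance * math.sqrt(2.0)
        return cls(cross_section_side=side,
                   height=side if height is None else height, **kwargs)

    @property
    def center_to_edge_distance(self) -> float:
        return self.cross_section_side / math.sqrt(2.0)

    @property
    def vessel_axes(self) -> tuple[tuple[float, float], ...]:
        """(x, y) of the five vertical vessel axes."""
        s = self.cross_section_side
        return ((s / 2, s / 2), (0, 0), (0, s), (s, 0), (s, s))


class DiscreteDomain:
    """A structured grid with vessel (Dirichlet) and outer-face (Neumann)
    node classification and the matching Laplacian stencil.

    Every node belongs to exactly one of three classes: *interior*,
    *dirichlet* (on a vessel wall, carrying a :class:`BoundarySupply`), or
    *neumann* (on an outer zero-flux face).  The Laplacian uses the
    standard 3/5/7-point stencil; zero normal flux is imposed by mirror
    ghost nodes, and Dirichlet rows are zeroed (those nodes are overwritten
    with their supply values by the solver).
    """

    def __init__(self, shape: tuple[int, ...], dx: float,
                 dirichlet_mask: np.ndarray, supply_index: np.ndarray,
                 supplies: Sequence[BoundarySupply]):
        self.shape = tuple(shape)
        self.ndim = len(self.shape)
        self.dx = float(dx)
        self.dirichlet_mask = dirichlet_mask.reshape(-1).astype(bool)
        self.supply_index = supply_index.reshape(-1).astype(np.int64)
        self.supplies = list(supplies)
        self.n_nodes = int(np.prod(self.shape))
        if self.dirichlet_mask.size != self.n_nodes:
            raise InvalidGeometryError("mask does not match grid shape")
        if not self.dirichlet_mask.any():
            raise InvalidGeometryError("domain has no vessel (Dirichlet) node")
        if self.dirichlet_mask.all():
            raise InvalidGeometryError("domain has no tissue node")
        self._laplacian: Optional[sp.csr_matrix] = None

    # -- node bookkeeping -------------------------------------------------
    @property
    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of non-vessel nodes (interior plus Neumann faces)."""
        return ~self.dirichlet_mask

    @property
    def boundary_mask(self) -> np.ndarray:
        """Nodes on the outer hull of the grid."""
        m = np.zeros(self.shape, dtype=bool)
        for ax in range(self.ndim):
            sl: list = [slice(None)] * self.ndim
            sl[ax] = 0
            m[tuple(sl)] = True
            sl[ax] = self.shape[ax] - 1
            m[tuple(sl)] = True
        return m.reshape(-1)

    @property
    def neumann_mask(self) -> np.ndarray:
        return self.boundary_mask & ~self.dirichlet_mask

    @property
    def interior_mask(self) -> np.ndarray:
        return ~self.boundary_mask & ~self.dirichlet_mask

    def coordinates(self) -> np.ndarray:
        """(n_nodes, ndim) array of physical node coordinates in μm."""
        axes = [np.arange(n) * self.dx for n in self.shape]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.reshape(-1) for g in grids], axis=1)

    def nearest_node(self, point: Sequence[float]) -> int:
        """Flat index of the grid node nearest to ``point`` (μm)."""
        point = np.asarray(point, dtype=float)
        if point.shape != (self.ndim,):
            raise InvalidGeometryError(
                f"probe point must have {self.ndim} coordinate(s)")
        idx = []
        for ax, p in enumerate(point):
            i = int(round(p / self.dx))
            if not 0 <= i < self.shape[ax]:
                raise InvalidGeometryError(
                    f"probe coordinate {p} μm outside the domain")
            idx.append(i)
        return int(np.ravel_multi_index(tuple(idx), self.shape))

    def supply_values(self, t: float) -> np.ndarray:
        """Per-Dirichlet-node supply values at time ``t`` (μM)."""
        levels = np.array([s.value_at(t) for s in self.supplies])
        return levels[self.supply_index[self.dirichlet_mask]]

    # -- discrete operators ----------------------------------------------
    def laplacian(self) -> sp.csr_matrix:
        """Sparse Laplacian (1/μm²); mirror ghosts on outer faces,
        Dirichlet rows zeroed."""
        if self._laplacian is not None:
            return self._laplacian
        n = self.n_nodes
        flat = np.arange(n).reshape(self.shape)
        rows, cols, vals = [], [], []
        diag = np.zeros(self.shape)
        for ax in range(self.ndim):
            size = self.shape[ax]
            if size < 2:
                continue
            for off in (-1, +1):
                idx = np.arange(size) + off
                # mirror ghost: the out-of-range neighbor reflects inward
                idx[idx < 0] = 1
                idx[idx >= size] = size - 2
                nbr = np.take(flat, idx, axis=ax)
                rows.append(flat.reshape(-1))
                cols.append(nbr.reshape(-1))
                vals.append(np.full(n, 1.0))
                diag -= 1.0
        L = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        L += sp.diags(diag.reshape(-1))
        L = L / self.dx**2
        # vessel nodes are fixed-value: their rows do not evolve
        L = sp.diags((~self.dirichlet_mask).astype(float)) @ L
        self._laplacian = L.tocsr()
        return self._laplacian


# -- domain builders ------------------------------------------------------

def _n_nodes(length: float, dx: float, what: str) -> int:
    n = int(round(length / dx)) + 1
    if n < 3:
        raise InvalidGeometryError(
            f"{what} of {length} μm is too short for dx = {dx} μm")
    return n


def make_domain_1d(geometry: Geometry1D, dx: float) -> DiscreteDomain:
    """Uniform 1D grid between the two vessels; end nodes Dirichlet."""
    if not dx > 0:
        raise InvalidGeometryError(f"dx must be > 0, got {dx!r}")
    n = _n_nodes(geometry.spacing, dx, "vessel spacing")
    mask = np.zeros(n, dtype=bool)
    mask[0] = mask[-1] = True
    supply_index = np.full(n, -1, dtype=np.int64)
    supply_index[0], supply_index[-1] = 0, 1
    return DiscreteDomain((n,), dx, mask, supply_index,
                          [geometry.left_supply, geometry.right_supply])


def make_domain_2d(geometry: Geometry2D, dx: float) -> DiscreteDomain:
    """Structured rectangle grid; border and internal-vessel nodes Dirichlet."""
    if not dx > 0:
        raise InvalidGeometryError(f"dx must be > 0, got {dx!r}")
    nx = _n_nodes(geometry.width, dx, "width")
    ny = _n_nodes(geometry.height, dx, "height")
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dx
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    mask = np.zeros((nx, ny), dtype=bool)
    supply_index = np.full((nx, ny), -1, dtype=np.int64)
    supplies: list[BoundarySupply] = []

    side_nodes = {
        "left": (slice(0, 1), slice(None)),
        "right": (slice(nx - 1, nx), slice(None)),
        "bottom": (slice(None), slice(0, 1)),
        "top": (slice(None), slice(ny - 1, ny)),
    }
    for side in ("left", "right", "bottom", "top"):
        if side not in geometry.border_supplies:
            continue
        supplies.append(geometry.border_supplies[side])
        sl = side_nodes[side]
        claim = np.zeros((nx, ny), dtype=bool)
        claim[sl] = True
        claim &= ~mask  # first side claiming a corner wins
        mask |= claim
        supply_index[claim] = len(supplies) - 1

    for vessel in geometry.vessels:
        supplies.append(vessel.supply)
        claim = vessel.distance(X, Y) <= vessel.radius
        conflict = claim & mask & (supply_index != len(supplies) - 1)
        for idx in zip(*np.nonzero(conflict)):
            other = supplies[supply_index[idx]]
            if other != vessel.supply:
                raise InvalidGeometryError(
                    "overlapping vessels with conflicting supplies at node "
                    f"({xs[idx[0]]}, {ys[idx[1]]}) μm")
        claim &= ~mask
        mask |= claim
        supply_index[claim] = len(supplies) - 1

    if not supplies:
        raise InvalidGeometryError("2D geometry defines no vessel at all")
    return DiscreteDomain((nx, ny), dx, mask, supply_index, supplies)


def make_domain_3d(geometry: Geometry3D, dx: float) -> DiscreteDomain:
    """Structured cuboid grid; nodes within ``vessel_radius`` of one of the
    five vertical vessel axes are Dirichlet, all outer faces Neumann."""
    if not dx > 0:
        raise InvalidGeometryError(f"dx must be > 0, got {dx!r}")
    nx = _n_nodes(geometry.cross_section_side, dx, "cross-section side")
    nz = _n_nodes(geometry.height, dx, "height")
    xs = np.arange(nx) * dx
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    section = np.zeros((nx, nx), dtype=bool)
    for ax, ay in geometry.vessel_axes:
        section |= (X - ax) ** 2 + (Y - ay) ** 2 <= geometry.vessel_radius ** 2
    if not section.any():
        raise InvalidGeometryError(
            f"dx = {dx} μm leaves no grid node inside the "
            f"{geometry.vessel_radius} μm vessel radius")
    mask = np.repeat(section[:, :, None], nz, axis=2)
    supply_index = np.where(mask, 0, -1).astype(np.int64)
    return DiscreteDomain((nx, nx, nz), dx, mask, supply_index,
                          [geometry.supply])


def default_probe_point(domain: DiscreteDomain) -> np.ndarray:
    """Default midpoint probe: the inter-vessel midpoint.

    1D: geometric center of the segment.  3D: midway between the center
    vessel and one edge vessel, at half height.  2D has no canonical
    probe; callers must pass an explicit point.
    """
    extent = (np.array(domain.shape) - 1) * domain.dx
    if domain.ndim == 1:
        return extent / 2
    if domain.ndim == 3:
        return np.array([extent[0] / 4, extent[1] / 4, extent[2] / 2])
    raise InvalidGeometryError(
        "no default probe point in 2D; pass an explicit coordinate")
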