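"""Discretized two-circle cell geometry on a regular Cartesian mesh.

The cell is two static nested discs: the nucleus (radius ``r1`` about ``p1``)
inside the outer cell boundary (radius ``r2`` about ``p2``).  Grid cells are
classified by their centre — a stair-step, O(h)-accurate representation of the
circular boundaries — and boundary *faces* (pairs of adjacent cells in
different compartments) carry all membrane transfer.  A third, smaller disc
(radius ``r3`` about ``p3``) marks the cytoplasmic region occupied by the
catalytic factor, by default tangent to the nuclear surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EXTERIOR",
    "CYTOPLASM",
    "NUCLEUS",
    "CellGeometry",
    "SimulationDomain",
    "GeometryError",
    "default_geometry",
    "build_domain",
    "initialize_catalytic_field",
    "place_region_at_distance",
]

EXTERIOR, CYTOPLASM, NUCLEUS = 0, 1, 2


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CellGeometry:
    """Continuous geometry: nucleus, outer cell boundary, catalytic region."""

    p1: tuple[float, float]
    r1: float
    p2: tuple[float, float]
    r2: float
    p3: tuple[float, float]
    r3: float
    Ec_init: float

    def __post_init__(self):
        if not (self.r1 > 0 and self.r2 > 0 and self.r3 >= 0):
            raise GeometryError("radii must satisfy r1 > 0, r2 > 0, r3 >= 0")
        d12 = float(np.hypot(self.p1[0] - self.p2[0], self.p1[1] - self.p2[1]))
        if not d12 + self.r1 < self.r2:
            raise GeometryError("nucleus disc must lie strictly inside the outer disc")
        object.__setattr__(self, "p1", (float(self.p1[0]), float(self.p1[1])))
        object.__setattr__(self, "p2", (float(self.p2[0]), float(self.p2[1])))
        object.__setattr__(self, "p3", (float(self.p3[0]), float(self.p3[1])))

    def replace(self, **kw) -> "CellGeometry":
        return dataclasses.replace(self, **kw)


def default_geometry() -> CellGeometry:
    from .io_cli import load_default_sections  # late import to avoid a cycle

    return load_default_sections()["geometry"]


@dataclass
class SimulationDomain:
    """A classified mesh plus the face lists that approximate Γn and Γc.

    ``mask`` holds one compartment label per cell (EXTERIOR / CYTOPLASM /
    NUCLEUS).  ``nuclear_faces`` is an ``(n, 2)`` array of flat cell indices
    ``(cytoplasm cell, nucleus cell)``; ``outer_faces`` analogously pairs
    cytoplasm with exterior cells.  Every face has length ``h`` (uniform,
    square cells) and each cell has area ``h**2``.
    """

    nx: int
    ny: int
    extent: tuple[tuple[float, float], tuple[float, float]]
    h: float
    xc: np.ndarray          # cell-centre x coordinates, shape (nx,)
    yc: np.ndarray          # cell-centre y coordinates, shape (ny,)
    mask: np.ndarray        # (ny, nx) int8 labels
    nuclear_faces: np.ndarray   # (n, 2) flat indices (cyt, nuc)
    outer_faces: np.ndarray     # (m, 2) flat indices (cyt, ext)
    geometry: CellGeometry

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    @property
    def face_length(self) -> float:
        return self.h

    def indices(self, label: int) -> np.ndarray:
        """Flat indices of all cells carrying ``label``."""
        return np.flatnonzero(self.mask.ravel() == label)

    def compartment_mean(self, field: np.ndarray, label: int) -> float:
        return float(field.ravel()[self.indices(label)].mean())

    def compartment_total(self, field: np.ndarray, label: int) -> float:
        """Domain integral of a concentration field over one compartment."""
        return float(field.ravel()[self.indices(label)].sum() * self.cell_area)


def _cell_centres(nx, ny, extent):
    (x0, x1), (y0, y1) = extent
    hx = (x1 - x0) / nx
    hy = (y1 - y0) / ny
    if abs(hx - hy) > 1e-12 * max(abs(hx), abs(hy)):
        raise GeometryError("grid cells must be square (extent/nx == extent/ny)")
    xc = x0 + (np.arange(nx) + 0.5) * hx
    yc = y0 + (np.arange(ny) + 0.5) * hy
    return xc, yc, hx


def build_domain(
    geom: CellGeometry,
    nx: int,
    ny: int,
    extent: tuple[tuple[float, float], tuple[float, float]] = ((-1.0, 1.0), (-1.0, 1.0)),
) -> SimulationDomain:
    """Classify every cell centre and enumerate the two boundary face lists.

    A centre x is a nucleus cell iff ``|x - p1| < r1``, a cytoplasm cell iff it
    is not nuclear and ``|x - p2| < r2``, and exterior otherwise (strict
    inequalities: a centre exactly on a circle falls outside that compartment).
    """
    if nx < 8 or ny < 8:
        raise GeometryError("grid must be at least 8x8")
    xc, yc, h = _cell_centres(nx, ny, extent)
    X, Y = np.meshgrid(xc, yc)
    in_nuc = (X - geom.p1[0]) ** 2 + (Y - geom.p1[1]) ** 2 < geom.r1 ** 2
    in_cell = (X - geom.p2[0]) ** 2 + (Y - geom.p2[1]) ** 2 < geom.r2 ** 2
    mask = np.full((ny, nx), EXTERIOR, dtype=np.int8)
    mask[in_cell & ~in_nuc] = CYTOPLASM
    mask[in_nuc] = NUCLEUS
    if not (mask == NUCLEUS).any() or not (mask == CYTOPLASM).any():
        raise GeometryError("grid too coarse: a compartment contains no cell")

    nuclear_faces = _faces_between(mask, CYTOPLASM, NUCLEUS)
    outer_faces = _faces_between(mask, CYTOPLASM, EXTERIOR)
    return SimulationDomain(
        nx=nx, ny=ny, extent=extent, h=h, xc=xc, yc=yc, mask=mask,
        nuclear_faces=nuclear_faces, outer_faces=outer_faces, geometry=geom,
    )


def _faces_between(mask: np.ndarray, label_a: int, label_b: int) -> np.ndarray:
    """All (cell with label_a, adjacent cell with label_b) index pairs."""
    ny, nx = mask.shape
    flat = np.arange(mask.size).reshape(ny, nx)
    pairs = []
    for (sa, sb) in (((slice(None), slice(0, -1)), (slice(None), slice(1, None))),
                     ((slice(0, -1), slice(None)), (slice(1, None), slice(None)))):
        ma, mb = mask[sa], mask[sb]
        fa, fb = flat[sa], flat[sb]
        sel = (ma == label_a) & (mb == label_b)
        pairs.append(np.stack([fa[sel], fb[sel]], axis=1))
        sel = (ma == label_b) & (mb == label_a)
        pairs.append(np.stack([fb[sel], fa[sel]], axis=1))
    return np.concatenate(pairs, axis=0)


def _circle_overlap_area(r_a: float, r_b: float, d: float) -> float:
    """Area of the intersection of two disks with radii r_a, r_b at centre
    distance d (standard lens formula)."""
    if d >= r_a + r_b:
        return 0.0
    if d <= abs(r_a - r_b):
        r = min(r_a, r_b)
        return float(np.pi * r * r)
    a2, b2, d2 = r_a * r_a, r_b * r_b, d * d
    alpha = np.arccos((d2 + a2 - b2) / (2 * d * r_a))
    beta = np.arccos((d2 + b2 - a2) / (2 * d * r_b))
    return float(
        a2 * alpha + b2 * beta
        - 0.5 * np.sqrt((-d + r_a + r_b) * (d + r_a - r_b)
                        * (d - r_a + r_b) * (d + r_a + r_b))
    )


def catalytic_region_area(geom: CellGeometry) -> float:
    """Continuum area of the catalytic region: the ball B(p3, r3) minus its
    overlap with the nucleus (the region lives in the cytoplasm only)."""
    d = float(np.hypot(geom.p3[0] - geom.p1[0], geom.p3[1] - geom.p1[1]))
    return float(np.pi * geom.r3 ** 2) - _circle_overlap_area(geom.r1, geom.r3, d)


_SUBSAMPLES = 32  # per axis, for fractional cell coverage of the region disk


def initialize_catalytic_field(domain: SimulationDomain, geom: CellGeometry) -> np.ndarray:
    """Catalytic-factor initial condition: the indicator of the ball
    B(p3, r3) restricted to cytoplasm cells, discretized by fractional cell
    coverage (supersampling) and rescaled so the total catalytic mass equals
    its continuum value ``Ec_init * catalytic_region_area(geom)`` exactly.

    The rescaling makes the conserved catalytic mass — and with it the
    experiment readouts — independent of grid resolution, instead of jumping
    with the stair-step count of covered cells."""
    X, Y = np.meshgrid(domain.xc, domain.yc)
    dist2 = (X - geom.p3[0]) ** 2 + (Y - geom.p3[1]) ** 2
    half_diag = domain.h * np.sqrt(0.5)
    candidate = (dist2 < (geom.r3 + half_diag) ** 2) & (domain.mask == CYTOPLASM)
    field = np.zeros((domain.ny, domain.nx))
    if geom.Ec_init == 0.0:
        return field
    jj, ii = np.nonzero(candidate)
    if jj.size:
        # fraction of each candidate cell covered by the disk
        off = (np.arange(_SUBSAMPLES) + 0.5) / _SUBSAMPLES - 0.5
        ox, oy = np.meshgrid(off * domain.h, off * domain.h)
        sx = domain.xc[ii][:, None] + ox.ravel()[None, :]
        sy = domain.yc[jj][:, None] + oy.ravel()[None, :]
        inside = ((sx - geom.p3[0]) ** 2 + (sy - geom.p3[1]) ** 2) < geom.r3 ** 2
        field[jj, ii] = inside.mean(axis=1)
    target_mass = geom.Ec_init * catalytic_region_area(geom)
    discrete_mass = field.sum() * domain.cell_area
    if discrete_mass == 0.0:
        raise GeometryError(
            "grid too coarse: the catalytic region covers no cytoplasm cell")
    field *= target_mass / discrete_mass
    return field


def place_region_at_distance(geom: CellGeometry, d: float) -> CellGeometry:
    """Relocate the catalytic region along the ray from the nucleus centre
    through its current position so its nearest point sits distance ``d``
    from the nuclear surface (``d = 0``: tangent, juxta-nuclear placement)."""
    if d < 0:
        raise GeometryError("distance d must be >= 0")
    dx = geom.p3[0] - geom.p1[0]
    dy = geom.p3[1] - geom.p1[1]
    norm = float(np.hypot(dx, dy))
    if norm == 0.0:
        raise GeometryError("p3 coincides with p1; relocation direction undefined")
    u = (dx / norm, dy / norm)
    rho = geom.r1 + geom.r3 + d
    p3 = (geom.p1[0] + rho * u[0], geom.p1[1] + rho * u[1])
    d2 = float(np.hypot(p3[0] - geom.p2[0], p3[1] - geom.p2[1]))
    if d2 + geom.r3 > geom.r2:
        raise GeometryError(
            f"relocated region (centre distance {d2:.4g}, radius {geom.r3}) "
            f"protrudes outside the cell boundary r2 = {geom.r2}"
        )
    return geom.replace(p3=p3)


def max_region_distance(geom: CellGeometry) -> float:
    """Largest admissible ``d`` for :func:`place_region_at_distance` along the
    current ray (concentric geometries: ``r2 - r1 - 2*r3``)."""
    dx = geom.p3[0] - geom.p1[0]
    dy = geom.p3[1] - geom.p1[1]
    norm = float(np.hypot(dx, dy))
    if norm == 0.0:
        raise GeometryError("p3 coincides with p1")
    u = (dx / norm, dy / norm)
    lo, hi = 0.0, 10.0 * geom.r2
    # bisect on admissibility of the centre position along the ray
    def ok(d):
        rho = geom.r1 + geom.r3 + d
        p3 = (geom.p1[0] + rho * u[0], geom.p1[1] + rho * u[1])
        d2 = float(np.hypot(p3[0] - geom.p2[0], p3[1] - geom.p2[1]))
        return d2 + geom.r3 <= geom.r2

    if not ok(0.0):
        raise GeometryError("no admissible placement on this ray")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo
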