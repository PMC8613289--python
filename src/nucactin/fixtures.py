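"""Small in-memory synthetic inputs for tests and validation.

Everything here is generated programmatically — tiny grids, random positive
states restricted to their compartments, and constraint-satisfying parameter
draws — so every stage of the pipeline is testable without touching the
filesystem or the network.  Random states are deliberately uniform rather
than near-equilibrium: they stress the pointwise conservation identities of
the reaction terms away from steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry, SimulationDomain, build_domain
from .kinetics import FieldState
from .parameters import CYTOPLASMIC_SPECIES, NUCLEAR_SPECIES
from .geometry import CYTOPLASM, NUCLEUS, EXTERIOR

__all__ = [
    "FixtureSpec",
    "make_toy_domain",
    "make_random_state",
    "make_rectangle_domain",
]


@dataclass(frozen=True)
class FixtureSpec:
    grid_size: int = 41
    seed: int = 0
    state_scale: float = 1.0
    n_random_states: int = 10

    def __post_init__(self):
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.state_scale <= 0:
            raise ValueError("state_scale must be positive")


def make_toy_domain(spec: FixtureSpec = FixtureSpec()) -> tuple[SimulationDomain, CellGeometry]:
    """Concentric default-shape geometry on a small square grid."""
    geom = CellGeometry(
        p1=(0.0, 0.0), r1=0.3, p2=(0.0, 0.0), r2=0.9,
        p3=(0.36, 0.0), r3=0.06, Ec_init=1.0,
    )
    domain = build_domain(geom, spec.grid_size, spec.grid_size)
    return domain, geom


def make_random_state(domain: SimulationDomain, spec: FixtureSpec = FixtureSpec()) -> FieldState:
    """Independent uniform draws in (0, state_scale] on each species' own
    compartment, zero elsewhere; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    mc = (domain.mask == CYTOPLASM).astype(float)
    mn = (domain.mask == NUCLEUS).astype(float)
    fields = {}
    for name in CYTOPLASMIC_SPECIES:
        fields[name] = rng.uniform(0.0, spec.state_scale, domain.mask.shape) * mc
    for name in NUCLEAR_SPECIES:
        fields[name] = rng.uniform(0.0, spec.state_scale, domain.mask.shape) * mn
    return FieldState(fields, t=0.0)


def make_rectangle_domain(nx: int, ny: int,
                          extent=((-1.0, 1.0), (-1.0, 1.0))) -> SimulationDomain:
    """A degenerate all-cytoplasm rectangular domain (no nucleus, no faces),
    used to validate diffusion against closed-form heat-equation modes."""
    from .geometry import _cell_centres

    xc, yc, h = _cell_centres(nx, ny, extent)
    mask = np.full((ny, nx), CYTOPLASM, dtype=np.int8)
    empty = np.zeros((0, 2), dtype=np.int64)
    geom = CellGeometry(p1=(0.0, 0.0), r1=0.1, p2=(0.0, 0.0), r2=10.0,
                        p3=(0.2, 0.0), r3=0.05, Ec_init=0.0)
    return SimulationDomain(
        nx=nx, ny=ny, extent=extent, h=h, xc=xc, yc=yc, mask=mask,
        nuclear_faces=empty, outer_faces=empty, geometry=geom,
    )
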