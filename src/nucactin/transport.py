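"""Membrane transfer across the nuclear envelope and the outer no-flux wall.

Transfer is a Robin-type exchange evaluated on the stair-step boundary faces:
for each face the flux density (amount per face length per time, positive into
the nucleus) is

* profilin and cofilin (free pools): ``beta_out * c_cyt - beta_in * c_nuc``
  (bidirectional),
* cofilin–actin Xi: ``beta_Xi_c * c_cyt`` (one-way import),
* profilin–actin Ups: ``-beta_Ups_n * c_nuc`` (one-way export),
* G-actin, F-actin, phospho-cofilin and the catalytic factor: no flux.

The amount ``flux * face_length * dt`` leaves the donor cell and enters the
acceptor cell (divided by the cell area), so every transfer conserves each
species' domain total exactly.  The outer cell boundary exports nothing.
Transfer is explicit in time; if a step would overdraw a donor cell, that
cell's outgoing transfers are scaled to empty it exactly and the event is
counted (the counter stays zero under the shipped scenarios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SimulationDomain
from .kinetics import FieldState
from .parameters import KineticParameters

__all__ = [
    "TransferLaw",
    "TransferSpec",
    "default_transfer_spec",
    "nuclear_face_flux",
    "apply_boundary_fluxes",
]


@dataclass(frozen=True)
class TransferLaw:
    """Flux law for one species pair across the nuclear envelope."""

    kind: str                 # bidirectional | into_nucleus | into_cytoplasm | no_flux
    beta_out: float = 0.0     # cytoplasm -> nucleus coefficient
    beta_in: float = 0.0      # nucleus -> cytoplasm coefficient


@dataclass(frozen=True)
class TransferSpec:
    """The full transfer table keyed by base species name.

    ``pairs`` maps each base name to its (cytoplasmic, nuclear) field names;
    species absent from one side (F, Theta, E) pair with ``None``.
    """

    laws: dict[str, TransferLaw]
    pairs: dict[str, tuple[str | None, str | None]]


_PAIRS = {
    "G": ("G_c", "G_n"),
    "F": ("F_c", None),
    "C": ("C_c", "C_n"),
    "Xi": ("Xi_c", "Xi_n"),
    "P": ("P_c", "P_n"),
    "Ups": ("Ups_c", "Ups_n"),
    "Theta": ("Theta_c", None),
    "E": ("E_c", None),
}


def default_transfer_spec(params: KineticParameters) -> TransferSpec:
    laws = {
        "P": TransferLaw("bidirectional", beta_out=params.beta_Pc, beta_in=params.beta_Pn),
        "C": TransferLaw("bidirectional", beta_out=params.beta_Cc, beta_in=params.beta_Cn),
        "Xi": TransferLaw("into_nucleus", beta_out=params.beta_Xi_c),
        "Ups": TransferLaw("into_cytoplasm", beta_in=params.beta_Ups_n),
        "G": TransferLaw("no_flux"),
        "F": TransferLaw("no_flux"),
        "Theta": TransferLaw("no_flux"),
        "E": TransferLaw("no_flux"),
    }
    return TransferSpec(laws=laws, pairs=dict(_PAIRS))


def nuclear_face_flux(species: str, c_cyt, c_nuc, spec: TransferSpec):
    """Signed flux density across one nuclear face (positive into nucleus)."""
    if species not in spec.laws:
        raise KeyError(f"unknown species {species!r} in transfer table")
    law = spec.laws[species]
    c_cyt = np.asarray(c_cyt, dtype=float)
    c_nuc = np.asarray(c_nuc, dtype=float)
    if np.any(c_cyt < 0) or np.any(c_nuc < 0):
        raise ValueError("negative concentration at nuclear face")
    if law.kind == "bidirectional":
        return law.beta_out * c_cyt - law.beta_in * c_nuc
    if law.kind == "into_nucleus":
        return law.beta_out * c_cyt
    if law.kind == "into_cytoplasm":
        return -law.beta_in * c_nuc
    return np.zeros_like(c_cyt)


def apply_boundary_fluxes(
    state: FieldState,
    domain: SimulationDomain,
    spec: TransferSpec,
    dt: float,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-cell concentration increments from one explicit transfer step.

    Returns ``(increments, n_limited)`` where increments maps field names to
    full-grid arrays (zero off the boundary cells) and ``n_limited`` counts
    faces whose transfer was scaled down to protect donor positivity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = domain.face_length
    area = domain.cell_area
    cyt_idx = domain.nuclear_faces[:, 0]
    nuc_idx = domain.nuclear_faces[:, 1]
    increments: dict[str, np.ndarray] = {}
    n_limited = 0

    for base, law in spec.laws.items():
        name_c, name_n = spec.pairs[base]
        if law.kind == "no_flux" or name_n is None:
            continue
        fc = state[name_c].ravel()
        fn = state[name_n].ravel()
        flux = nuclear_face_flux(base, fc[cyt_idx], fn[nuc_idx], spec)
        amount = flux * h * dt  # conc * area, positive = into nucleus

        # donor-positivity limiter, aggregated per donor cell
        scale = np.ones_like(amount)
        for donor_idx, donor_conc, outgoing in (
            (cyt_idx, fc, np.maximum(amount, 0.0)),
            (nuc_idx, fn, np.maximum(-amount, 0.0)),
        ):
            withdraw = np.zeros(fc.shape[0])
            np.add.at(withdraw, donor_idx, outgoing)
            avail = donor_conc * area
            over = withdraw[donor_idx] > avail[donor_idx]
            if np.any(over & (outgoing > 0)):
                with np.errstate(divide="ignore", invalid="ignore"):
                    s = np.where(
                        withdraw[donor_idx] > 0,
                        np.minimum(1.0, avail[donor_idx] / withdraw[donor_idx]),
                        1.0,
                    )
                limited = (s < 1.0) & (outgoing > 0)
                scale = np.where(limited, np.minimum(scale, s), scale)
                n_limited += int(limited.sum())
        amount = amount * scale

        dc = np.zeros(fc.shape[0])
        dn = np.zeros(fc.shape[0])
        np.add.at(dc, cyt_idx, -amount / area)
        np.add.at(dn, nuc_idx, amount / area)
        increments[name_c] = dc.reshape(domain.ny, domain.nx)
        increments[name_n] = dn.reshape(domain.ny, domain.nx)

    return increments, n_limited
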