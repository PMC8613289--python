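"""Pointwise mass-action reaction terms (everything except diffusion).

Cytoplasm: G-actin polymerizes to F-actin at rate ``gamma_Gc * (1 + mu1*E_c)``
and F-actin depolymerizes at ``gamma_Fc``; cofilin binds G-actin (forming the
import carrier Xi) and profilin binds G-actin (forming the export carrier
Ups); free cofilin is phosphorylated at ``alpha_Theta_c * (1 + mu2*E_c)`` to
Theta and dephosphorylated back at ``gamma_Theta_c``.  The nucleus carries
only the carrier association/dissociation cycles — no polymerization and no
phosphorylation.

The terms cancel pairwise within each conserved group, so the reactions
conserve total actin (G + F + Xi + Ups), total cofilin (C + Xi + Theta) and
total profilin (P + Ups) at every point; the test suite leans on exactly
these identities.

All functions accept scalars or numpy arrays (vectorized over grid cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import CYTOPLASMIC_SPECIES, NUCLEAR_SPECIES, KineticParameters

__all__ = [
    "FieldState",
    "NegativeConcentrationError",
    "cytoplasm_reaction_rates",
    "nucleus_reaction_rates",
]


class NegativeConcentrationError(ValueError):
    """Signals a positivity breach handed to the reaction terms."""


@dataclass
class FieldState:
    """The 13 concentration fields at one instant.

    Each value is a full-grid array, zero outside its own compartment
    (8 cytoplasmic species, 5 nuclear species); ``t`` is model time.
    """

    fields: dict[str, np.ndarray]
    t: float = 0.0

    def __getitem__(self, species: str) -> np.ndarray:
        return self.fields[species]

    def copy(self) -> "FieldState":
        return FieldState({k: v.copy() for k, v in self.fields.items()}, self.t)


def _check_nonnegative(local: Mapping, names) -> None:
    for name in names:
        v = np.asarray(local[name])
        if np.any(v < 0):
            raise NegativeConcentrationError(f"negative concentration in {name}")


def cytoplasm_reaction_rates(local: Mapping, params: KineticParameters) -> dict:
    """Non-diffusive right-hand sides for the eight cytoplasmic species."""
    _check_nonnegative(local, CYTOPLASMIC_SPECIES)
    p = params
    G, F, C = local["G_c"], local["F_c"], local["C_c"]
    Xi, P, Ups = local["Xi_c"], local["P_c"], local["Ups_c"]
    Theta, E = local["Theta_c"], local["E_c"]

    poly = p.gamma_Gc * (1.0 + p.mu1 * E) * G
    depoly = p.gamma_Fc * F
    assoc_xi = p.alpha_Xi_c * G * C
    dissoc_xi = p.gamma_Xi_c * Xi
    assoc_ups = p.alpha_Ups_c * G * P
    dissoc_ups = p.gamma_Ups_c * Ups
    phos = p.alpha_Theta_c * (1.0 + p.mu2 * E) * C
    dephos = p.gamma_Theta_c * Theta
    if p.ec_decay == "first_order":
        e_sink = -p.gamma_Ec * E
    else:  # zeroth order, as printed; inert at the default gamma_Ec = 0
        e_sink = -p.gamma_Ec * np.ones_like(np.asarray(E, dtype=float))

    return {
        "G_c": depoly - poly + dissoc_xi - assoc_xi + dissoc_ups - assoc_ups,
        "F_c": poly - depoly,
        "C_c": dissoc_xi - assoc_xi + dephos - phos,
        "Xi_c": assoc_xi - dissoc_xi,
        "P_c": dissoc_ups - assoc_ups,
        "Ups_c": assoc_ups - dissoc_ups,
        "Theta_c": phos - dephos,
        "E_c": e_sink,
    }


def nucleus_reaction_rates(local: Mapping, params: KineticParameters) -> dict:
    """Non-diffusive right-hand sides for the five nuclear species."""
    _check_nonnegative(local, NUCLEAR_SPECIES)
    p = params
    G, C, Xi = local["G_n"], local["C_n"], local["Xi_n"]
    P, Ups = local["P_n"], local["Ups_n"]

    assoc_xi = p.alpha_Xi_n * G * C
    dissoc_xi = p.gamma_Xi_n * Xi
    assoc_ups = p.alpha_Ups_n * G * P
    dissoc_ups = p.gamma_Ups_n * Ups

    return {
        "G_n": dissoc_xi - assoc_xi + dissoc_ups - assoc_ups,
        "C_n": dissoc_xi - assoc_xi,
        "Xi_n": assoc_xi - dissoc_xi,
        "P_n": dissoc_ups - assoc_ups,
        "Ups_n": assoc_ups - dissoc_ups,
    }
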