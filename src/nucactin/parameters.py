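"""Kinetic, transport and diffusion parameters of the two-compartment actin model.

All quantities are in the model's arbitrary units (concentration, length,
"time units"); no unit conversions are performed anywhere in the package.
The default values ship in ``data/default_config.yaml`` and are loaded from
there — operations never hard-code them.

The model imposes a set of inequality constraints on the rate constants that
encode the biology of the two shuttles:

* cofilin–actin (the import carrier) associates faster in the cytoplasm and
  dissociates faster in the nucleus;
* profilin–actin (the export carrier) is the mirror image;
* cofilin and profilin transfer coefficients are symmetric across the nuclear
  envelope so their free pools equilibrate to similar levels on both sides;
* the import coefficient exceeds the export coefficient, which (together with
  fast carrier release) yields a higher nuclear than cytoplasmic G-actin level;
* F-actin and the catalytic factor do not diffuse, and the catalytic factor
  does not decay (its total amount is conserved).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "CYTOPLASMIC_SPECIES",
    "NUCLEAR_SPECIES",
    "SHUTTLING_PAIRS",
    "KineticParameters",
    "ConstraintCheck",
    "ParameterError",
    "default_parameters",
    "validate_parameters",
    "sample_constrained_parameters",
    "default_sampling_ranges",
]

CYTOPLASMIC_SPECIES = ("G_c", "F_c", "C_c", "Xi_c", "P_c", "Ups_c", "Theta_c", "E_c")
NUCLEAR_SPECIES = ("G_n", "C_n", "Xi_n", "P_n", "Ups_n")
SPECIES = CYTOPLASMIC_SPECIES + NUCLEAR_SPECIES

#: species present on both sides of the nuclear envelope (cyt name, nuc name)
SHUTTLING_PAIRS = (
    ("G_c", "G_n"),
    ("C_c", "C_n"),
    ("Xi_c", "Xi_n"),
    ("P_c", "P_n"),
    ("Ups_c", "Ups_n"),
)

_SCALAR_FIELDS = (
    "gamma_Gc", "gamma_Fc",
    "alpha_Xi_c", "gamma_Xi_c", "alpha_Xi_n", "gamma_Xi_n",
    "alpha_Ups_c", "gamma_Ups_c", "alpha_Ups_n", "gamma_Ups_n",
    "alpha_Theta_c", "gamma_Theta_c",
    "mu1", "mu2", "gamma_Ec",
    "beta_Pc", "beta_Pn", "beta_Cc", "beta_Cn", "beta_Xi_c", "beta_Ups_n",
)


class ParameterError(ValueError):
    """A parameter field is missing, non-finite, or structurally invalid."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"parameter '{field_name}': {message}")


@dataclass(frozen=True)
class KineticParameters:
    """Every rate constant, transfer coefficient and diffusion coefficient.

    Rates carry units of 1/time (first order) or 1/(conc·time) (association),
    transfer coefficients length/time, diffusion coefficients length²/time.
    ``ec_decay`` selects whether the catalytic-factor sink term is zeroth
    order (as printed in the governing equations) or first order; the choice
    is inert at the default ``gamma_Ec = 0``.
    """

    gamma_Gc: float
    gamma_Fc: float
    alpha_Xi_c: float
    gamma_Xi_c: float
    alpha_Xi_n: float
    gamma_Xi_n: float
    alpha_Ups_c: float
    gamma_Ups_c: float
    alpha_Ups_n: float
    gamma_Ups_n: float
    alpha_Theta_c: float
    gamma_Theta_c: float
    mu1: float
    mu2: float
    gamma_Ec: float
    D: Mapping[str, float]
    beta_Pc: float
    beta_Pn: float
    beta_Cc: float
    beta_Cn: float
    beta_Xi_c: float
    beta_Ups_n: float
    ec_decay: str = "zeroth_order"

    def __post_init__(self):
        for name in _SCALAR_FIELDS:
            v = getattr(self, name)
            if v is None:
                raise ParameterError(name, "missing")
            if not math.isfinite(float(v)):
                raise ParameterError(name, f"non-finite value {v!r}")
        if not isinstance(self.D, Mapping):
            raise ParameterError("D", "must be a mapping species -> diffusion coefficient")
        missing = [s for s in SPECIES if s not in self.D]
        if missing:
            raise ParameterError("D", f"missing diffusion coefficients for {missing}")
        for s, v in self.D.items():
            if s not in SPECIES:
                raise ParameterError("D", f"unknown species {s!r}")
            if v is None or not math.isfinite(float(v)):
                raise ParameterError(f"D[{s}]", f"non-finite value {v!r}")
        if self.ec_decay not in ("zeroth_order", "first_order"):
            raise ParameterError("ec_decay", "must be 'zeroth_order' or 'first_order'")
        object.__setattr__(self, "D", dict(self.D))

    def replace(self, **kwargs) -> "KineticParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in _SCALAR_FIELDS}
        d["D"] = {s: float(v) for s, v in self.D.items()}
        d["ec_decay"] = self.ec_decay
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown parameter key")
        return cls(**d)


@dataclass(frozen=True)
class ConstraintCheck:
    """One named pass/fail entry of a validation report."""

    name: str
    passed: bool
    detail: str


def _load_default_config() -> dict:
    text = resources.files("nucactin").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters() -> KineticParameters:
    """The shipped default parameter set, read from the packaged config file."""
    return KineticParameters.from_dict(_load_default_config()["parameters"])


def validate_parameters(params: KineticParameters, margin: float = 1e-9) -> list[ConstraintCheck]:
    """Check every declared model constraint; returns one entry per constraint.

    Strict inequalities are enforced with a minimum margin (default 1e-9) so
    that degenerate equality sets fail.  The function is pure: it never
    mutates its input and identical inputs yield identical reports.
    """
    p = params
    checks: list[ConstraintCheck] = []

    def add(name: str, passed: bool, detail: str) -> None:
        checks.append(ConstraintCheck(name, bool(passed), detail))

    neg = [n for n in _SCALAR_FIELDS if getattr(p, n) < 0]
    neg += [f"D[{s}]" for s, v in p.D.items() if v < 0]
    add("non-negative rates", not neg,
        "all rates and coefficients >= 0" if not neg else f"negative: {neg}")

    add("F-actin non-diffusing", p.D["F_c"] == 0.0, f"D[F_c] = {p.D['F_c']}")
    add("catalytic factor non-diffusing", p.D["E_c"] == 0.0, f"D[E_c] = {p.D['E_c']}")
    add("catalytic factor conserved", p.gamma_Ec == 0.0, f"gamma_Ec = {p.gamma_Ec}")

    add("cytoplasmic cofilin-actin association faster",
        p.alpha_Xi_c > p.alpha_Xi_n + margin,
        f"alpha_Xi_c = {p.alpha_Xi_c} vs alpha_Xi_n = {p.alpha_Xi_n}")
    add("nuclear cofilin-actin dissociation faster",
        p.gamma_Xi_c + margin < p.gamma_Xi_n,
        f"gamma_Xi_c = {p.gamma_Xi_c} vs gamma_Xi_n = {p.gamma_Xi_n}")
    add("nuclear profilin-actin association faster",
        p.alpha_Ups_n > p.alpha_Ups_c + margin,
        f"alpha_Ups_n = {p.alpha_Ups_n} vs alpha_Ups_c = {p.alpha_Ups_c}")
    add("cytoplasmic profilin-actin dissociation faster",
        p.gamma_Ups_n + margin < p.gamma_Ups_c,
        f"gamma_Ups_n = {p.gamma_Ups_n} vs gamma_Ups_c = {p.gamma_Ups_c}")

    add("cofilin transfer symmetry", p.beta_Cc == p.beta_Cn,
        f"beta_Cc = {p.beta_Cc} vs beta_Cn = {p.beta_Cn}")
    add("profilin transfer symmetry", p.beta_Pc == p.beta_Pn,
        f"beta_Pc = {p.beta_Pc} vs beta_Pn = {p.beta_Pn}")
    add("import exceeds export", p.beta_Xi_c > p.beta_Ups_n + margin,
        f"beta_Xi_c = {p.beta_Xi_c} vs beta_Ups_n = {p.beta_Ups_n}")

    bad = [f"{cn}<= {cc}" for cc, cn in SHUTTLING_PAIRS
           if not (p.D[cn] > p.D[cc] + margin)]
    add("nuclear diffusion faster", not bad,
        "D nuclear > D cytoplasmic for all shuttling species"
        if not bad else f"violations: {bad}")

    return checks


def report_passed(checks: list[ConstraintCheck]) -> bool:
    return all(c.passed for c in checks)


# ---------------------------------------------------------------------------
# constrained sampling


def default_sampling_ranges() -> dict[str, tuple[float, float]]:
    """Default per-parameter sampling intervals around the shipped defaults.

    Paired inequality parameters get disjoint intervals so constraints hold
    by construction; wider user-supplied ranges fall back to rejection.
    Equality-constrained pairs (cofilin and profilin transfer symmetry) are
    sampled once via the ``beta_C`` / ``beta_P`` keys; diffusion is sampled as
    one cytoplasmic and one faster nuclear coefficient (``D_cyt`` / ``D_nuc``).
    """
    return {
        "gamma_Gc": (0.06, 0.15),
        "gamma_Fc": (0.06, 0.15),
        "alpha_Xi_c": (0.7, 1.5),
        "gamma_Xi_c": (0.05, 0.2),
        "alpha_Xi_n": (0.05, 0.2),
        "gamma_Xi_n": (0.7, 1.5),
        "alpha_Ups_c": (0.05, 0.2),
        "gamma_Ups_c": (0.7, 1.5),
        "alpha_Ups_n": (0.7, 1.5),
        "gamma_Ups_n": (0.05, 0.2),
        "alpha_Theta_c": (0.07, 0.15),
        "gamma_Theta_c": (0.07, 0.15),
        "mu1": (0.2, 1.0),
        "mu2": (20.0, 100.0),
        "beta_P": (0.2, 0.4),
        "beta_C": (0.2, 0.4),
        "beta_Xi_c": (0.3, 0.45),
        "beta_Ups_n": (0.1, 0.2),
        "D_cyt": (0.005, 0.02),
        "D_nuc": (0.05, 0.2),
    }


MAX_REJECTIONS = 1000


def sample_constrained_parameters(
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> KineticParameters:
    """Draw one constraint-satisfying parameter set (deterministic per seed).

    Draws each free parameter uniformly from its interval and rejects the
    whole draw if any strict inequality fails, up to ``MAX_REJECTIONS``
    attempts.  The default ranges are disjoint across every constrained pair,
    so the first draw always validates.
    """
    rng = np.random.default_rng(seed)
    r = dict(default_sampling_ranges())
    if ranges:
        unknown = set(ranges) - set(r)
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown sampling-range key")
        r.update(ranges)

    for _ in range(MAX_REJECTIONS):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in r.items()}
        D = {s: draw["D_cyt"] for s in ("G_c", "C_c", "Xi_c", "P_c", "Ups_c", "Theta_c")}
        D.update({s: draw["D_nuc"] for s in ("G_n", "C_n", "Xi_n", "P_n", "Ups_n")})
        D["F_c"] = 0.0
        D["E_c"] = 0.0
        params = KineticParameters(
            gamma_Gc=draw["gamma_Gc"], gamma_Fc=draw["gamma_Fc"],
            alpha_Xi_c=draw["alpha_Xi_c"], gamma_Xi_c=draw["gamma_Xi_c"],
            alpha_Xi_n=draw["alpha_Xi_n"], gamma_Xi_n=draw["gamma_Xi_n"],
            alpha_Ups_c=draw["alpha_Ups_c"], gamma_Ups_c=draw["gamma_Ups_c"],
            alpha_Ups_n=draw["alpha_Ups_n"], gamma_Ups_n=draw["gamma_Ups_n"],
            alpha_Theta_c=draw["alpha_Theta_c"], gamma_Theta_c=draw["gamma_Theta_c"],
            mu1=draw["mu1"], mu2=draw["mu2"], gamma_Ec=0.0,
            D=D,
            beta_Pc=draw["beta_P"], beta_Pn=draw["beta_P"],
            beta_Cc=draw["beta_C"], beta_Cn=draw["beta_C"],
            beta_Xi_c=draw["beta_Xi_c"], beta_Ups_n=draw["beta_Ups_n"],
        )
        if report_passed(validate_parameters(params)):
            return params
    raise ParameterError(
        "ranges", f"no constraint-satisfying draw within {MAX_REJECTIONS} attempts"
    )
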