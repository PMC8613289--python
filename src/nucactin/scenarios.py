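"""In-silico experiments: equilibration, catalytic knockouts, region relocation.

The experimental protocol mirrors the model's study design:

1. **Equilibrate** the no-catalysis system (catalytic factor absent) from
   documented uniform seed concentrations until every compartment mean is
   stationary, then use the spatially constant compartment averages as initial
   conditions (the equilibrium *profiles* are not flat, so subsequent runs do
   not start exactly at steady state).
2. **Scenario run**: install the localized catalytic field at t = 0 with the
   catalysed-polymerization (mu1) and/or catalysed-cofilin-phosphorylation
   (mu2) pathways switched on, integrate to t_end, and record compartment-level
   G-actin, F-actin and phospho-cofilin series plus snapshots.
3. **Knockout matrix**: the four on/off combinations of the two pathways,
   compared by the nuclear G-actin depletion fraction
   ``delta = 1 - mean_Gn(t_end) / mean_Gn(0)``.
4. **Relocation**: move the catalytic region away from the nuclear surface and
   measure how the depletion (the G-actin mobilized out of the nucleus) falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    CYTOPLASM,
    NUCLEUS,
    CellGeometry,
    SimulationDomain,
    build_domain,
    initialize_catalytic_field,
    max_region_distance,
    place_region_at_distance,
)
from .kinetics import FieldState
from .parameters import (
    CYTOPLASMIC_SPECIES,
    NUCLEAR_SPECIES,
    KineticParameters,
    sample_constrained_parameters,
)
from .solver import DiffusionWorkspace, SolverConfig, Trajectory, run, summarize_state
from .transport import default_transfer_spec

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "EquilibrationResult",
    "EquilibrationError",
    "DEFAULT_SEED_CONCENTRATIONS",
    "KNOCKOUT_VARIANTS",
    "equilibrate",
    "run_scenario",
    "knockout_comparison",
    "relocation_comparison",
    "knockout_robustness",
]

#: uniform per-compartment seed concentrations used to start equilibration;
#: free pools start at unit concentration, complexes and phospho-cofilin empty.
DEFAULT_SEED_CONCENTRATIONS = {
    "G_c": 1.0, "F_c": 1.0, "C_c": 1.0, "Xi_c": 0.0, "P_c": 1.0,
    "Ups_c": 0.0, "Theta_c": 0.0, "E_c": 0.0,
    "G_n": 1.0, "C_n": 1.0, "Xi_n": 0.0, "P_n": 1.0, "Ups_n": 0.0,
}


class EquilibrationError(RuntimeError):
    def __init__(self, residual: float, n_steps: int):
        self.residual = residual
        self.n_steps = n_steps
        super().__init__(
            f"equilibration did not converge within {n_steps} steps "
            f"(residual {residual:.3e} per time unit)"
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One in-silico experiment: pathway flags, region placement, schedule."""

    params: KineticParameters
    geometry: CellGeometry
    name: str = "full_model"
    mu1_active: bool = True
    mu2_active: bool = True
    region_distance: float = 0.0
    t_end: float = 400.0
    snapshot_times: tuple[float, ...] = (0.0, 50.0, 400.0)
    nx: int = 201
    ny: int = 201
    extent: tuple = ((-1.0, 1.0), (-1.0, 1.0))
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0
    eq_tolerance: float = 1e-6
    eq_max_steps: int = 200_000
    eq_check_every: int = 100

    def __post_init__(self):
        if self.snapshot_times and self.t_end < max(self.snapshot_times):
            raise ValueError("t_end must cover every snapshot time")

    def replace(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)


@dataclass
class EquilibrationResult:
    state: FieldState              # spatially constant at the compartment averages
    averages: dict[str, float]
    n_steps: int
    residual: float                # max relative change per time unit at exit
    converged: bool


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    domain: SimulationDomain
    trajectory: Trajectory
    equilibrium: EquilibrationResult

    @property
    def summary(self) -> pd.DataFrame:
        return self.trajectory.summary

    @property
    def depletion(self) -> float:
        """Nuclear G-actin depletion fraction 1 - mean_Gn(t_end)/mean_Gn(0)."""
        s = self.trajectory.summary
        return 1.0 - float(s["mean_Gn"].iloc[-1] / s["mean_Gn"].iloc[0])


def _uniform_state(domain: SimulationDomain, values: dict[str, float]) -> FieldState:
    mc = (domain.mask == CYTOPLASM).astype(float)
    mn = (domain.mask == NUCLEUS).astype(float)
    fields = {}
    for name in CYTOPLASMIC_SPECIES:
        fields[name] = values.get(name, 0.0) * mc
    for name in NUCLEAR_SPECIES:
        fields[name] = values.get(name, 0.0) * mn
    return FieldState(fields, t=0.0)


def _compartment_averages(state: FieldState, domain: SimulationDomain) -> dict[str, float]:
    out = {}
    for name in CYTOPLASMIC_SPECIES:
        out[name] = domain.compartment_mean(state[name], CYTOPLASM)
    for name in NUCLEAR_SPECIES:
        out[name] = domain.compartment_mean(state[name], NUCLEUS)
    return out


def equilibrate(
    params: KineticParameters,
    domain: SimulationDomain,
    cfg: SolverConfig,
    seeds: dict[str, float] | None = None,
    tolerance: float = 1e-6,
    max_steps: int = 200_000,
    check_every: int = 100,
    workspace: DiffusionWorkspace | None = None,
) -> EquilibrationResult:
    """Relax the catalysis-free system and return flat averaged initials.

    The catalytic factor is held at zero, so neither mu pathway acts.  Every
    ``check_every`` steps the compartment mean of each species is compared with
    its previous value; the run stops once the largest relative change per
    time unit drops below ``tolerance``.  The returned state is spatially
    constant at the computed averages — a near, not exact, steady state.
    """
    from .solver import PackedIntegrator

    seeds = dict(DEFAULT_SEED_CONCENTRATIONS, **(seeds or {}))
    seeds["E_c"] = 0.0
    state = _uniform_state(domain, seeds)
    ws = workspace or DiffusionWorkspace(domain)
    spec = default_transfer_spec(params)
    it = PackedIntegrator(domain, params, spec, cfg, ws)
    packed = it.pack(state)
    prev = it.averages(packed)
    elapsed = check_every * cfg.dt
    residual = np.inf
    k = 0
    while k < max_steps:
        for _ in range(check_every):
            k += 1
            packed = it.step_packed(packed, k)
        cur = it.averages(packed)
        residual = max(
            abs(cur[n] - prev[n]) / (max(abs(prev[n]), 1e-12) * elapsed) for n in cur
        )
        prev = cur
        if residual < tolerance:
            flat = _uniform_state(domain, cur)
            return EquilibrationResult(flat, cur, k, residual, True)
    raise EquilibrationError(residual, k)


def _effective_params(spec: ScenarioSpec) -> KineticParameters:
    p = spec.params
    if not spec.mu1_active:
        p = p.replace(mu1=0.0)
    if not spec.mu2_active:
        p = p.replace(mu2=0.0)
    return p


def run_scenario(
    spec: ScenarioSpec,
    domain: SimulationDomain | None = None,
    equilibrium: EquilibrationResult | None = None,
    workspace: DiffusionWorkspace | None = None,
) -> ScenarioResult:
    """Equilibrate, install the catalytic field, integrate to ``t_end``.

    ``domain``/``equilibrium``/``workspace`` may be supplied to share the mesh
    and the equilibrated initial condition across a family of scenarios (the
    knockout matrix runs all four variants from identical initials).
    """
    geom = place_region_at_distance(spec.geometry, spec.region_distance) \
        if spec.region_distance > 0 else spec.geometry
    if domain is None:
        domain = build_domain(spec.geometry, spec.nx, spec.ny, spec.extent)
    ws = workspace or DiffusionWorkspace(domain)
    cfg = spec.solver
    if equilibrium is None:
        equilibrium = equilibrate(
            spec.params, domain, cfg,
            tolerance=spec.eq_tolerance, max_steps=spec.eq_max_steps,
            check_every=spec.eq_check_every, workspace=ws,
        )
    state0 = equilibrium.state.copy()
    state0.fields["E_c"] = initialize_catalytic_field(domain, geom)
    state0.t = 0.0
    params = _effective_params(spec)
    traj = run(
        state0, domain, params, default_transfer_spec(params),
        cfg.replace(t_end=spec.t_end), snapshot_times=spec.snapshot_times,
        workspace=ws,
    )
    return ScenarioResult(spec=spec, domain=domain, trajectory=traj,
                          equilibrium=equilibrium)


KNOCKOUT_VARIANTS = {
    "both": (True, True),
    "mu1_only": (True, False),   # catalysed phosphorylation off (mu2 = 0)
    "mu2_only": (False, True),   # catalysed polymerization off (mu1 = 0)
    "neither": (False, False),
}


def knockout_comparison(base: ScenarioSpec) -> tuple[pd.DataFrame, dict[str, ScenarioResult]]:
    """Run the four pathway on/off combinations from identical equilibrated
    initials and report each variant's nuclear G-actin depletion fraction,
    ordered from strongest to weakest depletion."""
    domain = build_domain(base.geometry, base.nx, base.ny, base.extent)
    ws = DiffusionWorkspace(domain)
    eq = equilibrate(
        base.params, domain, base.solver,
        tolerance=base.eq_tolerance, max_steps=base.eq_max_steps,
        check_every=base.eq_check_every, workspace=ws,
    )
    results: dict[str, ScenarioResult] = {}
    rows = []
    for name, (m1, m2) in KNOCKOUT_VARIANTS.items():
        spec = base.replace(name=name, mu1_active=m1, mu2_active=m2)
        res = run_scenario(spec, domain=domain, equilibrium=eq, workspace=ws)
        results[name] = res
        rows.append({
            "scenario": name, "mu1_active": m1, "mu2_active": m2,
            "mean_Gn_0": res.summary["mean_Gn"].iloc[0],
            "mean_Gn_end": res.summary["mean_Gn"].iloc[-1],
            "depletion": res.depletion,
        })
    report = (pd.DataFrame(rows)
              .sort_values("depletion", ascending=False)
              .reset_index(drop=True))
    return report, results


def relocation_comparison(
    base: ScenarioSpec, distances: list[float]
) -> tuple[pd.DataFrame, dict[float, ScenarioResult]]:
    """Run the full model with the catalytic region at each distance from the
    nuclear surface; report the mobilized (depleted) fraction per distance."""
    for d in distances:
        place_region_at_distance(base.geometry, d)  # validate admissibility
    domain = build_domain(base.geometry, base.nx, base.ny, base.extent)
    ws = DiffusionWorkspace(domain)
    eq = equilibrate(
        base.params, domain, base.solver,
        tolerance=base.eq_tolerance, max_steps=base.eq_max_steps,
        check_every=base.eq_check_every, workspace=ws,
    )
    results: dict[float, ScenarioResult] = {}
    rows = []
    for d in distances:
        spec = base.replace(name=f"relocation_d={d:g}", region_distance=float(d),
                            mu1_active=True, mu2_active=True)
        res = run_scenario(spec, domain=domain, equilibrium=eq, workspace=ws)
        results[float(d)] = res
        rows.append({"distance": float(d), "depletion": res.depletion})
    return pd.DataFrame(rows), results


def knockout_robustness(
    base: ScenarioSpec,
    n_sets: int = 20,
    seed: int = 0,
    ranges=None,
) -> pd.DataFrame:
    """Re-run the two single-pathway knockouts under sampled parameter sets.

    For each constraint-satisfying draw the report records whether the
    headline ordering — knocking out catalysed polymerization (mu1 = 0)
    depletes nuclear G-actin more than knocking out catalysed phosphorylation
    (mu2 = 0) — holds.
    """
    domain = build_domain(base.geometry, base.nx, base.ny, base.extent)
    ws = DiffusionWorkspace(domain)
    rows = []
    for i in range(n_sets):
        params = sample_constrained_parameters(seed + i, ranges)
        eq = equilibrate(
            params, domain, base.solver,
            tolerance=base.eq_tolerance, max_steps=base.eq_max_steps,
            check_every=base.eq_check_every, workspace=ws,
        )
        deltas = {}
        for name in ("mu1_only", "mu2_only"):
            m1, m2 = KNOCKOUT_VARIANTS[name]
            spec = base.replace(name=name, mu1_active=m1, mu2_active=m2,
                                params=params, seed=seed + i)
            res = run_scenario(spec, domain=domain, equilibrium=eq, workspace=ws)
            deltas[name] = res.depletion
        rows.append({
            "set": i, "seed": seed + i,
            "depletion_mu1_only": deltas["mu1_only"],
            "depletion_mu2_only": deltas["mu2_only"],
            "ordering_holds": deltas["mu2_only"] > deltas["mu1_only"],
        })
    return pd.DataFrame(rows)
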