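"""Semi-implicit finite-volume time integration of the full 13-species system.

Each fixed step of size ``dt`` applies, in this order (Lie splitting, O(dt)):

1. explicit-Euler reaction increments (``kinetics``),
2. explicit membrane transfers on the nuclear faces (``transport``),
3. one backward-Euler diffusion solve per species within its own compartment,
   with homogeneous Neumann (no-flux) closure on every compartment edge.

The diffusion matrix ``I - dt*D*L`` (5-point finite-volume Laplacian over the
cells of one compartment only) is a symmetric M-matrix, so the implicit solve
conserves mass to solver precision and preserves positivity; it is
LU-factorized once per (compartment, D, dt) and reused for every step, with
species sharing a factorization solved as a single multi-right-hand-side
batch.  Factorizations are direct (SuperLU), giving residuals far below the
1e-10 relative budget that keeps conservation drift inside 0.1% over 400 time
units.

Internally the integrator works on *packed* vectors — one contiguous array per
species over its own compartment's cells — and converts to full-grid
:class:`~nucactin.kinetics.FieldState` objects only when recording output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CYTOPLASM, NUCLEUS, SimulationDomain
from .kinetics import FieldState, cytoplasm_reaction_rates, nucleus_reaction_rates
from .parameters import CYTOPLASMIC_SPECIES, NUCLEAR_SPECIES, KineticParameters
from .transport import TransferSpec, apply_boundary_fluxes

__all__ = [
    "SolverConfig",
    "Trajectory",
    "SolverError",
    "DiffusionWorkspace",
    "diffusion_step",
    "step",
    "run",
    "summarize_state",
    "explicit_reference_run",
]

_COMPARTMENT_OF = {s: CYTOPLASM for s in CYTOPLASMIC_SPECIES}
_COMPARTMENT_OF.update({s: NUCLEUS for s in NUCLEAR_SPECIES})


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Fixed-step integrator settings (default step 0.01 time units)."""

    dt: float = 0.01
    t_end: float = 400.0
    output_every: int = 100
    positivity_tolerance: float = 1e-10
    diffusion_scheme: str = "implicit_backward_euler"
    reaction_scheme: str = "explicit_euler"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.output_every < 1:
            raise ValueError("output_every must be >= 1")
        if self.diffusion_scheme != "implicit_backward_euler":
            raise ValueError("only implicit_backward_euler diffusion is supported")
        if self.reaction_scheme != "explicit_euler":
            raise ValueError("only explicit_euler reactions are supported")

    def replace(self, **kw) -> "SolverConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Trajectory:
    """Recorded output of one run: a compartment-averaged time series, optional
    field snapshots, and the solver's bookkeeping counters."""

    summary: pd.DataFrame
    snapshots: list[FieldState]
    clip_events: int = 0
    limited_faces: int = 0


class DiffusionWorkspace:
    """Per-domain cache of compartment Laplacians and LU factorizations."""

    def __init__(self, domain: SimulationDomain):
        self.domain = domain
        self._laplacians: dict[int, tuple[np.ndarray, sp.csr_matrix]] = {}
        self._solvers: dict[tuple[int, float, float], object] = {}

    def laplacian(self, label: int) -> tuple[np.ndarray, sp.csr_matrix]:
        """(flat cell indices, finite-volume Laplacian on those cells)."""
        if label not in self._laplacians:
            dom = self.domain
            idx = dom.indices(label)
            pos = -np.ones(dom.nx * dom.ny, dtype=np.int64)
            pos[idx] = np.arange(idx.size)
            mask = dom.mask.ravel()
            rows, cols = [], []
            for off in (1, dom.nx):  # right and down neighbours
                a = np.arange(mask.size - off)
                if off == 1:  # exclude row-wrapping pairs
                    a = a[(a % dom.nx) != dom.nx - 1]
                sel = (mask[a] == label) & (mask[a + off] == label)
                rows.append(pos[a[sel]])
                cols.append(pos[a[sel] + off])
            r = np.concatenate(rows)
            c = np.concatenate(cols)
            w = np.ones(r.size) / dom.h**2
            n = idx.size
            L = sp.coo_matrix(
                (np.concatenate([w, w, -w, -w]),
                 (np.concatenate([r, c, r, c]), np.concatenate([c, r, r, c]))),
                shape=(n, n),
            ).tocsr()
            self._laplacians[label] = (idx, L)
        return self._laplacians[label]

    def solver(self, label: int, D: float, dt: float):
        key = (label, float(D), float(dt))
        if key not in self._solvers:
            idx, L = self.laplacian(label)
            A = sp.identity(idx.size, format="csc") - dt * D * L.tocsc()
            self._solvers[key] = spla.splu(A)
        return self._solvers[key]


def _diffusion_groups(params: KineticParameters):
    """Group species by (compartment, D) so they share one factorization."""
    groups: dict[tuple[int, float], list[str]] = {}
    for name in _COMPARTMENT_OF:
        D = float(params.D[name])
        if D > 0.0:
            groups.setdefault((_COMPARTMENT_OF[name], D), []).append(name)
    return groups


def diffusion_step(
    field_arr: np.ndarray,
    domain: SimulationDomain,
    label: int,
    D: float,
    dt: float,
    workspace: DiffusionWorkspace | None = None,
) -> np.ndarray:
    """One backward-Euler diffusion solve for a single species' field.

    ``D = 0`` is an exact identity.  The field is only read and written on the
    cells of ``label``; other cells pass through unchanged.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if D == 0.0:
        return field_arr.copy()
    ws = workspace or DiffusionWorkspace(domain)
    idx, _ = ws.laplacian(label)
    lu = ws.solver(label, D, dt)
    out = field_arr.copy()
    flat = out.ravel()
    sol = lu.solve(flat[idx])
    if not np.all(np.isfinite(sol)):
        raise SolverError("linear solve produced non-finite values")
    flat[idx] = sol
    return out


class PackedIntegrator:
    """The integration engine on compartment-packed vectors.

    Holds everything reusable across steps: packed cell indices, face
    positions within the packed arrays, the transfer table in array form and
    the cached LU factorizations.
    """

    def __init__(
        self,
        domain: SimulationDomain,
        params: KineticParameters,
        spec: TransferSpec,
        cfg: SolverConfig,
        workspace: DiffusionWorkspace | None = None,
    ):
        self.domain = domain
        self.params = params
        self.spec = spec
        self.cfg = cfg
        self.ws = workspace or DiffusionWorkspace(domain)
        self.idx = {
            CYTOPLASM: self.ws.laplacian(CYTOPLASM)[0],
            NUCLEUS: self.ws.laplacian(NUCLEUS)[0],
        }
        # positions of the nuclear-face cells inside the packed arrays
        self.face_c = np.searchsorted(self.idx[CYTOPLASM], domain.nuclear_faces[:, 0])
        self.face_n = np.searchsorted(self.idx[NUCLEUS], domain.nuclear_faces[:, 1])
        self.groups = [
            (label, self.ws.solver(label, D, cfg.dt), names)
            for (label, D), names in _diffusion_groups(params).items()
        ]
        # transfer laws as (base, cyt name, nuc name, law)
        self.transfers = [
            (base, *spec.pairs[base], law)
            for base, law in spec.laws.items()
            if law.kind != "no_flux" and spec.pairs[base][1] is not None
        ]
        self.t = 0.0
        self.clip_events = 0
        self.limited_faces = 0
        self._nc = self.idx[CYTOPLASM].size
        self._nn = self.idx[NUCLEUS].size

    # -- conversions -------------------------------------------------------
    def pack(self, state: FieldState) -> dict[str, np.ndarray]:
        p = {}
        for name in CYTOPLASMIC_SPECIES:
            p[name] = state[name].ravel()[self.idx[CYTOPLASM]].copy()
        for name in NUCLEAR_SPECIES:
            p[name] = state[name].ravel()[self.idx[NUCLEUS]].copy()
        self.t = state.t
        return p

    def unpack(self, packed: dict[str, np.ndarray]) -> FieldState:
        dom = self.domain
        fields = {}
        for name, vec in packed.items():
            arr = np.zeros(dom.nx * dom.ny)
            arr[self.idx[_COMPARTMENT_OF[name]]] = vec
            fields[name] = arr.reshape(dom.ny, dom.nx)
        return FieldState(fields, t=self.t)

    # -- physics -----------------------------------------------------------
    def _transfer_amounts(self, packed, dt):
        """Per-face transferred amounts (conc*area, positive into nucleus),
        donor-limited; returns {(cyt name, nuc name): amounts}."""
        from .transport import nuclear_face_flux

        h = self.domain.face_length
        area = self.domain.cell_area
        out = {}
        for base, name_c, name_n, law in self.transfers:
            fc = packed[name_c]
            fn = packed[name_n]
            flux = nuclear_face_flux(base, fc[self.face_c], fn[self.face_n], self.spec)
            amount = flux * h * dt
            scale = np.ones_like(amount)
            for pos, donor, outgoing, n_cells in (
                (self.face_c, fc, np.maximum(amount, 0.0), self._nc),
                (self.face_n, fn, np.maximum(-amount, 0.0), self._nn),
            ):
                withdraw = np.zeros(n_cells)
                np.add.at(withdraw, pos, outgoing)
                if np.any(withdraw[pos] > donor[pos] * area):
                    with np.errstate(divide="ignore", invalid="ignore"):
                        s = np.where(
                            withdraw[pos] > 0,
                            np.minimum(1.0, donor[pos] * area / withdraw[pos]),
                            1.0,
                        )
                    limited = (s < 1.0) & (outgoing > 0)
                    scale = np.where(limited, np.minimum(scale, s), scale)
                    self.limited_faces += int(limited.sum())
            out[(name_c, name_n)] = amount * scale
        return out

    def step_packed(self, packed: dict[str, np.ndarray], step_no: int) -> dict:
        dt = self.cfg.dt
        area = self.domain.cell_area
        # reactions and transfers both evaluate the beginning-of-step state
        rc = cytoplasm_reaction_rates(packed, self.params)
        rn = nucleus_reaction_rates(packed, self.params)
        amounts = self._transfer_amounts(packed, dt)

        new = {}
        for name, rate in rc.items():
            new[name] = packed[name] + dt * rate
        for name, rate in rn.items():
            new[name] = packed[name] + dt * rate
        for (name_c, name_n), amount in amounts.items():
            np.add.at(new[name_c], self.face_c, -amount / area)
            np.add.at(new[name_n], self.face_n, amount / area)

        tol = self.cfg.positivity_tolerance
        for name, vec in new.items():
            mn = vec.min() if vec.size else 0.0
            if mn < 0.0:
                if mn < -tol:
                    raise SolverError(
                        f"{name} fell to {mn:.3e} (below -positivity_tolerance) "
                        f"at step {step_no}"
                    )
                np.clip(vec, 0.0, None, out=vec)
                self.clip_events += 1
            if not np.isfinite(vec).all():
                bad = "NaN" if np.isnan(vec).any() else "Inf"
                raise SolverError(f"{bad} in {name} at step {step_no}")

        for label, lu, names in self.groups:
            rhs = np.stack([new[n] for n in names], axis=1)
            sol = lu.solve(rhs)
            if not np.all(np.isfinite(sol)):
                raise SolverError(
                    f"non-finite diffusion solve for {names} at step {step_no}"
                )
            for j, n in enumerate(names):
                new[n] = np.ascontiguousarray(sol[:, j])

        self.t += dt
        return new

    def summarize(self, packed) -> dict:
        area = self.domain.cell_area
        tot = lambda *names: float(sum(packed[n].sum() for n in names) * area)
        return {
            "t": self.t,
            "mean_Gn": float(packed["G_n"].mean()),
            "mean_Gc": float(packed["G_c"].mean()),
            "total_Fc": tot("F_c"),
            "total_Theta_c": tot("Theta_c"),
            "total_actin": tot("G_c", "F_c", "Xi_c", "Ups_c", "G_n", "Xi_n", "Ups_n"),
            "total_cofilin": tot("C_c", "Xi_c", "Theta_c", "C_n", "Xi_n"),
            "total_profilin": tot("P_c", "Ups_c", "P_n", "Ups_n"),
            "total_E": tot("E_c"),
        }

    def averages(self, packed) -> dict[str, float]:
        return {name: float(vec.mean()) for name, vec in packed.items()}


def step(
    state: FieldState,
    domain: SimulationDomain,
    params: KineticParameters,
    spec: TransferSpec,
    cfg: SolverConfig,
    workspace: DiffusionWorkspace | None = None,
    integrator: PackedIntegrator | None = None,
    _step_no: int = 0,
) -> tuple[FieldState, int, int]:
    """Advance one dt: reactions, transfers, implicit diffusion.

    Returns ``(new_state, clip_events, limited_faces)``.  This is the
    full-grid convenience wrapper; long runs use :class:`PackedIntegrator`
    directly to avoid repeated packing.
    """
    it = integrator or PackedIntegrator(domain, params, spec, cfg, workspace)
    c0, l0 = it.clip_events, it.limited_faces
    packed = it.pack(state)
    packed = it.step_packed(packed, _step_no)
    out = it.unpack(packed)
    return out, it.clip_events - c0, it.limited_faces - l0


def summarize_state(state: FieldState, domain: SimulationDomain) -> dict:
    """One summary row: compartment means of G-actin, F-actin and
    phospho-cofilin totals, and the four conserved-group totals."""
    area = domain.cell_area
    f = state.fields
    tot = lambda *names: float(sum(f[n].sum() for n in names) * area)
    return {
        "t": state.t,
        "mean_Gn": domain.compartment_mean(f["G_n"], NUCLEUS),
        "mean_Gc": domain.compartment_mean(f["G_c"], CYTOPLASM),
        "total_Fc": tot("F_c"),
        "total_Theta_c": tot("Theta_c"),
        "total_actin": tot("G_c", "F_c", "Xi_c", "Ups_c", "G_n", "Xi_n", "Ups_n"),
        "total_cofilin": tot("C_c", "Xi_c", "Theta_c", "C_n", "Xi_n"),
        "total_profilin": tot("P_c", "Ups_c", "P_n", "Ups_n"),
        "total_E": tot("E_c"),
    }


def run(
    state0: FieldState,
    domain: SimulationDomain,
    params: KineticParameters,
    spec: TransferSpec,
    cfg: SolverConfig,
    snapshot_times: tuple[float, ...] = (),
    workspace: DiffusionWorkspace | None = None,
) -> Trajectory:
    """Integrate to ``t_end``, recording a summary row every ``output_every``
    steps and a full snapshot at each requested time (matched to the nearest
    step)."""
    it = PackedIntegrator(domain, params, spec, cfg, workspace)
    packed = it.pack(state0)
    n_steps = int(round((cfg.t_end - state0.t) / cfg.dt))
    snap_steps = {int(round((t - state0.t) / cfg.dt)) for t in snapshot_times}

    rows = [it.summarize(packed)]
    snapshots = [it.unpack(packed)] if 0 in snap_steps else []
    for k in range(1, n_steps + 1):
        packed = it.step_packed(packed, k)
        it.t = state0.t + k * cfg.dt  # exact multiples, no accumulation drift
        if k % cfg.output_every == 0 or k == n_steps:
            rows.append(it.summarize(packed))
        if k in snap_steps:
            snapshots.append(it.unpack(packed))
    summary = pd.DataFrame(rows).drop_duplicates(subset="t").reset_index(drop=True)
    return Trajectory(summary=summary, snapshots=snapshots,
                      clip_events=it.clip_events, limited_faces=it.limited_faces)


def explicit_reference_run(
    state0: FieldState,
    domain: SimulationDomain,
    params: KineticParameters,
    spec: TransferSpec,
    dt: float,
    n_steps: int,
) -> FieldState:
    """Fully explicit Euler integrator (explicit diffusion included).

    An independent, brute-force reference used to validate the semi-implicit
    scheme; subject to the explicit diffusion stability limit
    ``dt <= h**2 / (4 * D_max)``.
    """
    ws = DiffusionWorkspace(domain)
    cfg = SolverConfig(dt=dt, t_end=dt * n_steps)
    it = PackedIntegrator(domain, params, spec, cfg, ws)
    packed = it.pack(state0)
    lap = {label: ws.laplacian(label)[1] for label in (CYTOPLASM, NUCLEUS)}
    groups = _diffusion_groups(params)
    for k in range(n_steps):
        rc = cytoplasm_reaction_rates(packed, params)
        rn = nucleus_reaction_rates(packed, params)
        amounts = it._transfer_amounts(packed, dt)
        new = {}
        for name, rate in {**rc, **rn}.items():
            new[name] = packed[name] + dt * rate
        area = domain.cell_area
        for (name_c, name_n), amount in amounts.items():
            np.add.at(new[name_c], it.face_c, -amount / area)
            np.add.at(new[name_n], it.face_n, amount / area)
        for (label, D), names in groups.items():
            for n in names:
                new[n] = new[n] + dt * D * (lap[label] @ packed[n])
        for name, vec in new.items():
            if vec.size and vec.min() < -1e-10:
                raise SolverError(f"explicit reference went negative in {name}")
            np.clip(vec, 0.0, None, out=vec)
        packed = new
        it.t += dt
    return it.unpack(packed)
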