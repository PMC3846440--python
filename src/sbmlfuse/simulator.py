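"""Kinetic ODE simulation of an SBML model.

The reaction network is turned into d[S]/dt = sum_r nu_{S,r} v_r / size(S)
(amount-valued species skip the division); boundary and constant species
keep zero derivative while still feeding rate laws.  Integration uses a
stiff-capable adaptive solver (LSODA) honoring the configured absolute and
relative tolerances; a fixed-step classical Runge-Kutta integrator is
provided as an independent reference oracle.

Assignment rules are evaluated before every derivative call; rate rules,
algebraic rules, events and delays are rejected (composition still
carries them through, they just cannot be integrated here).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import mathexpr
from .mathexpr import MATHML_NS, MathExpr, evaluate, parse_mathml
from .model import SbmlModel


class SimulationError(ValueError):
    """Model cannot be simulated (missing law, unresolved identifier,
    solver failure, non-finite state)."""


class UnsupportedModelError(SimulationError):
    """Model uses a construct the simulator does not integrate."""


@dataclass
class SimulationSettings:
    t_start: float = 0.0
    t_end: float = 10.0
    n_points: int = 100
    abs_tol: float = 1e-16  # engine defaults
    rel_tol: float = 1e-6
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    initial_overrides: dict[str, float] = field(default_factory=dict)
    selected_species: Optional[set[str]] = None  # None = all
    selected_fluxes: Optional[set[str]] = None  # None = all

    def validate(self) -> None:
        if not self.t_end > self.t_start:
            raise SimulationError("t_end must be greater than t_start")
        if self.n_points < 1:
            raise SimulationError("n_points must be a positive integer")
        if not (self.abs_tol > 0 and self.rel_tol > 0):
            raise SimulationError("tolerances must be positive")
        for sid, value in self.initial_overrides.items():
            if not value > 0:
                raise SimulationError(
                    f"initial override for {sid!r} must be strictly positive"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationSettings":
        s = cls(
            t_start=float(data.get("tStart", 0.0)),
            t_end=float(data.get("tEnd", 10.0)),
            n_points=int(data.get("nPoints", 100)),
            abs_tol=float(data.get("absTol", 1e-16)),
            rel_tol=float(data.get("relTol", 1e-6)),
            parameter_overrides={k: float(v) for k, v in data.get("parameterOverrides", {}).items()},
            initial_overrides={k: float(v) for k, v in data.get("initialOverrides", {}).items()},
            selected_species=set(data["selectedSpecies"]) if "selectedSpecies" in data else None,
            selected_fluxes=set(data["selectedFluxes"]) if "selectedFluxes" in data else None,
        )
        s.validate()
        return s


@dataclass
class SimulationResult:
    time_grid: np.ndarray
    species_series: dict[str, np.ndarray]
    flux_series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        header = ["time", *self.species_series, *self.flux_series]
        writer.writerow(header)
        columns = [self.time_grid, *self.species_series.values(), *self.flux_series.values()]
        for row in zip(*columns):
            writer.writerow([repr(float(v)) for v in row])
        return buf.getvalue()


@dataclass
class ExperimentalSeries:
    time: np.ndarray
    columns: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# ODE system construction

class OdeSystem:
    """Callable rate function plus bookkeeping for one model."""

    def __init__(self, model: SbmlModel, settings: Optional[SimulationSettings] = None):
        self.model = model
        settings = settings or SimulationSettings()
        self._reject_unsupported(model)
        self.functions = _parse_function_definitions(model)
        self.assignment_rules = _parse_assignment_rules(model)

        self.species_ids = [s.id for s in model.species]
        self._index = {sid: i for i, sid in enumerate(self.species_ids)}
        self.compartment_sizes = {
            c.id: (c.size if c.size is not None else 1.0) for c in model.compartments
        }
        self.parameters: dict[str, float] = {}
        for p in model.parameters:
            if p.value is not None:
                self.parameters[p.id] = p.value
        for pid, value in settings.parameter_overrides.items():
            if pid not in {p.id for p in model.parameters} and not any(
                pid in {lp.id for lp in r.local_parameters} for r in model.reactions
            ):
                raise SimulationError(f"parameter override targets unknown id {pid!r}")
            self.parameters[pid] = value
        self._local_overrides = settings.parameter_overrides

        self.y0 = np.zeros(len(self.species_ids))
        for i, sp in enumerate(model.species):
            value = sp.initial_value if sp.initial_value is not None else 0.0
            size = self.compartment_sizes[sp.compartment]
            if sp.has_only_substance_units:
                # state carries amount
                if sp.initial_kind == "concentration":
                    value *= size
            else:
                # state carries concentration
                if sp.initial_kind == "amount":
                    value = value / size if size != 0 else value
            self.y0[i] = value
        for sid, value in settings.initial_overrides.items():
            if sid not in self._index:
                raise SimulationError(f"initial override targets unknown species {sid!r}")
            self.y0[self._index[sid]] = value

        self._dynamic = np.array(
            [not (s.boundary_condition or s.constant) for s in model.species]
        )
        self._rates = []
        for r in model.reactions:
            if r.kinetic_math is None:
                raise SimulationError(f"reaction {r.id!r} has no kinetic law")
            locals_ = {p.id: p.value for p in r.local_parameters if p.value is not None}
            for pid in locals_:
                if pid in self._local_overrides:
                    locals_[pid] = self._local_overrides[pid]
            self._rates.append((r.id, r.kinetic_math, locals_))
        self._divisor = np.ones(len(self.species_ids))
        for i, sp in enumerate(model.species):
            if not sp.has_only_substance_units:
                size = self.compartment_sizes[sp.compartment]
                self._divisor[i] = size if size != 0 else 1.0
        # stoichiometry matrix: species x reactions
        self.stoich = np.zeros((len(self.species_ids), len(model.reactions)))
        for j, r in enumerate(model.reactions):
            for ref in r.reactants:
                self.stoich[self._index[ref.species], j] -= ref.stoichiometry
            for ref in r.products:
                self.stoich[self._index[ref.species], j] += ref.stoichiometry
        self._check_resolvable()

    @staticmethod
    def _reject_unsupported(model: SbmlModel) -> None:
        for op in model.other_elements:
            tag = op.element.tag.rsplit("}", 1)[-1]
            if tag == "event":
                raise UnsupportedModelError("events are unsupported for simulation")
            if tag == "rateRule":
                raise UnsupportedModelError("rate rules are unsupported for simulation")
            if tag == "algebraicRule":
                raise UnsupportedModelError("algebraic rules are unsupported for simulation")

    def _check_resolvable(self) -> None:
        known = set(self.species_ids) | set(self.compartment_sizes) | set(self.parameters)
        known |= set(self.functions) | {v for v, _ in self.assignment_rules}
        for rid, expr, locals_ in self._rates:
            for ident in mathexpr.identifiers(expr):
                if ident not in known and ident not in locals_:
                    raise SimulationError(
                        f"reaction {rid!r}: unresolved identifier {ident!r} in kinetic law"
                    )

    def _env(self, t: float, y: np.ndarray) -> dict[str, float]:
        env = dict(self.parameters)
        env.update(self.compartment_sizes)
        for sid, value in zip(self.species_ids, y):
            env[sid] = value
        for variable, expr in self.assignment_rules:
            env[variable] = evaluate(expr, env, time=t, functions=self.functions)
        return env

    def rates(self, t: float, y: np.ndarray) -> np.ndarray:
        env = self._env(t, y)
        out = np.empty(len(self._rates))
        for j, (_, expr, locals_) in enumerate(self._rates):
            local_env = {**env, **locals_} if locals_ else env
            out[j] = evaluate(expr, local_env, time=t, functions=self.functions)
        return out

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        if not self._rates:
            return np.zeros_like(y)
        dy = (self.stoich @ self.rates(t, y)) / self._divisor
        return np.where(self._dynamic, dy, 0.0)


def _parse_function_definitions(model: SbmlModel) -> dict[str, mathexpr.FunctionDef]:
    out: dict[str, mathexpr.FunctionDef] = {}
    for op in model.other_elements:
        if op.element.tag.rsplit("}", 1)[-1] != "functionDefinition":
            continue
        fid = op.element.get("id")
        math_elem = op.element.find(f"{{{MATHML_NS}}}math")
        if fid is None or math_elem is None:
            continue
        lam = math_elem.find(f"{{{MATHML_NS}}}lambda")
        if lam is None:
            continue
        params: list[str] = []
        body: Optional[MathExpr] = None
        for child in lam:
            tag = child.tag.rsplit("}", 1)[-1]
            if tag == "bvar":
                ci = child.find(f"{{{MATHML_NS}}}ci")
                if ci is not None and ci.text:
                    params.append(ci.text.strip())
            else:
                body = parse_mathml(child)
        if body is not None:
            out[fid] = (tuple(params), body)
    return out


def _parse_assignment_rules(model: SbmlModel) -> list[tuple[str, MathExpr]]:
    out = []
    for op in model.other_elements:
        if op.element.tag.rsplit("}", 1)[-1] != "assignmentRule":
            continue
        variable = op.element.get("variable")
        math_elem = op.element.find(f"{{{MATHML_NS}}}math")
        if variable and math_elem is not None:
            out.append((variable, parse_mathml(math_elem)))
    return out


def build_ode_system(
    model: SbmlModel, settings: Optional[SimulationSettings] = None
) -> OdeSystem:
    """Validated rate function ``f(t, y) -> dy`` for the model."""
    return OdeSystem(model, settings)


# ---------------------------------------------------------------------------
# integration

def time_grid(settings: SimulationSettings) -> np.ndarray:
    return np.linspace(settings.t_start, settings.t_end, settings.n_points)


def simulate(model: SbmlModel, settings: Optional[SimulationSettings] = None) -> SimulationResult:
    """Adaptive stiff-capable integration sampled on the settings grid."""
    settings = settings or SimulationSettings()
    settings.validate()
    system = build_ode_system(model, settings)
    grid = time_grid(settings)
    if len(system.species_ids) == 0 or not system._rates:
        y = np.tile(system.y0, (len(grid), 1))
    else:
        sol = solve_ivp(
            system,
            (settings.t_start, settings.t_end),
            system.y0,
            method="LSODA",
            t_eval=grid,
            atol=settings.abs_tol,
            rtol=settings.rel_tol,
        )
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}")
        y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state encountered during integration")
    return _package(system, settings, grid, y, solver="LSODA")


def simulate_reference(
    model: SbmlModel,
    settings: Optional[SimulationSettings] = None,
    max_step: Optional[float] = None,
) -> SimulationResult:
    """Independent fixed-step classical 4th-order Runge-Kutta oracle.

    Step size defaults to 1e-4 of the simulated span, subdivided so that
    grid points are hit exactly.
    """
    settings = settings or SimulationSettings()
    settings.validate()
    system = build_ode_system(model, settings)
    grid = time_grid(settings)
    span = settings.t_end - settings.t_start
    h_target = max_step if max_step is not None else 1e-4 * span
    y = np.empty((len(grid), len(system.y0)))
    y[0] = system.y0
    state = system.y0.astype(float).copy()
    t = grid[0]
    for i in range(1, len(grid)):
        dt = grid[i] - t
        n_sub = max(1, int(np.ceil(dt / h_target)))
        h = dt / n_sub
        for _ in range(n_sub):
            k1 = system(t, state)
            k2 = system(t + h / 2.0, state + h / 2.0 * k1)
            k3 = system(t + h / 2.0, state + h / 2.0 * k2)
            k4 = system(t + h, state + h * k3)
            state = state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        t = grid[i]
        y[i] = state
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state in reference integration")
    return _package(system, settings, grid, y, solver="rk4-reference")


def _package(system, settings, grid, y, solver):
    species_sel = settings.selected_species
    flux_sel = settings.selected_fluxes
    species_series = {
        sid: y[:, i]
        for i, sid in enumerate(system.species_ids)
        if species_sel is None or sid in species_sel
    }
    flux_ids = [rid for rid, _, _ in system._rates]
    flux_series: dict[str, np.ndarray] = {
        rid: np.empty(len(grid)) for rid in flux_ids if flux_sel is None or rid in flux_sel
    }
    if flux_series:
        for k, (t, state) in enumerate(zip(grid, y)):
            rates = system.rates(t, state)
            for j, rid in enumerate(flux_ids):
                if rid in flux_series:
                    flux_series[rid][k] = rates[j]
    return SimulationResult(
        time_grid=grid,
        species_series=species_series,
        flux_series=flux_series,
        metadata={"solver": solver, "absTol": settings.abs_tol, "relTol": settings.rel_tol},
    )


# ---------------------------------------------------------------------------
# experimental data

def load_experimental_csv(text: str) -> ExperimentalSeries:
    """Time-course CSV: first column is time; optional single header row;
    headerless input gets positional labels col1, col2, ..."""
    rows = [row for row in csv.reader(io.StringIO(text)) if row and any(c.strip() for c in row)]
    if not rows:
        return ExperimentalSeries(np.array([]), {})
    width = len(rows[0])

    def numeric_row(row):
        try:
            return [float(c) for c in row]
        except ValueError:
            return None

    first = numeric_row(rows[0])
    if first is None:
        labels = [c.strip() for c in rows[0][1:]]
        data_rows = rows[1:]
        start_line = 2
    else:
        labels = [f"col{i}" for i in range(1, width)]
        data_rows = rows
        start_line = 1
    data: list[list[float]] = []
    for offset, row in enumerate(data_rows):
        line_no = start_line + offset
        if len(row) != width:
            raise ValueError(
                f"ragged CSV row at line {line_no}: expected {width} cells, got {len(row)}"
            )
        values = numeric_row(row)
        if values is None:
            raise ValueError(f"non-numeric cell in CSV at line {line_no}")
        data.append(values)
    data.sort(key=lambda r: r[0])
    times = np.array([r[0] for r in data])
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("experimental time column must be strictly increasing")
    columns = {
        label: np.array([r[i + 1] for r in data]) for i, label in enumerate(labels)
    }
    return ExperimentalSeries(time=times, columns=columns)


@dataclass
class OverlayResult:
    table: "object"  # pandas DataFrame
    rms: dict[str, float]
    unmatched: list[str]


def overlay(result: SimulationResult, exp: ExperimentalSeries) -> OverlayResult:
    """Align simulation output with experimental points on the union time
    grid; simulated series are linearly interpolated at experimental time
    points and per-column RMS deviation is reported for labels that match
    a species or flux id."""
    import pandas as pd

    sim_series = {**result.species_series, **result.flux_series}
    union = np.union1d(result.time_grid, exp.time)
    table = pd.DataFrame({"time": union})
    for sid, series in sim_series.items():
        table[sid] = np.interp(union, result.time_grid, series)
    rms: dict[str, float] = {}
    unmatched: list[str] = []
    for label, values in exp.columns.items():
        col = np.full(len(union), np.nan)
        idx = np.searchsorted(union, exp.time)
        col[idx] = values
        table[f"exp:{label}"] = col
        if label in sim_series:
            sim_at_exp = np.interp(exp.time, result.time_grid, sim_series[label])
            rms[label] = float(np.sqrt(np.mean((sim_at_exp - values) ** 2))) if len(values) else 0.0
        else:
            unmatched.append(label)
    return OverlayResult(table=table, rms=rms, unmatched=unmatched)
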