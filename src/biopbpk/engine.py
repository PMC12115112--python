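"""Numerical simulation of compiled models and VPop batch execution.

Simulation uses a stiff-capable SciPy integrator (LSODA by default) on the
amount-space right-hand side produced by the compiler.  Bolus doses are
applied as exact state discontinuities: the time axis is split at every dose
time and the solver is restarted, rather than smuggling the dose in through a
forcing function.  Repeated assignments are part of the generated right-hand
side, so they are re-evaluated at every internal solver step.

Virtual-population (VPop) files are CSV tables with an integer ``ID`` column,
an optional ``LABEL`` column, and one column per overridden quantity, named by
its expanded component (e.g. ``P_A`` or ``V_va_he``).  Each row yields one
simulation: row values replace the model defaults before initial assignments
run.  Quantities defined by assignment nodes cannot be overridden and are
rejected with an explicit message.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compiler import CompiledModel

__all__ = [
    "SolverOptions",
    "SimulationResult",
    "VPopTable",
    "VPopRow",
    "simulate",
    "read_vpop",
    "write_vpop",
    "run_vpop",
    "results_to_frame",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the integrator fails or the RHS produces non-finite values."""


@dataclass
class SolverOptions:
    """Integrator settings.

    Amounts are in moles and can be very small, hence the tight absolute
    tolerance default.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    max_step: float = np.inf


@dataclass
class SimulationResult:
    """Per-run time series of state amounts and derived observers."""

    label: str
    times: np.ndarray
    states: pd.DataFrame
    observers: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.states[name].to_numpy()

    def observer(self, name: str) -> np.ndarray:
        return self.observers[name].to_numpy()

    def total_amount(self, states: Sequence[str] | None = None) -> np.ndarray:
        cols = list(states) if states is not None else list(self.states.columns)
        return self.states[cols].to_numpy().sum(axis=1)


def _check_rhs_finite(model: CompiledModel, t, y, p):
    dy = model.rhs(t, y, p)
    if not np.all(np.isfinite(dy)):
        bad = [model.state_names[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise SimulationError(f"non-finite RHS at t={t:g} for states {bad[:5]}")


def simulate(
    model: CompiledModel,
    t_end: float,
    output_times: Sequence[float] | None = None,
    overrides: Mapping[str, float] | None = None,
    options: SolverOptions | None = None,
    label: str = "run",
    extra_doses: Sequence[tuple[float, str, float]] | None = None,
) -> SimulationResult:
    """Integrate ``model`` from t=0 to ``t_end`` and return trajectories.

    ``extra_doses`` are (time, state name, amount in moles) boluses applied in
    addition to the model's own dosing plans.  State trajectories are reported
    as amounts; observer trajectories are whatever the model's observer
    expressions compute (typically concentrations).  Small negative amounts
    within solver tolerance are clipped to zero in the reported output only;
    persistent negativity is reported in ``diagnostics``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    opts = options or SolverOptions()
    y0, p, doses = model.initialize(overrides)
    if not np.all(np.isfinite(p)):
        bad = [model.parameter_names[i] for i in np.flatnonzero(~np.isfinite(p))]
        raise SimulationError(f"non-finite parameters: {bad[:5]}")
    for t, name, amount in extra_doses or ():
        doses.append((float(t), model.state_index[name], float(amount)))
    doses = sorted((d for d in doses if d[0] <= t_end), key=lambda d: d[0])

    if output_times is None:
        output_times = np.linspace(0.0, t_end, 201)
    tgrid = np.asarray(output_times, dtype=float)
    if tgrid.ndim != 1 or np.any(np.diff(tgrid) <= 0):
        raise ValueError("output_times must be strictly increasing")

    boundaries = sorted({0.0, t_end} | {t for t, _, _ in doses if t < t_end})
    y = y0.copy()
    rec_t: list[float] = []
    rec_y: list[np.ndarray] = []
    nfev = 0
    started = _time.perf_counter()
    for a, b in zip(boundaries, boundaries[1:] + [t_end]):
        if a >= t_end:
            break
        for t, idx, amount in doses:
            if t == a:
                y[idx] += amount
        if a == 0.0 and tgrid[0] == 0.0:
            rec_t.append(0.0)
            rec_y.append(y.copy())
        b = min(b, t_end)
        if b <= a:
            continue
        t_eval = tgrid[(tgrid > a) & (tgrid <= b)]
        _check_rhs_finite(model, a, y, p)
        sol = solve_ivp(
            model.rhs,
            (a, b),
            y,
            args=(p,),
            method=opts.method,
            rtol=opts.rtol,
            atol=opts.atol,
            max_step=opts.max_step,
            t_eval=t_eval if len(t_eval) else None,
            dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed on [{a:g}, {b:g}] ({sol.message}); "
                f"{len(rec_t)} points recorded"
            )
        nfev += sol.nfev
        if len(t_eval):
            rec_t.extend(sol.t.tolist())
            rec_y.extend(list(sol.y.T))
        y = sol.y[:, -1] if sol.y.size else y

    Y = np.vstack(rec_y) if rec_y else np.empty((0, model.n_states))
    times = np.asarray(rec_t)
    min_amount = float(Y.min()) if Y.size else 0.0
    diagnostics = {
        "nfev": nfev,
        "wall_time_s": _time.perf_counter() - started,
        "min_amount": min_amount,
    }
    if min_amount < -100 * opts.atol:
        diagnostics["negative_states"] = True
    Yc = np.where(Y < 0, 0.0, Y)
    states = pd.DataFrame(Yc, index=times, columns=model.state_names)
    states.index.name = "time"
    obs = np.array([model.observe(t, yrow, p) for t, yrow in zip(times, Y)])
    observers = pd.DataFrame(
        obs if obs.size else np.empty((len(times), 0)),
        index=times,
        columns=model.observer_names,
    )
    observers.index.name = "time"
    return SimulationResult(label, times, states, observers, diagnostics)


# ------------------------------------------------------------------------ VPop

@dataclass
class VPopRow:
    id: int
    label: str | None
    overrides: dict[str, float]


@dataclass
class VPopTable:
    """Row-wise quantity-override sets keyed by unique integer ID."""

    rows: list[VPopRow]

    def __post_init__(self):
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ID in VPop table")
        if any((not isinstance(r.id, (int, np.integer))) or r.id <= 0 for r in self.rows):
            raise ValueError("VPop IDs must be positive integers")

    def to_frame(self) -> pd.DataFrame:
        cols: list[str] = []
        for r in self.rows:
            for k in r.overrides:
                if k not in cols:
                    cols.append(k)
        data = []
        for r in self.rows:
            row = {"ID": r.id}
            if r.label is not None:
                row["LABEL"] = r.label
            row.update(r.overrides)
            data.append(row)
        lead = ["ID"] + (["LABEL"] if any(r.label is not None for r in self.rows) else [])
        return pd.DataFrame(data, columns=lead + cols)


def read_vpop(path) -> VPopTable:
    """Read a VPop CSV (comma-separated, UTF-8, header row, '.' decimal)."""
    df = pd.read_csv(path)
    if "ID" not in df.columns:
        raise ValueError("VPop file must have an 'ID' column")
    has_label = "LABEL" in df.columns
    rows = []
    for _, rec in df.iterrows():
        overrides = {}
        for col in df.columns:
            if col in ("ID", "LABEL"):
                continue
            val = rec[col]
            if pd.isna(val):
                raise ValueError(f"missing value for {col!r} in VPop row ID={rec['ID']}")
            overrides[col] = float(val)
        label = str(rec["LABEL"]) if has_label and not pd.isna(rec["LABEL"]) else None
        rows.append(VPopRow(int(rec["ID"]), label, overrides))
    return VPopTable(rows)


def write_vpop(table: VPopTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def run_vpop(
    model: CompiledModel,
    vpop: VPopTable,
    t_end: float,
    output_times: Sequence[float] | None = None,
    options: SolverOptions | None = None,
    base_overrides: Mapping[str, float] | None = None,
) -> list[SimulationResult]:
    """One simulation per VPop row, in row order.

    Unknown override columns and overrides of assignment-defined quantities
    raise before any simulation starts, so a bad table fails fast.
    """
    for row in vpop.rows:
        model.validate_overrides(row.overrides)
    results = []
    for row in vpop.rows:
        overrides = dict(base_overrides or {})
        overrides.update(row.overrides)
        label = row.label if row.label is not None else f"ID {row.id}"
        results.append(
            simulate(model, t_end, output_times, overrides, options, label=label)
        )
    return results


def results_to_frame(results: Sequence[SimulationResult]) -> pd.DataFrame:
    """Tidy long-format table: (run, time, variable, value)."""
    frames = []
    for res in results:
        for df in (res.states, res.observers):
            if df.shape[1] == 0:
                continue
            long = df.reset_index().melt(id_vars="time", var_name="variable")
            long.insert(0, "run", res.label)
            frames.append(long)
    if not frames:
        return pd.DataFrame(columns=["run", "time", "variable", "value"])
    return pd.concat(frames, ignore_index=True)
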