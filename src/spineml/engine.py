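"""Reference interpreter for elaborated models.

Advances every component instance through time with the declared hybrid
semantics: per-regime ODE integration (forward Euler or classical RK4),
boolean-triggered regime transitions, event/impulse routing with delays,
synchronous analogue propagation with reduce-port summation, and logging.

One step of duration dt executes five phases in a fixed order:

  1. analogue propagation — every analogue edge copies the source port's
     value (as computed at the END of the previous step) into the
     destination buffer; reduce ports sum all arrivals and are zero-filled
     when nothing arrives; current-input drivers add onto the buffers
  2. integration — each instance's active-regime time derivatives are
     advanced by dt with the experiment's integrator
  3. delivery — events/impulses whose delivery step is due fire the
     OnEvent/OnImpulse handlers of the recipients' current regimes
  4. conditions — OnCondition triggers are evaluated on the
     post-integration state (at time t+dt); on the first true trigger, in
     document order, state assignments apply simultaneously against
     pre-assignment values, outputs are emitted, and the regime switches;
     at most one transition per instance per step
  5. the clock advances to t+dt; post-step port values are snapshotted and
     log records appended

An output emitted at step n carries emission time (n+1)*dt and is
delivered at step (n+1) + round(delay/dt): zero-delay messages arrive in
the next step's phase 3, which removes intra-step ordering ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import Diagnostic, ModelError
from .experiment import Experiment, validate_experiment
from .expr import EvaluationError, ExpressionTree, evaluate, free_symbols
from .network import EdgeGroup, FlatModel, InstanceSet

__all__ = ["LogSet", "simulate", "integrator_step", "SimState"]


# ---------------------------------------------------------------------------
# Integration


def integrator_step(derivatives, state_values: dict, env: dict, dt: float,
                    method: str, aliases=()):
    """Advance one dt of the ODE system defined by ``derivatives``.

    derivatives  iterable of (state variable name, ExpressionTree)
    state_values name -> scalar or array; variables without a derivative
                 are returned unchanged
    env          additional bindings (parameters, inputs, 't' in ms)
    aliases      topologically ordered (name, ExpressionTree) recomputed at
                 every evaluation point

    Supports ``forward_euler`` (x += dt*f(x,t)) and the classical 4-stage
    ``rk4``.
    """
    derivs = list(derivatives)
    if not derivs:
        return dict(state_values)
    t0 = env.get("t", 0.0)

    def f(states, t):
        e = {**env, **states, "t": t}
        for name, expr in aliases:
            e[name] = evaluate(expr, e)
        return {var: evaluate(expr, e) for var, expr in derivs}

    out = dict(state_values)
    if method == "forward_euler":
        k1 = f(state_values, t0)
        for var in k1:
            out[var] = state_values[var] + dt * k1[var]
        return out
    if method == "rk4":
        k1 = f(state_values, t0)
        s2 = {**state_values,
              **{v: state_values[v] + 0.5 * dt * k1[v] for v in k1}}
        k2 = f(s2, t0 + 0.5 * dt)
        s3 = {**state_values,
              **{v: state_values[v] + 0.5 * dt * k2[v] for v in k2}}
        k3 = f(s3, t0 + 0.5 * dt)
        s4 = {**state_values, **{v: state_values[v] + dt * k3[v] for v in k3}}
        k4 = f(s4, t0 + dt)
        for v in k1:
            out[v] = state_values[v] + (dt / 6.0) * (
                k1[v] + 2.0 * k2[v] + 2.0 * k3[v] + k4[v])
        return out
    raise ValueError(f"unknown integrator {method!r}")


# ---------------------------------------------------------------------------
# Logging


@dataclass
class LogSet:
    """Recorded outputs, one entry per LogRequest.

    Analog logs are DataFrames with columns (t_ms, index, value); event
    logs with (t_ms, index).  Records are time-sorted.
    """

    frames: dict[str, pd.DataFrame] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, df in self.frames.items():
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)


# ---------------------------------------------------------------------------
# Per-set runtime


def _topo_aliases(comp):
    names = {a.name: a for a in comp.aliases}
    order, done = [], set()

    def visit(n):
        if n in done:
            return
        done.add(n)
        for dep in free_symbols(names[n].expression):
            if dep in names:
                visit(dep)
        order.append((n, names[n].expression))

    for n in names:
        visit(n)
    return order


class _SetRuntime:
    def __init__(self, iset: InstanceSet):
        self.name = iset.name
        self.comp = iset.component
        self.size = iset.size
        self.params = {k: v.astype(float) for k, v in iset.parameters.items()}
        self.states = {k: v.copy().astype(float)
                       for k, v in iset.initial_state.items()}
        self.aliases = _topo_aliases(self.comp)
        self.regime_names = [r.name for r in self.comp.regimes]
        self.regimes = {r.name: i for i, r in enumerate(self.comp.regimes)}
        init = self.regimes[self.comp.initial_regime]
        self.regime_ids = np.full(self.size, init, dtype=np.int8)
        self.single_regime = len(self.comp.regimes) == 1
        self.analog_in = {
            p.name: np.zeros(self.size)
            for p in self.comp.ports
            if p.mode == "analog" and p.direction == "receive"
        }
        self.analog_send_ports = [
            p.name for p in self.comp.ports
            if p.mode == "analog" and p.direction == "send"
        ]
        self.analog_out: dict[str, np.ndarray] = {}
        # handlers[(mode, port)] -> list of (regime id, handler)
        self.handlers: dict[tuple[str, str], list] = {}
        for rid, regime in enumerate(self.comp.regimes):
            for ev in regime.on_events:
                self.handlers.setdefault(("event", ev.source_port), []).append(
                    (rid, ev))
            for im in regime.on_impulses:
                self.handlers.setdefault(("impulse", im.source_port), []).append(
                    (rid, im))
        self.has_derivatives = any(r.time_derivatives for r in self.comp.regimes)
        # instances that already switched regime during the current step
        self.step_transitioned = np.zeros(self.size, dtype=bool)

    def env(self, t: float) -> dict:
        e = {"t": t}
        e.update(self.params)
        e.update(self.states)
        e.update(self.analog_in)
        for name, expr in self.aliases:
            e[name] = evaluate(expr, e)
        return e

    def sub_env(self, idx: np.ndarray, t: float, extra: dict | None = None) -> dict:
        e = {"t": t}
        for k, v in self.params.items():
            e[k] = v[idx]
        for k, v in self.states.items():
            e[k] = v[idx]
        for k, v in self.analog_in.items():
            e[k] = v[idx]
        if extra:
            e.update(extra)
        for name, expr in self.aliases:
            e[name] = evaluate(expr, e)
        return e

    def snapshot_outputs(self, t: float) -> None:
        """Post-step values exposed on analogue send ports."""
        if not self.analog_send_ports:
            return
        env = None
        for p in self.analog_send_ports:
            if p in self.states:
                self.analog_out[p] = self.states[p].copy()
            else:  # alias-backed
                if env is None:
                    env = self.env(t)
                self.analog_out[p] = np.broadcast_to(
                    np.asarray(env[p], dtype=float), (self.size,)).copy()


# ---------------------------------------------------------------------------
# Event routing


class _EventRoute:
    """CSR fan-out of one (src_set, src_port) edge group."""

    def __init__(self, edge: EdgeGroup, dt: float):
        order = np.argsort(edge.src_indices, kind="stable")
        self.src_sorted = edge.src_indices[order]
        self.dst_sorted = edge.dst_indices[order]
        # round half up: a delay exactly between two steps lands on the later
        self.delay_steps = np.floor(
            edge.delays_ms[order] / dt + 0.5).astype(np.int64)
        self.dst_set = edge.dst_set
        self.dst_port = edge.dst_port
        self.mode = edge.mode

    def fan_out(self, fired: np.ndarray, values: np.ndarray | None):
        """Map fired source indices to (dst_idx, delay_steps, values)."""
        starts = np.searchsorted(self.src_sorted, fired, side="left")
        ends = np.searchsorted(self.src_sorted, fired, side="right")
        counts = ends - starts
        total = int(counts.sum())
        if total == 0:
            return None
        offsets = np.repeat(starts, counts)
        base = np.repeat(np.cumsum(counts) - counts, counts)
        rows = offsets + (np.arange(total) - base)
        dst = self.dst_sorted[rows]
        delays = self.delay_steps[rows]
        vals = np.repeat(values, counts) if values is not None else None
        return dst, delays, vals


def _duplicate_rounds(idx: np.ndarray, values: np.ndarray | None):
    """Split delivery indices into rounds with unique indices each.

    Several messages may reach one instance in the same step (e.g. many
    impulses summing into one post-synapse); handlers are applied round by
    round so sequential semantics hold per instance.
    """
    order = np.argsort(idx, kind="stable")
    s = idx[order]
    sv = values[order] if values is not None else None
    occ = np.arange(s.size) - np.searchsorted(s, s, side="left")
    for k in range(int(occ.max()) + 1 if s.size else 0):
        sel = occ == k
        yield s[sel], (sv[sel] if sv is not None else None)


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class SimState:
    """Exposed snapshot of the engine mid-run (mainly for tests)."""

    t_ms: float
    step: int
    regime_ids: dict[str, np.ndarray]
    states: dict[str, dict[str, np.ndarray]]


class _Engine:
    def __init__(self, flat: FlatModel, exp: Experiment, seed: int = 0):
        diags = validate_experiment(exp, flat)
        errors = [d for d in diags if d.severity == "error"]
        if errors:
            raise ModelError("experiment does not validate", errors)
        self.flat = flat
        self.exp = exp
        self.dt = exp.dt_ms
        self.n_steps = exp.n_steps
        self.runtimes = {name: _SetRuntime(s) for name, s in flat.sets.items()}

        self.analog_edges = []
        self.routes: dict[tuple[str, str], list[_EventRoute]] = {}
        for e in flat.edges:
            if e.mode == "analog":
                self.analog_edges.append(e)
            else:
                self.routes.setdefault((e.src_set, e.src_port), []).append(
                    _EventRoute(e, self.dt))

        # delivery queue: step -> list of (dst_set, dst_port, idx, values)
        self.queue: dict[int, list] = {}

        # input drivers
        self.current_drivers = []
        self.spike_drivers = []
        for i, drv in enumerate(exp.inputs):
            if drv.kind in ("constant_current", "time_varying_current"):
                self.current_drivers.append(drv)
            else:
                rng = np.random.default_rng(
                    [seed % (2**31), drv.seed if drv.seed is not None else i])
                self.spike_drivers.append((drv, rng))

        # explicit spike schedules -> delivery steps
        for drv, _ in self.spike_drivers:
            if drv.kind == "explicit_spike_source":
                rt = self.runtimes[drv.target]
                port_mode = rt.comp.port(drv.port).mode
                for t_spk in drv.spike_times_ms:
                    step = int(math.floor(t_spk / self.dt + 0.5))
                    idx = np.arange(rt.size)
                    vals = (np.full(rt.size, drv.value)
                            if port_mode == "impulse" else None)
                    self.queue.setdefault(step, []).append(
                        (drv.target, drv.port, idx, vals))

        # logging
        self.analog_logs = []  # (log, runtime)
        self.event_hooks: dict[tuple[str, str], list] = {}
        self.log_buffers: dict[str, list] = {}
        for log in exp.logs:
            self.log_buffers[log.name] = []
            rt = self.runtimes[log.target]
            if log.mode == "analog":
                self.analog_logs.append((log, rt))
            else:
                self.event_hooks.setdefault((log.target, log.port), []).append(log)

    # -- emission ---------------------------------------------------------

    def emit(self, src_set: str, src_port: str, fired: np.ndarray,
             values: np.ndarray | None, step: int, t_emit: float) -> None:
        if fired.size == 0:
            return
        for log in self.event_hooks.get((src_set, src_port), ()):
            idx = fired
            if log.indices is not None:
                idx = fired[np.isin(fired, log.indices)]
            if idx.size:
                self.log_buffers[log.name].append(
                    (np.full(idx.size, t_emit), idx.copy()))
        for route in self.routes.get((src_set, src_port), ()):
            out = route.fan_out(fired, values)
            if out is None:
                continue
            dst, delays, vals = out
            target_steps = step + 1 + delays
            if np.all(delays == delays[0]):
                ts = int(target_steps[0])
                if ts < self.n_steps:
                    self.queue.setdefault(ts, []).append(
                        (route.dst_set, route.dst_port, dst, vals))
            else:
                for ts in np.unique(target_steps):
                    if ts >= self.n_steps:
                        continue
                    sel = target_steps == ts
                    self.queue.setdefault(int(ts), []).append(
                        (route.dst_set, route.dst_port, dst[sel],
                         vals[sel] if vals is not None else None))

    def apply_transition(self, rt: _SetRuntime, tr, idx: np.ndarray,
                         extra: dict | None, step: int, t_eval: float) -> None:
        env = rt.sub_env(idx, t_eval, extra)
        try:
            assigned = [(var, evaluate(e, env)) for var, e in tr.state_assignments]
            impulse_vals = [(port, evaluate(e, env))
                            for port, e in tr.impulse_outputs]
        except EvaluationError as exc:
            raise ModelError(
                f"evaluation failed in {rt.name} transition to "
                f"{tr.target_regime!r} at t={t_eval} ms: {exc}") from exc
        for var, val in assigned:
            rt.states[var][idx] = val
        rid = rt.regimes[tr.target_regime]
        changed = rt.regime_ids[idx] != rid
        if changed.any():
            rt.step_transitioned[idx[changed]] = True
        rt.regime_ids[idx] = rid
        for port in tr.event_outputs:
            self.emit(rt.name, port, idx, None, step, t_eval)
        for port, val in impulse_vals:
            self.emit(rt.name, port, idx,
                      np.broadcast_to(np.asarray(val, dtype=float),
                                      idx.shape).copy(),
                      step, t_eval)

    # -- phases -----------------------------------------------------------

    def phase_analog(self, t: float) -> None:
        for rt in self.runtimes.values():
            rt.step_transitioned.fill(False)
            for buf in rt.analog_in.values():
                buf.fill(0.0)
        for e in self.analog_edges:
            src_vals = self.runtimes[e.src_set].analog_out[e.src_port]
            buf = self.runtimes[e.dst_set].analog_in[e.dst_port]
            np.add.at(buf, e.dst_indices, src_vals[e.src_indices])
        for drv in self.current_drivers:
            buf = self.runtimes[drv.target].analog_in[drv.port]
            if drv.kind == "constant_current":
                buf += drv.value
            else:
                val = 0.0
                for t_pt, v in drv.schedule:
                    if t >= t_pt:
                        val = v
                buf += val

    def phase_integrate(self, t: float, step: int) -> None:
        method = self.exp.integrator
        dt = self.dt
        for rt in self.runtimes.values():
            if not rt.has_derivatives or rt.size == 0:
                continue
            base_env = {"t": t}
            base_env.update(rt.params)
            base_env.update(rt.analog_in)
            try:
                if rt.single_regime:
                    regime = rt.comp.regimes[0]
                    new = integrator_step(regime.time_derivatives, rt.states,
                                          base_env, dt, method, rt.aliases)
                    rt.states.update(new)
                else:
                    updates = {}
                    for rid, regime in enumerate(rt.comp.regimes):
                        if not regime.time_derivatives:
                            continue
                        mask = rt.regime_ids == rid
                        if not mask.any():
                            continue
                        new = integrator_step(regime.time_derivatives, rt.states,
                                              base_env, dt, method, rt.aliases)
                        for var in (v for v, _ in regime.time_derivatives):
                            updates.setdefault(var, rt.states[var].copy())
                            updates[var] = np.where(mask, new[var], updates[var])
                    rt.states.update(updates)
            except EvaluationError as exc:
                raise ModelError(
                    f"evaluation failed integrating {rt.name!r} at "
                    f"t={t} ms: {exc}") from exc

    def phase_deliver(self, step: int, t_eval: float) -> None:
        deliveries = self.queue.pop(step, [])
        # poisson sources draw fresh arrivals each step
        for drv, rng in self.spike_drivers:
            if drv.kind != "poisson_spike_source":
                continue
            rt = self.runtimes[drv.target]
            p = drv.rate_hz * self.dt / 1000.0
            idx = np.flatnonzero(rng.random(rt.size) < p)
            if idx.size:
                port_mode = rt.comp.port(drv.port).mode
                vals = (np.full(idx.size, drv.value)
                        if port_mode == "impulse" else None)
                deliveries.append((drv.target, drv.port, idx, vals))
        for dst_set, dst_port, idx, vals in deliveries:
            rt = self.runtimes[dst_set]
            port_mode = rt.comp.port(dst_port).mode
            handlers = rt.handlers.get((port_mode, dst_port), ())
            if not handlers:
                continue
            for u_idx, u_vals in _duplicate_rounds(idx, vals):
                for rid, handler in handlers:
                    if rt.single_regime:
                        sel_idx = u_idx
                        sel_vals = u_vals
                    else:
                        sel = rt.regime_ids[u_idx] == rid
                        if not sel.any():
                            continue
                        sel_idx = u_idx[sel]
                        sel_vals = u_vals[sel] if u_vals is not None else None
                    extra = ({handler.value_symbol: sel_vals}
                             if port_mode == "impulse" else None)
                    self.apply_transition(rt, handler, sel_idx, extra,
                                          step, t_eval)

    def phase_conditions(self, step: int, t_eval: float) -> None:
        for rt in self.runtimes.values():
            if not any(r.on_conditions for r in rt.comp.regimes):
                continue
            transitioned = None
            for rid, regime in enumerate(rt.comp.regimes):
                for cond in regime.on_conditions:
                    env = rt.env(t_eval)
                    try:
                        trig = np.asarray(evaluate(cond.trigger, env))
                    except EvaluationError as exc:
                        raise ModelError(
                            f"trigger evaluation failed in {rt.name!r} regime "
                            f"{regime.name!r} ({cond.trigger.source_text!r}) "
                            f"at t={t_eval} ms: {exc}") from exc
                    mask = (rt.regime_ids == rid) & trig & ~rt.step_transitioned
                    if transitioned is not None:
                        mask &= ~transitioned
                    if not mask.any():
                        continue
                    if transitioned is None:
                        transitioned = np.zeros(rt.size, dtype=bool)
                    transitioned |= mask
                    self.apply_transition(rt, cond, np.flatnonzero(mask),
                                          None, step, t_eval)

    def phase_log(self, t_new: float) -> None:
        for rt in self.runtimes.values():
            rt.snapshot_outputs(t_new)
        for log, rt in self.analog_logs:
            if log.port in rt.analog_out:
                vals = rt.analog_out[log.port]
            else:  # receive-port logging reads this step's input buffer
                vals = rt.analog_in[log.port]
            idx = (np.asarray(log.indices, dtype=np.int64)
                   if log.indices is not None else np.arange(rt.size))
            self.log_buffers[log.name].append(
                (np.full(idx.size, t_new), idx, vals[idx].copy()))

    # -- driver -----------------------------------------------------------

    def run(self) -> LogSet:
        for rt in self.runtimes.values():
            rt.snapshot_outputs(0.0)
        for step in range(self.n_steps):
            t = step * self.dt
            t_post = (step + 1) * self.dt
            self.phase_analog(t)
            self.phase_integrate(t, step)
            self.phase_deliver(step, t_post)
            self.phase_conditions(step, t_post)
            self.phase_log(t_post)
        return self.collect()

    def collect(self) -> LogSet:
        out = LogSet()
        for log in self.exp.logs:
            chunks = self.log_buffers[log.name]
            if log.mode == "analog":
                if chunks:
                    df = pd.DataFrame({
                        "t_ms": np.concatenate([c[0] for c in chunks]),
                        "index": np.concatenate([c[1] for c in chunks]),
                        "value": np.concatenate([c[2] for c in chunks]),
                    })
                else:
                    df = pd.DataFrame(columns=["t_ms", "index", "value"])
            else:
                if chunks:
                    df = pd.DataFrame({
                        "t_ms": np.concatenate([c[0] for c in chunks]),
                        "index": np.concatenate([c[1] for c in chunks]),
                    })
                else:
                    df = pd.DataFrame(columns=["t_ms", "index"])
            df = df.sort_values("t_ms", kind="stable").reset_index(drop=True)
            out.frames[log.name] = df
            out.modes[log.name] = log.mode or "analog"
        return out

    def state(self) -> SimState:
        return SimState(
            t_ms=0.0, step=0,
            regime_ids={n: rt.regime_ids.copy()
                        for n, rt in self.runtimes.items()},
            states={n: {k: v.copy() for k, v in rt.states.items()}
                    for n, rt in self.runtimes.items()},
        )


def simulate(flat: FlatModel, exp: Experiment, seed: int = 0) -> LogSet:
    """Run ``exp`` on the elaborated model; returns the recorded LogSet.

    Executes exactly ceil(duration/dt) steps.  Deterministic for fixed
    (model, experiment, seed); ``seed`` feeds the stochastic input drivers
    only.  Numeric-domain failures abort with the instance set, regime and
    expression named.
    """
    return _Engine(flat, exp, seed).run()
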