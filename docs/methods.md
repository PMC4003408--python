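# Methods

## The model class

`spineml` implements a declarative description of networks of spiking
point neurons as hybrid dynamical systems, split over three XML layers:

* **Component layer.** A `ComponentClass` is a dynamical unit — neuron
  body, weight update, post-synapse, or generic process — defined by
  read-only parameters, state variables, aliases (named expressions),
  communication ports and *regimes*. Each regime carries a set of time
  derivatives dx/dt = f(x, θ, inputs, t); transitions between regimes are
  fired by boolean triggers (`OnCondition`), incoming events (`OnEvent`)
  or incoming impulses, i.e. events carrying a value (`OnImpulse`), and
  may assign state variables and emit events/impulses. Exactly one regime
  is initial. Ports come in three modes: analogue (a value every step;
  the *reduce* variant sums many incoming signals into one), event
  (valueless, instantaneous) and impulse (event + value).
* **Network layer.** Populations of neuron-body instances are connected
  by projections; each synapse couples a connectivity pattern with a
  weight-update component (one instance per connection) and a
  post-synapse component (one instance per destination neuron). The
  low-level extension adds `Group`s (instance sets that are not neuron
  bodies) and generic `Input`s (direct port-to-port connections), which
  is how gap junctions and other non-synaptic communication are wired.
* **Experiment layer.** Simulation duration, step size, integrator,
  external input drivers and log requests.

*Elaboration* expands the declarative network into a flat instance graph:
array-backed instance sets plus directed, delayed (port → port) edges.

## Expression language

All formulae are C-style infix text: `+ − * /`, unary minus, comparisons,
`&& || !`, parentheses, and the functions `exp log ln sin cos sqrt pow
fabs`. The dialect does not pin down a function list, so this set is a
design choice of this package (the common lineage of such model languages
uses C-like strings). Boolean operators are only legal in triggers; the
component validator rejects them in time derivatives and assignments.
Serialisation is fully parenthesised, so parse∘serialize∘parse is the
identity on trees. Arithmetic is IEEE double precision and evaluation is
polymorphic over scalars and numpy arrays — the engine evaluates one
expression per instance *set* per step, not per instance.

## Validation

Component invariants checked: one initial regime; unique names (with one
deliberate exception: an analogue *send* port must carry the same name as
the state variable or alias it exposes, mirroring the NineML-style
convention — receive-port names may not collide with value symbols);
every free symbol resolves to a parameter, state variable, alias,
analogue receive port or the reserved clock `t`; acyclic aliases; at most
one derivative per state variable per regime; transition targets exist;
per-symbol SI dimension strings must come from a fixed lookup table
(`V mV uV A mA uA nA pA S mS uS nS F uF nF pF s ms us Hz none`).
Dimensional consistency of whole expressions is *not* enforced — the
check is a per-symbol lookup, not unit algebra.

Network resolution checks URL loadability, set-name uniqueness,
projection targets, property names, and the mode/direction compatibility
of every port binding in the synaptic chain (pre-neuron → weight update →
post-synapse → destination neuron, plus optional feedback edges).
Elaboration additionally requires every non-reduce analogue receive port
to have exactly one incoming edge.

## Connectivity and properties

Built-in connectivity kinds: `one_to_one` (requires equal sizes),
`all_to_all`, `fixed_probability` (each ordered pair sampled
independently with probability p; self-connections allowed when a set
projects to itself), and explicit `connection_list` (CSV import/export
with columns `src,dst,delay_ms`). New connectivity elements can be
registered by XML element name, mirroring schema substitution groups
without XSD machinery; a registered reader materialises its pairs into a
connection list. The single `Delay` scalar applies per connectivity for
the non-list kinds; connection lists carry per-row delays. The delay
rides on the pre-neuron → weight-update edge.

Property values: fixed, uniform, normal (parameterised by mean and
**variance**, not standard deviation), Poisson (integer counts with the
given mean), or explicit value lists. Indices are 0-based; a partial
value list leaves unlisted instances at the default 0, and a property
not set at all yields an all-zero vector. Every stochastic draw is
seeded: an embedded per-element seed wins, otherwise a seed is derived
deterministically from the elaboration seed and the (set, property)
name, so a fixed (model, seed) pair elaborates to bitwise-identical
arrays and edge lists.

## Engine semantics

The step order is a design choice of this engine (the dialect leaves it
open, and cross-simulator traces are expected to diverge numerically):

1. **Analogue propagation.** Edges copy each send port's value *as
   computed at the end of the previous step* (synchronous-update
   contract); reduce ports sum arrivals and are zero-filled when nothing
   arrives; current drivers add onto the buffers.
2. **Integration** of the active regime's derivatives (forward Euler or
   classical RK4; within an RK4 step, inputs are held constant).
   Variables without a derivative in the current regime are held.
3. **Delivery** of due events/impulses; handlers run against the
   recipients' current regimes. Several messages reaching one instance
   in the same step are applied sequentially (round-by-round), so e.g.
   coincident impulses all accumulate into a post-synaptic current.
4. **Conditions.** Triggers are evaluated on the post-integration state
   at time t+dt; the first true trigger in document order wins, its
   state assignments are evaluated simultaneously against pre-assignment
   values, outputs are emitted, and the regime switches. At most one
   regime switch per instance per step, counting handler-driven
   switches from phase 3.
5. The clock advances; post-step values are snapshotted and logged.

An output emitted at step n carries emission time (n+1)·dt and is
delivered at step (n+1) + ⌊delay/dt + 0.5⌋ (round half *up*); zero-delay
messages therefore arrive in the next step's phase 3. Ties among
simultaneously true conditions are broken by document order. Messages
scheduled beyond the end of the run are dropped; anything scheduled
inside it is delivered exactly once.

Numeric-domain failures (unbound symbol, log of a non-positive value,
division by zero) abort the run with the instance set, regime and
expression named. Degenerate but legal inputs — empty connectivity,
size-0 weight-update sets, experiments with no inputs — simulate cleanly.

### Input drivers and logs

Current drivers (constant or piecewise-constant schedules) add to
analogue receive buffers each step. Spike drivers (Poisson per instance,
or explicit time lists) are delivered through phase 3 like internal
events; when the target port is an impulse port the driver's `value`
field is the carried amplitude. A log request records either event times
(`t_ms,index` CSV) or per-step values (`t_ms,index,value` CSV); an
optional `indices` attribute restricts recording to chosen instances so
that long runs need not log whole populations.

## Fixture components

* **LIF**: two regimes. `integrating` (initial) evolves
  dv/dt = (I_Syn + i_offset)/c_m + (v_rest − v)/tau_m; when v > v_thresh
  it resets v, stores t_spike = t, emits `spike`, and enters
  `refractory`, which holds all state until t > t_spike + tau_refractory
  (expressed through the alias `refractory_end`). Closed form for
  constant suprathreshold current I:
  ISI = tau_ref + tau_m·ln((v_inf − v_reset)/(v_inf − v_thresh)) with
  v_inf = v_rest + (I/c_m)·tau_m — used as the simulation oracle.
* **FixedWeight**: a spike event in, an impulse of the weight w out.
* **ExpPSC**: dI_Syn/dt = −I_Syn/tau_syn; each impulse increments I_Syn
  by its value. Closed form w·exp(−Δt/tau_syn) is the decay oracle.
* **GapJunction**: analogue inputs v_pre, v_post, alias-backed outputs
  I_pre = g·(v_post − v_pre) and I_post = −I_pre. Anti-symmetry and the
  vanishing current at equal potentials are exact properties.

Units: mV, ms, nA, nF, uS — chosen so that I/c_m and g·Δv/c_m both land
in mV/ms without conversion factors.

## Benchmark network

`BenchmarkSpec` builds the classic sparse excitatory/inhibitory
benchmark in its current-based form: 4000 neurons (80 % excitatory),
fixed-probability connectivity p = 0.02 between and within populations,
LIF bodies with tau_m = 20 ms, v_thresh = −50 mV, v_reset = −60 mV,
tau_ref = 5 ms and a leak reversal of −49 mV (just above threshold, so
activity is self-sustaining and no external drive is needed), delta
current impulses of +0.081 nA (exc, tau_syn = 5 ms) and −0.45 nA (inh,
tau_syn = 10 ms), initial v ~ U(−60, −50) mV, uniform 0.1 ms delays.
The numbers are configuration, not normative: the weights are the
widely-used voltage-jump values divided by tau_m to convert the
voltage-kick convention into this package's current-impulse convention.
A 1 s run at dt = 0.1 ms elaborates ~650 k bindings and completes in
well under a minute on one core.

Spike statistics (`spike_stats`) compute per-instance inter-spike
intervals after an optional equilibration discard (default 0 in unit
tests, 1000 ms recommended for long benchmark analyses), CV =
std(ISI)/mean(ISI), and mean rates over the effective window; instances
with fewer than two retained spikes are excluded from the CV and
counted.

## What the synthetic models do and do not show

All test inputs are generated programmatically; there are no recorded
datasets. The fixtures exercise the declared semantics exactly — regime
algebra, routing, delays, reductions, determinism — and the physical
oracles (LIF period, exponential decay, binomial connection counts,
integrator convergence orders) validate the numerics. They do not
establish biological realism of any particular parameterisation, nor
numerical agreement with other simulators beyond the convergence orders
shown: cross-simulator traces of chaotic network activity diverge after
a short time for any fixed-step scheme.

## Known limitations

* Only `sum` is supported as a reduce operator (the schema field is
  reserved for alternatives).
* Plastic weight updates with continuous dynamics are expressible but
  untested; distance-based and CSA connectivity are left to the plug-in
  registry.
* Whole-expression dimensional analysis is out of scope (per-symbol unit
  lookup only).
* The engine logs post-step values; tools expecting pre-integration
  logging will see a one-step offset.
* Per-regime derivative evaluation computes candidate updates over the
  full instance array and applies them under the regime mask; expressions
  whose domain depends on the regime (e.g. a log only valid in one
  regime) may raise spurious domain errors.
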