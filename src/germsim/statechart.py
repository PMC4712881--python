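"""Generic hierarchical statechart machinery.

A chart is a set of orthogonal *regions*, each holding a flat set of states
and guarded transitions between them.  Every region has exactly one active
state at any time.  Within a simulation step, regions update independently
against a frozen snapshot of the cell's configuration, so the update order
of regions cannot influence the result.  Within one region, transitions may
chain ("eager" semantics: an enabled transition fires immediately), up to a
fixed hop limit that guards against mis-specified charts.

Guards are pure predicates over a :class:`CellContext` plus a read-only
view of the instance (elapsed timer, sampled phase durations, the frozen
active configuration).  Actions are named effects looked up in the chart's
action registry; the stock actions emit events (division, death, fate
commitment, ...) and sample phase durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

#: Maximum number of chained transitions one region may take in a single step.
CHAIN_LIMIT = 8


class StatechartError(Exception):
    """Malformed chart or guard cycle (chain limit exceeded)."""


@dataclass(frozen=True)
class CellContext:
    """Frozen per-step snapshot of everything a guard may read.

    Attributes
    ----------
    time_hph:
        Simulation clock, hours post-hatch.
    dtc_distance_um:
        Arclength distance from the distal tip cell along the gonad path.
    volume_fraction:
        Compressed volume over rest volume, in (0, 1].
    radius_um:
        Current cell radius.
    life_stage:
        One of ``"larval"``, ``"transition"``, ``"adult"``.
    rng:
        Random source for stochastic guards (apoptosis); consumed in a
        deterministic per-cell order by the simulation loop.
    dt_h:
        Length of the step being taken, needed to convert per-hour hazards
        into per-step probabilities.
    """

    time_hph: float
    dtc_distance_um: float
    volume_fraction: float = 1.0
    radius_um: float = 2.7
    life_stage: str = "larval"
    rng: object = None
    dt_h: float = 0.0


@dataclass
class StateNode:
    name: str
    region: str
    entry_actions: tuple = ()
    during_actions: tuple = ()
    #: optional predicate (ctx, view) -> bool; while true the state's timer
    #: does not advance (used for the compression arrest of G2).
    timer_freeze: Optional[Callable] = None


@dataclass
class TransitionRule:
    source: str
    target: str
    guard: Callable  # (ctx, view) -> bool
    actions: tuple = ()
    label: str = ""


@dataclass
class Region:
    name: str
    states: dict  # name -> StateNode
    transitions: list  # of TransitionRule, document order = priority order
    initial_state: Optional[str] = None

    def __post_init__(self):
        for tr in self.transitions:
            if tr.source not in self.states or tr.target not in self.states:
                raise StatechartError(
                    f"transition {tr.source}->{tr.target} references unknown "
                    f"state in region {self.name!r}"
                )
        self._by_source = {}
        for tr in self.transitions:
            self._by_source.setdefault(tr.source, []).append(tr)

    def outgoing(self, state: str):
        return self._by_source.get(state, ())


class Chart:
    """A full statechart: regions + action registry + duration samplers."""

    def __init__(self, regions, actions=None, samplers=None, cycle_phases=()):
        self.regions = {r.name: r for r in regions}
        if len(self.regions) != len(regions):
            raise StatechartError("duplicate region names")
        #: action name -> callable(instance, ctx, events)
        self.actions = dict(actions or {})
        #: phase name -> callable(ctx, rng) -> duration (hours)
        self.samplers = dict(samplers or {})
        #: phases whose durations are freshly resampled on division
        self.cycle_phases = tuple(cycle_phases)

    def initial_instance(self):
        active = {}
        for name, region in self.regions.items():
            if region.initial_state is not None:
                active[name] = region.initial_state
        return StatechartInstance(
            active=active,
            timers={name: 0.0 for name in self.regions},
            sampled_durations={},
        )

    def run_actions(self, names, inst, ctx, events):
        for name in names:
            try:
                fn = self.actions[name]
            except KeyError:
                raise StatechartError(f"unknown action {name!r}")
            fn(inst, ctx, events)

    def describe(self) -> str:
        """One line per region: states, transitions and guard labels."""
        lines = []
        for region in self.regions.values():
            parts = [
                f"{t.source}->{t.target}[{t.label or t.guard.__name__}]"
                for t in region.transitions
            ]
            lines.append(
                f"{region.name}: states={sorted(region.states)} "
                f"init={region.initial_state} " + " ".join(parts)
            )
        return "\n".join(lines)


@dataclass
class StatechartInstance:
    """Active configuration of one cell across all orthogonal regions."""

    active: dict  # region name -> state name
    timers: dict  # region name -> hours elapsed in the active state
    sampled_durations: dict  # phase name -> hours

    def copy(self):
        return StatechartInstance(
            active=dict(self.active),
            timers=dict(self.timers),
            sampled_durations=dict(self.sampled_durations),
        )


class GuardView:
    """Read-only view handed to guards and timer-freeze predicates.

    ``state_of`` reports the frozen start-of-step configuration for other
    regions, and the region's own current state while it chains.
    """

    __slots__ = ("_frozen", "_region", "state", "timer", "durations")

    def __init__(self, frozen, region, state, timer, durations):
        self._frozen = frozen
        self._region = region
        self.state = state
        self.timer = timer
        self.durations = durations

    def state_of(self, region: str) -> str:
        if region == self._region:
            return self.state
        return self._frozen[region]

    def in_state(self, region: str, name: str) -> bool:
        return self.state_of(region) == name


def step_statechart(inst: StatechartInstance, chart: Chart, ctx: CellContext,
                    dt: float):
    """Advance one cell's statechart by ``dt`` hours.

    Mutates ``inst`` in place and returns the list of emitted events
    (tuples whose first element is the event kind).  For each region the
    first enabled transition in document order fires; chaining continues
    until quiescent or :data:`CHAIN_LIMIT` hops.  Timers advance by ``dt``
    only in regions whose state did not change (and are not frozen), and
    reset to zero on state entry.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    events: list = []
    frozen = dict(inst.active)
    for rname, region in chart.regions.items():
        state = inst.active.get(rname)
        if state is None:
            raise StatechartError(f"region {rname!r} has no active state")
        if state not in region.states:
            raise StatechartError(f"unknown state {state!r} in region {rname!r}")
        timer = inst.timers[rname]
        durations = inst.sampled_durations
        # the elapsed time accrues before guards are evaluated, so a phase
        # of duration D lasts ceil(D/dt) steps rather than one extra
        node = region.states[state]
        frozen_timer = node.timer_freeze is not None and node.timer_freeze(
            ctx, GuardView(frozen, rname, state, timer, durations))
        if not frozen_timer:
            timer += dt
        for hop in range(CHAIN_LIMIT + 1):
            view = GuardView(frozen, rname, state, timer, durations)
            taken = None
            for tr in region.outgoing(state):
                if tr.guard(ctx, view):
                    taken = tr
                    break
            if taken is None:
                break
            if hop == CHAIN_LIMIT:
                raise StatechartError(
                    f"chain limit exceeded in region {rname!r} "
                    f"(last state {state!r}): guard cycle in chart?"
                )
            chart.run_actions(taken.actions, inst, ctx, events)
            state = taken.target
            timer = 0.0
            node = region.states[state]
            chart.run_actions(node.entry_actions, inst, ctx, events)
        if node.during_actions:
            chart.run_actions(node.during_actions, inst, ctx, events)
        inst.active[rname] = state
        inst.timers[rname] = timer
    return events


def fork_on_division(parent: StatechartInstance, chart: Chart,
                     ctx: CellContext, rng):
    """Split a dividing cell's statechart into two daughter instances.

    Both daughters inherit the parent's active configuration; all phase
    timers reset to zero and the cell-cycle phase durations are freshly and
    independently resampled for each daughter (avoiding synchronized
    sibling cycles).
    """
    daughters = []
    for _ in range(2):
        d = parent.copy()
        for rname in d.timers:
            d.timers[rname] = 0.0
        for phase in chart.cycle_phases:
            sampler = chart.samplers.get(phase)
            if sampler is not None:
                d.sampled_durations[phase] = sampler(ctx, rng)
        daughters.append(d)
    return daughters[0], daughters[1]
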