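"""The germ-cell statechart: cell cycle, GLP-1/Notch response, sex fate.

Five orthogonal regions drive each germ cell:

``CellCycle``
    G1 -> S -> G2 -> M, with G1 and G2 durations drawn from a normal
    distribution N(mu, (s*mu)^2) (s = 0.1) to desynchronize the tissue, and
    S/M fixed at their means.  A division event is emitted on entry into M;
    daughters inherit M and finish it before their own G1.  Cells may leave
    the mitotic cycle only from G1, and only while the GLD pathways are
    active; they then pass through a fixed-length premeiotic G1 and meiotic
    S before settling in meiotic prophase.  In adults, G2 progress is
    frozen while the cell is compressed below 70% of its rest volume
    (contact-inhibition feedback).

``GLP1Receptor`` / ``LAG1`` / ``GLD``
    A threshold caricature of DTC signaling: the receptor binds ligand
    within 35 um of the DTC and loses signal at >= 70 um; LAG-1 follows the
    receptor and the GLD-1/GLD-2 pathways activate when LAG-1 shuts off,
    licensing meiotic entry.  Between 35 and 70 um a bound receptor stays
    bound (hysteresis).

``SexDetermination``
    Precursors commit on reaching 200 um from the DTC: sperm-fated before
    32.5 hph, oocyte-fated at or after it.  Sperm-fated cells divide twice
    (after a short delay each) producing four sperm.  Oocyte-fated cells
    grow, mature at 10 um radius, and while immature in adults risk
    apoptosis at rate P per hour until they reach the proximal gonad
    (>= 250 um from the DTC), after which they are committed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .statechart import (CellContext, Chart, Region, StateNode,
                         TransitionRule)

# State-name constants
MITOTIC_PHASES = ("G1", "S", "G2", "M")
MEIOTIC_STATES = ("NonProliferative", "MeioticS", "MeioticProphase")
CYCLE_REGION = "CellCycle"
GLP1_REGION = "GLP1Receptor"
LAG1_REGION = "LAG1"
GLD_REGION = "GLD"
SEX_REGION = "SexDetermination"


@dataclass
class CellCycleParams:
    """Cell-cycle timing.  Totals are 3 h (larval) and 8 h (adult); the
    split across phases is a free choice (G1 is very short in this system)
    and only the totals are biologically pinned."""

    total_cycle_larval_h: float = 3.0
    total_cycle_adult_h: float = 8.0
    frac_G1: float = 0.05
    frac_S: float = 0.50
    frac_G2: float = 0.35
    frac_M: float = 0.10
    s: float = 0.1  # phase-length coefficient of variation for G1 and G2
    fixed_meiotic_G1_h: float = 0.5
    fixed_meiotic_S_h: float = 3.0
    arrest_volume_fraction: float = 0.70
    #: larval->adult parameter ramp window (hours post-hatch); filled in
    #: from the stage schedule by the configuration layer.
    ramp_start_hph: float = 29.5
    ramp_end_hph: float = 34.0

    def __post_init__(self):
        fr = self.frac_G1 + self.frac_S + self.frac_G2 + self.frac_M
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if not (0 < self.arrest_volume_fraction < 1):
            raise ValueError("arrest_volume_fraction must be in (0,1)")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        for v in (self.total_cycle_larval_h, self.total_cycle_adult_h,
                  self.fixed_meiotic_G1_h, self.fixed_meiotic_S_h):
            if v <= 0:
                raise ValueError("durations must be positive")

    def total_cycle_h(self, time_hph: float) -> float:
        """Expected total cycle length at clock time, with a linear ramp
        from the larval to the adult value across the mid-L4->adult window."""
        t0, t1 = self.ramp_start_hph, self.ramp_end_hph
        if time_hph <= t0:
            return self.total_cycle_larval_h
        if time_hph >= t1:
            return self.total_cycle_adult_h
        w = (time_hph - t0) / (t1 - t0)
        return (1 - w) * self.total_cycle_larval_h + w * self.total_cycle_adult_h

    def phase_mean_h(self, phase: str, time_hph: float) -> float:
        frac = {"G1": self.frac_G1, "S": self.frac_S,
                "G2": self.frac_G2, "M": self.frac_M}[phase]
        return frac * self.total_cycle_h(time_hph)


@dataclass
class SignalingParams:
    bound_threshold_um: float = 35.0
    absent_threshold_um: float = 70.0

    def __post_init__(self):
        if not (0 < self.bound_threshold_um < self.absent_threshold_um):
            raise ValueError("need 0 < bound threshold < absent threshold")


@dataclass
class FateParams:
    sex_decision_distance_um: float = 200.0
    sperm_time_threshold_hph: float = 32.5
    sperm_division_delay_h: float = 1.0
    max_meiotic_radius_um: float = 4.0
    oocyte_mature_radius_um: float = 10.0
    meiotic_growth_rate_um_per_h: float = 0.1
    oocyte_growth_rate_um_per_h: float = 0.15
    apoptosis_prob_per_h: float = 0.3
    proximal_protect_distance_um: float = 250.0
    sperm_radius_um: float = 1.5

    def __post_init__(self):
        if not (0 <= self.apoptosis_prob_per_h <= 1):
            raise ValueError("apoptosis probability must be in [0,1]")
        if self.oocyte_mature_radius_um <= self.max_meiotic_radius_um:
            raise ValueError("oocyte mature radius must exceed meiotic cap")
        for v in (self.sex_decision_distance_um, self.proximal_protect_distance_um,
                  self.max_meiotic_radius_um, self.oocyte_mature_radius_um):
            if v <= 0:
                raise ValueError("radii and distances must be positive")


def sample_phase_duration(mean: float, s: float, rng) -> float:
    """Draw one phase duration from N(mean, (s*mean)^2), clamped below at
    0.01*mean so a tail draw can never be zero or negative."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if s == 0:
        return mean
    draw = rng.normal(mean, s * mean)
    return max(0.01 * mean, draw)


def contact_inhibition_guard(ctx: CellContext, cc: CellCycleParams) -> bool:
    """True (arrest) iff an *adult* cell is compressed below the arrest
    threshold.  Larval cells are never arrested."""
    return (ctx.life_stage == "adult"
            and ctx.volume_fraction < cc.arrest_volume_fraction)


def decide_sex_fate(ctx: CellContext, fate: FateParams) -> str:
    """Sperm before the time threshold, oocyte at or after it.  Only
    meaningful once the cell has reached the decision distance."""
    if ctx.dtc_distance_um < fate.sex_decision_distance_um:
        raise ValueError("cell has not reached the sex-decision distance")
    if ctx.time_hph < fate.sperm_time_threshold_hph:
        return "sperm_fated"
    return "oocyte_fated"


def grow_cell(radius: float, cycle_state: str, sex_state: str,
              fate: FateParams, dt: float) -> float:
    """Radius update for one step: meiotic (non-oocyte) cells grow to the
    4 um cap, oocyte-fated cells to the 10 um maturity radius, mitotic
    cells and sperm do not grow."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if sex_state in ("OocyteFated", "MatureOocyte"):
        return min(fate.oocyte_mature_radius_um,
                   radius + fate.oocyte_growth_rate_um_per_h * dt)
    if cycle_state in MEIOTIC_STATES and sex_state in (
            "Precursor", "SpermFated1", "SpermFated2"):
        return min(fate.max_meiotic_radius_um,
                   radius + fate.meiotic_growth_rate_um_per_h * dt)
    return radius


def apoptosis_step_probability(p_per_h: float, dt: float) -> float:
    """Geometric-hazard conversion of a per-hour death probability to a
    per-step probability, so outcomes are step-size invariant."""
    return 1.0 - (1.0 - p_per_h) ** dt


def apoptosis_draw(ctx: CellContext, fate: FateParams, dt: float, rng) -> bool:
    """One apoptosis lottery for an immature oocyte-fated cell.

    Death is only possible in adults, and only while the cell has not yet
    reached the proximal gonad (dtc distance < 250 um); beyond that cells
    are committed to becoming mature gametes and never die.
    """
    if ctx.life_stage != "adult":
        return False
    if ctx.dtc_distance_um >= fate.proximal_protect_distance_um:
        return False
    p = apoptosis_step_probability(fate.apoptosis_prob_per_h, dt)
    if p <= 0:
        return False
    if p >= 1:
        return True
    return rng.random() < p


def build_germline_chart(cc: CellCycleParams, sig: SignalingParams,
                         fate: FateParams,
                         contact_inhibition_enabled: bool = True) -> Chart:
    """Assemble the five-region germ-cell chart."""

    # ---- duration samplers (consume the cell's rng via ctx) -------------
    def _sampler(phase, stochastic):
        def sample(ctx, rng):
            mean = cc.phase_mean_h(phase, ctx.time_hph)
            return sample_phase_duration(mean, cc.s if stochastic else 0.0, rng)
        sample.__name__ = f"sample_{phase}"
        return sample

    samplers = {
        "G1": _sampler("G1", True),
        "S": _sampler("S", False),
        "G2": _sampler("G2", True),
        "M": _sampler("M", False),
    }

    # ---- actions --------------------------------------------------------
    def make_sample_action(phase):
        def act(inst, ctx, events):
            inst.sampled_durations[phase] = samplers[phase](ctx, ctx.rng)
        return act

    def emit(kind):
        def act(inst, ctx, events):
            events.append((kind,))
        return act

    actions = {
        "sample_G1": make_sample_action("G1"),
        "sample_S": make_sample_action("S"),
        "sample_G2": make_sample_action("G2"),
        "sample_M": make_sample_action("M"),
        "emit_division": emit("division"),
        "emit_meiotic_entry": emit("meiotic_entry"),
        "emit_fate_sperm": emit("fate_sperm"),
        "emit_fate_oocyte": emit("fate_oocyte"),
        "emit_mature_oocyte": emit("mature_oocyte"),
        "emit_death": emit("death"),
    }

    # ---- guards ---------------------------------------------------------
    def timer_done(phase):
        def g(ctx, view):
            return view.timer >= view.durations[phase]
        g.__name__ = f"timer>=dur({phase})"
        return g

    def fixed_timer_done(duration):
        def g(ctx, view):
            return view.timer >= duration
        g.__name__ = f"timer>={duration}h"
        return g

    def meiotic_entry_allowed(ctx, view):
        # GLD pathways on *and* outside the 70 um exclusion zone: cells may
        # never enter meiosis within signaling range of the DTC, even if
        # crowding jitters an already-committed cell back across the line
        return (view.in_state(GLD_REGION, "Active")
                and ctx.dtc_distance_um >= sig.absent_threshold_um)

    def receptor_in_range(ctx, view):
        return ctx.dtc_distance_um < sig.bound_threshold_um

    def signal_lost(ctx, view):
        return ctx.dtc_distance_um >= sig.absent_threshold_um

    def glp1_bound(ctx, view):
        return view.in_state(GLP1_REGION, "Bound")

    def glp1_absent(ctx, view):
        return view.in_state(GLP1_REGION, "Absent")

    def lag1_off(ctx, view):
        return view.in_state(LAG1_REGION, "Inactive")

    def lag1_on(ctx, view):
        return view.in_state(LAG1_REGION, "Active")

    def at_sex_decision_sperm(ctx, view):
        return (ctx.dtc_distance_um >= fate.sex_decision_distance_um
                and ctx.time_hph < fate.sperm_time_threshold_hph)

    def at_sex_decision(ctx, view):
        return ctx.dtc_distance_um >= fate.sex_decision_distance_um

    def oocyte_mature(ctx, view):
        return ctx.radius_um >= fate.oocyte_mature_radius_um

    def apoptosis_guard(ctx, view):
        return apoptosis_draw(ctx, fate, ctx.dt_h, ctx.rng)

    def g2_frozen(ctx, view):
        return (contact_inhibition_enabled
                and contact_inhibition_guard(ctx, cc))

    # ---- regions --------------------------------------------------------
    cell_cycle = Region(
        name=CYCLE_REGION,
        states={
            "G1": StateNode("G1", CYCLE_REGION, entry_actions=("sample_G1",)),
            "S": StateNode("S", CYCLE_REGION, entry_actions=("sample_S",)),
            "G2": StateNode("G2", CYCLE_REGION, entry_actions=("sample_G2",),
                            timer_freeze=g2_frozen),
            "M": StateNode("M", CYCLE_REGION,
                           entry_actions=("sample_M", "emit_division")),
            "NonProliferative": StateNode(
                "NonProliferative", CYCLE_REGION,
                entry_actions=("emit_meiotic_entry",)),
            "MeioticS": StateNode("MeioticS", CYCLE_REGION),
            "MeioticProphase": StateNode("MeioticProphase", CYCLE_REGION),
        },
        transitions=[
            # meiotic exit takes priority over cycling, and is possible
            # only from G1 while the GLD pathways are active
            TransitionRule("G1", "NonProliferative", meiotic_entry_allowed,
                           label="GLD active & d>=70um"),
            TransitionRule("G1", "S", timer_done("G1"), label="G1 elapsed"),
            TransitionRule("S", "G2", timer_done("S"), label="S elapsed"),
            TransitionRule("G2", "M", timer_done("G2"), label="G2 elapsed"),
            TransitionRule("M", "G1", timer_done("M"), label="M elapsed"),
            TransitionRule("NonProliferative", "MeioticS",
                           fixed_timer_done(cc.fixed_meiotic_G1_h),
                           label="premeiotic G1 elapsed"),
            TransitionRule("MeioticS", "MeioticProphase",
                           fixed_timer_done(cc.fixed_meiotic_S_h),
                           label="meiotic S elapsed"),
        ],
        initial_state=None,  # randomized externally at initialization
    )

    glp1 = Region(
        name=GLP1_REGION,
        states={
            "Unbound": StateNode("Unbound", GLP1_REGION),
            "Bound": StateNode("Bound", GLP1_REGION),
            "Absent": StateNode("Absent", GLP1_REGION),
        },
        transitions=[
            TransitionRule("Unbound", "Bound", receptor_in_range,
                           label="d<35um"),
            TransitionRule("Bound", "Absent", signal_lost, label="d>=70um"),
        ],
        initial_state="Bound",  # all founders sit within signaling range
    )

    lag1 = Region(
        name=LAG1_REGION,
        states={
            "Active": StateNode("Active", LAG1_REGION),
            "Inactive": StateNode("Inactive", LAG1_REGION),
        },
        transitions=[
            TransitionRule("Inactive", "Active", glp1_bound,
                           label="GLP-1 bound"),
            TransitionRule("Active", "Inactive", glp1_absent,
                           label="GLP-1 absent"),
        ],
        initial_state="Active",
    )

    gld = Region(
        name=GLD_REGION,
        states={
            "Inactive": StateNode("Inactive", GLD_REGION),
            "Active": StateNode("Active", GLD_REGION),
        },
        transitions=[
            TransitionRule("Inactive", "Active", lag1_off, label="LAG-1 off"),
            TransitionRule("Active", "Inactive", lag1_on, label="LAG-1 on"),
        ],
        initial_state="Inactive",
    )

    sex = Region(
        name=SEX_REGION,
        states={
            "Precursor": StateNode("Precursor", SEX_REGION),
            "SpermFated1": StateNode("SpermFated1", SEX_REGION,
                                     entry_actions=("emit_fate_sperm",)),
            "SpermFated2": StateNode("SpermFated2", SEX_REGION,
                                     entry_actions=("emit_division",)),
            "Sperm": StateNode("Sperm", SEX_REGION,
                               entry_actions=("emit_division",)),
            "OocyteFated": StateNode("OocyteFated", SEX_REGION,
                                     entry_actions=("emit_fate_oocyte",)),
            "MatureOocyte": StateNode("MatureOocyte", SEX_REGION,
                                      entry_actions=("emit_mature_oocyte",)),
            "Dying": StateNode("Dying", SEX_REGION,
                               entry_actions=("emit_death",)),
        },
        transitions=[
            # document order resolves the tie at exactly 32.5 hph to oocyte
            TransitionRule("Precursor", "SpermFated1", at_sex_decision_sperm,
                           label="d>=200um & t<32.5hph"),
            TransitionRule("Precursor", "OocyteFated", at_sex_decision,
                           label="d>=200um"),
            TransitionRule("SpermFated1", "SpermFated2",
                           fixed_timer_done(fate.sperm_division_delay_h),
                           label="delay elapsed"),
            TransitionRule("SpermFated2", "Sperm",
                           fixed_timer_done(fate.sperm_division_delay_h),
                           label="delay elapsed"),
            TransitionRule("OocyteFated", "MatureOocyte", oocyte_mature,
                           label="radius>=10um"),
            TransitionRule("OocyteFated", "Dying", apoptosis_guard,
                           label="apoptosis draw (adult, d<250um)"),
        ],
        initial_state="Precursor",
    )

    return Chart(
        regions=[cell_cycle, glp1, lag1, gld, sex],
        actions=actions,
        samplers=samplers,
        cycle_phases=MITOTIC_PHASES,
    )


def randomize_cycle_phase(inst, chart: Chart, ctx: CellContext, rng):
    """Start a founder cell at a uniformly random point of the mitotic
    cycle: the phase is chosen with probability proportional to its
    expected duration and the elapsed time uniform within the phase."""
    durations = {p: chart.samplers[p](ctx, rng) for p in MITOTIC_PHASES}
    total = sum(durations.values())
    u = rng.random() * total
    acc = 0.0
    for phase in MITOTIC_PHASES:
        acc += durations[phase]
        if u <= acc:
            break
    inst.active[CYCLE_REGION] = phase
    inst.sampled_durations.update(durations)
    elapsed = rng.random() * durations[phase]
    inst.timers[CYCLE_REGION] = elapsed
    return inst
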