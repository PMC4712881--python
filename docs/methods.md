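# Methods

`germsim` simulates one hermaphrodite gonad arm of *C. elegans* from the
end of L2 through adulthood, combining center-based sphere mechanics with
a per-cell hierarchical statechart ("mechano-logical" modeling). This
note records the model, its assumptions, the parameters that matter, and
the choices made where the design was genuinely open.

## Cell mechanics

Germ cells are deformable spheres with positions in 3D. Overlapping
pairs repel along the line of centers with a linear overlap spring,
`F = k * delta`, where `delta = r_i + r_j - d` is the overlap. Motion is
overdamped (no inertia): `x <- x + (F / drag) * dt_mech`, forward Euler.
The linear spring is the standard choice for this class of center-based
model; the stiffness `k` (default 60 force/µm) and the drag (1
force·h/µm, identical for all cells) are calibration parameters — only
`k·dt/drag` is identifiable, so drag is fixed at 1 and `k` absorbs the
scale. Each simulation step of `dt = 0.02 h` runs several mechanics
substeps (`dt_mech = 0.0025 h`), and the boundary constraints are
re-applied after every substep. A safety check aborts if any cell would
move more than half its own radius in one substep, which signals an
unstable stiffness/time-step combination rather than silently letting
cells tunnel through each other. (The check is per cell: a global
smallest-radius bound would be meaningless once 1.5 µm sperm coexist
with 10 µm oocytes.)

Compression is measured geometrically: the compressed volume of a cell
is its rest volume minus one spherical cap per overlapping neighbor, cut
at the radical plane of the two spheres (for equal radii this is the
plane through the lens midpoint). The result is clamped below at 5% of
the rest volume. Caps are treated as disjoint (their volumes add); the
approximation is validated against Monte Carlo integration in the test
suite for two- and three-neighbor configurations. Neighbor search uses
a k-d tree (`scipy.spatial.cKDTree`), checked against the all-pairs scan.

## Gonad geometry

The gonad boundary is a tube of radius `r(t)` around the path traced by
the distal tip cell (DTC). The DTC starts at the proximal origin,
migrates along the distal axis at a stage-dependent prescribed rate,
turns through a semicircle at a prescribed time (24 hph by default), and
returns antiparallel. Cells live at path arclengths `s ∈ [0,
dtc_arclength]`; every distance used by the statechart is the arclength
distance to the DTC, which is what row counts "in cell diameters from
the distal tip" measure in vivo and which behaves correctly around the
turn. Migration pauses whenever the DTC would pull more than one cell
diameter ahead of the distal-most germ cell. Because the turn time is
prescribed, a paused DTC turns closer to the center of the animal.

Three constraints act on cells each substep: the tube
(`rho + radius <= r(t)`), the rachis (cells in the distal arm and turn
are kept lining the tube wall, `rho >= r(t) - 2·radius`, leaving a
hollow core), and the tip/end caps (`0 <= s <= dtc_arclength`). The
tube radius follows a piecewise-linear schedule (9 µm at simulation
start to 12.5 µm in the adult — a desk-scale choice, see below). The
turn radius (13 µm) is deliberately larger than the adult tube radius so
the two limbs of the U never overlap in space; if they did, cells could
"tunnel" between limbs and carry distal signaling state into the
proximal arm.

Late-L4 stretching translates the turn away from the center at a
constant rate inside a configurable window. Both limbs lengthen by the
turn displacement, so the total path length grows by twice the
displacement. How cells are advected was an open choice: cells proximal
of the turn move with the stretching frame (they spread apart as the
proximal region lengthens), cells in the turn translate with it, and
cells on the distal limb keep their arclength distance to the DTC — they
do not move in space at all, and the new room opens just distal of the
turn, where cells then flow to fill it. The alternative (stretching the
distal limb affinely as well) dilutes the stem-cell zone and empties the
space behind the DTC, which both contradicts the observed cell flow
toward the turn during stretching and leaves the adult tissue tens of
hours from packing equilibrium.

## The germ-cell statechart

Each cell carries a statechart with five orthogonal regions; one state
per region is active at all times. Within a step, regions update
independently against a frozen snapshot of the configuration (so region
order is irrelevant); within a region, enabled transitions fire eagerly
and may chain, up to a hop limit of 8 that catches mis-wired guard
cycles. When several guards are true simultaneously, document order of
the transition list decides — a fixed rule that keeps runs reproducible.

* **CellCycle** — G1 → S → G2 → M; a division event is emitted on entry
  into M; both daughters inherit the parent's configuration (M with a
  fresh timer), finish M, and start their own G1. G1 and G2 durations
  are drawn from `N(mu, (s·mu)^2)` with `s = 0.1` to desynchronize the
  tissue; S and M are fixed at their means; draws are clamped below at
  1% of the mean. Phase means are fractions (5/50/35/10%) of the stage
  total — 3 h in larvae, 8 h in adults, ramped linearly from mid-L4 to
  adulthood. Cells leave the cycle only from G1, only while the GLD
  pathways are active, and only at ≥ 70 µm from the DTC; they then pass a
  fixed premeiotic G1 (0.5 h) and meiotic S (3 h) before meiotic
  prophase. Emitting the division at the M/G1 boundary (rather than
  having daughters restart in G1 immediately) keeps the realized
  generation time equal to G1+S+G2+M, i.e. to the published stage
  totals, which the test suite verifies to 2%.
* **GLP1Receptor / LAG1 / GLD** — the threshold caricature of DTC
  signaling: the receptor binds within 35 µm of the DTC and the signal is
  lost at ≥ 70 µm (bound cells between 35 and 70 µm stay bound —
  hysteresis); LAG-1 follows the receptor, and the GLD-1/GLD-2 pathways
  activate when LAG-1 shuts off, licensing meiotic entry. A cell in S or
  G2 when GLD activates therefore divides once (and only once) before
  both daughters exit at their next G1.
* **SexDetermination** — precursors commit on reaching 200 µm from the
  DTC: sperm-fated strictly before 32.5 hph, oocyte-fated at or after it
  (the tie at exactly 32.5 goes to oocyte). Sperm-fated cells divide
  twice, one short delay (1 h) apart, yielding exactly four sperm of
  radius 1.5 µm (sperm are much smaller than germ cells). Oocyte-fated
  cells grow and mature at 10 µm radius. While immature, adult
  oocyte-fated cells die with probability `P` per hour (converted to
  per-step probability by the geometric hazard `1-(1-P)^dt`, making
  outcomes step-size invariant) for each hour spent short of the
  proximal gonad; on reaching ≥ 250 µm from the DTC they are committed to
  becoming mature gametes and never die. Note the orientation: the
  apoptosis-competent region is the 200–250 µm band (the loop), and
  protection lies *beyond* 250 µm, which is where oocytes queue for
  ovulation.

Contact inhibition: adult cells (only) whose compressed volume falls
below 70% of the rest volume have their G2 timer frozen; G2 was chosen
as the arrest point because that cycle portion responds to other
environmental cues. Larval cells are never arrested.

Mature oocytes within one oocyte diameter of the proximal path end are
removed together with one sperm (ovulation); with no sperm left, oocytes
accumulate.

All boundary senses follow the printed forms: `< 35`, `>= 70`, `>= 200`,
strictly-before 32.5 hph, `< 70%`, `< 250` µm.

## Initialization and staging

Simulations begin with 16 germ cells packed at the distal end of a
20 µm initial path, each in a uniformly random point of the mitotic
cycle (phase chosen with probability proportional to its expected
duration, elapsed time uniform within the phase). Signaling regions
start in their distal states (receptor bound, LAG-1 on, GLD off, sex
precursor), since every founder lies within signaling range.

Stage times default to t_start = 16, L4 at 25, adulthood at 34, end of
run at 85 hph. These are faster than textbook 20°C staging; they are
the package's own calibration. With the published 3 h larval cycle, 16
founders, 70 µm meiotic threshold and the 200 µm / 32.5 hph sperm rule,
a later clock cannot put any cell 200 µm from the DTC before 32.5 hph —
front growth is proliferation-limited at roughly 70·ln2/3 ≈ 16 µm/h —
so no sperm would ever form. The chosen staging makes sperm commitment
happen in late L4 and is consistent with published in-silico tracking
snapshots of this system (stretching under way at ~33.5 hph, adult
behavior by 35.5 hph).

## Desk-scale geometry and what it implies

The simulated organ is deliberately smaller than a real adult gonad arm
(~220 µm final path length and 12.5 µm adult tube radius, vs. roughly
450 µm and ~23 µm in vivo), keeping full runs at 500–1100 cells so a
development-through-homeostasis simulation completes in minutes on one
CPU. All absolute census curves are therefore *not* calibrated —
sperm count (~150) and zone geometry land in realistic ranges, but total
cell numbers are roughly half scale. Properties tied to printed
thresholds (meiotic entry ≥ 70 µm, sex decision at 200 µm, protection at
250 µm, arrest at 70% volume) are unaffected by the scaling because they
are enforced by guards, not emergent. One consequence of the scale is
that the proximal gonad beyond 250 µm barely exists, so few oocytes are
protected and ovulation is rare within a default run; the apoptosis
hazard `P` (default 0.3/h) is the dominant adult drain.

## Simulation step order

Per `dt`: (1) per-cell context (arclength DTC distance, compressed
volume fraction, life stage); (2) statechart updates, cells in id order,
one RNG stream (bitwise reproducibility); (3) event processing — deaths,
divisions (daughters at parent ± 0.5·radius along a uniformly random
axis), growth, ovulation; (4) mechanics substeps with boundary
enforcement; (5) DTC migration, turn fixing, stretching; (6) clock.
Statecharts run before mechanics so guards read settled positions from
the previous step, making the per-cell update order irrelevant.

## Metrics

Rows are arclength bins of one cell diameter (CD = 5.4 µm; base mitotic
radius 2.7 µm, from the printed equivalence 70 µm ≈ 13 CD). The
proliferative zone ends at the first row containing ≥ 2 meiotic cells;
"meiotic" starts at commitment (NonProliferative onward), when meiotic
nuclear morphology appears in vivo. The proximal-most proliferative row
is the largest row index containing a cycling cell. The mitotic index
is the M-phase fraction within the zone. The internuclear distance
index (µm per row of nuclei to the meiotic boundary) uses *rank* rows —
cells sorted by DTC distance, grouped by the ring capacity of the tube —
rather than fixed-width bins, because the index must scale exactly with
axial compression (a bin-based row count would not).

## Lineage

Every cell carries an inherited clone label; the ancestry graph is a
forest rooted at the 16 founders. Labeling helpers reproduce the two
standard in-silico experiments: all cells labeled at one time point, or
one distal / one mid / one proximal cell. Sperm inherit labels but are
excluded from monoclonality summaries (the question concerns the
maintained germ line). Trajectories are sampled every 0.5 h when
tracking is enabled.

## Numerical and reproducibility notes

* Single `numpy` Generator per run, consumed in cell-id order; identical
  seeds give byte-identical event logs and snapshots.
* Timers accrue before guard evaluation, so a phase of duration D lasts
  `ceil(D/dt)` steps; the mean overshoot is dt/2 per phase (~0.5% of an
  adult cycle at dt = 0.02 h).
* Coincident sphere centers repel along a deterministic pseudo-random
  axis derived from the id pair.
* Projection ties at the turn resolve to the smaller arclength.
* The statechart chain limit (8) is far above the longest legitimate
  chain in the germline chart (2).

## Known limitations

* Absolute cell counts and the Fig-style census curves are half-scale by
  design; only threshold-pinned and qualitative properties are expected
  to transfer to the full-size organ.
* The adult proliferative pool approaches its packing equilibrium over
  tens of simulated hours after the larval-to-adult transition; the
  default run extends to 85 hph so that the final day of simulated
  adulthood is at steady state.
* Meiotic cells can be pushed back into the distal zone by transient
  pressure fluctuations (nothing in the model ejects them), which can
  depress the row-based zone-length metric in mid-adulthood snapshots.
* The turn region is crowded — a cluster rather than a single file of
  growing oocytes — matching the known limitation of this model class at
  small radii.
* No adhesion, no cell polarity, no DTC force on cells, no aging, a
  single gonad arm, and no molecular detail of GLP-1 signaling beyond
  the threshold logic.
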