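# germsim

A mechano-logical 3D simulation of the *C. elegans* hermaphrodite
germ line: one gonad arm from the end of L2 through adult homeostasis.

Germ cells are spheres moving under overdamped center-based mechanics
(linear overlap springs, `F = k·δ`, `ẋ = F/γ`) inside a growing U-shaped
tube that forms along the migration path of the distal tip cell (DTC).
Each cell carries a hierarchical statechart with orthogonal regions for
the cell cycle, GLP-1/Notch signaling (bound < 35 µm from the DTC,
signal lost ≥ 70 µm), the LAG-1 → GLD-1/GLD-2 switch that licenses
meiotic entry, and sex determination (sperm- vs oocyte-fated at 200 µm
from the DTC, before vs after 32.5 hours post-hatch). Cells exit
mitosis only from G1 while GLD is active — so cells caught in S or G2
divide exactly once more — grow to 4 µm in meiosis, and, if
oocyte-fated, to 10 µm at maturity. Adult cells compressed below 70% of
their rest volume arrest in G2 (contact inhibition), the feedback that
stabilizes the proliferative zone; immature oocytes die with probability
*P* per hour until they reach the proximal gonad (≥ 250 µm from the
DTC); ovulation removes one mature oocyte and one sperm at the proximal
end. Lineage labels are inherited through divisions for in-silico
clonal analysis.

The science, defaults and design choices are documented in
[docs/methods.md](docs/methods.md). The model is deliberately
desk-scale (final gonad ≈ 220 µm, 500–1100 cells) so a full
development-plus-homeostasis run takes minutes on one CPU; printed
thresholds are exact, absolute census counts are roughly half scale.

## Worked example

Run the default wild-type scenario for the first larval day and write
snapshots, events and metrics:

```sh
germsim run --seed 1 --until 30 --out out/demo --snapshot-every 2
```

which prints

```
finished at t=30.00 hph: 434 cells (195 proliferative, 0 sperm,
0 mature oocytes); gonad length 127.7 um
```

— by 30 hph (mid-L4 on this model's clock) the 16 founders have grown
to 434 cells; 195 are still in the mitotic cycle and the rest have
committed to meiosis beyond the 70 µm boundary, while the gonad arm has
elongated from 20 µm to ~128 µm behind the migrating DTC. No gametes
exist yet: sperm fate begins only once cells lie 200 µm from the DTC
(late L4). `out/demo/metrics.csv` holds the per-snapshot census, zone
lengths in cell diameters, mitotic index and internuclear distance
index; `out/demo/snap_*.csv` are per-cell point clouds (add `--vtk` for
ParaView-readable files); `events.csv` logs every division, meiotic
entry, fate commitment, death and ovulation with time and position.

The same in Python:

```python
from germsim import preset, run_simulation

config = preset("default", seed=1)
state = run_simulation(config, until=30.0, metrics_every=2.0)
print(state.census())
# {'total': 434, 'proliferative': 195, 'meiotic': 239, 'sperm_fated': 0,
#  'sperm': 0, 'oocyte_fated': 0, 'mature_oocyte': 0}
```

Named presets reproduce the in-silico experiments around gonadal
stretching and homeostasis (`germsim presets list`):
`no_stretch_fast_dtc` (46 µm/h DTC, no pausing — the DTC outruns the
germ cells), `no_stretch_pausing` (same rate with pausing — a shortened
adult gonad), and `no_feedback_fixed_death` (contact inhibition off,
fixed death probability — proliferative-cell explosion at any death
rate).

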