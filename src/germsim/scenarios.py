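"""Named experiment presets.

Each preset is the default configuration plus a documented set of deltas,
reproducing the in-silico experiments around gonadal stretching and
proliferative-zone homeostasis:

``default`` / ``feedback_on``
    Full model: DTC pausing, late-L4 stretching, contact-inhibition
    feedback on the adult cell cycle.
``no_stretch_fast_dtc``
    Stretching disabled, DTC pausing disabled, late-L4 migration raised to
    46 um/h to compensate: the DTC pulls ahead of the germ cells and the
    proliferative zone is lost.
``no_stretch_pausing``
    Same raised migration rate but with pausing: the DTC waits for the
    germ cells, producing a shortened adult gonad.
``no_feedback_fixed_death``
    Contact inhibition disabled; homeostasis is attempted by balancing a
    fixed division rate against a fixed (swept) death probability, which
    always fails by proliferative-cell explosion.
"""

from __future__ import annotations


from .config import SimulationConfig

#: per-hour oocyte death probabilities swept in the no-feedback scenario
FIXED_DEATH_SWEEP = (0.05, 0.2, 0.8)

PRESET_NAMES = ("default", "feedback_on", "no_stretch_fast_dtc",
                "no_stretch_pausing", "no_feedback_fixed_death")


def preset(name: str, seed: int = 0, death_prob: float | None = None
           ) -> SimulationConfig:
    """Build the configuration for a named scenario."""
    config = SimulationConfig()
    config.run.seed = seed
    if name in ("default", "feedback_on"):
        return config
    if name == "no_stretch_fast_dtc":
        config.path.stretch_enabled = False
        config.path.dtc_pausing = False
        config.path.stage_migration_rates = dict(
            config.path.stage_migration_rates, L4=46.0)
        return config
    if name == "no_stretch_pausing":
        config.path.stretch_enabled = False
        config.path.dtc_pausing = True
        config.path.stage_migration_rates = dict(
            config.path.stage_migration_rates, L4=46.0)
        return config
    if name == "no_feedback_fixed_death":
        config.run.contact_inhibition = False
        config.run.fixed_death_probs = FIXED_DEATH_SWEEP
        if death_prob is not None:
            config.fate.apoptosis_prob_per_h = death_prob
        return config
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def describe(name: str) -> str:
    config = preset(name)
    base = SimulationConfig()
    from .config import to_flat
    deltas = {k: v for k, v in to_flat(config).items()
              if to_flat(base).get(k) != v}
    lines = [f"preset {name}:"]
    lines += [f"  {k} = {v}" for k, v in sorted(deltas.items())] or \
        ["  (defaults)"]
    return "\n".join(lines)
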