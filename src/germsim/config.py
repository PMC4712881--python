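"""Run configuration: one flat, diff-able ``key = value`` text format.

Every tunable of the simulation lives in :class:`SimulationConfig`,
assembled from the per-module parameter blocks.  The dump labels each key
``[paper-fixed]`` (a printed biological number: thresholds, cycle totals,
founder count, ...) or ``[free]`` (fitted or unavailable, chosen here),
and a save/load round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

from .germline import CellCycleParams, FateParams, SignalingParams
from .geometry import DTCPathSpec
from .mechanics import ForceParams

#: keys whose values are printed biological quantities
PAPER_FIXED_KEYS = frozenset({
    "signaling.bound_threshold_um",
    "signaling.absent_threshold_um",
    "fate.sex_decision_distance_um",
    "fate.sperm_time_threshold_hph",
    "fate.proximal_protect_distance_um",
    "fate.max_meiotic_radius_um",
    "fate.oocyte_mature_radius_um",
    "cell_cycle.total_cycle_larval_h",
    "cell_cycle.total_cycle_adult_h",
    "cell_cycle.s",
    "cell_cycle.arrest_volume_fraction",
    "run.n_founders",
    "run.sperm_per_sperm_fated",
    "run.dtc_gap_cell_diameters",
})


@dataclass
class RunParams:
    seed: int = 0
    t_start_hph: float = 16.0
    t_L4_hph: float = 25.0
    t_adult_hph: float = 34.0
    t_end_hph: float = 85.0
    dt_h: float = 0.02
    snapshot_every_h: float = 1.0
    n_founders: int = 16
    sperm_per_sperm_fated: int = 4  # 2 divisions per sperm-fated cell
    dtc_gap_cell_diameters: float = 1.0
    base_radius_um: float = 2.7  # mitotic cell radius; CD = 5.4 um
    drag: float = 1.0
    ovulation_window_oocyte_diameters: float = 1.0
    contact_inhibition: bool = True
    #: fixed-death scenarios: extra per-hour death probability list swept
    #: when mechanical feedback is disabled (presets only)
    fixed_death_probs: tuple = ()
    track_trajectories: bool = False
    trajectory_dt_h: float = 0.5

    def __post_init__(self):
        if not (self.t_start_hph < self.t_L4_hph < self.t_adult_hph
                < self.t_end_hph):
            raise ValueError("stage times must be strictly increasing")
        if self.dt_h <= 0:
            raise ValueError("dt must be positive")

    @property
    def cell_diameter_um(self) -> float:
        return 2.0 * self.base_radius_um

    def life_stage(self, t: float, ramp_start: float) -> str:
        if t < ramp_start:
            return "larval"
        if t < self.t_adult_hph:
            return "transition"
        return "adult"

    def stage_name(self, t: float) -> str:
        if t < self.t_L4_hph:
            return "L3"
        if t < self.t_adult_hph:
            return "L4"
        return "adult"


@dataclass
class SimulationConfig:
    run: RunParams = field(default_factory=RunParams)
    cell_cycle: CellCycleParams = field(default_factory=CellCycleParams)
    signaling: SignalingParams = field(default_factory=SignalingParams)
    fate: FateParams = field(default_factory=FateParams)
    force: ForceParams = field(default_factory=ForceParams)
    path: DTCPathSpec = field(default_factory=DTCPathSpec)

    def __post_init__(self):
        # larval->adult ramp: mid-L4 to adulthood by default
        self.cell_cycle.ramp_start_hph = 0.5 * (self.run.t_L4_hph
                                                + self.run.t_adult_hph)
        self.cell_cycle.ramp_end_hph = self.run.t_adult_hph


# ----------------------------------------------------------------------
_BLOCKS = ("run", "cell_cycle", "signaling", "fate", "force", "path")


def _encode(value):
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float, str)):
        return repr(value) if isinstance(value, float) else str(value)
    if isinstance(value, dict):
        return ",".join(f"{k}:{_encode(v)}" for k, v in value.items())
    if isinstance(value, (tuple, list)):
        return ";".join(
            ",".join(_encode(x) for x in v) if isinstance(v, (tuple, list))
            else _encode(v)
            for v in value)
    raise TypeError(f"cannot encode {value!r}")


def _decode(text, template):
    text = text.strip()
    if isinstance(template, bool):
        return text == "true"
    if isinstance(template, int):
        return int(text)
    if isinstance(template, float):
        return float(text)
    if isinstance(template, str):
        return text
    if isinstance(template, dict):
        out = {}
        if text:
            for item in text.split(","):
                k, v = item.split(":")
                tmpl = next(iter(template.values())) if template else 0.0
                out[k] = _decode(v, tmpl)
        return out
    if isinstance(template, (tuple, list)):
        if not text:
            return ()
        if template and isinstance(template[0], (tuple, list)):
            return tuple(
                tuple(_decode(x, template[0][0]) for x in part.split(","))
                for part in text.split(";"))
        tmpl = template[0] if template else 0.0
        parts = text.split(";") if ";" in text else text.split(",")
        return tuple(_decode(p, tmpl) for p in parts)
    raise TypeError(f"cannot decode into {template!r}")


def to_flat(config: SimulationConfig) -> dict:
    flat = {}
    for block in _BLOCKS:
        obj = getattr(config, block)
        for f in fields(obj):
            flat[f"{block}.{f.name}"] = getattr(obj, f.name)
    return flat


def dumps(config: SimulationConfig) -> str:
    lines = ["# germsim run configuration"]
    for key, value in to_flat(config).items():
        tag = "paper-fixed" if key in PAPER_FIXED_KEYS else "free"
        lines.append(f"{key} = {_encode(value)}  # [{tag}]")
    return "\n".join(lines) + "\n"


def loads(text: str) -> SimulationConfig:
    config = SimulationConfig()
    blocks = {b: dataclasses.asdict(getattr(config, b)) for b in _BLOCKS}
    templates = {b: getattr(config, b) for b in _BLOCKS}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        block, _, name = key.partition(".")
        if block not in blocks or name not in blocks[block]:
            raise KeyError(f"unknown config key {key!r}")
        template = getattr(templates[block], name)
        blocks[block][name] = _decode(value, template)
    return SimulationConfig(**{
        b: type(templates[b])(**blocks[b]) for b in _BLOCKS})


def save(config: SimulationConfig, path):
    with open(path, "w") as fh:
        fh.write(dumps(config))


def load(path) -> SimulationConfig:
    with open(path) as fh:
        return loads(fh.read())
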