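"""Run configuration: schema, defaults, YAML round-trip.

The default configuration encodes the model's study conditions: the 200x90
lattice at 2 μm/voxel and 6 min/MCS, the Hill-regulated growth constants,
the 1/720-per-MCS sloughing hazard, and the EGF transport constants.  CPM
mechanics constants (contact-energy matrix, temperature, constraint
strengths, link and chemotaxis couplings) and the tear-source concentration
are calibrated model constants, frozen here and flagged in CALIBRATED.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .behaviors import GrowthParams, SloughParams
from .fields import FieldParams
from .injury import InjurySpec
from .potts import ChemotaxisSpec, ContactEnergyTable, LinkSet, PottsParams
from .tissue import GeometrySpec

__all__ = ["RunConfig", "RunSettings", "load_config", "save_config",
           "default_config", "CALIBRATED"]

#: parameters whose values are model calibration (not literature constants)
CALIBRATED = [
    "potts.temperature", "potts.lambda_volume", "potts.lambda_surface",
    "contact_energies", "links.lam", "links.target_length",
    "chemotaxis.egf", "egf.source_value", "growth.lambda_for_pressure",
    "chem.D_global", "chem.kd", "injury.cell_threshold",
    "injury.membrane_threshold", "injury.death_rate",
    "target_volume_by_type.WING", "target_volume_by_type.SUPER",
]

# Contact-energy matrix (calibrated).  Lower = more adhesive.  The hierarchy
# realizes: strong stem anchoring to the limbal membrane, basal anchoring to
# the central membrane, cohesive epithelial layers with a mild penalty for
# non-adjacent-layer mixing, tear wetting the superficial surface, and a
# high cell-medium tension keeping the tissue compact.
DEFAULT_CONTACT = {
    ("MEDIUM", "MEDIUM"): 0.0,
    ("MEDIUM", "TEAR"): 8.0,
    ("TEAR", "TEAR"): 0.0,
    ("STEM", "STEM"): 6.0, ("BASAL", "BASAL"): 6.0,
    ("WING", "WING"): 6.0, ("SUPER", "SUPER"): 5.0,
    ("STEM", "BASAL"): 8.0, ("BASAL", "WING"): 8.0, ("WING", "SUPER"): 8.0,
    ("STEM", "WING"): 14.0, ("STEM", "SUPER"): 16.0, ("BASAL", "SUPER"): 14.0,
    ("STEM", "LIMB"): 5.0, ("BASAL", "LIMB"): 6.0,
    ("STEM", "MEMB"): 6.0, ("BASAL", "MEMB"): 3.0,
    ("WING", "LIMB"): 16.0, ("WING", "MEMB"): 16.0,
    ("SUPER", "LIMB"): 20.0, ("SUPER", "MEMB"): 20.0,
    ("STEM", "TEAR"): 22.0, ("BASAL", "TEAR"): 22.0,
    ("WING", "TEAR"): 18.0, ("SUPER", "TEAR"): 14.0,
    ("STEM", "MEDIUM"): 35.0, ("BASAL", "MEDIUM"): 35.0,
    ("WING", "MEDIUM"): 35.0, ("SUPER", "MEDIUM"): 35.0,
    ("STEM", "STROMA"): 12.0, ("BASAL", "STROMA"): 12.0,
    ("WING", "STROMA"): 16.0, ("SUPER", "STROMA"): 20.0,
    ("LIMB", "TEAR"): 12.0, ("MEMB", "TEAR"): 12.0,
    ("LIMB", "MEDIUM"): 20.0, ("MEMB", "MEDIUM"): 20.0,
}


@dataclass
class RunSettings:
    days: float = 15.0
    sample_every_mcs: int = 40        # one sample per 4 simulated hours
    seed: int = 1
    replicates: int = 1
    output_dir: str = "out"
    snapshot_every_mcs: int = 0       # 0 = no periodic snapshots


@dataclass
class LinkParams:
    lam: float = 0.5
    target_length: float = 6.0
    max_distance: float = 11.0
    max_partners: int | None = None   # None = every neighbor within range

    def build(self) -> LinkSet:
        return LinkSet(self.lam, self.target_length, self.max_distance,
                       self.max_partners)


@dataclass
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    potts: PottsParams = field(default_factory=PottsParams)
    contact_energies: dict = field(default_factory=lambda: dict(DEFAULT_CONTACT))
    contact_default: float = 20.0
    # Tear-source concentration is a calibrated constant: it sets the scale
    # on which the half-max constants km_EGF (3.5 / 7.0 arb. units) act.
    egf: FieldParams = field(default_factory=lambda: FieldParams(
        source_value=110.0))
    chem: FieldParams = field(default_factory=lambda: FieldParams(
        D_global=12.0, D_by_type={"LIMB": 12.0, "MEMB": 12.0, "SUPER": 12.0,
                                  "WALL": 0.0, "MEDIUM": 0.0},
        kd=0.02, source_value=None, dirichlet_top_bottom=True))
    bias: FieldParams | None = None   # movement-bias field; inactive default
    growth: GrowthParams = field(default_factory=GrowthParams)
    slough: SloughParams = field(default_factory=SloughParams)
    chemotaxis: dict = field(default_factory=lambda: {
        "egf": {"BASAL": 1.0}})
    links: LinkParams = field(default_factory=LinkParams)
    injury: InjurySpec | None = None
    run: RunSettings = field(default_factory=RunSettings)
    fragment_cull_volume: int = 3     # cells below this volume are culled
    # Per-type target volumes (voxels).  Proliferative cells start at 25
    # (100 μm²) and divide at 50; post-mitotic cells condense as they
    # differentiate, which keeps the superficial layer populous enough for
    # the fixed 1/720 sloughing hazard to sustain physiological turnover.
    target_volume_by_type: dict = field(default_factory=lambda: {
        "STEM": 25.0, "BASAL": 25.0, "WING": 16.0, "SUPER": 10.0})

    def contact_table(self) -> ContactEnergyTable:
        return ContactEnergyTable.from_dict(self.contact_energies,
                                            default=self.contact_default)

    def chemotaxis_spec(self) -> ChemotaxisSpec:
        return ChemotaxisSpec(lambda_by_type=self.chemotaxis,
                              field_names=("egf", "bias"))

    def field_params(self) -> dict:
        out = {"egf": self.egf, "chem": self.chem}
        if self.bias is not None:
            out["bias"] = self.bias
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(to_plain(self), sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# (de)serialization with unknown-key rejection

def to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_plain(getattr(obj, f.name)) for f in dc_fields(obj)}
    if isinstance(obj, dict):
        return {_key_str(k): to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_plain(v) for v in obj]
    return obj


def _key_str(k):
    if isinstance(k, tuple):
        return "-".join(str(x) for x in k)
    return k


def _from_plain(cls, data, path=""):
    if data is None:
        return None
    if not dataclasses.is_dataclass(cls):
        return data
    known = {f.name: f for f in dc_fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under "
                         f"'{path or cls.__name__}'")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = _NESTED.get((cls, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_plain(sub, value, f"{path}.{name}" if path else name)
        elif name == "center" and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (RunConfig, "geometry"): GeometrySpec,
    (RunConfig, "potts"): PottsParams,
    (RunConfig, "egf"): FieldParams,
    (RunConfig, "chem"): FieldParams,
    (RunConfig, "bias"): FieldParams,
    (RunConfig, "growth"): GrowthParams,
    (RunConfig, "slough"): SloughParams,
    (RunConfig, "links"): LinkParams,
    (RunConfig, "injury"): InjurySpec,
    (RunConfig, "run"): RunSettings,
}


def default_config(**overrides) -> RunConfig:
    cfg = RunConfig()
    for key, val in overrides.items():
        parts = key.split(".")
        obj = cfg
        for p in parts[:-1]:
            obj = getattr(obj, p)
        if not hasattr(obj, parts[-1]):
            raise AttributeError(f"no config field {key!r}")
        setattr(obj, parts[-1], val)
    return cfg


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_plain(RunConfig, data)


def save_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(to_plain(cfg), fh, sort_keys=False)
    return path
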