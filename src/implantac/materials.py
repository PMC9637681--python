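"""Material table: linear attenuation coefficients (cm^-1) at 511 keV.

The default table covers the tissue and implant classes needed for a
segmentation-based attenuation map around a total knee arthroplasty:
air, soft tissue, adipose tissue, cortical bone, the polyethylene tibial
insert, and the cobalt-chromium femoral/tibial components.  Vial contents
are water-equivalent and carry the soft-tissue coefficient.

Users may supply their own table (e.g. to model a titanium component) via
the constructor or a YAML file of ``material: lac`` pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: LACs in cm^-1 for 511 keV annihilation photons.
DEFAULT_LACS: dict[str, float] = {
    "air": 0.0,
    "soft_tissue": 0.0927,
    "adipose": 0.0854,
    "bone": 0.13,
    "polyethylene": 0.079,
    "cobalt_chromium": 0.72,
}


@dataclass
class MaterialTable:
    """Mapping material name -> linear attenuation coefficient (cm^-1)."""

    lacs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LACS))

    def __post_init__(self):
        self.lacs = {str(k): float(v) for k, v in self.lacs.items()}
        negative = {k: v for k, v in self.lacs.items() if v < 0}
        if negative:
            raise ValueError(f"negative attenuation coefficients: {negative}")
        if self.lacs.get("air", 0.0) != 0.0:
            raise ValueError("air must have an attenuation coefficient of exactly 0")

    @classmethod
    def default(cls) -> "MaterialTable":
        return cls()

    def __getitem__(self, name: str) -> float:
        return self.lacs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.lacs

    def get(self, name: str, default=None):
        return self.lacs.get(name, default)

    @property
    def max_lac(self) -> float:
        return max(self.lacs.values())

    def with_updates(self, **lacs: float) -> "MaterialTable":
        merged = dict(self.lacs)
        merged.update(lacs)
        return MaterialTable(merged)

    @classmethod
    def from_yaml(cls, path) -> "MaterialTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of material -> LAC")
        return cls(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.lacs, fh, sort_keys=True)
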