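"""Run configuration: every pipeline constant in one serializable object.

Defaults carry the study-level constants of the method: plate QC minimum
z-score 0.4, GIS decision threshold 0.48 with +/-0.25 indeterminate margin,
RECAP PC1 cutoff -0.5, and the 6-month platinum-sensitivity PFI rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .imaging import ImagingConfig


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    # cohort
    n_hrd: int = 5
    n_hrp: int = 5
    image_shape: tuple = (384, 384)
    nucleus_count: int = 60
    # imaging chain
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    # scoring / integration cutoffs
    recap_cutoff: float = -0.5
    gis_threshold: float = 0.48
    gis_margin: float = 0.25
    qc_min: float = 0.4
    pfi_sensitive_months: float = 6.0
    # drug screen
    drugs: tuple = ("carboplatin", "olaparib")
    # planted GIS-HRP / RECAP-HRD discordant models
    n_discordant: int = 0
    # expression block
    n_genes: int = 1500
    n_pairs: int = 8
    k_true: int = 4
    nmf_ranks: tuple = tuple(range(2, 8))
    embed_method: str = "umap"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "imaging" in d and isinstance(d["imaging"], dict):
            d["imaging"] = ImagingConfig(**d["imaging"])
        for key in ("image_shape", "drugs", "nmf_ranks"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
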