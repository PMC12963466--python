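"""Study configuration: one serializable object that pins every choice.

A ``StudyConfig`` carries the cohort distribution parameters, observer
panel, window list, slab thickness, CI method and all seeds, and
round-trips losslessly through JSON, so a demo run is reproducible from
its logged config alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .readers import DEFAULT_OBSERVER_PARAMS, ObserverProfile

__all__ = ["StudyConfig"]

_DEFAULT_OBSERVERS = tuple(
    {
        "observer_id": oid,
        "edge_fraction": ef,
        "caliper_sd": 0.10,
        "roi_center_sd": 0.5,
        "seed": i,
    }
    for i, (oid, ef) in enumerate(DEFAULT_OBSERVER_PARAMS)
)


@dataclass(frozen=True)
class StudyConfig:
    """All parameters of an end-to-end simulated reader study."""

    seed: int = 0
    n_stones: int = 40
    # cohort distributions (emulation choices; see docs/methods.md)
    size_log_mu: float = math.log(4.8)
    size_log_sigma: float = 0.35
    size_min: float = 2.0
    hu_mean: float = 850.0
    hu_sd: float = 150.0
    hu_min: float = 300.0
    background_hu: float = -80.0
    anisotropy_min: float = 0.75
    passage_intercept: float = 4.4
    passage_slope: float = -0.85
    # imaging
    psf_fwhm: float = 1.0
    noise_sd: float = 15.0
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    slab_thickness: float = 3.0
    # study design
    observers: tuple[dict, ...] = _DEFAULT_OBSERVERS
    windows: tuple[str, ...] = (
        "bone",
        "soft_tissue",
        "half_value_mean",
        "half_value_max",
    )
    exclude: tuple[tuple[str, str], ...] = ()
    # analysis
    level: float = 0.95
    ci_method: str = "mls"

    def observer_profiles(self) -> list[ObserverProfile]:
        return [ObserverProfile(**o) for o in self.observers]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        raw = json.loads(text)
        raw["voxel_spacing"] = tuple(raw["voxel_spacing"])
        raw["observers"] = tuple(raw["observers"])
        raw["windows"] = tuple(raw["windows"])
        raw["exclude"] = tuple(tuple(e) for e in raw["exclude"])
        return cls(**raw)

    @classmethod
    def load(cls, path) -> "StudyConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def with_(self, **kw) -> "StudyConfig":
        return replace(self, **kw)
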