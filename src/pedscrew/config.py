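"""Analysis configuration: every tunable convention in one place.

Defaults match the documented design choices of the measurement chain
(distances in mm, angles in degrees at all interfaces).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["AnalysisConfig", "TECHNIQUE_CALIBRATION"]

# Per-technique calibration targets for the insertion-error simulator: mean
# entry point error (mm) and mean orientation angle error (deg) as achieved
# by each guidance technique.  The simulator draws half-normal magnitudes,
# whose scale is mean * sqrt(pi/2).
TECHNIQUE_CALIBRATION = {
    "conventional": {"mean_ee": 3.4, "mean_e_alpha": 7.9},
    "cbct": {"mean_ee": 2.5, "mean_e_alpha": 5.2},
    "navigation": {"mean_ee": 2.4, "mean_e_alpha": 5.9},
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Conventions and parameters of the full measurement chain."""

    # geometry
    error_direction: str = "plan_to_actual"  # or "actual_to_plan"
    report_diameter: bool = False  # coaxiality as max distance (False) or doubled
    # screw + digitization
    screw_radius: float = 2.5  # mm (5 mm diameter screws)
    screw_length: float = 45.0  # mm
    probe_radius: float = 1.0  # mm (2 mm spherical CMM sensor)
    radius_mode: str = "fixed"  # "fixed" (at screw_radius) or "free"
    digitizer_noise_sd: float = 0.2  # mm, CMM precision
    n_screw_points: int = 30
    n_surface_points: int = 200
    # registration
    icp_max_iter: int = 100
    icp_tol: float = 1e-6
    icp_trim_fraction: float = 0.1
    # wall distance + grading
    station_step: float = 0.1  # mm along the axis
    gertzbein_boundaries: tuple = (2.0, 4.0)  # mm depth cut points
    heary_canal_threshold: float = 4.0  # mm medial depth for grade V
    # agreement
    binary_positive_grades: tuple = ("1", "2", "3", "4")
    binary_exclude: tuple = ("/",)
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        """Short stable digest of the configuration, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
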