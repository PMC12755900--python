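"""Run configuration: every tunable of the measurement chain in one place.

Defaults are the standard operating point of the method: scans from -10 to
+10 nm in 0.25 nm steps, 12 nm geodesic averaging radius with w(d)=1/(1+d),
8 nm edge exclusion, dual-Gaussian mean bounds +-[0.5, 6] nm, subcompartment
thresholds 4/14 nm beyond the modal intermembrane spacing, 12 nm patch
radius, 24 nm particle-to-surface cutoff and extended patch scans to +30 nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = ["RunConfig", "FitBounds"]


@dataclass
class FitBounds:
    """Box constraints of the dual-Gaussian fit (nm)."""

    mu_min: float = 0.5     # |peak centre| lower bound
    mu_max: float = 6.0     # |peak centre| upper bound
    sigma_min: float = 0.2
    sigma_max: float = 3.0


@dataclass
class RunConfig:
    # line scans
    scan_lo: float = -10.0
    scan_hi: float = 10.0
    scan_step: float = 0.25
    min_valid_frac: float = 0.75
    # neighbourhood averaging
    averaging_radius: float = 12.0
    weight_function: str = "inverse_1p"   # w(d) = 1/(1+d)
    # edge exclusion
    edge_threshold: float = 8.0
    # fitting
    fit_bounds: FitBounds = field(default_factory=FitBounds)
    # subcompartment classification
    ibm_threshold: float = 4.0
    junction_threshold: float = 14.0
    distance_bin_width: float = 1.0
    # patches
    patch_radius: float = 12.0
    particle_cutoff: float = 24.0
    patch_scan_hi: float = 30.0
    randomized_min_sep: float = 12.0
    # quantile partition
    quantile_edges: tuple = (0.0, 0.5, 0.9, 0.95, 0.99, 1.0)
    # misc
    contrast: str = "heads_bright"
    seed: int = 0

    def snapshot(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.snapshot(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        fb = d.pop("fit_bounds", None)
        cfg = cls(**{k: v for k, v in d.items()
                     if k in cls.__dataclass_fields__})
        if fb:
            cfg.fit_bounds = FitBounds(**fb)
        if "quantile_edges" in d:
            cfg.quantile_edges = tuple(d["quantile_edges"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
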