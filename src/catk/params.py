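"""Analysis parameter bundle shared across stages.

The eight scientific parameters are the ones a user tunes per dataset:

==========  =========  ===================================================
parameter   unit       role
==========  =========  ===================================================
sigma_a     pixels     narrow Gaussian of the DoG blob detector
sigma_b     pixels     wide Gaussian (band-pass partner, ~1.6 sigma_a)
th_dog      --         DoG response threshold defining ROI boundaries
k_window    frames     trailing window K of the sliding baseline
q_percent   %          lowest-q% of the window averaged into Flow
lf_window   frames     trailing window Lf of the sliding Z-score
th_z        --         Z-score peak threshold
jin         --         smoothing factor damping peaks in the Z-score buffer
==========  =========  ===================================================

plus bookkeeping fields (min_area, correlation settings, acquisition rate,
frame range, seed) that the pipeline needs to be reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import yaml

from .errors import InvalidParameterError

#: accepted aliases for config-file keys (Table-style short names included)
_KEY_ALIASES = {
    "sigma_a": "sigma_a",
    "sigma_b": "sigma_b",
    "th_dog": "th_dog",
    "thdog": "th_dog",
    "k": "k_window",
    "k_window": "k_window",
    "q": "q_percent",
    "q_percent": "q_percent",
    "lf": "lf_window",
    "lf_window": "lf_window",
    "th_z": "th_z",
    "thz": "th_z",
    "jin": "jin",
    "min_area": "min_area",
    "correlation_threshold": "correlation_threshold",
    "basis": "basis",
    "rate_hz": "rate_hz",
    "frame_range": "frame_range",
    "seed": "seed",
}


@dataclass
class AnalysisParams:
    """All user-set parameters of the analysis chain."""

    # ROI detection
    sigma_a: float = 3.0
    sigma_b: float = 4.8
    th_dog: float = 0.0032
    min_area: int = 4
    # signal extraction
    k_window: int = 25
    q_percent: float = 15.0
    # peak detection
    lf_window: int = 25
    th_z: float = 3.0
    jin: float = 0.15
    # network analysis
    correlation_threshold: float = 0.7
    basis: str = "pf"
    # acquisition / bookkeeping
    rate_hz: float = 1.0
    frame_range: Optional[Tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a <= 0 or self.sigma_b <= self.sigma_a:
            raise InvalidParameterError(
                f"require 0 < sigma_a < sigma_b, got {self.sigma_a}, {self.sigma_b}"
            )
        if self.th_dog <= 0:
            raise InvalidParameterError("th_dog must be > 0")
        if self.k_window < 1:
            raise InvalidParameterError("k_window must be >= 1")
        if not 0 < self.q_percent < 50:
            raise InvalidParameterError("q_percent must lie in (0, 50)")
        if self.lf_window < 2:
            raise InvalidParameterError("lf_window must be >= 2")
        if self.th_z <= 0:
            raise InvalidParameterError("th_z must be > 0 (the SD floor is 1/(10*th_z))")
        if not 0 <= self.jin <= 1:
            raise InvalidParameterError("jin must lie in [0, 1]")
        if self.basis not in ("pf", "dff"):
            raise InvalidParameterError("basis must be 'pf' or 'dff'")
        if self.rate_hz <= 0:
            raise InvalidParameterError("rate_hz must be > 0")
        if self.frame_range is not None:
            a, b = self.frame_range
            if b <= a or a < 0:
                raise InvalidParameterError(f"empty or invalid frame_range {self.frame_range}")
            self.frame_range = (int(a), int(b))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["frame_range"] is not None:
            d["frame_range"] = list(d["frame_range"])
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "AnalysisParams":
        kwargs = {}
        for key, value in mapping.items():
            canon = _KEY_ALIASES.get(str(key).lower())
            if canon is None:
                raise InvalidParameterError(f"unknown parameter {key!r} in config")
            kwargs[canon] = value
        if kwargs.get("frame_range") is not None:
            kwargs["frame_range"] = tuple(kwargs["frame_range"])
        return cls(**kwargs)

    @classmethod
    def from_config(cls, path) -> "AnalysisParams":
        """Read parameters from a flat key: value text file (YAML mapping)."""
        with open(path, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise InvalidParameterError(f"config {path} is not a flat key-value mapping")
        return cls.from_dict(mapping)
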