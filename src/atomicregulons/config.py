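"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable parameters of the atomic-regulon pipeline.

    Defaults are the published operating point: pairwise PCC > 0.7 to keep
    genes in a split cluster, average distance <= 0.25 to accrete, 200 bp
    operon gap, ON/OFF percentiles 10/80/25, CLR cutoff at mean + 4 SD.
    """

    pcc_threshold: float = 0.7
    max_avg_dist: float = 0.25
    max_operon_gap: int = 200
    distance_form: str = "linear"  # linear: (1-PCC)/2; squared: (1-PCC)^2
    on_percentile: float = 10.0
    off_percentile: float = 80.0
    d_percentile: float = 25.0
    clr_k_sd: float = 4.0
    clr_n_bins: int | None = None  # None -> min(10, floor(sqrt(#experiments)))
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not -1.0 <= self.pcc_threshold <= 1.0:
            raise ValueError(f"pcc_threshold must be in [-1, 1], got {self.pcc_threshold}")
        if self.max_avg_dist < 0:
            raise ValueError("max_avg_dist must be >= 0")
        if self.max_operon_gap < 0:
            raise ValueError("max_operon_gap must be >= 0")
        if self.distance_form not in ("linear", "squared"):
            raise ValueError(f"distance_form must be 'linear' or 'squared', got {self.distance_form!r}")
        for name in ("on_percentile", "off_percentile", "d_percentile"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentile in [0, 100], got {v}")
        if self.clr_k_sd < 0:
            raise ValueError("clr_k_sd must be >= 0")
        if self.clr_n_bins is not None and self.clr_n_bins < 2:
            raise ValueError("clr_n_bins must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML (or flat ``key: value``) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
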