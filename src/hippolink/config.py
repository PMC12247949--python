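"""Pipeline configuration: every stated analysis threshold in one place.

Defaults mirror the published analysis settings: differential expression is
called at a Benjamini-Hochberg adjusted p-value below 0.05, the promoter is
the 1,500 bp flanking the transcription start site, gene-set
over-representation keeps terms with at least 30 genes and calls GO-style
collections at adjusted p < 0.01 and KEGG-style collections at adjusted
p < 0.05, and a control library is flagged as an outlier when its normalized
marker expression sits more than 3 scaled median absolute deviations from its
peer controls.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    de_alpha: float = 0.05
    promoter_flank: int = 1500
    flank_mode: str = "symmetric"  # or "upstream"
    go_min_set_size: int = 30
    go_padj_cutoff: float = 0.01
    kegg_padj_cutoff: float = 0.05
    outlier_mad_k: float = 3.0
    include_opposite_in_shared: bool = True
    max_shortest_paths: int = 1000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("de_alpha", "go_padj_cutoff", "kegg_padj_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        if self.promoter_flank <= 0:
            raise ValueError(f"promoter_flank must be > 0, got {self.promoter_flank!r}")
        if self.flank_mode not in ("symmetric", "upstream"):
            raise ValueError(f"flank_mode must be 'symmetric' or 'upstream', got {self.flank_mode!r}")
        if self.go_min_set_size < 1:
            raise ValueError(f"go_min_set_size must be >= 1, got {self.go_min_set_size!r}")
        if self.outlier_mad_k <= 0:
            raise ValueError(f"outlier_mad_k must be > 0, got {self.outlier_mad_k!r}")
        if self.max_shortest_paths < 1:
            raise ValueError("max_shortest_paths must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping; unknown keys land in ``extra``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d.update(d.pop("extra"))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced (CLI flags win)."""
        d = asdict(self)
        extra = d.pop("extra")
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**d, extra=extra)
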