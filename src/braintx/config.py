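"""Analysis configuration: gene panel, surrogate counts, seeds, paths."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: ten GWAS-derived risk genes plus the two alpha-synuclein clearance genes
DEFAULT_GENE_PANEL = (
    "APOE",
    "APP",
    "BIN1",
    "GBA",
    "LRP1",
    "MAPT",
    "PARK7",
    "PINK1",
    "PSEN1",
    "PSEN2",
    "SNCA",
    "TMEM175",
)


@dataclass
class AnalysisConfig:
    """Everything needed to run the end-to-end analysis reproducibly.

    If ``atlas_path``/``subjects_path``/``expression_path`` are unset the
    pipeline simulates its own inputs from the ``synthetic`` block.
    """

    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL
    n_surrogates_regression: int = 10_000
    n_surrogates_forest: int = 1_000
    q: float = 0.05
    sided: str = "two"
    seed: int = 0
    # forest
    ntree: int = 500
    mtry: int | None = None
    nodesize: int = 2
    # inputs (all optional; synthetic fallback)
    atlas_path: str | None = None
    subjects_path: str | None = None
    expression_path: str | None = None
    donor_dir: str | None = None
    # synthetic generation parameters
    n_controls: int = 164
    n_patients: int = 164
    length_scale: float = 40.0
    noise_sd: float = 0.5
    effect_coefficients: dict = field(default_factory=dict)
    # subgroup selectors: name -> list of patient ids
    subgroups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_panel = tuple(self.gene_panel)
        if not self.gene_panel:
            raise ValueError("gene panel must not be empty")
        if self.n_surrogates_regression < 1 or self.n_surrogates_forest < 1:
            raise ValueError("surrogate counts must be >= 1")
        if self.n_surrogates_forest > self.n_surrogates_regression:
            raise ValueError(
                "forest null count cannot exceed the cached regression ensembles"
            )
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_panel"] = list(self.gene_panel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> AnalysisConfig:
    """A small fully synthetic configuration that runs in well under a
    minute (200 regression surrogates, 100 forest nulls, 50 trees)."""
    return AnalysisConfig(
        n_surrogates_regression=200,
        n_surrogates_forest=100,
        ntree=50,
        seed=seed,
        n_controls=80,
        n_patients=80,
        effect_coefficients={"GBA": -0.5},
    )
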