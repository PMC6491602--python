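"""Run configuration: every knob of the pipeline in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ParameterError
from .varpart import ION_TERMS, MORPHOMETRIC_TERMS


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``contours_csv``/``masks_dir`` and ``metadata_csv`` are unset the
    morphometric stage runs on the synthetic vineyard; likewise ``ion_csv``
    for the ionomic stage.
    """

    outdir: str = "vineleaf_out"
    seed: int = 0
    # inputs (None -> synthetic)
    contours_csv: str | None = None
    masks_dir: str | None = None
    metadata_csv: str | None = None
    ion_csv: str | None = None
    # synthetic scale
    leaves_per_vine: int = 4
    years: tuple[int, ...] = (2014, 2016)
    # contour / featurization parameters
    n_points: int = 1000
    n_rings: int = 16
    n_thresholds: int = 100
    bandwidth: float = 0.05
    connectivity_eps_factor: float = 2.5
    n_components: int = 20
    # modeling
    morpho_terms: list[str] = field(default_factory=lambda: list(MORPHOMETRIC_TERMS))
    ion_terms: list[str] = field(default_factory=lambda: list(ION_TERMS))
    alpha: float = 0.05
    iqr_k: float = 5.0
    imagej_circularity: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 3 or self.n_rings < 1 or self.n_thresholds < 2:
            raise ParameterError("n_points >= 3, n_rings >= 1, n_thresholds >= 2 required")
        if self.bandwidth <= 0 or self.connectivity_eps_factor <= 0:
            raise ParameterError("bandwidth and connectivity_eps_factor must be positive")
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must be in (0, 1]")
        if self.iqr_k < 0:
            raise ParameterError("iqr_k must be >= 0")
        self.years = tuple(int(y) for y in self.years)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
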