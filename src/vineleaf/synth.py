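"""Synthetic vineyard: factorial design, grapevine-like leaf contours, and ion
tables with known injected effects.

The generator emulates the structure of a 288-vine factorial experiment —
four root treatments (ungrafted, 1103P, 3309C, SO4) by three irrigation
regimes (none, partial, full) assigned by vineyard row, nine rows grouped
into three blocks, eight vine replicates — sampled over two years, with four
middle-shoot leaves per vine for morphometrics and three developmental leaf
positions (old, mid, young) per vine for ionomics.

Leaves are five-lobed, serrated polar curves:

    r(theta) = R * (1 - d * |cos(L*theta/2)|**p + s * cos(m*theta))

with lobe depth ``d``, serration amplitude ``s``, serration frequency ``m``,
shape exponent ``p``, a y-axis stretch ``e`` (elongation) and radial Gaussian
noise. This is a stand-in shape family, not a botanical model: it gives the
downstream pipeline controllable lobing/serration/elongation with known
ground truth, which is what the recovery tests need.

Factor effects are injected on the *generator parameters* (elongation shifts
by year, lobe-depth shifts by the rootstock x irrigation cell, radius drift
by block) so the entire contour -> feature -> ANOVA chain is exercised. Ion
concentrations are log-normal around element-specific baselines with injected
leaf-position gradients (Ca up, K down with leaf age, etc.), rootstock shifts
(Ni highest on SO4) and rootstock-by-irrigation patterns (Mo and others),
plus a small fraction of extreme outliers (x1000) to exercise the IQR filter.

All randomness flows from one seed through fixed per-stage child streams, so
outputs are byte-identical across runs with the same seed and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contours import Contour, LeafRecord
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ROOTSTOCKS",
    "IRRIGATION_LEVELS",
    "LEAF_POSITIONS",
    "ELEMENTS",
    "LeafGenParams",
    "EffectConfig",
    "make_design",
    "generate_leaf_contour",
    "generate_dataset",
    "generate_ionome",
]

ROOTSTOCKS = ["1103P", "3309C", "SO4", "ungrafted"]
IRRIGATION_LEVELS = ["full", "none", "partial"]
BLOCKS = ["A", "B", "C"]
LEAF_POSITIONS = ["old", "mid", "young"]
YEARS = (2014, 2016)

# 17 elements with realistic leaf-tissue baselines, mg per kg dry weight
ELEMENTS: dict[str, float] = {
    "Al": 60.0,
    "Ca": 18000.0,
    "Cd": 0.05,
    "Co": 0.1,
    "Cu": 8.0,
    "Fe": 90.0,
    "K": 12000.0,
    "Mg": 3500.0,
    "Mn": 120.0,
    "Mo": 0.4,
    "Na": 150.0,
    "Ni": 1.5,
    "P": 2500.0,
    "Rb": 15.0,
    "S": 2000.0,
    "Sr": 60.0,
    "Zn": 25.0,
}

# fixed rootstock x irrigation pattern (rows = sorted rootstocks, cols = sorted
# irrigation levels); deliberately not expressible as row + column effects, so
# the interaction term carries signal even after the main effects
_INTERACTION_PATTERN = np.array(
    [
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
    ]
)

# per-stage child-seed tags for the fixed seed-splitting rule
_STAGE = {"design": 11, "leaves": 23, "ions": 37}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage]]))


@dataclass(frozen=True)
class LeafGenParams:
    """Parameters of one generated leaf outline."""

    radius: float = 1.0
    n_lobes: int = 5
    lobe_depth: float = 0.30
    serration_amp: float = 0.10
    serration_freq: int = 40
    lobe_exponent: float = 2.0
    elongation: float = 1.0
    noise_sd: float = 0.01
    seed: int | None = None

    def validate(self, context: str = "") -> None:
        where = f" ({context})" if context else ""
        if self.radius <= 0:
            raise ParameterError(f"radius must be positive{where}")
        if not 0 <= self.lobe_depth < 0.9:
            raise ParameterError(f"lobe_depth {self.lobe_depth} outside [0, 0.9){where}")
        if not 0 <= self.serration_amp < 0.3:
            raise ParameterError(
                f"serration_amp {self.serration_amp} outside [0, 0.3){where}"
            )
        if self.lobe_depth + self.serration_amp >= 1:
            raise ParameterError(f"lobe_depth + serration_amp must be < 1{where}")
        if self.elongation <= 0:
            raise ParameterError(f"elongation must be positive{where}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0{where}")


@dataclass(frozen=True)
class EffectConfig:
    """Injected factor effects, on generator parameters and log-ion means.

    Shape effects: ``year_elongation`` adds to the y-stretch per year;
    ``block_radius`` drifts the base radius per block (note the morphometric
    chain normalizes size away, so this drift is invisible downstream by
    design); ``rootstock_irrigation_lobe_amp`` scales the fixed interaction
    pattern added to lobe depth. Vine- and leaf-level noise act on lobe depth
    and serration.

    Ion effects are additive shifts on the log-mean concentration; residual
    spread is ``ion_sigma`` log units. ``outlier_fraction`` of rows are
    multiplied by ``outlier_scale`` to plant extreme outliers.
    """

    year_elongation: dict[int, float] = field(
        default_factory=lambda: {2014: 0.0, 2016: 0.08}
    )
    block_radius: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.05, "C": 0.10}
    )
    rootstock_irrigation_lobe_amp: float = 0.10
    vine_lobe_sd: float = 0.02
    leaf_lobe_sd: float = 0.02
    leaf_serration_sd: float = 0.01

    leaf_position_ion: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Ca": {"old": 0.5, "mid": 0.0, "young": -0.5},
            "K": {"old": -0.45, "mid": 0.0, "young": 0.45},
            "Mn": {"old": 0.4, "mid": 0.0, "young": -0.4},
            "Al": {"old": 0.35, "mid": 0.0, "young": -0.35},
            "Rb": {"old": -0.35, "mid": 0.0, "young": 0.35},
        }
    )
    rootstock_ion: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Ni": {"ungrafted": 0.0, "1103P": 0.05, "3309C": 0.10, "SO4": 0.45},
            "Mo": {"ungrafted": 0.0, "1103P": 0.15, "3309C": 0.30, "SO4": 0.45},
        }
    )
    rootstock_irrigation_ion: dict[str, float] = field(
        default_factory=lambda: {"Mo": 0.4, "P": 0.3, "Sr": 0.3, "Rb": 0.3}
    )
    ion_sigma: float = 0.3
    outlier_fraction: float = 0.01
    outlier_scale: float = 1e3


def make_design(seed: int = 0) -> pd.DataFrame:
    """The 288-vine factorial design table.

    Nine rows in three blocks; each block contains one row per irrigation
    level (order permuted by the seed); each row holds eight replicates of the
    four root treatments (planting order permuted by the seed). Margins are
    fixed: 72 vines per rootstock, 96 per irrigation level.
    """
    rng = _rng(seed, "design")
    rows = []
    vine = 0
    for b, block in enumerate(BLOCKS):
        irr_order = list(rng.permutation(IRRIGATION_LEVELS))
        for r in range(3):
            row_num = 3 * b + r + 1
            irrigation = irr_order[r]
            cells = [(rs, rep) for rep in range(1, 9) for rs in ROOTSTOCKS]
            order = rng.permutation(len(cells))
            for pos, idx in enumerate(order, start=1):
                rs, rep = cells[idx]
                vine += 1
                rows.append(
                    {
                        "vine_id": f"V{vine:03d}",
                        "block": block,
                        "row": row_num,
                        "position": pos,
                        "rootstock": rs,
                        "irrigation": irrigation,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def generate_leaf_contour(
    params: LeafGenParams,
    n_points: int = 1000,
    rng: np.random.Generator | None = None,
) -> Contour:
    """Sample one closed leaf outline from the polar shape family."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = params.radius * (
        1.0
        - params.lobe_depth
        * np.abs(np.cos(params.n_lobes * theta / 2.0)) ** params.lobe_exponent
        + params.serration_amp * np.cos(params.serration_freq * theta)
    )
    if params.noise_sd > 0:
        r = r + rng.normal(0.0, params.noise_sd * params.radius, n_points)
    if np.any(r <= 0):
        raise ParameterError("generated radius not strictly positive; reduce depth/noise")
    pts = np.column_stack(
        [r * np.cos(theta), params.elongation * r * np.sin(theta)]
    )
    return Contour(points=pts, closed=True)


def _shifted_params(
    base: LeafGenParams,
    effects: EffectConfig,
    block: str,
    year: int,
    rootstock: str,
    irrigation: str,
    vine_id: str,
) -> LeafGenParams:
    d_shift = effects.rootstock_irrigation_lobe_amp * _INTERACTION_PATTERN[
        ROOTSTOCKS.index(rootstock), IRRIGATION_LEVELS.index(irrigation)
    ]
    p = replace(
        base,
        radius=base.radius + effects.block_radius.get(block, 0.0),
        elongation=base.elongation + effects.year_elongation.get(year, 0.0),
        lobe_depth=base.lobe_depth + d_shift,
    )
    try:
        p.validate(context=f"vine {vine_id}, factors block={block}/year={year}/"
                           f"rootstock={rootstock}/irrigation={irrigation}")
    except ParameterError:
        raise
    return p


def generate_dataset(
    design: pd.DataFrame,
    effects: EffectConfig = EffectConfig(),
    leaves_per_vine: int = 4,
    years: tuple[int, ...] = YEARS,
    seed: int = 0,
    n_points: int = 1000,
    base: LeafGenParams = LeafGenParams(),
) -> tuple[list[LeafRecord], pd.DataFrame, pd.DataFrame]:
    """Generate leaf contours for every vine-year with injected effects.

    Returns ``(records, metadata, truth)``: one :class:`LeafRecord` per leaf
    (``len(design) * len(years) * leaves_per_vine`` in total), the per-vine
    metadata table, and a ground-truth table of the generator parameters
    actually used for each leaf.
    """
    rng = _rng(seed, "leaves")
    records: list[LeafRecord] = []
    truth_rows = []
    for _, vine in design.sort_values("vine_id").iterrows():
        for year in years:
            cell = _shifted_params(
                base,
                effects,
                vine["block"],
                year,
                vine["rootstock"],
                vine["irrigation"],
                vine["vine_id"],
            )
            vine_noise = rng.normal(0.0, effects.vine_lobe_sd)
            for leaf in range(1, leaves_per_vine + 1):
                d = cell.lobe_depth + vine_noise + rng.normal(0.0, effects.leaf_lobe_sd)
                s = cell.serration_amp + rng.normal(0.0, effects.leaf_serration_sd)
                d = float(np.clip(d, 0.0, 0.89))
                s = float(np.clip(s, 0.0, 0.29))
                leaf_params = replace(cell, lobe_depth=d, serration_amp=s)
                leaf_params.validate(context=f"vine {vine['vine_id']} leaf {leaf}")
                contour = generate_leaf_contour(leaf_params, n_points=n_points, rng=rng)
                leaf_id = f"{vine['vine_id']}_{year}_L{leaf}"
                records.append(
                    LeafRecord(
                        leaf_id=leaf_id,
                        vine_id=vine["vine_id"],
                        year=int(year),
                        contour=contour,
                    )
                )
                truth_rows.append(
                    {
                        "leaf_id": leaf_id,
                        "vine_id": vine["vine_id"],
                        "year": int(year),
                        "radius": leaf_params.radius,
                        "lobe_depth": d,
                        "serration_amp": s,
                        "elongation": leaf_params.elongation,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    logger.info("generated %d leaf contours", len(records))
    return records, design.copy(), truth


def generate_ionome(
    design: pd.DataFrame,
    effects: EffectConfig = EffectConfig(),
    years: tuple[int, ...] = YEARS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format ion table with injected gradients.

    Returns ``(table, truth)``; the truth frame repeats the table's keys with
    the noiseless log-mean and an ``is_outlier`` flag for planted extremes.
    One row per vine x year x leaf position x element.
    """
    if effects.ion_sigma < 0:
        raise ParameterError("ion_sigma must be >= 0")
    if not 0 <= effects.outlier_fraction < 1:
        raise ParameterError("outlier_fraction must be in [0, 1)")
    rng = _rng(seed, "ions")
    design = design.sort_values("vine_id")
    n_rows = len(design) * len(years) * len(LEAF_POSITIONS) * len(ELEMENTS)
    vine_rep = design.loc[design.index.repeat(len(years) * len(LEAF_POSITIONS) * len(ELEMENTS))]
    year_col = np.tile(
        np.repeat(list(years), len(LEAF_POSITIONS) * len(ELEMENTS)), len(design)
    )
    pos_col = np.tile(np.repeat(LEAF_POSITIONS, len(ELEMENTS)), len(design) * len(years))
    elem_col = np.tile(list(ELEMENTS), len(design) * len(years) * len(LEAF_POSITIONS))

    log_mean = np.log([ELEMENTS[e] for e in elem_col])
    rs = vine_rep["rootstock"].to_numpy()
    irr = vine_rep["irrigation"].to_numpy()
    for element, shifts in effects.leaf_position_ion.items():
        mask = elem_col == element
        log_mean[mask] += np.vectorize(shifts.get)(pos_col[mask])
    for element, shifts in effects.rootstock_ion.items():
        mask = elem_col == element
        log_mean[mask] += np.vectorize(shifts.get)(rs[mask])
    if effects.rootstock_irrigation_ion:
        pattern = _INTERACTION_PATTERN[
            np.searchsorted(ROOTSTOCKS, rs), np.searchsorted(IRRIGATION_LEVELS, irr)
        ]
        for element, amp in effects.rootstock_irrigation_ion.items():
            mask = elem_col == element
            log_mean[mask] += amp * pattern[mask]

    log_conc = log_mean + rng.normal(0.0, effects.ion_sigma, n_rows)
    conc = np.exp(log_conc)
    is_outlier = rng.random(n_rows) < effects.outlier_fraction
    conc[is_outlier] *= effects.outlier_scale

    table = pd.DataFrame(
        {
            "vine_id": vine_rep["vine_id"].to_numpy(),
            "year": year_col.astype(int),
            "leaf_position": pos_col,
            "element": elem_col,
            "concentration": conc,
        }
    )
    truth = table.drop(columns="concentration").assign(
        log_mean=log_mean, is_outlier=is_outlier
    )
    logger.info("generated %d ion rows (%d planted outliers)", n_rows, is_outlier.sum())
    return table, truth
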