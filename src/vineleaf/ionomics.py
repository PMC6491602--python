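"""Leaf ionomics QC and per-element variance partitioning.

Concentration tables arrive in long format (one row per vine x year x leaf
position x element, mg per kg dry weight). QC removes extreme outliers per
element within each sampling year using a wide interquartile-range fence:
values outside [Q1 - k*IQR, Q3 + k*IQR] with k = 5 are dropped — wide enough
to keep biological variation and catch only instrument-scale artifacts.
Quantiles use the linear-interpolation convention (R type 7). Each element is
then modeled with the ordered 8-term design (block, irrigation, leaf
position, irrigation:leaf, rootstock, rootstock:irrigation, rootstock:leaf,
year) and sequential sums of squares.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .exceptions import DataError
from .varpart import ION_TERMS, sequential_anova

logger = logging.getLogger(__name__)

__all__ = ["filter_outliers_iqr", "filter_ion_table", "run_per_element"]

ION_COLUMNS = ["vine_id", "year", "leaf_position", "element", "concentration"]


def filter_outliers_iqr(
    values: np.ndarray, k: float = 5.0
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """IQR fence filter on one stratum of concentrations.

    Returns ``(kept_values, removed_indices, (lower, upper))`` with
    lower = Q1 - k*IQR and upper = Q3 + k*IQR under the linear-interpolation
    quantile convention. Fewer than 4 values: nothing is filtered (a warning
    is emitted) and the bounds are (-inf, inf).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 values; outlier filter skipped", stacklevel=2)
        return values, np.empty(0, dtype=int), (-np.inf, np.inf)
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation (R type 7)
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    keep = (values >= lower) & (values <= upper)
    return values[keep], np.flatnonzero(~keep), (float(lower), float(upper))


def filter_ion_table(
    table: pd.DataFrame, k: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the IQR fence within each (element, year) stratum.

    Returns ``(filtered_table, report)`` where the report has one row per
    stratum: n_before, n_removed, n_after and the bounds used.
    """
    missing = [c for c in ION_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"ion table missing columns: {missing}")
    if not np.all(np.isfinite(table["concentration"])) or (table["concentration"] <= 0).any():
        raise DataError("concentrations must be finite and positive")
    kept_frames = []
    report_rows = []
    for (element, year), grp in table.groupby(["element", "year"], sort=True):
        vals = grp["concentration"].to_numpy(float)
        _, removed_idx, (lo, hi) = filter_outliers_iqr(vals, k=k)
        keep_mask = np.ones(len(grp), dtype=bool)
        keep_mask[removed_idx] = False
        kept_frames.append(grp.iloc[keep_mask])
        report_rows.append(
            {
                "element": element,
                "year": year,
                "n_before": len(grp),
                "n_removed": int((~keep_mask).sum()),
                "n_after": int(keep_mask.sum()),
                "lower": lo,
                "upper": hi,
            }
        )
        if (~keep_mask).any():
            logger.info(
                "element %s year %s: removed %d outliers", element, year, (~keep_mask).sum()
            )
    filtered = pd.concat(kept_frames, ignore_index=True)
    return filtered, pd.DataFrame(report_rows)


def run_per_element(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str] = ION_TERMS,
    k: float = 5.0,
    elements: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Outlier-filter then variance-partition each element.

    ``metadata`` provides the design factors per vine (block, row, rootstock,
    irrigation). Returns ``(anova_tables, filter_report)`` with one ANOVA
    table per element present. Requested elements absent from the table are
    skipped with a warning.
    """
    filtered, report = filter_ion_table(table, k=k)
    present = sorted(filtered["element"].unique())
    wanted = present if elements is None else elements
    meta_cols = [c for c in metadata.columns if c != "year"]
    tables: dict[str, pd.DataFrame] = {}
    for element in wanted:
        if element not in present:
            warnings.warn(f"element {element!r} absent from ion table; skipped", stacklevel=2)
            continue
        sub = filtered[filtered["element"] == element].merge(
            metadata[meta_cols], on="vine_id", how="left", validate="many_to_one"
        )
        factor_cols = sorted(
            {f for t in terms for f in t.split(":") if f in meta_cols}
        )
        if sub[factor_cols].isna().any(axis=1).any():
            bad = sorted(sub.loc[sub[factor_cols].isna().any(axis=1), "vine_id"].unique())
            raise DataError(f"metadata does not cover vines: {bad[:10]}")
        tables[element] = sequential_anova(sub, "concentration", terms)
    return tables, report
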