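"""Ordered-factor linear models with sequential (Type I) sums of squares.

Each response (a shape descriptor, a morphometric PC score, or an element
concentration) is fit by ordinary least squares on an ordered list of
categorical terms (main effects and pairwise interactions, treatment-coded
with the alphabetically first level as reference). Each term's sum of squares
is the drop in residual SS when its columns are added after all preceding
terms — R's ``anova(lm(...))`` decomposition — so on unbalanced data the term
order matters and is recorded with every table.

Percent variance explained is 100 * SS_term / SS_total where SS_total is the
total sum of squares about the mean (terms plus residual), i.e. each factor's
share of all variation in the response. No multiple-testing correction is
applied across responses or terms; reports keep raw p-values and filter at
p < alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "MORPHOMETRIC_TERMS",
    "ION_TERMS",
    "build_design",
    "sequential_anova",
    "filter_significant",
    "run_pc_models",
]

# term orders follow the study's figure layout per response family
MORPHOMETRIC_TERMS = ["block", "year", "rootstock", "irrigation", "rootstock:irrigation"]
ION_TERMS = [
    "block",
    "irrigation",
    "leaf_position",
    "irrigation:leaf_position",
    "rootstock",
    "rootstock:irrigation",
    "rootstock:leaf_position",
    "year",
]


def _indicator_block(series: pd.Series, factor: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicators (reference = alphabetically first level)."""
    values = series.astype(str).to_numpy()
    levels = sorted(pd.unique(values))
    if isinstance(series.dtype, pd.CategoricalDtype):
        declared = [str(level) for level in series.dtype.categories]
        unused = sorted(set(declared) - set(levels))
        if unused:
            warnings.warn(
                f"factor {factor!r}: declared levels {unused} unobserved; ignored",
                stacklevel=3,
            )
    cols = [(values == lvl).astype(float) for lvl in levels[1:]]
    names = [f"{factor}[{lvl}]" for lvl in levels[1:]]
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def build_design(
    table: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, dict[str, slice], list[str], list[str]]:
    """Expand ordered terms into a design matrix with intercept.

    Returns ``(X, term_slices, column_names, dropped_terms)``. Interaction
    columns are products of the parents' indicator columns. A term whose
    factor has a single observed level contributes no columns and is dropped
    with a warning.
    """
    n = len(table)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["Intercept"]
    term_slices: dict[str, slice] = {}
    dropped: list[str] = []
    start = 1
    for term in terms:
        factors = term.split(":")
        for f in factors:
            if f not in table.columns:
                raise DataError(f"term {term!r}: factor {f!r} not in table")
        if len(factors) == 1:
            block, bnames = _indicator_block(table[factors[0]], factors[0])
        elif len(factors) == 2:
            a, anames = _indicator_block(table[factors[0]], factors[0])
            b, bnames_ = _indicator_block(table[factors[1]], factors[1])
            block = np.einsum("ni,nj->nij", a, b).reshape(n, -1)
            bnames = [f"{x}:{y}" for x in anames for y in bnames_]
        else:
            raise ParameterError(f"only main effects and pairwise interactions: {term!r}")
        if block.shape[1] == 0:
            warnings.warn(f"term {term!r} has a single observed level; dropped", stacklevel=2)
            dropped.append(term)
            continue
        blocks.append(block)
        names.extend(bnames)
        term_slices[term] = slice(start, start + block.shape[1])
        start += block.shape[1]
    return np.hstack(blocks), term_slices, names, dropped


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def sequential_anova(
    table: pd.DataFrame, response: str, terms: list[str]
) -> pd.DataFrame:
    """Type I ANOVA table for one response.

    Returns a frame with one row per term plus a ``Residual`` row and columns
    ``term, df, ss, mean_sq, F, p, percent_var``. Aliased terms (zero rank
    gain) keep df = 0 with undefined F/p. Raises if the model leaves no
    residual degrees of freedom.
    """
    y = table[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise DataError(f"response {response!r} has non-finite values")
    X, term_slices, _, dropped = build_design(table, terms)
    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0:
        raise DataError(f"response {response!r} is constant")
    kept = [t for t in terms if t not in dropped]
    rows = []
    Xc = X[:, :1]
    rss_prev, rank_prev = _rss_rank(Xc, y)
    for term in kept:
        Xc = np.hstack([Xc, X[:, term_slices[term]]])
        rss, rank = _rss_rank(Xc, y)
        df_t = rank - rank_prev
        ss = max(rss_prev - rss, 0.0)
        if df_t == 0:
            warnings.warn(f"term {term!r} aliased with earlier terms (df = 0)", stacklevel=2)
        rows.append({"term": term, "df": df_t, "ss": ss})
        rss_prev, rank_prev = rss, rank
    rss_full, rank_full = rss_prev, rank_prev
    df_resid = n - rank_full
    if df_resid <= 0:
        raise DataError("zero residual degrees of freedom; model is saturated")
    ms_resid = rss_full / df_resid
    for row in rows:
        if row["df"] > 0 and ms_resid > 0:
            row["mean_sq"] = row["ss"] / row["df"]
            row["F"] = row["mean_sq"] / ms_resid
            row["p"] = float(stats.f.sf(row["F"], row["df"], df_resid))
        else:
            row["mean_sq"] = np.nan
            row["F"] = np.nan
            row["p"] = np.nan
        row["percent_var"] = 100.0 * row["ss"] / ss_total
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "ss": rss_full,
            "mean_sq": ms_resid,
            "F": np.nan,
            "p": np.nan,
            "percent_var": 100.0 * rss_full / ss_total,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["response"] = response
    out.attrs["term_order"] = list(kept)
    return out


def filter_significant(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Long-format report of significant terms across responses.

    Keeps rows with p < alpha (the Residual row never qualifies), sorted by
    response name then by each table's own term order. Raw p-values; no
    multiple-testing correction.
    """
    records = []
    for response in sorted(tables):
        tab = tables[response]
        for _, row in tab.iterrows():
            if row["term"] != "Residual" and np.isfinite(row["p"]) and row["p"] < alpha:
                records.append(
                    {
                        "response": response,
                        "term": row["term"],
                        "percent_var": row["percent_var"],
                        "p": row["p"],
                    }
                )
    return pd.DataFrame(records, columns=["response", "term", "percent_var", "p"])


def run_pc_models(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str] = MORPHOMETRIC_TERMS,
    pc_percent_variance: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """One sequential ANOVA per PC score column.

    ``scores`` carries ``vine_id``, ``year`` and ``PC*`` columns; ``metadata``
    the design factors per vine (optionally per vine-year). If supplied,
    ``pc_percent_variance`` (each PC's own share of total shape variance) is
    attached to each table's attrs, mirroring how the share is reported next
    to the factor decomposition.
    """
    join_keys = ["vine_id", "year"] if "year" in metadata.columns else ["vine_id"]
    merged = scores.merge(metadata, on=join_keys, how="left", validate="many_to_one")
    factor_cols = sorted({f for t in terms for f in t.split(":") if f in metadata.columns})
    missing = merged[factor_cols].isna().any(axis=1)
    if missing.any():
        bad = sorted(merged.loc[missing, "vine_id"].unique())
        raise DataError(f"metadata join missed vines: {bad[:10]}")
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    out: dict[str, pd.DataFrame] = {}
    for j, pc in enumerate(pc_cols):
        tab = sequential_anova(merged, pc, terms)
        if pc_percent_variance is not None and j < len(pc_percent_variance):
            tab.attrs["pc_percent_variance"] = float(pc_percent_variance[j])
        out[pc] = tab
    return out


def anova_long_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-response ANOVA tables into one long CSV-ready frame."""
    frames = []
    for response in sorted(tables):
        tab = tables[response].copy()
        tab.insert(0, "response", response)
        if "pc_percent_variance" in tables[response].attrs:
            tab["pc_percent_variance"] = tables[response].attrs["pc_percent_variance"]
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
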