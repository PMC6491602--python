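"""End-to-end orchestration: synthetic or file inputs -> descriptor tables,
ECC feature matrix, PCA, variance-partition tables, ionomics QC and models,
and a machine-readable summary.

Every intermediate is persisted as CSV in the output directory and the run
configuration is serialized alongside, so any run is reproducible from its
output directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import contours as cio
from . import descriptors as desc
from . import ionomics as ion
from . import synth
from . import tda
from . import varpart as vp
from .config import RunConfig
from .contours import LeafRecord
from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = ["run_morphometrics", "run_ionomics", "report", "load_leaf_records"]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    return out


def _parse_leaf_id(leaf_id: str) -> tuple[str, int]:
    """Leaf ids follow ``<vine>_<year>_<leaf>``; vine may not contain '_'."""
    parts = leaf_id.split("_")
    if len(parts) < 3:
        raise DataError(
            f"leaf id {leaf_id!r} not of the form <vine>_<year>_<leaf>"
        )
    return parts[0], int(parts[1])


def load_leaf_records(config: RunConfig) -> tuple[list[LeafRecord], pd.DataFrame]:
    """Resolve leaf contours + metadata from config (synthetic or files)."""
    if config.contours_csv:
        raw = cio.read_contours_csv(config.contours_csv)
        records = []
        for leaf_id, contour in raw.items():
            vine_id, year = _parse_leaf_id(leaf_id)
            records.append(LeafRecord(leaf_id, vine_id, year, contour))
        metadata = pd.read_csv(config.metadata_csv)
    elif config.masks_dir:
        records = []
        paths = sorted(
            p
            for p in Path(config.masks_dir).iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        for path in paths:
            leaf_id = path.stem
            vine_id, year = _parse_leaf_id(leaf_id)
            mask = cio.load_mask(path)
            records.append(LeafRecord(leaf_id, vine_id, year, cio.extract_contour(mask)))
        metadata = pd.read_csv(config.metadata_csv)
    else:
        design = synth.make_design(config.seed)
        records, metadata, truth = synth.generate_dataset(
            design,
            leaves_per_vine=config.leaves_per_vine,
            years=config.years,
            seed=config.seed,
            n_points=config.n_points,
        )
        truth.to_csv(Path(config.outdir) / "ground_truth_leaves.csv", index=False)
    return records, metadata


def run_morphometrics(config: RunConfig) -> dict[str, object]:
    """Full morphometric chain; persists every intermediate.

    Outputs: per-leaf and per-plant descriptor tables, the per-plant ECC
    feature matrix, PCA scores/loadings/percent-variance, one ANOVA table per
    descriptor and per PC (long CSVs), and the significant-term matrix.
    """
    out = _outdir(config)
    records, metadata = load_leaf_records(config)
    logger.info("morphometrics: %d leaves read", len(records))

    tda_cfg = tda.TDAConfig(
        n_rings=config.n_rings,
        n_thresholds=config.n_thresholds,
        bandwidth=config.bandwidth,
        connectivity_eps_factor=config.connectivity_eps_factor,
        n_points=config.n_points,
        n_components=config.n_components,
    )

    desc_rows = []
    feat_records = []
    n_dropped = 0
    for rec in records:
        try:
            prepared = cio.normalize_contour(
                cio.resample_contour(rec.contour, config.n_points)
            )
            d = desc.compute_descriptors(
                prepared, include_pi=config.imagej_circularity, validate=False
            )
            vec = tda.featurize_leaf(prepared, tda_cfg)
        except Exception as exc:
            n_dropped += 1
            logger.warning("dropping leaf %s: %s", rec.leaf_id, exc)
            continue
        desc_rows.append(
            {"leaf_id": rec.leaf_id, "vine_id": rec.vine_id, "year": rec.year, **d.as_dict()}
        )
        feat_records.append((rec.leaf_id, rec.vine_id, rec.year, vec))
    logger.info("morphometrics: %d leaves featurized, %d dropped", len(desc_rows), n_dropped)

    leaf_desc = pd.DataFrame(desc_rows)
    leaf_desc.to_csv(out / "leaf_descriptors.csv", index=False)
    plant_desc = desc.aggregate_per_plant(leaf_desc.drop(columns=["leaf_id"]))
    plant_desc.to_csv(out / "plant_descriptors.csv", index=False)

    features = tda.feature_frame(feat_records)
    plant_features = tda.average_plant_features(features)
    plant_features.to_csv(out / "feature_matrix.csv", index=False)
    logger.info("morphometrics: %d plants averaged", len(plant_features))

    pca = tda.pca_features(plant_features, config.n_components)
    pca.scores.to_csv(out / "pca_scores.csv", index=False)
    pca.loadings.to_csv(out / "pca_loadings.csv")
    pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(len(pca.percent_variance))],
            "percent_variance": pca.percent_variance,
        }
    ).to_csv(out / "pca_percent_variance.csv", index=False)

    join_keys = ["vine_id", "year"] if "year" in metadata.columns else ["vine_id"]
    desc_tables: dict[str, pd.DataFrame] = {}
    merged = plant_desc.merge(metadata, on=join_keys, validate="many_to_one")
    for col in desc.DESCRIPTOR_COLUMNS:
        desc_tables[col] = vp.sequential_anova(merged, col, config.morpho_terms)
    vp.anova_long_table(desc_tables).to_csv(out / "anova_descriptors.csv", index=False)

    pc_tables = vp.run_pc_models(
        pca.scores, metadata, config.morpho_terms, pca.percent_variance
    )
    vp.anova_long_table(pc_tables).to_csv(out / "anova_pcs.csv", index=False)

    sig = vp.filter_significant({**desc_tables, **pc_tables}, config.alpha)
    sig.to_csv(out / "significant_terms_morphometrics.csv", index=False)

    return {
        "leaf_descriptors": leaf_desc,
        "plant_descriptors": plant_desc,
        "feature_matrix": plant_features,
        "pca": pca,
        "descriptor_tables": desc_tables,
        "pc_tables": pc_tables,
        "significant": sig,
        "n_dropped": n_dropped,
    }


def run_ionomics(config: RunConfig) -> dict[str, object]:
    """Ionomics QC + per-element variance partitioning; persists CSVs."""
    out = _outdir(config)
    if config.ion_csv:
        table = pd.read_csv(config.ion_csv)
        missing = [c for c in ion.ION_COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"ion CSV missing columns: {missing}")
        metadata = pd.read_csv(config.metadata_csv)
    else:
        design = synth.make_design(config.seed)
        table, truth = synth.generate_ionome(design, years=config.years, seed=config.seed)
        truth.to_csv(out / "ground_truth_ions.csv", index=False)
        metadata = design
    table.to_csv(out / "ion_table.csv", index=False)

    tables, filter_report = ion.run_per_element(
        table, metadata, terms=config.ion_terms, k=config.iqr_k
    )
    filter_report.to_csv(out / "ion_filter_report.csv", index=False)
    vp.anova_long_table(tables).to_csv(out / "anova_elements.csv", index=False)
    sig = vp.filter_significant(tables, config.alpha)
    sig.to_csv(out / "significant_terms_ions.csv", index=False)
    filtered, _ = ion.filter_ion_table(table, k=config.iqr_k)
    filtered.to_csv(out / "ion_table_filtered.csv", index=False)
    return {
        "ion_table": table,
        "element_tables": tables,
        "filter_report": filter_report,
        "significant": sig,
    }


def report(outdir: str | Path, make_figures: bool = True) -> dict[str, object]:
    """Summarize a completed run: headline numbers as JSON, plus figures.

    For each element the factor with the largest percent variance is
    identified and its grouped distribution is drawn as a boxplot; the
    significant-term matrices are rendered as heatmaps. Figures are
    conveniences — every underlying table is already on disk as CSV.
    """
    out = Path(outdir)
    summary: dict[str, object] = {}

    pv_path = out / "pca_percent_variance.csv"
    if pv_path.exists():
        pv = pd.read_csv(pv_path)
        summary["pc1_percent_variance"] = float(pv["percent_variance"].iloc[0])
        summary["pc_cumulative_percent_variance"] = float(pv["percent_variance"].sum())

    sig_m = out / "significant_terms_morphometrics.csv"
    if sig_m.exists():
        sig = pd.read_csv(sig_m)
        summary["n_significant_morphometric_terms"] = int(len(sig))
        if sig.empty:
            summary["morphometrics_note"] = "no significant terms"

    top_factors: dict[str, dict[str, float | str]] = {}
    anova_e = out / "anova_elements.csv"
    if anova_e.exists():
        tab = pd.read_csv(anova_e)
        tab = tab[tab["term"] != "Residual"]
        for element, grp in tab.groupby("response"):
            best = grp.loc[grp["percent_var"].idxmax()]
            top_factors[element] = {
                "factor": best["term"],
                "percent_var": float(best["percent_var"]),
                "p": float(best["p"]) if np.isfinite(best["p"]) else None,
            }
        summary["element_top_factors"] = top_factors
    sig_i = out / "significant_terms_ions.csv"
    if sig_i.exists():
        sig = pd.read_csv(sig_i)
        summary["n_significant_ion_terms"] = int(len(sig))
        if sig.empty:
            summary["ionomics_note"] = "no significant terms"

    if make_figures:
        _figures(out, top_factors)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _pivot_heatmap(ax, sig: pd.DataFrame, title: str) -> None:
    pivot = sig.pivot_table(
        index="response", columns="term", values="percent_var", aggfunc="first"
    )
    im = ax.imshow(pivot.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="% variance")


def _figures(out: Path, top_factors: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, fname in [
        ("significant_terms_morphometrics.csv", "fig_morphometrics_matrix.png"),
        ("significant_terms_ions.csv", "fig_ions_matrix.png"),
    ]:
        path = out / name
        if path.exists():
            sig = pd.read_csv(path)
            if not sig.empty:
                fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * sig["response"].nunique())))
                _pivot_heatmap(ax, sig, name.replace(".csv", ""))
                fig.tight_layout()
                fig.savefig(out / fname, dpi=120)
                plt.close(fig)

    ion_path = out / "ion_table_filtered.csv"
    if ion_path.exists() and top_factors:
        ions = pd.read_csv(ion_path)
        meta = None
        design_factors = {"rootstock", "irrigation", "block"}
        for element, info in list(top_factors.items())[:6]:
            factor = str(info["factor"]).split(":")[0]
            sub = ions[ions["element"] == element]
            if factor in ("leaf_position", "year"):
                groups = sub.groupby(factor)["concentration"]
            elif factor in design_factors:
                if meta is None:
                    cfg_path = out / "config.yaml"
                    seed = RunConfig.from_yaml(cfg_path).seed if cfg_path.exists() else 0
                    meta = synth.make_design(seed)[
                        ["vine_id", "rootstock", "irrigation", "block"]
                    ]
                joined = sub.merge(meta, on="vine_id", how="left")
                if joined[factor].isna().all():
                    continue
                groups = joined.groupby(factor)["concentration"]
            else:
                continue
            fig, ax = plt.subplots(figsize=(5, 4))
            labels, data = zip(*[(k, v.to_numpy()) for k, v in groups])
            ax.boxplot(data, tick_labels=labels)
            ax.set_yscale("log")
            ax.set_ylabel(f"{element} (mg/kg)")
            ax.set_title(f"{element} by {factor}")
            fig.tight_layout()
            fig.savefig(out / f"fig_box_{element}.png", dpi=120)
            plt.close(fig)
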