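"""Structure-activity reporting: selectivity arithmetic, panel summaries, and
the end-to-end study pipeline.

The lead-compound narrative of a kinase-inhibitor campaign rests on simple
ratio arithmetic over measured IC50s — fold-selectivity between kinases,
tumour-versus-normal selectivity indices across cell lines, and a
percent-inhibition screen over a kinase panel. This module implements that
arithmetic and orchestrates the full bundled-data analysis: consistency
checks, both QSAR model refits with leave-one-out validation and 95%
confidence/prediction bands, and the selectivity report for the most
potent compound.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset_io, mlr_core
from .dataset_io import DatasetError

logger = logging.getLogger("qsarforge")

#: The two study models: response column -> descriptor subset.
STUDY_MODELS = {
    "pIC50_RAF1": ("IW1", "FLEX"),
    "pIC50_V600E": ("ACDODO", "IW2", "DD8", "PSA"),
}

#: Lead compound of the bundled study data.
LEAD_COMPOUND = "1zb"
LEAD_ON_TARGET = "V600E-B-RAF"


def selectivity_ratio(off_target_ic50: float, on_target_ic50: float) -> float:
    """Fold-selectivity of an inhibitor for its on-target kinase.

    Both IC50s in molar; returns off/on unrounded (>1 means the compound is
    that many fold more potent against the on-target kinase). Display
    convention is two decimals.
    """
    if not (off_target_ic50 > 0 and on_target_ic50 > 0):
        raise DatasetError("IC50 values must be positive")
    return off_target_ic50 / on_target_ic50


def cell_selectivity_index(normal_ic50: float, tumour_ic50: float) -> float:
    """Selectivity index normal-cell IC50 / tumour-cell IC50 (molar inputs)."""
    if not (normal_ic50 > 0 and tumour_ic50 > 0):
        raise DatasetError("IC50 values must be positive")
    return normal_ic50 / tumour_ic50


def panel_summary(panel: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Kinases whose mean percent inhibition meets the threshold, sorted descending.

    ``panel`` needs columns ``kinase`` and ``pct_inhibition``; values may be
    negative (activation) and are never clamped. Inclusion is
    ``pct_inhibition >= threshold``; pass a strict screen (e.g. 'more than
    75%') by nudging the threshold above the printed cut, see
    :func:`strict_hits`.
    """
    if not -100.0 <= threshold <= 110.0:
        raise ValueError(f"threshold {threshold} outside the plausible range [-100, 110]")
    hits = panel[panel["pct_inhibition"] >= threshold]
    return hits.sort_values("pct_inhibition", ascending=False).reset_index(drop=True)


def strict_hits(panel: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Kinases with percent inhibition strictly greater than the threshold.

    The follow-up-selection screen ('more than 75% inhibition goes to
    10-dose IC50 determination') is a strict inequality, unlike the
    inclusive :func:`panel_summary`.
    """
    hits = panel[panel["pct_inhibition"] > threshold]
    return hits.sort_values("pct_inhibition", ascending=False).reset_index(drop=True)


def lead_selectivity_report(
    compound: str = LEAD_COMPOUND,
    on_target: str = LEAD_ON_TARGET,
) -> dict:
    """Kinase fold-selectivities and cell-line selectivity indices for a compound.

    Ratios are computed from unrounded molar IC50s and reported both raw
    and at the conventional two decimals.
    """
    kin = [r for r in dataset_io.load_kinase_potencies() if r.compound_id == compound]
    on = [r for r in kin if r.target == on_target]
    if not on:
        raise DatasetError(f"no on-target ({on_target}) potency for {compound}")
    on_ic50 = on[0].ic50

    off_targets = []
    for rec in kin:
        if rec.target == on_target:
            continue
        ratio = selectivity_ratio(rec.ic50, on_ic50)
        off_targets.append({
            "target": rec.target,
            "ic50_molar": rec.ic50,
            "fold_ratio": ratio,
            "fold_ratio_2dp": round(ratio, 2),
        })

    cells = dataset_io.load_cell_potencies()
    cells = cells[cells["compound"] == compound]
    normal = cells[cells["group"] == "normal_skin"]
    if len(normal) != 1:
        raise DatasetError(f"expected exactly one normal-cell line for {compound}")
    normal_ic50 = float(normal["ic50_molar"].iloc[0])
    cell_lines = []
    for r in cells[cells["group"] == "melanoma"].itertuples():
        idx = cell_selectivity_index(normal_ic50, r.ic50_molar)
        cell_lines.append({
            "cell_line": r.cell_line,
            "ic50_molar": r.ic50_molar,
            "selectivity_index": idx,
            "selectivity_index_2dp": round(idx, 2),
        })

    return {
        "compound_id": compound,
        "on_target": {"target": on_target, "ic50_molar": on_ic50},
        "off_targets": off_targets,
        "normal_cell_line": {"cell_line": str(normal["cell_line"].iloc[0]),
                             "ic50_molar": normal_ic50},
        "cell_lines": cell_lines,
    }


def run_study_analysis(out_dir: str | Path) -> dict:
    """Run the complete bundled-data analysis and write the report bundle.

    Steps: verify the potency/descriptor fixtures agree; refit the
    two-descriptor and four-descriptor QSAR models on their respective
    response sets; leave-one-out validate both; export model JSONs, a
    statistics table, experimental-versus-predicted scatter CSVs with 95%
    confidence and prediction bands, the lead-compound selectivity report,
    and the kinase-panel hit lists. The pipeline is deterministic — no
    random numbers anywhere — so reruns are byte-identical.
    """
    out_dir = Path(out_dir)
    (out_dir / "models").mkdir(parents=True, exist_ok=True)

    logger.info("checking fixture consistency")
    table = dataset_io.load_descriptor_table()
    potencies = dataset_io.load_kinase_potencies()
    problems = dataset_io.check_fixture_consistency(potencies, table)
    if problems:
        raise DatasetError(f"fixture potency/pIC50 mismatch: {problems}")

    stats_rows = []
    results: dict = {"models": {}}
    for response, subset in STUDY_MODELS.items():
        logger.info("fitting %s on %s", response, subset)
        ds = dataset_io.build_qsar_dataset(table, response, subset)
        model = mlr_core.fit_ols(ds)
        stats = mlr_core.goodness_of_fit(model, ds)
        loo = mlr_core.loo_cross_validate(ds)
        band = mlr_core.prediction_band(model, ds, level=0.95)

        tag = response.removeprefix("pIC50_")
        mlr_core.model_to_json(model, ds, stats, loo, out_dir / "models" / f"{tag}.json")
        stats_rows.append({
            "model": tag, "n": ds.n, "p": ds.p,
            "R2": stats.R2, "Q2_LOO": loo.Q2, "F": stats.F, "s": stats.s,
            "RSS": stats.RSS, "PRESS": loo.PRESS,
            "intercept": model.intercept,
            **{f"b_{nm}": c for nm, c in zip(model.descriptor_names, model.coefficients)},
        })
        fitted = band["fit"]
        scatter = pd.DataFrame({
            "compound": ds.ids,
            "experimental": ds.y,
            "predicted": fitted,
            "loo_predicted": loo.heldout_predictions,
            "conf95_lo": fitted - band["confidence_halfwidth"],
            "conf95_hi": fitted + band["confidence_halfwidth"],
            "pred95_lo": fitted - band["prediction_halfwidth"],
            "pred95_hi": fitted + band["prediction_halfwidth"],
        })
        scatter.to_csv(out_dir / f"scatter_{tag}.csv", index=False, float_format="%.6f")
        results["models"][tag] = {"model": model, "stats": stats, "loo": loo, "dataset": ds}

    pd.DataFrame(stats_rows).to_csv(out_dir / "stats.csv", index=False, float_format="%.6f")

    logger.info("building selectivity report for %s", LEAD_COMPOUND)
    selectivity = lead_selectivity_report()
    (out_dir / f"selectivity_{LEAD_COMPOUND}.json").write_text(json.dumps(selectivity, indent=1))

    panel = dataset_io.load_kinase_panel()
    hits50 = panel_summary(panel, 50.0)
    hits50.to_csv(out_dir / "panel_hits.csv", index=False)
    results["selectivity"] = selectivity
    results["panel_hits_50pct"] = hits50
    results["panel_hits_over75pct"] = strict_hits(panel, 75.0)
    results["stats_table"] = pd.DataFrame(stats_rows)
    logger.info("report bundle written to %s", out_dir)
    return results
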