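"""End-to-end run orchestration and deterministic run reports."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import elisa as elisa_mod
from .io import (
    FormatError,
    SampleManifest,
    SpotTable,
    read_gpr,
    read_manifest,
    write_results,
    write_snr_matrix,
)
from .preprocess import NegativityThresholds, preprocess_cohort
from .ranking import rf_importance
from .screening import (
    ScreenCriteria,
    classify_marker,
    screen_all,
    summarize_counts,
    volcano_table,
)

COUNT_CHECK_COLUMNS = ("isotype", "rc_pos", "hc_pos", "fc", "p")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def dump_report(report: dict, path: str | Path) -> None:
    """Serialize a run report deterministically (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_screen(
    spot_tables: list[SpotTable],
    manifest: SampleManifest,
    *,
    criteria: ScreenCriteria | None = None,
    thresholds: NegativityThresholds | None = None,
    negativity_on: str = "raw",
    negativity_mode: str = "per_isotype",
    rf_trees: int = 500,
    seed: int = 0,
    top_k: int = 30,
    out_dir: str | Path | None = None,
) -> dict:
    """Preprocess -> screen -> rank, returning (and optionally writing) a report.

    The report carries the resolved configuration, per-isotype label counts
    (a partition of the protein universe), the volcano table size, the
    top-k random-forest importances over Up markers, and any warnings.
    Deterministic given identical inputs and seed.
    """
    criteria = criteria or ScreenCriteria()
    thresholds = thresholds or NegativityThresholds()
    manifest.validate()
    normalized, excluded = preprocess_cohort(
        spot_tables,
        thresholds=thresholds,
        negativity_on=negativity_on,  # type: ignore[arg-type]
        negativity_mode=negativity_mode,  # type: ignore[arg-type]
    )
    results = screen_all(
        normalized["IgG"], normalized["IgM"], manifest, criteria, excluded
    )
    counts = summarize_counts(results)
    volcano = volcano_table(results)

    warnings: list[str] = []
    importance_records: list[dict] = []
    up = results[results["label"] == "Up"]
    if len(up) >= 1:
        # feature matrix: samples x Up markers, one column per protein x isotype
        cols = {}
        for r in up.itertuples():
            matrix = normalized[r.isotype].values
            cols[f"{r.protein_id}|{r.isotype}"] = matrix.loc[r.protein_id]
        feats = pd.DataFrame(cols)
        y = manifest.groups.loc[feats.index].to_numpy()
        importance = rf_importance(feats, y, n_trees=rf_trees, seed=seed)
        importance_records = importance.head(top_k).to_dict("records")
    else:
        warnings.append("no Up markers; importance ranking skipped")

    report = {
        "config": {
            "criteria": asdict(criteria),
            "negativity": {
                "igg_max": thresholds.igg_max,
                "igm_max": thresholds.igm_max,
                "on": negativity_on,
                "mode": negativity_mode,
            },
            "rf_trees": rf_trees,
            "seed": seed,
        },
        "n_arrays": int(len(spot_tables)),
        "group_counts": manifest.group_counts(),
        "counts": counts,
        "n_volcano_rows": int(len(volcano)),
        "top_importance": importance_records,
        "warnings": warnings,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results(results, out_dir / "screen_results.tsv")
        volcano.to_csv(out_dir / "volcano.tsv", sep="\t", index=False)
        for iso, m in normalized.items():
            write_snr_matrix(m, out_dir / f"snr_{iso}_normalized.tsv")
        if importance_records:
            pd.DataFrame(importance_records).to_csv(
                out_dir / "importance.tsv", sep="\t", index=False
            )
        dump_report(report, out_dir / "report.json")
    report["_results"] = results
    return report


def run_count_check(
    table: str | Path | pd.DataFrame, criteria: ScreenCriteria | None = None
) -> dict:
    """Classify each row of a per-marker statistics table and count labels.

    The table needs columns isotype, rc_pos, hc_pos, fc, p (positive
    ratios as fractions). Returns per-isotype per-label counts plus
    convenience totals.
    """
    criteria = criteria or ScreenCriteria()
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    missing = [c for c in COUNT_CHECK_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"count-check table missing columns: {missing}")
    counts: dict[str, dict[str, int]] = {}
    for r in table.itertuples():
        fc = None if pd.isna(r.fc) else float(r.fc)
        label, _ = classify_marker(
            float(r.rc_pos), float(r.hc_pos), fc, float(r.p), criteria
        )
        counts.setdefault(str(r.isotype), {}).setdefault(label, 0)
        counts[str(r.isotype)][label] += 1

    def get(iso: str, label: str) -> int:
        return counts.get(iso, {}).get(label, 0)

    up_total = sum(get(iso, "Up") for iso in counts)
    down_total = sum(get(iso, "Down") for iso in counts)
    return {
        "by_isotype": counts,
        "up_igg": get("IgG", "Up"),
        "up_igm": get("IgM", "Up"),
        "down_igg": get("IgG", "Down"),
        "down_igm": get("IgM", "Down"),
        "up_total": up_total,
        "down_total": down_total,
        "differential_total": up_total + down_total,
    }


def run_elisa(
    plates, groups: pd.Series, *, min_specificity: float = 0.90,
    min_plate_snr: float = 1.0, panel: list[str] | None = None,
    panel_method: str = "logistic",
) -> dict:
    """Score plates, evaluate each marker's ROC, optionally a panel.

    ``plates`` may mix markers; the marker name is taken from the plate id
    prefix before ``_P``. Returns a JSON-ready report.
    """
    by_marker: dict[str, list] = {}
    for p in plates:
        marker = p.plate_id.rsplit("_P", 1)[0]
        by_marker.setdefault(marker, []).append(p)

    scores = {}
    metrics = {}
    for marker, mplates in sorted(by_marker.items()):
        s = elisa_mod.score_cohort(mplates, min_plate_snr=min_plate_snr)
        scores[marker] = s
        rc = s[groups.loc[s.index] == "RC"]
        hc = s[groups.loc[s.index] == "HC"]
        metrics[marker] = elisa_mod.evaluate_marker(rc, hc, min_specificity).to_dict()

    report = {"markers": metrics, "plate_snr": {
        p.plate_id: elisa_mod.plate_snr(p) for p in plates
    }}
    if panel:
        table = pd.DataFrame({m: scores[m] for m in panel}).dropna()
        y = groups.loc[table.index].to_numpy()
        res = elisa_mod.evaluate_panel(
            table, y, method=panel_method, min_specificity=min_specificity
        )
        report["panel"] = {"markers": list(panel), **res.to_dict(),
                           "note": "in-sample combination; AUC is optimistic"}
    return report


def load_cohort_dir(path: str | Path, channel_map: Mapping[str, str]):
    """Read a directory of GPR files plus manifest.(c|t)sv."""
    path = Path(path)
    manifest_file = None
    for name in ("manifest.csv", "manifest.tsv"):
        if (path / name).exists():
            manifest_file = path / name
            break
    if manifest_file is None:
        raise FormatError(f"{path}: no manifest.csv/manifest.tsv found")
    manifest = read_manifest(manifest_file)
    tables = [
        read_gpr(path / f"{array_id}.gpr", channel_map, array_id=array_id)
        for array_id in manifest.table.index
    ]
    return tables, manifest
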