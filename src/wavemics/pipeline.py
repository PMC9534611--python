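"""End-to-end orchestration: simulate -> extract -> filter-icc -> select ->
wavelet -> evaluate -> report.

One global seed fans out deterministically to per-stage seeds (a CRC32 hash
of the stage name, folded below 2^31), so a single integer reproduces every
artifact. Each stage writes its outputs under the working directory and the
final manifest lists every artifact with a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from . import io
from .datatypes import PatientCase
from .evaluation import CLASSIFIER_FAMILIES, comparison_rows, evaluate_grid, select_best
from .extract import extract_cohort_table
from .reliability import build_reliability_stacks, filter_by_icc, icc_report
from .selection import assemble_table, lasso_select, zscore_apply, zscore_fit
from .synthetic import CohortConfig, generate_cohort
from .wavelet import FILTER_BANKS, build_all_profiles

logger = logging.getLogger("wavemics")


@dataclass
class PipelineConfig:
    out_dir: str = "wavemics_run"
    seed: int = 0
    # simulate
    n_patients: int = 16
    class_balance: float = 51.0 / 91.0
    volume_shape: tuple[int, int, int] = (24, 32, 32)
    tumor_radius_range_per_class: dict[int, tuple[float, float]] | None = None
    reader_jitter: float = 0.15
    # extract
    bin_width: float = 64.0
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # filter
    icc_threshold: float = 0.75
    # select
    selection_folds: int = 10
    train_fraction: float = 0.7
    # wavelet
    banks: tuple[str, ...] = FILTER_BANKS
    # evaluate
    families: tuple[str, ...] = CLASSIFIER_FAMILIES
    folds: int = 5
    repeats: int = 100
    stages: tuple[str, ...] = (
        "simulate", "extract", "filter-icc", "select", "wavelet", "evaluate", "report",
    )

    def stage_seed(self, stage: str) -> int:
        return (self.seed + zlib.crc32(stage.encode())) % (2**31 - 1)

    def validate(self) -> None:
        unknown = [b for b in self.banks if b not in FILTER_BANKS]
        if unknown:
            raise ValueError(f"unknown filter bank(s): {unknown}; valid: {list(FILTER_BANKS)}")
        bad = [f for f in self.families if f not in CLASSIFIER_FAMILIES]
        if bad:
            raise ValueError(f"unknown classifier(s): {bad}; valid: {list(CLASSIFIER_FAMILIES)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        for name in ("volume_shape", "target_spacing", "banks", "families", "stages"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _select_features(table: pd.DataFrame, kept: list[str], cfg: PipelineConfig):
    """70/30 stratified split, train-only z-scores, LASSO on the training
    rows; widens the penalty until at least 4 features survive (the wavelet
    layout needs one value per sequence row). Returns the selected names and
    the training normalization (the wavelet stage consumes z-scored values,
    since the DWT mixes columns and needs them on comparable scales)."""
    y = table["label"].to_numpy().astype(int)
    X = table[kept]
    seed = cfg.stage_seed("select")
    idx_train, _ = train_test_split(
        np.arange(len(table)),
        train_size=cfg.train_fraction,
        stratify=y,
        random_state=seed,
    )
    norm = zscore_fit(X.iloc[idx_train])
    Xtr = zscore_apply(norm, X.iloc[idx_train])
    min_class = int(np.bincount(y[idx_train]).min())
    if min_class < 2:
        raise RuntimeError(
            "stage select: need at least 2 training patients per class; "
            "increase n_patients or train_fraction"
        )
    result = lasso_select(Xtr, y[idx_train],
                          folds=min(cfg.selection_folds, min_class), seed=seed)
    selected = result.selected
    c = result.c_chosen
    while len(selected) < 4:
        c *= 3.0
        model = LogisticRegression(
            penalty="l1", C=c, solver="liblinear", max_iter=2000, random_state=seed
        )
        model.fit(Xtr.to_numpy(), y[idx_train])
        coef = pd.Series(model.coef_.ravel(), index=Xtr.columns)
        selected = list(coef[coef != 0].index)
        if c > 1e6:
            raise RuntimeError("selection kept fewer than 4 features at any penalty")
    return selected, norm


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    report: dict = {"seed": config.seed, "stages": {}}

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    t0 = time.time()
    cases: list[PatientCase] | None = None
    reference = occasions = kept = sel_table = profiles = None

    def need_reference():
        nonlocal reference
        if reference is None:
            reference = io.load_table(out / "features_reference.csv")
        return reference

    def need_sel_table():
        nonlocal sel_table
        if sel_table is None:
            sel_table = io.load_table(out / "features_selected.csv")
        return sel_table

    if stage_enabled("simulate"):
        t = time.time()
        kwargs = {}
        if config.tumor_radius_range_per_class is not None:
            kwargs["tumor_radius_range_per_class"] = {
                int(k): tuple(v) for k, v in config.tumor_radius_range_per_class.items()
            }
        cohort_cfg = CohortConfig(
            n_patients=config.n_patients,
            class_balance=config.class_balance,
            volume_shape=config.volume_shape,
            reader_jitter=config.reader_jitter,
            seed=config.stage_seed("simulate"),
            **kwargs,
        )
        cases = generate_cohort(cohort_cfg)
        io.save_cohort(cases, out / "cohort")
        artifacts.append(out / "cohort" / "labels.csv")
        logger.info("simulate: %d patients in %.1fs", len(cases), time.time() - t)
        report["stages"]["simulate"] = {"n_patients": len(cases)}

    if stage_enabled("extract"):
        t = time.time()
        if cases is None:
            cases = io.load_cohort(out / "cohort")
        reference = extract_cohort_table(cases, config.bin_width, config.target_spacing)
        io.save_table(reference, out / "features_reference.csv")
        artifacts.append(out / "features_reference.csv")
        occasions = {}
        for occ in [(0, 0), (0, 1), (1, 0)]:
            rows = []
            for case in cases:
                from .extract import extract_all

                row = extract_all(case, config.bin_width, config.target_spacing,
                                  mask=case.masks[occ])
                row["label"] = case.label
                rows.append(pd.Series(row, name=case.patient_id))
            occ_table = pd.DataFrame(rows)
            occasions[occ] = occ_table
            path = out / f"features_r{occ[0]}s{occ[1]}.csv"
            io.save_table(occ_table, path)
            artifacts.append(path)
        report["stages"]["extract"] = {"n_columns": reference.shape[1] - 1}
        logger.info("extract: %s columns in %.1fs", reference.shape[1] - 1, time.time() - t)

    if stage_enabled("filter-icc"):
        t = time.time()
        if occasions is None:
            occasions = {
                occ: io.load_table(out / f"features_r{occ[0]}s{occ[1]}.csv")
                for occ in [(0, 0), (0, 1), (1, 0)]
            }
        intra, inter = build_reliability_stacks(occasions)
        kept = filter_by_icc(intra, inter, config.icc_threshold)
        icc_report(intra, inter).to_csv(out / "icc_report.csv")
        io.save_json({"threshold": config.icc_threshold, "kept": kept}, out / "icc_kept.json")
        artifacts += [out / "icc_report.csv", out / "icc_kept.json"]
        report["stages"]["filter-icc"] = {"n_kept": len(kept)}
        logger.info("filter-icc: kept %d/%d in %.1fs", len(kept),
                    need_reference().shape[1] - 1, time.time() - t)
        if not kept:
            raise RuntimeError("stage filter-icc: no feature passed the reliability threshold")

    if stage_enabled("select"):
        t = time.time()
        if kept is None:
            kept = json.loads((out / "icc_kept.json").read_text())["kept"]
        if not kept:
            raise RuntimeError("no feature passed the reliability threshold")
        reference = need_reference()
        selected, norm = _select_features(reference, kept, config)
        sel_table = assemble_table(reference, selected)
        # z-score with the training-split statistics before the wavelet stage
        sel_table = (sel_table - norm.mean[sel_table.columns]) / norm.sd[sel_table.columns]
        sel_table["label"] = reference["label"]
        io.save_table(sel_table, out / "features_selected.csv")
        io.save_json({"selected": list(sel_table.columns[:-1])}, out / "selection.json")
        artifacts += [out / "features_selected.csv", out / "selection.json"]
        report["stages"]["select"] = {"n_selected": len(selected)}
        logger.info("select: %d features in %.1fs", len(selected), time.time() - t)

    if stage_enabled("wavelet"):
        t = time.time()
        profiles = build_all_profiles(need_sel_table(), config.banks)
        for bank, prof in profiles.items():
            path = out / f"profile_{bank}.csv"
            io.save_table(prof, path)
            artifacts.append(path)
        report["stages"]["wavelet"] = {"n_banks": len(profiles)}
        logger.info("wavelet: %d banks in %.1fs", len(profiles), time.time() - t)

    if stage_enabled("evaluate"):
        t = time.time()
        if profiles is None:
            # stand-alone evaluate: pick up whichever profile tables exist
            paths = sorted(out.glob("profile_*.csv"))
            if not paths:
                raise RuntimeError("stage evaluate: no profile_<bank>.csv found; run wavelet first")
            profiles = {
                p.stem.removeprefix("profile_"): io.load_table(p) for p in paths
            }
        sel_table = need_sel_table()
        y = sel_table["label"].to_numpy().astype(int)
        grid = evaluate_grid(
            sel_table, profiles, y, config.families,
            folds=config.folds, repeats=config.repeats,
            seed=config.stage_seed("evaluate"),
        )
        for metric in ("accuracy", "f1", "auc"):
            grid.metric_table(metric).to_csv(out / f"grid_{metric}.csv")
            artifacts.append(out / f"grid_{metric}.csv")
        grid.plain_table().to_csv(out / "grid_plain.csv")
        artifacts.append(out / "grid_plain.csv")
        comparisons = {m: comparison_rows(grid, m) for m in ("accuracy", "f1", "auc")}
        for m, cmp_df in comparisons.items():
            cmp_df.to_csv(out / f"comparison_{m}.csv")
            artifacts.append(out / f"comparison_{m}.csv")
        best = select_best(grid)
        report["stages"]["evaluate"] = {
            "n_wavelet_cells": grid.n_wavelet_cells(),
            "best_bank": best[0],
            "best_classifier": best[1],
            "best_auc": grid.cells[best].mean_auc,
            "best_accuracy": grid.cells[best].mean_accuracy,
            "best_f1": grid.cells[best].mean_f1,
        }
        logger.info("evaluate: %d cells in %.1fs", len(grid.cells), time.time() - t)

    if stage_enabled("report"):
        manifest = {
            str(p.relative_to(out)): {"sha256": _sha256(p), "seed": config.seed}
            for p in artifacts
            if p.exists()
        }
        io.save_json(manifest, out / "manifest.json")
        report["manifest"] = str(out / "manifest.json")

    report["elapsed_s"] = round(time.time() - t0, 1)
    io.save_json(report, out / "report.json")
    return report
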