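"""End-to-end study orchestration.

``run_study`` composes the whole analysis: simulate (or image) a
cohort, apply the eligibility and statistical-subgroup filters, score
masses and readers, and emit the diagnostic-accuracy report — ROC/AUC
with bootstrap CIs per arm, per-reader operating points with
lower-bound AUCs, DeLong comparisons, the Fleiss-kappa agreement table
with difference tests, threshold confusion counts, and a manifest that
records every seed so a run can be reproduced exactly.

Seed fan-out: the master seed is hashed together with each stage name
so stages draw from independent, individually reproducible streams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    STUDY_CATEGORY_COUNTS,
    STUDY_EXCLUSION_COUNTS,
    apply_eligibility_filters,
    binary_truth_labels,
    select_statistical_subgroup,
)
from .metrics import ClassifierParams
from .pipeline import ImagingConfig, simulate_imaging_cohort
from .stats import (
    bootstrap_reader_mean_auc,
    delong_test,
    fleiss_kappa,
    kappa_difference_test,
    lower_bound_auc,
    mann_whitney_auc,
    roc_curve,
)
from .synthetic_cohort import (
    READER_TASKS,
    ReaderPanelSpec,
    panel_to_label_matrix,
    simulate_cohort,
    simulate_reader_panel,
    simulate_reader_scores,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "threshold_tradeoff_report", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of one study run in one place."""

    seed: int = 0
    mode: str = "statistics"  # or "imaging"
    category_counts: dict = field(default_factory=lambda: dict(STUDY_CATEGORY_COUNTS))
    exclusion_counts: dict = field(default_factory=lambda: dict(STUDY_EXCLUSION_COUNTS))
    n_readers: int = 6
    reader_sd: float = 0.05
    panel_task1: ReaderPanelSpec = field(default_factory=lambda: ReaderPanelSpec())
    panel_task2: ReaderPanelSpec = field(
        default_factory=lambda: ReaderPanelSpec(
            sens_fluid=0.72, spec_fluid=0.90, mixed_rate=0.05,
            uncertain_rate=0.05, agreement_coupling=0.55,
        )
    )
    bootstrap_iter: int = 1000
    threshold: float = 0.76
    alt_threshold: float = 0.73
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("statistics", "imaging"):
            raise ValueError("mode must be 'statistics' or 'imaging'")
        if self.bootstrap_iter < 1:
            raise ValueError("bootstrap_iter must be >= 1")
        ClassifierParams(threshold=self.threshold)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("panel_task1", "panel_task2"):
            if key in raw:
                raw[key] = ReaderPanelSpec(**raw[key])
        if "imaging" in raw:
            raw["imaging"] = ImagingConfig(**raw["imaging"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["imaging"] = {k: v for k, v in d["imaging"].items() if not isinstance(v, dict)}
        return d


@dataclass
class StudyReport:
    out_dir: Path
    summary: dict
    files: list[str]


def threshold_tradeoff_report(scores, truth_categories, thresholds) -> pd.DataFrame:
    """Counts of correct cyst/solid calls and missed cancers per threshold.

    A "missed cancer" is a malignant solid mass whose score is at or
    above the threshold (i.e. called fluid). Lower thresholds improve
    agreement but raise this count, which is the clinical risk the
    tradeoff table makes explicit.
    """
    scores = np.asarray(scores, dtype=float)
    cats = np.asarray(truth_categories)
    if scores.shape != cats.shape:
        raise ValueError("scores and truth_categories must align")
    is_cyst = cats == "complicated_cyst"
    is_solid = np.isin(cats, ("solid_benign", "solid_malignant"))
    is_malignant = cats == "solid_malignant"
    rows = []
    for tau in thresholds:
        called_fluid = scores >= tau
        rows.append(
            {
                "threshold": float(tau),
                "cysts_called_fluid": int((is_cyst & called_fluid).sum()),
                "n_cysts": int(is_cyst.sum()),
                "solids_called_solid": int((is_solid & ~called_fluid).sum()),
                "n_solids": int(is_solid.sum()),
                "malignant_called_fluid": int((is_malignant & called_fluid).sum()),
                "n_malignant": int(is_malignant.sum()),
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_mean_auc(score_matrix, labels, n_iter, seed, alpha=0.05):
    """CI for the mean AUC across readers, bootstrapping masses."""
    rng = np.random.default_rng(seed)
    n, n_readers = score_matrix.shape
    means = np.empty(n_iter)
    for b in range(n_iter):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        means[b] = np.mean(
            [mann_whitney_auc(score_matrix[idx, r], lab) for r in range(n_readers)]
        )
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _reader_operating_points(panel, task, subgroup):
    """(sens, spec) per reader from categorical content ratings."""
    truth = subgroup.set_index("mass_id")["truth_category"]
    sub = panel.loc[panel["task"] == task]
    sub = sub.loc[sub["mass_id"].isin(truth.index)]
    points = []
    for reader, grp in sub.groupby("reader_id", sort=True):
        cats = truth.loc[grp["mass_id"]].to_numpy()
        ratings = grp["rating"].to_numpy()
        cyst = cats == "complicated_cyst"
        solid = np.isin(cats, ("solid_benign", "solid_malignant"))
        sens = float((ratings[cyst] == "fluid").mean())
        spec = float((ratings[solid] == "solid").mean())
        points.append((reader, sens, spec))
    return points


def run_study(config: StudyConfig, out_dir) -> StudyReport:
    """Run the full study and write its report files under ``out_dir``.

    Any stage failure removes the partial outputs and re-raises with
    the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    def save_json(obj: dict, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        written.append(path)

    try:
        # --- cohort -----------------------------------------------------
        stage = "cohort"
        if config.mode == "statistics":
            cohort = simulate_cohort(
                config.category_counts,
                seed=stage_seed(config.seed, "cohort"),
                exclusion_counts=config.exclusion_counts,
            )
        else:
            imaged = simulate_imaging_cohort(
                config.category_counts,
                seed=stage_seed(config.seed, "cohort"),
                config=config.imaging,
            )
            excluded = simulate_cohort(
                {}, seed=stage_seed(config.seed, "exclusions"),
                exclusion_counts=config.exclusion_counts,
            )
            cohort = pd.concat([imaged, excluded], ignore_index=True)
            cohort["mass_id"] = [f"M{i + 1:03d}" for i in range(len(cohort))]
        save_df(cohort, "cohort.csv")

        # --- filters ----------------------------------------------------
        stage = "filter"
        eligible, filter_report = apply_eligibility_filters(cohort)
        subgroup, subgroup_counts = select_statistical_subgroup(eligible)
        labels = binary_truth_labels(subgroup)
        save_json({"eligibility": filter_report, "subgroup": subgroup_counts},
                  "filter_report.json")

        # --- readers ----------------------------------------------------
        stage = "readers"
        reader_scores = simulate_reader_scores(
            subgroup, n_readers=config.n_readers, reader_sd=config.reader_sd,
            seed=stage_seed(config.seed, "reader_scores"),
        )
        panel = simulate_reader_panel(
            eligible,
            {"task1_bmode": config.panel_task1, "task2_bmode_slsc": config.panel_task2},
            seed=stage_seed(config.seed, "reader_panel"),
        )
        save_df(reader_scores, "reader_scores.csv")
        save_df(panel, "reader_panel.csv")

        # --- gCNR ROC arms ----------------------------------------------
        stage = "stats"
        readers = sorted(reader_scores["reader_id"].unique())
        mass_order = subgroup["mass_id"].to_numpy()
        summary: dict = {
            "config_mode": config.mode,
            "n_eligible": filter_report["eligible"],
            "n_subgroup": subgroup_counts["total"],
            "n_fluid_positive": int(labels.sum()),
            "n_solid_negative": int(labels.size - labels.sum()),
        }
        score_mats = {}
        for arm in ("gcnr_bmode", "gcnr_slsc"):
            wide = reader_scores.pivot(index="mass_id", columns="reader_id", values=arm)
            wide = wide.loc[mass_order, readers]
            mat = wide.to_numpy()
            score_mats[arm] = mat
            per_reader_auc = [mann_whitney_auc(mat[:, r], labels) for r in range(len(readers))]
            ci = _bootstrap_mean_auc(
                mat, labels, config.bootstrap_iter,
                stage_seed(config.seed, f"bootstrap_{arm}"),
            )
            mean_scores = mat.mean(axis=1)
            roc = roc_curve(mean_scores, labels)
            save_df(
                pd.DataFrame(
                    {
                        "threshold": roc.thresholds,
                        "sens": roc.sens,
                        "one_minus_spec": roc.one_minus_spec,
                    }
                ),
                f"roc_{arm}.csv",
            )
            summary[f"auc_{arm}_per_reader"] = [round(a, 6) for a in per_reader_auc]
            summary[f"mean_auc_{arm}"] = float(np.mean(per_reader_auc))
            summary[f"mean_auc_{arm}_ci"] = [round(c, 6) for c in ci]

        # --- reader operating points ------------------------------------
        for task, tag in zip(READER_TASKS, ("task1_bmode", "task2_bmode_slsc")):
            pts = _reader_operating_points(panel, task, subgroup)
            lb = [lower_bound_auc(s, p) for _, s, p in pts]
            mean_lb, lo, hi = bootstrap_reader_mean_auc(
                [(s, p) for _, s, p in pts], n_iter=config.bootstrap_iter,
                seed=stage_seed(config.seed, f"bootstrap_{tag}"),
            )
            summary[f"lower_bound_auc_{tag}_per_reader"] = [round(a, 6) for a in lb]
            summary[f"mean_lower_bound_auc_{tag}"] = mean_lb
            summary[f"mean_lower_bound_auc_{tag}_ci"] = [round(lo, 6), round(hi, 6)]

        # --- DeLong: reader binary calls vs gCNR(SLSC) -------------------
        truth = subgroup.set_index("mass_id")["truth_category"]
        task1 = panel.loc[
            (panel["task"] == "task1_bmode") & panel["mass_id"].isin(truth.index)
        ]
        delong_rows = []
        for r, reader in enumerate(readers):
            calls = (
                task1.loc[task1["reader_id"] == reader]
                .set_index("mass_id")["rating"]
                .loc[mass_order]
                .eq("fluid")
                .to_numpy()
                .astype(float)
            )
            res = delong_test(score_mats["gcnr_slsc"][:, r], calls, labels)
            delong_rows.append(
                {
                    "reader_id": reader,
                    "auc_gcnr_slsc": res.auc_a,
                    "auc_bmode_reading": res.auc_b,
                    "delta": res.delta,
                    "p_value": res.p_value,
                }
            )
        save_df(pd.DataFrame(delong_rows), "delong_task1_vs_gcnr_slsc.csv")
        summary["delong_p_task1_vs_gcnr_slsc"] = [round(r["p_value"], 8) for r in delong_rows]

        # --- agreement ---------------------------------------------------
        stage = "agreement"
        kappas = {}
        for task in READER_TASKS:
            mat = panel_to_label_matrix(panel.loc[panel["mass_id"].isin(eligible["mass_id"])], task)
            kappas[task] = fleiss_kappa(mat)
        for tau, tag in ((config.threshold, "gcnr_slsc"), (config.alt_threshold, "gcnr_slsc_alt")):
            calls = np.where(score_mats["gcnr_slsc"] >= tau, "fluid", "solid")
            kappas[tag] = fleiss_kappa(calls)
        kappa_rows = []
        for name, res in kappas.items():
            kappa_rows.append(
                {
                    "panel": name,
                    "kappa": res.kappa,
                    "variance": res.variance,
                    "z": res.z,
                    "p_value": res.p_value,
                    "band": res.band,
                }
            )
        dk, zk, pk = kappa_difference_test(kappas["gcnr_slsc"], kappas["task1_bmode"])
        dk2, zk2, pk2 = kappa_difference_test(kappas["gcnr_slsc_alt"], kappas["task1_bmode"])
        save_df(pd.DataFrame(kappa_rows), "kappa_table.csv")
        summary["kappa"] = {k: round(v.kappa, 6) for k, v in kappas.items()}
        summary["kappa_bands"] = {k: v.band for k, v in kappas.items()}
        summary["kappa_diff_gcnr_vs_task1"] = {"delta": round(dk, 6), "p": pk,
                                               "independence_approx": True}
        summary["kappa_diff_gcnr_alt_vs_task1"] = {"delta": round(dk2, 6), "p": pk2,
                                                   "independence_approx": True}

        # --- threshold tradeoff -------------------------------------------
        stage = "tradeoff"
        taus = sorted({config.threshold, config.alt_threshold})
        per_reader_tables = []
        cats = subgroup["truth_category"].to_numpy()
        for r, reader in enumerate(readers):
            tbl = threshold_tradeoff_report(score_mats["gcnr_slsc"][:, r], cats, taus)
            tbl.insert(0, "reader_id", reader)
            per_reader_tables.append(tbl)
        tradeoff = pd.concat(per_reader_tables, ignore_index=True)
        save_df(tradeoff, "tradeoff.csv")
        agg = tradeoff.groupby("threshold").agg(
            cysts_called_fluid_min=("cysts_called_fluid", "min"),
            cysts_called_fluid_max=("cysts_called_fluid", "max"),
            solids_called_solid_min=("solids_called_solid", "min"),
            solids_called_solid_max=("solids_called_solid", "max"),
            malignant_called_fluid_max=("malignant_called_fluid", "max"),
        )
        summary["tradeoff"] = {
            str(t): {k: int(v) for k, v in row.items()} for t, row in agg.iterrows()
        }

        # --- manifest ------------------------------------------------------
        stage = "manifest"
        stages = [
            "cohort", "exclusions", "reader_scores", "reader_panel",
            "bootstrap_gcnr_bmode", "bootstrap_gcnr_slsc",
            "bootstrap_task1_bmode", "bootstrap_task2_bmode_slsc",
        ]
        manifest = {
            "package_version": __version__,
            "master_seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
            "config": _jsonable(config.to_dict()),
        }
        save_json(manifest, "manifest.json")
        save_json(_jsonable(summary), "stats_summary.json")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"study stage '{stage}' failed: {exc}") from exc

    return StudyReport(out_dir=out, summary=summary, files=[p.name for p in written])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
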