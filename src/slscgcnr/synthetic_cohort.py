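"""Synthetic cohorts and reader panels.

The clinical raw data behind this analysis are not public, so the
package generates statistical stand-ins: cohort tables whose category
composition mirrors the emulated study (145 eligible masses of 175
potentially eligible), per-mass gCNR scores drawn from truncated
normal distributions per category and imaging arm, and categorical
reader panels with controllable accuracy and inter-reader coupling.

The generative gCNR means encode the qualitative separation the method
exploits: on coherence (SLSC) images fluid masses score high and solid
masses low, while on B-mode the separation is compressed because
acoustic clutter fills fluid masses with speckle-like texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EXCLUSION_REASONS, STUDY_CATEGORY_COUNTS, TRUTH_CATEGORIES

__all__ = [
    "RATING_CATEGORIES",
    "READER_TASKS",
    "DEFAULT_GCNR_PARAMS",
    "ReaderPanelSpec",
    "simulate_cohort",
    "simulate_reader_scores",
    "simulate_reader_panel",
    "panel_to_label_matrix",
    "binormal_auc",
]

RATING_CATEGORIES = ("solid", "fluid", "mixed", "uncertain")
READER_TASKS = ("task1_bmode", "task2_bmode_slsc")

#: Per-category (mean, sd) of the generative gCNR distributions on each
#: imaging arm, truncated to [0, 1] at sampling time.
DEFAULT_GCNR_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "complicated_cyst": {"bmode": (0.70, 0.14), "slsc": (0.82, 0.10)},
    "simple_cyst": {"bmode": (0.85, 0.08), "slsc": (0.90, 0.05)},
    "solid_benign": {"bmode": (0.52, 0.16), "slsc": (0.30, 0.15)},
    "solid_malignant": {"bmode": (0.50, 0.16), "slsc": (0.25, 0.13)},
    "mixed": {"bmode": (0.60, 0.15), "slsc": (0.55, 0.18)},
}


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form AUC of two normal score distributions,
    Phi(delta_mu / sqrt(sd_pos^2 + sd_neg^2))."""
    from scipy.stats import norm

    return float(norm.cdf((mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)))


@dataclass(frozen=True)
class ReaderPanelSpec:
    """Generative model of one categorical reading task.

    ``sens_fluid`` / ``spec_fluid`` are the per-reader probabilities of
    rating a true-fluid mass as fluid and a true-solid mass as solid,
    conditional on not giving a mixed/uncertain rating.
    ``agreement_coupling`` is the probability that a reader copies a
    shared latent rating instead of drawing independently; 1 forces a
    unanimous panel, 0 makes readers independent.
    """

    n_readers: int = 6
    sens_fluid: float = 0.60
    spec_fluid: float = 0.85
    mixed_rate: float = 0.08
    uncertain_rate: float = 0.07
    # Default coupling calibrated so a six-reader panel over the default
    # cohort lands in the "fair" agreement regime (kappa ~ 0.4) that
    # characterizes subjective B-mode content readings.
    agreement_coupling: float = 0.60

    def __post_init__(self) -> None:
        if self.n_readers < 1:
            raise ValueError("n_readers must be >= 1")
        for name in ("sens_fluid", "spec_fluid", "mixed_rate", "uncertain_rate", "agreement_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mixed_rate + self.uncertain_rate > 1.0:
            raise ValueError("mixed_rate + uncertain_rate must not exceed 1")

    def rating_probs(self, truth_category: str) -> np.ndarray:
        """Probabilities over RATING_CATEGORIES given the truth."""
        rem = 1.0 - self.mixed_rate - self.uncertain_rate
        if truth_category in ("complicated_cyst", "simple_cyst"):
            p_fluid = self.sens_fluid * rem
            p_solid = (1.0 - self.sens_fluid) * rem
        elif truth_category in ("solid_benign", "solid_malignant"):
            p_solid = self.spec_fluid * rem
            p_fluid = (1.0 - self.spec_fluid) * rem
        else:  # mixed-content truth: no right binary answer
            p_solid = p_fluid = rem / 2.0
        return np.array([p_solid, p_fluid, self.mixed_rate, self.uncertain_rate])


def _sample_scores(rng: np.random.Generator, params: tuple[float, float], n: int) -> np.ndarray:
    mean, sd = params
    if not 0.0 <= mean <= 1.0:
        raise ValueError("generative gCNR means must lie in [0, 1]")
    return np.clip(rng.normal(mean, sd, n), 0.0, 1.0)


def simulate_cohort(
    category_counts: dict[str, int] | None = None,
    gcnr_generative_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    exclusion_counts: dict[str, int] | None = None,
    sample_scores: bool = True,
) -> pd.DataFrame:
    """Simulate a cohort table of mass records.

    Parameters
    ----------
    category_counts:
        Eligible masses per truth category; defaults to the emulated
        study composition (145 masses).
    gcnr_generative_params:
        Per-category ``{"bmode": (mean, sd), "slsc": (mean, sd)}``
        generative distributions; merged over the defaults. Scores are
        only sampled when ``sample_scores`` is true (statistics-only
        cohorts that bypass beamforming).
    exclusion_counts:
        Additional excluded records per exclusion reason, appended with
        ``exclusion_reason`` set (pass
        :data:`~slscgcnr.cohort.STUDY_EXCLUSION_COUNTS` to mirror the
        30 exclusions of the emulated study).
    """
    if category_counts is None:
        category_counts = STUDY_CATEGORY_COUNTS
    bad = set(category_counts) - set(TRUTH_CATEGORIES)
    if bad:
        raise ValueError(f"unknown truth categories: {sorted(bad)}")
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("category counts must be >= 0")
    params = {k: dict(v) for k, v in DEFAULT_GCNR_PARAMS.items()}
    for cat, arms in (gcnr_generative_params or {}).items():
        params.setdefault(cat, {}).update(arms)

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for cat in TRUTH_CATEGORIES:
        for _ in range(int(category_counts.get(cat, 0))):
            rows.append(
                {
                    "truth_category": cat,
                    "exclusion_reason": "",
                    "depth_mm": float(np.clip(rng.normal(11.0, 4.0), 5.5, 40.0)),
                    "size_mm": float(np.clip(rng.normal(13.8, 9.8), 3.0, 60.0)),
                }
            )
    for reason in EXCLUSION_REASONS:
        for _ in range(int((exclusion_counts or {}).get(reason, 0))):
            depth = rng.uniform(2.0, 4.9) if reason == "superficial" else float(
                np.clip(rng.normal(11.0, 4.0), 5.5, 40.0)
            )
            rows.append(
                {
                    "truth_category": str(rng.choice(TRUTH_CATEGORIES)),
                    "exclusion_reason": reason,
                    "depth_mm": depth,
                    "size_mm": float(np.clip(rng.normal(13.8, 9.8), 3.0, 60.0)),
                }
            )
    unknown = set(exclusion_counts or {}) - set(EXCLUSION_REASONS)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")

    df = pd.DataFrame(rows, columns=["truth_category", "exclusion_reason", "depth_mm", "size_mm"])
    df.insert(0, "mass_id", [f"M{i + 1:03d}" for i in range(len(df))])
    # Roughly a quarter of patients contribute a second mass.
    patient_ids = []
    pid = 0
    pending = 0
    for _ in range(len(df)):
        if pending:
            pending -= 1
        else:
            pid += 1
            pending = int(rng.random() < 0.2)
        patient_ids.append(f"P{pid:03d}")
    df.insert(1, "patient_id", patient_ids)

    if sample_scores and len(df):
        for arm, col in (("bmode", "gcnr_bmode"), ("slsc", "gcnr_slsc")):
            vals = np.empty(len(df))
            for cat in df["truth_category"].unique():
                idx = np.flatnonzero((df["truth_category"] == cat).to_numpy())
                vals[idx] = _sample_scores(rng, params[cat][arm], idx.size)
            df[col] = vals
    return df


def simulate_reader_scores(
    cohort: pd.DataFrame,
    n_readers: int = 6,
    reader_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-reader gCNR scores around each mass's latent value.

    Emulates reader-drawn ROI variability: each reader's score is the
    mass's latent gCNR plus independent normal noise of scale
    ``reader_sd``, clipped to [0, 1]. Returns a long table with columns
    ``mass_id, reader_id, gcnr_bmode, gcnr_slsc``.
    """
    if "gcnr_slsc" not in cohort.columns:
        raise ValueError("cohort must carry latent gcnr columns (sample_scores=True)")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in cohort.iterrows():
        for r in range(n_readers):
            rows.append(
                {
                    "mass_id": rec["mass_id"],
                    "reader_id": f"R{r + 1}",
                    "gcnr_bmode": float(np.clip(rec["gcnr_bmode"] + rng.normal(0, reader_sd), 0, 1)),
                    "gcnr_slsc": float(np.clip(rec["gcnr_slsc"] + rng.normal(0, reader_sd), 0, 1)),
                }
            )
    return pd.DataFrame(rows)


def simulate_reader_panel(
    cohort: pd.DataFrame,
    spec: ReaderPanelSpec | dict[str, ReaderPanelSpec],
    seed: int = 0,
    tasks: tuple[str, ...] = READER_TASKS,
) -> pd.DataFrame:
    """Categorical content ratings per mass x reader x task.

    ``spec`` is a single :class:`ReaderPanelSpec` applied to every task
    or a mapping from task name to spec. Returns a long table with
    columns ``mass_id, reader_id, task, rating``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    specs = {t: spec for t in tasks} if isinstance(spec, ReaderPanelSpec) else dict(spec)
    for t in tasks:
        if t not in specs:
            raise ValueError(f"no ReaderPanelSpec for task {t!r}")
    n_readers = {specs[t].n_readers for t in tasks}
    if len(n_readers) > 1:
        raise ValueError("all tasks must use the same number of readers")

    rng = np.random.default_rng(seed)
    cats = np.arange(len(RATING_CATEGORIES))
    rows = []
    for _, rec in cohort.iterrows():
        for task in tasks:
            sp = specs[task]
            probs = sp.rating_probs(rec["truth_category"])
            latent = rng.choice(cats, p=probs)
            for r in range(sp.n_readers):
                if rng.random() < sp.agreement_coupling:
                    rating = latent
                else:
                    rating = rng.choice(cats, p=probs)
                rows.append(
                    {
                        "mass_id": rec["mass_id"],
                        "reader_id": f"R{r + 1}",
                        "task": task,
                        "rating": RATING_CATEGORIES[rating],
                    }
                )
    return pd.DataFrame(rows)


def panel_to_label_matrix(panel: pd.DataFrame, task: str) -> np.ndarray:
    """Pivot a long reader panel into a (n_masses, n_readers) label matrix."""
    sub = panel.loc[panel["task"] == task]
    if sub.empty:
        raise ValueError(f"no ratings for task {task!r}")
    wide = sub.pivot(index="mass_id", columns="reader_id", values="rating")
    if wide.isna().any().any():
        raise ValueError("every (mass, reader) pair must be rated exactly once")
    return wide.to_numpy()
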