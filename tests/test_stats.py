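"""ROC/AUC, bootstrap, DeLong and Fleiss-kappa statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from slscgcnr.stats import (
    auc_trapezoid,
    bootstrap_auc_ci,
    bootstrap_reader_mean_auc,
    delong_test,
    fleiss_kappa,
    kappa_band,
    kappa_difference_test,
    lower_bound_auc,
    mann_whitney_auc,
    roc_curve,
)


def _pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney oracle: all (pos, neg) pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (pos.size * neg.size)


# --- ROC curve ------------------------------------------------------------


def test_perfect_separation_gives_unit_auc():
    scores = [0.9, 0.95, 0.1, 0.2, 0.3]
    labels = [1, 1, 0, 0, 0]
    res = roc_curve(scores, labels)
    assert res.auc == pytest.approx(1.0)
    assert res.n_pos == 2 and res.n_neg == 3
    # the curve reaches (0, 1): perfect operating point present
    assert np.any((res.one_minus_spec == 0.0) & (res.sens == 1.0))


def test_all_tied_scores_give_chance_auc():
    res = roc_curve([0.5] * 6, [1, 1, 0, 0, 0, 0])
    assert res.auc == pytest.approx(0.5)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_curve([0.1, 0.2], [1, 1])


def test_roc_monotone_in_threshold():
    rng = np.random.default_rng(0)
    scores = rng.random(40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    res = roc_curve(scores, labels)
    assert np.all(np.diff(res.sens) <= 1e-12)
    assert np.all(np.diff(res.one_minus_spec) <= 1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_auc_equals_pairwise_statistic_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n)
    labels = np.zeros(n, int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    assert roc_curve(scores, labels).auc == pytest.approx(_pairwise_auc(scores, labels))


def test_auc_equals_pairwise_statistic_exhaustive_small():
    """Exhaustive tie-structure check at n = 5 over a 3-point score grid."""
    labels = np.array([1, 1, 0, 0, 0])
    for combo in itertools.product([0.0, 0.5, 1.0], repeat=5):
        scores = np.array(combo)
        assert roc_curve(scores, labels).auc == pytest.approx(
            _pairwise_auc(scores, labels)
        )


def test_auc_matches_sklearn_cross_check():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    scores = rng.random(60)
    labels = (rng.random(60) < 0.4).astype(int)
    labels[:2] = [0, 1]
    assert roc_curve(scores, labels).auc == pytest.approx(
        roc_auc_score(labels, scores)
    )


# --- trapezoidal integration ---------------------------------------------


def test_trapezoid_reference_shapes():
    assert auc_trapezoid([0, 0, 1], [0, 1, 1]) == pytest.approx(1.0)
    assert auc_trapezoid([0, 1], [0, 1]) == pytest.approx(0.5)


def test_trapezoid_matches_quadrature_oracle():
    xs = np.array([0.0, 0.25, 1.0])
    ys = np.array([0.0, 0.75, 1.0])
    f = lambda x: np.interp(x, xs, ys)
    expected, _ = quad(f, 0, 1, points=[0.25])
    assert auc_trapezoid(xs, ys) == pytest.approx(expected)
    assert expected == pytest.approx(0.75)


def test_trapezoid_sorts_unsorted_input():
    assert auc_trapezoid([1.0, 0.0, 0.25], [1.0, 0.0, 0.75]) == pytest.approx(0.75)


@given(seed=st.integers(0, 100))
def test_trapezoid_duplicate_x_adds_zero_width(seed):
    rng = np.random.default_rng(seed)
    xs = np.sort(rng.random(6))
    ys = np.sort(rng.random(6))
    base = auc_trapezoid(xs, ys)
    xs2 = np.concatenate([xs, [xs[2]]])
    ys2 = np.concatenate([ys, [ys[2]]])
    assert auc_trapezoid(xs2, ys2) == pytest.approx(base)


# --- bootstrap CI ---------------------------------------------------------


def test_bootstrap_ci_degenerates_for_replicated_separation():
    scores = np.array([0.9] * 20 + [0.1] * 20)
    labels = np.array([1] * 20 + [0] * 20)
    lo, hi = bootstrap_auc_ci(scores, labels, n_iter=200, seed=0)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_ci_deterministic_given_seed():
    rng = np.random.default_rng(1)
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    a = bootstrap_auc_ci(scores, labels, n_iter=300, seed=42)
    b = bootstrap_auc_ci(scores, labels, n_iter=300, seed=42)
    assert a == b
    assert a[0] <= mann_whitney_auc(scores, labels) <= a[1]


def test_bootstrap_ci_coverage_at_known_auc():
    """Coverage simulation: percentile CIs at binormal true AUC 0.8
    cover the truth in 95% +- 4% of simulated cohorts."""
    true_auc = 0.8
    delta = norm.ppf(true_auc) * np.sqrt(2)  # unit-sd binormal
    rng = np.random.default_rng(7)
    n_pos, n_neg = 40, 40
    covered = 0
    n_cohorts = 200
    for k in range(n_cohorts):
        pos = rng.normal(delta, 1, n_pos)
        neg = rng.normal(0, 1, n_neg)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * n_pos + [0] * n_neg)
        lo, hi = bootstrap_auc_ci(scores, labels, n_iter=300, seed=1000 + k)
        covered += lo <= true_auc <= hi
    assert 0.91 <= covered / n_cohorts <= 0.99


# --- lower-bound AUC ------------------------------------------------------


def test_lower_bound_reference_points():
    assert lower_bound_auc(1.0, 1.0) == 1.0
    assert lower_bound_auc(0.5, 0.5) == 0.5


@given(sens=st.floats(0, 1), spec=st.floats(0, 1))
def test_lower_bound_matches_two_segment_quadrature(sens, spec):
    xs = np.array([0.0, 1.0 - spec, 1.0])
    ys = np.array([0.0, sens, 1.0])
    assert lower_bound_auc(sens, spec) == pytest.approx(auc_trapezoid(xs, ys))


def test_lower_bound_never_exceeds_concave_roc_auc():
    """For a proper (concave) ROC curve, the two-segment lower bound
    through any of its operating points never exceeds the full AUC."""
    delta = 1.2  # binormal separation, unit sds
    t = np.linspace(-6, 8, 2001)
    fpr = norm.sf(t)
    sens = norm.sf(t - delta)
    full_auc = auc_trapezoid(fpr, sens)
    assert full_auc == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=1e-4)
    for s, f in zip(sens[::50], fpr[::50]):
        assert lower_bound_auc(s, 1 - f) <= full_auc + 1e-9


# --- reader-mean bootstrap ------------------------------------------------


def test_identical_readers_have_zero_width_ci():
    mean, lo, hi = bootstrap_reader_mean_auc([(0.8, 0.9)] * 6, n_iter=200, seed=0)
    assert mean == lo == hi == pytest.approx((0.8 + 0.9) / 2)


def test_reader_bootstrap_deterministic():
    pts = [(1.0, 1.0), (0.5, 0.5), (0.7, 0.9)]
    a = bootstrap_reader_mean_auc(pts, n_iter=500, seed=3)
    assert a == bootstrap_reader_mean_auc(pts, n_iter=500, seed=3)


def test_two_reader_bootstrap_matches_exhaustive_enumeration():
    """Two readers at (1,1) and (0.5,0.5): the 4 equally likely
    resamples give means {0.5, 0.75, 1.0} with probs {1/4, 1/2, 1/4}."""
    pts = [(1.0, 1.0), (0.5, 0.5)]
    rng_draws = 20000
    _, lo, hi = bootstrap_reader_mean_auc(pts, n_iter=rng_draws, seed=11)
    # support check via quantiles of the resampling distribution
    rng = np.random.default_rng(11)
    idx = rng.integers(0, 2, (rng_draws, 2))
    lb = np.array([1.0, 0.5])
    means = lb[idx].mean(axis=1)
    freqs = {v: np.mean(means == v) for v in (0.5, 0.75, 1.0)}
    assert set(np.unique(means)) == {0.5, 0.75, 1.0}
    assert freqs[0.5] == pytest.approx(0.25, abs=0.02)
    assert freqs[0.75] == pytest.approx(0.5, abs=0.02)
    assert freqs[1.0] == pytest.approx(0.25, abs=0.02)
    assert lo == 0.5 and hi == 1.0


# --- DeLong ---------------------------------------------------------------


def _paired_scores(seed=0, n_pos=10, n_neg=20):
    rng = np.random.default_rng(seed)
    truth = np.array([1] * n_pos + [0] * n_neg)
    latent = truth * 0.8 + rng.normal(0, 0.6, truth.size)
    a = latent + rng.normal(0, 0.4, truth.size)
    b = 0.8 * latent + rng.normal(0, 0.55, truth.size)
    return a, b, truth


def test_delong_identical_scores_give_p_one():
    a, _, labels = _paired_scores()
    res = delong_test(a, a, labels)
    assert res.delta == 0.0
    assert res.p_value == 1.0


def test_delong_aucs_match_roc_curve():
    a, b, labels = _paired_scores(3)
    res = delong_test(a, b, labels)
    assert res.auc_a == pytest.approx(roc_curve(a, labels).auc)
    assert res.auc_b == pytest.approx(roc_curve(b, labels).auc)


def test_delong_detects_large_difference():
    rng = np.random.default_rng(4)
    labels = np.array([1] * 30 + [0] * 30)
    good = labels + rng.normal(0, 0.2, 60)
    noise = rng.normal(0, 1, 60)
    res = delong_test(good, noise, labels)
    assert res.p_value < 0.01
    assert res.delta > 0.3


def test_delong_degenerate_zero_variance_flagged():
    labels = np.array([1, 1, 0, 0])
    a = np.array([1.0, 1.0, 0.0, 0.0])
    b = np.array([0.0, 0.0, 1.0, 1.0])
    res = delong_test(a, b, labels)
    assert res.degenerate
    assert res.p_value <= 1e-16


def _permutation_p(a, b, labels, n_rep=10000, seed=0):
    """Paired permutation oracle: swap the two modalities per mass."""
    rng = np.random.default_rng(seed)
    obs = abs(mann_whitney_auc(a, labels) - mann_whitney_auc(b, labels))
    count = 0
    for _ in range(n_rep):
        flip = rng.random(labels.size) < 0.5
        aa = np.where(flip, b, a)
        bb = np.where(flip, a, b)
        d = abs(mann_whitney_auc(aa, labels) - mann_whitney_auc(bb, labels))
        count += d >= obs - 1e-12
    return count / n_rep


def _exchangeable_scores(seed, n_pos=60, n_neg=60):
    """Paired modalities that are exchangeable under the null, so the
    sign-flip permutation distribution is exact."""
    rng = np.random.default_rng(seed)
    truth = np.array([1] * n_pos + [0] * n_neg)
    latent = truth * 1.0 + rng.normal(0, 0.6, truth.size)
    a = latent + rng.normal(0, 0.5, truth.size)
    b = latent + rng.normal(0, 0.5, truth.size)
    return a, b, truth


def test_delong_p_matches_permutation_oracle():
    """DeLong's normal-approximation P agrees with a 10^4-replicate
    paired-permutation oracle at the 0.02 level on average."""
    diffs = []
    for seed in range(5):
        a, b, labels = _exchangeable_scores(seed)
        res = delong_test(a, b, labels)
        p_perm = _permutation_p(a, b, labels, n_rep=10000, seed=900 + seed)
        diffs.append(abs(res.p_value - p_perm))
        assert diffs[-1] <= 0.05
    assert np.mean(diffs) <= 0.02


# --- Fleiss kappa ---------------------------------------------------------


def _hand_fleiss(counts):
    """Independent oracle: plain-loop kappa computation."""
    counts = np.asarray(counts, float)
    n_subj, _ = counts.shape
    n = counts[0].sum()
    p_j = counts.sum(axis=0) / (n_subj * n)
    p_i = [(sum(c * c for c in row) - n) / (n * (n - 1)) for row in counts]
    p_bar = sum(p_i) / n_subj
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def test_perfect_agreement_on_two_categories():
    ratings = np.array([["fluid"] * 4, ["solid"] * 4, ["fluid"] * 4])
    res = fleiss_kappa(ratings)
    assert res.kappa == pytest.approx(1.0)
    assert res.band == "perfect"
    assert not res.degenerate


def test_printed_band_mapping():
    assert kappa_band(0.40) == "fair"
    assert kappa_band(0.59) == "moderate"
    assert kappa_band(0.70) == "substantial"
    assert kappa_band(-0.1) == "poor"
    assert kappa_band(0.1) == "slight"
    assert kappa_band(0.95) == "perfect"


def test_toy_table_matches_hand_computation():
    rng = np.random.default_rng(6)
    ratings = rng.choice(["fluid", "solid"], (10, 3))
    ratings[0] = "fluid"  # ensure both categories and some agreement
    res = fleiss_kappa(ratings)
    counts = np.stack(
        [(ratings == "fluid").sum(axis=1), (ratings == "solid").sum(axis=1)], axis=1
    )
    assert res.kappa == pytest.approx(_hand_fleiss(counts))


def test_kappa_matches_statsmodels_cross_check():
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

    rng = np.random.default_rng(8)
    ratings = rng.choice(["a", "b", "c", "d"], (40, 6))
    counts, _ = aggregate_raters(ratings)
    assert fleiss_kappa(ratings).kappa == pytest.approx(sm_fleiss(counts))


def test_degenerate_single_category_flagged():
    ratings = np.full((5, 4), "solid")
    res = fleiss_kappa(ratings, categories=["solid", "fluid"])
    assert res.degenerate
    assert res.kappa == 1.0


def test_variance_methods_positive_and_close():
    rng = np.random.default_rng(9)
    ratings = rng.choice(["a", "b"], (60, 6))
    fnl = fleiss_kappa(ratings, variance_method="fnl")
    fl = fleiss_kappa(ratings, variance_method="fleiss")
    assert fnl.variance > 0 and fl.variance > 0
    assert fnl.kappa == fl.kappa
    assert np.isfinite(fnl.z) and 0 < fnl.p_value <= 1


def test_unbalanced_rater_counts_rejected():
    with pytest.raises(ValueError, match="same number of raters"):
        fleiss_kappa(np.array([[3, 1], [2, 1]]), counts=True)


# --- kappa difference -----------------------------------------------------


def test_kappa_difference_identical_gives_p_one():
    rng = np.random.default_rng(10)
    ratings = rng.choice(["a", "b"], (30, 4))
    res = fleiss_kappa(ratings)
    delta, z, p = kappa_difference_test(res, res)
    assert delta == 0.0 and p == 1.0


def test_kappa_difference_antisymmetric():
    rng = np.random.default_rng(11)
    r1 = fleiss_kappa(rng.choice(["a", "b"], (40, 5)))
    r2 = fleiss_kappa(rng.choice(["a", "b", "c"], (40, 5)))
    d12, z12, p12 = kappa_difference_test(r1, r2)
    d21, z21, p21 = kappa_difference_test(r2, r1)
    assert d12 == -d21 and z12 == -z21 and p12 == p21


def test_kappa_difference_z_matches_resampling_oracle():
    """Near the null, the analytic z of the kappa difference agrees
    with a 5000-replicate mass-resampling bootstrap within 5%."""
    from slscgcnr.synthetic_cohort import (
        ReaderPanelSpec,
        panel_to_label_matrix,
        simulate_cohort,
        simulate_reader_panel,
    )

    cohort = simulate_cohort({"complicated_cyst": 60, "solid_benign": 60}, seed=1)
    spec = ReaderPanelSpec(
        sens_fluid=0.5, spec_fluid=0.5, mixed_rate=0.0, uncertain_rate=0.0,
        agreement_coupling=0.0,
    )
    mat_a = panel_to_label_matrix(simulate_reader_panel(cohort, spec, seed=2), "task1_bmode")
    mat_b = panel_to_label_matrix(simulate_reader_panel(cohort, spec, seed=3), "task1_bmode")
    ra, rb = fleiss_kappa(mat_a), fleiss_kappa(mat_b)
    delta, z, _ = kappa_difference_test(ra, rb)

    rng = np.random.default_rng(4)
    n = mat_a.shape[0]
    deltas = np.empty(5000)
    for i in range(5000):
        ia = rng.integers(0, n, n)
        ib = rng.integers(0, n, n)
        deltas[i] = fleiss_kappa(mat_a[ia]).kappa - fleiss_kappa(mat_b[ib]).kappa
    z_boot = delta / deltas.std(ddof=1)
    assert z == pytest.approx(z_boot, rel=0.05, abs=0.05)
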