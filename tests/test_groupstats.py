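import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twignet as tn
from twignet.groupstats import anova_oneway, duncan_groups


# ---------------------------------------------------------------- K-S check

def test_ks_statistic_small_for_normal_quantiles():
    n = 100
    x = stats.norm.ppf(np.arange(1, n + 1) / (n + 1))
    stat, p = tn.ks_normality(x)
    assert stat < 0.05
    assert p > 0.5


def test_ks_constant_sample_raises():
    with pytest.raises(ValueError, match="constant"):
        tn.ks_normality([3.0] * 10)
    with pytest.raises(ValueError):
        tn.ks_normality([1.0, 2.0])


def test_ks_pvalues_roughly_uniform_under_normality():
    """Repeated draws from the fitted normal give p-values whose ECDF is
    consistent with uniformity (fitting-bias conservatism allowed: the
    check only rejects gross miscalibration at alpha=0.01... the plain
    K-S variant is conservative, the Lilliefors variant calibrated)."""
    rng = np.random.default_rng(0)
    ps = [tn.ks_normality(rng.normal(size=100), lilliefors=True)[1] for _ in range(200)]
    ps = np.clip(ps, 0, 1)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ------------------------------------------------------------------- ANOVA

def test_oneway_hand_computed_sums_of_squares():
    res = anova_oneway({"a": [1, 2, 3], "b": [4, 5, 6]})
    assert res.F == pytest.approx(13.5)
    assert (res.df_between, res.df_within) == (1, 4)
    assert res.p == pytest.approx(stats.f.sf(13.5, 1, 4))


def test_oneway_matches_scipy_on_random_groups():
    rng = np.random.default_rng(1)
    groups = {k: rng.normal(loc=i, size=8) for i, k in enumerate("abcd")}
    res = anova_oneway(groups)
    ref = stats.f_oneway(*groups.values())
    assert res.F == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue)


def test_oneway_identical_constants_give_zero_f():
    res = anova_oneway({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
    assert res.F == 0.0
    assert res.p == 1.0


def test_oneway_f_is_squared_t_for_two_groups():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=10), rng.normal(0.5, 1, size=10)
    res = anova_oneway({"a": a, "b": b})
    t = stats.ttest_ind(a, b).statistic
    assert res.F == pytest.approx(t**2)


def test_oneway_small_group_rejected():
    with pytest.raises(ValueError, match="'b'"):
        anova_oneway({"a": [1, 2], "b": [1.0]})


def _grid_frame(cell_means, reps=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (n, p), mu in cell_means.items():
        for _ in range(reps):
            rows.append({"n_rate": n, "p_rate": p, "y": mu + noise * rng.normal()})
    return pd.DataFrame(rows)


def test_twoway_additive_means_have_no_interaction():
    cells = {(n, p): 1.0 + 2 * n + 3 * p for n in (0, 1) for p in (0, 1, 2)}
    df = _grid_frame(cells, reps=3, noise=1e-9, seed=3)
    res = tn.anova_twoway(df, "y")
    assert res.F_interaction < 1e-6 * res.F_N
    assert res.p_N < 1e-6 and res.p_P < 1e-6


def test_twoway_balanced_2x2_hand_computed():
    # cells: (0,0)->{1,3}, (0,1)->{2,4}, (1,0)->{5,7}, (1,1)->{10,12}
    df = pd.DataFrame(
        {
            "n_rate": [0, 0, 0, 0, 1, 1, 1, 1],
            "p_rate": [0, 0, 1, 1, 0, 0, 1, 1],
            "y": [1, 3, 2, 4, 5, 7, 10, 12],
        }
    )
    res = tn.anova_twoway(df, "y")
    # hand decomposition: SS_N = 72, SS_P = 18, SS_int = 8, SS_err = 8 on 4 df
    assert res.F_N == pytest.approx(72 / (8 / 4))
    assert res.F_P == pytest.approx(18 / (8 / 4))
    assert res.F_interaction == pytest.approx(8 / (8 / 4))
    assert res.df == {"N": 1, "P": 1, "interaction": 1, "residual": 4}


def test_twoway_permuting_replicates_leaves_f_unchanged():
    cells = {(n, p): 1.0 + n + p + 0.5 * n * p for n in (0, 1) for p in (0, 1)}
    df = _grid_frame(cells, reps=4, noise=0.3, seed=4)
    res1 = tn.anova_twoway(df, "y")
    res2 = tn.anova_twoway(df.sample(frac=1.0, random_state=5), "y")
    assert res1.F_N == pytest.approx(res2.F_N)
    assert res1.F_interaction == pytest.approx(res2.F_interaction)


def test_twoway_incomplete_grid_lists_missing_cells():
    df = _grid_frame({(0, 0): 1.0, (0, 1): 2.0, (1, 0): 3.0}, reps=2)
    with pytest.raises(ValueError, match=r"\(1, 1\)"):
        tn.anova_twoway(df, "y")


def test_twoway_runs_on_both_design_subgrids(plot_table):
    from twignet.pipeline import TWOWAY_GRIDS

    for levels in TWOWAY_GRIDS.values():
        sub = plot_table[plot_table["level"].isin(levels)]
        res = tn.anova_twoway(sub, "L")
        assert np.isfinite(res.F_interaction)


# ----------------------------------------------------------------- Duncan

def _duncan_oracle(groups, alpha=0.05):
    """Independent all-spans implementation: a pair shares a letter iff it
    lies inside some span whose extreme range is below R_p and which is not
    separated by an enclosing rejected span test (top-down protection)."""
    aov = anova_oneway(groups)
    labels = sorted(groups, key=lambda k: -aov.group_mean[k])
    means = [aov.group_mean[k] for k in labels]
    k = len(labels)
    sizes = [aov.group_n[lab] for lab in labels]
    n_h = k / sum(1.0 / s for s in sizes)
    homogeneous = set()

    def rp(p):
        if aov.mse == 0:
            return 0.0
        prot = 1 - (1 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1 - prot, p, aov.df_within)
        return q * np.sqrt(aov.mse / n_h)

    rp_table = {p: rp(p) for p in range(2, k + 1)}
    seen = set()

    def visit(i, j):
        if i >= j or (i, j) in seen:
            return
        seen.add((i, j))
        if means[i] - means[j] < max(rp_table[p] for p in range(2, j - i + 2)) or means[i] == means[j]:
            for a, b in itertools.combinations(range(i, j + 1), 2):
                homogeneous.add((a, b))
        else:
            visit(i, j - 1)
            visit(i + 1, j)

    visit(0, k - 1)
    return labels, homogeneous


def _share_letter(letters, a, b):
    return bool(set(letters[a]) & set(letters[b]))


def test_duncan_two_identical_groups_share_a_letter():
    letters = duncan_groups({"a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9]})
    assert letters["a"] == letters["b"] == "a"


def test_duncan_forced_separation():
    letters = duncan_groups({"lo": [1.0, 1.1, 0.9], "hi": [100.0, 100.1, 99.9]})
    assert letters["hi"] == "a"
    assert letters["lo"] == "b"


@pytest.mark.parametrize("seed", range(6))
def test_duncan_matches_all_spans_oracle(seed):
    rng = np.random.default_rng(seed)
    shift = rng.uniform(0, 3, 4)
    groups = {f"g{i}": rng.normal(shift[i], 1.0, 5) for i in range(4)}
    letters = duncan_groups(groups)
    labels, homogeneous = _duncan_oracle(groups)
    idx = {lab: i for i, lab in enumerate(labels)}
    for a, b in itertools.combinations(labels, 2):
        i, j = sorted((idx[a], idx[b]))
        assert _share_letter(letters, a, b) == ((i, j) in homogeneous), (a, b)


def test_duncan_ranges_monotone_in_span():
    from twignet.groupstats import _duncan_ranges

    r = _duncan_ranges(6, 20, 2.0, 5.0, 0.05)
    assert np.all(np.diff(r) >= -1e-12)


def test_duncan_letters_transitively_consistent(plot_table):
    groups = {
        lv: g["L"].to_numpy() for lv, g in plot_table.groupby("level")
    }
    letters = duncan_groups(groups)
    labels, homogeneous = _duncan_oracle(groups)
    idx = {lab: i for i, lab in enumerate(labels)}
    # groups sharing a letter were part of an accepted span in the oracle
    for a, b in itertools.combinations(labels, 2):
        if _share_letter(letters, a, b):
            i, j = sorted((idx[a], idx[b]))
            assert (i, j) in homogeneous
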