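"""Statistical battery: worked examples, distribution oracles, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mitomorph as mm
from mitomorph.groupstats import _max_abs_t_null


WORKED = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [3.0, 4.0, 5.0]}


# ------------------------------------------------------------- aggregation

def test_per_cell_mean():
    df = pd.DataFrame(
        {
            "cell_id": ["c1", "c1"],
            "condition": ["ctrl", "ctrl"],
            **{p: [1000.0, 2000.0] if p == "area" else [1.0, 3.0] for p in mm.PARAMETERS},
        }
    )
    cells = mm.aggregate_per_cell(df)
    assert len(cells) == 1
    assert cells.loc[0, "area"] == 1500.0
    assert cells.loc[0, "n_particles"] == 2


def test_global_mean_is_weighted_cell_mean():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "cell_id": rng.choice(["c1", "c2", "c3"], 60),
            "condition": "ctrl",
            **{p: rng.normal(10, 2, 60) for p in mm.PARAMETERS},
        }
    )
    cells = mm.aggregate_per_cell(df)
    w = cells["n_particles"]
    assert np.average(cells["area"], weights=w) == pytest.approx(df["area"].mean())


# ------------------------------------------------------------ Shapiro-Wilk

def test_shapiro_normal_scores_near_one():
    x = sps.norm.ppf((np.arange(1, 51) - 0.375) / (50 + 0.25))
    w, p = mm.shapiro_wilk(x)
    assert w > 0.99


def test_shapiro_flags_heavy_tails():
    rng = np.random.default_rng(4)
    ps = [mm.shapiro_wilk(rng.standard_cauchy(50))[1] for _ in range(300)]
    assert np.median(ps) < 0.05


def test_shapiro_rejects_degenerate_input():
    with pytest.raises(ValueError):
        mm.shapiro_wilk([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        mm.shapiro_wilk([1.0, 2.0])


# ------------------------------------------------------------------- ANOVA

def test_anova_worked_example():
    res = mm.one_way_anova(WORKED)
    assert res.f_statistic == pytest.approx(3.0, abs=1e-12)
    assert (res.df_between, res.df_within) == (2, 6)
    # p against an independent F-distribution evaluation
    assert res.p_value == pytest.approx(float(sps.f.sf(3.0, 2, 6)), abs=1e-12)


def test_anova_identical_means_f_zero():
    res = mm.one_way_anova({"a": [1, 2, 3], "b": [2, 1, 3]})
    assert res.f_statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_degenerate_variance():
    with pytest.raises(ValueError):
        mm.one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})


def test_anova_matches_scipy():
    rng = np.random.default_rng(9)
    groups = {k: rng.normal(k_i, 1, 12) for k_i, k in enumerate("abc")}
    res = mm.one_way_anova(groups)
    f, p = sps.f_oneway(*groups.values())
    assert res.f_statistic == pytest.approx(float(f), rel=1e-12)
    assert res.p_value == pytest.approx(float(p), rel=1e-9)


# ----------------------------------------------------------------- Dunnett

def test_dunnett_k2_reduces_to_t_test():
    rng = np.random.default_rng(12)
    for _ in range(5):
        groups = {"ctrl": rng.normal(0, 1, 15), "t1": rng.normal(0.7, 1, 15)}
        res = mm.dunnett(groups, "ctrl")[0]
        _, p_t = sps.ttest_ind(groups["t1"], groups["ctrl"])
        assert res.p_adjusted == pytest.approx(float(p_t), abs=0.005)


def test_dunnett_matches_scipy_reference():
    """Monte Carlo adjustment vs scipy's multivariate-t evaluation (k=3)."""
    rng = np.random.default_rng(5)
    control = rng.normal(0, 1, 20)
    t1 = rng.normal(0.8, 1, 20)
    t2 = rng.normal(-0.2, 1, 20)
    ours = mm.dunnett({"ctrl": control, "t1": t1, "t2": t2}, "ctrl")
    ref = sps.dunnett(t1, t2, control=control)
    for r, p_ref in zip(ours, ref.pvalue):
        assert r.p_adjusted == pytest.approx(float(p_ref), abs=0.01)


def test_dunnett_adjusted_p_at_least_lsd_p():
    rng = np.random.default_rng(6)
    groups = {
        "ctrl": rng.normal(0, 1, 10),
        "t1": rng.normal(0.5, 1, 10),
        "t2": rng.normal(1.0, 1, 10),
    }
    dn = {r.comparison: r.p_adjusted for r in mm.dunnett(groups, "ctrl")}
    lsd = {r.comparison: r.p_adjusted for r in mm.fisher_lsd(groups, "ctrl")}
    for comp in dn:
        assert lsd[comp] <= dn[comp] + 1e-9


def test_dunnett_missing_control():
    with pytest.raises(ValueError):
        mm.dunnett({"a": [1, 2], "b": [2, 3]}, "ctrl")


def _simulate_rates(delta: float, n_datasets: int, seed: int, n: int = 24) -> float:
    """Fraction of null/shifted datasets with any Dunnett rejection (k=3)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_datasets):
        groups = {
            "ctrl": rng.normal(0, 1, n),
            "t1": rng.normal(delta, 1, n),
            "t2": rng.normal(0, 1, n),
        }
        res = mm.dunnett(groups, "ctrl")
        hits += any(r.significant for r in res)
    return hits / n_datasets


def test_dunnett_familywise_error_calibrated():
    fwer = _simulate_rates(0.0, 1000, seed=77)
    assert fwer == pytest.approx(0.05, abs=0.02)


def test_dunnett_power_for_two_sd_shift():
    power = _simulate_rates(2.0, 200, seed=78)
    assert power >= 0.95


def test_lsd_per_comparison_error_not_familywise():
    rng = np.random.default_rng(13)
    rejections = 0
    comparisons = 0
    for _ in range(500):
        groups = {k: rng.normal(0, 1, 15) for k in ("ctrl", "t1", "t2")}
        for r in mm.fisher_lsd(groups, "ctrl"):
            comparisons += 1
            rejections += r.significant
    assert rejections / comparisons == pytest.approx(0.05, abs=0.02)


def test_null_cache_reuse():
    d = (0.7071067811865476,)
    s1 = _max_abs_t_null(d, 30, 10_000, 1)
    s2 = _max_abs_t_null(d, 30, 10_000, 1)
    assert s1 is s2


# ------------------------------------------------------- run_group_analysis

def _cells_frame(rng, n=12, shift=0.0):
    rows = []
    for cond, mu in (("control", 0.0), ("treated", shift)):
        for i in range(n):
            rows.append(
                {
                    "cell_id": f"{cond}{i}",
                    "condition": cond,
                    **{p: rng.normal(10 + mu, 1) for p in mm.PARAMETERS},
                }
            )
    return pd.DataFrame(rows)


def test_run_group_analysis_structure_and_sem():
    rng = np.random.default_rng(3)
    cells = _cells_frame(rng, shift=2.0)
    anova, comps = mm.run_group_analysis(cells, "control")
    assert len(anova) == len(mm.PARAMETERS)
    assert len(comps) == len(mm.PARAMETERS)  # one treatment
    ctrl = cells[cells.condition == "control"]["area"]
    row = anova[anova.parameter == "area"].iloc[0]
    assert row["sem_control"] == pytest.approx(ctrl.std(ddof=1) / np.sqrt(len(ctrl)))
    assert comps["significant"].all()


def test_run_group_analysis_needs_control():
    cells = _cells_frame(np.random.default_rng(0))
    with pytest.raises(ValueError):
        mm.run_group_analysis(cells, "missing")
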