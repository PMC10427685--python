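"""Per-cell aggregation and group comparison statistics.

The statistical unit is the cell: each cell's particles are averaged into
one row per parameter, and conditions are compared on those per-cell means.
The battery mirrors common practice for this kind of morphometry: a
Shapiro-Wilk normality screen (advisory — it is logged, never switches the
test), one-way ANOVA, and Dunnett's many-to-one procedure comparing every
treatment against the shared control with family-wise error control.
Fisher's LSD (unadjusted pairwise t-tests on the pooled error term) is
available for analyses where per-comparison error is the convention.

Dunnett-adjusted p-values are computed by seeded Monte Carlo over the joint
null distribution of the maximum absolute t statistic: the k-1 statistics
share the control mean, giving correlation
rho_ij = sqrt(n_i n_j / ((n_i + n_0)(n_j + n_0))) (0.5 when balanced).  The
null sample is cached per (k, df, correlation, draws, seed), so repeated
calls — e.g. simulation calibration — pay the sampling cost once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import PARAMETERS

logger = logging.getLogger("mitomorph")

__all__ = [
    "AnovaResult",
    "DunnettResult",
    "aggregate_per_cell",
    "shapiro_wilk",
    "one_way_anova",
    "dunnett",
    "fisher_lsd",
    "run_group_analysis",
]

DEFAULT_MC_DRAWS = 100_000
DEFAULT_MC_SEED = 20260928


@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict
    group_sems: dict
    ms_within: float


@dataclass(frozen=True)
class DunnettResult:
    parameter: str
    comparison: str          # "<treatment> vs <control>"
    estimate: float          # treatment mean - control mean
    t_statistic: float
    p_adjusted: float
    alpha: float
    significant: bool


def aggregate_per_cell(records: pd.DataFrame, parameters=PARAMETERS) -> pd.DataFrame:
    """Arithmetic mean of each parameter over each cell's particles.

    Input is the particle table from :func:`mitomorph.morphometry.measure_image`
    (one row per particle, with ``cell_id`` and ``condition``).  Cells with
    zero particles simply have no rows and are omitted; the particle count
    per cell is recorded as ``n_particles``.
    """
    required = {"cell_id", "condition"} | set(parameters)
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"particle table lacks columns: {sorted(missing)}")
    if records.empty:
        return pd.DataFrame(columns=["cell_id", "condition", *parameters, "n_particles"])
    g = records.groupby(["cell_id", "condition"], sort=True)
    out = g[list(parameters)].mean()
    out["n_particles"] = g.size()
    return out.reset_index()


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation, via scipy).

    Requires 3 <= n <= 5000 and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: Shapiro-Wilk undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _check_groups(groups: dict) -> dict[str, np.ndarray]:
    g = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(g) < 2:
        raise ValueError("need at least two groups")
    for k, v in g.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    return g


def one_way_anova(groups: dict, parameter: str = "") -> AnovaResult:
    """Classic one-way fixed-effects ANOVA from the between/within decomposition."""
    g = _check_groups(groups)
    ns = {k: len(v) for k, v in g.items()}
    N = sum(ns.values())
    k = len(g)
    grand = np.concatenate(list(g.values())).mean()
    ssb = sum(n * (v.mean() - grand) ** 2 for (key, v), n in zip(g.items(), ns.values()))
    ssw = sum(((v - v.mean()) ** 2).sum() for v in g.values())
    dfb, dfw = k - 1, N - k
    if ssw == 0:
        raise ValueError("zero within-group variance in every group")
    msb, msw = ssb / dfb, ssw / dfw
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(
        parameter=parameter,
        f_statistic=float(f),
        df_between=dfb,
        df_within=dfw,
        p_value=p,
        group_means={key: float(v.mean()) for key, v in g.items()},
        group_sems={key: float(v.std(ddof=1) / np.sqrt(len(v))) for key, v in g.items()},
        ms_within=float(msw),
    )


_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _max_abs_t_null(
    d: tuple[float, ...], df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Sorted Monte Carlo sample of max_i |T_i| under the Dunnett null.

    T_i = Z_i / sqrt(chi2_df/df) with Z_i = sqrt(1-d_i^2) U_i + d_i U_0,
    U iid standard normal, which induces corr(Z_i, Z_j) = d_i d_j — exactly
    the correlation of the k-1 mean contrasts sharing the control,
    d_i = sqrt(n_i/(n_i + n_0)).
    """
    key = (d, df, n_draws, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        k1 = len(d)
        u0 = rng.standard_normal(n_draws)
        u = rng.standard_normal((n_draws, k1))
        dv = np.asarray(d)
        z = u * np.sqrt(1.0 - dv**2) + u0[:, None] * dv
        s = np.sqrt(rng.chisquare(df, n_draws) / df)
        _NULL_CACHE[key] = np.sort(np.abs(z / s[:, None]).max(axis=1))
    return _NULL_CACHE[key]


def dunnett(
    groups: dict,
    control_label: str,
    alpha: float = 0.05,
    *,
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = DEFAULT_MC_SEED,
    parameter: str = "",
) -> list[DunnettResult]:
    """Dunnett's many-to-one comparisons, two-sided.

    Each treatment i is compared to the control with
    t_i = (mean_i - mean_0) / sqrt(MSW * (1/n_i + 1/n_0)); the adjusted p is
    P(max_j |T_j| >= |t_i|) under the joint null, evaluated on the seeded
    Monte Carlo sample of :func:`_max_abs_t_null` (the seed is part of the
    API so results are reproducible and auditable).
    """
    g = _check_groups(groups)
    if control_label not in g:
        raise ValueError(f"control group {control_label!r} missing")
    anova = one_way_anova(groups, parameter)
    msw, dfw = anova.ms_within, anova.df_within
    x0 = g[control_label]
    n0 = len(x0)
    treatments = [k for k in g if k != control_label]
    d = tuple(
        float(np.sqrt(len(g[k]) / (len(g[k]) + n0))) for k in treatments
    )
    null = _max_abs_t_null(d, dfw, n_draws, seed)
    results = []
    for k_t, d_i in zip(treatments, d):
        x = g[k_t]
        est = x.mean() - x0.mean()
        t = est / np.sqrt(msw * (1.0 / len(x) + 1.0 / n0))
        # P(max|T| >= |t|) with a +1 continuity guard against p = 0
        idx = np.searchsorted(null, abs(t), side="left")
        p_adj = float((len(null) - idx + 1) / (len(null) + 1))
        p_adj = min(1.0, p_adj)
        results.append(
            DunnettResult(
                parameter=parameter,
                comparison=f"{k_t} vs {control_label}",
                estimate=float(est),
                t_statistic=float(t),
                p_adjusted=p_adj,
                alpha=alpha,
                significant=p_adj < alpha,
            )
        )
    return results


def fisher_lsd(
    groups: dict, control_label: str, alpha: float = 0.05, parameter: str = ""
) -> list[DunnettResult]:
    """Fisher's LSD: unadjusted t-tests on the pooled ANOVA error term."""
    g = _check_groups(groups)
    if control_label not in g:
        raise ValueError(f"control group {control_label!r} missing")
    anova = one_way_anova(groups, parameter)
    msw, dfw = anova.ms_within, anova.df_within
    x0 = g[control_label]
    results = []
    for k_t in (k for k in g if k != control_label):
        x = g[k_t]
        est = x.mean() - x0.mean()
        t = est / np.sqrt(msw * (1.0 / len(x) + 1.0 / len(x0)))
        p = float(2.0 * sps.t.sf(abs(t), dfw))
        results.append(
            DunnettResult(
                parameter=parameter,
                comparison=f"{k_t} vs {control_label}",
                estimate=float(est),
                t_statistic=float(t),
                p_adjusted=p,
                alpha=alpha,
                significant=p < alpha,
            )
        )
    return results


def run_group_analysis(
    cells: pd.DataFrame,
    control_label: str,
    alpha: float = 0.05,
    *,
    parameters=PARAMETERS,
    test: str = "dunnett",
    seed: int = DEFAULT_MC_SEED,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normality screen + ANOVA + many-to-one comparisons per parameter.

    ``cells`` is the per-cell table from :func:`aggregate_per_cell`.  Returns
    ``(anova_table, comparisons_table)``.  The anova table carries per-group
    mean, SEM and the Shapiro-Wilk screen (advisory; a warning is logged for
    p < 0.05 but the parametric battery proceeds, matching the protocol of
    screening before assuming a Gaussian model).
    """
    if "condition" not in cells.columns:
        raise ValueError("cell table needs a 'condition' column")
    conds = list(dict.fromkeys(cells["condition"]))
    if control_label not in conds:
        raise ValueError(f"control condition {control_label!r} not present")
    if len(conds) < 2:
        raise ValueError("need control plus at least one treatment")
    compare = dunnett if test == "dunnett" else fisher_lsd
    anova_rows, comp_rows = [], []
    for param in parameters:
        groups = {c: cells.loc[cells["condition"] == c, param].to_numpy() for c in conds}
        for c, v in groups.items():
            if len(v) >= 3 and np.ptp(v) > 0:
                w, p_norm = shapiro_wilk(v)
                if p_norm < 0.05:
                    logger.warning(
                        "normality screen: %s in %s deviates (W=%.3f, p=%.3g)",
                        param, c, w, p_norm,
                    )
        a = one_way_anova(groups, param)
        anova_rows.append(
            {
                "parameter": param,
                "F": a.f_statistic,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "p_value": a.p_value,
                **{f"mean_{c}": a.group_means[c] for c in conds},
                **{f"sem_{c}": a.group_sems[c] for c in conds},
            }
        )
        if test == "dunnett":
            res = compare(groups, control_label, alpha, parameter=param, seed=seed)
        else:
            res = compare(groups, control_label, alpha, parameter=param)
        for r in res:
            comp_rows.append(
                {
                    "parameter": param,
                    "comparison": r.comparison,
                    "estimate": r.estimate,
                    "t": r.t_statistic,
                    "p_adj": r.p_adjusted,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(anova_rows), pd.DataFrame(comp_rows)
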