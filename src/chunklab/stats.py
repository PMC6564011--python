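"""Inferential layer: ANOVAs, t-tests, correlation, planned comparisons.

Per-game summary measures (mean latency, chunk count, proportion chunked,
time savings, the randomness statistic) are analysed with additive two-way
ANOVAs — factors League (skill, 8 levels) and Species (the player's chosen
race, a nuisance factor) — reporting F, p and partial η² per factor, plus
paired/one-sample t-tests, Pearson correlation with a Fisher-z interval,
and family-wise-corrected pairwise league comparisons.

Degrees of freedom are always computed from the data actually supplied,
never forced to match any external report.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

GAME_LEVEL_COLUMNS = [
    "game_id", "league", "species", "mean_latency_ms", "n_chunks",
    "prop_chunked", "total_savings_s", "first_action_savings_s",
    "inter_action_savings_s", "randomness",
]


@dataclass
class AnovaResult:
    """One factor's row of an additive two-way ANOVA."""
    factor: str
    F: float
    df_effect: int
    df_residual: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_residual: float


@dataclass
class TTestResult:
    """t, df, p and a 95% CI; ``degenerate`` flags zero-variance input."""
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    estimate: float
    degenerate: bool = False


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def anova_additive(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = ("league", "species"),
    ss_type: str = "marginal",
) -> dict[str, AnovaResult]:
    """Additive (no-interaction) ANOVA with marginal F tests per factor.

    ``ss_type="marginal"`` gives each factor's sum of squares adjusted for
    the other (Type II — well defined in an additive model);
    ``"sequential"`` gives Type I in the order the factors are listed.
    Partial η² = SS_effect / (SS_effect + SS_residual).  Factors that are
    constant in the supplied data are dropped with a warning, so a design
    with one effective factor reduces exactly to one-way ANOVA.
    """
    if ss_type not in ("marginal", "sequential"):
        raise ValueError(f"unknown ss_type {ss_type!r}")
    df = table.dropna(subset=[response, *factors]).copy()
    used = []
    for f in factors:
        if df[f].nunique() < 2:
            warnings.warn(f"factor {f!r} is constant in the data; dropped")
        else:
            used.append(f)
    if not used:
        raise ValueError("no non-constant factor to test")
    y = df[response].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        # constant response: every effect SS is exactly zero
        df_res = len(df) - 1 - sum(df[f].nunique() - 1 for f in used)
        return {f: AnovaResult(factor=f, F=0.0,
                               df_effect=df[f].nunique() - 1,
                               df_residual=df_res, p=1.0,
                               partial_eta_sq=0.0, ss_effect=0.0,
                               ss_residual=0.0)
                for f in used}
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in used)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < \
            model.model.exog.shape[1]:
        raise ValueError(
            f"singular design for factors {used}: some factor levels are "
            "aliased (confounded); merge or drop levels")
    typ = 2 if ss_type == "marginal" else 1
    tab = sm.stats.anova_lm(model, typ=typ)
    ss_res = float(tab.loc["Residual", "sum_sq"])
    df_res = int(tab.loc["Residual", "df"])
    out: dict[str, AnovaResult] = {}
    for f in used:
        row = tab.loc[f"C({f})"]
        ss = float(row["sum_sq"])
        out[f] = AnovaResult(
            factor=f, F=float(row["F"]), df_effect=int(row["df"]),
            df_residual=df_res, p=float(row["PR(>F)"]),
            partial_eta_sq=ss / (ss + ss_res),
            ss_effect=ss, ss_residual=ss_res,
        )
    return out


def one_sample_t(x, mu0: float = 0.0) -> TTestResult:
    """Classical one-sample t-test of mean(x) against mu0, with 95% CI."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        # zero variance: t undefined unless the mean already equals mu0
        t = 0.0 if mean == mu0 else float("nan")
        return TTestResult(t=t, df=df, p=float("nan"),
                           ci_low=mean, ci_high=mean,
                           estimate=mean, degenerate=True)
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(0.975, df)
    return TTestResult(t=float(t), df=df, p=float(p),
                       ci_low=mean - tc * se, ci_high=mean + tc * se,
                       estimate=mean)


def paired_t(x, y) -> TTestResult:
    """Paired t-test on per-game differences x − y (df = pairs − 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0)


def pearson_r_t(x, y) -> CorrelationResult:
    """Pearson r with its t statistic and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    n = len(x)
    df = n - 2
    if x.std() == 0.0 or y.std() == 0.0:
        return CorrelationResult(r=float("nan"), t=float("nan"), df=df,
                                 p=float("nan"), ci_low=float("nan"),
                                 ci_high=float("nan"), degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, t=float("inf") * np.sign(r), df=df,
                                 p=0.0, ci_low=r, ci_high=r, degenerate=True)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    z = np.arctanh(r)
    zse = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.975)
    return CorrelationResult(r=r, t=float(t), df=df, p=float(p),
                             ci_low=float(np.tanh(z - zc * zse)),
                             ci_high=float(np.tanh(z + zc * zse)))


def planned_comparisons(
    table: pd.DataFrame,
    value: str,
    group: str = "league",
    correction: str = "holm",
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise two-sample t-tests on groups, family-wise adjusted.

    Holm adjustment by default (``bonferroni`` also available); pooled
    variance by default per classic planned-comparison practice, Welch via
    ``equal_var=False``.  Groups with fewer than 2 observations are dropped
    with a warning.
    """
    if correction not in ("holm", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    df = table.dropna(subset=[value, group])
    groups = {}
    for g, sub in df.groupby(group):
        vals = sub[value].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {g!r} has < 2 observations; dropped")
            continue
        groups[g] = vals
    levels = sorted(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 usable groups")
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        a, b = groups[g1], groups[g2]
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "group1": g1, "group2": g2,
            "mean1": float(a.mean()), "mean2": float(b.mean()),
            "t": float(res.statistic), "df": float(res.df),
            "p_raw": float(res.pvalue),
        })
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha,
                                        method=correction)
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out


def build_game_summaries(
    games,
    detections: dict,
    savings: dict,
    diversity: dict | None = None,
    rightclick: dict | None = None,
) -> pd.DataFrame:
    """Assemble the per-game summary table from module outputs.

    ``detections``, ``savings``, ``diversity`` and ``rightclick`` map
    game_id to a DetectionResult, SavingsSummary, DiversityResult (or None
    for excluded games), and redundant right-click mean latency.
    """
    rows = []
    for g in games:
        det = detections[g.game_id]
        sav = savings[g.game_id]
        lat = g.actions["latency_ms"]
        n_in = int(det.annotation.in_chunk.sum())
        row = {
            "game_id": g.game_id,
            "league": g.league,
            "species": g.species,
            "mean_latency_ms": float(lat.mean()) if lat.notna().any() else np.nan,
            "n_chunks": len(det.confirmed),
            "prop_chunked": n_in / g.a if g.a else np.nan,
            "total_savings_s": sav.total_savings_s,
            "first_action_savings_s": sav.first_action_savings_s,
            "inter_action_savings_s": sav.inter_action_savings_s,
            "randomness": np.nan,
            "rightclick_latency_ms": np.nan,
        }
        if diversity is not None and diversity.get(g.game_id) is not None:
            row["randomness"] = diversity[g.game_id].randomness
        if rightclick is not None and rightclick.get(g.game_id) is not None:
            row["rightclick_latency_ms"] = rightclick[g.game_id]
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_tables(
    summaries: pd.DataFrame, outdir, analyses: dict[str, pd.DataFrame] | None = None
) -> None:
    """Write game_level.csv plus optional per-analysis tables under outdir."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [c for c in GAME_LEVEL_COLUMNS if c in summaries.columns]
    summaries[cols].to_csv(outdir / "game_level.csv", index=False)
    for name, tab in (analyses or {}).items():
        tab.to_csv(outdir / f"{name}.csv", index=False)


def read_supplementary(path) -> pd.DataFrame:
    """Read a published per-game summary CSV for re-running the inference.

    A light wrapper over ``pandas.read_csv`` that strips column-name
    whitespace, so the inferential functions above can be pointed directly
    at externally released per-game summary tables.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    return df
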