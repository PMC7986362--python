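"""Cohort-level statistics: day-type contrasts, adjusted means, correlations,
time-of-day profiles and matched-control selection.

Reproduces the study's statistical surface on minute-grid summaries:
per-participant mean vector magnitude and behaviour hours by day type,
group mean (SE) tables, paired t-tests for dialysis vs non-dialysis
days, linear-model estimated marginal means adjusted for age, sex and
leg weakness, Spearman correlations with questionnaire scores,
time-of-day mean/CI curves, and greedy age/sex/season-matched control
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import STATES
from .wear_qc import MinuteGrid

__all__ = [
    "ActivitySummary",
    "MatchedSet",
    "summarize_participant",
    "summaries_to_frame",
    "group_mean_se",
    "paired_daytype_test",
    "adjusted_marginal_means",
    "questionnaire_correlations",
    "time_of_day_profile",
    "match_controls",
]

OUTCOMES = ("vm",) + tuple(f"hours_{s}" for s in STATES)


@dataclass
class ActivitySummary:
    """Per-participant activity summary by day type and overall.

    ``by_daytype`` maps "dialysis" / "non-dialysis" / "overall" to a dict
    with mean ``vm`` (mg), ``hours_<state>`` (h/day) and ``n_days``.
    "overall" is the mean over all included days — a wear-time-weighted
    reading, not the mean of the two day-type means.
    """

    participant_id: str
    by_daytype: dict = field(default_factory=dict)

    def get(self, day_type: str, outcome: str) -> float:
        d = self.by_daytype.get(day_type)
        return float("nan") if d is None else d.get(outcome, float("nan"))


def _summarize_days(vm: np.ndarray, state: np.ndarray) -> dict:
    """Summaries over a (days x 1440) block; missing minutes are excluded."""
    n_days = len(vm)
    out = {"n_days": n_days, "vm": float(np.nanmean(vm)) if np.isfinite(vm).any() else float("nan")}
    for s in STATES:
        out[f"hours_{s}"] = float((state == s).sum()) / 60.0 / n_days
    return out


def summarize_participant(grid: MinuteGrid) -> ActivitySummary:
    """Mean vm and behaviour hours per day type for one (imputed) grid.

    Day-type mean vm averages all non-missing minutes of that type's
    days; state hours/day are minutes in state / 60 averaged over the
    type's days. Excluded (partial) days never contribute. A day type
    with zero included days is left missing.
    """
    summary = ActivitySummary(participant_id=grid.participant_id)
    for ty in ("dialysis", "non-dialysis"):
        mask = grid.day_mask(ty)
        if mask.any():
            summary.by_daytype[ty] = _summarize_days(grid.vm[mask], grid.state[mask])
    inc = grid.included_mask
    if inc.any():
        summary.by_daytype["overall"] = _summarize_days(grid.vm[inc], grid.state[inc])
    return summary


def summaries_to_frame(summaries: list[ActivitySummary]) -> pd.DataFrame:
    """Flatten summaries to one row per participant (columns like
    ``vm_overall``, ``hours_sleep_dialysis``)."""
    rows = []
    for s in summaries:
        row = {"id": s.participant_id}
        for ty, vals in s.by_daytype.items():
            for k, v in vals.items():
                if k != "n_days":
                    row[f"{k}_{ty}"] = v
            row[f"n_days_{ty}"] = vals["n_days"]
        rows.append(row)
    return pd.DataFrame(rows)


def group_mean_se(
    df: pd.DataFrame, group: str, outcomes: list[str] | None = None
) -> pd.DataFrame:
    """Mean (SE = sd/sqrt(n)) per group per outcome; single-member groups get
    their mean with missing SE, empty groups are omitted."""
    if outcomes is None:
        outcomes = [c for c in df.columns if c not in ("id", group)]
    rows = []
    for g, sub in df.groupby(group, dropna=False, sort=True, observed=True):
        if len(sub) == 0:
            continue
        row = {group: g, "n": len(sub)}
        for out in outcomes:
            vals = sub[out].dropna().to_numpy(dtype=float)
            row[f"{out}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{out}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def paired_daytype_test(df: pd.DataFrame, outcome: str) -> dict:
    """Paired t-test of dialysis vs non-dialysis day values.

    Uses participants with both day-type values; returns the mean
    within-participant difference (dialysis minus non-dialysis), t and
    the two-sided p. Zero-variance differences with a nonzero mean are
    reported at the machine floor with ``degenerate=True``.
    """
    a = df[f"{outcome}_dialysis"].to_numpy(dtype=float)
    b = df[f"{outcome}_non-dialysis"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("need at least 2 participants with both day-type values")
    diff = a[ok] - b[ok]
    mean_diff = float(diff.mean())
    degenerate = diff.std(ddof=1) == 0.0
    if degenerate:
        if mean_diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if mean_diff > 0 else -np.inf
            p = float(np.finfo(float).tiny)
    else:
        t, p = stats.ttest_rel(a[ok], b[ok])
    return {
        "outcome": outcome,
        "n": int(ok.sum()),
        "mean_difference": mean_diff,
        "t": float(t),
        "p": float(p),
        "degenerate": bool(degenerate),
    }


def adjusted_marginal_means(
    df: pd.DataFrame,
    outcome: str,
    group: str,
    adjust_for: tuple[str, ...] = ("age", "sex", "leg_weakness"),
    ordered_levels: list | None = None,
) -> dict:
    """Estimated marginal means from a covariate-adjusted linear model.

    Fits ``outcome ~ group + covariates`` by least squares and predicts
    each group's mean at the cohort-average covariate values. The
    heterogeneity p comes from the F-test of the group term; the trend p
    from re-coding ordered groups 0, 1, 2, ... as a slope.
    """
    import statsmodels.api as sm

    data = df[[outcome, group, *adjust_for]].dropna().copy()
    levels = ordered_levels if ordered_levels is not None else sorted(data[group].unique())
    X_parts = {f"g_{lev}": (data[group] == lev).astype(float) for lev in levels[1:]}
    for cov in adjust_for:
        col = data[cov]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            X_parts[cov] = pd.get_dummies(col, drop_first=True).iloc[:, 0].astype(float)
        else:
            X_parts[cov] = col.astype(float)
    X = pd.DataFrame(X_parts, index=data.index)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased column: the first whose removal restores full rank
        for c in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                raise ValueError(f"design matrix rank deficient: term {c!r} is aliased")
        raise ValueError("design matrix rank deficient")
    fit = sm.OLS(data[outcome].astype(float), X).fit()

    cov_means = {c: X[c].mean() for c in X.columns if c == "const" or c in adjust_for}
    marginal = {}
    for lev in levels:
        xrow = pd.Series(0.0, index=X.columns)
        for c, v in cov_means.items():
            xrow[c] = v
        if lev != levels[0]:
            xrow[f"g_{lev}"] = 1.0
        pred = fit.get_prediction(xrow.to_frame().T)
        marginal[lev] = (float(pred.predicted_mean[0]), float(pred.se_mean[0]))

    group_cols = [f"g_{lev}" for lev in levels[1:]]
    contrast = np.zeros((len(group_cols), X.shape[1]))
    for i, c in enumerate(group_cols):
        contrast[i, X.columns.get_loc(c)] = 1.0
    het = fit.f_test(contrast)

    codes = data[group].map({lev: i for i, lev in enumerate(levels)}).astype(float)
    Xt = X.drop(columns=group_cols)
    Xt["trend"] = codes
    trend_fit = sm.OLS(data[outcome].astype(float), Xt).fit()
    return {
        "marginal_means": marginal,
        "heterogeneity_p": float(het.pvalue),
        "trend_p": float(trend_fit.pvalues["trend"]),
        "model": fit,
    }


def questionnaire_correlations(
    df: pd.DataFrame,
    activity_cols: list[str],
    score_cols: list[str],
    fdr: bool = False,
) -> pd.DataFrame:
    """Spearman rank correlations (average-rank ties, two-sided p) between
    activity measures and questionnaire scores; constant columns flagged.

    No multiplicity adjustment is applied by default (matching the
    original analysis's narrative caution); ``fdr=True`` adds a
    Benjamini-Hochberg adjusted-p column.
    """
    rows = []
    for a in activity_cols:
        for s in score_cols:
            pair = df[[a, s]].dropna()
            if len(pair) < 3:
                raise ValueError(f"need >= 3 complete pairs for {a} vs {s}")
            x, y = pair[a].to_numpy(float), pair[s].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"activity": a, "score": s, "rho": float("nan"),
                             "p": float("nan"), "n": len(pair), "constant": True})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"activity": a, "score": s, "rho": float(rho), "p": float(p),
                         "n": len(pair), "constant": False})
    out = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_fdr"] = adj
    return out


def time_of_day_profile(
    grids: list[MinuteGrid],
    day_type: str | None = None,
    bin_min: int = 10,
    outcome: str = "vm",
    state: str | None = None,
) -> pd.DataFrame:
    """Mean and 95% CI across participants per clock-time bin.

    For each participant, bin values are averaged over their days of the
    requested type (``None`` = all included days); the curve is the mean
    across participants with CI half-width 1.96 x SE. ``outcome='vm'``
    profiles intensity; ``outcome='state'`` profiles the probability of
    ``state``.
    """
    if 1440 % bin_min != 0:
        raise ValueError("bin_min must divide 1440")
    n_bins = 1440 // bin_min
    per_part = []
    for grid in grids:
        mask = grid.included_mask if day_type is None else grid.day_mask(day_type)
        if not mask.any():
            continue
        if outcome == "vm":
            vals = grid.vm[mask].reshape(-1, n_bins, bin_min)
            with np.errstate(invalid="ignore"):
                per_part.append(np.nanmean(vals, axis=(0, 2)))
        elif outcome == "state":
            if state is None:
                raise ValueError("state required for outcome='state'")
            st = grid.state[mask]
            present = st != None  # noqa: E711  (object array)
            hit = (st == state).reshape(-1, n_bins, bin_min)
            pres = present.reshape(-1, n_bins, bin_min)
            with np.errstate(invalid="ignore"):
                per_part.append(hit.sum(axis=(0, 2)) / pres.sum(axis=(0, 2)))
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
    arr = np.asarray(per_part)
    mean = np.nanmean(arr, axis=0)
    n_eff = np.isfinite(arr).sum(axis=0)
    sd = np.nanstd(arr, axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(n_eff, 1))
    return pd.DataFrame(
        {
            "bin_start_min": np.arange(n_bins) * bin_min,
            "mean": mean,
            "se": se,
            "ci_low": mean - 1.96 * se,
            "ci_high": mean + 1.96 * se,
            "n": n_eff,
        }
    )


@dataclass
class MatchedSet:
    case_id: str
    control_ids: list[str]
    match_keys: tuple  # (age, sex, season)


def match_controls(
    cases: list,
    pool: list,
    k: int = 5,
    age_caliper: float = 3.0,
    seed: int = 0,
) -> tuple[list[MatchedSet], list[str]]:
    """Greedy without-replacement matching: exact sex and wear season,
    nearest age within the caliper, up to ``k`` controls per case.

    Cases are visited in a seed-randomised order so no case systematically
    exhausts the pool. Returns ``(matched_sets, unmatched_case_ids)``;
    cases outside the pool's age range (no eligible control) are reported
    unmatched rather than force-matched.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    case_ids = {c.id for c in cases}
    if any(p.id in case_ids for p in pool):
        raise ValueError("control pool overlaps the case set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    available = {p.id: p for p in pool}
    sets, unmatched = [], []
    for i in order:
        case = cases[i]
        elig = [
            p
            for p in available.values()
            if p.sex == case.sex
            and p.wear_season == case.wear_season
            and abs(p.age - case.age) <= age_caliper
        ]
        if not elig:
            unmatched.append(case.id)
            continue
        elig.sort(key=lambda p: (abs(p.age - case.age), p.id))
        chosen = elig[:k]
        for p in chosen:
            del available[p.id]
        sets.append(
            MatchedSet(
                case_id=case.id,
                control_ids=[p.id for p in chosen],
                match_keys=(case.age, case.sex, case.wear_season),
            )
        )
    sets.sort(key=lambda s: s.case_id)
    return sets, sorted(unmatched)
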