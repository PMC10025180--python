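"""Normality-routed group comparisons, matching, and summary tables.

The statistical stage mirrors a small matched case-control study
design: per-joint two-group comparisons routed by Shapiro-Wilk
normality (independent t / Mann-Whitney U unpaired; paired t / Wilcoxon
signed-rank for matched pairs), Pearson chi-squared for proportions,
tie-safe Spearman correlations with exact permutation p-values at small
n, greedy 1:1 sex/age-strata matching, and the percent-difference
contrasts used to report group effects. All tests are two-sided; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "MatchedPairs",
    "shapiro_normality",
    "compare_groups",
    "chi_squared_proportions",
    "spearman_corr",
    "match_case_control",
    "percent_difference",
    "assemble_group_table",
    "correlation_table",
]

#: Normality gate for test routing (Shapiro-Wilk p at or above => normal).
NORMALITY_ALPHA = 0.05

#: Largest group size for which exact small-sample p-values are used.
EXACT_N = 8

#: Width of the age-matching strata in years, anchored at multiples of 5.
AGE_STRATUM_YEARS = 5


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    route: str = ""
    is_normal: bool | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class MatchedPairs:
    """1:1 case-control pairs sharing sex and 5-year age stratum."""

    pairs: list[tuple[str, str, tuple[str, int]]]
    unmatched_cases: list[str] = field(default_factory=list)


def shapiro_normality(values, alpha: float = NORMALITY_ALPHA) -> StatResult:
    """Shapiro-Wilk normality test; ``is_normal`` is ``p >= alpha``."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if np.all(x == x[0]):
        raise ValueError("constant input")
    w, p = sps.shapiro(x)
    return StatResult(
        test="shapiro_wilk", statistic=float(w), p_value=float(p),
        n=(int(x.size),), is_normal=bool(p >= alpha),
    )


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if x.size < 3 or np.all(x == x[0]):
        return False
    return bool(sps.shapiro(x)[1] >= alpha)


def compare_groups(
    a,
    b,
    paired: bool = False,
    force: str | None = None,
    alpha: float = NORMALITY_ALPHA,
    equal_var: bool = True,
) -> StatResult:
    """Two-group comparison routed by normality.

    Unpaired: independent (pooled-variance) t-test when both groups pass
    Shapiro-Wilk at ``alpha``, else Mann-Whitney U (exact when the
    smaller group has at most 8 observations and there are no ties,
    mid-rank + normal approximation otherwise). Paired: the route is
    decided on the differences (paired t vs Wilcoxon signed-rank).
    ``force`` overrides routing with one of ``t | mann_whitney |
    paired_t | wilcoxon_signed_rank``. Two-sided p-values throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return StatResult(test="paired_t", statistic=0.0, p_value=1.0,
                              n=(a.size, b.size), route="degenerate")
        normal = _is_normal(d, alpha)
        use_t = force == "paired_t" if force else normal
        if force == "wilcoxon_signed_rank":
            use_t = False
        if use_t:
            t, p = sps.ttest_rel(a, b)
            return StatResult(test="paired_t", statistic=float(t), p_value=float(p),
                              n=(a.size, b.size), route="normal")
        nz = d[d != 0]
        method = "exact" if (nz.size <= 25 and len(set(np.abs(nz))) == nz.size) else "approx"
        w, p = sps.wilcoxon(a, b, zero_method="wilcox", method=method)
        return StatResult(test="wilcoxon_signed_rank", statistic=float(w), p_value=float(p),
                          n=(a.size, b.size), route="nonnormal")

    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return StatResult(test="t", statistic=0.0, p_value=1.0,
                          n=(a.size, b.size), route="degenerate")
    normal = _is_normal(a, alpha) and _is_normal(b, alpha)
    use_t = force == "t" if force else normal
    if force == "mann_whitney":
        use_t = False
    if use_t:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return StatResult(test="t", statistic=float(t), p_value=float(p),
                          n=(a.size, b.size), route="normal")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_N and not ties) else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(test="mann_whitney", statistic=float(u), p_value=float(p),
                      n=(a.size, b.size), route=f"nonnormal:{method}")


def chi_squared_proportions(counts) -> StatResult:
    """Pearson chi-squared on a 2x2 table, no continuity correction."""
    t = np.asarray(counts)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.rint(t)):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return StatResult(test="chi_squared", statistic=float(chi2), p_value=float(p),
                      n=(int(t.sum()),), route=f"df={dof}")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of mid-rank vectors (tie-safe Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def spearman_corr(x, y, exact_n: int = EXACT_N) -> StatResult:
    """Spearman rho with a permutation-exact two-sided p at small n.

    rho is the Pearson correlation of mid-ranks. For n <= ``exact_n``
    the p-value enumerates all n! orderings; otherwise the usual t
    approximation on n-2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult(test="spearman", statistic=float("nan"), p_value=float("nan"),
                          n=(n,), route="constant-input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_n:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c * rx_c).sum() * (ry_c * ry_c).sum())
        rhos = (rx_c[None, :] * ry_c[perms]).sum(axis=1) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        route = "exact-permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        route = "t-approximation"
    return StatResult(test="spearman", statistic=rho, p_value=p, n=(n,), route=route)


def age_stratum(age: float, width: int = AGE_STRATUM_YEARS) -> int:
    """Left edge of the age band, anchored at multiples of the width."""
    return int(np.floor(age / width) * width)


def match_case_control(
    cases: pd.DataFrame, controls: pd.DataFrame, stratum_years: int = AGE_STRATUM_YEARS
) -> MatchedPairs:
    """Greedy 1:1 matching within (sex, age-band) strata.

    Within each stratum, candidate pairs are taken in order of smallest
    absolute age difference, ties broken by lexicographically smallest
    (case id, control id); ids are never reused. Unmatched cases are
    reported, not raised. ``cases``/``controls`` need columns
    ``id, sex, age``.
    """
    for df, name in ((cases, "cases"), (controls, "controls")):
        missing = {"id", "sex", "age"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    pairs = []
    used_controls: set[str] = set()
    matched_cases: set[str] = set()
    cases = cases.assign(_band=[age_stratum(a, stratum_years) for a in cases["age"]])
    controls = controls.assign(_band=[age_stratum(a, stratum_years) for a in controls["age"]])
    for (sex, band), case_grp in sorted(
        cases.groupby(["sex", "_band"]), key=lambda kv: (str(kv[0][0]), kv[0][1])
    ):
        ctrl_grp = controls[(controls["sex"] == sex) & (controls["_band"] == band)]
        candidates = sorted(
            (
                (abs(float(c.age) - float(k.age)), str(k.id), str(c.id))
                for k in case_grp.itertuples()
                for c in ctrl_grp.itertuples()
            )
        )
        for _, case_id, ctrl_id in candidates:
            if case_id in matched_cases or ctrl_id in used_controls:
                continue
            matched_cases.add(case_id)
            used_controls.add(ctrl_id)
            pairs.append((case_id, ctrl_id, (str(sex), int(band))))
    unmatched = [str(i) for i in cases["id"] if str(i) not in matched_cases]
    return MatchedPairs(pairs=pairs, unmatched_cases=unmatched)


def percent_difference(reference_mean: float, comparison_mean: float, ndigits: int = 1) -> float:
    """Percent difference of a comparison group relative to a reference,
    ``100 * (comparison - reference) / reference``, rounded for
    reporting (one decimal by default)."""
    if reference_mean == 0:
        raise ValueError("zero reference mean")
    return round(100.0 * (comparison_mean - reference_mean) / reference_mean, ndigits)


def correlation_table(
    cohort: pd.DataFrame,
    clinical_cols: tuple[str, ...],
    value_cols: tuple[str, ...] | None = None,
    joint_col: str = "joint",
) -> pd.DataFrame:
    """Spearman rho of each joint parameter against each clinical
    covariate, per joint — the layout of a clinical-correlation matrix.

    One row per (joint, parameter, covariate) with rho, p and n;
    ankylotic joints excluded; pairs with missing values dropped.
    """
    df = cohort[~cohort.get("ankylotic", False).astype(bool)]
    if value_cols is None:
        value_cols = tuple(
            c for c in ("jsv_mm3", "jsw_mm", "jsw_min_mm", "jsw_max_mm", "jsw_as", "jsw_sd_mm")
            if c in df.columns
        )
    rows = []
    for joint, jdf in df.groupby(joint_col):
        for col in value_cols:
            for clin in clinical_cols:
                sub = jdf[[col, clin]].dropna()
                if len(sub) < 3:
                    continue
                res = spearman_corr(sub[col].to_numpy(), sub[clin].to_numpy())
                rows.append({
                    "joint": joint, "parameter": col, "covariate": clin,
                    "rho": res.statistic, "p_value": res.p_value, "n": len(sub),
                })
    return pd.DataFrame(rows)


def assemble_group_table(
    cohort: pd.DataFrame,
    grouping: str = "group",
    value_cols: tuple[str, ...] | None = None,
    joint_col: str = "joint",
    paired: bool = False,
) -> pd.DataFrame:
    """Per-joint, per-parameter group summary with routed p-values.

    For each joint and parameter: mean and SD per group plus the
    routed two-group p-value (only emitted when exactly two groups are
    present). Ankylotic joints are excluded. Layout: one row per
    (joint, parameter).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if grouping not in cohort.columns:
        raise ValueError(f"grouping column {grouping!r} absent")
    df = cohort[~cohort.get("ankylotic", False).astype(bool)]
    if value_cols is None:
        value_cols = tuple(
            c for c in ("jsv_mm3", "jsw_mm", "jsw_sd_mm", "jsw_min_mm", "jsw_max_mm", "jsw_as")
            if c in df.columns
        )
    groups = sorted(df[grouping].unique())
    rows = []
    for joint, jdf in df.groupby(joint_col):
        for col in value_cols:
            row: dict = {"joint": joint, "parameter": col}
            samples = []
            for g in groups:
                vals = jdf.loc[jdf[grouping] == g, col].dropna().to_numpy(dtype=float)
                row[f"{g}_mean"] = vals.mean() if vals.size else float("nan")
                row[f"{g}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
                row[f"{g}_n"] = vals.size
                samples.append(vals)
            if len(groups) == 2 and all(s.size >= 2 for s in samples):
                res = compare_groups(samples[0], samples[1], paired=paired)
                row["p_value"] = res.p_value
                row["test"] = res.test
            rows.append(row)
    return pd.DataFrame(rows)
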