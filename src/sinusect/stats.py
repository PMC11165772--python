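"""Cohort statistics: normality screening, sex comparisons, anterior vs
posterior aspect-ratio contrasts, left-right symmetry and post-hoc power.

The unit of analysis is the sinus (one record per subject side), with
subject-level aggregation available behind a flag. Sex comparisons are
two-sided pooled-variance t-tests by default (Welch behind a flag); no
multiple-testing correction is applied by default (Holm behind a flag).
Normality screening is a one-sample Kolmogorov-Smirnov test against a
normal with the sample's own mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatReport",
    "check_normality",
    "compare_sexes",
    "ap_contrast",
    "symmetry_contrast",
    "posthoc_power",
    "holm_adjust",
]

ALPHA = 0.05

ANTERIOR_FRACTIONS = (10, 20, 30, 40, 50)
POSTERIOR_FRACTIONS = (50, 60, 70, 80, 90)
MIRROR_PAIRS = ((10, 90), (20, 80), (30, 70), (40, 60))

#: interior fractions used for cohort statistics (endpoint sections are
#: degenerate by construction)
INTERIOR_FRACTIONS = tuple(range(10, 100, 10))


@dataclass
class StatReport:
    """One test's summary in the layout of a comparison-table row."""

    parameter: str
    group_names: tuple
    means: tuple
    sds: tuple
    ns: tuple
    test: str
    statistic: float
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "groups": list(self.group_names),
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "ns": [int(n) for n in self.ns],
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "significant": self.significant,
        }


def check_normality(
    groups: dict[str, np.ndarray],
    alpha: float = ALPHA,
    lilliefors: bool = False,
) -> dict:
    """One-sample KS test of each group against N(mean, sd).

    Parameters are estimated from the sample; by default no small-sample
    correction is applied (mirroring common statistical-package usage),
    which makes the screen conservative. ``lilliefors=True`` switches to
    the corrected null distribution (via statsmodels). Groups with
    p <= alpha are flagged non-normal.
    """
    out = {}
    for name, values in groups.items():
        x = np.asarray(values, float)
        if len(x) < 5:
            raise ValueError(f"group {name!r}: need n >= 5 for the KS screen")
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"group {name!r}: zero variance")
        if lilliefors:
            from statsmodels.stats.diagnostic import lilliefors as _lf

            stat, p = _lf(x, dist="norm")
        else:
            stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
        out[name] = {
            "statistic": float(stat),
            "p_value": float(p),
            "non_normal": bool(p <= alpha),
        }
    return out


def _per_sinus(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the tidy fraction-level table to one row per sinus."""
    return (
        table.drop_duplicates(["subject", "side"])[
            ["subject", "sex", "side", "length_mm"]
        ]
        .reset_index(drop=True)
    )


def _parameter_values(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Rows (subject, sex, side, value) for one parameter name.

    ``parameter`` is ``"length"`` or ``"<W|H|AR>_<fraction>"``.
    """
    if parameter == "length":
        df = _per_sinus(table).rename(columns={"length_mm": "value"})
        return df[["subject", "sex", "side", "value"]]
    name, _, frac = parameter.partition("_")
    col = {"W": "W_mm", "H": "H_mm", "AR": "AR"}.get(name)
    if col is None or not frac.isdigit():
        raise ValueError(
            f"unknown parameter {parameter!r}; use 'length' or e.g. 'W_40'"
        )
    sel = table[table["fraction"] == int(frac)]
    if sel.empty:
        raise ValueError(f"no rows at fraction {frac}% for {parameter!r}")
    out = sel[["subject", "sex", "side", col]].rename(columns={col: "value"})
    return out.reset_index(drop=True)


def compare_sexes(
    table: pd.DataFrame,
    parameter: str,
    welch: bool = False,
    subject_level: bool = False,
    alpha: float = ALPHA,
) -> StatReport:
    """Independent t-test of one parameter between the sexes."""
    values = _parameter_values(table, parameter)
    if subject_level:
        values = (
            values.groupby(["subject", "sex"], as_index=False)["value"].mean()
        )
    male = values.loc[values["sex"] == "male", "value"].to_numpy(float)
    female = values.loc[values["sex"] == "female", "value"].to_numpy(float)
    for name, grp in (("male", male), ("female", female)):
        if len(grp) == 0:
            raise ValueError(f"no {name} records in cohort table")
    if len(male) < 2 or len(female) < 2:
        stat = p = float("nan")
    else:
        stat, p = sps.ttest_ind(male, female, equal_var=not welch)
    return StatReport(
        parameter=parameter,
        group_names=("male", "female"),
        means=(male.mean(), female.mean()),
        sds=(
            male.std(ddof=1) if len(male) > 1 else float("nan"),
            female.std(ddof=1) if len(female) > 1 else float("nan"),
        ),
        ns=(len(male), len(female)),
        test="welch_t" if welch else "pooled_t",
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
    )


def compare_sexes_all(
    table: pd.DataFrame,
    welch: bool = False,
    alpha: float = ALPHA,
    fractions=None,
) -> pd.DataFrame:
    """Comparison-table layout: every parameter x fraction, plus length.

    ``fractions`` defaults to the interior fractions present in the table.
    """
    if fractions is None:
        fractions = sorted(
            f for f in table["fraction"].unique() if 0 < f < 100
        )
    params = ["length"] + [
        f"{name}_{fr}" for name in ("W", "H", "AR") for fr in fractions
    ]
    rows = []
    for param in params:
        r = compare_sexes(table, param, welch=welch, alpha=alpha)
        rows.append(
            {
                "parameter": param,
                "male_mean": r.means[0],
                "male_sd": r.sds[0],
                "female_mean": r.means[1],
                "female_sd": r.sds[1],
                "t": r.statistic,
                "p": r.p_value,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def _ar_wide(table: pd.DataFrame, fractions) -> pd.DataFrame:
    """One row per sinus, one AR column per requested fraction."""
    sel = table[table["fraction"].isin(fractions)]
    wide = sel.pivot_table(
        index=["subject", "side"], columns="fraction", values="AR"
    )
    missing = [f for f in fractions if f not in wide.columns]
    if missing or wide.isna().any().any():
        gaps = missing or sorted(
            wide.columns[wide.isna().any()].tolist()
        )
        raise ValueError(f"incomplete AR profiles; missing fractions: {gaps}")
    return wide


@dataclass
class APContrast:
    pair_tests: list[StatReport]
    anterior_mean: float
    posterior_mean: float
    percent_difference: float  # (1 - anterior/posterior) * 100
    anterior_vs_posterior: StatReport | None = None

    def to_dict(self) -> dict:
        return {
            "pair_tests": [r.to_dict() for r in self.pair_tests],
            "anterior_mean": self.anterior_mean,
            "posterior_mean": self.posterior_mean,
            "percent_difference": self.percent_difference,
            "anterior_vs_posterior": (
                None
                if self.anterior_vs_posterior is None
                else self.anterior_vs_posterior.to_dict()
            ),
        }


def ap_contrast(table: pd.DataFrame, alpha: float = ALPHA) -> APContrast:
    """Anterior vs posterior aspect-ratio contrasts.

    Paired t-tests for the mirrored fraction pairs (10 vs 90, 20 vs 80,
    30 vs 70, 40 vs 60) plus the anterior (10-50%) vs posterior (50-90%)
    per-sinus mean AR, with the percent difference
    ``(1 - anterior_mean / posterior_mean) * 100``.
    """
    fractions = sorted(set(ANTERIOR_FRACTIONS) | set(POSTERIOR_FRACTIONS))
    wide = _ar_wide(table, fractions)
    n = len(wide)
    pair_tests = []
    for fa, fb in MIRROR_PAIRS:
        a, b = wide[fa].to_numpy(), wide[fb].to_numpy()
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_rel(a, b)
        pair_tests.append(
            StatReport(
                parameter=f"AR_{fa}_vs_AR_{fb}",
                group_names=(f"AR_{fa}", f"AR_{fb}"),
                means=(a.mean(), b.mean()),
                sds=(a.std(ddof=1), b.std(ddof=1)),
                ns=(n, n),
                test="paired_t",
                statistic=float(stat),
                p_value=float(p),
                alpha=alpha,
            )
        )
    anterior = wide[list(ANTERIOR_FRACTIONS)].mean(axis=1).to_numpy()
    posterior = wide[list(POSTERIOR_FRACTIONS)].mean(axis=1).to_numpy()
    if np.allclose(anterior, posterior):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.ttest_rel(anterior, posterior)
    ant_mean, post_mean = float(anterior.mean()), float(posterior.mean())
    return APContrast(
        pair_tests=pair_tests,
        anterior_mean=ant_mean,
        posterior_mean=post_mean,
        percent_difference=(1.0 - ant_mean / post_mean) * 100.0,
        anterior_vs_posterior=StatReport(
            parameter="AR_anterior_vs_posterior",
            group_names=("anterior", "posterior"),
            means=(ant_mean, post_mean),
            sds=(anterior.std(ddof=1), posterior.std(ddof=1)),
            ns=(n, n),
            test="paired_t",
            statistic=float(stat),
            p_value=float(p),
            alpha=alpha,
        ),
    )


def symmetry_contrast(table: pd.DataFrame, alpha: float = ALPHA) -> StatReport:
    """Paired left-vs-right t-test on per-subject mean aspect ratio."""
    sel = table[table["fraction"].isin(INTERIOR_FRACTIONS)]
    per = sel.groupby(["subject", "side"])["AR"].mean().unstack("side")
    per = per.dropna(subset=["left", "right"], how="any")
    if len(per) < 2:
        raise ValueError("need >= 2 subjects with both sides")
    left, right = per["left"].to_numpy(), per["right"].to_numpy()
    if np.allclose(left, right):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.ttest_rel(left, right)
    return StatReport(
        parameter="AR_left_vs_right",
        group_names=("left", "right"),
        means=(left.mean(), right.mean()),
        sds=(left.std(ddof=1), right.std(ddof=1)),
        ns=(len(per), len(per)),
        test="paired_t",
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
    )


def posthoc_power(
    mean1: float,
    mean2: float,
    sd_pooled: float,
    n1: int,
    n2: int,
    alpha: float = ALPHA,
) -> float:
    """Post-hoc power of a two-sided two-sample pooled t-test.

    Exact noncentral-t computation: with effect size
    ``d = |mean1 - mean2| / sd_pooled`` the noncentrality is
    ``d * sqrt(n1 n2 / (n1 + n2))`` on ``n1 + n2 - 2`` df.
    """
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    d = abs(mean1 - mean2) / sd_pooled
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = 1.0 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc)
    return float(power)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def cohort_report(
    table: pd.DataFrame,
    welch: bool = False,
    holm: bool = False,
    alpha: float = ALPHA,
) -> dict:
    """Full cohort analysis as a JSON-serializable dict."""
    comparison = compare_sexes_all(table, welch=welch, alpha=alpha)
    if holm:
        comparison["p_holm"] = holm_adjust(comparison["p"].to_numpy())
        comparison["significant"] = comparison["p_holm"] < alpha
    normality = {}
    for param in ("length", "W_50", "H_50", "AR_50"):
        try:
            values = _parameter_values(table, param)
            groups = {
                sex: grp["value"].to_numpy()
                for sex, grp in values.groupby("sex")
            }
            normality[param] = check_normality(groups, alpha=alpha)
        except ValueError:
            continue
    report: dict = {
        "alpha": alpha,
        "normality": normality,
        "sex_comparison": comparison.to_dict(orient="records"),
    }
    try:
        report["ap_contrast"] = ap_contrast(table, alpha=alpha).to_dict()
    except ValueError as exc:  # e.g. non-default fraction step
        report["ap_contrast"] = {"error": str(exc)}
    try:
        report["symmetry"] = symmetry_contrast(table, alpha=alpha).to_dict()
    except ValueError as exc:
        report["symmetry"] = {"error": str(exc)}
    return report
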