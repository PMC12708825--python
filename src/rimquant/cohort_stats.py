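"""Cohort-level statistics for the fluorescence parameters.

Normally distributed parameters are summarized as mean ± SD and compared with
a one-way ANOVA (for two groups identical to the pooled two-sample t-test,
F = t²); skewed parameters as median [Q1, Q3] compared with a two-sided
Mann–Whitney U test (exact by enumeration for small untied samples, normal
approximation with tie and continuity correction otherwise).  Categorical
covariates are compared with Pearson's chi-square (no continuity correction),
the steatosis grades with a Kruskal–Wallis test, and tumor size against each
fluorescence parameter with Spearman's rank correlation.  Multiple linear
regression with an intercept regresses each of MSFI, MBFI, SBR and maximum
intensity on pretreatment, superficiality and tumor size; per-coefficient
two-sided t tests use n − 4 degrees of freedom.  No multiple-testing
correction is applied; significance threshold 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05

#: default test per fluorescence / covariate parameter, mirroring how each is
#: reported (mean ± SD → ANOVA, median [IQR] → Mann–Whitney)
DEFAULT_TEST_PER_PARAMETER: dict[str, str] = {
    "msfi_au": "mann_whitney_u",
    "mbfi_au": "mann_whitney_u",
    "sbr": "mann_whitney_u",
    "max_intensity_au": "anova",
    "size_cm": "anova",
    "age_years": "anova",
    "bmi": "anova",
}


@dataclass
class Summary:
    """Location/dispersion summary of one group."""

    n: int
    location: float          # mean or median
    dispersion: tuple        # (sd,) or (q1, q3)
    kind: str                # "normal" | "non_normal"

    def to_dict(self) -> dict:
        if self.kind == "normal":
            return {"n": self.n, "mean": self.location, "sd": self.dispersion[0]}
        return {
            "n": self.n,
            "median": self.location,
            "q1": self.dispersion[0],
            "q3": self.dispersion[1],
        }


@dataclass
class GroupComparison:
    parameter: str
    group_labels: list[str]
    summaries: list[Summary]
    test: str
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "groups": {
                label: s.to_dict() for label, s in zip(self.group_labels, self.summaries)
            },
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_display": format_p(self.p_value),
        }


@dataclass
class RegressionFit:
    dependent: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    n: int
    terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "n": self.n,
            "terms": {
                t: {
                    "coefficient": self.coefficients[t],
                    "se": self.standard_errors[t],
                    "p_value": self.p_values[t],
                    "p_display": format_p(self.p_values[t]),
                }
                for t in self.terms
            },
        }


def format_p(p: float) -> str:
    """Display-style p value: half-up to 3 decimals, '< 0.001' below that."""
    p = float(p)
    if math.isnan(p):
        return "NA"
    if p < 0.001:
        return "< 0.001"
    return str(Decimal(repr(p)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def summarize(values: Sequence[float], distribution: str = "normal") -> Summary:
    """Mean ± sample SD for normal data, median [Q1, Q3] (linear-interpolation
    quantiles) for non-normal data."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if distribution == "normal":
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return Summary(n=arr.size, location=float(arr.mean()), dispersion=(sd,), kind="normal")
    if distribution == "non_normal":
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        return Summary(
            n=arr.size, location=float(med), dispersion=(float(q1), float(q3)), kind="non_normal"
        )
    raise ValueError(f"unknown distribution {distribution!r}")


def anova_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """One-way two-group ANOVA from group summaries.

    Uses the pooled-variance identity F = t² with df = (1, n1 + n2 − 2),
    allowing validation directly against published mean ± SD tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        return math.inf, 0.0
    t = (mean1 - mean2) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    f = t * t
    p = float(stats.f.sf(f, 1, df))
    return f, p


def anova_two_group(
    values: Sequence[float], groups: Sequence, parameter: str = ""
) -> GroupComparison:
    """Two-group one-way ANOVA on raw data (equals the summary-based form)."""
    split = _split_two_groups(values, groups)
    (label1, g1), (label2, g2) = split
    s1 = summarize(g1, "normal")
    s2 = summarize(g2, "normal")
    f, p = anova_from_summary(
        s1.location, s1.dispersion[0], s1.n, s2.location, s2.dispersion[0], s2.n
    )
    return GroupComparison(
        parameter=parameter,
        group_labels=[label1, label2],
        summaries=[s1, s2],
        test="anova",
        statistic=f,
        p_value=p,
    )


def _split_two_groups(values, groups):
    arr = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    labels = pd.unique(grp)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    return [(str(lab), arr[grp == lab]) for lab in labels]


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by enumerating all group labelings."""
    n1, n = len(x), len(x) + len(y)
    combined = np.sort(np.concatenate([x, y]))
    # U statistic of the observed split (count of (x, y) pairs with x > y)
    u_obs = sum(1.0 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    u_min = min(u_obs, len(x) * len(y) - u_obs)
    count_le = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        in1 = np.zeros(n, dtype=bool)
        in1[list(idx)] = True
        a, b = combined[in1], combined[~in1]
        u = sum(1.0 for ai in a for bi in b if ai > bi)
        total += 1
        if min(u, len(a) * len(b) - u) <= u_min + 1e-12:
            count_le += 1
    return u_obs, min(1.0, count_le / total)


def mann_whitney_u(
    values: Sequence[float], groups: Sequence, parameter: str = ""
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    Exact null distribution by enumeration for n1 + n2 ≤ 12 without ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    split = _split_two_groups(values, groups)
    (label1, g1), (label2, g2) = split
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(g1), len(g2)
    combined = np.concatenate([g1, g2])
    has_ties = len(np.unique(combined)) < len(combined)
    if n1 + n2 <= 12 and not has_ties:
        u, p = _exact_mwu_p(g1, g2)
    else:
        ranks = stats.rankdata(combined)
        r1 = ranks[:n1].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts)
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
            z = max(z, 0.0)
            p = float(2 * stats.norm.sf(z))
        p = min(p, 1.0)
    return GroupComparison(
        parameter=parameter,
        group_labels=[label1, label2],
        summaries=[summarize(g1, "non_normal"), summarize(g2, "non_normal")],
        test="mann_whitney_u",
        statistic=float(u),
        p_value=float(p),
    )


def pearson_chi_square(table: Sequence[Sequence[int]], parameter: str = "") -> GroupComparison:
    """Pearson chi-square on a 2-way count table, no continuity correction.

    Zero-margin rows/columns are dropped with a warning before testing.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    row_keep = obs.sum(axis=1) > 0
    col_keep = obs.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.warning("dropping zero-margin rows/columns before chi-square test")
        obs = obs[row_keep][:, col_keep]
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    if dof == 0:
        chi2, p = 0.0, 1.0
    return GroupComparison(
        parameter=parameter,
        group_labels=[str(i) for i in range(obs.shape[0])],
        summaries=[],
        test="pearson_chi_square",
        statistic=float(chi2),
        p_value=float(p),
    )


def kruskal_wallis(
    values: Sequence[float], groups: Sequence, parameter: str = ""
) -> GroupComparison:
    """Kruskal–Wallis H test (tie-corrected, chi-square approximation)."""
    arr = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    pairs = [(lab, arr[grp == lab]) for lab in pd.unique(grp)]
    pairs = [(lab, s) for lab, s in pairs if len(s) > 0]
    labels = [lab for lab, _ in pairs]
    samples = [s for _, s in pairs]
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if all(np.array_equal(np.sort(s), np.sort(samples[0])) for s in samples) and all(
        len(np.unique(s)) == 1 for s in samples
    ):
        h, p = 0.0, 1.0  # all observations identical; scipy raises here
    else:
        h, p = stats.kruskal(*samples)
    return GroupComparison(
        parameter=parameter,
        group_labels=[str(lab) for lab in labels],
        summaries=[summarize(s, "non_normal") for s in samples],
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


REGRESSION_TERMS = ("intercept", "pretreatment", "superficiality", "size_cm")


def fit_ols(
    y: Sequence[float],
    covariates: pd.DataFrame | Mapping[str, Sequence],
    dependent: str = "",
) -> RegressionFit:
    """OLS of a fluorescence parameter on pretreatment (0/1), superficiality
    (0/1) and tumor size (cm), with intercept and per-coefficient t tests."""
    cov = pd.DataFrame(covariates)
    missing = [c for c in ("pretreatment", "superficiality", "size_cm") if c not in cov]
    if missing:
        raise ValueError(f"missing covariate column(s): {', '.join(missing)}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= 4:
        raise ValueError("need n > 4 observations for the 4-term model")
    X = np.column_stack(
        [
            np.ones(n),
            cov["pretreatment"].to_numpy(dtype=float),
            cov["superficiality"].to_numpy(dtype=float),
            cov["size_cm"].to_numpy(dtype=float),
        ]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        deficient = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear column(s): {', '.join(deficient)}")
    model = sm.OLS(y, X).fit()
    terms = list(REGRESSION_TERMS)
    return RegressionFit(
        dependent=dependent,
        coefficients=dict(zip(terms, model.params)),
        standard_errors=dict(zip(terms, model.bse)),
        p_values=dict(zip(terms, model.pvalues)),
        n=n,
        terms=terms,
    )


def _collinear_columns(X: np.ndarray) -> list[str]:
    names = list(REGRESSION_TERMS)
    bad = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or names[1:]


FLUORESCENCE_PARAMETERS = ("msfi_au", "mbfi_au", "sbr", "max_intensity_au")


def run_cohort_analyses(
    records: pd.DataFrame,
    test_per_parameter: Mapping[str, str] | None = None,
) -> dict:
    """Run the full cohort battery on a per-lesion record table.

    ``records`` needs columns ``msfi_au, mbfi_au, sbr, max_intensity_au,
    pretreated (bool), superficiality, steatosis_grade, size_cm`` and
    optionally ``recist``.  Produces per-parameter comparisons by
    pretreatment and by superficiality (test chosen per parameter), a
    Kruskal–Wallis of MBFI across steatosis grades, Spearman correlations of
    tumor size with each parameter, the four OLS fits, and — descriptively
    only, with no test — the stratification by radiological response.
    """
    config = dict(DEFAULT_TEST_PER_PARAMETER)
    if test_per_parameter:
        config.update(test_per_parameter)
    report: dict = {
        "n": int(len(records)),
        "group_comparisons": [],
        "steatosis_kruskal_wallis": None,
        "spearman_size": {},
        "regressions": {},
        "recist_descriptive": [],
        "skipped": [],
    }
    usable = records.dropna(subset=["msfi_au"])
    for stratum, column in (("pretreatment", "pretreated"), ("superficiality", "superficiality")):
        grp = usable[column].astype(str)
        if grp.nunique() != 2 or grp.value_counts().min() < 2:
            report["skipped"].append(f"{stratum}: needs two groups with n >= 2")
            logger.info("skipping %s comparison: degenerate grouping", stratum)
            continue
        for param in FLUORESCENCE_PARAMETERS:
            vals = usable[param]
            ok = vals.notna()
            test = config.get(param, "mann_whitney_u")
            try:
                if test == "anova":
                    cmp_ = anova_two_group(vals[ok], grp[ok], parameter=f"{param}|{stratum}")
                else:
                    cmp_ = mann_whitney_u(vals[ok], grp[ok], parameter=f"{param}|{stratum}")
            except ValueError as exc:
                report["skipped"].append(f"{param}|{stratum}: {exc}")
                continue
            report["group_comparisons"].append(cmp_.to_dict())
    # steatosis vs background fluorescence
    st_ok = usable["mbfi_au"].notna()
    grades = usable.loc[st_ok, "steatosis_grade"].astype(str)
    if grades.nunique() >= 2:
        kw = kruskal_wallis(
            usable.loc[st_ok, "mbfi_au"], grades, parameter="mbfi_au|steatosis"
        )
        report["steatosis_kruskal_wallis"] = kw.to_dict()
    else:
        report["skipped"].append("steatosis: fewer than 2 grades present")
    # size correlations
    for param in FLUORESCENCE_PARAMETERS:
        ok = usable[param].notna() & usable["size_cm"].notna()
        if ok.sum() >= 3:
            if usable.loc[ok, "size_cm"].nunique() < 2 or usable.loc[ok, param].nunique() < 2:
                report["skipped"].append(f"spearman:{param}: constant input")
                continue
            rho, p = spearman(usable.loc[ok, "size_cm"], usable.loc[ok, param])
            report["spearman_size"][param] = {
                "rho": rho,
                "p_value": p,
                "p_display": format_p(p),
                "n": int(ok.sum()),
            }
    # multiple linear regression per fluorescence parameter
    sup01 = (usable["superficiality"].astype(str) == "subcapsular").astype(float)
    cov = pd.DataFrame(
        {
            "pretreatment": usable["pretreated"].astype(float),
            "superficiality": sup01,
            "size_cm": usable["size_cm"].astype(float),
        }
    )
    for param in FLUORESCENCE_PARAMETERS:
        ok = usable[param].notna() & cov.notna().all(axis=1)
        if ok.sum() > 4:
            try:
                fit = fit_ols(usable.loc[ok, param], cov.loc[ok], dependent=param)
                report["regressions"][param] = fit.to_dict()
            except ValueError as exc:
                report["skipped"].append(f"ols:{param}: {exc}")
    # RECIST stratification: descriptive summaries only, no test
    if "recist" in usable.columns:
        for label, sub in usable.groupby(usable["recist"].astype(str)):
            row = {"response": label, "n": int(len(sub))}
            for param in FLUORESCENCE_PARAMETERS:
                vals = sub[param].dropna()
                if len(vals):
                    row[param] = summarize(vals, "non_normal").to_dict()
            report["recist_descriptive"].append(row)
    return report
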