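"""Dose-grouped statistics: ANOVA chain and log-dose regression.

For each feature measured over images grouped by drug concentration the
analysis runs the classical chain: Bartlett's test gates between the
standard one-way ANOVA and Welch's variance-weighted variant; Tukey's
honestly-significant-difference test assigns compact letter groups to the
dose means; and ordinary least squares fits linear and quadratic models
of the feature against x = log10(dose in ng/mL) with the untreated
control mapped to x = 0.

Model selection uses the incremental-variance rule: the quadratic model
is kept only when its R-squared gain exceeds 5% of the variance the
linear model leaves unexplained.  A fit is called *successful* when it
captures more than 90% of the between-group (dose) variance.  In a
balanced design the fitted coefficients from per-image values equal those
from the six group means, which is what lets the published group-mean
table stand in for raw data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DoseGroupedFeature",
    "AnovaResult",
    "TukeyGrouping",
    "DoseRegressionResult",
    "log_dose_x",
    "bartlett_gate",
    "oneway_anova",
    "welch_anova_stat",
    "tukey_hsd_letters",
    "fit_log_dose_regression",
    "fit_group_means",
    "variance_explained_ratio",
    "pearson_dose_correlation",
    "analyze_all_features",
    "load_reference_group_means",
]

ALPHA = 0.05


def log_dose_x(dose: float) -> float:
    """x = log10(dose ng/mL), with the 0-dose control mapped to x = 0."""
    return 0.0 if dose <= 0 else math.log10(dose)


@dataclass
class DoseGroupedFeature:
    """One feature's per-image values grouped by (strictly increasing) dose."""

    feature_name: str
    groups: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two dose groups")
        doses = [d for d, _ in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        self.groups = [(float(d), np.asarray(v, dtype=float)) for d, v in self.groups]

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for d, _ in self.groups])

    @property
    def x(self) -> np.ndarray:
        return np.array([log_dose_x(d) for d in self.doses])

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-image (x, y) pairs."""
        xs, ys = [], []
        for d, v in self.groups:
            xs.append(np.full(len(v), log_dose_x(d)))
            ys.append(v)
        return np.concatenate(xs), np.concatenate(ys)

    def group_means(self) -> np.ndarray:
        return np.array([v.mean() for _, v in self.groups])


@dataclass
class AnovaResult:
    r_squared: float  # percent of total variance between groups
    f_statistic: float
    p_value: float
    used_welch: bool
    bartlett_p: float


@dataclass
class TukeyGrouping:
    doses: list[float]
    letters: list[str]  # per-dose compact letter display
    not_different: np.ndarray  # boolean pairwise "no significant difference"


@dataclass
class DoseRegressionResult:
    feature_name: str
    linear_coef: tuple[float, float]  # (slope, intercept)
    linear_r2: float  # percent, total-variance scale
    quadratic_coef: tuple[float, float, float]  # (a, b, c)
    quadratic_r2: float
    selected_model: str  # "linear" | "quadratic"
    variance_explained: float  # percent of between-group variance, capped at 100
    successful: bool

    @property
    def equation(self) -> str:
        if self.selected_model == "quadratic":
            a, b, c = self.quadratic_coef
            return f"{a:+.4g}x^2 {b:+.4g}x {c:+.4g}"
        m, c = self.linear_coef
        return f"{m:+.4g}x {c:+.4g}"


def bartlett_gate(data: DoseGroupedFeature) -> tuple[float, bool]:
    """Bartlett's homoscedasticity test; homoscedastic iff p >= 0.05.

    A zero-variance group leaves the statistic undefined; the feature is
    then flagged heteroscedastic with a warning.
    """
    values = [v for _, v in data.groups]
    if any(len(v) < 2 for v in values):
        raise ValueError("each group needs >= 2 values for Bartlett's test")
    if any(np.var(v) == 0 for v in values):
        logger.warning(
            "%s: zero-variance group, Bartlett statistic undefined; "
            "treating as heteroscedastic",
            data.feature_name,
        )
        return math.nan, False
    stat, p = stats.bartlett(*values)
    return float(p), bool(p >= ALPHA)


def _sums_of_squares(data: DoseGroupedFeature) -> tuple[float, float, float]:
    _, y = data.flat()
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss_between = float(
        sum(len(v) * (v.mean() - grand) ** 2 for _, v in data.groups)
    )
    ss_within = ss_total - ss_between
    return ss_total, ss_between, ss_within


def welch_anova_stat(values: list[np.ndarray]) -> tuple[float, float]:
    """Welch's variance-weighted one-way ANOVA (F*, p)."""
    k = len(values)
    n = np.array([len(v) for v in values], dtype=float)
    m = np.array([v.mean() for v in values])
    s2 = np.array([v.var(ddof=1) for v in values])
    w = n / s2
    sw = w.sum()
    mw = np.sum(w * m) / sw
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = 3.0 * np.sum((1 - w / sw) ** 2 / (n - 1)) / (k**2 - 1)
    f = a / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df1 = k - 1
    df2 = 1.0 / lam
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def oneway_anova(data: DoseGroupedFeature, use_welch: bool) -> AnovaResult:
    """One-way ANOVA with R^2 = 100 * SS_between / SS_total.

    The R^2 (percent of total variation lying between dose groups) is the
    same decomposition in both variants; F and p come from the standard
    or the Welch formulas as gated by Bartlett's test.
    """
    values = [v for _, v in data.groups]
    ss_total, ss_between, ss_within = _sums_of_squares(data)
    r2 = 100.0 * ss_between / ss_total if ss_total > 0 else 0.0
    if use_welch:
        f, p = welch_anova_stat(values)
    else:
        f, p = stats.f_oneway(*values)
    return AnovaResult(r2, float(f), float(p), use_welch, math.nan)


def _tukey_not_different(data: DoseGroupedFeature, alpha: float = ALPHA) -> np.ndarray:
    """Pairwise Tukey HSD decisions (True = means not significantly different)."""
    values = [v for _, v in data.groups]
    res = stats.tukey_hsd(*values)
    k = len(values)
    nd = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i != j:
                nd[i, j] = res.pvalue[i, j] >= alpha
    return nd


def compact_letter_display(not_different: np.ndarray, order: np.ndarray) -> list[str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Groups are processed in ``order`` (typically by descending mean); two
    groups share a letter iff they are not significantly different, and
    the display is consistent with the pairwise decision matrix.
    """
    k = not_different.shape[0]
    # Each letter is a set of group indices, all mutually not-different.
    letters: list[set[int]] = []
    for g in order:
        placed = False
        for s in letters:
            if all(not_different[g, h] for h in s):
                s.add(int(g))
                placed = True
        if not placed:
            # new letter: g plus every earlier group compatible with it
            letters.append({int(g)})
    # absorb: drop letter sets fully contained in another
    changed = True
    while changed:
        changed = False
        for i, s in enumerate(letters):
            if any(i != j and s < t for j, t in enumerate(letters)):
                letters.pop(i)
                changed = True
                break
    # ensure every not-different pair shares some letter
    for i in range(k):
        for j in range(i + 1, k):
            if not_different[i, j] and not any(i in s and j in s for s in letters):
                merged = {i, j}
                for h in range(k):
                    if h not in merged and all(not_different[h, g] for g in merged):
                        merged.add(h)
                letters.append(merged)
    letters.sort(key=lambda s: min(s))
    out = []
    for g in range(k):
        out.append("".join(chr(ord("A") + i) for i, s in enumerate(letters) if g in s))
    return out


def tukey_hsd_letters(data: DoseGroupedFeature) -> TukeyGrouping:
    """All-pairs Tukey HSD at alpha = 0.05 with compact letter groups."""
    nd = _tukey_not_different(data)
    means = data.group_means()
    order = np.argsort(-means)
    letters = compact_letter_display(nd, order)
    return TukeyGrouping(list(data.doses), letters, nd)


# ---------------------------------------------------------------------------
# regression on log dose


def _model_ss_between(x_groups, means, counts, coeffs) -> float:
    """Between-group SS captured by a polynomial fit, at the group x's."""
    yhat = np.polyval(coeffs, x_groups)
    total = np.sum(counts * means) / np.sum(counts)
    ss_b = float(np.sum(counts * (means - total) ** 2))
    ss_resid = float(np.sum(counts * (means - yhat) ** 2))
    return max(ss_b - ss_resid, 0.0), ss_b


def fit_log_dose_regression(
    data: DoseGroupedFeature, success_threshold: float = 90.0
) -> DoseRegressionResult:
    """OLS linear and quadratic fits on x = log10(dose); pick per the 5% rule.

    R^2 values are on the total-variance scale (model SS over total SS of
    the per-image values).  The quadratic model is selected when its R^2
    gain over the linear model exceeds 5% of the linear model's
    unexplained variance; with fewer than three distinct x values the
    quadratic fit is skipped.  ``variance_explained`` is the share of
    between-group variance captured by the selected model, capped at 100
    for reporting.
    """
    x, y = data.flat()
    ss_total = float(np.sum((y - y.mean()) ** 2))
    counts = np.array([len(v) for _, v in data.groups], dtype=float)
    means = data.group_means()
    xg = data.x

    lin = np.polyfit(x, y, 1)
    ss_lin, ss_b = _model_ss_between(xg, means, counts, lin)
    r2_lin = 100.0 * ss_lin / ss_total if ss_total > 0 else 0.0

    if len(np.unique(x)) >= 3:
        quad = np.polyfit(x, y, 2)
        ss_quad, _ = _model_ss_between(xg, means, counts, quad)
        r2_quad = 100.0 * ss_quad / ss_total if ss_total > 0 else 0.0
        select_quad = (r2_quad - r2_lin) > 0.05 * (100.0 - r2_lin)
    else:
        quad = np.array([0.0, *lin])
        r2_quad = r2_lin
        select_quad = False

    selected = "quadratic" if select_quad else "linear"
    ss_model = ss_quad if select_quad else ss_lin
    if ss_b > 0:
        ve_raw = 100.0 * ss_model / ss_b
    else:
        logger.warning("%s: zero between-group variance", data.feature_name)
        ve_raw = math.nan
    if ve_raw == ve_raw and ve_raw > 100.0:
        logger.debug("%s: raw variance-explained %.3f capped at 100", data.feature_name, ve_raw)
    ve = min(ve_raw, 100.0) if ve_raw == ve_raw else math.nan

    return DoseRegressionResult(
        feature_name=data.feature_name,
        linear_coef=(float(lin[0]), float(lin[1])),
        linear_r2=r2_lin,
        quadratic_coef=tuple(float(c) for c in quad),
        quadratic_r2=r2_quad,
        selected_model=selected,
        variance_explained=ve,
        successful=bool(ve == ve and ve > success_threshold),
    )


def fit_group_means(
    doses: np.ndarray,
    means: np.ndarray,
    anova_r2: float | None = None,
    feature_name: str = "",
    success_threshold: float = 90.0,
) -> DoseRegressionResult:
    """Log-dose regression from published group means (balanced design).

    With equal group sizes the OLS coefficients from group means equal
    those from per-image values.  The between-group variance share of
    each model is computed from the means alone; when the feature's ANOVA
    R^2 (percent of *total* variance between groups) is supplied, the
    model R^2 values are rescaled to the total-variance scale so the 5%
    selection rule is applied exactly as with raw data.
    """
    doses = np.asarray(doses, dtype=float)
    means = np.asarray(means, dtype=float)
    x = np.array([log_dose_x(d) for d in doses])
    ss_b = float(np.sum((means - means.mean()) ** 2))

    lin = np.polyfit(x, means, 1)
    quad = np.polyfit(x, means, 2)
    ratio_lin = 1.0 - float(np.sum((means - np.polyval(lin, x)) ** 2)) / ss_b
    ratio_quad = 1.0 - float(np.sum((means - np.polyval(quad, x)) ** 2)) / ss_b

    scale = anova_r2 if anova_r2 is not None else 100.0
    r2_lin = ratio_lin * scale
    r2_quad = ratio_quad * scale
    select_quad = (r2_quad - r2_lin) > 0.05 * (100.0 - r2_lin)
    ve = 100.0 * (ratio_quad if select_quad else ratio_lin)
    ve = min(ve, 100.0)
    return DoseRegressionResult(
        feature_name=feature_name,
        linear_coef=(float(lin[0]), float(lin[1])),
        linear_r2=r2_lin,
        quadratic_coef=tuple(float(c) for c in quad),
        quadratic_r2=r2_quad,
        selected_model="quadratic" if select_quad else "linear",
        variance_explained=ve,
        successful=bool(ve > success_threshold),
    )


def variance_explained_ratio(fit: DoseRegressionResult, data: DoseGroupedFeature) -> float:
    """Percent of between-group SS captured by the selected model's fit."""
    counts = np.array([len(v) for _, v in data.groups], dtype=float)
    means = data.group_means()
    coeffs = (
        np.array(fit.quadratic_coef)
        if fit.selected_model == "quadratic"
        else np.array([*fit.linear_coef])
    )
    ss_model, ss_b = _model_ss_between(data.x, means, counts, coeffs)
    if ss_b == 0:
        return math.nan
    return 100.0 * ss_model / ss_b


def pearson_dose_correlation(data: DoseGroupedFeature) -> float:
    """Pearson r between per-image feature values and log dose (NaN if degenerate)."""
    x, y = data.flat()
    if len(y) < 3:
        raise ValueError("need at least 3 images")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# whole-table report


@dataclass
class FeatureReport:
    anova: AnovaResult
    tukey: TukeyGrouping
    regression: DoseRegressionResult
    shapiro_p: list[float] = field(default_factory=list)
    pearson_r: float = math.nan


def _grouped(table: pd.DataFrame, feature: str, dose_column: str) -> DoseGroupedFeature:
    groups = [
        (dose, sub[feature].to_numpy(dtype=float))
        for dose, sub in table.groupby(dose_column, sort=True)
    ]
    return DoseGroupedFeature(feature, groups)


def analyze_all_features(
    table: pd.DataFrame, dose_column: str = "dose_ng_per_ml"
) -> dict[str, FeatureReport]:
    """Bartlett gate -> ANOVA variant -> Tukey HSD -> log-dose regression.

    Runs the full chain for every numeric feature column of ``table``.
    Shapiro-Wilk normality p-values are reported per group but do not
    gate anything; only Bartlett's test selects the ANOVA variant.
    """
    out: dict[str, FeatureReport] = {}
    features = [
        c for c in table.columns if c != dose_column and pd.api.types.is_numeric_dtype(table[c])
    ]
    for feat in features:
        data = _grouped(table.dropna(subset=[feat]), feat, dose_column)
        bart_p, homo = bartlett_gate(data)
        anova = oneway_anova(data, use_welch=not homo)
        anova.bartlett_p = bart_p
        tukey = tukey_hsd_letters(data)
        reg = fit_log_dose_regression(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro = [
                float(stats.shapiro(v).pvalue) if len(v) >= 3 and np.std(v) > 0 else math.nan
                for _, v in data.groups
            ]
        out[feat] = FeatureReport(
            anova=anova,
            tukey=tukey,
            regression=reg,
            shapiro_p=shapiro,
            pearson_r=pearson_dose_correlation(data),
        )
    return out


def reports_to_frames(
    reports: dict[str, FeatureReport]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble (anova_report, regression_report) tables from per-feature reports."""
    anova_rows, reg_rows = [], []
    for feat, rep in reports.items():
        row = {
            "feature": feat,
            "anova_r2": rep.anova.r_squared,
            "f_statistic": rep.anova.f_statistic,
            "p_value": rep.anova.p_value,
            "used_welch": rep.anova.used_welch,
            "bartlett_p": rep.anova.bartlett_p,
            "pearson_r": rep.pearson_r,
        }
        for dose, letter in zip(rep.tukey.doses, rep.tukey.letters):
            row[f"letters_{dose:g}"] = letter
        anova_rows.append(row)
        reg = rep.regression
        reg_rows.append(
            {
                "feature": feat,
                "anova_r2": rep.anova.r_squared,
                "linear_r2": reg.linear_r2,
                "quadratic_r2": reg.quadratic_r2,
                "selected_model": reg.selected_model,
                "variance_explained": reg.variance_explained,
                "successful": reg.successful,
                "equation": reg.equation,
            }
        )
    return pd.DataFrame(anova_rows), pd.DataFrame(reg_rows)


def load_reference_group_means() -> pd.DataFrame:
    """Published six-dose group means of the 13 neuromorphology features.

    Columns: feature, anova_r2, then one column per dose (ng/mL); values
    are in pixels/counts with each row's print scale factor applied.
    """
    with resources.files("hcsneurons.data").joinpath("reference_group_means.csv").open() as fh:
        return read_annotated_csv(fh)


def read_annotated_csv(fh_or_path) -> pd.DataFrame:
    """Read a CSV whose leading lines may be '#' provenance comments.

    Feature names legitimately contain '#' (e.g. branchPoint#), so only
    *leading* comment lines are stripped, never in-row characters.
    """
    import io

    if hasattr(fh_or_path, "read"):
        text = fh_or_path.read()
    else:
        text = Path(fh_or_path).read_text()
    lines = text.splitlines()
    start = 0
    while start < len(lines) and lines[start].lstrip().startswith("#"):
        start += 1
    return pd.read_csv(io.StringIO("\n".join(lines[start:])))
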