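"""Method-agreement statistics over per-eye exposure-rate tables.

Implements the validation battery used to compare an automated
measurement method against a manual reference: paired t-tests, one-way
and two-way ANOVA, single-measure intraclass correlation coefficients
with 95% confidence intervals (McGraw & Wong mean-square forms, matching
SPSS), Bland-Altman bias and limits of agreement, and severity-stratified
improvement rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

SEVERITIES = ("mild", "moderate_severe")
METHODS = ("ai1", "ai2", "manual")
PHASES = ("pre", "post")
REQUIRED_COLUMNS = ("patient_id", "eye", "severity", "method", "phase", "eer")

#: Agreement interpretation bands for a single-measure ICC.
ICC_BANDS = ((0.8, "excellent"), (0.6, "substantial"), (0.41, "moderate"), (-1.0, "poor"))

_HEADER_SYNONYMS = {
    "patient": "patient_id",
    "patient_id": "patient_id",
    "id": "patient_id",
    "subject": "patient_id",
    "eye": "eye",
    "side": "eye",
    "severity": "severity",
    "group": "severity",
    "method": "method",
    "phase": "phase",
    "time": "phase",
    "eer": "eer",
    "value": "eer",
    "eer_percent": "eer",
}


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format measurement table; returns a clean copy."""
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_")
        if key in _HEADER_SYNONYMS:
            mapping[col] = _HEADER_SYNONYMS[key]
    df = df.rename(columns=mapping)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    if len(df) == 0:
        raise ValidationError("measurement table is empty")
    eer = pd.to_numeric(df["eer"], errors="coerce")
    bad = df.index[eer.isna()].tolist()
    if bad:
        raise ValidationError(f"non-numeric eer values at rows {bad}")
    df["eer"] = eer.astype(float)
    out_of_range = df.index[(df["eer"] < 0) | (df["eer"] > 100)].tolist()
    if out_of_range:
        raise ValidationError(f"eer outside [0, 100] at rows {out_of_range}")
    key = ["patient_id", "eye", "method", "phase"]
    dup = df.index[df.duplicated(subset=key, keep=False)].tolist()
    if dup:
        raise ValidationError(f"duplicate (patient, eye, method, phase) keys at rows {dup}")
    return df.reset_index(drop=True)


def read_table(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a CSV or XLSX measurement table and validate it."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        raw = pd.read_csv(path)
    elif fmt == "xlsx":
        raw = pd.read_excel(path)
    else:
        raise ValidationError(f"unknown table format {fmt!r}")
    return validate_table(raw)


def paired_t(before, after) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired_t needs two equal-length vectors of length >= 2")
    d = b - a
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    p: float
    model: str
    interpretation: str

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci95": [self.ci_low, self.ci_high],
            "p": self.p,
            "model": self.model,
            "interpretation": self.interpretation,
        }


def _interpret_icc(value: float) -> str:
    for lo, name in ICC_BANDS:
        if value >= lo:
            return name
    return "poor"


def icc(values, model: str = "twoway_random_agreement", conf: float = 0.95) -> IccResult:
    """Single-measure intraclass correlation from the mean-square decomposition.

    ``values`` is an (n subjects x k raters) matrix with no missing cells.
    Models: "oneway_random" (ICC(1,1)), "twoway_random_agreement"
    (ICC(A,1), the standard method-agreement choice), and
    "twoway_mixed_consistency" (ICC(C,1)).  Confidence bounds follow the
    F-distribution formulas of McGraw & Wong.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("icc needs an (n >= 2) x (k >= 2) matrix")
    if np.isnan(x).any():
        raise ValidationError("icc does not accept missing cells")
    n, k = x.shape
    alpha = 1.0 - conf
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    msw = np.sum((x - row_m[:, None]) ** 2) / (n * (k - 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "oneway_random":
            value = (msr - msw) / (msr + (k - 1) * msw)
            f_obs = msr / msw
            df2 = n * (k - 1)
            p = float(sps.f.sf(f_obs, n - 1, df2))
            fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, n - 1)
            lo = (fl - 1) / (fl + (k - 1))
            hi = (fu - 1) / (fu + (k - 1))
        elif model == "twoway_mixed_consistency":
            value = (msr - mse) / (msr + (k - 1) * mse)
            f_obs = msr / mse
            df2 = (n - 1) * (k - 1)
            p = float(sps.f.sf(f_obs, n - 1, df2))
            fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, n - 1)
            lo = (fl - 1) / (fl + (k - 1))
            hi = (fu - 1) / (fu + (k - 1))
        elif model == "twoway_random_agreement":
            value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            f_obs = msr / mse
            df2 = (n - 1) * (k - 1)
            p = float(sps.f.sf(f_obs, n - 1, df2))
            if mse == 0 and msc == 0:
                lo = hi = 1.0  # degenerate: columns identical
            else:
                fj = msc / mse if mse > 0 else np.inf
                vn = df2 * (k * value * fj + n * (1 + (k - 1) * value) - k * value) ** 2
                vd = (n - 1) * k**2 * value**2 * fj**2 + (
                    n * (1 + (k - 1) * value) - k * value
                ) ** 2
                v = vn / vd
                f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
        else:
            raise ValidationError(f"unknown ICC model {model!r}")

    value = float(value)
    if np.isnan(value):
        raise ValidationError("ICC undefined: no between-subject variance")
    lo = float(min(max(lo, -1.0), 1.0)) if np.isfinite(lo) else -1.0
    hi = float(min(max(hi, -1.0), 1.0)) if np.isfinite(hi) else 1.0
    if np.isnan(p):
        p = 0.0 if value == 1.0 else 1.0
    return IccResult(value, lo, hi, p, model, _interpret_icc(value))


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray

    def to_dict(self) -> dict:
        return {"bias": self.bias, "loa_low": self.loa_low, "loa_high": self.loa_high}

    def plot_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.means,
                "difference": self.diffs,
                "bias": self.bias,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
            }
        )


def bland_altman(a, b) -> BlandAltman:
    """Bias and 95% limits of agreement for paired measurements (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("bland_altman needs two equal-length vectors of length >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, (a + b) / 2.0, d)


def improvement_rate(pre_mean: float, post_mean: float) -> float:
    """Percent change of the group mean, 100 (post - pre) / pre, 2 decimals."""
    if pre_mean <= 0:
        raise ValidationError("pre_mean must be > 0")
    return round(100.0 * (post_mean - pre_mean) / pre_mean, 2)


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("anova_oneway needs >= 2 groups of >= 2 values")
    k = len(groups)
    n = sum(len(g) for g in groups)
    allvals = np.concatenate(groups)
    if np.all(allvals == allvals[0]):
        return 0.0, k - 1, n - k, 1.0
    res = sps.f_oneway(*groups)
    return float(res.statistic), k - 1, n - k, float(res.pvalue)


def anova_twoway(table: pd.DataFrame, method: str = "ai1") -> pd.DataFrame:
    """Fixed-effects severity x phase ANOVA (type-II SS) on EER.

    Returns a tidy frame with one row per effect (severity, phase,
    interaction, residual) carrying sum_sq, df, F and p.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = validate_table(table)
    df = df[df["method"] == method]
    if df.empty:
        raise ValidationError(f"no rows for method {method!r}")
    for col, levels in (("severity", None), ("phase", None)):
        if df[col].nunique() < 2:
            raise ValidationError(f"factor {col!r} needs at least two levels")
    if df["eer"].std() == 0:
        # all-identical response: every effect is exactly null
        cells = df.groupby(["severity", "phase"]).size()
        out = pd.DataFrame(
            {
                "effect": ["severity", "phase", "severity:phase", "residual"],
                "sum_sq": 0.0,
                "df": [
                    df["severity"].nunique() - 1,
                    df["phase"].nunique() - 1,
                    (df["severity"].nunique() - 1) * (df["phase"].nunique() - 1),
                    len(df) - cells.size,
                ],
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            }
        )
        return out
    model = smf.ols("eer ~ C(severity) * C(phase)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(severity)": "severity",
        "C(phase)": "phase",
        "C(severity):C(phase)": "severity:phase",
        "Residual": "residual",
    }
    aov = aov.rename(index=rename).reset_index(names="effect")
    aov = aov.rename(columns={"PR(>F)": "p"})
    return aov[["effect", "sum_sq", "df", "F", "p"]]


def format_p(p: float) -> str:
    """p-value formatting convention: three decimals, '< .001' floor."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "< .001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.000"


@dataclass
class AgreementReport:
    """All statistics of the validation battery, assembled from one table."""

    phase_summary: pd.DataFrame  # method x phase means/sds + paired t
    method_summary: pd.DataFrame  # per-method pooled means/sds
    oneway: dict
    iccs: dict[str, dict]
    bland_altman: dict[str, BlandAltman]
    severity_summary: pd.DataFrame  # severity-stratified means + improvement
    twoway: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "phase_summary": self.phase_summary.to_dict(orient="records"),
            "method_summary": self.method_summary.to_dict(orient="records"),
            "oneway_anova": self.oneway,
            "icc": self.iccs,
            "bland_altman": {k: v.to_dict() for k, v in self.bland_altman.items()},
            "severity_summary": self.severity_summary.to_dict(orient="records"),
            "twoway_anova": self.twoway.to_dict(orient="records"),
            "warnings": self.warnings,
        }


def _paired_wide(df: pd.DataFrame, phase: str | None = None) -> pd.DataFrame:
    sub = df if phase is None else df[df["phase"] == phase]
    wide = sub.pivot_table(
        index=["patient_id", "eye"] + ([] if phase else ["phase"]),
        columns="method",
        values="eer",
    )
    return wide.dropna(axis=0, how="any")

def build_report(table: pd.DataFrame, icc_model: str = "twoway_random_agreement") -> AgreementReport:
    """Assemble the full agreement report from a validated table."""
    df = validate_table(table)
    methods = [m for m in METHODS if m in set(df["method"])]
    if not set(df["phase"]) >= {"pre", "post"}:
        raise ValidationError("table must contain both pre and post phases")

    # Per-phase summary with pre-vs-post paired t per method.
    rows = []
    for m in methods:
        sub = df[df["method"] == m]
        wide = sub.pivot_table(index=["patient_id", "eye"], columns="phase", values="eer")
        wide = wide.dropna(axis=0, how="any")
        if len(wide) < 2:
            raise ValidationError(f"method {m!r} needs pre and post for >= 2 eyes")
        t, dof, p = paired_t(wide["pre"], wide["post"])
        rows.append(
            {
                "method": m,
                "pre_mean": wide["pre"].mean(),
                "pre_sd": wide["pre"].std(ddof=1),
                "post_mean": wide["post"].mean(),
                "post_sd": wide["post"].std(ddof=1),
                "t": t,
                "df": dof,
                "p": p,
                "p_label": format_p(p),
            }
        )
    phase_summary = pd.DataFrame(rows)

    # Pooled per-method summary + one-way ANOVA across methods.
    pooled = [df.loc[df["method"] == m, "eer"].to_numpy() for m in methods]
    method_summary = pd.DataFrame(
        {
            "method": methods,
            "mean": [g.mean() for g in pooled],
            "sd": [g.std(ddof=1) for g in pooled],
        }
    )
    oneway = {}
    if len(methods) >= 2:
        F, dfb, dfw, p = anova_oneway(pooled)
        oneway = {"F": F, "df_between": dfb, "df_within": dfw, "p": p, "p_label": format_p(p)}

    # ICC and Bland-Altman per method pair.
    iccs: dict[str, dict] = {}
    ba: dict[str, BlandAltman] = {}
    pairs = [p for p in (("ai1", "ai2"), ("ai1", "manual")) if set(p) <= set(methods)]
    for m1, m2 in pairs:
        key = f"{m1}_vs_{m2}"
        for phase in PHASES:
            wide = _paired_wide(df[df["method"].isin([m1, m2])], phase)
            if len(wide) >= 2:
                res = icc(wide[[m1, m2]].to_numpy(), model=icc_model)
                iccs[f"{key}_{phase}"] = res.to_dict()
        wide_all = _paired_wide(df[df["method"].isin([m1, m2])])
        ba[key] = bland_altman(wide_all[m1].to_numpy(), wide_all[m2].to_numpy())

    # Severity-stratified pre/post means and improvement rates (first
    # automated measurement, as in the reference analysis).
    base = methods[0]
    sev_rows = []
    sub = df[df["method"] == base]
    groups = [("all", sub)] + [(s, sub[sub["severity"] == s]) for s in sorted(set(sub["severity"]))]
    for name, g in groups:
        if g.empty:
            continue
        pre = g.loc[g["phase"] == "pre", "eer"]
        post = g.loc[g["phase"] == "post", "eer"]
        sev_rows.append(
            {
                "group": name,
                "n_eyes": int(len(pre)),
                "pre_mean": pre.mean(),
                "pre_sd": pre.std(ddof=1),
                "post_mean": post.mean(),
                "post_sd": post.std(ddof=1),
                "improvement_rate": improvement_rate(pre.mean(), post.mean()),
            }
        )
    severity_summary = pd.DataFrame(sev_rows)
    warnings: list[str] = []
    try:
        twoway = anova_twoway(df, method=base)
    except ValidationError as e:
        twoway = pd.DataFrame(columns=["effect", "sum_sq", "df", "F", "p"])
        warnings.append(f"two-way ANOVA unavailable: {e}")

    return AgreementReport(
        phase_summary=phase_summary,
        method_summary=method_summary,
        oneway=oneway,
        iccs=iccs,
        bland_altman=ba,
        severity_summary=severity_summary,
        twoway=twoway,
        warnings=warnings,
    )


def reproduce_s1_checks(path) -> dict:
    """Recompute the published cohort statistics from the deposited table.

    ``path`` must point at the deposited per-eye EER workbook (or an
    equivalently shaped CSV).  Returns the recomputed means/SDs per
    method and phase, the AI-vs-manual ICC per phase, and the
    AI-vs-manual Bland-Altman limits, for comparison against the
    published values.
    """
    df = read_table(path)
    report = build_report(df)
    out = {"phase_summary": report.phase_summary.to_dict(orient="records")}
    out["icc"] = report.iccs
    out["bland_altman"] = {k: v.to_dict() for k, v in report.bland_altman.items()}
    return out
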