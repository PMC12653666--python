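"""Method-agreement and validity statistics for pendulum parameters.

The statistical battery mirrors standard method-comparison practice for
validating a new measurement device (pose estimation) against a
reference (electronic goniometer):

* Bland–Altman bias and 95% limits of agreement, with a proportional-
  bias regression of the pairwise difference on the pairwise mean.
* Intraclass correlation, two-way random-effects single-rater model of
  the consistency type: ICC = (MSR − MSE) / (MSR + (k−1)·MSE), with
  F-distribution confidence bounds.
* Paired t-test between affected and unaffected limbs with paired
  Cohen's d.
* Spearman rank correlation between pendulum parameters and Modified
  Ashworth Scale scores (midrank ties; MAS is heavily tied), preceded
  by Tukey interquartile-range outlier screening.
* Shapiro–Wilk normality gate on method differences; a failed gate
  annotates downstream parametric results, it never blocks them.

No multiple-testing correction is applied; α = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PARAMETERS = ("P1", "P2", "P3")


@dataclass
class PairedMeasurements:
    """Trial-aligned values from two methods (x = reference, y = test)."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple = ()
    stratum: str = "overall"
    parameter: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be aligned one-dimensional arrays")
        if len(self.x) < 3:
            raise ValueError("need at least 3 pairs")


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    prop_bias_slope: float
    prop_bias_r2: float
    prop_bias_p: float
    n: int
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model_tag: str
    n_subjects: int
    n_raters: int
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class PairedComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    t_stat: float
    p_value: float
    d_paired: float
    n: int
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_used: int
    n_removed: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def bland_altman(pm: PairedMeasurements) -> BlandAltmanResult:
    """Bias, 95% limits of agreement, and proportional-bias regression.

    The limits of agreement are bias ± 1.96·SD of the pairwise
    differences.  Proportional bias is tested by ordinary least squares
    of the difference (y − x) on the pairwise mean (x + y)/2.
    """
    diff = pm.y - pm.x
    mean = 0.5 * (pm.x + pm.y)
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    flags: list[str] = []
    if sd == 0:
        flags.append("zero_variance_differences")
        slope, r2, p = 0.0, float("nan"), float("nan")
    elif np.std(mean) == 0:
        flags.append("constant_means_regression_undefined")
        slope, r2, p = float("nan"), float("nan"), float("nan")
    else:
        fit = stats.linregress(mean, diff)
        slope, r2, p = float(fit.slope), float(fit.rvalue**2), float(fit.pvalue)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        prop_bias_slope=slope,
        prop_bias_r2=r2,
        prop_bias_p=p,
        n=len(diff),
        flags=tuple(flags),
    )


def _two_way_anova(values: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, error) of a complete two-way layout."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_consistency(
    values: np.ndarray,
    alpha: float = 0.05,
    form: str = "consistency",
) -> ICCResult:
    """Single-rater intraclass correlation from a subjects × raters matrix.

    The default ``consistency`` form ignores systematic rater offsets:
    ICC = (MSR − MSE) / (MSR + (k−1)·MSE), with the 95% confidence
    interval from F-distribution bounds on MSR/MSE.  The
    ``absolute`` form additionally penalizes rater mean differences
    (point estimate only; no closed-form CI is reported for it).

    A complete-case matrix is required; negative estimates (MSR < MSE)
    are reported as-is with a flag, never clamped.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a subjects x raters matrix")
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing/non-finite cells; a complete-case matrix is required")
    msr, msc, mse = _two_way_anova(values)
    flags: list[str] = []
    if form == "consistency":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else float("nan")
        if mse == 0:
            # Perfectly consistent columns: F-bounds degenerate.
            icc, ci_low, ci_high = 1.0, 1.0, 1.0
            flags.append("zero_residual_variance")
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
            f_lower_q = stats.f.ppf(1 - alpha / 2, df2, df1)
            fl = f_obs / f_upper
            fu = f_obs * f_lower_q
            ci_low = (fl - 1) / (fl + k - 1)
            ci_high = (fu - 1) / (fu + k - 1)
        tag = "two-way random, single rater, consistency"
    elif form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom if denom > 0 else float("nan")
        ci_low, ci_high = float("nan"), float("nan")
        flags.append("ci_unavailable_for_absolute_form")
        tag = "two-way random, single rater, absolute agreement"
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if np.isfinite(icc) and icc < 0:
        flags.append("negative_icc")
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        model_tag=tag,
        n_subjects=n,
        n_raters=k,
        flags=tuple(flags),
    )


def paired_limb_comparison(
    affected: np.ndarray, unaffected: np.ndarray
) -> PairedComparison:
    """Paired t-test between limbs with paired Cohen's d.

    ``mean_diff`` is mean(affected) − mean(unaffected); the paired
    effect size d is mean(differences)/SD(differences).  Zero-variance
    differences leave t undefined and are flagged.
    """
    a = np.asarray(affected, dtype=float)
    u = np.asarray(unaffected, dtype=float)
    if a.shape != u.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need aligned arrays of length >= 3")
    diff = a - u
    sd_diff = float(np.std(diff, ddof=1))
    flags: list[str] = []
    if sd_diff == 0:
        flags.append("zero_variance_differences")
        t_stat, p, d = float("nan"), float("nan"), float("nan")
    else:
        res = stats.ttest_rel(a, u)
        t_stat, p = float(res.statistic), float(res.pvalue)
        d = float(np.mean(diff) / sd_diff)
    return PairedComparison(
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(u)),
        sd_b=float(np.std(u, ddof=1)),
        mean_diff=float(np.mean(a) - np.mean(u)),
        t_stat=t_stat,
        p_value=p,
        d_paired=d,
        n=len(a),
        flags=tuple(flags),
    )


def between_limb_effect(mean_affected: float, mean_unaffected: float) -> float:
    """Between-limb effect as reported in the study tables.

    The tabulated "effect size" column equals the raw between-limb mean
    difference (affected − unaffected); the standardized paired d is
    reported separately by :func:`paired_limb_comparison`.
    """
    return float(mean_affected) - float(mean_unaffected)


def iqr_filter(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Tukey interquartile-range outlier screening.

    Quartiles use linear interpolation of order statistics; values
    outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed.  Returns the kept
    values and the removal count (an empty removal is valid).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need a one-dimensional sample of length >= 4")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return v[keep], int(np.sum(~keep))


def spearman_mas(
    params: np.ndarray,
    mas: np.ndarray,
    apply_iqr: bool = True,
) -> CorrelationResult:
    """Spearman correlation between pendulum parameters and MAS scores.

    Parameters are IQR-screened first (outliers typically reflect
    inadequate muscle relaxation during a trial); the paired MAS values
    of removed trials are dropped alongside.  Ties — ubiquitous in the
    ordinal MAS — are handled by midranks, and the p-value is two-sided.
    """
    p = np.asarray(params, dtype=float)
    m = np.asarray(mas, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or len(p) < 5:
        raise ValueError("need aligned arrays of length >= 5")
    removed = 0
    if apply_iqr:
        q1, q3 = np.percentile(p, [25, 75])
        iqr = q3 - q1
        keep = (p >= q1 - 1.5 * iqr) & (p <= q3 + 1.5 * iqr)
        removed = int(np.sum(~keep))
        p, m = p[keep], m[keep]
    flags: list[str] = []
    if np.all(m == m[0]) or np.all(p == p[0]):
        flags.append("degenerate_constant_input")
        rho, pval = float("nan"), float("nan")
    else:
        res = stats.spearmanr(p, m)
        rho, pval = float(res.statistic), float(res.pvalue)
    return CorrelationResult(
        rho=rho, p_value=pval, n_used=len(p), n_removed=removed, flags=tuple(flags)
    )


def shapiro_gate(differences: np.ndarray, alpha: float = 0.05):
    """Shapiro–Wilk normality check on method differences.

    Returns ``(statistic, p, passed)`` where ``passed`` means p > α.
    Downstream paired t-tests and Bland–Altman summaries annotate on a
    failed gate; they are never blocked by it.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or not (3 <= len(d) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(d == d[0]):
        return float("nan"), float("nan"), False
    w, p = stats.shapiro(d)
    return float(w), float(p), bool(p > alpha)


# ---------------------------------------------------------------------------
# Study-level reporting
# ---------------------------------------------------------------------------

@dataclass
class StudyTables:
    """The three study-level result tables plus Bland–Altman scatter data."""

    icc_table: pd.DataFrame
    limb_table: pd.DataFrame
    correlation_table: pd.DataFrame
    bland_altman_scatter: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("table1_icc", self.icc_table),
            ("table2_limbs", self.limb_table),
            ("table3_spearman", self.correlation_table),
        ):
            df.to_csv(out / f"{name}.csv", index=False)
            df.to_json(out / f"{name}.json", orient="records", indent=1)
        self.bland_altman_scatter.to_csv(out / "bland_altman_scatter.csv", index=False)


_TRIAL_KEY = ["subject_id", "limb", "trial_index"]


def _icc_grid(df: pd.DataFrame, icc_form: str) -> pd.DataFrame:
    gonio = df[df["device"] == "goniometer"]
    rows = []
    for device in [d for d in df["device"].unique() if d != "goniometer"]:
        pose = df[df["device"] == device]
        merged = gonio.merge(pose, on=_TRIAL_KEY, suffixes=("_ref", "_test"))
        for stratum in ("affected", "unaffected", "overall"):
            if stratum == "overall":
                sub = merged
            else:
                sub = merged[merged["affected_ref"] == (stratum == "affected")]
            for param in PARAMETERS:
                pair = sub[[f"{param}_ref", f"{param}_test"]].dropna()
                row = {"device": device, "stratum": stratum, "parameter": param,
                       "n": len(pair)}
                if len(pair) >= 3:
                    res = icc_consistency(pair.to_numpy(), form=icc_form)
                    row.update(icc=res.icc, ci_low=res.ci_low, ci_high=res.ci_high,
                               available=True)
                else:
                    row.update(icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                               available=False)
                rows.append(row)
    return pd.DataFrame(rows)


def _limb_grid(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    df = df.assign(side_class=np.where(df["affected"], "affected", "unaffected"))
    for device in df["device"].unique():
        sub = df[df["device"] == device]
        # Subject-level trial means per limb class give one paired
        # observation per subject.
        per_subject = sub.groupby(["subject_id", "side_class"])[list(PARAMETERS)].mean()
        for param in PARAMETERS:
            wide = per_subject[param].unstack("side_class")
            row = {"device": device, "parameter": param, "n_subjects": 0}
            paired = None
            if {"affected", "unaffected"}.issubset(wide.columns):
                paired = wide[["affected", "unaffected"]].dropna()
                row["n_subjects"] = len(paired)
            if paired is not None and len(paired) >= 3:
                cmp = paired_limb_comparison(
                    paired["affected"].to_numpy(), paired["unaffected"].to_numpy()
                )
                row.update(
                    mean_affected=cmp.mean_a, sd_affected=cmp.sd_a,
                    mean_unaffected=cmp.mean_b, sd_unaffected=cmp.sd_b,
                    effect=cmp.mean_diff, d_paired=cmp.d_paired,
                    t_stat=cmp.t_stat, p_value=cmp.p_value, available=True,
                )
            else:
                row.update(
                    mean_affected=np.nan, sd_affected=np.nan,
                    mean_unaffected=np.nan, sd_unaffected=np.nan,
                    effect=np.nan, d_paired=np.nan, t_stat=np.nan,
                    p_value=np.nan, available=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _correlation_grid(df: pd.DataFrame, iqr_scope: str) -> pd.DataFrame:
    rows = []
    for device in df["device"].unique():
        sub = df[df["device"] == device]
        for muscle, mas_col in (("flexors", "mas_flexor"), ("extensors", "mas_extensor")):
            for param in PARAMETERS:
                data = sub[[param, mas_col]].dropna()
                row = {"device": device, "muscle": muscle, "parameter": param}
                if len(data) >= 5:
                    res = spearman_mas(
                        data[param].to_numpy(), data[mas_col].to_numpy(),
                        apply_iqr=(iqr_scope == "per_stratum"),
                    )
                    row.update(rho=res.rho, p_value=res.p_value, n_used=res.n_used,
                               n_removed=res.n_removed, available=True)
                else:
                    row.update(rho=np.nan, p_value=np.nan, n_used=len(data),
                               n_removed=0, available=False)
                rows.append(row)
    return pd.DataFrame(rows)


def _ba_scatter(df: pd.DataFrame) -> pd.DataFrame:
    gonio = df[df["device"] == "goniometer"]
    frames = []
    for device in [d for d in df["device"].unique() if d != "goniometer"]:
        pose = df[df["device"] == device]
        merged = gonio.merge(pose, on=_TRIAL_KEY, suffixes=("_ref", "_test"))
        for param in PARAMETERS:
            pair = merged[
                _TRIAL_KEY + ["affected_ref", f"{param}_ref", f"{param}_test"]
            ].dropna()
            if pair.empty:
                continue
            frames.append(pd.DataFrame({
                "device": device,
                "parameter": param,
                "subject_id": pair["subject_id"],
                "limb": pair["limb"],
                "trial_index": pair["trial_index"],
                "stratum": np.where(pair["affected_ref"], "affected", "unaffected"),
                "mean": 0.5 * (pair[f"{param}_ref"] + pair[f"{param}_test"]),
                "difference": pair[f"{param}_test"] - pair[f"{param}_ref"],
            }))
    if not frames:
        return pd.DataFrame(
            columns=["device", "parameter", "subject_id", "limb", "trial_index",
                     "stratum", "mean", "difference"]
        )
    return pd.concat(frames, ignore_index=True)


def study_report(
    trials: pd.DataFrame,
    icc_form: str = "consistency",
    iqr_scope: str = "per_stratum",
) -> StudyTables:
    """Build the three study-level tables from per-trial records.

    ``trials`` needs one row per (subject, limb, device, trial) with
    the metadata columns and P1/P2/P3.  Cells whose preconditions fail
    (e.g. fewer than 3 paired subjects) are reported as unavailable,
    never silently dropped.  Row order never affects any cell.
    """
    required = set(_TRIAL_KEY) | {"device", "affected", "mas_flexor",
                                  "mas_extensor", *PARAMETERS}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing column(s) {sorted(missing)}")
    df = trials.sort_values(_TRIAL_KEY + ["device"]).reset_index(drop=True)
    return StudyTables(
        icc_table=_icc_grid(df, icc_form),
        limb_table=_limb_grid(df),
        correlation_table=_correlation_grid(df, iqr_scope),
        bland_altman_scatter=_ba_scatter(df),
    )
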