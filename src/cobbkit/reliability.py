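"""Validity and absolute-reliability statistics for observer studies.

Given a long-format study table (curve × observer × round × method),
this module builds per-comparison error distributions, prunes outliers
with Tukey fences, checks normality, and reports the reliability
quantities used in absolute-reliability work on angle measurement:

* MBE — mean bias error, the mean of the per-curve errors;
* SD — sample standard deviation of the errors;
* SE — standard error of the sample, ``SD / sqrt(gl)`` where ``gl`` is
  the retained sample size after outlier removal;
* MDC95 — minimum detectable change at 95% confidence,
  ``1.96 * sqrt(2) * SE``;
* ICC(2,1) — intraclass correlation, two-way random effects, single
  measure, absolute agreement (Shrout–Fleiss / McGraw–Wong case 2A),
  with its F-based 95% confidence interval and Landis–Koch label.

Comparison identifiers follow the AXBY convention: ``E1E2`` is the
error between expert rounds 1 and 2, ``E1N1`` between experts and
novices in round 1; pooled ids ``E``, ``N`` and ``EN`` average the
three pairwise round comparisons per curve.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ErrorDistribution",
    "ReliabilityStats",
    "IccResult",
    "BlandAltman",
    "MethodAgreement",
    "FullReport",
    "INTRA_COMPARISONS",
    "INTER_COMPARISONS",
    "remove_outliers",
    "tukey_fences",
    "error_distribution",
    "normality_gate",
    "summary_stats",
    "mdc95",
    "icc_2_1",
    "landis_koch",
    "bland_altman",
    "method_agreement",
    "compare_mbe_anova",
    "compare_methods_ttest",
    "full_report",
]

GROUP_OF = {"E": "expert", "N": "novice"}
INTRA_COMPARISONS = ("E1E2", "E2E3", "E1E3", "E", "N1N2", "N2N3", "N1N3", "N")
INTER_COMPARISONS = ("E1N1", "E2N2", "E3N3", "EN")
_ROUND_PAIRS = ((1, 2), (2, 3), (1, 3))

MDC_FACTOR = 1.96 * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# outlier pruning


def tukey_fences(
    values: np.ndarray, quartile_method: str = "linear"
) -> tuple[float, float]:
    """Lower/upper Tukey fences Q1 - 1.5*IQR, Q3 + 1.5*IQR.

    ``quartile_method`` selects the quartile convention: ``"linear"``
    (interpolated percentiles, the default) or ``"hinges"`` (Tukey's
    median-of-halves hinges).
    """
    values = np.asarray(values, dtype=float)
    if quartile_method == "linear":
        q1, q3 = np.percentile(values, [25, 75])
    elif quartile_method == "hinges":
        s = np.sort(values)
        n = len(s)
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError("quartile_method must be 'linear' or 'hinges'")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def remove_outliers(
    values: Sequence[float],
    ids: Sequence | None = None,
    quartile_method: str = "linear",
) -> tuple[np.ndarray, list[tuple]]:
    """Single-pass Tukey-fence filter.

    Returns ``(retained, removed)`` where removed is a list of
    ``(id, value)`` pairs (ids default to positional indices).  The
    filter is applied exactly once, not iterated to a fixed point.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    if ids is None:
        ids = list(range(len(values)))
    lo, hi = tukey_fences(values, quartile_method)
    keep = (values >= lo) & (values <= hi)
    removed = [(i, float(v)) for i, v, k in zip(ids, values, keep) if not k]
    return values[keep], removed


@dataclass(frozen=True)
class ErrorDistribution:
    """Per-curve error values of one comparison after outlier pruning."""

    comparison_id: str
    method: str
    values: np.ndarray
    curve_ids: tuple[str, ...]
    removed: tuple[tuple[str, float], ...] = ()

    @property
    def gl(self) -> int:
        """Retained sample size (curves minus removed outliers)."""
        return len(self.values)


# ---------------------------------------------------------------------------
# error distributions from the study table


def _group_round_means(sub: pd.DataFrame) -> pd.DataFrame:
    """curves × rounds matrix of group-mean angles (complete cells only)."""
    return sub.pivot_table(
        index="curve_id", columns="round", values="cobb_deg", aggfunc="mean"
    )


def _intra_pair_errors(table: pd.DataFrame, group: str, rx: int, ry: int) -> pd.Series:
    # per observer |round rx - round ry|, then mean over the group's observers
    sub = table[table["group"] == group]
    piv = sub.pivot_table(
        index=["curve_id", "observer_id"], columns="round", values="cobb_deg"
    )
    for r in (rx, ry):
        if r not in piv.columns:
            raise ValueError(f"study table has no round {r} for group {group!r}")
    err = (piv[rx] - piv[ry]).abs()
    return err.groupby(level="curve_id").mean()


def _inter_pair_errors(table: pd.DataFrame, rx: int, ry: int) -> pd.Series:
    em = _group_round_means(table[table["group"] == "expert"])
    nm = _group_round_means(table[table["group"] == "novice"])
    if rx not in em.columns or ry not in nm.columns:
        raise ValueError(f"study table lacks expert round {rx} or novice round {ry}")
    return (em[rx] - nm[ry]).abs().dropna()


def _per_curve_errors(table: pd.DataFrame, comparison_id: str) -> pd.Series:
    if comparison_id in GROUP_OF:  # pooled intra: E or N
        group = GROUP_OF[comparison_id]
        parts = [_intra_pair_errors(table, group, rx, ry) for rx, ry in _ROUND_PAIRS]
        return pd.concat(parts, axis=1).mean(axis=1)
    if comparison_id == "EN":  # pooled inter
        parts = [_inter_pair_errors(table, r, r) for r in (1, 2, 3)]
        return pd.concat(parts, axis=1).mean(axis=1)
    m = re.fullmatch(r"([EN])([123])([EN])([123])", comparison_id)
    if not m:
        raise ValueError(f"unrecognised comparison id: {comparison_id!r}")
    ga, rx, gb, ry = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if ga == gb:
        return _intra_pair_errors(table, GROUP_OF[ga], rx, ry)
    if (ga, gb) != ("E", "N"):
        raise ValueError(f"inter-group comparisons are written E<x>N<y>: {comparison_id!r}")
    return _inter_pair_errors(table, rx, ry)


def error_distribution(
    table: pd.DataFrame,
    comparison_id: str,
    method: str = "software",
    quartile_method: str = "linear",
    prune: bool = True,
) -> ErrorDistribution:
    """Build one comparison's per-curve error distribution.

    Intra-group ``AxAy``: per curve, the group's observers' mean
    absolute round-to-round difference.  Inter-group ``ExNy``: per
    curve, the absolute difference of the two group means.  Pooled
    ``E``/``N``/``EN``: per curve, the mean of the three pairwise round
    values.  Outlier pruning (Tukey fences) is applied to the resulting
    error distribution, mirroring the retained count ``gl``.
    """
    sub = table[table["method"] == method]
    if not len(sub):
        raise ValueError(f"study table has no rows for method {method!r}")
    errors = _per_curve_errors(sub, comparison_id)
    curve_ids = [str(c) for c in errors.index]
    values = errors.to_numpy(dtype=float)
    if prune:
        if len(values) < 4:
            raise ValueError("need at least 4 curves for outlier pruning")
        lo, hi = tukey_fences(values, quartile_method)
        keep = (values >= lo) & (values <= hi)
        retained = values[keep]
        removed = [(c, float(v)) for c, v, k in zip(curve_ids, values, keep) if not k]
        kept_ids = tuple(c for c, k in zip(curve_ids, keep) if k)
    else:
        retained, removed, kept_ids = values, [], tuple(curve_ids)
    return ErrorDistribution(
        comparison_id=comparison_id,
        method=method,
        values=np.asarray(retained, dtype=float),
        curve_ids=tuple(kept_ids),
        removed=tuple((str(c), v) for c, v in removed),
    )


# ---------------------------------------------------------------------------
# scalar statistics


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro–Wilk normality check: returns (p, p > alpha).

    Degenerate (constant) input has no defined W statistic and is
    reported as a gate failure with ``p = nan``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 values")
    if np.ptp(values) == 0:
        return float("nan"), False
    p = float(stats.shapiro(values).pvalue)
    return p, p > alpha


def summary_stats(dist: ErrorDistribution | Sequence[float]) -> tuple[float, float, float]:
    """(MBE, SD, SE): mean, sample SD (n-1), and SD/sqrt(gl)."""
    values = dist.values if isinstance(dist, ErrorDistribution) else np.asarray(dist, float)
    gl = len(values)
    mbe = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if gl > 1 else 0.0
    return mbe, sd, sd / math.sqrt(gl)


def mdc95(sd: float, gl: int) -> float:
    """Minimum detectable change at 95% confidence: 1.96*sqrt(2)*SD/sqrt(gl).

    Note this uses the sample's standard error, not the classical
    ``SEM = SD * sqrt(1 - ICC)``; see the methods note for why this
    convention is used here.
    """
    if gl < 1:
        raise ValueError("gl must be >= 1")
    return MDC_FACTOR * sd / math.sqrt(gl)


def landis_koch(icc: float) -> str:
    """Qualitative agreement band for a concordance coefficient."""
    if icc < 0:
        return "poor"
    if icc <= 0.20:
        return "slight"
    if icc <= 0.40:
        return "fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    label: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


def icc_2_1(matrix: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``matrix`` is targets × raters (curves × rounds/groups/methods) and
    must be complete — listwise deletion is never applied silently.
    The point estimate comes from the two-way ANOVA mean squares

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    and the confidence interval from the McGraw–Wong F-based
    construction with Satterthwaite degrees of freedom.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (targets x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(x).any():
        raise ValueError("matrix is incomplete; remove or impute missing cells explicitly")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise ValueError("degenerate matrix: no variance anywhere")
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        ci = (icc, icc)  # perfect agreement, no sampling noise model
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        if not math.isfinite(a):
            ci = (icc, icc)
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (
                    n * (msr - f_lower * mse)
                    / (f_lower * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
                hi = (
                    n * (f_upper * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_upper * msr)
                )
            # Satterthwaite df can degenerate (v -> 0) for strongly
            # negative agreement; fall back to the ICC domain limits
            lo = min(float(lo), icc) if math.isfinite(lo) else -1.0
            hi = max(float(hi), icc) if math.isfinite(hi) else 1.0
            ci = (lo, hi)
    return IccResult(
        icc=float(icc), ci95=ci, label=landis_koch(float(icc)),
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse), n=n, k=k,
    )


# ---------------------------------------------------------------------------
# method agreement


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltman:
    """Bland–Altman agreement of paired measurements.

    ``diffs = a - b``; bias is the mean difference and the 95% limits
    of agreement are ``bias ± 1.96 * SD(diffs)``.  Returns plot-ready
    per-pair means and differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return BlandAltman(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        means=means, diffs=diffs,
    )


@dataclass(frozen=True)
class MethodAgreement:
    """Software-vs-manual concordance on per-curve consensus means."""

    curve_ids: tuple[str, ...]
    software_means: np.ndarray
    manual_means: np.ndarray
    bland_altman: BlandAltman
    icc: IccResult
    mbe: float
    sd: float
    sem: float
    mdc95: float
    gl: int
    removed: tuple[tuple[str, float], ...]


def method_agreement(
    table: pd.DataFrame, quartile_method: str = "linear"
) -> MethodAgreement:
    """Concordance between the two measurement methods.

    Each curve is summarised per method by the mean of all its
    measurements (all observers × rounds, up to 24 per method);
    Bland–Altman and ICC(2,1) (methods as the 2 "raters") run on the
    paired means, and SEM/MDC95 on the signed per-curve differences
    after Tukey-fence pruning.
    """
    methods = sorted(table["method"].unique())
    if set(methods) < {"software", "manual"}:
        raise ValueError("method agreement needs both 'software' and 'manual' rows")
    means = table.pivot_table(
        index="curve_id", columns="method", values="cobb_deg", aggfunc="mean"
    ).dropna()
    curve_ids = tuple(str(c) for c in means.index)
    sw = means["software"].to_numpy(dtype=float)
    man = means["manual"].to_numpy(dtype=float)

    ba = bland_altman(sw, man)
    icc = icc_2_1(np.column_stack([sw, man]))
    retained, removed = remove_outliers(ba.diffs, curve_ids, quartile_method)
    mbe, sd, sem = summary_stats(retained)
    return MethodAgreement(
        curve_ids=curve_ids, software_means=sw, manual_means=man,
        bland_altman=ba, icc=icc, mbe=mbe, sd=sd, sem=sem,
        mdc95=mdc95(sd, len(retained)), gl=len(retained),
        removed=tuple((str(c), v) for c, v in removed),
    )


# ---------------------------------------------------------------------------
# group comparisons


def compare_mbe_anova(
    distributions: Iterable[ErrorDistribution],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across error distributions + Tukey HSD pairwise.

    Returns ``(F, p, tukey_table)`` where the Tukey table holds the
    family-wise-adjusted pairwise p-values at 95% confidence.
    """
    dists = list(distributions)
    if len(dists) < 2:
        raise ValueError("need at least two distributions to compare")
    groups = [d.values for d in dists]
    f_stat, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate(
        [[f"{d.comparison_id}-{d.method}"] * len(d.values) for d in dists]
    )
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return float(f_stat), float(p), tukey


def compare_methods_ttest(
    dist_a: ErrorDistribution, dist_b: ErrorDistribution
) -> tuple[float, float]:
    """Independent two-sample Student's t on two error distributions."""
    t, p = stats.ttest_ind(dist_a.values, dist_b.values)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# the full report


@dataclass(frozen=True)
class ReliabilityStats:
    """One report row: validity + reliability of one comparison."""

    comparison_id: str
    method: str
    mbe: float
    sd: float
    gl: int
    se: float
    mdc95: float
    icc: float
    ci95: tuple[float, float]
    landis_koch: str
    shapiro_p: float
    removed: tuple[tuple[str, float], ...] = ()


def _icc_matrix(table: pd.DataFrame, comparison_id: str) -> np.ndarray:
    """curves × raters matrix for a comparison's ICC.

    Intra rows use group-mean angles per round (2 rounds for a pairwise
    row, 3 for pooled); inter rows use the two group means.  Built from
    the unpruned table: outlier pruning applies to error distributions,
    not raw measurements.
    """
    if comparison_id in GROUP_OF:
        piv = _group_round_means(table[table["group"] == GROUP_OF[comparison_id]])
        return piv[[1, 2, 3]].dropna().to_numpy()
    if comparison_id == "EN":
        e = _group_round_means(table[table["group"] == "expert"]).mean(axis=1)
        n = _group_round_means(table[table["group"] == "novice"]).mean(axis=1)
        return pd.concat([e, n], axis=1).dropna().to_numpy()
    m = re.fullmatch(r"([EN])([123])([EN])([123])", comparison_id)
    ga, rx, gb, ry = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    a = _group_round_means(table[table["group"] == GROUP_OF[ga]])[rx]
    b = _group_round_means(table[table["group"] == GROUP_OF[gb]])[ry]
    return pd.concat([a, b], axis=1).dropna().to_numpy()


@dataclass(frozen=True)
class FullReport:
    rows: pd.DataFrame
    agreement: MethodAgreement | None
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    ttest_t: float
    ttest_p: float
    stats: tuple[ReliabilityStats, ...] = field(repr=False, default=())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False, float_format="%.4f")
        return path

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "rows": json.loads(self.rows.to_json(orient="records")),
            "anova": {"F": self.anova_f, "p": self.anova_p},
            "tukey": json.loads(self.tukey.to_json(orient="records")),
            "ttest_intergroup": {"t": self.ttest_t, "p": self.ttest_p},
        }
        if self.agreement is not None:
            ag = self.agreement
            doc["method_agreement"] = {
                "mbe": ag.mbe, "sd": ag.sd, "sem": ag.sem, "mdc95": ag.mdc95,
                "gl": ag.gl, "icc": ag.icc.icc, "ci95": list(ag.icc.ci95),
                "bias": ag.bland_altman.bias,
                "loa": [ag.bland_altman.loa_low, ag.bland_altman.loa_high],
            }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return path


def full_report(
    table: pd.DataFrame,
    quartile_method: str = "linear",
    alpha: float = 0.05,
) -> FullReport:
    """Run the complete reliability analysis of a study table.

    Emits one :class:`ReliabilityStats` row per comparison (12 per
    method), the software/manual method agreement when both methods are
    present, the across-groups ANOVA + Tukey HSD on the pooled
    intra-group distributions, and the software-vs-manual t-test on the
    pooled inter-group distributions.
    """
    methods = sorted(table["method"].unique())
    rounds = sorted(table["round"].unique())
    if len(rounds) < 2:
        raise ValueError(
            f"study table holds a single round {rounds}; reliability "
            "comparisons need repeated measurement rounds"
        )

    all_stats: list[ReliabilityStats] = []
    pooled_intra: dict[tuple[str, str], ErrorDistribution] = {}
    pooled_inter: dict[str, ErrorDistribution] = {}
    for method in methods:
        sub = table[table["method"] == method]
        for cid in (*INTRA_COMPARISONS, *INTER_COMPARISONS):
            dist = error_distribution(table, cid, method, quartile_method)
            mbe, sd, se = summary_stats(dist)
            icc = icc_2_1(_icc_matrix(sub, cid), alpha=alpha)
            shapiro_p, _ = normality_gate(dist.values, alpha)
            all_stats.append(
                ReliabilityStats(
                    comparison_id=cid, method=method, mbe=mbe, sd=sd,
                    gl=dist.gl, se=se, mdc95=mdc95(sd, dist.gl),
                    icc=icc.icc, ci95=icc.ci95, landis_koch=icc.label,
                    shapiro_p=shapiro_p, removed=dist.removed,
                )
            )
            if cid in GROUP_OF:
                pooled_intra[(cid, method)] = dist
            elif cid == "EN":
                pooled_inter[method] = dist

    rows = pd.DataFrame(
        [
            {
                "comparison": s.comparison_id, "method": s.method,
                "MBE": s.mbe, "SD": s.sd, "gl": s.gl, "SE": s.se,
                "MDC95": s.mdc95, "ICC": s.icc,
                "CI95_low": s.ci95[0], "CI95_high": s.ci95[1],
                "landis_koch": s.landis_koch, "shapiro_p": s.shapiro_p,
                "n_removed": len(s.removed),
            }
            for s in all_stats
        ]
    )

    anova_f, anova_p, tukey = compare_mbe_anova(pooled_intra.values())
    if len(pooled_inter) == 2:
        ttest_t, ttest_p = compare_methods_ttest(
            pooled_inter["software"], pooled_inter["manual"]
        )
        agreement = method_agreement(table, quartile_method)
    else:
        ttest_t = ttest_p = float("nan")
        agreement = None
    return FullReport(
        rows=rows, agreement=agreement, anova_f=anova_f, anova_p=anova_p,
        tukey=tukey, ttest_t=ttest_t, ttest_p=ttest_p, stats=tuple(all_stats),
    )
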