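"""Statistical analysis of evacuation-compliance experiments.

Covers the full analysis pipeline for a condition-by-outcome contingency
table: Pearson chi-square test of independence with adjusted standardized
residuals, pooled framing-level compliance rates, grouped logistic regression
with odds ratios against a control framing, and the a-priori sample-size
computation from Cohen's w via the noncentral chi-square distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class AnalysisError(ValueError):
    """Raised for inputs on which an analysis is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """Condition x (evacuated, not evacuated) counts."""

    row_labels: tuple[str, ...]
    counts: np.ndarray  # shape (n_rows, 2), nonnegative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] == 0:
            raise AnalysisError("counts must be a nonempty rows x 2 array")
        if len(self.row_labels) != counts.shape[0]:
            raise AnalysisError("row_labels must match counts rows")
        if (counts < 0).any():
            raise AnalysisError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=["evacuated", "not_evacuated"]
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    adjusted_residuals: np.ndarray  # rows x 2


@dataclass(frozen=True)
class GroupEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False  # continuity correction applied (zero cell)


@dataclass(frozen=True)
class LogisticFit:
    reference_label: str
    estimates: Mapping[str, GroupEstimate]
    baseline_odds: float


def load_published_counts() -> ContingencyTable:
    """The packaged per-condition evacuation counts fixture (16 conditions,
    206 evacuated of 3,550)."""
    with resources.as_file(
        resources.files("evactwin.data").joinpath("table_counts.csv")
    ) as p:
        return build_table(p)


def build_table(source) -> ContingencyTable:
    """Build a contingency table from an ExperimentResult, a counts CSV path
    (columns condition, evacuated, not_evacuated), or a DataFrame.

    Row order follows the input (design order for simulated results).
    """
    from .engine import ExperimentResult

    if isinstance(source, ExperimentResult):
        labels = tuple(source.per_condition_counts)
        counts = np.array([source.per_condition_counts[c] for c in labels])
    elif isinstance(source, pd.DataFrame):
        labels = tuple(source["condition"].astype(str))
        counts = source[["evacuated", "not_evacuated"]].to_numpy()
    elif isinstance(source, (str, Path)):
        df = pd.read_csv(source)
        missing = {"condition", "evacuated", "not_evacuated"} - set(df.columns)
        if missing:
            raise AnalysisError(f"counts file missing column(s): {sorted(missing)}")
        labels = tuple(df["condition"].astype(str))
        counts = df[["evacuated", "not_evacuated"]].to_numpy()
    else:
        raise AnalysisError(f"cannot build a table from {type(source).__name__}")
    if len(labels) == 0:
        raise AnalysisError("empty counts input")
    return ContingencyTable(row_labels=labels, counts=counts)


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence with adjusted standardized
    residuals.

    residual_ij = (O - E) / sqrt(E * (1 - row_total/N) * (1 - col_total/N)),
    approximately standard normal under independence.
    """
    O = table.counts.astype(float)
    N = table.grand_total
    if N <= 0:
        raise AnalysisError("chi-square undefined for an all-zero table")
    rt = table.row_totals.astype(float)
    ct = table.col_totals.astype(float)
    if (rt == 0).any() or (ct == 0).any():
        raise AnalysisError("zero row or column marginal: expected counts undefined")
    if O.shape[0] < 2:
        raise AnalysisError("chi-square needs at least two rows (df would be 0)")
    E = np.outer(rt, ct) / N
    statistic = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    adj = (O - E) / np.sqrt(E * (1 - rt[:, None] / N) * (1 - ct[None, :] / N))
    return ChiSquareResult(statistic=statistic, df=df, p_value=p, adjusted_residuals=adj)


def residual_star_threshold(n_cells: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected two-sided normal cutoff for starring residuals."""
    return float(sps.norm.isf(alpha / n_cells / 2.0))


def pool_counts(
    table: ContingencyTable, grouping: Mapping[str, str]
) -> ContingencyTable:
    """Collapse conditions into framing groups (first-appearance order)."""
    unmapped = [r for r in table.row_labels if r not in grouping]
    if unmapped:
        raise AnalysisError(f"condition(s) not mapped to a framing: {unmapped}")
    order: list[str] = []
    sums: dict[str, np.ndarray] = {}
    for label, row in zip(table.row_labels, table.counts):
        g = grouping[label]
        if g not in sums:
            sums[g] = np.zeros(2, dtype=np.int64)
            order.append(g)
        sums[g] += row
    return ContingencyTable(tuple(order), np.array([sums[g] for g in order]))


def framing_rates(
    table: ContingencyTable, grouping: Mapping[str, str]
) -> dict[str, float]:
    """Pooled compliance rate per framing, in percent."""
    pooled = pool_counts(table, grouping)
    return {
        g: float(100.0 * ev / (ev + stay))
        for g, (ev, stay) in zip(pooled.row_labels, pooled.counts)
    }


def fit_grouped_logistic(
    table: ContingencyTable,
    grouping: Mapping[str, str],
    reference: str,
) -> LogisticFit:
    """Grouped (binomial) logistic regression of evacuation on framing dummies.

    Fit by iteratively reweighted least squares on the pooled group counts;
    for this saturated dummy coding the fitted odds ratio equals the 2x2
    cross-product ratio against the reference group (asserted to 1e-8).
    Wald confidence intervals on the log-odds scale. Groups with a zero cell
    get a Haldane–Anscombe +0.5 continuity correction on their 2x2 and are
    flagged ``corrected``.
    """
    pooled = pool_counts(table, grouping)
    labels = list(pooled.row_labels)
    if reference not in labels:
        raise AnalysisError(f"reference framing {reference!r} not present")
    ref_idx = labels.index(reference)
    ref_ev, ref_stay = (int(x) for x in pooled.counts[ref_idx])
    if ref_ev == 0 or ref_stay == 0:
        raise AnalysisError("reference group needs nonzero counts in both outcomes")

    others = [g for g in labels if g != reference]
    X = np.zeros((len(labels), 1 + len(others)))
    X[:, 0] = 1.0
    for j, g in enumerate(others):
        X[labels.index(g), 1 + j] = 1.0
    endog = np.column_stack([pooled.counts[:, 0], pooled.counts[:, 1]])

    zero_groups = {
        g
        for g, row in zip(labels, pooled.counts)
        if (row == 0).any() and g != reference
    }
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # the dummy coding is saturated, so statsmodels flags perfect
        # prediction and a 0/0 scale; both are expected here
        warnings.simplefilter("ignore")
        res = model.fit(tol=1e-12)

    estimates: dict[str, GroupEstimate] = {}
    conf = res.conf_int()
    for j, g in enumerate(others):
        k = 1 + j
        a, b = (int(x) for x in pooled.counts[labels.index(g)])
        if g in zero_groups:
            # infinite MLE; report the continuity-corrected 2x2 estimate
            a_, b_, c_, d_ = a + 0.5, b + 0.5, ref_ev + 0.5, ref_stay + 0.5
            or_ = (a_ * d_) / (b_ * c_)
            se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
            lo, hi = np.log(or_) - 1.959963984540054 * se, np.log(or_) + 1.959963984540054 * se
            z = np.log(or_) / se
            estimates[g] = GroupEstimate(
                odds_ratio=float(or_),
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)),
                p_value=float(2 * sps.norm.sf(abs(z))),
                corrected=True,
            )
            continue
        or_mle = float(np.exp(res.params[k]))
        cross = (a * ref_stay) / (b * ref_ev)
        assert abs(or_mle - cross) <= 1e-8 * max(1.0, cross), (
            "saturated-model identity violated: MLE OR != cross-product ratio"
        )
        estimates[g] = GroupEstimate(
            odds_ratio=or_mle,
            ci_low=float(np.exp(conf[k][0])),
            ci_high=float(np.exp(conf[k][1])),
            p_value=float(res.pvalues[k]),
        )
    return LogisticFit(
        reference_label=reference,
        estimates=estimates,
        baseline_odds=ref_ev / ref_stay,
    )


def required_sample_size(
    w: float, alpha: float = 0.05, power: float = 0.80, df: int = 1, n_max: int = 10**7
) -> int:
    """Smallest per-group n achieving the target power for a chi-square test
    with effect size Cohen's w (noncentrality n * w^2)."""
    if w <= 0:
        raise AnalysisError("effect size w must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise AnalysisError("alpha and power must lie in (0, 1)")
    if df < 1:
        raise AnalysisError("df must be >= 1")
    crit = sps.chi2.ppf(1 - alpha, df)

    def achieved(n: int) -> float:
        return float(sps.ncx2.sf(crit, df, n * w * w))

    if achieved(n_max) < power:
        raise AnalysisError(f"power {power} unreachable below n = {n_max}")
    lo, hi = 1, 1
    while achieved(hi) < power:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def analysis_report(
    table: ContingencyTable,
    grouping: Mapping[str, str],
    reference: str = "control",
    star_alpha: float = 0.05,
) -> str:
    """Human-readable markdown report: counts, chi-square with residuals,
    pooled rates, and odds ratios vs the reference framing."""
    chi = chi_square_test(table)
    thresh = residual_star_threshold(table.counts.size, star_alpha)
    rates = framing_rates(table, grouping)
    fit = fit_grouped_logistic(table, grouping, reference)

    lines = ["# Evacuation-compliance analysis", "", "## Counts by condition", ""]
    lines.append("| condition | evacuated | not evacuated | % | adj. residual |")
    lines.append("|---|---|---|---|---|")
    for i, label in enumerate(table.row_labels):
        ev, stay = table.counts[i]
        pct = 100.0 * ev / (ev + stay)
        r = chi.adjusted_residuals[i, 0]
        star = "*" if abs(r) > thresh else ""
        lines.append(f"| {label} | {ev} | {stay} | {pct:.1f}% | {r:+.2f}{star} |")
    lines += [
        "",
        f"Chi-square test of independence: chi2 = {chi.statistic:.1f}, "
        f"df = {chi.df}, N = {table.grand_total}, p = {chi.p_value:.3g}",
        f"(residuals starred beyond |z| > {thresh:.2f}, Bonferroni over "
        f"{table.counts.size} cells at alpha = {star_alpha})",
        "",
        "## Pooled compliance rates by framing",
        "",
    ]
    for g, rate in rates.items():
        lines.append(f"- {g}: {rate:.1f}%")
    lines += [
        "",
        f"## Odds ratios vs {fit.reference_label} "
        f"(baseline odds {fit.baseline_odds:.4f})",
        "",
        "| framing | OR | 95% CI | p |",
        "|---|---|---|---|",
    ]
    for g, est in fit.estimates.items():
        flag = " (corrected)" if est.corrected else ""
        lines.append(
            f"| {g} | {est.odds_ratio:.2f}{flag} | "
            f"[{est.ci_low:.2f}, {est.ci_high:.2f}] | {est.p_value:.3g} |"
        )
    return "\n".join(lines) + "\n"
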