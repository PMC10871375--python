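"""Epidemiological measures computable from aggregate counts alone.

Given a (possibly merged, suppressed) aggregate matrix, this module
extracts 2x2 contingency tables by marginal subtraction and computes the
standard count-based measures:

* prevalence            p = n(level) / N
* conditional probability   P(outcome | exposure) = a / (a + b)
* odds ratio            OR = (a d) / (b c), log-scale Wald 95% CI
* relative risk         RR = [a/(a+b)] / [c/(c+d)], log-scale Wald 95% CI
* chi-square (1 df)     X^2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]

with the usual 2x2 labelling a = exposed & outcome, b = exposed & not,
c = unexposed & outcome, d = neither.  A needed cell that is suppressed or
absent raises :class:`~fedcube.errors.IncomputableError` — under
aggregate-only federation a missing cell is information, never a zero, so
nothing is imputed.  Zero cells in the odds ratio are handled with the
Haldane-Anscombe 0.5 correction and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from fedcube.errors import IncomputableError
from fedcube.aggregate import AggregateMatrix

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CrossTab:
    """Exposure x outcome 2x2 table: a=E&O, b=E&~O, c=~E&O, d=~E&~O."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise IncomputableError("2x2 cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class MeasureResult:
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    corrected: bool = False  # zero-cell or continuity correction applied
    notes: list[str] = field(default_factory=list)


def _require(matrix: AggregateMatrix, mapping: dict[str, str], what: str) -> int:
    count = matrix.count(mapping)
    if count is None:
        raise IncomputableError(
            f"cell needed for {what} is suppressed or absent: {mapping or 'null set'}")
    return count


def crosstab(
    matrix: AggregateMatrix,
    exposure: tuple[str, str],
    outcome: tuple[str, str],
) -> CrossTab:
    """Extract a 2x2 table from the joint cell, both marginals, and the total.

    b, c, d come from subtraction, so only four rows are needed; any of them
    suppressed makes the table incomputable.
    """
    evar, elevel = exposure
    ovar, olevel = outcome
    a = _require(matrix, {evar: elevel, ovar: olevel}, "joint cell")
    marg_e = _require(matrix, {evar: elevel}, "exposure marginal")
    marg_o = _require(matrix, {ovar: olevel}, "outcome marginal")
    total = _require(matrix, {}, "cohort total")
    b = marg_e - a
    c = marg_o - a
    d = total - a - b - c
    if min(b, c, d) < 0:
        raise IncomputableError("inconsistent marginals produce a negative 2x2 cell")
    return CrossTab(a=a, b=b, c=c, d=d,
                    exposure_label=f"{evar}={elevel}", outcome_label=f"{ovar}={olevel}")


def odds_ratio(t: CrossTab) -> MeasureResult:
    """(a d)/(b c) with a log-scale Wald 95% interval; zero cells corrected."""
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(est) - Z95 * se), math.exp(math.log(est) + Z95 * se)
    notes = ["Haldane-Anscombe 0.5 correction applied to zero cell(s)"] if corrected else []
    return MeasureResult(est, lo, hi, corrected=corrected, notes=notes)


def relative_risk(t: CrossTab) -> MeasureResult:
    """Risk ratio [a/(a+b)] / [c/(c+d)] with a log-scale Wald 95% interval."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise IncomputableError("a row of the 2x2 table is empty; risk undefined")
    if t.a == 0 or t.c == 0:
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
        corrected = True
    else:
        a, b, c, d = t.a, t.b, t.c, t.d
        corrected = False
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo, hi = math.exp(math.log(est) - Z95 * se), math.exp(math.log(est) + Z95 * se)
    notes = ["Haldane-Anscombe 0.5 correction applied to zero cell(s)"] if corrected else []
    return MeasureResult(est, lo, hi, corrected=corrected, notes=notes)


def conditional_probability(t: CrossTab, direction: str = "outcome_given_exposure") -> float:
    """P(outcome | exposure) = a/(a+b), or P(exposure | outcome) = a/(a+c)."""
    if direction == "outcome_given_exposure":
        denom = t.a + t.b
    elif direction == "exposure_given_outcome":
        denom = t.a + t.c
    else:
        raise IncomputableError(f"unknown direction {direction!r}")
    if denom == 0:
        raise IncomputableError("conditioning event has zero count")
    return t.a / denom


def prevalence(matrix: AggregateMatrix, variable: str, level: str) -> float:
    """Level count divided by the null-set (total cohort) count."""
    num = _require(matrix, {variable: level}, "prevalence numerator")
    total = _require(matrix, {}, "cohort total")
    if total == 0:
        raise IncomputableError("cohort total is zero")
    return num / total


def chi_square(t: CrossTab, yates: bool = False) -> MeasureResult:
    """Closed-form 2x2 chi-square with 1 df; Yates continuity optional."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise IncomputableError("a margin of the 2x2 table is zero; chi-square undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    statistic = n * diff * diff / denom
    p = float(stats.chi2.sf(statistic, df=1))
    return MeasureResult(statistic, p_value=p, corrected=yates)


@dataclass
class TrendPoint:
    month: str
    nlp_percent: float
    icd_percent: float
    denominator: int


@dataclass
class TrendSeries:
    points: list[TrendPoint]
    omitted_months: list[str]  # denominators or numerators suppressed/absent


def trend_series(
    matrix: AggregateMatrix,
    nlp_variable: str,
    icd_variable: str,
    month_variable: str = "month",
    positive_level: str = "true",
) -> TrendSeries:
    """Monthly percentage of units positive by each detection method.

    For each month m present in the matrix: 100 * n(method=true, month=m)
    / n(month=m), for the text-derived (NLP) variable and the diagnosis-code
    (ICD) variable.  Months whose denominator — or either numerator cell —
    is suppressed or absent are omitted and listed, never imputed.
    """
    months = sorted({dict(a).get(month_variable) for a in matrix.rows
                     if len(a) == 1 and a[0][0] == month_variable} - {None})
    points, omitted = [], []
    for m in months:
        denom = matrix.count({month_variable: m})
        nlp_n = matrix.count({month_variable: m, nlp_variable: positive_level})
        icd_n = matrix.count({month_variable: m, icd_variable: positive_level})
        if denom is None or denom == 0 or nlp_n is None or icd_n is None:
            omitted.append(m)
            continue
        points.append(TrendPoint(month=m, nlp_percent=100.0 * nlp_n / denom,
                                 icd_percent=100.0 * icd_n / denom, denominator=denom))
    return TrendSeries(points=points, omitted_months=omitted)


def plot_trend(series: TrendSeries, path: str) -> None:
    """Dashboard-style line chart of the two detection methods by month."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    months = [p.month for p in series.points]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(months, [p.nlp_percent for p in series.points], marker="o", label="NLP (note text)")
    ax.plot(months, [p.icd_percent for p in series.points], marker="s", label="ICD-10 codes")
    ax.set_xlabel("encounter month")
    ax.set_ylabel("% of encounters with symptom")
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
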