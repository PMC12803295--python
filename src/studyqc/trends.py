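"""Monthly error-count series and count-regression trend models.

Flags are bucketed into calendar-month series per CRF domain (zero-filled
between the first and last flagged months).  The observed percent change is
the raw difference between the first and last monthly counts,
``100 * (last - first) / first``.  The model-estimated change comes from a
count regression with a log link on the month index: per-domain models, and
a pooled model with domain-level intercepts and a shared slope.  With slope
``b`` (log count per month) and a span of ``dt`` months between the first
and last observations, the model percent change is ``100 * (exp(b*dt) - 1)``.

The model family is Poisson, switching to negative binomial when the Pearson
dispersion statistic exceeds 2.  The interface follows the fitted-model
convention: ``ErrorTrendModel(series).fit()`` returns a results object with
estimates, standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .util import round_half_away

__all__ = [
    "MonthlyErrorSeries",
    "monthly_counts",
    "total_series",
    "observed_percent_change",
    "ErrorTrendModel",
    "PooledErrorTrendModel",
    "ErrorTrendResults",
    "trend_summary_table",
]

#: Pearson dispersion above which the Poisson family is swapped for NB
DISPERSION_SWITCH = 2.0


@dataclass
class MonthlyErrorSeries:
    """Contiguous calendar-month error counts for one domain."""

    domain: str
    months: pd.PeriodIndex  # contiguous, freq='M'
    counts: np.ndarray  # non-negative ints, zero-filled interior months
    first_date: dt.date | None = None  # earliest/latest underlying flag dates
    last_date: dt.date | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.months) != len(self.counts):
            raise ValueError("months and counts must align")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def first_count(self) -> int:
        return int(self.counts[0]) if len(self) else 0

    @property
    def last_count(self) -> int:
        return int(self.counts[-1]) if len(self) else 0

    @property
    def span_months(self) -> int:
        return len(self) - 1 if len(self) else 0

    @classmethod
    def from_counts(cls, domain: str, start: str | pd.Period, counts) -> "MonthlyErrorSeries":
        """Build from a raw count vector, trimming leading/trailing zero months."""
        counts = np.asarray(counts, dtype=int)
        nonzero = np.nonzero(counts)[0]
        if len(nonzero) == 0:
            return cls(domain, pd.PeriodIndex([], freq="M"), np.array([], dtype=int))
        lo, hi = nonzero[0], nonzero[-1] + 1
        start = pd.Period(start, freq="M") + int(lo)
        months = pd.period_range(start, periods=hi - lo, freq="M")
        return cls(domain, months, counts[lo:hi])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months.astype(str), "count": self.counts, "domain": self.domain})


def monthly_counts(flags: pd.DataFrame, by: str = "domain") -> dict[str, MonthlyErrorSeries]:
    """Calendar-month error series per group (default: per CRF domain).

    Months with no flags inside a domain's observed span are included with
    count zero; a group with no flags yields an empty series.
    """
    out: dict[str, MonthlyErrorSeries] = {}
    for key, group in flags.groupby(by, sort=True):
        dates = pd.to_datetime(group["flag_date"])
        periods = dates.dt.to_period("M")
        span = pd.period_range(periods.min(), periods.max(), freq="M")
        counts = periods.value_counts().reindex(span, fill_value=0).sort_index()
        out[key] = MonthlyErrorSeries(
            domain=str(key),
            months=span,
            counts=counts.to_numpy(),
            first_date=dates.min().date(),
            last_date=dates.max().date(),
        )
    return out


def total_series(flags: pd.DataFrame) -> MonthlyErrorSeries:
    """Month-wise series over all domains pooled together."""
    pooled = flags.copy()
    pooled["_all"] = "Total"
    return monthly_counts(pooled, by="_all")["Total"]


def observed_percent_change(series: MonthlyErrorSeries) -> float | None:
    """Raw change between the first and last monthly counts, one decimal.

    Undefined (None) when the series has fewer than two months or a zero
    first count.
    """
    if len(series) < 2 or series.first_count == 0:
        return None
    return round_half_away(100.0 * (series.last_count - series.first_count) / series.first_count, 1)


# ---------------------------------------------------------------------------
# trend models
# ---------------------------------------------------------------------------


@dataclass
class ErrorTrendResults:
    """Fitted error-trend estimates for one domain (or the pooled model)."""

    domain: str
    family: str  # poisson | negative_binomial
    slope: float  # log count per month
    slope_se: float
    span_months: int
    dispersion: float
    intercepts: dict[str, float] = field(default_factory=dict)
    nobs: int = 0

    @property
    def monthly_percent_change(self) -> float:
        return 100.0 * (np.exp(self.slope) - 1.0)

    @property
    def percent_change(self) -> float:
        """Model-estimated percent change over the observed span."""
        return 100.0 * (np.exp(self.slope * self.span_months) - 1.0)

    def summary(self) -> str:
        lines = [
            f"Error trend model — {self.domain}",
            "=" * 40,
            f"family               {self.family}",
            f"observations         {self.nobs}",
            f"slope (log/month)    {self.slope:+.4f} (se {self.slope_se:.4f})",
            f"monthly % change     {self.monthly_percent_change:+.1f}%",
            f"span (months)        {self.span_months}",
            f"span % change        {self.percent_change:+.1f}%",
            f"Pearson dispersion   {self.dispersion:.2f}",
        ]
        for name, value in self.intercepts.items():
            lines.append(f"intercept[{name}]      {value:+.4f}")
        return "\n".join(lines)


def _check_series(series: MonthlyErrorSeries) -> None:
    if len(series) < 3:
        raise ValueError(f"{series.domain}: need at least 3 observation months, have {len(series)}")
    if series.counts.sum() == 0:
        raise ValueError(f"{series.domain}: all-zero series, trend fit refused")


def _dispersion(result) -> float:
    df = result.df_resid
    return float(result.pearson_chi2 / df) if df > 0 else 0.0


def _fit_glm(y: np.ndarray, X: np.ndarray) -> tuple:
    """Poisson GLM, refit as negative binomial when overdispersed."""
    poisson = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    dispersion = _dispersion(poisson)
    if dispersion <= DISPERSION_SWITCH:
        return poisson, "poisson", dispersion
    # moment estimate of the NB alpha via the auxiliary regression
    mu = poisson.fittedvalues
    alpha = float(np.sum(((y - mu) ** 2 - y) / mu**2) / max(len(y) - X.shape[1], 1))
    alpha = min(max(alpha, 0.01), 10.0)
    nb = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    return nb, "negative_binomial", dispersion


class ErrorTrendModel:
    """Count regression of one domain's monthly errors on the month index."""

    def __init__(self, series: MonthlyErrorSeries):
        _check_series(series)
        self.series = series

    def fit(self) -> ErrorTrendResults:
        y = self.series.counts.astype(float)
        month_index = np.arange(len(y), dtype=float)
        X = sm.add_constant(month_index)
        result, family, dispersion = _fit_glm(y, X)
        return ErrorTrendResults(
            domain=self.series.domain,
            family=family,
            slope=float(result.params[1]),
            slope_se=float(result.bse[1]),
            span_months=self.series.span_months,
            dispersion=dispersion,
            intercepts={self.series.domain: float(result.params[0])},
            nobs=len(y),
        )


class PooledErrorTrendModel:
    """Shared-slope model over all domains with domain-level intercepts.

    Month indices live on a common calendar so the shared slope is a per-
    calendar-month rate; the pooled percent change spans the earliest first
    observation to the latest last observation across domains.
    """

    def __init__(self, series_by_domain: dict[str, MonthlyErrorSeries]):
        series = {k: s for k, s in series_by_domain.items() if len(s) >= 1 and s.counts.sum() > 0}
        if len(series) < 2:
            raise ValueError("pooled trend needs at least 2 non-empty domain series")
        self.series_by_domain = dict(sorted(series.items()))

    def fit(self) -> ErrorTrendResults:
        origin = min(s.months[0] for s in self.series_by_domain.values())
        last = max(s.months[-1] for s in self.series_by_domain.values())
        rows = []
        for domain, series in self.series_by_domain.items():
            for month, count in zip(series.months, series.counts):
                rows.append((domain, (month - origin).n, count))
        frame = pd.DataFrame(rows, columns=["domain", "month", "count"])
        dummies = pd.get_dummies(frame["domain"], dtype=float)
        X = np.column_stack([dummies.to_numpy(), frame["month"].to_numpy(dtype=float)])
        y = frame["count"].to_numpy(dtype=float)
        result, family, dispersion = _fit_glm(y, X)
        return ErrorTrendResults(
            domain="pooled",
            family=family,
            slope=float(result.params[-1]),
            slope_se=float(result.bse[-1]),
            span_months=(last - origin).n,
            dispersion=dispersion,
            intercepts={name: float(p) for name, p in zip(dummies.columns, result.params[:-1])},
            nobs=len(y),
        )


# ---------------------------------------------------------------------------
# report table
# ---------------------------------------------------------------------------


def trend_summary_table(flags: pd.DataFrame, include_model: bool = True) -> pd.DataFrame:
    """Per-domain first/last dates and counts, observed percent change, and
    (optionally) model-estimated percent change, with a Total row.

    The Total first/last counts are the sums of the domain first/last counts
    — the aggregate drop across domains from their initial to their latest
    months — and the Total model estimate comes from the pooled shared-slope
    model.
    """
    by_domain = monthly_counts(flags)
    rows = []
    for domain, series in by_domain.items():
        model_change = np.nan
        if include_model and len(series) >= 3:
            model_change = round_half_away(ErrorTrendModel(series).fit().percent_change, 1)
        rows.append(
            {
                "domain": domain,
                "first_date": series.first_date.isoformat(),
                "first_count": series.first_count,
                "last_date": series.last_date.isoformat(),
                "last_count": series.last_count,
                "observed_pct_change": observed_percent_change(series),
                "model_pct_change": model_change,
            }
        )
    first_total = sum(s.first_count for s in by_domain.values())
    last_total = sum(s.last_count for s in by_domain.values())
    pooled_change = np.nan
    if include_model and len(by_domain) >= 2:
        try:
            pooled_change = round_half_away(PooledErrorTrendModel(by_domain).fit().percent_change, 1)
        except ValueError:
            pass
    rows.append(
        {
            "domain": "Total",
            "first_date": "",
            "first_count": first_total,
            "last_date": "",
            "last_count": last_total,
            "observed_pct_change": (
                round_half_away(100.0 * (last_total - first_total) / first_total, 1) if first_total else None
            ),
            "model_pct_change": pooled_change,
        }
    )
    return pd.DataFrame(
        rows,
        columns=[
            "domain",
            "first_date",
            "first_count",
            "last_date",
            "last_count",
            "observed_pct_change",
            "model_pct_change",
        ],
    )
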