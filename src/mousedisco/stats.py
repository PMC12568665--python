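"""Chamber-occupancy preference statistics.

The place-preference assay yields, per animal, the cumulative dwell time in
each of four stimulus chambers over a 3600 s session.  The analysis chain is

1. per-condition outlier calling with the ROUT method at FDR level Q
   (default 1%) — flagged values are *reported* and excluded from the test
   statistics, never silently dropped;
2. one-way ANOVA across conditions on the retained values;
3. if the omnibus test is significant (configurable), all pairwise
   homoskedastic (pooled-variance) t-tests;
4. Benjamini–Hochberg step-up adjustment of the pairwise p-values over the
   full family of C(k, 2) comparisons, with significance called at
   q < alpha.

The ROUT variant here is the single-column case: the robust "fit" is the
sample median, the robust residual scale (RSDR) is the 68.27th percentile of
absolute residuals with a sqrt(n/(n-1)) small-sample correction, residual
p-values come from the t distribution with n-1 df, and flagging is a
BH-style step-up at level Q.

The module exposes both plain functions (:func:`rout_outliers`,
:func:`one_way_anova`, :func:`pairwise_t`, :func:`bh_adjust`) and a
model/results pair (:class:`ChamberPreference` → :class:`PreferenceResults`)
in the style of statsmodels: build the model from a long-format table with
columns ``animal_id, condition, seconds``, call :meth:`ChamberPreference.fit`,
and read estimates, tests and diagnostics off the results object.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from ._errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyTable",
    "OutlierReport",
    "AnovaResult",
    "PairwiseResult",
    "rout_outliers",
    "one_way_anova",
    "f_tail_prob",
    "pairwise_t",
    "bh_adjust",
    "ChamberPreference",
    "PreferenceResults",
    "preference_pipeline",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class OccupancyTable:
    """Long-format dwell times: one row per (animal, condition).

    Validates that every dwell time lies in [0, session_s] and that no
    animal's chamber times sum to more than the session length (time in the
    connecting tunnels is unassigned).
    """

    data: pd.DataFrame
    session_s: float = 3600.0

    REQUIRED = ("animal_id", "condition", "seconds")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ParameterError(f"occupancy table missing columns: {missing}")
        if len(self.data) == 0:
            raise ParameterError("occupancy table is empty")
        secs = self.data["seconds"].to_numpy(dtype=float)
        if np.any(secs < 0) or np.any(secs > self.session_s):
            raise ParameterError("dwell times must lie in [0, session_s]")
        sums = self.data.groupby("animal_id")["seconds"].sum()
        if np.any(sums.to_numpy() > self.session_s * (1 + 1e-9)):
            bad = sums[sums > self.session_s].index.tolist()
            raise ParameterError(
                f"animals exceed the session length when summed: {bad}"
            )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique().tolist())

    def values_for(self, condition: str) -> np.ndarray:
        rows = self.data[self.data["condition"] == condition]
        return rows["seconds"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, session_s: float = 3600.0) -> "OccupancyTable":
        return cls(pd.read_csv(path), session_s=session_s)


@dataclass
class OutlierReport:
    """ROUT output for one condition: everything reported, nothing dropped."""

    values: np.ndarray
    flagged: np.ndarray  # boolean mask over values
    robust_center: float
    rsdr: float
    Q: float
    p_values: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def retained(self) -> np.ndarray:
        return self.values[~self.flagged]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    degenerate: bool = False


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    q: float = math.nan
    m: int = 0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def rout_outliers(values, Q: float = 0.01) -> OutlierReport:
    """ROUT outlier calling on a single sample at FDR level ``Q``.

    Center = median; RSDR = 68.27th percentile (linear interpolation) of
    absolute residuals times sqrt(n/(n-1)); per-value two-tailed p from the
    t distribution of residual/RSDR with n-1 df; flags via BH step-up at
    level Q over the n residual p-values.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise InsufficientDataError("ROUT needs at least 3 values per condition")
    if not (0 < Q < 0.5):
        raise ParameterError("Q must be in (0, 0.5)")
    center = float(np.median(v))
    res = v - center
    rsdr = float(np.percentile(np.abs(res), 68.27) * np.sqrt(n / (n - 1)))
    if rsdr == 0:
        if np.all(res == 0):
            return OutlierReport(v, np.zeros(n, bool), center, 0.0, Q, np.ones(n))
        raise DegenerateDataError(
            "robust residual scale is zero while values differ"
        )
    p = 2.0 * sps.t.sf(np.abs(res) / rsdr, df=n - 1)
    order = np.argsort(p, kind="stable")
    thresh = Q * np.arange(1, n + 1) / n
    below = np.nonzero(p[order] <= thresh)[0]
    flagged = np.zeros(n, dtype=bool)
    if below.size:
        flagged[order[: below[-1] + 1]] = True
        logger.info("ROUT flagged %d of %d values (Q=%g)", flagged.sum(), n, Q)
    return OutlierReport(v, flagged, center, rsdr, Q, p)


def f_tail_prob(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution (regularized inc. beta)."""
    if df1 < 1 or df2 < 1:
        raise ParameterError("degrees of freedom must be >= 1")
    if F < 0:
        raise ParameterError("F must be non-negative")
    if math.isinf(F):
        return 0.0
    return float(special.fdtrc(df1, df2, F))


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on retained values.

    ``groups`` maps condition label to its sample.  Degenerate inputs (zero
    within-group variance) return sentinel results with a flag instead of
    raising, so batch simulations never crash: equal means give F=0, p=1;
    unequal means give F=inf, p=0.
    """
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 conditions")
    arrs = {k: np.asarray(g, dtype=float) for k, g in groups.items()}
    for k, g in arrs.items():
        if g.size < 2:
            raise InsufficientDataError(f"condition {k!r} has < 2 retained values")
    all_vals = np.concatenate(list(arrs.values()))
    grand = all_vals.mean()
    k = len(arrs)
    n_total = all_vals.size
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrs.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrs.values())
    df_b, df_w = k - 1, n_total - k
    means = {c: float(g.mean()) for c, g in arrs.items()}
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, means, degenerate=True)
        return AnovaResult(math.inf, df_b, df_w, 0.0, means, degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(float(F), df_b, df_w, f_tail_prob(F, df_b, df_w), means)


def pairwise_t(a, b, labels: tuple[str, str] = ("A", "B")) -> PairwiseResult:
    """Homoskedastic (pooled-variance) two-sample t-test, two-tailed.

    df = nA + nB - 2.  Zero pooled variance yields sentinel results: equal
    means → t=0, p=1; unequal means → infinite t with a degeneracy flag.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("pairwise t needs >= 2 retained values per side")
    df = x.size + y.size - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return PairwiseResult(labels, 0.0, df, 1.0, degenerate=True)
        return PairwiseResult(labels, math.copysign(math.inf, diff), df, 0.0,
                              degenerate=True)
    t = diff / math.sqrt(sp2 * (1 / x.size + 1 / y.size))
    p = 2.0 * float(sps.t.sf(abs(t), df=df))
    return PairwiseResult(labels, float(t), df, p)


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values).

    ``q_(i) = min_{j >= i} (p_(j) * m / j)``, capped at 1, mapped back to the
    input order.  ``m`` defaults to the number of supplied p-values; passing
    a larger ``m`` treats the supplied values as the smallest members of a
    bigger comparison family (the remaining members are assumed large enough
    not to enter any min chain).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p_values must be a non-empty 1-D collection")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ParameterError("family size m cannot be smaller than len(p_values)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ChamberPreference:
    """Chamber-preference model for one occupancy session set.

    Parameters
    ----------
    table
        An :class:`OccupancyTable` (or a long-format DataFrame with columns
        ``animal_id, condition, seconds``).
    session_s
        Session length in seconds (default 3600).

    Examples
    --------
    >>> model = ChamberPreference.from_dataframe(df)
    >>> res = model.fit(outlier_q=0.01, alpha=0.05)
    >>> print(res.summary())
    """

    def __init__(self, table: OccupancyTable | pd.DataFrame, session_s: float = 3600.0):
        if isinstance(table, pd.DataFrame):
            table = OccupancyTable(table, session_s=session_s)
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, session_s: float = 3600.0):
        return cls(OccupancyTable(df.copy(), session_s=session_s))

    @classmethod
    def from_csv(cls, path, session_s: float = 3600.0):
        return cls(OccupancyTable.from_csv(path, session_s=session_s))

    def fit(
        self,
        outlier_q: float = 0.01,
        alpha: float = 0.05,
        always_posthoc: bool = False,
    ) -> "PreferenceResults":
        """Run ROUT → ANOVA → (gated) pairwise t-tests → BH adjustment.

        Pairwise testing is gated on omnibus significance (p < alpha) unless
        ``always_posthoc`` is set.  The BH family is all C(k, 2) pairwise
        comparisons (m = 6 for four conditions).
        """
        conds = self.table.conditions
        outliers: dict[str, OutlierReport] = {}
        retained: dict[str, np.ndarray] = {}
        for c in conds:
            rep = rout_outliers(self.table.values_for(c), Q=outlier_q)
            outliers[c] = rep
            retained[c] = rep.retained

        anova = one_way_anova(retained)
        raw_means = {c: float(self.table.values_for(c).mean()) for c in conds}

        pairs = list(itertools.combinations(conds, 2))
        m = len(pairs)
        pairwise: list[PairwiseResult] = []
        posthoc_run = always_posthoc or anova.p < alpha
        if posthoc_run:
            for a, b in pairs:
                pairwise.append(pairwise_t(retained[a], retained[b], (a, b)))
            qs = bh_adjust([r.p_raw for r in pairwise], m=m)
            for r, q in zip(pairwise, qs):
                r.q = float(q)
                r.m = m
        return PreferenceResults(
            table=self.table,
            outliers=outliers,
            anova=anova,
            pairwise=pairwise,
            alpha=alpha,
            outlier_q=outlier_q,
            posthoc_run=posthoc_run,
            raw_group_means=raw_means,
        )


@dataclass
class PreferenceResults:
    """Fitted chamber-preference analysis.

    Carries the outlier reports, the omnibus ANOVA, the (possibly empty)
    pairwise family with BH-adjusted q-values, and both raw and
    outlier-excluded group means — flagged points are excluded from the
    tests but stay visible in the report.
    """

    table: OccupancyTable
    outliers: dict[str, OutlierReport]
    anova: AnovaResult
    pairwise: list[PairwiseResult]
    alpha: float
    outlier_q: float
    posthoc_run: bool
    raw_group_means: dict[str, float] = field(default_factory=dict)

    @property
    def group_means(self) -> dict[str, float]:
        """Per-condition means of retained (outlier-excluded) values."""
        return self.anova.group_means

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [r.pair for r in self.pairwise if r.q < self.alpha]

    def pairwise_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition_a": r.pair[0],
                "condition_b": r.pair[1],
                "t": r.t,
                "df": r.df,
                "p_raw": r.p_raw,
                "q": r.q,
                "m": r.m,
                "significant": bool(r.q < self.alpha),
            }
            for r in self.pairwise
        ]
        return pd.DataFrame(
            rows,
            columns=["condition_a", "condition_b", "t", "df", "p_raw", "q", "m",
                     "significant"],
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "outlier_q": self.outlier_q,
            "group_means_retained": self.group_means,
            "group_means_raw": self.raw_group_means,
            "outliers": {
                c: {
                    "flagged_values": rep.values[rep.flagged].tolist(),
                    "n_flagged": rep.n_flagged,
                    "robust_center": rep.robust_center,
                    "rsdr": rep.rsdr,
                }
                for c, rep in self.outliers.items()
            },
            "anova": {
                "F": self.anova.F,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
                "p": self.anova.p,
                "degenerate": self.anova.degenerate,
            },
            "posthoc_run": self.posthoc_run,
            "pairwise": self.pairwise_frame().to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        """Human-readable report in the spirit of statsmodels summaries."""
        lines = ["Chamber-preference analysis", "=" * 60]
        lines.append(f"conditions: {', '.join(self.table.conditions)}")
        n_flag = sum(r.n_flagged for r in self.outliers.values())
        lines.append(
            f"ROUT outliers (Q={self.outlier_q:g}): {n_flag} flagged "
            "(excluded from tests, retained in report)"
        )
        lines.append("")
        lines.append(f"{'condition':<16}{'mean (s)':>12}{'raw mean (s)':>14}{'n':>5}")
        for c in self.table.conditions:
            rep = self.outliers[c]
            lines.append(
                f"{c:<16}{self.group_means[c]:>12.1f}"
                f"{self.raw_group_means[c]:>14.1f}{rep.retained.size:>5d}"
            )
        a = self.anova
        lines.append("")
        lines.append(
            f"one-way ANOVA: F({a.df_between}, {a.df_within}) = {a.F:.4g}, "
            f"p = {a.p:.4g}" + ("  [degenerate]" if a.degenerate else "")
        )
        if self.posthoc_run:
            lines.append("")
            lines.append(
                f"{'pair':<28}{'t':>9}{'df':>5}{'p_raw':>10}{'q':>10}  sig(q<"
                f"{self.alpha:g})"
            )
            for r in self.pairwise:
                mark = "*" if r.q < self.alpha else ""
                lines.append(
                    f"{r.pair[0] + ' vs ' + r.pair[1]:<28}{r.t:>9.3f}{r.df:>5d}"
                    f"{r.p_raw:>10.4f}{r.q:>10.4f}  {mark}"
                )
        else:
            lines.append("post hoc tests not run (omnibus p >= alpha)")
        return "\n".join(lines)


def preference_pipeline(
    table: OccupancyTable | pd.DataFrame,
    Q: float = 0.01,
    alpha: float = 0.05,
    always_posthoc: bool = False,
) -> PreferenceResults:
    """Functional entry point: build the model and fit it in one call."""
    return ChamberPreference(table).fit(
        outlier_q=Q, alpha=alpha, always_posthoc=always_posthoc
    )
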