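"""Association and survival statistics.

Score-score / score-gene associations use Pearson or Spearman correlation
with two-sided p-values from the t transform, and Benjamini-Hochberg FDR
adjustment applied per explicitly declared family of tests.

Survival association between dichotomized signature groups and outcome uses
the Kaplan-Meier product-limit estimator, the two-group log-rank test, and
a binary-covariate Cox proportional-hazards model (Breslow tie handling by
default, Efron optional). Confidence intervals are 95% Wald intervals and
all p-values are two-sided.

Kaplan-Meier curves are fitted with lifelines; the Cox model is fitted with
statsmodels' PHReg; the log-rank test accumulates the hypergeometric
observed/expected terms directly so the per-group counts can be reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, StatError
from .io import SurvivalTable
from .scoring import ScoreVector


# ---------------------------------------------------------------------------
# Correlation + FDR
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    name_x: str
    name_y: str
    method: str
    coefficient: float
    p_value: float
    n: int
    q_value: float | None = None


def _paired_values(x, y) -> tuple[np.ndarray, np.ndarray, str, str]:
    def unpack(v, default):
        if isinstance(v, ScoreVector):
            return v.scores, v.signature_name or default
        if isinstance(v, pd.Series):
            return v, str(v.name) if v.name is not None else default
        return pd.Series(np.asarray(v, float)), default

    sx, nx = unpack(x, "x")
    sy, ny = unpack(y, "y")
    if isinstance(x, (ScoreVector, pd.Series)) and isinstance(y, (ScoreVector, pd.Series)):
        common = sx.index.intersection(sy.index)
        sx, sy = sx.loc[common], sy.loc[common]
    else:
        if len(sx) != len(sy):
            raise ValueError("x and y must have equal length")
        sy.index = sx.index
    return sx.to_numpy(float), sy.to_numpy(float), nx, ny


def correlate(
    x,
    y,
    method: str = "pearson",
    name_x: str | None = None,
    name_y: str | None = None,
) -> AssociationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Inputs may be ScoreVectors, Series (aligned on their index) or plain
    arrays; pairs with a missing value in either vector are dropped
    (pairwise-complete deletion). The q_value is left unset; fill it with
    :func:`adjust_family` over a declared family of results.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    ax, ay, nx, ny = _paired_values(x, y)
    mask = ~(np.isnan(ax) | np.isnan(ay))
    ax, ay = ax[mask], ay[mask]
    n = ax.size
    if n < 3:
        raise ValueError(f"need at least 3 paired samples, got {n}")
    if np.ptp(ax) == 0 or np.ptp(ay) == 0:
        raise StatError("correlation undefined: zero variance in an input vector")
    if method == "pearson":
        res = sps.pearsonr(ax, ay)
    else:
        res = sps.spearmanr(ax, ay)
    return AssociationResult(
        name_x=name_x or nx,
        name_y=name_y or ny,
        method=method,
        coefficient=float(res.statistic if hasattr(res, "statistic") else res[0]),
        p_value=float(res.pvalue if hasattr(res, "pvalue") else res[1]),
        n=int(n),
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list[AssociationResult]) -> list[AssociationResult]:
    """Fill q_values by BH over one declared family of association tests."""
    qs = adjust_bh([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [r.name_x for r in results],
            "y": [r.name_y for r in results],
            "method": [r.method for r in results],
            "coefficient": [r.coefficient for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "n": [r.n for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve: S(0) = 1, nonincreasing steps at
    distinct event times; ``at_risk`` / ``events`` recorded per time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    group: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(s: SurvivalTable, group: str | None = None) -> KMCurve:
    """Kaplan-Meier curve, optionally restricted to one group label."""
    df = s.data
    if group is not None:
        if s.group is None:
            raise ValueError("survival table has no group column")
        df = df[df["group"] == group]
        if df.empty:
            raise ValueError(f"no samples in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    tab = kmf.event_table  # indexed by observed times, includes t=0 row
    times = tab.index.to_numpy(float)
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    if times[0] != 0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
        tab = pd.concat(
            [pd.DataFrame({"at_risk": [len(df)], "observed": [0]}, index=[0.0]), tab]
        )
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(float),
        events=tab["observed"].to_numpy(float),
        group=group,
    )


def median_survival(k: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when never reached."""
    hit = np.nonzero(k.survival <= 0.5)[0]
    if hit.size == 0:
        return None
    return float(k.times[hit[0]])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    groups: tuple[str, str] = field(default=("", ""))


def _two_groups(s: SurvivalTable) -> tuple[pd.DataFrame, str, str]:
    if s.group is None:
        raise ValueError("survival table has no group column")
    labels = sorted(s.group.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    return s.data, labels[0], labels[1]


def logrank_test(s: SurvivalTable) -> LogrankResult:
    """Two-group log-rank test (asymptotic chi-square, 1 df).

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation given the risk sets; the variance
    accumulates the hypergeometric terms.
    """
    df, a, b = _two_groups(s)
    if int(df["event"].sum()) == 0:
        raise StatError("log-rank test undefined: no events observed")
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(int)
    in_a = (df["group"] == a).to_numpy(bool)
    o_a = e_a = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = float(at_risk.sum())
        n_a = float((at_risk & in_a).sum())
        deaths = (time == t) & (event == 1)
        d = float(deaths.sum())
        d_a = float((deaths & in_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    o_b = float(event.sum()) - o_a
    e_b = float(event.sum()) - e_a
    if v <= 0:
        raise StatError("log-rank variance is zero; test degenerate")
    chi2 = (o_a - e_a) ** 2 / v
    p = float(sps.chi2.sf(chi2, df=1))
    return LogrankResult(
        chi2=float(chi2),
        p_value=p,
        observed={a: o_a, b: o_b},
        expected={a: e_a, b: e_b},
        groups=(a, b),
    )


# ---------------------------------------------------------------------------
# Binary-covariate Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    log_hr: float
    hr: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n_events: int
    tie_method: str
    exposed_group: str


def cox_binary(
    s: SurvivalTable,
    tie_method: str = "breslow",
    exposed_label: str | None = None,
) -> CoxResult:
    """Cox PH fit of a single High-vs-Low group indicator.

    The hazard ratio compares the ``exposed`` group (indicator 1; "High"
    when present, otherwise the lexicographically later label) against the
    other group. Raises :class:`ConvergenceError` when the partial
    likelihood is unbounded (complete separation).
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError(f"unknown tie_method {tie_method!r}")
    df, a, b = _two_groups(s)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise StatError("Cox model undefined: no events observed")
    if exposed_label is None:
        exposed_label = "High" if "High" in (a, b) else b
    elif exposed_label not in (a, b):
        raise ValueError(f"exposed_label {exposed_label!r} not among groups {(a, b)}")
    x = (df["group"] == exposed_label).to_numpy(float)[:, None]
    model = PHReg(
        df["time"].to_numpy(float),
        x,
        status=df["event"].to_numpy(int),
        ties=tie_method,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=False)
        except Exception as exc:  # numerical blow-up inside the optimizer
            raise ConvergenceError(
                f"Cox partial-likelihood maximization failed: {exc}"
            ) from exc
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 50:
        raise ConvergenceError(
            "Cox partial likelihood appears unbounded (complete separation: "
            f"beta={beta:.3g}, se={se:.3g}); the hazard ratio is not estimable"
        )
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return CoxResult(
        log_hr=beta,
        hr=float(np.exp(beta)),
        se=se,
        ci95=(float(lo), float(hi)),
        p_value=float(fit.pvalues[0]),
        n_events=n_events,
        tie_method=tie_method,
        exposed_group=exposed_label,
    )
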