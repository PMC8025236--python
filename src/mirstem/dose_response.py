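"""Four-parameter logistic (4PL) dose-response fitting and relative potency.

The inhibition model is

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill),

decreasing in x for hill > 0 and passing through (top + bottom)/2 exactly
at x = ic50.  Fitting is unweighted least squares on log-concentration
internally (for conditioning), with deterministic initialization
(top = max y, bottom = min y, ic50 = geometric mid-concentration, hill = 1)
and box bounds ic50 in [min conc / 100, max conc * 100], hill in (0.1, 10].
Ascending (activation-shaped) data are detected automatically and handled
by reflecting the response, so the reported hill stays positive.

Relative potency between two conditions is estimated by a shared-shape
parallel fit: top, bottom and hill are common, each group gets its own
log-IC50, and the potency ratio is exp(difference of log-IC50s) with a
Wald CI from the difference's standard error.  Shape heterogeneity is
screened by an F-test of the constrained fit against the two free fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import four_pl

__all__ = [
    "FourPLModel",
    "FourPLResults",
    "PotencyRatio",
    "fit_4pl",
    "relative_potency",
    "fold_sensitivity",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a table cannot support a free 4PL fit."""


@dataclass
class FourPLResults:
    """Fitted 4PL parameters with standard errors and diagnostics."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    bse: dict
    ascending: bool = False
    degenerate: bool = False
    group: str | None = None
    n_obs: int = 0

    @property
    def params(self) -> dict:
        return {"top": self.top, "bottom": self.bottom, "ic50": self.ic50, "hill": self.hill}

    def predict(self, x):
        """Fitted viability at concentration(s) x."""
        sign = -1.0 if self.ascending else 1.0
        return four_pl(x, self.top, self.bottom, self.ic50, sign * self.hill)

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit" + (f" ({self.group})" if self.group else ""),
            f"  top    : {self.top:10.4g}  (se {self.bse.get('top', float('nan')):.3g})",
            f"  bottom : {self.bottom:10.4g}  (se {self.bse.get('bottom', float('nan')):.3g})",
            f"  IC50   : {self.ic50:10.4g}  (se {self.bse.get('ic50', float('nan')):.3g})",
            f"  hill   : {self.hill:10.4g}  (se {self.bse.get('hill', float('nan')):.3g})",
            f"  RSS    : {self.rss:.4g} on {self.n_obs} observations",
            f"  converged: {self.converged}"
            + (", ascending data (curve reflected)" if self.ascending else "")
            + (", DEGENERATE (flat response, IC50 unidentifiable)" if self.degenerate else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Plot fitted curve over a log-spaced concentration grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.ic50 / 1e3, self.ic50 * 1e3
        grid = np.geomspace(lo, hi, 200)
        ax.semilogx(grid, self.predict(grid), **kwargs)
        ax.set_xlabel("concentration (nM)")
        ax.set_ylabel("viability")
        return ax


def _prepare(dr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str | None]:
    required = {"concentration_nM", "viability"}
    missing = required - set(dr.columns)
    if missing:
        raise ValueError(f"dose-response table missing column(s): {sorted(missing)}")
    x = dr["concentration_nM"].to_numpy(dtype=float)
    y = dr["viability"].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if not np.isfinite(y).all():
        raise ValueError("viability values must be finite")
    if len(np.unique(x)) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {len(np.unique(x))}"
        )
    group = None
    if "group" in dr.columns:
        unique = dr["group"].unique()
        if len(unique) == 1:
            group = str(unique[0])
    return x, y, group


class FourPLModel:
    """Least-squares 4PL model for a concentration-viability table."""

    def __init__(self, concentration, viability, group: str | None = None):
        self.df = pd.DataFrame(
            {"concentration_nM": concentration, "viability": viability}
        )
        if group is not None:
            self.df["group"] = group
        self.x, self.y, self.group = _prepare(self.df)

    @classmethod
    def from_dataframe(cls, dr: pd.DataFrame, group: str | None = None):
        if group is not None and "group" in dr.columns:
            dr = dr[dr["group"] == group]
            if dr.empty:
                raise ValueError(f"no rows for group {group!r}")
        x, y, g = _prepare(dr)
        return cls(x, y, group=group or g)

    def fit(self, xtol: float = 1e-12, ftol: float = 1e-10) -> FourPLResults:
        x, y = self.x, self.y
        # Flat response: IC50 unidentifiable, return a flagged degenerate fit.
        if np.ptp(y) < 1e-12:
            return FourPLResults(
                top=float(y[0]), bottom=float(y[0]), ic50=float("nan"),
                hill=float("nan"), rss=0.0, converged=False,
                bse={}, degenerate=True, group=self.group, n_obs=len(y),
            )
        # Ascending data: reflect y so the canonical decreasing form applies.
        slope = stats.linregress(np.log(x), y).slope
        ascending = slope > 0
        y_fit = -y if ascending else y

        logx = np.log(x)
        theta0 = np.array([y_fit.max(), y_fit.min(),
                           0.5 * (logx.min() + logx.max()), 0.0])  # log ic50, log hill
        lb = [-np.inf, -np.inf, np.log(x.min() / 100.0), np.log(0.1)]
        ub = [np.inf, np.inf, np.log(x.max() * 100.0), np.log(10.0)]

        def resid(theta):
            top, bottom, log_ic50, log_hill = theta
            return four_pl(x, top, bottom, np.exp(log_ic50), np.exp(log_hill)) - y_fit

        sol = optimize.least_squares(resid, theta0, bounds=(lb, ub),
                                     xtol=xtol, ftol=ftol, method="trf")
        top, bottom, log_ic50, log_hill = sol.x
        ic50, hill = float(np.exp(log_ic50)), float(np.exp(log_hill))
        rss = float(2.0 * sol.cost)

        bse = {}
        dof = len(y) - 4
        if dof > 0:
            try:
                J = sol.jac
                cov_log = np.linalg.inv(J.T @ J) * (rss / dof)
                se = np.sqrt(np.diag(cov_log))
                # delta method back from log ic50 / log hill
                bse = {
                    "top": float(se[0]), "bottom": float(se[1]),
                    "ic50": float(se[2] * ic50), "hill": float(se[3] * hill),
                }
            except np.linalg.LinAlgError:
                bse = {}
        if ascending:
            top, bottom = -bottom, -top
            if bse:
                bse["top"], bse["bottom"] = bse["bottom"], bse["top"]
        if bottom > top:  # pathological; keep the invariant, note nothing else
            top, bottom = bottom, top
        return FourPLResults(
            top=float(top), bottom=float(bottom), ic50=ic50, hill=hill,
            rss=rss, converged=bool(sol.success), bse=bse,
            ascending=bool(ascending), group=self.group, n_obs=len(y),
        )


def fit_4pl(dr: pd.DataFrame, group: str | None = None) -> FourPLResults:
    """Fit a 4PL curve to a dose-response table (functional wrapper)."""
    return FourPLModel.from_dataframe(dr, group=group).fit()


@dataclass
class PotencyRatio:
    """IC50 ratio reference/test from a shared-shape parallel fit."""

    ratio: float
    ci_lower: float
    ci_upper: float
    log_ratio_se: float
    ic50_reference: float
    ic50_test: float
    independent_ratio: float  # ratio of separately fitted IC50s
    f_statistic: float
    f_p_value: float
    shape_warning: bool
    shared: dict  # shared top/bottom/hill of the constrained fit

    def summary(self) -> str:
        flag = "  [shape heterogeneity warning]" if self.shape_warning else ""
        return (
            f"Relative potency (reference/test IC50): {self.ratio:.3g} "
            f"[{self.ci_lower:.3g}, {self.ci_upper:.3g}]{flag}"
        )


def relative_potency(reference: pd.DataFrame, test: pd.DataFrame) -> PotencyRatio:
    """Shared-shape parallel 4PL fit giving the reference/test IC50 ratio.

    Both curves share top, bottom and hill; the test group's log-IC50 is
    the reference's plus a shift, and the reported ratio is exp(-shift)
    i.e. IC50_ref / IC50_test, >1 when the test condition is more potent
    (lower IC50).  If the constrained fit is much worse than the two free
    fits (F-test p < 0.01) a shape warning is attached, but the ratio is
    still reported.
    """
    x1, y1, _ = _prepare(reference)
    x2, y2, _ = _prepare(test)
    free1 = FourPLModel(x1, y1).fit()
    free2 = FourPLModel(x2, y2).fit()

    # Orientation must agree for a parallel fit on the raw scale.
    if free1.ascending != free2.ascending:
        raise ValueError("reference and test curves have opposite orientation")
    flip = free1.ascending
    y1f = -y1 if flip else y1
    y2f = -y2 if flip else y2

    x = np.concatenate([x1, x2])
    is_test = np.concatenate([np.zeros(len(x1), bool), np.ones(len(x2), bool)])
    yf = np.concatenate([y1f, y2f])

    top0 = max(y1f.max(), y2f.max())
    bot0 = min(y1f.min(), y2f.min())
    log_ic50_0 = 0.5 * (np.log(x.min()) + np.log(x.max()))
    theta0 = np.array([top0, bot0, log_ic50_0, 0.0, 0.0])  # ..., log hill, shift
    lb = [-np.inf, -np.inf, np.log(x.min() / 100.0), np.log(0.1), -np.inf]
    ub = [np.inf, np.inf, np.log(x.max() * 100.0), np.log(10.0), np.inf]

    def resid(theta):
        top, bottom, log_ic50_ref, log_hill, shift = theta
        log_ic50 = log_ic50_ref + shift * is_test
        return four_pl(x, top, bottom, np.exp(log_ic50), np.exp(log_hill)) - yf

    sol = optimize.least_squares(resid, theta0, bounds=(lb, ub), xtol=1e-12, ftol=1e-10)
    top, bottom, log_ic50_ref, log_hill, shift = sol.x
    rss_c = float(2.0 * sol.cost)
    n = len(yf)
    dof_c = n - 5

    se_shift = float("nan")
    if dof_c > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss_c / dof_c)
            se_shift = float(np.sqrt(cov[4, 4]))
        except np.linalg.LinAlgError:
            pass

    ic50_ref = float(np.exp(log_ic50_ref))
    ic50_test = float(np.exp(log_ic50_ref + shift))
    ratio = ic50_ref / ic50_test  # = exp(-shift)
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(-shift - z * se_shift)), float(np.exp(-shift + z * se_shift)))

    rss_free = free1.rss + free2.rss
    df_num = 3  # free fits have 8 params, constrained 5
    df_den = n - 8
    if df_den > 0 and rss_free > 0:
        f_stat = ((rss_c - rss_free) / df_num) / (rss_free / df_den)
        f_p = float(stats.f.sf(max(f_stat, 0.0), df_num, df_den))
    else:
        f_stat, f_p = float("nan"), float("nan")
    shape_warning = bool(np.isfinite(f_p) and f_p < 0.01)
    if shape_warning:
        warnings.warn(
            "constrained shared-shape fit is much worse than free fits "
            f"(F p = {f_p:.2g}); the potency ratio may be unreliable",
            stacklevel=2,
        )
    if flip:
        top, bottom = -bottom, -top
    return PotencyRatio(
        ratio=float(ratio),
        ci_lower=min(ci),
        ci_upper=max(ci),
        log_ratio_se=se_shift,
        ic50_reference=ic50_ref,
        ic50_test=ic50_test,
        independent_ratio=free1.ic50 / free2.ic50,
        f_statistic=float(f_stat),
        f_p_value=f_p,
        shape_warning=shape_warning,
        shared={"top": float(top), "bottom": float(bottom), "hill": float(np.exp(log_hill))},
    )


def fold_sensitivity(ic50_a: float, ic50_b: float) -> float:
    """Ratio of two IC50s, e.g. resistant over sensitive condition."""
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("IC50s must be positive")
    return ic50_a / ic50_b
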