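"""Stem/tumor-initiating cell frequency from limiting-dilution assays.

Under the single-hit model a graft of ``d`` cells produces a tumor with
probability ``1 - exp(-f * d)``, where ``f`` is the frequency of
tumor-initiating cells (TICs).  Taking the complementary log-log of that
probability gives ``log f + log d``, so ``f`` is estimated by a binomial
GLM with cloglog link, an intercept, and ``log(dose)`` as a fixed-unit
offset — the same construction ELDA uses.  The default 95% CI is Wald on
``log f`` back-transformed to the frequency scale; a profile-likelihood
interval is available.

Group comparison is a likelihood-ratio test (df = 1) of a shared frequency
against group-specific frequencies; adequacy of the single-hit assumption
is a Wald test of slope = 1 in a free-slope fit on ``log(dose)``.

Also provides the small phenotype formulas: sphere-forming efficiency and
caliper tumor volume (L * W^2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "LimitingDilutionModel",
    "FrequencyEstimate",
    "GroupComparison",
    "AdequacyResult",
    "estimate_frequency",
    "compare_frequencies",
    "single_hit_adequacy",
    "sphere_forming_efficiency",
    "tumor_volume",
]


class BoundaryError(ValueError):
    """Raised when an operation needs a non-boundary (interior) estimate."""


@dataclass
class FrequencyEstimate:
    """Fitted TIC frequency with 95% CI, ELDA-style.

    ``frequency`` is in cells^-1; ``one_in`` is the reciprocal rounded to
    whole cells ("1 in N").  ``boundary_flag`` is ``"none"`` for interior
    estimates, else ``"all_responded"`` (lower-bound-only) or
    ``"none_responded"`` (frequency 0, upper-bound-only).
    """

    frequency: float
    ci_lower: float
    ci_upper: float
    log_likelihood: float
    boundary_flag: str = "none"
    group: str | None = None
    ci_method: str = "wald"

    @property
    def one_in(self) -> float:
        return float("inf") if self.frequency == 0 else round(1.0 / self.frequency)

    def summary(self) -> str:
        lines = [
            "Single-hit limiting dilution estimate"
            + (f" ({self.group})" if self.group else ""),
            f"  frequency      : {self.frequency:.4g} per cell (1 in {self.one_in:g})",
            f"  95% CI         : [{self.ci_lower:.4g}, {self.ci_upper:.4g}] "
            f"({self.ci_method})",
            f"  log-likelihood : {self.log_likelihood:.4f}",
            f"  boundary       : {self.boundary_flag}",
        ]
        return "\n".join(lines)


@dataclass
class GroupComparison:
    fold_change: float  # f_a / f_b
    lr_statistic: float
    p_value: float
    frequency_a: FrequencyEstimate
    frequency_b: FrequencyEstimate

    def summary(self) -> str:
        return (
            f"Frequency ratio {self.fold_change:.3g} "
            f"(LRT = {self.lr_statistic:.3f}, df = 1, p = {self.p_value:.3g})"
        )


@dataclass
class AdequacyResult:
    slope: float
    se: float
    z: float
    p_value: float


def _validate_assay(df: pd.DataFrame) -> pd.DataFrame:
    required = {"dose", "n_tested", "n_responded"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing column(s): {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("assay table is empty")
    if (df["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    if ((df["n_responded"] < 0) | (df["n_responded"] > df["n_tested"])).any():
        raise ValueError("need 0 <= n_responded <= n_tested")
    return df


def _loglik(f: float, dose, n, k) -> float:
    p = 1.0 - np.exp(-f * dose)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(k * np.log(p) - f * dose * (n - k)))


class LimitingDilutionModel:
    """Single-hit model for limiting-dilution dose/response counts.

    Parameters
    ----------
    dose, n_tested, n_responded : array-like
        Cells injected per graft, grafts tested, grafts responding.
    group : str, optional
        Label carried through to results.

    Examples
    --------
    >>> model = LimitingDilutionModel([1000], [10], [5])
    >>> res = model.fit()
    >>> round(res.one_in)
    1443
    """

    def __init__(self, dose, n_tested, n_responded, group: str | None = None):
        self.data = _validate_assay(
            pd.DataFrame(
                {
                    "dose": np.asarray(dose, dtype=float),
                    "n_tested": np.asarray(n_tested, dtype=int),
                    "n_responded": np.asarray(n_responded, dtype=int),
                }
            )
        )
        self.group = group

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group: str | None = None):
        """Build from a table with columns group/dose/n_tested/n_responded."""
        if group is not None and "group" in df.columns:
            df = df[df["group"] == group]
            if df.empty:
                raise ValueError(f"no rows for group {group!r}")
        elif group is None and "group" in df.columns:
            unique = df["group"].unique()
            if len(unique) == 1:
                group = str(unique[0])
        return cls(df["dose"], df["n_tested"], df["n_responded"], group=group)

    # -- fitting -----------------------------------------------------------

    def _glm(self, free_slope: bool = False):
        d = self.data
        endog = np.column_stack([d["n_responded"], d["n_tested"] - d["n_responded"]])
        logd = np.log(d["dose"].to_numpy())
        link = sm.families.links.CLogLog()
        if free_slope:
            exog = sm.add_constant(logd)
            return sm.GLM(endog, exog, family=sm.families.Binomial(link))
        exog = np.ones((len(d), 1))
        return sm.GLM(endog, exog, family=sm.families.Binomial(link), offset=logd)

    def fit(self, alpha: float = 0.05, ci_method: str = "wald") -> FrequencyEstimate:
        """Maximum-likelihood frequency with a 95% (or 1-alpha) CI.

        Saturated assays (all or no grafts responding) cannot support an
        interior MLE; they return a one-sided bound with the matching
        ``boundary_flag`` instead of failing.
        """
        d = self.data
        dose = d["dose"].to_numpy()
        n = d["n_tested"].to_numpy()
        k = d["n_responded"].to_numpy()
        z = stats.norm.ppf(1 - alpha / 2)
        z1 = stats.norm.ppf(1 - alpha)

        if k.sum() == 0:
            # P(no responses) >= alpha bounds f from above (one-sided).
            upper = -np.log(alpha) / float((dose * n).sum())
            return FrequencyEstimate(0.0, 0.0, upper, _loglik(0.0, dose, n, k),
                                     "none_responded", self.group, "one-sided")
        if k.sum() == n.sum():
            # P(all respond | f) = alpha bounds f from below (one-sided).
            def logp_all(logf):
                p = 1.0 - np.exp(-np.exp(logf) * dose)
                return float(np.sum(n * np.log(np.clip(p, 1e-300, 1)))) - np.log(alpha)

            lo = optimize.brentq(logp_all, np.log(1e-12 / dose.max()), np.log(1e6 / dose.min()))
            return FrequencyEstimate(np.inf, float(np.exp(lo)), np.inf,
                                     0.0, "all_responded", self.group, "one-sided")

        with warnings.catch_warnings():
            # a single dose level leaves zero residual df; the scale is not used
            warnings.simplefilter("ignore", RuntimeWarning)
            res = self._glm().fit()
        logf = float(res.params[0])
        se = float(res.bse[0])
        f = float(np.exp(logf))
        if ci_method == "wald":
            lo, hi = np.exp(logf - z * se), np.exp(logf + z * se)
        elif ci_method == "profile":
            lo, hi = self._profile_ci(logf, dose, n, k, alpha)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        return FrequencyEstimate(
            f, float(lo), float(hi), _loglik(f, dose, n, k), "none", self.group, ci_method
        )

    def _profile_ci(self, logf_hat, dose, n, k, alpha):
        ll_hat = _loglik(np.exp(logf_hat), dose, n, k)
        crit = stats.chi2.ppf(1 - alpha, df=1) / 2

        def drop(logf):
            return ll_hat - _loglik(np.exp(logf), dose, n, k) - crit

        lo = optimize.brentq(drop, logf_hat - 20, logf_hat)
        hi = optimize.brentq(drop, logf_hat, logf_hat + 20)
        return np.exp(lo), np.exp(hi)

    def fit_free_slope(self):
        """GLM with a free slope on log(dose) (adequacy diagnostics)."""
        if self.data["dose"].nunique() < 2:
            raise ValueError("slope unidentifiable with a single dose level")
        return self._glm(free_slope=True).fit()


def estimate_frequency(assay: pd.DataFrame, group: str | None = None,
                       ci_method: str = "wald") -> FrequencyEstimate:
    """Estimate the TIC frequency from a take table (functional wrapper)."""
    return LimitingDilutionModel.from_dataframe(assay, group=group).fit(ci_method=ci_method)


def compare_frequencies(a: pd.DataFrame, b: pd.DataFrame) -> GroupComparison:
    """Likelihood-ratio test of equal frequencies between two assays.

    Fits group-specific frequencies and a pooled shared frequency; the LRT
    statistic (2 * difference in log-likelihood) is referred to chi2(1).
    Boundary assays (fully saturated either way) are rejected with a
    BoundaryError pointing at the boundary handling in ``fit``.
    """
    model_a = LimitingDilutionModel.from_dataframe(a)
    model_b = LimitingDilutionModel.from_dataframe(b)
    fit_a = model_a.fit()
    fit_b = model_b.fit()
    for label, fit in (("a", fit_a), ("b", fit_b)):
        if fit.boundary_flag != "none":
            raise BoundaryError(
                f"assay {label} is at the boundary ({fit.boundary_flag}); "
                "only one-sided bounds are available — see FrequencyEstimate"
            )
    pooled = pd.concat([model_a.data, model_b.data], ignore_index=True)
    fit_pool = LimitingDilutionModel(
        pooled["dose"], pooled["n_tested"], pooled["n_responded"]
    ).fit()
    lr = 2.0 * (fit_a.log_likelihood + fit_b.log_likelihood - fit_pool.log_likelihood)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return GroupComparison(
        fold_change=fit_a.frequency / fit_b.frequency,
        lr_statistic=float(lr),
        p_value=p,
        frequency_a=fit_a,
        frequency_b=fit_b,
    )


def single_hit_adequacy(assay: pd.DataFrame) -> AdequacyResult:
    """Wald test of the single-hit assumption (dose-response slope = 1).

    Fits the cloglog regression with a free coefficient on log(dose); under
    the single-hit model the coefficient is exactly 1.  Needs >= 2 distinct
    dose levels.
    """
    model = LimitingDilutionModel.from_dataframe(assay)
    res = model.fit_free_slope()
    slope = float(res.params[1])
    se = float(res.bse[1])
    z = (slope - 1.0) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return AdequacyResult(slope=slope, se=se, z=z, p_value=p)


def sphere_forming_efficiency(n_spheres: int, n_plated: int) -> float:
    """SFE as a percentage: 100 * spheres formed / cells plated."""
    if n_plated <= 0:
        raise ValueError("n_plated must be > 0")
    return 100.0 * n_spheres / n_plated


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume L * W^2 / 2 (mm^3), L = longest diameter.

    If the inputs are reversed (width > length) they are swapped with a
    warning rather than rejected.
    """
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        warnings.warn("width > length; swapping inputs", stacklevel=2)
        length, width = width, length
    return length * width**2 / 2.0
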