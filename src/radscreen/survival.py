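"""Clonogenic survival statistics.

The colony formation assay measures reproductive survival of single cells:
a known number of cells is plated, colonies are counted after 1-2 weeks,
and the plating efficiency (PE) and surviving fraction (SF) are derived,

    PE = mean colony number / cells plated
    SF(D) = PE(D) / PE(0 Gy)

Dose-response curves are summarised by the linear-quadratic (LQ) model

    SF(D) = exp(-(alpha*D + beta*D**2)),  alpha [Gy^-1] >= 0, beta [Gy^-2] >= 0,

fitted here by non-negative least squares on log survival.  Radiosensitization
between two conditions is quantified by the sensitization enhancement ratio at
10% survival (SER10), the ratio of the doses at which each fitted curve
crosses SF = 0.10.  Whole-curve differences are tested by two-way ANOVA with
dose and condition as categorical factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class OverUnitySurvivalWarning(UserWarning):
    """A surviving fraction exceeded 1 (kept as-is, not clipped)."""


def lq_survival(dose, alpha: float, beta: float):
    """Linear-quadratic surviving fraction exp(-(alpha*D + beta*D^2))."""
    d = np.asarray(dose, dtype=float)
    out = np.exp(-(alpha * d + beta * d**2))
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def plating_efficiency(colonies, cells_plated: int) -> float:
    """Mean colony count over replicate wells divided by cells plated."""
    counts = np.asarray(colonies, dtype=float)
    if counts.size == 0:
        raise ValueError("plating_efficiency requires at least one replicate well")
    if (counts < 0).any():
        raise ValueError("colony counts must be non-negative")
    if cells_plated <= 0:
        raise ValueError("cells_plated must be > 0")
    return float(counts.mean() / cells_plated)


def surviving_fraction(pe_dose: float, pe_0gy: float) -> float:
    """SF = PE at dose / PE at 0 Gy.

    Values above 1 are biologically possible with noisy counts; they are
    returned unchanged but flagged with :class:`OverUnitySurvivalWarning`
    because clipping them would bias downstream fits.
    """
    if pe_0gy <= 0:
        raise ValueError("pe_0gy must be > 0: unirradiated plating efficiency of "
                         "zero makes the experiment uninterpretable")
    if pe_dose < 0:
        raise ValueError("pe_dose must be >= 0")
    sf = pe_dose / pe_0gy
    if sf > 1:
        warnings.warn(f"surviving fraction {sf:.4g} exceeds 1 (not clipped)",
                      OverUnitySurvivalWarning, stacklevel=2)
    return float(sf)


@dataclass
class SurvivalCurve:
    """Dose -> surviving-fraction points for one condition.

    ``points`` has columns ``dose``, ``sf``, ``se`` (NaN when a single well)
    and ``n_wells``; by construction there is exactly one 0 Gy point with
    sf = 1.
    """

    condition: str
    points: pd.DataFrame

    def __post_init__(self):
        pts = self.points
        zero = pts[pts["dose"] == 0]
        if len(zero) != 1 or not math.isclose(float(zero["sf"].iloc[0]), 1.0):
            raise ValueError("a SurvivalCurve needs exactly one 0 Gy point with sf = 1")

    @classmethod
    def from_wells(cls, wells: pd.DataFrame, condition: str = "") -> "SurvivalCurve":
        """Build a curve from well records (``dose``, ``cells_plated``, ``colonies``).

        PE is computed per dose over replicate wells; SF is the ratio to the
        0 Gy PE.  The per-dose standard error is that of the per-well SF.
        """
        if 0 not in set(wells["dose"]):
            raise ValueError("well records must include 0 Gy wells to define SF")
        pe0 = plating_efficiency(wells.loc[wells["dose"] == 0, "colonies"],
                                 int(wells.loc[wells["dose"] == 0, "cells_plated"].iloc[0]))
        if pe0 <= 0:
            raise ValueError("0 Gy plating efficiency is zero; SF undefined")
        rows = []
        for dose, grp in wells.groupby("dose"):
            per_well = grp["colonies"].to_numpy(float) / grp["cells_plated"].to_numpy(float) / pe0
            sf = 1.0 if dose == 0 else float(per_well.mean())
            se = float(per_well.std(ddof=1) / math.sqrt(len(per_well))) if len(per_well) > 1 else float("nan")
            rows.append({"dose": float(dose), "sf": sf, "se": se, "n_wells": len(grp),
                         "total_colonies": int(grp["colonies"].sum())})
        pts = pd.DataFrame(rows).sort_values("dose", ignore_index=True)
        over = pts[(pts["dose"] > 0) & (pts["sf"] > 1)]
        if len(over):
            warnings.warn(
                f"surviving fraction exceeds 1 at dose(s) {over['dose'].tolist()} (not clipped)",
                OverUnitySurvivalWarning, stacklevel=2)
        return cls(condition=condition, points=pts)


class LinearQuadraticModel:
    """LQ dose-response model fitted on log survival.

    Parameters
    ----------
    dose, sf : array-like
        Paired dose (Gy) and surviving-fraction observations.  All sf must be
        strictly positive (the model is linear in -ln SF); sf > 1 is allowed
        but flagged upstream.
    weights : array-like, optional
        Per-point weights for weighted least squares (e.g. 1/se**2).
        Unweighted by default.
    cov : (m, m) array, optional
        Known error covariance of -ln sf at the *positive-dose* points, in
        dose order.  When given, the fit is generalised least squares with
        Cholesky whitening and the parameter covariance is the exact
        (X' Sigma^-1 X)^-1 — no residual variance is estimated.  This is how
        Poisson colony counts are handled: all SF points share the 0 Gy
        plating-efficiency denominator, so their log errors are correlated
        (see :func:`fit_linear_quadratic` ``weights='poisson'``).
    fix_beta : bool
        Constrain beta = 0 and fit the purely exponential model.

    The fit solves ``min ||sqrt(w) (X b + ln sf)||`` subject to b >= 0 with
    ``X = [D, D^2]`` via non-negative least squares, so alpha and beta cannot
    go negative (non-physical).  Without ``cov`` the parameter covariance is
    the usual linearised-model estimate s^2 (X'WX)^-1, where s^2 counts only
    informative points (the structural 0 Gy anchor with sf = 1 has a zero
    residual by construction and is excluded from the degrees of freedom).
    """

    def __init__(self, dose, sf, weights=None, cov=None, fix_beta: bool = False):
        dose = np.asarray(dose, dtype=float)
        sf = np.asarray(sf, dtype=float)
        if dose.shape != sf.shape or dose.ndim != 1:
            raise ValueError("dose and sf must be 1-D arrays of equal length")
        bad = np.nonzero(sf <= 0)[0]
        if bad.size:
            pts = ", ".join(f"(D={dose[i]:g}, sf={sf[i]:g})" for i in bad)
            raise ValueError(f"surviving fractions must be > 0 to fit on ln SF; got {pts}")
        min_doses = 2 if fix_beta else 3
        if np.unique(dose).size < min_doses:
            raise ValueError(f"need >= {min_doses} distinct dose points (including 0 Gy)")
        if 0 not in dose:
            raise ValueError("the 0 Gy anchor point is required")
        self.dose = dose
        self.sf = sf
        self.fix_beta = fix_beta
        self.cov = None if cov is None else np.asarray(cov, dtype=float)
        if self.cov is not None:
            m = int((dose > 0).sum())
            if self.cov.shape != (m, m):
                raise ValueError(f"cov must be ({m}, {m}) for the positive-dose points")
        if weights is None:
            self.weights = np.ones_like(dose)
        else:
            self.weights = np.asarray(weights, dtype=float)
            if (self.weights <= 0).any():
                raise ValueError("weights must be positive")

    def fit(self) -> "LQFit":
        y = -np.log(self.sf)
        if self.fix_beta:
            X = self.dose[:, None]
        else:
            X = np.column_stack([self.dose, self.dose**2])
        n, p = len(y), X.shape[1]
        if self.cov is not None:
            # known-covariance GLS on the positive-dose points
            order = np.argsort(self.dose)
            pos = order[self.dose[order] > 0]
            Xp, yp = X[pos], y[pos]
            from scipy.linalg import solve_triangular
            L = np.linalg.cholesky(self.cov)
            Xw = solve_triangular(L, Xp, lower=True)
            yw = solve_triangular(L, yp, lower=True)
            coef, _ = optimize.nnls(Xw, yw)
            ssr = float(np.sum((yw - Xw @ coef) ** 2))
            cov_p = np.linalg.pinv(Xw.T @ Xw)
        else:
            sw = np.sqrt(self.weights)
            coef, _ = optimize.nnls(X * sw[:, None], y * sw)
            resid = y - X @ coef
            ssr = float(np.sum(self.weights * resid**2))
            structural = int(((self.dose == 0) & (y == 0)).sum())
            dof = (n - structural) - p
            s2 = ssr / dof if dof > 0 else float("nan")
            xtx = (X * self.weights[:, None]).T @ X
            cov_p = s2 * np.linalg.pinv(xtx)
        if self.fix_beta:
            alpha, beta = float(coef[0]), 0.0
            cov = np.zeros((2, 2))
            cov[0, 0] = cov_p[0, 0]
        else:
            alpha, beta = float(coef[0]), float(coef[1])
            cov = cov_p
        return LQFit(alpha=alpha, beta=beta, cov_params=cov, residual_ss=ssr,
                     n_points=n, model=self)


@dataclass
class LQFit:
    """Results of a linear-quadratic fit.

    ``alpha`` (Gy^-1) and ``beta`` (Gy^-2) are both constrained non-negative;
    ``cov_params`` is the 2x2 covariance of (alpha, beta) from the linearised
    log-survival model.
    """

    alpha: float
    beta: float
    cov_params: np.ndarray
    residual_ss: float
    n_points: int
    model: LinearQuadraticModel | None = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (alpha, beta)."""
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    def sf(self, dose):
        """Predicted surviving fraction at ``dose``."""
        return lq_survival(dose, self.alpha, self.beta)

    def dose_at_sf(self, sf_target: float) -> float:
        return dose_at_sf(self, sf_target)

    def conf_int(self, nsig: float = 2.0) -> np.ndarray:
        """(2, 2) array of +-nsig standard-error intervals for alpha and beta."""
        se = self.bse
        return np.column_stack([self.params - nsig * se, self.params + nsig * se])

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Linear-quadratic survival fit",
            "=============================",
            f"n points:     {self.n_points}",
            f"alpha (Gy^-1): {self.alpha:.5f}  (se {se[0]:.5f})",
            f"beta  (Gy^-2): {self.beta:.5f}  (se {se[1]:.5f})",
            f"residual SS (ln SF): {self.residual_ss:.5g}",
        ]
        if self.alpha + self.beta > 0:
            lines.append(f"D(SF=0.10):   {self.dose_at_sf(0.10):.4f} Gy")
        return "\n".join(lines)


def fit_linear_quadratic(curve: SurvivalCurve | pd.DataFrame, weights=None,
                         fix_beta: bool = False) -> LQFit:
    """Fit the LQ model to a :class:`SurvivalCurve` (or its points frame).

    ``weights`` options: ``None`` (unweighted, the default), ``"se"``
    (1/se^2 of the SF points, propagated to the log scale as (sf/se)^2),
    ``"poisson"`` (inverse delta-method variance of ln SF from total colony
    counts, 1/(1/C_D + 1/C_0) — appropriate for Poisson-distributed counts),
    or an explicit array of log-scale weights.
    """
    pts = curve.points if isinstance(curve, SurvivalCurve) else curve
    w = None
    if weights == "se":
        w = (pts["sf"].to_numpy(float) / pts["se"].to_numpy(float)) ** 2
        w[~np.isfinite(w)] = np.nanmax(w[np.isfinite(w)])
    elif weights == "poisson":
        pts = pts.sort_values("dose")
        c = pts.loc[pts["dose"] > 0, "total_colonies"].to_numpy(float)
        c0 = float(pts.loc[pts["dose"] == 0, "total_colonies"].iloc[0])
        # ln SF errors: independent Poisson term per dose plus the shared
        # 0 Gy plating-efficiency denominator
        sigma = np.diag(1.0 / c) + 1.0 / c0
        return LinearQuadraticModel(pts["dose"].to_numpy(float),
                                    pts["sf"].to_numpy(float),
                                    cov=sigma, fix_beta=fix_beta).fit()
    elif weights is not None:
        w = weights
    return LinearQuadraticModel(pts["dose"].to_numpy(float),
                                pts["sf"].to_numpy(float),
                                weights=w, fix_beta=fix_beta).fit()


def dose_at_sf(fit: LQFit, sf_target: float) -> float:
    """Dose (Gy) at which the fitted curve crosses ``sf_target``.

    Solves beta*D^2 + alpha*D + ln(sf_target) = 0 for the unique positive
    root; reduces to -ln(sf_target)/alpha when beta = 0.
    """
    if not 0 < sf_target < 1:
        raise ValueError("sf_target must be strictly between 0 and 1")
    a, b = fit.alpha, fit.beta
    if a == 0 and b == 0:
        raise ValueError("alpha = beta = 0: flat curve never reaches the target")
    ln_s = -math.log(sf_target)  # > 0
    # stable form of the positive quadratic root; reduces to ln_s/a as b -> 0
    return 2 * ln_s / (a + math.sqrt(a * a + 4 * b * ln_s))


def ser10(control_fit: LQFit, treated_fit: LQFit, sf_target: float = 0.10) -> float:
    """Sensitization enhancement ratio at 10% survival.

    Ratio of control to treated dose producing SF = ``sf_target``; values > 1
    indicate radiosensitization of the treated condition.
    """
    return dose_at_sf(control_fit, sf_target) / dose_at_sf(treated_fit, sf_target)


@dataclass
class CurveAnovaResult:
    p_condition: float
    p_interaction: float | None
    table: pd.DataFrame

    def __iter__(self):  # allow tuple unpacking
        return iter((self.p_condition, self.p_interaction, self.table))


def compare_curves_anova(data: pd.DataFrame, sf_col: str = "sf",
                         dose_col: str = "dose", condition_col: str = "condition",
                         log_sf: bool = False, interaction: bool = True) -> CurveAnovaResult:
    """Two-way fixed-effects ANOVA comparing survival curves.

    Survival is the dependent variable; dose and condition are categorical
    factors.  The condition main-effect p-value is the reported curve
    difference; the dose x condition interaction (shape difference) is
    included by default.  ``log_sf`` switches the response to ln SF.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data[[sf_col, dose_col, condition_col]].rename(
        columns={sf_col: "sf", dose_col: "dose", condition_col: "condition"}).copy()
    doses = df["dose"].unique()
    conds = df["condition"].unique()
    if len(doses) < 2 or len(conds) < 2:
        raise ValueError("need >= 2 doses and >= 2 conditions")
    counts = df.groupby(["dose", "condition"], observed=True).size()
    missing = [(d, c) for d in doses for c in conds if (d, c) not in counts.index]
    if missing:
        raise ValueError(f"empty dose x condition cells: {missing}")
    if log_sf:
        if (df["sf"] <= 0).any():
            raise ValueError("log transform requires sf > 0")
        df["sf"] = np.log(df["sf"])
    rhs = "C(dose) * C(condition)" if interaction else "C(dose) + C(condition)"
    fitted = smf.ols(f"sf ~ {rhs}", data=df).fit()
    if fitted.df_resid <= 0:
        raise ValueError("no residual degrees of freedom; need >= 2 replicates per cell")
    table = anova_lm(fitted, typ=2)
    p_cond = float(table.loc["C(condition)", "PR(>F)"])
    p_int = float(table.loc["C(dose):C(condition)", "PR(>F)"]) if interaction else None
    return CurveAnovaResult(p_condition=p_cond, p_interaction=p_int, table=table)


def plot_survival_curves(curves, fits=None, ax=None, dose_grid=None):
    """Plot SF points (log scale) with optional fitted LQ curves.

    ``curves`` is an iterable of :class:`SurvivalCurve`; ``fits`` an optional
    parallel iterable of :class:`LQFit`.  Returns the matplotlib axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fits = list(fits) if fits is not None else [None] * len(list(curves))
    for curve, fit in zip(curves, fits):
        pts = curve.points
        line = ax.errorbar(pts["dose"], pts["sf"], yerr=pts["se"], fmt="o",
                           label=curve.condition, capsize=3)
        if fit is not None:
            grid = dose_grid if dose_grid is not None else np.linspace(0, pts["dose"].max(), 100)
            ax.plot(grid, fit.sf(grid), "-", color=line.lines[0].get_color())
    ax.set_yscale("log")
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Surviving fraction")
    ax.legend()
    return ax
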