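"""Compositional group comparison and isotemporal-substitution modelling.

Two model classes, organised like statsmodels (a model built from data whose
``fit()`` returns a results object):

* :class:`CompositionalMANCOVA` -- multivariate linear model of the ilr
  coordinates on group + covariates; the group effect is tested with
  Wilks' lambda and Rao's F approximation.
* :class:`IlrRegression` -- OLS of an outcome (motor competence) on the ilr
  coordinates + covariates.  Its results expose the composition-block Type
  II Wald chi-square test and isotemporal-substitution predictions with
  delta-method (or bootstrap) confidence intervals.

Plus two standalone procedures: stratified bootstrap percentile intervals
for between-group log-ratio differences of compositional means
(back-transformed to percentages), and the Pearson chi-square test for
lifestyle contingency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import DEFAULT_PARTS, IlrBasis, close, compositional_mean, ilr, pivot_basis

__all__ = [
    "CompositionalMANCOVA",
    "MANCOVAResults",
    "IlrRegression",
    "IlrRegressionResults",
    "GroupDifferenceResult",
    "bootstrap_logratio_differences",
    "chi_square_table",
    "mancova_group_test",
    "fit_ilr_regression",
    "wald_type2_composition_test",
    "isotemporal_substitution",
]


def _design(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the guilty columns: those whose removal restores full rank
        guilty = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is singular; collinear columns: {guilty}")


# ---------------------------------------------------------------------------
# compositional MANCOVA


@dataclass
class MANCOVAResults:
    """Wilks' lambda test of the group effect on the ilr coordinates."""

    wilks_lambda: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    n_obs: int
    n_coords: int

    def summary(self) -> str:
        return (
            "Compositional MANCOVA (group effect on ilr coordinates)\n"
            f"  n = {self.n_obs}, coordinates = {self.n_coords}\n"
            f"  Wilks' lambda = {self.wilks_lambda:.4f}\n"
            f"  F({self.df_num:.0f}, {self.df_den:.0f}) = {self.f_value:.3f}, "
            f"p = {self.p_value:.4f}"
        )


class CompositionalMANCOVA:
    """Multivariate analysis of covariance on ilr coordinates.

    The D-part compositions are mapped to D-1 ilr coordinates, which become
    the multivariate response in a linear model on group membership plus
    covariates.  ``fit()`` tests the group effect (adjusted for the
    covariates) with Wilks' lambda and Rao's F approximation.  The test is
    invariant to the ilr basis chosen, because any two orthonormal bases
    differ by a rotation of the response space.
    """

    def __init__(
        self,
        compositions,
        group,
        covariates: pd.DataFrame | None = None,
        basis: IlrBasis | None = None,
        parts=DEFAULT_PARTS,
    ):
        comp = np.asarray(compositions, dtype=float)
        self.basis = basis or pivot_basis(parts, parts[0])
        self.Y = ilr(comp, self.basis)
        group = np.asarray(group)
        self.group_levels = sorted(pd.unique(group))
        if len(self.group_levels) < 2:
            raise ValueError("need at least 2 groups")
        # treatment-coded dummies, first level is the reference
        G = np.column_stack([(group == g).astype(float) for g in self.group_levels[1:]])
        n = len(group)
        Xc, names = _design(covariates, n)
        self.X_full = np.column_stack([Xc, G])
        self.names = names + [f"group[{g}]" for g in self.group_levels[1:]]
        self.X_reduced = Xc
        self.q = G.shape[1]
        if n <= self.X_full.shape[1] + self.Y.shape[1]:
            raise ValueError("too few observations for the number of predictors")
        _check_full_rank(self.X_full, self.names)

    @staticmethod
    def _residual_sscp(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    def fit(self) -> MANCOVAResults:
        E = self._residual_sscp(self.X_full, self.Y)
        E_red = self._residual_sscp(self.X_reduced, self.Y)
        H = E_red - E
        p = self.Y.shape[1]
        q = self.q
        n = self.Y.shape[0]
        nu_e = n - self.X_full.shape[1]
        lam = np.linalg.det(E) / np.linalg.det(E + H)
        # Rao's F approximation for Wilks' lambda
        s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
        m = nu_e - (p - q + 1) / 2.0
        df1 = p * q
        df2 = m * s - p * q / 2.0 + 1.0
        lam_s = lam ** (1.0 / s)
        f = (1.0 - lam_s) / lam_s * df2 / df1
        pval = stats.f.sf(f, df1, df2)
        return MANCOVAResults(
            wilks_lambda=float(lam),
            f_value=float(f),
            df_num=float(df1),
            df_den=float(df2),
            p_value=float(pval),
            n_obs=n,
            n_coords=p,
        )


def mancova_group_test(
    compositions, group, covariates=None, basis=None, parts=DEFAULT_PARTS
) -> MANCOVAResults:
    """Functional wrapper: fit a :class:`CompositionalMANCOVA` and test group."""
    return CompositionalMANCOVA(compositions, group, covariates, basis, parts).fit()


# ---------------------------------------------------------------------------
# ilr outcome regression + isotemporal substitution


@dataclass
class IlrRegressionResults:
    """OLS results for outcome ~ ilr coordinates + covariates."""

    model: "IlrRegression"
    params: pd.Series
    cov_params: pd.DataFrame
    df_resid: float
    rsquared: float
    resid: np.ndarray = field(repr=False)

    @property
    def ilr_names(self) -> list[str]:
        return self.model.basis.coord_names()

    def composition_test(self) -> tuple[float, int, float]:
        """Type II Wald chi-square for the whole composition block.

        chi2 = beta' V^-1 beta over the ilr coefficients (df = number of
        coordinates); invariant to the pivot chosen for the basis because a
        basis change rotates beta and V together.
        """
        idx = [self.params.index.get_loc(c) for c in self.ilr_names]
        b = self.params.iloc[idx].to_numpy()
        V = self.cov_params.iloc[idx, idx].to_numpy()
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as e:
            raise ValueError("singular coefficient covariance") from e
        df = len(idx)
        return chi2, df, float(stats.chi2.sf(chi2, df))

    def isotemporal(
        self,
        from_part: str,
        to_part: str,
        minutes_grid=None,
        reference=None,
        alpha: float = 0.05,
        method: str = "delta",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Predicted outcome change for pairwise time reallocations.

        For each offset t, t minutes are moved from ``from_part`` to
        ``to_part`` at the reference composition (default: the sample
        compositional mean of the fitted data) with the remaining behaviours
        held constant; the predicted change is the ilr displacement dotted
        with the fitted composition coefficients.  CIs come from the delta
        method on the coefficient covariance with a t reference
        (``method="delta"``), or from refitting on bootstrap resamples
        (``method="bootstrap"``).  Offsets that would drive a part to zero
        or below are rejected.
        """
        basis = self.model.basis
        parts = list(basis.parts)
        for p in (from_part, to_part):
            if p not in parts:
                raise ValueError(f"unknown part {p!r}")
        if minutes_grid is None:
            minutes_grid = np.arange(-30, 31, 5)
        minutes_grid = np.asarray(minutes_grid, dtype=float)
        ref = (
            compositional_mean(self.model.comp, total=self.model.total)
            if reference is None
            else close(np.asarray(reference, float), self.model.total)
        )
        i, j = parts.index(from_part), parts.index(to_part)
        z0 = ilr(ref, basis)
        dz = np.zeros((len(minutes_grid), basis.n_coords))
        for k, t in enumerate(minutes_grid):
            new = ref.copy()
            new[i] -= t
            new[j] += t
            if new[i] <= 0 or new[j] <= 0:
                raise ValueError(
                    f"reallocating {t:+g} min drives a part to zero "
                    f"(reference {from_part}={ref[i]:.1f}, {to_part}={ref[j]:.1f})"
                )
            dz[k] = ilr(new, basis) - z0

        idx = [self.params.index.get_loc(c) for c in self.ilr_names]
        b = self.params.iloc[idx].to_numpy()
        delta = dz @ b
        if method == "delta":
            V = self.cov_params.iloc[idx, idx].to_numpy()
            se = np.sqrt(np.einsum("ij,jk,ik->i", dz, V, dz))
            tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
            lo, hi = delta - tcrit * se, delta + tcrit * se
        elif method == "bootstrap":
            rng = np.random.default_rng(seed)
            n = len(self.model.outcome)
            draws = np.empty((n_boot, len(minutes_grid)))
            for r in range(n_boot):
                take = rng.integers(0, n, n)
                res = IlrRegression(
                    self.model.comp[take],
                    self.model.outcome[take],
                    None
                    if self.model.covariates is None
                    else self.model.covariates.iloc[take].reset_index(drop=True),
                    basis=basis,
                    total=self.model.total,
                ).fit()
                bb = res.params.loc[self.ilr_names].to_numpy()
                draws[r] = dz @ bb
            lo = np.percentile(draws, 100 * alpha / 2, axis=0)
            hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
            zero = minutes_grid == 0
            lo[zero] = hi[zero] = 0.0
        else:
            raise ValueError("method must be 'delta' or 'bootstrap'")
        return pd.DataFrame(
            {
                "from_part": from_part,
                "to_part": to_part,
                "minutes": minutes_grid,
                "delta_outcome": delta,
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    def summary(self) -> str:
        chi2, df, p = self.composition_test()
        lines = [
            f"OLS of {self.model.outcome_name} on ilr coordinates "
            f"(pivot = {self.model.basis.pivot})",
            f"  n = {len(self.model.outcome)}, df_resid = {self.df_resid:.0f}, "
            f"R^2 = {self.rsquared:.3f}",
            f"  composition block: Wald chi2({df}) = {chi2:.3f}, p = {p:.4f}",
            "  coefficients (SE):",
        ]
        se = np.sqrt(np.diag(self.cov_params))
        for name, b, s in zip(self.params.index, self.params, se):
            lines.append(f"    {name:<12} {b: .4f} ({s:.4f})")
        return "\n".join(lines)


class IlrRegression:
    """OLS of an outcome on ilr coordinates of a composition + covariates.

    This is the workhorse of the analysis: the fitted composition block is
    the basis for the Type II Wald test and for isotemporal-substitution
    predictions.  Fitting is delegated to statsmodels OLS.
    """

    def __init__(
        self,
        compositions,
        outcome,
        covariates: pd.DataFrame | None = None,
        basis: IlrBasis | None = None,
        parts=DEFAULT_PARTS,
        total: float = 1440.0,
        outcome_name: str = "outcome",
    ):
        self.comp = np.asarray(compositions, dtype=float)
        self.outcome = np.asarray(outcome, dtype=float)
        if len(self.comp) != len(self.outcome):
            raise ValueError("compositions and outcome length mismatch")
        self.covariates = covariates
        self.basis = basis or pivot_basis(parts, parts[0])
        self.total = total
        self.outcome_name = outcome_name
        z = ilr(self.comp, self.basis)
        Xc, names = _design(covariates, len(self.outcome))
        self.X = np.column_stack([Xc[:, :1], z, Xc[:, 1:]])
        self.names = ["intercept"] + self.basis.coord_names() + names[1:]
        if len(self.outcome) <= self.X.shape[1] + 1:
            raise ValueError("too few observations for the number of predictors")
        _check_full_rank(self.X, self.names)

    @classmethod
    def from_frames(
        cls,
        data: pd.DataFrame,
        outcome_col: str,
        parts=DEFAULT_PARTS,
        covariate_cols=(),
        basis: IlrBasis | None = None,
        total: float = 1440.0,
    ) -> "IlrRegression":
        cov = data[list(covariate_cols)] if covariate_cols else None
        return cls(
            data[list(parts)].to_numpy(),
            data[outcome_col].to_numpy(),
            cov,
            basis=basis,
            parts=tuple(parts),
            total=total,
            outcome_name=outcome_col,
        )

    def fit(self) -> IlrRegressionResults:
        import statsmodels.api as sm

        res = sm.OLS(self.outcome, self.X).fit()
        params = pd.Series(res.params, index=self.names)
        cov = pd.DataFrame(res.cov_params(), index=self.names, columns=self.names)
        return IlrRegressionResults(
            model=self,
            params=params,
            cov_params=cov,
            df_resid=float(res.df_resid),
            rsquared=float(res.rsquared),
            resid=np.asarray(res.resid),
        )


def fit_ilr_regression(
    compositions, outcome, covariates=None, basis=None, parts=DEFAULT_PARTS, total=1440.0
) -> IlrRegressionResults:
    """Functional wrapper around :class:`IlrRegression`."""
    return IlrRegression(compositions, outcome, covariates, basis, parts, total).fit()


def wald_type2_composition_test(fit: IlrRegressionResults) -> tuple[float, int, float]:
    """Type II Wald chi-square for the composition block of a fitted model."""
    return fit.composition_test()


def isotemporal_substitution(
    fit: IlrRegressionResults, from_part: str, to_part: str, **kwargs
) -> pd.DataFrame:
    """Functional wrapper around :meth:`IlrRegressionResults.isotemporal`."""
    return fit.isotemporal(from_part, to_part, **kwargs)


# ---------------------------------------------------------------------------
# bootstrap group differences


@dataclass
class GroupDifferenceResult:
    """Per-part log-ratio differences of group compositional means.

    ``table`` columns: part, logratio_diff (B relative to A), percent
    (= (exp(d) - 1) * 100) and bootstrap percentile CI bounds in percent.
    """

    table: pd.DataFrame
    n_boot: int
    seed: int
    group_a: str
    group_b: str

    def summary(self) -> str:
        lines = [
            f"Bootstrap log-ratio differences ({self.group_b} vs {self.group_a}; "
            f"B = {self.n_boot})"
        ]
        for r in self.table.itertuples(index=False):
            lines.append(
                f"  {r.part:<6} {r.percent:+6.1f}%  "
                f"[{r.ci_low_pct:+6.1f}%, {r.ci_high_pct:+6.1f}%]"
            )
        return "\n".join(lines)


def bootstrap_logratio_differences(
    set_a,
    set_b,
    n_boot: int = 2000,
    seed: int = 0,
    parts=DEFAULT_PARTS,
    total: float = 1440.0,
    alpha: float = 0.05,
    label_a: str = "td",
    label_b: str = "sdcd",
) -> GroupDifferenceResult:
    """Percentile bootstrap CIs for log-ratio differences of group means.

    The point estimate per part k is ``ln(m_b[k]) - ln(m_a[k])`` where m are
    the group compositional means closed to ``total``; resampling is
    stratified within group, with replacement.  Percent differences are the
    back-transform ``(exp(d) - 1) * 100``.
    """
    A = np.asarray(set_a, dtype=float)
    B = np.asarray(set_b, dtype=float)
    if len(A) < 3 or len(B) < 3:
        raise ValueError("each group needs at least 3 compositions")
    if n_boot < 200:
        raise ValueError("use at least 200 bootstrap resamples")

    def logmean(x: np.ndarray) -> np.ndarray:
        return np.log(compositional_mean(x, total))

    d = logmean(B) - logmean(A)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(parts)))
    logA = np.log(A)
    logB = np.log(B)
    for r in range(n_boot):
        ga = logA[rng.integers(0, len(A), len(A))].mean(axis=0)
        gb = logB[rng.integers(0, len(B), len(B))].mean(axis=0)
        ma = np.log(close(np.exp(ga), total))
        mb = np.log(close(np.exp(gb), total))
        boots[r] = mb - ma
    lo = np.percentile(boots, 100 * alpha / 2, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
    table = pd.DataFrame(
        {
            "part": list(parts),
            "logratio_diff": d,
            "percent": (np.exp(d) - 1.0) * 100.0,
            "ci_low_pct": (np.exp(lo) - 1.0) * 100.0,
            "ci_high_pct": (np.exp(hi) - 1.0) * 100.0,
        }
    )
    return GroupDifferenceResult(table, n_boot, seed, label_a, label_b)


# ---------------------------------------------------------------------------
# contingency tables


def chi_square_table(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for an r x c table.

    Rows/columns with a zero margin are dropped with a warning; a table that
    degenerates below 2 x 2 is rejected.
    """
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2 x 2 table")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping rows/columns with zero margin")
        t = t[rows][:, cols]
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table degenerates below 2 x 2 after dropping zero margins")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
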