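"""Age trajectories of gene expression and cell-type statistics.

The workhorse is a penalized cubic B-spline (P-spline) of expression on
age with k=5 basis functions and a second-difference penalty, the
penalty weight chosen by generalized cross-validation. Around it:

* per-gene age-trend detection with Benjamini-Hochberg FDR control;
* cell-type mean trajectories (genes standardized, averaged within a
  set, then spline-fitted);
* peak growth of expression (age of maximum first derivative);
* crossover age of two curves (first sign change of their difference —
  in log expression space a curve difference is a log expression ratio);
* hypergeometric cell-type enrichment of age-associated genes.

The smooth-term p-value is an F-test of the full (unpenalized) k-basis
smooth against the covariate-only model. With the penalty fixed at zero
for testing, the null distribution of p is exactly uniform under
Gaussian noise, which keeps BH selection calibrated; the GCV-penalized
fit is used for curves and derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset, GeneSetCollection

__all__ = [
    "SplineBasis",
    "AgeSplineModel",
    "AgeSplineResults",
    "fit_age_spline",
    "select_age_genes",
    "cross_dataset_overlap",
    "celltype_mean_trajectory",
    "peak_growth_age",
    "PeakGrowth",
    "crossover_age",
    "CrossoverResult",
    "celltype_enrichment",
    "benjamini_hochberg",
]

GRID_STEP = 0.1  # years, resolution for curves, derivatives and crossings
_LAMBDA_GRID = np.logspace(-4, 6, 41)


class SplineBasis:
    """Cubic B-spline basis on an age range with a sum-to-zero constraint.

    ``k`` basis functions (knots at age quantiles) are reparametrized to
    k-1 columns orthogonal to the constant, so the smooth represents
    deviations around the intercept. Carries the second-difference
    penalty in the constrained parametrization.
    """

    degree = 3

    def __init__(self, age: np.ndarray, k: int = 5):
        age = np.asarray(age, float)
        if k <= self.degree:
            raise ValueError(f"need k > {self.degree} basis functions")
        if np.ptp(age) <= 0:
            raise ValueError("ages span zero; smooth of age is rank deficient")
        self.k = k
        lo, hi = float(age.min()), float(age.max())
        n_int = k - self.degree - 1
        interior = (
            np.quantile(age, np.linspace(0, 1, n_int + 2)[1:-1])
            if n_int > 0
            else np.array([])
        )
        self.knots = np.r_[[lo] * (self.degree + 1), interior, [hi] * (self.degree + 1)]
        self.lo, self.hi = lo, hi

        B = self._raw(age)  # (n, k)
        # null space of the constraint mean(B c) = 0 -> (k, k-1) transform
        con = B.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(con)
        self.Q = vt[1:].T  # (k, k-1)
        D = np.diff(np.eye(k), 2, axis=0)  # second-difference penalty
        self.penalty = self.Q.T @ (D.T @ D) @ self.Q

    def _raw(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def design(self, x) -> np.ndarray:
        """Constrained design matrix (len(x), k-1)."""
        return self._raw(x) @ self.Q

    def curve(self, coefs_constrained, x) -> np.ndarray:
        return self.design(x) @ coefs_constrained

    def derivative(self, coefs_constrained, x) -> np.ndarray:
        spl = BSpline(self.knots, self.Q @ coefs_constrained, self.degree)
        return spl.derivative()(np.clip(x, self.lo, self.hi))


@dataclass
class AgeSplineResults:
    """A fitted expression-age trajectory.

    ``curve`` and ``derivative`` are evaluated on ``age_grid`` (0.1-year
    steps over the observed range); ``p_smooth`` is the smooth-term
    p-value against the covariate-only model and ``edf`` the effective
    degrees of freedom of the (penalized) smooth.
    """

    age_grid: np.ndarray
    curve: np.ndarray
    derivative: np.ndarray
    p_smooth: float
    edf: float
    k: int
    lam: float
    n: int

    def __post_init__(self) -> None:
        assert self.age_grid.shape == self.curve.shape == self.derivative.shape

    def centered(self) -> "AgeSplineResults":
        """Same fit with the curve demeaned over the age grid."""
        return AgeSplineResults(
            self.age_grid,
            self.curve - self.curve.mean(),
            self.derivative,
            self.p_smooth,
            self.edf,
            self.k,
            self.lam,
            self.n,
        )

    def summary(self) -> str:
        return (
            f"age-spline fit: n={self.n}, k={self.k}, edf={self.edf:.2f}, "
            f"lambda={self.lam:.3g}, p_smooth={self.p_smooth:.3g}, "
            f"ages {self.age_grid[0]:.1f}-{self.age_grid[-1]:.1f} y"
        )

    def plot(self, ax=None, label=None):
        """Fitted trajectory on the age grid; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.age_grid, self.curve, label=label)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("expression")
        if label:
            ax.legend()
        return ax


class AgeSplineModel:
    """Penalized spline of one response on age, with linear covariates.

    Parameters
    ----------
    y
        Response values per sample.
    age
        Ages (years); must span a positive range.
    covariates
        Optional (n, p) array or DataFrame of linear confounders (e.g.
        RIN, sex, region dummies). Columns are mean-centered so the
        fitted curve is the trajectory at covariate reference levels.
    groups
        Optional donor labels: adds a donor random intercept (mixed
        model; penalty off, Wald test on the spline block).
    k
        Number of spline basis functions (default 5).
    """

    def __init__(self, y, age, covariates=None, groups=None, k: int = 5):
        self.y = np.asarray(y, float)
        self.age = np.asarray(age, float)
        if self.y.shape != self.age.shape:
            raise ValueError("y and age lengths differ")
        if len(self.y) < 2 * k:
            raise ValueError(f"need at least 2k={2 * k} samples")
        self.basis = SplineBasis(self.age, k)
        if covariates is None:
            cov = np.empty((len(self.y), 0))
        else:
            cov = np.asarray(
                covariates if not isinstance(covariates, pd.DataFrame) else covariates.to_numpy(),
                float,
            )
            cov = cov - cov.mean(axis=0, keepdims=True)
        self.covariates = cov
        self.groups = None if groups is None else np.asarray(groups)
        self.k = k

    @property
    def age_grid(self) -> np.ndarray:
        lo, hi = self.age.min(), self.age.max()
        return np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)

    def fit(self, lam="gcv") -> AgeSplineResults:
        if self.groups is not None:
            return self._fit_mixed()
        Z = self.basis.design(self.age)  # (n, k-1)
        C = np.column_stack([np.ones(len(self.y)), self.covariates])
        fit = _penalized_fit(
            self.y[:, None], Z, C, self.basis.penalty, lam
        )
        coefs = fit["coefs"][:, 0]
        grid = self.age_grid
        curve = fit["alpha"][0] + self.basis.curve(coefs, grid)
        deriv = self.basis.derivative(coefs, grid)
        return AgeSplineResults(
            grid,
            curve,
            deriv,
            float(fit["p"][0]),
            float(fit["edf"][0]),
            self.k,
            float(fit["lam"][0]),
            len(self.y),
        )

    def _fit_mixed(self) -> AgeSplineResults:
        import warnings

        Z = self.basis.design(self.age)
        exog = np.column_stack([np.ones(len(self.y)), Z, self.covariates])
        with warnings.catch_warnings():
            # a near-zero donor variance pushes the REML optimum onto the
            # boundary; the fixed-effect estimates remain valid
            warnings.simplefilter("ignore")
            res = MixedLM(self.y, exog, groups=self.groups).fit(reml=True)
        sl = slice(1, 1 + Z.shape[1])
        b = res.fe_params[sl]
        V = np.asarray(res.cov_params())[sl, sl]
        chi2 = float(b @ np.linalg.solve(V, b))
        p = float(stats.chi2.sf(chi2, Z.shape[1]))
        grid = self.age_grid
        curve = res.fe_params[0] + self.basis.curve(b, grid)
        deriv = self.basis.derivative(b, grid)
        return AgeSplineResults(
            grid, curve, deriv, p, float(Z.shape[1]), self.k, 0.0, len(self.y)
        )


def _penalized_fit(Y, Z, C, P, lam="gcv"):
    """Shared-design penalized spline fit, vectorized over columns of Y.

    Y: (n, G) responses; Z: (n, q) constrained spline design; C: (n, p0)
    unpenalized block (intercept + centered covariates); P: (q, q)
    penalty. Returns per-column GCV lambda, edf, coefficients, intercept
    block estimates, and the exact F-test p-value of the unpenalized
    smooth against the C-only model.
    """
    n, G = Y.shape
    q = Z.shape[1]
    Qc, _ = np.linalg.qr(C)
    Yt = Y - Qc @ (Qc.T @ Y)
    Zt = Z - Qc @ (Qc.T @ Z)
    R = np.linalg.cholesky(Zt.T @ Zt + 1e-10 * np.eye(q)).T
    Rinv = np.linalg.inv(R)
    A = Rinv.T @ P @ Rinv
    s, U = np.linalg.eigh(A)
    s = np.clip(s, 0, None)
    Q2 = Zt @ Rinv  # orthonormal columns
    u = U.T @ (Q2.T @ Yt)  # (q, G)
    yy = np.sum(Yt * Yt, axis=0)  # (G,)

    # exact F-test at lambda = 0
    rss1 = np.maximum(yy - np.sum(u * u, axis=0), 0.0)
    p0 = C.shape[1]
    df2 = n - p0 - q
    if df2 <= 0:
        raise ValueError("too few samples for the smooth F-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((yy - rss1) / q) / (rss1 / df2)
    pvals = np.where(
        yy <= 1e-300, 1.0, stats.f.sf(F, q, df2)
    )

    if lam == "gcv":
        gcv = np.empty((len(_LAMBDA_GRID), G))
        for i, lm in enumerate(_LAMBDA_GRID):
            w = 1.0 / (1.0 + lm * s)
            uw = u * w[:, None]
            rss = yy - 2 * np.sum(u * uw, axis=0) + np.sum(uw * uw, axis=0)
            edf = p0 + w.sum()
            gcv[i] = n * np.maximum(rss, 0) / (n - edf) ** 2
        lam_idx = np.argmin(gcv, axis=0)
        lam_sel = _LAMBDA_GRID[lam_idx]
    else:
        lam_sel = np.full(G, float(lam))

    coefs = np.empty((q, G))
    edfs = np.empty(G)
    for j in range(G):
        w = 1.0 / (1.0 + lam_sel[j] * s)
        d = U @ (w * u[:, j])
        coefs[:, j] = Rinv @ d
        edfs[j] = w.sum()
    alpha = np.linalg.lstsq(C, Y - Z @ coefs, rcond=None)[0]  # (p0, G)
    return dict(
        coefs=coefs, alpha=alpha[0], edf=edfs, p=pvals, lam=lam_sel, rss1=rss1
    )


def fit_age_spline(y, age, covariates=None, groups=None, k: int = 5) -> AgeSplineResults:
    """Fit one expression-age trajectory (functional wrapper)."""
    return AgeSplineModel(y, age, covariates, groups, k).fit()


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def _dialect_covariates(ds: ExpressionDataset) -> np.ndarray | None:
    """Linear confounders for the RNA-seq dialect: RIN, sex, region dummies."""
    if ds.dialect != "rnaseq-log2rpkm":
        return None
    cols = []
    if "rin" in ds.samples:
        cols.append(ds.samples["rin"].to_numpy(float))
    if "sex" in ds.samples:
        sex = ds.samples["sex"]
        cols.append((sex.astype(str) == sex.astype(str).iloc[0]).to_numpy(float))
    if "region" in ds.samples and ds.samples["region"].nunique() > 1:
        dummies = pd.get_dummies(ds.samples["region"], drop_first=True)
        cols.extend(dummies[c].to_numpy(float) for c in dummies)
    return np.column_stack(cols) if cols else None


def select_age_genes(ds: ExpressionDataset, alpha: float = 0.05, k: int = 5) -> pd.DataFrame:
    """Per-gene age-trend test with BH correction.

    Microarray dialect: vectorized exact F-test of the k-basis smooth.
    RNA-seq dialect: per-gene mixed model with a donor random intercept
    and RIN/sex/region confounders, Wald test on the smooth block.

    Returns a table (index = gene) with ``p``, ``p_fdr`` and
    ``selected`` (p_fdr < alpha).
    """
    age = ds.ages
    Y = ds.expression.to_numpy(float).T  # (n, G)
    cov = _dialect_covariates(ds)
    if ds.dialect == "rnaseq-log2rpkm" and "donor" in ds.samples:
        pvals = np.array(
            [
                AgeSplineModel(
                    Y[:, j], age, cov, groups=ds.samples["donor"].to_numpy(), k=k
                )
                .fit()
                .p_smooth
                for j in range(Y.shape[1])
            ]
        )
    else:
        basis = SplineBasis(age, k)
        Z = basis.design(age)
        C = np.column_stack([np.ones(len(age))] + (
            [cov - cov.mean(axis=0)] if cov is not None else []
        ))
        pvals = _penalized_fit(Y, Z, C, basis.penalty, lam=0.0)["p"]
    p_fdr = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {"p": pvals, "p_fdr": p_fdr, "selected": p_fdr < alpha}, index=ds.genes
    )


def cross_dataset_overlap(selected_a, selected_b) -> tuple[int, float]:
    """Overlap count and fraction-of-a between two selected gene sets."""
    a, b = set(selected_a), set(selected_b)
    if not a:
        raise ValueError("first selection is empty; fraction undefined")
    count = len(a & b)
    return count, count / len(a)


def celltype_mean_trajectory(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    mode: str = "zscore",
    k: int = 5,
) -> dict[str, AgeSplineResults]:
    """Spline trajectory of the mean standardized expression per cell type.

    ``mode="zscore"`` standardizes each gene to mean 0 / sd 1 across
    samples, ``"demeaned"`` only removes the gene mean (both center the
    fitted curve over the age grid), ``"none"`` averages raw values.
    """
    if mode not in ("zscore", "demeaned", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for name in sets:
        genes = [g for g in sets[name] if g in ds.expression.index]
        if not genes:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        X = ds.expression.loc[genes].to_numpy(float)
        if mode in ("zscore", "demeaned"):
            X = X - X.mean(axis=1, keepdims=True)
            if mode == "zscore":
                sd = X.std(axis=1, keepdims=True)
                X = X / np.where(sd == 0, 1.0, sd)
        profile = X.mean(axis=0)
        fit = AgeSplineModel(profile, ds.ages, k=k).fit()
        out[name] = fit.centered() if mode in ("zscore", "demeaned") else fit
    return out


@dataclass(frozen=True)
class PeakGrowth:
    """Age of maximal expression growth (first-derivative peak)."""

    age: float
    boundary: bool  # peak at an end of the age grid
    growing: bool  # peak derivative is positive


def peak_growth_age(fit: AgeSplineResults, mode: str = "derivative") -> PeakGrowth:
    """Grid age maximizing the first derivative (or the level).

    Ties break toward the youngest age; a peak at either end of the
    grid is flagged as a boundary maximum, and a non-positive peak
    derivative is flagged as non-growth.
    """
    values = fit.derivative if mode == "derivative" else fit.curve
    i = int(np.argmax(np.round(values, 12)))  # round so exact ties go young
    peak = float(values[i])
    return PeakGrowth(
        age=float(fit.age_grid[i]),
        boundary=i in (0, len(values) - 1),
        growing=bool(peak > 0) if mode == "derivative" else True,
    )


@dataclass(frozen=True)
class CrossoverResult:
    """First crossing of two trajectories, if any."""

    age: float | None
    leads_before: str  # "a" or "b": which curve is higher before the crossing
    leads_after: str
    region: str | None = None


def crossover_age(
    fit_a: AgeSplineResults, fit_b: AgeSplineResults, region: str | None = None
) -> CrossoverResult:
    """First age where curve_a - curve_b changes sign.

    Located by linear interpolation between grid points; in log
    expression space the curve difference is the log expression ratio,
    so this is the age at which the expression ratio crosses 1. Returns
    ``age=None`` when the curves do not cross.
    """
    if not np.allclose(fit_a.age_grid, fit_b.age_grid):
        raise ValueError("curves must share an age grid")
    diff = fit_a.curve - fit_b.curve
    sign = np.sign(diff)
    lead0 = "a" if (sign[sign != 0][0] if (sign != 0).any() else 1) > 0 else "b"
    idx = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if idx.size == 0:
        return CrossoverResult(None, lead0, lead0, region)
    i = int(idx[0])
    x0, x1 = fit_a.age_grid[i], fit_a.age_grid[i + 1]
    y0, y1 = diff[i], diff[i + 1]
    age = float(x0) if y1 == y0 else float(x0 - y0 * (x1 - x0) / (y1 - y0))
    return CrossoverResult(age, lead0, "b" if lead0 == "a" else "a", region)


def celltype_enrichment(
    age_genes, sets: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric enrichment of age-associated genes per cell type.

    One-sided upper-tail p per set (drawing |age_genes| genes from the
    universe, counting overlap with the set), BH-corrected across sets;
    the odds ratio is the sample odds ratio of the 2x2 table.
    """
    age_genes = set(age_genes)
    universe = set(sets.universe)
    if not universe:
        raise ValueError("empty background universe")
    if not age_genes <= universe:
        raise ValueError("age genes must lie within the background universe")
    M, n_draw = len(universe), len(age_genes)
    rows = []
    for name in sets:
        s = set(sets[name])
        a = len(age_genes & s)
        b = n_draw - a
        c = len(s) - a
        d = M - len(s) - b
        p = float(stats.hypergeom.sf(a - 1, M, len(s), n_draw))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            dict(cell_type=name, set_size=len(s), overlap=a, odds_ratio=odds, p=p)
        )
    table = pd.DataFrame(rows).set_index("cell_type")
    table["p_fdr"] = benjamini_hochberg(table["p"])
    table["enriched"] = table["p_fdr"] < alpha
    return table
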