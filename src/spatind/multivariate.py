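"""Linking biomass to spatial structure: PCA + stepwise regression.

The indicator panel has one row per (species, sub-area, year).  Before any
pooled analysis, each indicator is divided by its (species, sub-area) mean —
so a value of 1 means "average for that stock in that area" and stocks of
very different absolute scale become comparable — except the number of
major patches and the CG coordinates, which stay in their natural units.
Standardized biomass and packing density are *supplementary* variables:
they are projected onto the principal axes through correlations with the
scores but do not influence the decomposition.

PCA runs on the Pearson correlation matrix of the active columns.  The
stepwise regression of standardized biomass on the leading scores uses
forward selection with an F-test; because scores are mutually orthogonal,
the selected set equals the individually significant axes and coefficients
equal their univariate estimates.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ACTIVE_COLUMNS",
    "SUPPLEMENTARY_COLUMNS",
    "PCAResult",
    "RegressionResult",
    "standardize_panel",
    "pca_with_supplementary",
    "stepwise_regression",
    "run_pooled_analyses",
]

#: active variables of the PCA, as produced by the indicator/variography stages
ACTIVE_COLUMNS = (
    "cg_lon", "cg_lat", "inertia", "isotropy", "n_major_patches",
    "positive_area", "spreading_area", "equivalent_area", "gic",
    "range_nmi", "nugget_pct",
)
#: projected onto the axes without influencing them
SUPPLEMENTARY_COLUMNS = ("biomass", "packing_density")
#: divided by the (species, sub-area) mean; NP and CG stay in natural units
_UNSTANDARDIZED = ("n_major_patches", "cg_lon", "cg_lat", "cg_x", "cg_y")


def standardize_panel(panel: pd.DataFrame,
                      group_keys: tuple[str, ...] = ("species", "sub_area"),
                      columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Divide indicator columns by their within-(species, sub-area) mean.

    After standardization every treated column has mean 1 within each group.
    Columns in ``_UNSTANDARDIZED`` pass through.  Zero group means are an
    error; singleton groups are flagged with a warning since a lone year
    standardizes to exactly 1 and carries no contrast.
    """
    if columns is None:
        columns = tuple(c for c in (*ACTIVE_COLUMNS, *SUPPLEMENTARY_COLUMNS)
                        if c in panel.columns)
    out = panel.copy()
    sizes = panel.groupby(list(group_keys)).size()
    if (sizes < 2).any():
        warnings.warn(f"singleton group(s) in panel: "
                      f"{sizes[sizes < 2].index.tolist()}", stacklevel=2)
    for col in columns:
        if col in _UNSTANDARDIZED:
            continue
        means = panel.groupby(list(group_keys))[col].transform("mean")
        if (means == 0).any():
            raise ValueError(f"zero group mean for column {col!r}")
        out[col] = panel[col] / means
    return out


# ---------------------------------------------------------------------------
# PCA with supplementary variables
# ---------------------------------------------------------------------------

def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t distribution."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    if n <= 2:
        return np.ones_like(r)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


@dataclasses.dataclass
class PCAResult:
    eigenvalues: np.ndarray            # sum = number of active variables
    loadings: pd.DataFrame             # variables x components, in [-1, 1]
    scores: pd.DataFrame               # rows x components
    variance_explained: np.ndarray     # percent per axis, sums to 100
    supplementary_correlations: pd.DataFrame
    loading_pvalues: pd.DataFrame
    supplementary_pvalues: pd.DataFrame
    n_rows: int

    def significant_loadings(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.loading_pvalues < alpha

    def n_axes_for_variance(self, target_pct: float = 85.0, cap: int = 5) -> int:
        """Smallest axis count reaching the cumulative-variance target."""
        cum = np.cumsum(self.variance_explained)
        k = int(np.searchsorted(cum, target_pct - 1e-9) + 1)
        return min(k, cap, len(cum))


def pca_with_supplementary(panel: pd.DataFrame,
                           active: tuple[str, ...] = ACTIVE_COLUMNS,
                           supplementary: tuple[str, ...] = SUPPLEMENTARY_COLUMNS,
                           ) -> PCAResult:
    """Correlation-matrix PCA with supplementary-variable projection.

    Active columns are z-scored; the eigendecomposition of their Pearson
    correlation matrix gives the axes.  Loadings are variable-score
    correlations (equivalently eigenvector * sqrt(eigenvalue)), and each
    supplementary column is correlated with every score column the same
    way.  Components are oriented so their largest-|loading| variable loads
    positively, making signs reproducible.
    """
    active = tuple(c for c in active if c in panel.columns)
    supplementary = tuple(c for c in supplementary if c in panel.columns)
    X = panel.loc[:, active].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [active[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant active column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = evecs * np.sqrt(evals)
    # orient each axis so its dominant variable loads positively
    for k in range(p):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            evecs[:, k] *= -1
    scores = Z @ evecs
    comp = [f"PC{k + 1}" for k in range(p)]
    load_df = pd.DataFrame(loadings, index=list(active), columns=comp)
    score_df = pd.DataFrame(scores, index=panel.index, columns=comp)

    sup_corr = np.zeros((len(supplementary), p))
    for i, col in enumerate(supplementary):
        v = panel[col].to_numpy(dtype=float)
        vs = v.std(ddof=1)
        for k in range(p):
            sk = scores[:, k].std(ddof=1)
            if vs > 0 and sk > 1e-12:
                sup_corr[i, k] = np.corrcoef(v, scores[:, k])[0, 1]
    sup_df = pd.DataFrame(sup_corr, index=list(supplementary), columns=comp)
    return PCAResult(
        eigenvalues=evals,
        loadings=load_df,
        scores=score_df,
        variance_explained=100.0 * evals / evals.sum(),
        supplementary_correlations=sup_df,
        loading_pvalues=pd.DataFrame(_corr_pvalue(loadings, n), index=list(active), columns=comp),
        supplementary_pvalues=pd.DataFrame(_corr_pvalue(sup_corr, n), index=list(supplementary), columns=comp),
        n_rows=n,
    )


# ---------------------------------------------------------------------------
# stepwise regression on PC scores
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegressionResult:
    selected: list[str]
    coefficients: dict[str, float]      # includes "intercept"
    r_squared: float
    residuals: np.ndarray
    entry_pvalues: dict[str, float]     # p-to-enter of each selected axis
    candidate_axes: list[str]

    @property
    def empty(self) -> bool:
        return len(self.selected) == 0


def stepwise_regression(response: np.ndarray | pd.Series, scores: pd.DataFrame,
                        alpha: float = 0.05) -> RegressionResult:
    """Forward stepwise OLS of a response on PC score columns.

    At each step the candidate with the smallest partial-F p-value enters if
    p < ``alpha``.  With orthogonal scores no removal step is needed and the
    final coefficients equal the univariate ones.  An empty model (intercept
    only) is a valid outcome and is flagged via ``RegressionResult.empty``.
    """
    y = np.asarray(response, dtype=float)
    candidates = list(scores.columns)
    selected: list[str] = []
    entry_p: dict[str, float] = {}
    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        best, best_p = None, 1.0
        for c in remaining:
            Xc = sm.add_constant(scores[selected + [c]].to_numpy())
            fit = sm.OLS(y, Xc).fit()
            p = float(fit.pvalues[-1])
            if p < best_p:
                best, best_p = c, p
        if best is None or best_p >= alpha:
            break
        selected.append(best)
        entry_p[best] = best_p
    X = sm.add_constant(scores[selected].to_numpy()) if selected else np.ones((len(y), 1))
    fit = sm.OLS(y, X).fit()
    coefs = {"intercept": float(fit.params[0])}
    for i, c in enumerate(selected):
        coefs[c] = float(fit.params[i + 1])
    return RegressionResult(
        selected=selected,
        coefficients=coefs,
        r_squared=float(fit.rsquared) if selected else 0.0,
        residuals=np.asarray(fit.resid, dtype=float),
        entry_pvalues=entry_p,
        candidate_axes=candidates,
    )


# ---------------------------------------------------------------------------
# pooled analyses
# ---------------------------------------------------------------------------

def run_pooled_analyses(panel: pd.DataFrame,
                        active: tuple[str, ...] = ACTIVE_COLUMNS,
                        alpha: float = 0.05,
                        variance_target_pct: float = 85.0,
                        max_axes: int = 5,
                        area_key: str = "sub_area") -> dict[str, dict]:
    """Standardize -> PCA -> stepwise regression under the standard poolings.

    One analysis pools each species across all areas and one pools each
    area across species.  Standardization always happens within
    (species, sub-area) cells before pooling, so pooled rows are
    comparable.  The regression relates standardized biomass to the leading
    axes jointly covering the variance target (capped at ``max_axes``).
    Poolings with fewer than 4 rows are skipped with a warning.
    """
    std = standardize_panel(panel)
    analyses: dict[str, pd.DataFrame] = {}
    for sp in sorted(std["species"].unique()):
        analyses[f"species:{sp}"] = std[std["species"] == sp]
    for area in sorted(std[area_key].unique()):
        analyses[f"area:{area}"] = std[std[area_key] == area]
    results: dict[str, dict] = {}
    for name, sub in analyses.items():
        if len(sub) < 4:
            warnings.warn(f"pooling {name!r} has only {len(sub)} rows; skipped",
                          stacklevel=2)
            continue
        pca = pca_with_supplementary(sub, active=active)
        k = pca.n_axes_for_variance(variance_target_pct, cap=max_axes)
        scores = pca.scores.iloc[:, :k]
        reg = stepwise_regression(sub["biomass"].to_numpy(dtype=float), scores, alpha=alpha)
        results[name] = {"panel": sub, "pca": pca, "regression": reg, "n_axes": k}
    return results
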