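"""Cross-site comparison of module strengths against ecosystem characteristics.

Each site contributes one row: the strengths of selected network modules
(links into biomass, links into richness, pairwise loop weights, triangular
loop weights) as responses, and site characteristics (depth, area, long-term
means of richness, temperature, nitrate, phosphate, biomass) as predictors.
Associations are summarized by redundancy analysis (RDA) — a PCA of the
fitted values from a multivariate linear regression of responses on
standardized predictors — with significance from permutation tests
(10,000 permutations by default), supplemented by paired permutation
comparisons of link strengths, stepwise regression, Kruskal-Wallis group
comparison and correlation with permutation tests.  These analyses describe
under which environmental conditions a module prevails; they make no causal
claim themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .network import SiteNetwork, all_pairwise_loops, triangular_loops

logger = logging.getLogger(__name__)

__all__ = [
    "CrossSystemTable",
    "RDAResult",
    "assemble_cross_system_table",
    "rda",
    "rda_permutation_test",
    "paired_permutation_test",
    "stepwise_regression",
    "StepwiseResult",
    "rank_group_compare",
    "correlate_with_environment",
]

PREDICTOR_COLUMNS = (
    "depth", "area", "mean_richness", "mean_temperature",
    "mean_po4", "mean_no3", "mean_biomass",
)
#: predictors log10-transformed by default (area/depth/biomass/nutrients span
#: orders of magnitude across sites)
DEFAULT_LOG10 = ("depth", "area", "mean_po4", "mean_no3", "mean_biomass")

RESPONSE_BLOCKS = ("links_to_biomass", "links_to_richness", "pairwise_loops", "triangular_loops")


@dataclass
class CrossSystemTable:
    """Site-by-module strengths plus standardized site characteristics."""

    responses: dict[str, pd.DataFrame]
    predictors: pd.DataFrame  # standardized, complete cases only
    predictors_raw: pd.DataFrame

    @property
    def sites(self) -> list[str]:
        return list(self.predictors.index)

    def block(self, name: str) -> pd.DataFrame:
        if name not in self.responses:
            raise ValidationError(f"unknown response block {name!r}")
        return self.responses[name]


@dataclass
class RDAResult:
    """First two constrained axes of a redundancy analysis."""

    site_scores: np.ndarray      # rows x 2
    variable_scores: np.ndarray  # response variables x 2
    predictor_scores: np.ndarray  # predictors x 2 (correlations with axes)
    explained_variance: float
    eigenvalues: np.ndarray
    permutation_p: float | None = None
    response_names: tuple[str, ...] = ()
    predictor_names: tuple[str, ...] = ()


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        v = out[c].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"predictor {c!r} has zero variance")
        out[c] = (v - v.mean()) / sd
    return out


def assemble_cross_system_table(
    networks: list[SiteNetwork],
    metadata: pd.DataFrame,
    log10_columns: tuple[str, ...] = DEFAULT_LOG10,
) -> CrossSystemTable:
    """Build the site-by-module table behind the cross-system analyses.

    ``metadata`` is indexed by site with the columns in
    :data:`PREDICTOR_COLUMNS`.  Sites lacking metadata (or with incomplete
    rows) are dropped with a warning; predictors are log10-transformed where
    requested and then standardized to zero mean, unit variance.
    """
    if len(networks) < 3:
        raise ValidationError("need at least 3 sites")
    for net in networks:
        if not net.standardized:
            raise ValidationError(f"network for site {net.site!r} is not standardized")

    rows_ef, rows_bd, rows_pw, rows_tri = {}, {}, {}, {}
    for net in networks:
        causes_ef = [v for v in net.variables if v != "biomass"]
        causes_bd = [v for v in net.variables if v != "richness"]
        rows_ef[net.site] = {
            f"{c}->biomass": net.link(c, "biomass").SLS for c in causes_ef
        }
        rows_bd[net.site] = {
            f"{c}->richness": net.link(c, "richness").SLS for c in causes_bd
        }
        rows_pw[net.site] = {
            f"{a}<->{b}": loop.loop_weight
            for (a, b), loop in all_pairwise_loops(net).items()
        }
        rows_tri[net.site] = {
            name: loop.loop_weight for name, loop in triangular_loops(net).items()
        }

    sites = [net.site for net in networks]
    meta = metadata.reindex(sites)
    keep = meta.notna().all(axis=1)
    dropped = [s for s, ok in keep.items() if not ok]
    if dropped:
        logger.warning("dropping sites with missing metadata: %s", dropped)
    meta = meta.loc[keep, list(PREDICTOR_COLUMNS)].astype(float)
    if len(meta) < 3:
        raise ValidationError("fewer than 3 complete site rows")
    raw = meta.copy()
    for c in log10_columns:
        if c in meta.columns:
            if np.any(meta[c] <= 0):
                raise ValidationError(f"log10 transform of {c!r} requires positive values")
            meta[c] = np.log10(meta[c])
    predictors = _standardize_columns(meta)
    responses = {
        "links_to_biomass": pd.DataFrame.from_dict(rows_ef, orient="index").loc[predictors.index],
        "links_to_richness": pd.DataFrame.from_dict(rows_bd, orient="index").loc[predictors.index],
        "pairwise_loops": pd.DataFrame.from_dict(rows_pw, orient="index").loc[predictors.index],
        "triangular_loops": pd.DataFrame.from_dict(rows_tri, orient="index").loc[predictors.index],
    }
    return CrossSystemTable(responses=responses, predictors=predictors, predictors_raw=raw)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns until X has full column rank (pivoted QR order)."""
    from scipy.linalg import qr

    if np.linalg.matrix_rank(X) == X.shape[1]:
        return X, names
    _, _, piv = qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    logger.warning("dropping collinear predictors: %s", dropped)
    return X[:, keep], [names[i] for i in keep]


def rda(
    response: pd.DataFrame | np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
) -> RDAResult:
    """Redundancy analysis: constrained ordination of responses on predictors.

    Responses are centered; predictors are standardized (if not already);
    the response matrix is regressed on the predictors by least squares and
    the fitted values are eigen-decomposed.  Explained variance is the ratio
    of the fitted to the total sum of squares — in the single-response case
    exactly the regression R^2.
    """
    Y, resp_names = _as_matrix(response)
    X, pred_names = _as_matrix(predictors)
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValidationError("response and predictor row counts differ")
    if n < X.shape[1] + 2:
        raise ValidationError("need at least predictors + 2 rows")
    Yc = Y - Y.mean(axis=0)
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("constant predictor column")
    Xs = Xs / sd
    Xs, pred_names = _drop_collinear(Xs, list(pred_names))
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    fitted = Xs @ coef
    total = float((Yc**2).sum())
    if total == 0:
        raise ValidationError("response matrix has zero variance")
    explained = float((fitted**2).sum()) / total
    # constrained axes: SVD of the fitted values
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(2, len(s))
    site_scores = U[:, :n_axes] * s[:n_axes]
    variable_scores = Vt[:n_axes].T
    if site_scores.shape[1] < 2:  # single constrained axis: pad for biplots
        site_scores = np.column_stack([site_scores, np.zeros(n)])
        variable_scores = np.column_stack([variable_scores, np.zeros(len(resp_names))])
    pred_scores = np.zeros((Xs.shape[1], 2))
    for j in range(Xs.shape[1]):
        for a in range(2):
            ss = site_scores[:, a]
            if ss.std() > 0:
                pred_scores[j, a] = np.corrcoef(Xs[:, j], ss)[0, 1]
    eig = (s**2) / (n - 1)
    return RDAResult(
        site_scores=site_scores,
        variable_scores=variable_scores,
        predictor_scores=pred_scores,
        explained_variance=explained,
        eigenvalues=eig,
        response_names=tuple(resp_names),
        predictor_names=tuple(pred_names),
    )


def _as_matrix(a) -> tuple[np.ndarray, list[str]]:
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float), list(a.columns)
    if isinstance(a, pd.Series):
        return a.to_numpy(dtype=float)[:, None], [a.name or "y"]
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"v{i}" for i in range(arr.shape[1])]


def rda_permutation_test(
    response,
    predictors,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[RDAResult, float]:
    """Permutation p-value for the RDA explained variance.

    Rows of the predictor block are permuted; p = (1 + #{perm >= obs}) /
    (1 + n_perm).  Returns the observed RDA (with ``permutation_p`` set) and
    the p-value.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    X, _ = _as_matrix(predictors)
    result = rda(response, predictors)
    obs = result.explained_variance
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        r = rda(response, X[perm])
        if r.explained_variance >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    result.permutation_p = p
    return result, p


def paired_permutation_test(
    a,
    b,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided paired permutation test on mean(a - b) by sign flips.

    The null distribution flips the sign of each site's difference
    independently; p carries the +1 Monte-Carlo correction.  Returns
    (observed mean difference, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    d = a - b
    obs = d.mean()
    rng = np.random.default_rng(seed)
    n = len(d)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_stats = (signs * d).mean(axis=1)
    count = int(np.sum(np.abs(perm_stats) >= abs(obs) - 1e-15))
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)


@dataclass
class StepwiseResult:
    """Best stepwise OLS model on standardized predictors."""

    selected: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    f_statistic: float | None
    df: tuple[int, int] | None
    p_value: float | None
    r_squared: float
    aic: float

    def formula(self, y_name: str = "y") -> str:
        terms = "".join(
            f" {'+' if c >= 0 else '-'} {abs(c):.3f}*{name}"
            for name, c in self.coefficients.items()
        )
        return f"{y_name} = {self.intercept:.3f}{terms}"


def stepwise_regression(
    y,
    predictors: pd.DataFrame,
    criterion: str = "aic",
) -> StepwiseResult:
    """Bidirectional stepwise OLS selection by AIC on standardized predictors.

    Starting from the intercept-only model, the single add-or-drop move that
    most improves AIC is applied until no move improves it.  Returns the
    fitted coefficients, overall F statistic with (k, n - k - 1) degrees of
    freedom, and its p-value; with an empty selection the intercept-only
    model is returned (F undefined).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = _standardize_columns(predictors.astype(float))
    n, k_all = X.shape
    if n <= k_all + 1:
        raise ValidationError("need more rows than predictors + 1")

    def fit(cols: tuple[str, ...]):
        design = sm.add_constant(X[list(cols)].to_numpy()) if cols else np.ones((n, 1))
        return sm.OLS(y, design).fit()

    current: tuple[str, ...] = ()
    current_fit = fit(current)
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, tuple[str, ...]]] = []
        for c in X.columns:
            if c not in current:
                cols = current + (c,)
                candidates.append((fit(cols).aic, cols))
        for c in current:
            cols = tuple(x for x in current if x != c)
            candidates.append((fit(cols).aic, cols))
        if not candidates:
            break
        best_aic, best_cols = min(candidates, key=lambda t: t[0])
        if best_aic < current_fit.aic - 1e-10:
            current, current_fit = best_cols, fit(best_cols)
            improved = True

    coefs = {}
    if current:
        for name, c in zip(current, current_fit.params[1:]):
            coefs[name] = float(c)
        fstat = float(current_fit.fvalue)
        df = (int(current_fit.df_model), int(current_fit.df_resid))
        pval = float(current_fit.f_pvalue)
    else:
        fstat, df, pval = None, None, None
    return StepwiseResult(
        selected=current,
        intercept=float(current_fit.params[0]),
        coefficients=coefs,
        f_statistic=fstat,
        df=df,
        p_value=pval,
        r_squared=float(current_fit.rsquared) if current else 0.0,
        aic=float(current_fit.aic),
    )


def rank_group_compare(groups: dict[str, np.ndarray] | list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups; returns (H, p)."""
    if isinstance(groups, dict):
        samples = list(groups.values())
    else:
        samples = list(groups)
    if len(samples) < 2 or any(len(np.asarray(g)) < 2 for g in samples):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in samples])
    return float(h), float(p)


def correlate_with_environment(
    module_strengths,
    env_values,
    n_perm: int = 10000,
    seed: int = 0,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation with a two-sided permutation p-value.

    ``method`` is "pearson" (default) or "spearman" (applied by ranking both
    samples first).  The environmental values are permuted across sites; p
    carries the +1 correction.
    """
    x = np.asarray(module_strengths, dtype=float)
    y = np.asarray(env_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    if len(x) < 5:
        raise ValidationError("need at least 5 pairs")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValidationError("zero variance input")
    obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    count = 0
    for _ in range(n_perm):
        yp = y[rng.permutation(len(y))]
        r = float(np.corrcoef(xc, yp)[0, 1])
        if abs(r) >= abs(obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return obs, float(p)
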