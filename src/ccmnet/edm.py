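"""State-space reconstruction primitives.

A scalar series is unfolded into a delay embedding (Takens reconstruction);
cross-mapping then uses simplex projection on that embedding to estimate the
states of a putative causal variable: for each prediction point the E+1
nearest library neighbours are found by Euclidean distance and combined with
exponentially decaying weights w_i = exp(-d_i / d_min).  Cross-map skill is
the Pearson correlation between the estimates and the observed values of the
causal variable.  Convergence of skill with library size — the operational
signature of causality — is measured by :func:`skill_curve`.

The heavy lifting is done by :class:`CrossMapProblem`, which computes the
pairwise distance matrix among embedded vectors once and reuses it across
library subsamples, lags and bootstrap replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .preprocessing import MonthlySeries

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpec",
    "DelayEmbedding",
    "SkillCurve",
    "CrossMapProblem",
    "embed",
    "cross_map",
    "skill_curve",
]

E_MIN, E_MAX = 2, 20
LAG_SET = (0, 1, 2, 3)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters.

    E is the embedding dimension (searched in 2..20), ``tau`` the lag between
    coordinates (1 month throughout this package), and ``k_lag`` the
    cross-map prediction lag in months (0..3).
    """

    E: int
    tau: int = 1
    k_lag: int = 0

    def __post_init__(self) -> None:
        if not E_MIN <= self.E <= E_MAX:
            raise ValidationError(f"E must be in [{E_MIN}, {E_MAX}], got {self.E}")
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.k_lag not in LAG_SET:
            raise ValidationError(f"k_lag must be one of {LAG_SET}")


@dataclass
class DelayEmbedding:
    """Delay-coordinate vectors (x(t), x(t-tau), ..., x(t-(E-1)tau)).

    ``vectors`` holds one row per admissible time point t (including rows
    touching missing values); ``valid`` marks rows free of missing values,
    which are the only ones used downstream.
    """

    vectors: np.ndarray
    time_index: np.ndarray
    valid: np.ndarray
    E: int
    tau: int

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_vectors(self) -> np.ndarray:
        return self.vectors[self.valid]

    @property
    def valid_times(self) -> np.ndarray:
        return self.time_index[self.valid]


@dataclass
class SkillCurve:
    """Cross-map skill as a function of library size.

    ``rho_reps[i]`` holds the replicate skills at ``library_sizes[i]``;
    ``n_pred`` is the number of prediction points (constant across L, the
    prediction set being the full usable embedding).
    """

    library_sizes: np.ndarray
    rho_mean: np.ndarray
    rho_reps: list[np.ndarray]
    n_subsamples: int
    n_pred: int
    #: autocorrelation-adjusted effective number of prediction points
    #: (Pyper-Peterman); equals n_pred for serially independent residuals
    n_eff: int = 0

    def __post_init__(self) -> None:
        if self.n_eff == 0:
            self.n_eff = self.n_pred

    @property
    def L0(self) -> int:
        return int(self.library_sizes[0])

    @property
    def Lmax(self) -> int:
        return int(self.library_sizes[-1])

    @property
    def rho_L0(self) -> float:
        return float(self.rho_mean[0])

    @property
    def rho_Lmax(self) -> float:
        return float(self.rho_mean[-1])

    def to_frame(self):
        import pandas as pd

        rows = [
            (int(L), rep, float(r))
            for L, reps in zip(self.library_sizes, self.rho_reps)
            for rep, r in enumerate(reps)
        ]
        return pd.DataFrame(rows, columns=["L", "replicate", "rho"])


def _as_values(series) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    return np.asarray(series, dtype=float)


def embed(series, spec: EmbeddingSpec) -> DelayEmbedding:
    """Unfold a series into delay coordinates.

    The vector at time t is (x(t), x(t-tau), ..., x(t-(E-1)tau)); vectors
    touching a missing value are flagged invalid and excluded from all
    nearest-neighbour computations.
    """
    x = _as_values(series)
    E, tau = spec.E, spec.tau
    span = (E - 1) * tau
    if len(x) < span + 2:
        raise ValidationError(
            f"series of length {len(x)} too short for E={E}, tau={tau}"
        )
    t = np.arange(span, len(x))
    cols = [x[t - j * tau] for j in range(E)]
    vectors = np.stack(cols, axis=1)
    valid = ~np.isnan(vectors).any(axis=1)
    return DelayEmbedding(vectors=vectors, time_index=t, valid=valid, E=E, tau=tau)


class CrossMapProblem:
    """Precomputed cross-mapping problem for one (effect, cause, E, k) tuple.

    The effect variable's embedding supplies the reconstructed state space;
    the vector at time t estimates the cause at time t - k ("cross-mapping
    between X(t + k) and Y(t)").  Usable points are valid vectors whose
    target exists and is non-missing; the full pairwise distance matrix among
    them is computed once.
    """

    def __init__(
        self,
        effect_embedding: DelayEmbedding,
        cause_values,
        k_lag: int = 0,
        exclusion_radius: int = 0,
    ):
        y_all = _as_values(cause_values)
        t = effect_embedding.valid_times
        V = effect_embedding.valid_vectors
        tgt = t - k_lag
        ok = (tgt >= 0) & (tgt < len(y_all))
        y = np.full(len(t), np.nan)
        y[ok] = y_all[tgt[ok]]
        usable = ~np.isnan(y)
        self.E = effect_embedding.E
        self.vectors = V[usable]
        self.times = t[usable]
        self.targets = y[usable]
        self.k_lag = k_lag
        self.exclusion_radius = exclusion_radius
        self.n = len(self.times)
        if self.n == 0:
            raise ValidationError("no usable points: embedding and cause do not overlap")
        self.dist = cdist(self.vectors, self.vectors)

    @property
    def n_neighbors(self) -> int:
        return self.E + 1

    def rho(self, library: np.ndarray | None = None, warn: bool = True) -> float:
        """Cross-map skill for a library subset (positions into usable points).

        ``None`` means the full library.  The prediction set is always all
        usable points; a prediction point present in the library never uses
        itself (nor any point within ``exclusion_radius`` months) as a
        neighbour.
        """
        yhat = self.predict(library, warn=warn)
        return _pearson(yhat, self.targets)

    def neighbors(self, library: np.ndarray | None = None) -> np.ndarray:
        """Library positions (into the usable set) of each prediction point's
        neighbours, time-ordered; for auditing the leave-one-out contract."""
        _, _, cols, lib = self._select(library, warn=False)
        return lib[cols]

    def predict(self, library: np.ndarray | None = None, warn: bool = True) -> np.ndarray:
        d_sel, y_sel, _, _ = self._select(library, warn)
        finite = np.isfinite(d_sel)
        d_min = d_sel[:, 0]
        w = np.zeros_like(d_sel)
        pos = d_min > 0
        with np.errstate(over="ignore", invalid="ignore"):
            w[pos] = np.exp(-d_sel[pos] / d_min[pos, None])
        # duplicate points: split weight equally among zero-distance neighbours
        zero_rows = ~pos & np.isfinite(d_min)
        w[zero_rows] = (d_sel[zero_rows] == 0).astype(float)
        w[~finite] = 0.0
        wsum = w.sum(axis=1)
        dead = wsum == 0  # e.g. the only library point was excluded
        wsum[dead] = 1.0
        yhat = (w * y_sel).sum(axis=1) / wsum
        yhat[dead] = np.nan
        return yhat

    def _select(self, library: np.ndarray | None, warn: bool):
        if library is None:
            lib = np.arange(self.n)
        else:
            lib = np.asarray(library, dtype=int)
        if lib.size == 0:
            raise ValidationError("library must be non-empty")
        # positions in the usable set are time-ordered, so an ascending sort
        # puts the library in time order; stable distance sorting below then
        # breaks ties in favour of the earliest time index
        lib = np.sort(lib)
        D = self.dist[:, lib]  # fancy indexing copies
        # temporal exclusion (Theiler window): never use the prediction point
        # itself, nor neighbours within the exclusion radius
        if self.exclusion_radius == 0:
            D[lib, np.arange(lib.size)] = np.inf
        else:
            dt = np.abs(self.times[:, None] - self.times[lib][None, :])
            D[dt <= self.exclusion_radius] = np.inf
        nn = self.n_neighbors
        if lib.size < nn:
            if warn:
                warnings.warn(
                    f"library of size {lib.size} smaller than E+1={nn} neighbours; "
                    "using all available",
                    stacklevel=2,
                )
            nn = lib.size
        rows = np.arange(self.n)[:, None]
        if lib.size > nn:
            cand = np.argpartition(D, nn - 1, axis=1)[:, :nn]
            cand.sort(axis=1)  # restore time order within the selected subset
        else:
            cand = np.broadcast_to(np.arange(nn), (self.n, nn)).copy()
        d_cand = D[rows, cand]
        order = np.argsort(d_cand, axis=1, kind="stable")
        d_sel = np.take_along_axis(d_cand, order, axis=1)
        cols = np.take_along_axis(cand, order, axis=1)
        y_sel = self.targets[lib[cols]]
        return d_sel, y_sel, cols, lib


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    var = (x**2).sum()
    if var == 0:
        return np.zeros(max_lag)
    return np.array([(x[:-k] * x[k:]).sum() / var for k in range(1, max_lag + 1)])


def effective_sample_size(a: np.ndarray, b: np.ndarray) -> int:
    """Pyper-Peterman effective n for the correlation of two time series.

    1/n_eff = 1/n * (1 + 2 * sum_k r_a(k) * r_b(k)); autocorrelated series
    carry fewer independent observations than their length suggests, and a
    significance test run at the raw n would be anticonservative.
    """
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 8:
        return n
    max_lag = min(n // 5, 24)
    s = float(np.sum(_autocorr(a, max_lag) * _autocorr(b, max_lag)))
    n_eff = n / max(1.0 + 2.0 * s, 1.0)
    return int(np.clip(round(n_eff), 8, n))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return 0.0
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def cross_map(
    effect_embedding: DelayEmbedding,
    cause_series,
    k_lag: int = 0,
    library: np.ndarray | None = None,
    exclusion_radius: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Estimate the cause from the effect's embedding over one library.

    Returns (predicted, observed, rho) over all usable prediction points.
    """
    problem = CrossMapProblem(effect_embedding, cause_series, k_lag, exclusion_radius)
    if library is not None:
        library = np.asarray(library, dtype=int)
        if library.size == 0:
            raise ValidationError("library must be non-empty")
    yhat = problem.predict(library)
    return yhat, problem.targets, _pearson(yhat, problem.targets)


def library_grid(L0: int, Lmax: int, n_L: int) -> np.ndarray:
    """n_L integer library sizes evenly spaced from L0 to Lmax, deduplicated."""
    if n_L < 2:
        raise ValidationError("n_L must be >= 2")
    grid = np.unique(np.round(np.linspace(L0, Lmax, n_L)).astype(int))
    return grid


def skill_curve(
    X,
    Y,
    spec: EmbeddingSpec,
    n_L: int = 20,
    n_subsamples: int = 100,
    seed: int = 0,
    exclusion_radius: int = 0,
    problem: CrossMapProblem | None = None,
) -> SkillCurve:
    """Cross-map skill of X cross-mapping Y as a function of library size.

    The library-size grid runs from L0 = E to Lmax = the number of usable
    embedded vectors.  At each L < Lmax, ``n_subsamples`` random library
    subsets of size L are drawn without replacement (within a draw); at Lmax
    the full library is used once.  A precomputed ``problem`` may be passed
    to reuse the distance matrix.
    """
    if problem is None:
        emb = embed(X, spec)
        problem = CrossMapProblem(emb, Y, spec.k_lag, exclusion_radius)
    rng = np.random.default_rng(seed)
    L0, Lmax = problem.E, problem.n
    if Lmax < L0 + 2:
        raise ValidationError("too few usable points for a skill curve")
    grid = library_grid(L0, Lmax, n_L)
    reps: list[np.ndarray] = []
    means = np.empty(len(grid))
    for i, L in enumerate(grid):
        if L >= Lmax:
            r = np.array([problem.rho(None, warn=False)])
        else:
            r = np.array(
                [
                    problem.rho(rng.choice(Lmax, size=L, replace=False), warn=False)
                    for _ in range(n_subsamples)
                ]
            )
        reps.append(r)
        means[i] = r.mean()
    yhat_full = problem.predict(None, warn=False)
    # serial dependence among prediction points enters both through the
    # cross-map estimates (a smoother of the target series) and through the
    # reconstructed states themselves; take the more conservative estimate
    n_eff = min(
        effective_sample_size(yhat_full, problem.targets),
        effective_sample_size(problem.vectors[:, 0], problem.targets),
    )
    return SkillCurve(
        library_sizes=grid,
        rho_mean=means,
        rho_reps=reps,
        n_subsamples=n_subsamples,
        n_pred=problem.n,
        n_eff=n_eff,
    )
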