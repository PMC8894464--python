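"""Seeded synthetic dynamical systems with known causal structure.

Two generators are provided.  ``simulate_coupled_logistic`` produces the
canonical coupled chaotic logistic maps used throughout the cross-mapping
literature as a causality benchmark.  ``simulate_mock_ecosystem`` produces a
five-variable monthly lake system — phytoplankton species richness, biomass,
nitrate, phosphate and water temperature — in which temperature is an
exogenous seasonal forcing and the biological/chemical variables are coupled
through a nonlinear skeleton.  Both return the ground-truth causal network
implied by their coupling matrix, which downstream recovery experiments score
against.

``add_observation_layer`` degrades a clean simulation the way monitoring data
are degraded: a long-term linear trend, an additional seasonal measurement
component, i.i.d. observation noise, and missing months.  These are exactly
the artefacts the preprocessing stage is designed to remove.

All values live on normalized (0, 1) scales; the inference pipeline is
invariant to affine rescaling, so physical units would add nothing to the
benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, ValidationError
from .preprocessing import MonthlySeries

__all__ = [
    "CouplingSpec",
    "GroundTruthNetwork",
    "ObservationSpec",
    "SiteDataset",
    "simulate_coupled_logistic",
    "simulate_mock_ecosystem",
    "add_observation_layer",
    "default_ecosystem_spec",
    "default_observation_spec",
    "two_species_spec",
    "simulate_ar1",
]

#: clipping tolerance keeping the logistic map inside (0, 1) under noise
CLIP_EPS = 1e-6

ECOSYSTEM_VARIABLES = ("richness", "biomass", "no3", "po4", "temperature")


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of a coupled nonlinear map.

    ``coupling_matrix[i][j]`` is the strength with which variable j forces
    variable i; a nonzero off-diagonal entry is a ground-truth causal edge
    j -> i.  Diagonal entries describe self-regulation and are never reported
    as edges.  For logistic variables ``growth_rates`` holds the map parameter
    r; for the mock ecosystem's nutrient stocks it holds the replenishment
    rate of the constant-loading term.
    """

    variable_names: tuple[str, ...]
    growth_rates: np.ndarray
    coupling_matrix: np.ndarray
    exogenous_flags: tuple[bool, ...]
    initial_state: np.ndarray
    process_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "growth_rates", np.asarray(self.growth_rates, float))
        object.__setattr__(self, "coupling_matrix", np.asarray(self.coupling_matrix, float))
        object.__setattr__(self, "initial_state", np.asarray(self.initial_state, float))
        n = len(self.variable_names)
        if self.growth_rates.shape != (n,) or self.initial_state.shape != (n,):
            raise ValidationError("growth_rates and initial_state must have one entry per variable")
        if self.coupling_matrix.shape != (n, n):
            raise ValidationError("coupling_matrix must be square with one row per variable")
        if len(self.exogenous_flags) != n:
            raise ValidationError("exogenous_flags must have one entry per variable")
        if not (
            np.isfinite(self.growth_rates).all()
            and np.isfinite(self.coupling_matrix).all()
            and np.isfinite(self.initial_state).all()
            and np.isfinite(self.process_noise_sd)
        ):
            raise ValidationError("non-finite parameter in CouplingSpec")
        if self.process_noise_sd < 0:
            raise ValidationError("process_noise_sd must be >= 0")
        off = self.coupling_matrix.copy()
        np.fill_diagonal(off, 0.0)
        for i, exo in enumerate(self.exogenous_flags):
            if exo and np.any(off[i] != 0):
                raise ValidationError(
                    f"exogenous variable {self.variable_names[i]!r} must have a zero "
                    "off-diagonal coupling row"
                )

    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    def ground_truth(self) -> "GroundTruthNetwork":
        """Edges j -> i for every nonzero off-diagonal coupling entry."""
        edges = set()
        for i in range(self.n_vars):
            for j in range(self.n_vars):
                if i != j and self.coupling_matrix[i, j] != 0:
                    edges.add((self.variable_names[j], self.variable_names[i]))
        return GroundTruthNetwork(frozenset(edges))


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Set of directed (cause, effect) pairs implied by a CouplingSpec."""

    edges: frozenset[tuple[str, str]]

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["cause", "effect"])


@dataclass(frozen=True)
class ObservationSpec:
    """Observation-layer artefacts added on top of a clean simulation.

    trend_slope and seasonal_amplitude are per-variable mappings (missing
    variables default to 0); seed fully determines noise and gap placement.
    """

    trend_slope: dict = field(default_factory=dict)  # units per month
    seasonal_amplitude: dict = field(default_factory=dict)
    seasonal_phase: float = 0.0
    obs_noise_sd: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must be in [0, 1)")
        if self.obs_noise_sd < 0:
            raise ValidationError("obs_noise_sd must be >= 0")


@dataclass
class SiteDataset:
    """One site's multivariate monthly dataset plus its ground truth."""

    site: str
    start: tuple[int, int]
    data: pd.DataFrame  # one column per variable, one row per month
    truth: GroundTruthNetwork
    spec: CouplingSpec

    def to_monthly_series(self) -> dict[str, MonthlySeries]:
        return {
            var: MonthlySeries(self.site, var, self.start, self.data[var].to_numpy())
            for var in self.data.columns
        }

    def to_long_frame(self) -> pd.DataFrame:
        frames = [s.to_frame() for s in self.to_monthly_series().values()]
        return pd.concat(frames, ignore_index=True)


def two_species_spec(
    beta_xy: float = 0.0,
    beta_yx: float = 0.1,
    r: tuple[float, float] = (3.8, 3.5),
    process_noise_sd: float = 0.0,
) -> CouplingSpec:
    """Two-species logistic benchmark: X forces Y with strength ``beta_yx``.

    The defaults (r = 3.8/3.5, unidirectional coupling 0.1) are the standard
    cross-mapping benchmark configuration from the empirical dynamic
    modelling literature.
    """
    return CouplingSpec(
        variable_names=("X", "Y"),
        growth_rates=np.array(r),
        coupling_matrix=np.array([[0.0, beta_xy], [beta_yx, 0.0]]),
        exogenous_flags=(False, False),
        initial_state=np.array([0.4, 0.2]),
        process_noise_sd=process_noise_sd,
    )


def simulate_coupled_logistic(
    spec: CouplingSpec,
    n_steps: int,
    burn_in: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruthNetwork]:
    """Iterate the coupled logistic map and return the post-burn-in record.

    Update rule for each variable i:

        x_i(t+1) = x_i(t) * (r_i - r_i*x_i(t) - sum_{j != i} beta_ij * x_j(t))
                   + process noise

    clipped to (CLIP_EPS, 1 - CLIP_EPS).  In noise-free mode a trajectory
    leaving (0, 1) means the parameters are outside the map's stable chaotic
    regime and raises :class:`InvalidParameterError` rather than being
    silently clipped.
    """
    if n_steps < 50:
        raise ValidationError("n_steps must be >= 50")
    if burn_in < 0:
        raise ValidationError("burn_in must be >= 0")
    if np.any(spec.initial_state <= 0) or np.any(spec.initial_state >= 1):
        raise ValidationError("initial states must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = spec.n_vars
    total = burn_in + n_steps
    out = np.empty((total, n))
    x = spec.initial_state.copy()
    r = spec.growth_rates
    beta = spec.coupling_matrix.copy()
    np.fill_diagonal(beta, 0.0)
    noise_free = spec.process_noise_sd == 0
    for t in range(total):
        out[t] = x
        nxt = x * (r - r * x - beta @ x)
        if noise_free:
            if np.any(nxt <= 0) or np.any(nxt >= 1):
                raise InvalidParameterError(
                    "trajectory left (0, 1) in noise-free mode; parameters are "
                    "outside the bounded regime"
                )
        else:
            nxt = nxt + rng.normal(0.0, spec.process_noise_sd, size=n)
        x = np.clip(nxt, CLIP_EPS, 1 - CLIP_EPS)
    frame = pd.DataFrame(out[burn_in:], columns=list(spec.variable_names))
    return frame, spec.ground_truth()


def default_ecosystem_spec(process_noise_sd: float = 0.02) -> CouplingSpec:
    """Default five-variable mock lake ecosystem.

    Richness and biomass follow chaotic logistic maps coupled to each other,
    to the nutrient stocks and to the temperature deviation; nitrate and
    phosphate are depleted by biomass (and, for nitrate, by community uptake
    that scales with richness) and replenished by constant loading.
    Temperature is exogenous: a seasonal sinusoid plus an AR(1) anomaly.
    Negative coupling entries are facilitative (nutrients enhance growth),
    positive entries suppressive; the sign is irrelevant to the ground-truth
    edge set.
    """
    names = ECOSYSTEM_VARIABLES
    # rows: richness, biomass, no3, po4, temperature; cols in the same order
    beta = np.array(
        [
            #  R      B      N      P      T
            [0.00,  0.15, -0.30,  0.00,  0.50],  # richness
            [0.15,  0.00, -0.30, -0.25,  0.50],  # biomass
            [0.10,  0.50,  0.00,  0.00,  0.25],  # no3
            [0.00,  0.40,  0.00,  0.00,  0.25],  # po4
            [0.00,  0.00,  0.00,  0.00,  0.00],  # temperature (exogenous)
        ]
    )
    return CouplingSpec(
        variable_names=names,
        growth_rates=np.array([3.70, 3.60, 0.30, 0.25, 0.0]),
        coupling_matrix=beta,
        exogenous_flags=(False, False, False, False, True),
        initial_state=np.array([0.4, 0.3, 0.6, 0.6, 0.5]),
        process_noise_sd=process_noise_sd,
    )


# temperature skeleton parameters (normalized scale)
_T_MEAN = 0.5
_T_SEASONAL_AMPLITUDE = 0.25
_T_AR_PHI = 0.6
_T_ANOMALY_SD = 0.12  # stationary sd of the AR(1) anomaly


def simulate_mock_ecosystem(
    n_years: int,
    seed: int = 0,
    spec: CouplingSpec | None = None,
    site: str = "site",
    start: tuple[int, int] = (2000, 1),
    burn_in: int = 120,
) -> SiteDataset:
    """Simulate one site of the mock lake ecosystem at monthly resolution.

    Temperature is a seasonal sinusoid plus an AR(1) anomaly and must be
    flagged exogenous in ``spec``; richness and biomass follow coupled
    logistic maps forced by nutrients and the temperature deviation; nutrient
    stocks follow

        n(t+1) = n(t) + lambda * (1 - n(t)) - n(t) * (uptake terms) + noise

    i.e. constant loading toward a normalized capacity of 1 and depletion
    proportional to the stock and its consumers.  All states are clipped to
    (CLIP_EPS, 1 - CLIP_EPS).
    """
    if not 16 <= n_years <= 41:
        raise ValidationError("n_years must be in [16, 41]")
    if spec is None:
        spec = default_ecosystem_spec()
    if tuple(spec.variable_names) != ECOSYSTEM_VARIABLES:
        raise ValidationError(f"spec must use variables {ECOSYSTEM_VARIABLES}")
    i_t = spec.variable_names.index("temperature")
    if not spec.exogenous_flags[i_t]:
        raise ValidationError("temperature must be flagged exogenous")

    rng = np.random.default_rng(seed)
    n_steps = n_years * 12
    total = burn_in + n_steps
    names = spec.variable_names
    idx = {v: names.index(v) for v in names}
    r = spec.growth_rates
    beta = spec.coupling_matrix.copy()
    np.fill_diagonal(beta, 0.0)
    noise_sd = spec.process_noise_sd

    # temperature: deterministic season + AR(1) anomaly (zero-noise -> anomaly 0)
    start_month = start[1]
    months = (start_month - 1 - burn_in + np.arange(total)) % 12 + 1
    season = _T_SEASONAL_AMPLITUDE * np.sin(2 * np.pi * months / 12.0)
    anomaly = np.zeros(total)
    if noise_sd > 0:
        innov_sd = _T_ANOMALY_SD * np.sqrt(1 - _T_AR_PHI**2)
        eps = rng.normal(0.0, innov_sd, size=total)
        for t in range(1, total):
            anomaly[t] = _T_AR_PHI * anomaly[t - 1] + eps[t]
    temp = _T_MEAN + season + anomaly

    logistic_vars = [idx["richness"], idx["biomass"]]
    nutrient_vars = [idx["no3"], idx["po4"]]

    out = np.empty((total, len(names)))
    x = spec.initial_state.copy()
    x[i_t] = temp[0]
    for t in range(total):
        out[t] = x
        drive = x.copy()
        drive[i_t] = x[i_t] - _T_MEAN  # couple to the temperature deviation
        nxt = x.copy()
        for i in logistic_vars:
            nxt[i] = x[i] * (r[i] - r[i] * x[i] - beta[i] @ drive)
        for i in nutrient_vars:
            nxt[i] = x[i] + r[i] * (1.0 - x[i]) - x[i] * (beta[i] @ drive)
        if noise_sd > 0:
            endo = logistic_vars + nutrient_vars
            nxt[endo] = nxt[endo] + rng.normal(0.0, noise_sd, size=len(endo))
        nxt[i_t] = temp[min(t + 1, total - 1)]
        x = np.clip(nxt, CLIP_EPS, 1 - CLIP_EPS)
        x[i_t] = nxt[i_t]  # temperature is not confined to (0, 1)
    frame = pd.DataFrame(out[burn_in:], columns=list(names))
    return SiteDataset(site=site, start=start, data=frame, truth=spec.ground_truth(), spec=spec)


def default_observation_spec(seed: int = 0) -> ObservationSpec:
    """Observation layer emulating long-term monitoring records.

    Slopes are a few 1e-4 normalized units per month (a visible multidecadal
    trend), the measurement-level seasonal component is small relative to the
    skeleton's own seasonality, observation noise is a few percent of the
    variables' range, and 3% of months are missing at random.
    """
    return ObservationSpec(
        trend_slope={"richness": 3e-4, "biomass": 2e-4, "no3": -2e-4, "po4": -1e-4,
                     "temperature": 2e-4},
        seasonal_amplitude={"richness": 0.03, "biomass": 0.03, "no3": 0.02, "po4": 0.02},
        seasonal_phase=0.0,
        obs_noise_sd=0.02,
        missing_fraction=0.03,
        seed=seed,
    )


def add_observation_layer(dataset: SiteDataset, obs: ObservationSpec) -> SiteDataset:
    """Overlay trend, seasonality, noise and gaps on a clean simulation.

    Adds slope * t and amplitude * sin(2*pi*month/12 + phase) per variable,
    i.i.d. Gaussian noise everywhere, and masks exactly
    round(missing_fraction * n) months per variable, uniformly at random
    under ``obs.seed``.
    """
    rng = np.random.default_rng(obs.seed)
    data = dataset.data.copy()
    n = len(data)
    t = np.arange(n, dtype=float)
    start_month = dataset.start[1]
    months = (start_month - 1 + np.arange(n)) % 12 + 1
    for var in data.columns:
        v = data[var].to_numpy(dtype=float).copy()
        v += obs.trend_slope.get(var, 0.0) * t
        amp = obs.seasonal_amplitude.get(var, 0.0)
        if amp:
            v += amp * np.sin(2 * np.pi * months / 12.0 + obs.seasonal_phase)
        if obs.obs_noise_sd > 0:
            v += rng.normal(0.0, obs.obs_noise_sd, size=n)
        n_missing = int(round(obs.missing_fraction * n))
        if n_missing:
            gaps = rng.choice(n, size=n_missing, replace=False)
            v[gaps] = np.nan
        data[var] = v
    return replace_dataset(dataset, data)


def replace_dataset(dataset: SiteDataset, data: pd.DataFrame) -> SiteDataset:
    return SiteDataset(dataset.site, dataset.start, data, dataset.truth, dataset.spec)


def simulate_ar1(n: int, phi: float = 0.5, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series; a linear-stochastic null for benchmarks."""
    rng = np.random.default_rng(seed)
    innov_sd = sd * np.sqrt(max(1 - phi**2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x
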