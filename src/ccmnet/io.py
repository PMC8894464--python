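"""Readers, writers, run configuration and the end-to-end pipeline.

The interchange format is a long-format CSV with columns
``site, year, month, variable, value`` (empty value = missing month); ground
truth travels as an edge-list CSV ``cause, effect``.  ``run_pipeline`` wires
the stages together — preprocessing, per-site network quantification,
standardization, loop weights, cross-system analyses — and writes every
export plus a manifest (full configuration, seed, package version, warnings)
that regenerates the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_system import (
    DEFAULT_LOG10,
    assemble_cross_system_table,
    rda_permutation_test,
)
from .exceptions import ValidationError
from .network import (
    SiteNetwork,
    build_site_network,
    loops_frame,
    standardize_network,
)
from .pipeline import CCMConfig
from .preprocessing import MonthlySeries, ProcessedSeries, preprocess
from .synthetic import (
    SiteDataset,
    add_observation_layer,
    default_ecosystem_spec,
    default_observation_spec,
    simulate_mock_ecosystem,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_long_csv",
    "write_long_csv",
    "write_truth_csv",
    "simulate_sites",
    "run_pipeline",
]

LONG_COLUMNS = ("site", "year", "month", "variable", "value")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    EDM defaults follow the analysis protocol where it states them
    (E in 2..20, lags 0..3, 500 bootstrap resamples, 10,000 permutations,
    monthly tau = 1); the rest are this package's documented choices.
    """

    data_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "ccmnet_output"
    variables: tuple[str, ...] = ("richness", "biomass", "no3", "po4", "temperature")
    exogenous: tuple[str, ...] = ("temperature",)
    ccm: CCMConfig = field(default_factory=CCMConfig)
    n_perm: int = 10000
    log10_columns: tuple[str, ...] = DEFAULT_LOG10
    # simulation settings (used by the `simulate` stage)
    n_sites: int = 19
    n_years_range: tuple[int, int] = (16, 41)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ccm" in d and isinstance(d["ccm"], dict):
            ccm = dict(d["ccm"])
            for key in ("e_range", "lags"):
                if key in ccm and isinstance(ccm[key], list):
                    ccm[key] = tuple(ccm[key])
            d["ccm"] = CCMConfig(**ccm)
        for key in ("variables", "exogenous", "log10_columns", "n_years_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_long_csv(series: list[MonthlySeries] | pd.DataFrame, path: str | Path) -> None:
    """Write monthly series as long-format CSV (empty cell = missing)."""
    if isinstance(series, pd.DataFrame):
        frame = series
    else:
        frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame.to_csv(path, index=False, columns=list(LONG_COLUMNS))


def write_truth_csv(truth, path: str | Path, coefficients: dict | None = None) -> None:
    frame = truth.to_frame()
    if coefficients:
        frame["coefficient"] = [coefficients.get(t, np.nan) for t in
                                frame[["cause", "effect"]].itertuples(index=False, name=None)]
    frame.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> dict[str, dict[str, MonthlySeries]]:
    """Read long-format CSV into MonthlySeries keyed by site then variable.

    Each (site, variable) gets a contiguous monthly index spanning its first
    to last recorded month; rows absent from the file and empty value cells
    both become missing months.  Duplicate (site, year, month, variable) rows
    and out-of-range months are rejected.
    """
    frame = pd.read_csv(path, dtype={"site": str, "variable": str})
    missing_cols = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"missing columns in {path}: {missing_cols}")
    bad_month = frame[(frame["month"] < 1) | (frame["month"] > 12)]
    if len(bad_month):
        raise ValidationError(
            f"month out of range 1..12 at rows {list(bad_month.index[:5])}"
        )
    values = pd.to_numeric(frame["value"], errors="coerce")
    unparseable = frame["value"].notna() & values.isna() & (frame["value"].astype(str).str.strip() != "")
    if unparseable.any():
        lines = [int(i) + 2 for i in frame.index[unparseable][:5]]  # 1-based + header
        raise ValidationError(f"unparseable value(s) at line(s) {lines}")
    frame = frame.assign(value=values)
    dup = frame.duplicated(subset=["site", "year", "month", "variable"], keep=False)
    if dup.any():
        offenders = frame.loc[dup, ["site", "year", "month", "variable"]].drop_duplicates()
        raise ValidationError(
            f"duplicate (site, year, month, variable) rows: {offenders.to_dict('records')[:5]}"
        )
    out: dict[str, dict[str, MonthlySeries]] = {}
    for (site, var), grp in frame.groupby(["site", "variable"], sort=True):
        period = pd.PeriodIndex.from_fields(
            year=grp["year"].astype(int), month=grp["month"].astype(int), freq="M"
        )
        s = pd.Series(grp["value"].to_numpy(), index=period)
        full = pd.period_range(period.min(), period.max(), freq="M")
        s = s.reindex(full)
        out.setdefault(site, {})[var] = MonthlySeries(
            site, var, (full[0].year, full[0].month), s.to_numpy(dtype=float)
        )
    if not out:
        raise ValidationError(f"no data rows in {path}")
    return out


def simulate_sites(config: RunConfig) -> tuple[list[SiteDataset], pd.DataFrame]:
    """Generate the configured number of mock-ecosystem sites plus metadata.

    Site record lengths are spread evenly across ``n_years_range`` and every
    site gets its own observation layer; the metadata table carries each
    site's depth, area (log-spread across sites) and long-term means of the
    five variables computed from the generated data themselves.
    """
    lo, hi = config.n_years_range
    rng = np.random.default_rng(config.seed)
    datasets = []
    meta_rows = {}
    spec = default_ecosystem_spec()
    for i in range(config.n_sites):
        n_years = int(round(lo + (hi - lo) * (i / max(config.n_sites - 1, 1))))
        site = f"site{i + 1:02d}"
        sim_seed = int(rng.integers(0, 2**31 - 1))
        obs_seed = int(rng.integers(0, 2**31 - 1))
        ds = simulate_mock_ecosystem(n_years, seed=sim_seed, spec=spec, site=site)
        ds = add_observation_layer(ds, default_observation_spec(seed=obs_seed))
        datasets.append(ds)
        means = ds.data.mean()
        meta_rows[site] = {
            "depth": float(10 ** rng.uniform(0.3, 2.3)),  # 2-200 m
            "area": float(10 ** rng.uniform(-1, 3.5)),    # 0.1-3000 km^2
            "mean_richness": float(means["richness"]),
            "mean_temperature": float(means["temperature"]),
            "mean_po4": float(means["po4"]),
            "mean_no3": float(means["no3"]),
            "mean_biomass": float(means["biomass"]),
        }
    metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    metadata.index.name = "site"
    return datasets, metadata


def preprocess_site(
    series_by_var: dict[str, MonthlySeries], variables: tuple[str, ...]
) -> dict[str, ProcessedSeries]:
    """Preprocess one site's series onto their common monthly index."""
    present = [v for v in variables if v in series_by_var]
    aligned = _align_site(series_by_var, present)
    return {v: preprocess(aligned[v]) for v in present}


def _align_site(
    series_by_var: dict[str, MonthlySeries], variables: list[str]
) -> dict[str, MonthlySeries]:
    """Pad each variable's series onto the union monthly index of the site."""
    periods = []
    for v in variables:
        s = series_by_var[v]
        start = pd.Period(year=s.start[0], month=s.start[1], freq="M")
        periods.append(pd.period_range(start, periods=len(s), freq="M"))
    union_start = min(p[0] for p in periods)
    union_end = max(p[-1] for p in periods)
    full = pd.period_range(union_start, union_end, freq="M")
    out = {}
    for v, per in zip(variables, periods):
        s = series_by_var[v]
        padded = pd.Series(s.values, index=per).reindex(full)
        out[v] = MonthlySeries(s.site, v, (full[0].year, full[0].month),
                               padded.to_numpy(dtype=float))
    return out


def run_pipeline(
    config: RunConfig,
    datasets: dict[str, dict[str, MonthlySeries]] | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Execute preprocess -> networks -> standardization -> loops -> cross-system.

    Data come either from ``config.data_path``/``metadata_path`` or directly
    as in-memory objects.  Outputs (per-site edge lists, loops table,
    cross-system tables, RDA summaries, manifest) are written under
    ``config.output_dir``; the returned bundle holds the same objects.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    if datasets is None:
        if config.data_path is None:
            raise ValidationError("no data: set data_path or pass datasets")
        datasets = read_long_csv(config.data_path)
    if metadata is None and config.metadata_path:
        metadata = pd.read_csv(config.metadata_path, index_col="site")

    networks: list[SiteNetwork] = []
    all_links = []
    all_loops = []
    for site in sorted(datasets):
        series_by_var = datasets[site]
        absent = [v for v in config.variables if v not in series_by_var]
        if absent:
            msg = f"site {site}: missing variables {absent}; skipped"
            warnings_log.append(msg)
            logger.warning(msg)
            continue
        try:
            processed = preprocess_site(series_by_var, config.variables)
            net = build_site_network(
                processed,
                variables=list(config.variables),
                config=config.ccm,
                exogenous=set(config.exogenous),
                site=site,
            )
            net = standardize_network(net)
        except ValidationError as exc:
            msg = f"site {site}: {exc}; skipped"
            warnings_log.append(msg)
            logger.warning(msg)
            continue
        networks.append(net)
        frame = net.to_frame()
        frame.to_csv(outdir / f"links_{site}.csv", index=False)
        all_links.append(frame)
        lf = loops_frame(net)
        lf.to_csv(outdir / f"loops_{site}.csv", index=False)
        all_loops.append(lf)
        with open(outdir / f"links_{site}.json", "w") as fh:
            json.dump(
                [l.result.to_record() for l in net.links.values() if l.result],
                fh, indent=1,
            )

    bundle: dict = {"networks": networks, "warnings": warnings_log}
    if all_links:
        pd.concat(all_links, ignore_index=True).to_csv(outdir / "links_all.csv", index=False)
        pd.concat(all_loops, ignore_index=True).to_csv(outdir / "loops_all.csv", index=False)

    if metadata is not None and len(networks) >= 3:
        table = assemble_cross_system_table(
            networks, metadata, log10_columns=config.log10_columns
        )
        table.predictors.to_csv(outdir / "cross_system_predictors.csv")
        rda_rows = []
        for block in table.responses:
            table.block(block).to_csv(outdir / f"cross_system_{block}.csv")
            result, p = rda_permutation_test(
                table.block(block), table.predictors,
                n_perm=config.n_perm, seed=config.seed,
            )
            rda_rows.append(
                {
                    "block": block,
                    "explained_variance": result.explained_variance,
                    "permutation_p": p,
                }
            )
            scores = pd.DataFrame(
                result.site_scores, index=table.sites, columns=["RDA1", "RDA2"]
            )
            scores.to_csv(outdir / f"rda_scores_{block}.csv")
        rda_frame = pd.DataFrame(rda_rows)
        rda_frame.to_csv(outdir / "rda_summary.csv", index=False)
        bundle["cross_system"] = table
        bundle["rda"] = rda_frame

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "n_sites_analyzed": len(networks),
        "warnings": warnings_log,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    bundle["manifest"] = manifest
    return bundle
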