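"""Synthetic-city generator with known ground-truth mobility-change effects.

The generator emulates the structure of the mobility data the analysis is
designed for, without attempting to replicate any real geography:

* origins are a ``grid_n x grid_n`` tiling of square cells (census-block
  scale, 200-800 residents each); destinations are the coarser tiling of
  ``dzn_block x dzn_block`` blocks of origin cells;
* a configurable fraction of origins "straddle" a destination boundary (the
  shared edge between two adjacent origin cells is shifted by half a cell),
  so their coverage container is undefined — this exercises the same
  exclusion path that complex real-world boundaries trigger;
* ER and EO index scores are drawn from a correlated Gaussian pair, with EO
  additionally tilted against distance to the city centre (mimicking the
  empirical pattern that high-education/occupation areas cluster centrally),
  then mapped to a SEIFA-like scale (mean 1000, s.d. 100);
* the true per-origin mobility change ``lambda_true`` is a linear field in
  the standardized EO, ER and distance covariates plus Gaussian noise;
* visits follow a gravity rule — expected daily flow from origin *i* to
  destination *z* proportional to ``pop(i) * exp(-d(i,z)/decay_km)``,
  truncated at a 50 km horizon and normalized so each origin emits
  ``visit_rate`` visits per resident per day in the baseline period.  Test
  period flows are baseline flows times ``exp(lambda_true)``.  Counts are
  Poisson per period (optionally gamma-mixed for overdispersion) and stored
  as mean counts per day;
* device-panel coverage counts are Poisson around a per-period rate,
  independent of ``lambda_true`` by default; expected visit flows co-scale
  with the same per-period panel level (both are tallies from one device
  panel), so the raw test/baseline visit ratio is biased by panel
  fluctuation and the coverage normalization removes that bias — the
  property the metric exists for.  A coupling switch exists to study
  coverage bias.

Determinism: one global seed expands to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage, substream))`` with fixed
stage numbers (0 partitions, 1 SES, 2 ground truth, 3 visits, 4 coverage;
substream 0 = baseline, 1 = test).  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import ConfigurationError
from .ingest import PartitionSet, write_partitions

_STAGE_PARTITIONS = 0
_STAGE_SES = 1
_STAGE_TRUTH = 2
_STAGE_VISITS = 3
_STAGE_COVERAGE = 4

_PERIOD_SUBSTREAM = {"baseline": 0, "test": 1}


@dataclass(frozen=True)
class PeriodSpec:
    """An observation window: label ('baseline' or 'test') and duration in days."""

    label: str
    duration_days: int = 30

    def __post_init__(self) -> None:
        if self.label not in _PERIOD_SUBSTREAM:
            raise ConfigurationError(f"period label must be baseline/test, got {self.label!r}")
        if int(self.duration_days) < 1:
            raise ConfigurationError("duration_days must be >= 1")


@dataclass
class CityConfig:
    """Parameters of the synthetic city.

    Effects (beta_*) are per standard deviation of the covariate, on the
    natural-log mobility-change scale.  Panel rates are expected coverage
    counts per origin per day.  ``rho_er_eo**2 + gamma_eo_dist**2`` must not
    exceed 1 (both enter the EO score as orthogonal components).
    """

    grid_n: int = 20
    dzn_block: int = 4
    cell_km: float = 1.0
    pop_range: tuple = (200, 800)
    rho_er_eo: float = 0.9
    gamma_eo_dist: float = -0.4
    beta_eo: float = -0.1
    beta_er: float = 0.0
    beta_dist: float = 0.0
    sigma_noise: float = 0.2
    panel_rate_base: float = 500.0
    panel_rate_test: float = 450.0
    visit_rate: float = 0.6
    decay_km: float = 5.0
    max_radius_km: float = 50.0
    straddle_fraction: float = 0.02
    nb_overdispersion: float = 0.0
    coverage_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.grid_n < 4:
            raise ConfigurationError("grid_n must be >= 4")
        if self.dzn_block < 1:
            raise ConfigurationError("dzn_block must be >= 1")
        if self.grid_n % self.dzn_block != 0:
            raise ConfigurationError(
                f"grid_n ({self.grid_n}) must be divisible by dzn_block ({self.dzn_block})"
            )
        lo, hi = self.pop_range
        if not (0 < lo <= hi):
            raise ConfigurationError("pop_range must satisfy 0 < min <= max")
        if abs(self.rho_er_eo) >= 1:
            raise ConfigurationError("|rho_er_eo| must be < 1")
        if self.rho_er_eo**2 + self.gamma_eo_dist**2 > 1:
            raise ConfigurationError("rho_er_eo**2 + gamma_eo_dist**2 must be <= 1")
        if self.sigma_noise < 0:
            raise ConfigurationError("sigma_noise must be >= 0")
        if self.panel_rate_base <= 0 or self.panel_rate_test <= 0:
            raise ConfigurationError("panel rates must be > 0")
        if not (0 <= self.straddle_fraction <= 1):
            raise ConfigurationError("straddle_fraction must be in [0, 1]")
        if self.visit_rate <= 0 or self.decay_km <= 0 or self.max_radius_km <= 0:
            raise ConfigurationError("visit_rate, decay_km and max_radius_km must be > 0")
        if self.cell_km <= 0:
            raise ConfigurationError("cell_km must be > 0")
        if self.nb_overdispersion < 0:
            raise ConfigurationError("nb_overdispersion must be >= 0")

    @property
    def centre(self) -> tuple:
        half = self.grid_n * self.cell_km / 2.0
        return (half, half)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pop_range"] = list(self.pop_range)
        return d


@dataclass
class SyntheticCity:
    """Bundle of everything one simulated city produces."""

    config: CityConfig
    periods: tuple
    origins: PartitionSet
    destinations: PartitionSet
    seifa: pd.DataFrame
    truth: pd.DataFrame
    visits: pd.DataFrame
    coverage: pd.DataFrame


def _stage_rng(seed: int, stage: int, substream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(stage, substream)))


def generate_partitions(config: CityConfig):
    """Build the origin and destination tilings, with straddling origins.

    A straddling origin is created by shifting the shared east/west edge of
    two origin cells adjacent to an internal destination-zone boundary half a
    cell eastwards: the west cell then crosses the zone boundary (flagged
    ``straddles``) while the east cell shrinks but stays inside its zone.
    Returns ``(origins, destinations)``.
    """
    config.validate()
    n, b, cell = config.grid_n, config.dzn_block, config.cell_km
    rng = _stage_rng(config.seed, _STAGE_PARTITIONS)

    # cell x-extents, possibly locally perturbed by straddle construction
    xs = np.tile(np.arange(n) * cell, (n, 1))  # [row, col] west edge
    xe = xs + cell
    straddles = np.zeros((n, n), dtype=bool)

    n_straddle = int(round(config.straddle_fraction * n * n))
    if n_straddle > 0:
        boundary_cols = [b * j for j in range(1, n // b)]  # internal zone boundaries
        positions = [(r, c) for r in range(n) for c in boundary_cols]
        if n_straddle > len(positions):
            raise ConfigurationError(
                f"straddle_fraction requests {n_straddle} straddling origins but only "
                f"{len(positions)} boundary positions exist"
            )
        chosen = rng.choice(len(positions), size=n_straddle, replace=False)
        for k in sorted(chosen):
            r, c = positions[k]
            xe[r, c - 1] += cell / 2.0
            xs[r, c] += cell / 2.0
            straddles[r, c - 1] = True

    ids, geoms = [], []
    for r in range(n):
        y0, y1 = r * cell, (r + 1) * cell
        for c in range(n):
            ids.append(f"o{r:03d}c{c:03d}")
            geoms.append(box(xs[r, c], y0, xe[r, c], y1))
    pops = rng.integers(config.pop_range[0], config.pop_range[1] + 1, size=n * n)
    origins = PartitionSet(
        "origin",
        pd.DataFrame(
            {"geometry": geoms, "population": pops, "straddles": straddles.ravel()},
            index=pd.Index(ids, name="region_id"),
        ),
    )

    m = n // b
    dids, dgeoms = [], []
    for r in range(m):
        for c in range(m):
            dids.append(f"dR{r:02d}C{c:02d}")
            dgeoms.append(box(c * b * cell, r * b * cell, (c + 1) * b * cell, (r + 1) * b * cell))
    destinations = PartitionSet(
        "destination",
        pd.DataFrame({"geometry": dgeoms}, index=pd.Index(dids, name="region_id")),
    )
    origins.validate()
    destinations.validate()
    return origins, destinations


def _zdist(origins: PartitionSet, centre) -> pd.Series:
    cents = origins.centroids()
    d = np.hypot(cents["x"] - centre[0], cents["y"] - centre[1])
    return (d - d.mean()) / d.std(ddof=0)


def generate_ses_scores(
    origins: PartitionSet, config: CityConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw correlated ER/EO scores on a SEIFA-like scale (mean 1000, s.d. 100).

    ER is a standard normal draw; EO mixes the same draw (weight
    ``rho_er_eo``), the standardized distance to centre (weight
    ``gamma_eo_dist``) and independent noise, so the target correlations hold
    in expectation.
    """
    config.validate()
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_SES)
    n = len(origins)
    zd = _zdist(origins, config.centre).to_numpy()
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    rho, gam = config.rho_er_eo, config.gamma_eo_dist
    er = u1
    eo = rho * u1 + gam * zd + np.sqrt(max(0.0, 1.0 - rho**2 - gam**2)) * u2

    def seifa_scale(x):
        return 1000.0 + 100.0 * (x - x.mean()) / x.std(ddof=0)

    return pd.DataFrame(
        {"er_score": seifa_scale(er), "eo_score": seifa_scale(eo), "city": "synthetic"},
        index=origins.table.index.copy(),
    )


def make_ground_truth(
    seifa: pd.DataFrame, origins: PartitionSet, config: CityConfig, seed: int | None = None
) -> pd.DataFrame:
    """True mobility-change field: linear in standardized EO, ER, distance + noise.

    Returns a frame indexed by origin id with ``lambda_true`` and the
    standardized covariates ``z_eo``, ``z_er``, ``z_dist`` used to build it.
    """
    config.validate()
    rng = _stage_rng(config.seed if seed is None else seed, _STAGE_TRUTH)

    def z(x):
        return (x - x.mean()) / x.std(ddof=0)

    z_eo = z(seifa["eo_score"].to_numpy())
    z_er = z(seifa["er_score"].to_numpy())
    z_d = _zdist(origins, config.centre).to_numpy()
    lam = (
        config.beta_eo * z_eo
        + config.beta_er * z_er
        + config.beta_dist * z_d
        + rng.normal(0.0, config.sigma_noise, size=len(seifa))
    )
    return pd.DataFrame(
        {"lambda_true": lam, "z_eo": z_eo, "z_er": z_er, "z_dist": z_d},
        index=seifa.index.copy(),
    )


def generate_visits(
    origins: PartitionSet,
    destinations: PartitionSet,
    truth: pd.DataFrame,
    period: PeriodSpec,
    config: CityConfig,
    seed: int | None = None,
):
    """Draw the visit edge list and coverage table for one period.

    Returns ``(visits, coverage)`` data frames.  Edges beyond the 50 km
    visit horizon are absent; zero-count edges within the horizon are kept.
    Coverage rows are absent for straddling origins (undefined coverage).
    """
    config.validate()
    base_seed = config.seed if seed is None else seed
    sub = _PERIOD_SUBSTREAM[period.label]
    rng_v = _stage_rng(base_seed, _STAGE_VISITS, sub)
    rng_c = _stage_rng(base_seed, _STAGE_COVERAGE, sub)

    oc = origins.centroids().to_numpy()
    dc = destinations.centroids().to_numpy()
    dist = np.hypot(oc[:, None, 0] - dc[None, :, 0], oc[:, None, 1] - dc[None, :, 1])
    mask = dist <= config.max_radius_km
    w = np.where(mask, np.exp(-dist / config.decay_km), 0.0)
    wsum = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        w_norm = np.where(wsum > 0, w / np.where(wsum > 0, wsum, 1.0), 0.0)
    pop = origins.table["population"].to_numpy().astype(float)
    flow = config.visit_rate * pop[:, None] * w_norm  # expected daily visits, baseline

    lam_true = truth["lambda_true"].reindex(origins.table.index).to_numpy()
    rate = config.panel_rate_base if period.label == "baseline" else config.panel_rate_test
    # visit counts come from the same device panel that coverage measures, so
    # expected flows co-scale with the period's panel level (visit_rate is
    # calibrated at the baseline panel); coverage normalization removes this.
    flow = flow * (rate / config.panel_rate_base)
    if period.label == "test":
        flow = flow * np.exp(lam_true)[:, None]

    days = int(period.duration_days)
    mean_rate = flow * days
    if config.nb_overdispersion > 0:
        a = config.nb_overdispersion
        mean_rate = mean_rate * rng_v.gamma(shape=1.0 / a, scale=a, size=mean_rate.shape)
    counts = rng_v.poisson(mean_rate)
    oi, di = np.nonzero(mask)
    visits = pd.DataFrame(
        {
            "origin_id": origins.ids[oi],
            "destination_id": destinations.ids[di],
            "period": period.label,
            "mean_daily_visits": counts[oi, di] / days,
        }
    )

    cov_rate = np.full(len(origins), float(rate))
    if config.coverage_coupling != 0:
        cov_rate = cov_rate * np.exp(config.coverage_coupling * lam_true)
    cov_counts = rng_c.poisson(cov_rate * days) / days
    defined = ~origins.table["straddles"].to_numpy()
    coverage = pd.DataFrame(
        {
            "origin_id": origins.ids[defined],
            "period": period.label,
            "coverage": cov_counts[defined],
        }
    )
    coverage = coverage[coverage["coverage"] > 0].reset_index(drop=True)
    return visits, coverage


DEFAULT_PERIODS = (PeriodSpec("baseline", 30), PeriodSpec("test", 30))


def simulate_city(config: CityConfig, periods=DEFAULT_PERIODS) -> SyntheticCity:
    """Run the whole generator: partitions, scores, truth, visits, coverage."""
    labels = [p.label for p in periods]
    if sorted(labels) != ["baseline", "test"]:
        raise ConfigurationError("periods must be exactly one baseline and one test")
    origins, destinations = generate_partitions(config)
    seifa = generate_ses_scores(origins, config)
    truth = make_ground_truth(seifa, origins, config)
    visits_parts, coverage_parts = [], []
    for period in periods:
        v, c = generate_visits(origins, destinations, truth, period, config)
        visits_parts.append(v)
        coverage_parts.append(c)
    # carry the scores on the origin partitions so GeoJSON output is self-contained
    origins.table["er_score"] = seifa["er_score"]
    origins.table["eo_score"] = seifa["eo_score"]
    return SyntheticCity(
        config=config,
        periods=tuple(periods),
        origins=origins,
        destinations=destinations,
        seifa=seifa,
        truth=truth,
        visits=pd.concat(visits_parts, ignore_index=True),
        coverage=pd.concat(coverage_parts, ignore_index=True),
    )


def write_city(city: SyntheticCity, outdir) -> dict:
    """Write the generator outputs as GeoJSON + CSV; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "origins": outdir / "origins.geojson",
        "destinations": outdir / "destinations.geojson",
        "visits": outdir / "visits.csv",
        "coverage": outdir / "coverage.csv",
        "ses": outdir / "ses.csv",
        "truth": outdir / "truth.csv",
    }
    write_partitions(city.origins, paths["origins"])
    write_partitions(city.destinations, paths["destinations"])
    city.visits.to_csv(paths["visits"], index=False, float_format="%.10g")
    city.coverage.to_csv(paths["coverage"], index=False, float_format="%.10g")
    city.seifa.rename_axis("origin_id").to_csv(paths["ses"], float_format="%.10g")
    city.truth.rename_axis("origin_id").to_csv(paths["truth"], float_format="%.10g")
    return paths
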