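"""Configured, logged, reproducible end-to-end runs.

A run takes a declarative YAML config that either simulates a synthetic city
or reads partitions/visits/coverage/SES from files, then executes:

    ingest -> geometric exclusion & coverage container -> lambda_mob
           -> decile stratification -> trend tests -> regression suite

and writes the numerical table analogues of the study's figures plus a
manifest (config echo, seed, package version, output digests and row
counts).  Identical config + seed produces byte-identical outputs; the
manifest deliberately carries no timestamps so its digest is reproducible.
Any stage failure halts the run, is reported with its stage name, and leaves
a manifest marking the run as failed at that stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MobishiftError
from .ingest import (
    coverage_container,
    find_excluded_pairs,
    read_coverage,
    read_partitions,
    read_ses,
    read_visits,
)
from .metric import aggregate_outflow, compute_lambda, lambda_summary
from .spatial import (
    build_weights,
    distance_to_cbd,
    fit_ols,
    fit_spatial_error,
    fit_spatial_lag,
    model_comparison,
    standardize_predictors,
)
from .strata import decile_assignment, decile_medians, joint_median_grid, letter_values
from .synthetic import CityConfig, PeriodSpec, simulate_city, write_city
from .trend import mk_test

log = logging.getLogger("mobishift")

_CITY_FIELDS = set(CityConfig.__dataclass_fields__)
_MODEL_NAMES = ("ols", "ols_cbd", "lag", "error")


@dataclass
class RunConfig:
    """Validated run configuration (see the YAML schema in the docs)."""

    seed: int = 0
    output_dir: str = "run"
    simulate: CityConfig | None = None
    inputs: dict | None = None
    periods: dict = field(default_factory=lambda: {"baseline": 30, "test": 30})
    scenarios: dict = field(default_factory=lambda: {"scenario": {"test": "test", "baseline": "baseline"}})
    cbd: tuple | None = None
    weights_k: int = 8
    mk_method: str = "normal_approx"
    models: tuple = _MODEL_NAMES
    histogram_bin_width: float = 0.1

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "inputs": dict(self.inputs) if self.inputs else None,
            "periods": dict(self.periods),
            "scenarios": {k: dict(v) for k, v in self.scenarios.items()},
            "cbd": list(self.cbd) if self.cbd else None,
            "weights_k": self.weights_k,
            "mk_method": self.mk_method,
            "models": list(self.models),
            "histogram_bin_width": self.histogram_bin_width,
        }


_TOP_KEYS = {
    "seed", "output_dir", "simulate", "inputs", "periods", "scenarios",
    "cbd", "weights_k", "mk_method", "models", "histogram_bin_width",
}
_INPUT_KEYS = {"origins", "destinations", "visits", "coverage", "ses"}


def parse_config(doc: dict):
    """Turn a parsed YAML document into (RunConfig, problems).

    ``problems`` is a list of ``(severity, message)`` with severity
    ``'error'`` (fatal) or ``'warning'``.
    """
    problems: list = []
    if not isinstance(doc, dict):
        return None, [("error", "config must be a mapping")]
    for key in doc:
        if key not in _TOP_KEYS:
            problems.append(("warning", f"unknown top-level key {key!r} ignored"))

    cfg = RunConfig()
    cfg.seed = int(doc.get("seed", 0))
    cfg.output_dir = str(doc.get("output_dir", "run"))

    sim = doc.get("simulate")
    inputs = doc.get("inputs")
    if sim is not None and inputs is not None:
        problems.append(("error", "give either a simulate block or an inputs block, not both"))
    if sim is None and inputs is None:
        problems.append(("error", "config needs a simulate block or an inputs block"))
    if sim is not None:
        unknown = set(sim) - _CITY_FIELDS
        for key in unknown:
            problems.append(("warning", f"unknown simulate key {key!r} ignored"))
        kwargs = {k: v for k, v in sim.items() if k in _CITY_FIELDS}
        if "pop_range" in kwargs:
            kwargs["pop_range"] = tuple(kwargs["pop_range"])
        kwargs.setdefault("seed", cfg.seed)
        try:
            city = CityConfig(**kwargs)
            city.validate()
            cfg.simulate = city
        except ConfigurationError as exc:
            problems.append(("error", f"simulate: {exc}"))
    if inputs is not None:
        missing = _INPUT_KEYS - set(inputs)
        if missing:
            problems.append(("error", f"inputs block missing {sorted(missing)}"))
        cfg.inputs = {k: str(v) for k, v in inputs.items() if k in _INPUT_KEYS}

    periods = doc.get("periods", {"baseline": 30, "test": 30})
    cfg.periods = {}
    for label, days in periods.items():
        try:
            if int(days) < 1:
                raise ValueError
            cfg.periods[str(label)] = int(days)
        except (TypeError, ValueError):
            problems.append(("error", f"period {label!r}: duration_days must be a positive integer"))
    scenarios = doc.get("scenarios", {"scenario": {"test": "test", "baseline": "baseline"}})
    cfg.scenarios = {}
    for name, pair in scenarios.items():
        if not isinstance(pair, dict) or "test" not in pair or "baseline" not in pair:
            problems.append(("error", f"scenario {name!r} must map 'test' and 'baseline' to period labels"))
            continue
        for role in ("test", "baseline"):
            if pair[role] not in cfg.periods:
                problems.append(
                    ("error", f"scenario {name!r} references unknown period label {pair[role]!r}")
                )
        cfg.scenarios[str(name)] = {"test": str(pair["test"]), "baseline": str(pair["baseline"])}
    if not cfg.scenarios:
        problems.append(("error", "at least one scenario is required"))

    if doc.get("cbd") is not None:
        cbd = doc["cbd"]
        if not (isinstance(cbd, (list, tuple)) and len(cbd) == 2):
            problems.append(("error", "cbd must be a [x, y] pair"))
        else:
            cfg.cbd = (float(cbd[0]), float(cbd[1]))
    cfg.weights_k = int(doc.get("weights_k", 8))
    if cfg.weights_k < 1:
        problems.append(("error", "weights_k must be >= 1"))
    cfg.mk_method = str(doc.get("mk_method", "normal_approx"))
    if cfg.mk_method not in ("normal_approx", "exact"):
        problems.append(("error", f"mk_method must be normal_approx or exact, got {cfg.mk_method!r}"))
    models = doc.get("models", list(_MODEL_NAMES))
    bad = [m for m in models if m not in _MODEL_NAMES]
    if bad:
        problems.append(("error", f"unknown model(s) {bad}; choose from {list(_MODEL_NAMES)}"))
    cfg.models = tuple(m for m in models if m in _MODEL_NAMES)
    cfg.histogram_bin_width = float(doc.get("histogram_bin_width", 0.1))
    if cfg.histogram_bin_width <= 0:
        problems.append(("error", "histogram_bin_width must be > 0"))
    return cfg, problems


def load_config(path):
    """Read and parse a YAML run config file."""
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        return None, [("error", f"{path}: invalid YAML: {exc}")]
    return parse_config(doc or {})


def validate_config(path) -> list:
    """Schema/cross-reference report for a config file: list of (severity, message)."""
    _, problems = load_config(path)
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


class _Stage:
    """Context that tags any exception with the failing stage name."""

    def __init__(self, runner, name):
        self.runner, self.name = runner, name

    def __enter__(self):
        self.runner.stage = self.name
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise MobishiftError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run(config: RunConfig, out_dir=None, seed=None) -> Path:
    """Execute the full pipeline; returns the run directory."""
    runner = _Runner(config, out_dir=out_dir, seed=seed)
    return runner.run()


class _Runner:
    def __init__(self, config: RunConfig, out_dir=None, seed=None):
        self.config = config
        if seed is not None:
            config.seed = int(seed)
            if config.simulate is not None:
                config.simulate.seed = int(seed)
        self.out = Path(out_dir if out_dir is not None else config.output_dir)
        self.stage = "init"
        self.outputs: dict = {}

    def run(self) -> Path:
        cfg = self.config
        self.out.mkdir(parents=True, exist_ok=True)
        try:
            return self._run_stages()
        except Exception as exc:
            manifest = {
                "status": "failed",
                "stage": self.stage,
                "error": str(exc),
                "config": cfg.to_dict(),
                "seed": cfg.seed,
                "version": __version__,
                "outputs": self.outputs,
            }
            (self.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise

    # -- stages ----------------------------------------------------------
    def _run_stages(self) -> Path:
        cfg = self.config
        with _Stage(self, "data"):
            if cfg.simulate is not None:
                periods = tuple(PeriodSpec(lbl, d) for lbl, d in sorted(cfg.periods.items()))
                city = simulate_city(cfg.simulate, periods=periods)
                origins, destinations = city.origins, city.destinations
                visits, coverage, seifa = city.visits, city.coverage, city.seifa
                write_city(city, self.out / "inputs")
                for name, p in (
                    ("inputs/" + f.name, f) for f in sorted((self.out / "inputs").iterdir())
                ):
                    self._register(name, p)
            else:
                origins = read_partitions(cfg.inputs["origins"], "origin")
                destinations = read_partitions(cfg.inputs["destinations"], "destination")
                visits = read_visits(cfg.inputs["visits"])
                coverage = read_coverage(cfg.inputs["coverage"])
                seifa = read_ses(cfg.inputs["ses"])
            log.info(
                "stage=data origins=%d destinations=%d visit_rows=%d coverage_rows=%d",
                len(origins), len(destinations), len(visits), len(coverage),
            )

        with _Stage(self, "geometry"):
            excluded = find_excluded_pairs(origins, destinations)
            container = coverage_container(origins, destinations)
            contained = {o for o, d in container.items() if d is not None}
            coverage = coverage[coverage["origin_id"].isin(contained)].reset_index(drop=True)
            log.info(
                "stage=geometry excluded_pairs=%d contained_origins=%d undefined=%d",
                len(excluded), len(contained), len(origins) - len(contained),
            )

        with _Stage(self, "deciles"):
            deciles = decile_assignment(seifa)
            self._write("deciles.csv", deciles.rename_axis("origin_id").reset_index())

        lambda_rows, excl_rows, med_rows, trend_rows = [], [], [], []
        grid_rows, lv_rows, model_rows, cmp_rows, summary_rows = [], [], [], [], []
        city_label = str(seifa["city"].iloc[0])
        for name, pair in sorted(self.config.scenarios.items()):
            with _Stage(self, f"lambda[{name}]"):
                universe = origins.ids
                out_t = aggregate_outflow(visits, excluded, pair["test"], origins=universe)
                out_b = aggregate_outflow(visits, excluded, pair["baseline"], origins=universe)
                change = compute_lambda(
                    out_t, out_b, coverage, period_test=pair["test"], period_base=pair["baseline"]
                )
                lam = change.lambda_mob.sort_index()
                tab = change.table.sort_index().rename_axis("origin_id").reset_index()
                tab.insert(0, "scenario", name)
                lambda_rows.append(tab)
                ex = change.exclusions.copy()
                ex.insert(0, "scenario", name)
                excl_rows.append(ex)
                median, count, _, _ = lambda_summary(change, self.config.histogram_bin_width)
                summary_rows.append(
                    {"scenario": name, "median_lambda": median, "n_origins": count}
                )
                log.info(
                    "stage=lambda scenario=%s defined=%d omitted=%d median=%.4f",
                    name, count, len(ex), median,
                )

            with _Stage(self, f"trends[{name}]"):
                for index_name, col in (("ER", "er_decile"), ("EO", "eo_decile")):
                    med = decile_medians(lam, deciles[col])
                    for d, m in enumerate(med, start=1):
                        med_rows.append(
                            {"scenario": name, "index": index_name, "decile": d, "median_lambda": m}
                        )
                    tr = mk_test(med, method=self.config.mk_method)
                    trend_rows.append(
                        {
                            "city": city_label, "scenario": name, "index": index_name,
                            "n": tr.n, "S": tr.S, "var_S": tr.var_S, "z": tr.z,
                            "p_two_sided": tr.p_two_sided, "method": tr.method,
                        }
                    )
                med_grid, cnt_grid = joint_median_grid(lam, deciles["er_decile"], deciles["eo_decile"])
                for er_d in med_grid.index:
                    for eo_d in med_grid.columns:
                        grid_rows.append(
                            {
                                "scenario": name, "er_decile": er_d, "eo_decile": eo_d,
                                "median_lambda": med_grid.loc[er_d, eo_d],
                                "count": cnt_grid.loc[er_d, eo_d],
                            }
                        )
                for index_name, col in (("ER", "er_decile"), ("EO", "eo_decile")):
                    for d in range(1, 11):
                        vals = lam[deciles[col].reindex(lam.index) == d]
                        if len(vals) == 0:
                            continue
                        lv = letter_values(vals)
                        lv.insert(0, "decile", d)
                        lv.insert(0, "index", index_name)
                        lv.insert(0, "scenario", name)
                        lv_rows.append(lv)

            if self.config.models:
                with _Stage(self, f"models[{name}]"):
                    model_df, cmp_df = self._fit_models(name, lam, seifa, origins)
                    model_rows.append(model_df)
                    cmp_rows.append(cmp_df)

        with _Stage(self, "outputs"):
            self._write("lambda.csv", pd.concat(lambda_rows, ignore_index=True))
            self._write("exclusions.csv", pd.concat(excl_rows, ignore_index=True))
            self._write("lambda_summary.csv", pd.DataFrame(summary_rows))
            self._write("decile_medians.csv", pd.DataFrame(med_rows))
            self._write("trend_results.csv", pd.DataFrame(trend_rows))
            self._write("joint_grid.csv", pd.DataFrame(grid_rows))
            self._write("letter_values.csv", pd.concat(lv_rows, ignore_index=True))
            if model_rows:
                self._write("model_summary.csv", pd.concat(model_rows, ignore_index=True))
                self._write("model_comparison.csv", pd.concat(cmp_rows, ignore_index=True))
            manifest = {
                "status": "ok",
                "config": self.config.to_dict(),
                "seed": self.config.seed,
                "version": __version__,
                "outputs": self.outputs,
            }
            (self.out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("stage=done outputs=%d dir=%s", len(self.outputs), self.out)
        return self.out

    def _fit_models(self, scenario: str, lam: pd.Series, seifa: pd.DataFrame, origins):
        cfg = self.config
        units = lam.index.sort_values()
        y = lam.loc[units]
        base = seifa.loc[units, ["er_score", "eo_score"]].rename(
            columns={"er_score": "ER", "eo_score": "EO"}
        )
        cents = origins.centroids()
        cbd = cfg.cbd if cfg.cbd is not None else (float(cents["x"].mean()), float(cents["y"].mean()))
        dist = distance_to_cbd(origins, cbd).loc[units]
        needs_spatial = any(m in cfg.models for m in ("lag", "error"))
        weights = build_weights(cents.loc[units], k=cfg.weights_k) if needs_spatial else None

        results = []
        if "ols" in cfg.models:
            Xz, _, _ = standardize_predictors(base)
            results.append(fit_ols(y, Xz, model_name="ols"))
        if "ols_cbd" in cfg.models:
            Xc = base.copy()
            Xc["dist_cbd"] = dist
            Xz, _, _ = standardize_predictors(Xc)
            results.append(fit_ols(y, Xz, model_name="ols_cbd"))
        if "lag" in cfg.models:
            Xz, _, _ = standardize_predictors(base)
            results.append(fit_spatial_lag(y, Xz, weights))
        if "error" in cfg.models:
            Xz, _, _ = standardize_predictors(base)
            results.append(fit_spatial_error(y, Xz, weights))
        frames = []
        for r in results:
            f = r.to_frame()
            f.insert(0, "scenario", scenario)
            frames.append(f)
        cmp_df = model_comparison(results)
        cmp_df.insert(0, "scenario", scenario)
        log.info(
            "stage=models scenario=%s n=%d models=%s", scenario, results[0].n,
            ",".join(r.model for r in results),
        )
        return pd.concat(frames, ignore_index=True), cmp_df

    # -- bookkeeping -----------------------------------------------------
    def _write(self, name: str, df: pd.DataFrame) -> None:
        path = self.out / name
        _write_csv(df, path)
        self._register(name, path)

    def _register(self, name: str, path: Path) -> None:
        rows = None
        if path.suffix == ".csv":
            with open(path, "rb") as fh:
                rows = max(sum(1 for _ in fh) - 1, 0)
        self.outputs[name] = {"sha256": _sha256(path), "rows": rows}
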