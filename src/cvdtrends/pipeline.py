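"""End-to-end orchestration: generate -> harmonize -> score -> estimate.

A :class:`RunConfig` fixes every input (scenario or raw-extract directory,
coefficient/recalibration tables, algorithm x variant set, seed, options)
and :func:`run_all` emits a reproducible artifact bundle of CSVs into the
output directory:

* ``harmonized.csv`` — pooled harmonized records (all raw columns kept)
* ``audit_<variant>.csv`` — per-year counts by eligibility status
* ``scored_<algorithm>_<variant>.csv`` — analytic sample with appended risks
* ``estimates_<algorithm>_<variant>.csv`` — per-year, per-sex design-based
  estimates of risk (as a percentage) and its components
* ``trends.csv`` — survey-weighted linear slope of mean risk on survey year
  per algorithm x variant x sex (percentage points per year)
* ``wald.csv`` — first-vs-last-year Wald tests of mean risk
* ``run_metadata.json`` — seed, config echo, per-stage record counts
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import harmonize as hz
from . import survey_stats as svy
from .errors import ConfigError
from .synthgen import TrendScenario, generate_pooled
from .tables import default_engine, load_table_config

log = logging.getLogger("cvdtrends")

ALGORITHMS = ("who_style", "globorisk_style")
VARIANTS = ("laboratory", "non_laboratory")


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)
    output_dir: Path
    seed: int = 1
    scenario: TrendScenario | None = None
    raw_dir: Path | None = None  # directory of per-year CSVs (alternative input)
    algorithms: list[str] = Field(default_factory=lambda: list(ALGORITHMS))
    variants: list[str] = Field(default_factory=lambda: list(VARIANTS))
    table_paths: dict[str, Path] = Field(default_factory=dict)  # "algo/variant" -> yaml
    sbp_rule: str = "strict"
    combination: str = "sum_hazards"
    age_basis: str = "attained"
    lonely_psu: str = "centered"

    def validate_inputs(self) -> None:
        if self.scenario is None and self.raw_dir is None:
            raise ConfigError("either a scenario or a raw-extract directory is required")
        if self.raw_dir is not None and not Path(self.raw_dir).is_dir():
            raise ConfigError(f"raw_dir does not exist: {self.raw_dir}")
        for key, p in self.table_paths.items():
            if not Path(p).is_file():
                raise ConfigError(f"table config for {key} not found: {p}")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ConfigError(f"unknown algorithm {a!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigError(f"unknown variant {v!r}")


def _load_raw(config: RunConfig) -> pd.DataFrame:
    if config.raw_dir is not None:
        frames = [pd.read_csv(p) for p in sorted(Path(config.raw_dir).glob("*.csv"))]
        if not frames:
            raise ConfigError(f"no per-year CSVs in {config.raw_dir}")
        return pd.concat(frames, ignore_index=True)
    scenario = config.scenario or TrendScenario()
    return generate_pooled(scenario, seed=config.seed)


def _engine_for(config: RunConfig, algorithm: str, variant: str):
    key = f"{algorithm}/{variant}"
    if key in config.table_paths:
        cfg = load_table_config(config.table_paths[key])
        if (cfg.algorithm, cfg.variant) != (algorithm, variant):
            raise ConfigError(
                f"table config {config.table_paths[key]} declares "
                f"{cfg.algorithm}/{cfg.variant}, expected {key}"
            )
        return cfg.build()
    return default_engine(algorithm, variant)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of the bundle members."""
    from .risk_engine import score_batch  # deferred: keeps import cycles away

    config.validate_inputs()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    meta: dict = {"seed": config.seed, "stages": {}}

    raw = _load_raw(config)
    meta["stages"]["raw_records"] = int(len(raw))
    log.info("raw records: %d across %d years", len(raw), raw["survey_year"].nunique())

    harmonized = hz.harmonize_records(raw, sbp_rule=config.sbp_rule)
    meta["stages"]["outlier_counts"] = harmonized.attrs.get("outlier_counts", {})
    p = out_dir / "harmonized.csv"
    harmonized.to_csv(p, index=False)
    artifacts["harmonized"] = p

    trend_rows = []
    wald_rows = []
    for variant in config.variants:
        analytic, audit = hz.build_analytic(harmonized, variant)
        ap = out_dir / f"audit_{variant}.csv"
        audit.to_csv(ap, index=False)
        artifacts[f"audit_{variant}"] = ap
        meta["stages"][f"analytic_n_{variant}"] = int(len(analytic))
        log.info("variant %s: analytic n = %d", variant, len(analytic))

        for algorithm in config.algorithms:
            models_by_sex, table = _engine_for(config, algorithm, variant)
            scored = score_batch(
                analytic,
                models_by_sex,
                table,
                combination=config.combination,
                age_basis=config.age_basis,
            )
            sp = out_dir / f"scored_{algorithm}_{variant}.csv"
            scored.to_csv(sp, index=False)
            artifacts[f"scored_{algorithm}_{variant}"] = sp

            est = svy.estimates_by_year(scored)
            ep = out_dir / f"estimates_{algorithm}_{variant}.csv"
            est.to_csv(ep, index=False)
            artifacts[f"estimates_{algorithm}_{variant}"] = ep

            tr = svy.trend_by_sex(scored)
            tr.insert(0, "algorithm", algorithm)
            tr.insert(1, "variant", variant)
            trend_rows.append(tr)

            risk_est = est[est["measure"] == "risk_pct"]
            for sex in ("male", "female"):
                sub = risk_est[risk_est["sex"] == sex].sort_values("year")
                if len(sub) < 2:
                    continue
                first, last = sub.iloc[0], sub.iloc[-1]
                mk = lambda r: svy.EstimateWithSE(
                    r["estimate"], r["se"], int(r["df"]), int(r["n"]), r["sum_weights"]
                )
                w = svy.wald_two_years(mk(first), mk(last))
                wald_rows.append(
                    {
                        "algorithm": algorithm,
                        "variant": variant,
                        "sex": sex,
                        "year_first": int(first["year"]),
                        "year_last": int(last["year"]),
                        "mean_first": first["estimate"],
                        "mean_last": last["estimate"],
                        "statistic": w.statistic,
                        "p_value": w.p_value,
                    }
                )

    tp = out_dir / "trends.csv"
    pd.concat(trend_rows, ignore_index=True).to_csv(tp, index=False)
    artifacts["trends"] = tp
    wp = out_dir / "wald.csv"
    pd.DataFrame(wald_rows).to_csv(wp, index=False)
    artifacts["wald"] = wp

    mp = out_dir / "run_metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True))
    artifacts["metadata"] = mp
    return artifacts
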