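"""Pipeline orchestration: configuration, artifact bundle, run manifest.

``run_emulation`` drives the whole analysis from a YAML/JSON-style config
mapping: load (or simulate) a registry, screen eligibility, clone, weight,
fit, optionally bootstrap, and write every artifact to the output directory
together with a manifest carrying the config hash, the seed, package
versions and a content hash of every file.  Re-running the same config is
byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, ipw, simulate
from .bootstrap import BootstrapSpec, bootstrap
from .clones import StrategyDef
from .estimation import CloneCensorWeight

__all__ = ["ConfigError", "load_config", "build_estimator", "run_emulation"]

log = logging.getLogger("pdatrial")

REQUIRED_KEYS = ("strategies", "output_dir")

VARIANTS = ("main", "cde", "site-covariate", "age-axis")

#: Grace windows of the age-axis sensitivity analysis: closure at a younger
#: (15-20 days of life) vs. older (21-35 days) age, among infants referred
#: before 14 days of age.
AGE_AXIS_STRATEGIES = [
    {"name": "younger", "axis": "age_days", "window": [15, 20], "max_age_at_referral": 13},
    {"name": "older", "axis": "age_days", "window": [21, 35], "max_age_at_referral": 13},
]


class ConfigError(ValueError):
    """The run configuration is missing or misuses a key."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _strategy_from_cfg(item: dict) -> StrategyDef:
    try:
        window = item["window"]
        return StrategyDef(
            name=item["name"],
            axis=item.get("axis", "referral_days"),
            window_start=int(window[0]),
            window_end=int(window[1]),
            max_age_at_referral=item.get("max_age_at_referral"),
        )
    except KeyError as exc:
        raise ConfigError(f"strategy entry is missing key {exc.args[0]!r}: {item}") from None


def apply_variant(cfg: dict, variant: str) -> dict:
    """Return a config adjusted for a named sensitivity analysis."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    cfg = dict(cfg)
    if variant == "cde":
        cfg["competing"] = "cde"
    elif variant == "site-covariate":
        covs = list(cfg.get("covariates", cohort.DEFAULT_ADJUSTMENT_SET))
        if "referral_site" not in covs:
            covs.append("referral_site")
        cfg["covariates"] = covs
    elif variant == "age-axis":
        cfg["strategies"] = AGE_AXIS_STRATEGIES
    return cfg


def build_estimator(cfg: dict) -> CloneCensorWeight:
    strategies = [_strategy_from_cfg(s) for s in cfg["strategies"]]
    return CloneCensorWeight(
        strategies=strategies,
        covariates=cfg.get("covariates"),
        time_spec=cfg.get("time_spec", "cubic"),
        truncation_pct=cfg.get("truncation_pct"),
        stabilized=cfg.get("stabilized", False),
        competing=cfg.get("competing", "total"),
        horizon=cfg.get("horizon", 45),
        screen_eligibility=cfg.get("screen_eligibility", True),
    )


def _get_registry(cfg: dict) -> tuple[pd.DataFrame, Optional[int]]:
    if "registry" in cfg and cfg["registry"]:
        return cohort.read_registry(cfg["registry"]), None
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        seed = int(sim.pop("seed", 0))
        params = simulate.params_from_config(sim)
        return simulate.simulate_registry(params, seed=seed), seed
    raise ConfigError("config must provide either 'registry' (path) or 'simulate' (params)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_emulation(cfg: dict, variant: str = "main") -> dict:
    """Run the configured emulation end to end; returns the manifest.

    Writes to ``cfg['output_dir']``: the exclusion tally, adherence flow,
    clone/weight diagnostics, baseline table, risk curves, effect report,
    figure, and a manifest listing every output with its content hash.
    """
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ConfigError(f"config is missing required key(s): {missing}")
    cfg = apply_variant(cfg, variant)

    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    registry, sim_seed = _get_registry(cfg)
    log.info("registry: %d subjects", len(registry))

    est = build_estimator(cfg)
    est.fit(registry)
    log.info(
        "eligible: %d subjects -> %d clones; adherence: %s",
        est.exclusion_tally_["n_eligible"],
        est.clone_log_["n_clones"],
        est.adherence_flow_,
    )

    report = est.effect_report_
    boot_cfg = cfg.get("bootstrap")
    if boot_cfg:
        spec = BootstrapSpec(
            n_boot=int(boot_cfg.get("n_boot", 200)), seed=int(boot_cfg.get("seed", 0))
        )
        result = bootstrap(registry, est, spec)
        report = result.report
        log.info("bootstrap: %d replicates, %d failed", spec.n_boot, result.n_failed)

    files: dict[str, Path] = {}

    def _write(name: str, writer):
        path = out / name
        writer(path)
        files[name] = path

    _write("exclusions.json", lambda p: p.write_text(json.dumps(est.exclusion_tally_, indent=2)))
    _write("adherence.json", lambda p: p.write_text(json.dumps(est.adherence_flow_, indent=2)))
    _write("person_days.csv", lambda p: est.person_days_.to_csv(p, index=False))
    if est.weight_table_ is not None:
        _write("weights.csv", lambda p: est.weight_table_.to_csv(p, index=False))
        diag = _weight_diagnostics(est)
        _write("weight_diagnostics.txt", lambda p: p.write_text(diag))
    if est.baseline_table_ is not None:
        _write("baseline_table.csv", lambda p: est.baseline_table_.to_csv(p, index=False))
    _write("curves.csv", lambda p: report.curves.to_csv(p, index=False))
    _write("effect_report.json", lambda p: p.write_text(report.to_json()))

    from .plots import risk_curve_figure

    fig = risk_curve_figure(report.curves, report.risk_difference, report.reference)
    _write("curves.png", lambda p: fig.savefig(p, dpi=120))

    manifest = {
        "package": "pdatrial",
        "version": __version__,
        "variant": variant,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "simulation_seed": sim_seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _weight_diagnostics(est: CloneCensorWeight) -> str:
    """Positivity diagnostics: per-day min/max initiation hazard and weights."""
    lines = ["initiation model coefficients:"]
    for k, v in est.initiation_model_.coefficients().items():
        lines.append(f"  {k:28s} {v:+.4f}")
    Xc, _ = ipw.covariate_matrix(est.eligible_, est.initiation_model_.covariates)
    H = est.initiation_model_.hazard_matrix(Xc)
    lines.append("")
    lines.append("day  min_hazard  max_hazard")
    for d in range(H.shape[1]):
        lines.append(f"{d:3d}  {H[:, d].min():10.5f}  {H[:, d].max():10.5f}")
    wt = est.weight_table_
    lines.append("")
    lines.append(
        "weights: mean={:.4f} max={:.2f} truncated_rows={}".format(
            wt["weight_used"].mean(), wt["weight_used"].max(), int(wt["truncated"].sum())
        )
    )
    return "\n".join(lines) + "\n"
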