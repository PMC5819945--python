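"""End-to-end orchestration: simulate → classify → summarize → fit → energetics.

A :class:`RunConfig` fully determines a run (scenario, classifier constants,
fit options, energetics constants, output directory, seed); the manifest
written at the end lists every stage output with a SHA-256 checksum, so a
rerun from the archived config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, energetics, io, simulate, trajectories

log = logging.getLogger("hiberphys")


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "run_out"
    n_weeks: int = 8
    scenario: dict = field(default_factory=dict)      # ScenarioConfig overrides
    classifier: dict = field(default_factory=dict)    # ClassifierParams overrides
    fit_mode: str = trajectories.RISE_THEN_PLATEAU
    rq: float = energetics.RQ_AD_LIBITUM
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_weeks < 1:
            raise ConfigError("n_weeks must be >= 1")
        try:
            self.scenario_config()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario block: {exc}") from exc
        try:
            self.classifier_params()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid classifier block: {exc}") from exc
        if self.fit_mode not in (trajectories.RISE_THEN_PLATEAU,
                                 trajectories.FLAT_THEN_CHANGE):
            raise ConfigError(f"unknown fit_mode {self.fit_mode!r}")

    def scenario_config(self) -> simulate.ScenarioConfig:
        overrides = {k: (tuple(map(tuple, v)) if isinstance(v, list)
                         and v and isinstance(v[0], list) else
                         tuple(v) if isinstance(v, list) else v)
                     for k, v in self.scenario.items()}
        return simulate.ScenarioConfig(seed=self.seed, n_weeks=self.n_weeks,
                                       **overrides)

    def classifier_params(self) -> classify.ClassifierParams:
        return classify.ClassifierParams(**self.classifier)


def demo_scenario_overrides() -> dict:
    """Scenario block of the demo run: an 8-week late-born-style season with
    nightly activity throughout and daily torpor bouts ramping up during the
    pre-hibernation fattening phase (weeks 6-8)."""
    return {
        "torpor_schedule": [[d, 480.0, 240.0 + 10.0 * (d - 35), 5.0]
                            for d in range(35, 56)],
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sc = cfg.scenario_config()
    nest, ambient, truth = simulate.simulate_prehibernation_trace(sc)
    body, hib_truth = simulate.simulate_hibernation_trace(sc)
    growth, growth_truth = simulate.simulate_growth_series(sc)
    respiro, respiro_truth = simulate.simulate_respirometry(sc)
    dlw, dlw_truth = simulate.simulate_dlw_samples(sc)
    food = simulate.simulate_food_intake(sc)

    io.write_trace_csv(nest, out / "nest.csv")
    io.write_trace_csv(ambient, out / "ambient.csv")
    io.write_trace_csv(body, out / "body.csv")
    growth.to_csv(out / "growth.csv", index=False, float_format="%.3f")
    respiro.to_csv(out / "respirometry.csv", index=False, float_format="%.6f")
    food.to_csv(out / "food.csv", index=False, float_format="%.2f")
    pd.DataFrame({
        "time_d": dlw.sample_times,
        "enrichment_2h": dlw.enrichment_d,
        "enrichment_18o": dlw.enrichment_o,
    }).to_csv(out / "dlw.csv", index=False, float_format="%.10g")
    io.write_ground_truth(truth, out / "nest_truth.json")
    io.write_ground_truth(hib_truth, out / "body_truth.json")
    return {"dlw_samples": dlw, "dlw_truth": dlw_truth,
            "growth_truth": growth_truth, "respiro_truth": respiro_truth,
            "files": ["nest.csv", "ambient.csv", "body.csv", "growth.csv",
                      "respirometry.csv", "food.csv", "dlw.csv",
                      "nest_truth.json", "body_truth.json"]}


def stage_classify(cfg: RunConfig, out: Path) -> dict:
    from .trace import align_ambient
    nest = io.read_trace_csv(out / "nest.csv", source="nest")
    ambient = io.read_trace_csv(out / "ambient.csv", source="ambient")
    body = io.read_trace_csv(out / "body.csv", source="body")
    params = cfg.classifier_params()
    amb1 = align_ambient(ambient, nest.timestamps)
    seg = classify.classify_activity(nest, amb1, params)
    bouts = classify.detect_torpor_bouts(nest, amb1, seg, params)
    weekly = classify.weekly_summaries(bouts, seg, n_weeks=cfg.n_weeks)
    pattern = classify.hibernation_metrics(body, params)

    io.write_episodes_csv(seg, out / "episodes.csv")
    io.write_bouts_csv(bouts, out / "bouts.csv")
    io.write_weekly_csv(weekly, out / "weekly.csv", animal_id="demo")
    with open(out / "hibernation.json", "w") as fh:
        json.dump(dataclasses.asdict(pattern), fh, indent=1, sort_keys=True)
    return {"files": ["episodes.csv", "bouts.csv", "weekly.csv",
                      "hibernation.json"]}


def stage_fit(cfg: RunConfig, out: Path) -> dict:
    growth = pd.read_csv(out / "growth.csv")
    weekly = io.read_weekly_csv(out / "weekly.csv")
    rows = []
    for col, kind in (("body_mass", "body_mass"), ("body_length", "body_length")):
        series = trajectories.TrajectorySeries(
            growth["week"].to_numpy(), growth[col].to_numpy(),
            response_kind=kind, animal_id="demo")
        fit = trajectories.fit_segmented(series, trajectories.RISE_THEN_PLATEAU)
        rows.append(dict(animal_id="demo", response=kind,
                         **dataclasses.asdict(fit)))
    if weekly.shape[0] >= 4:
        series = trajectories.TrajectorySeries(
            weekly["week_index"].to_numpy(dtype=float),
            weekly["total_torpor_duration"].to_numpy(dtype=float),
            response_kind="total_torpor_duration", animal_id="demo")
        fit = trajectories.fit_segmented(series, trajectories.FLAT_THEN_CHANGE)
        rows.append(dict(animal_id="demo", response="total_torpor_duration",
                         **dataclasses.asdict(fit)))
    pd.DataFrame(rows).to_csv(out / "fits.csv", index=False, float_format="%.6g")
    return {"files": ["fits.csv"]}


def stage_energetics(cfg: RunConfig, out: Path, dlw_samples=None) -> dict:
    sc = cfg.scenario_config()
    respiro = pd.read_csv(out / "respirometry.csv")
    v = energetics.vo2_series(respiro["fd_lh"], respiro["fio2"],
                              respiro["feo2"], rq=cfg.rq)
    admr, mr_day, mr_night = energetics.mr_summaries(
        respiro["time_min"], v, night_window=sc.night_window)

    food = pd.read_csv(out / "food.csv")
    diet = energetics.DietComposition.cat_food()
    weekly_kj = [energetics.gross_energy_intake(g, diet) for g in food["food_g"]]
    ecum, ecum_mean, missing = energetics.cumulative_energy(weekly_kj,
                                                            n_weeks=cfg.n_weeks)
    if dlw_samples is None:
        dlw_samples, _ = simulate.simulate_dlw_samples(sc)
    comp = energetics.body_composition_from_dilution(dlw_samples)
    budget = energetics.dlw_energy_budget(dlw_samples, rq=cfg.rq)

    summary = {
        "admr_ml_o2_h": admr, "mr_day_ml_o2_h": mr_day,
        "mr_night_ml_o2_h": mr_night,
        "ecum_mj": ecum, "ecum_mean_mj_week": ecum_mean,
        "missing_weeks": missing,
        "tbw_g": comp.tbw, "ffm_g": comp.ffm, "fm_g": comp.fm,
        "tee_kj_day": budget.tee, "rh2o_g_day": budget.rh2o,
        "k_o_per_day": budget.k_o, "k_d_per_day": budget.k_d,
        "rco2_equation": budget.equation,
    }
    with open(out / "energetics.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {"files": ["energetics.json"], "summary": summary}


def stage_report(cfg: RunConfig, out: Path) -> dict:
    """Per-animal weekly table and trajectory-fit table in one place."""
    weekly = io.read_weekly_csv(out / "weekly.csv")
    fits = pd.read_csv(out / "fits.csv")
    weekly.to_csv(out / "report_weekly.csv", index=False)
    fits[["animal_id", "response", "mode", "slope", "plateau", "breakpoint",
          "slope_se", "rss", "n"]].to_csv(out / "report_fits.csv", index=False)
    return {"files": ["report_weekly.csv", "report_fits.csv"]}


STAGES = ("simulate", "classify", "fit", "energetics", "report")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write a checksummed manifest; returns the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    state: dict = {}
    for stage in STAGES:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                res = stage_simulate(cfg, out)
                state["dlw_samples"] = res["dlw_samples"]
            elif stage == "classify":
                res = stage_classify(cfg, out)
            elif stage == "fit":
                res = stage_fit(cfg, out)
            elif stage == "energetics":
                res = stage_energetics(cfg, out, state.get("dlw_samples"))
            else:
                res = stage_report(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        files.extend(res["files"])
    manifest = {
        "package": "hiberphys",
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "n_weeks": cfg.n_weeks,
            "scenario": cfg.scenario,
            "classifier": cfg.classifier,
            "fit_mode": cfg.fit_mode,
            "rq": cfg.rq,
        },
        "outputs": {name: _sha256(out / name) for name in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
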