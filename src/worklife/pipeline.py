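"""End-to-end orchestration: simulate/load -> counting process -> estimates
-> simulation intervals -> discrete-time hazard models -> tidy CSV report.

A single master seed is fanned out to independent per-stage seeds, every
output table passes its conservation checks before being written, and a
JSON manifest records the configuration hash, the per-stage seeds and the
counts at each filtering step, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from .episodes import (count_transitions, episodes_to_process,
                       filter_rare_transitions, merge_states,
                       observation_window)
from .estimators import (aalen_johansen, nelson_aalen,
                         occupation_probabilities, restricted_mean_times)
from .hazard import build_panel, fit_cloglog_gee, hrr_table
from .inference import simulation_ci
from .io import (read_covariates, read_episodes, write_covariates,
                 write_episodes)
from .simulate import default_config, generate_cohort
from .states import FULL_STATES, merged_state_space

log = logging.getLogger("worklife")

MERGED_LABELS = {1: "employment", 2: "sick leave", 3: "time limited benefits",
                 4: "disability benefits", 5: "emigrated", 6: "dead"}


@dataclass
class PipelineConfig:
    """User-facing configuration (YAML/JSON mappable)."""

    simulate: bool = True
    scale: int = 1000
    episodes_csv: str | None = None
    covariates_csv: str | None = None
    seed: int = 0
    min_count: int = 10
    mean_ages: tuple[float, float] = (20.0, 45.0)
    mean_ci_level: float = 0.99
    hrr_level: float = 0.95
    ci_reps: int = 1000
    outcome_states: tuple[int, ...] = (6, 5, 4, 3, 2)  # merged-space codes
    adjusted_models: bool = True
    group_curves: bool = True
    origin_age: float = 20.0
    grid_ages: tuple[float, ...] = tuple(float(a) for a in range(20, 59))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("mean_ages", "outcome_states", "grid_ages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    transition_counts: pd.DataFrame
    restricted_means: pd.DataFrame
    occupation_curves: pd.DataFrame | None
    hrr: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _check_conservation(report: AnalysisReport, span: float) -> None:
    """Refuse to emit tables violating the conservation invariants."""
    rm = report.restricted_means
    for grp, sub in rm.groupby("population"):
        tot = sub["estimate"].sum()
        if abs(tot - span) > 1e-6:
            raise AssertionError(
                f"restricted means for {grp!r} sum to {tot}, not {span}")
    if report.occupation_curves is not None:
        oc = report.occupation_curves
        sums = oc.groupby(["population", "age"])["estimate"].sum()
        if (np.abs(sums - 1.0) > 1e-8).any():
            raise AssertionError("occupation probabilities do not sum to 1")
    ref = report.hrr
    if not ref.empty:
        ref_rows = ref[(ref["iq"] == "average") & (ref["mental"] == "none")]
        if not np.allclose(ref_rows["hrr"], 1.0):
            raise AssertionError("reference-group HRR differs from 1")


def run_pipeline(config: PipelineConfig | str | Path,
                 out_dir: str | Path | None = None) -> AnalysisReport:
    """Run all stages in order; write CSVs + manifest when out_dir given."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_ci, seed_spare = [int(s.generate_state(1)[0]) % (2 ** 31)
                                     for s in ss.spawn(3)]
    manifest: dict = {"config_hash": config.config_hash(),
                      "seeds": {"master": config.seed, "simulate": seed_sim,
                                "ci": seed_ci}}

    # --- stage 1: cohort -------------------------------------------------
    if config.simulate:
        cohort = generate_cohort(default_config(config.scale), seed=seed_sim)
        episodes, covariates = cohort.episodes, cohort.covariates
        windows = cohort.windows
    else:
        if not (config.episodes_csv and config.covariates_csv):
            raise ValueError("simulate=False needs episodes_csv and "
                             "covariates_csv")
        episodes = read_episodes(config.episodes_csv)
        covariates = read_covariates(config.covariates_csv)
        entry, exit_ = observation_window(covariates["birth_year"])
        windows = pd.DataFrame({"person_id": covariates["person_id"],
                                "entry_age": entry, "exit_age": exit_})
    manifest["n_persons"] = int(len(windows))
    log.info("cohort: %d persons, %d episodes", len(windows), len(episodes))

    # --- stage 2: counting process --------------------------------------
    events, intervals = episodes_to_process(episodes, windows, FULL_STATES)
    counts = count_transitions(events, intervals, FULL_STATES)
    log.info("transitions observed: %d (plus %d censored spells)",
             counts.total_transitions, counts.total_censored)
    filt = filter_rare_transitions(events, intervals, counts,
                                   min_count=config.min_count, space=FULL_STATES)
    manifest["removed_rare_transitions"] = [list(p) for p in filt.removed]
    manifest["n_events_raw"] = int(len(events))
    manifest["n_events_retained"] = int(len(filt.events))
    log.info("rare-transition filter (<%d events): removed pairs %s",
             config.min_count, filt.removed)

    # --- stage 3: estimation on the merged six-state space ---------------
    ev6, iv6, merged = merge_states(filt.events, filt.intervals, FULL_STATES)
    H6 = nelson_aalen(ev6, iv6, merged)
    t0, t1 = config.mean_ages
    ci = simulation_ci(H6, "restricted_mean", origin_age=config.origin_age,
                       t0=t0, t1=t1, B=config.ci_reps,
                       level=config.mean_ci_level, seed=seed_ci)
    rm_rows = [dict(population="all", state=merged.labels[c],
                    estimate=ci.point[i], lower=ci.lower[i],
                    upper=ci.upper[i], level=config.mean_ci_level)
               for i, c in enumerate(merged.codes)]
    restricted_means = pd.DataFrame(rm_rows)

    # --- stage 4: per-group occupation curves on the full space ----------
    occupation = None
    if config.group_curves:
        cls = cov.classify_cohort(covariates)
        grid = np.asarray(config.grid_ages, dtype=float)
        frames = []
        pops = {"all": pd.Series(True, index=cls.index)}
        for group in sorted(cls["group"].dropna().unique()):
            pops[group] = cls["group"] == group
        for pop, mask in pops.items():
            ids = set(cls.loc[mask, "person_id"])
            sub_ev = filt.events[filt.events["person_id"].isin(ids)]
            sub_iv = filt.intervals[filt.intervals["person_id"].isin(ids)]
            if sub_iv.empty:
                continue
            Hg = nelson_aalen(sub_ev, sub_iv, FULL_STATES)
            curve = occupation_probabilities(Hg, config.origin_age)
            f = curve.to_frame(grid=grid[grid >= config.origin_age])
            f.insert(0, "population", pop)
            frames.append(f)
        occupation = pd.concat(frames, ignore_index=True)

    # --- stage 5: discrete-time hazard models ----------------------------
    fits = []
    for outcome in config.outcome_states:
        panel = build_panel(iv6, ev6, covariates, outcome, merged,
                            windows=windows)
        for adjusted in ([False, True] if config.adjusted_models
                         else [False]):
            try:
                fits.append(fit_cloglog_gee(panel, adjusted=adjusted,
                                            outcome_state=outcome))
            except ValueError as err:
                log.warning("outcome %s (adjusted=%s) skipped: %s",
                            MERGED_LABELS.get(outcome, outcome), adjusted,
                            err)
    hrr = hrr_table(fits, level=config.hrr_level, space=merged) if fits \
        else pd.DataFrame(columns=["outcome", "iq", "mental", "period",
                                   "hrr", "lo", "hi", "p", "adjusted"])

    report = AnalysisReport(
        transition_counts=counts.counts.copy(),
        restricted_means=restricted_means,
        occupation_curves=occupation,
        hrr=hrr,
        manifest=manifest,
    )
    _check_conservation(report, span=t1 - t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.simulate:
            write_episodes(episodes, out / "episodes.csv")
            write_covariates(covariates, out / "covariates.csv")
        report.transition_counts.to_csv(out / "transition_counts.csv")
        report.restricted_means.to_csv(out / "restricted_means.csv",
                                       index=False, float_format="%.6f")
        if report.occupation_curves is not None:
            report.occupation_curves.to_csv(out / "occupation_curves.csv",
                                            index=False,
                                            float_format="%.6f")
        report.hrr.to_csv(out / "hrr.csv", index=False, float_format="%.6f")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
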