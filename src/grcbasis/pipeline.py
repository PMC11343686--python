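"""End-to-end session analysis: generate → condition → align → classify →
plasticity → readout/decode, with deterministic seeding, per-stage logging,
persisted intermediates, and a machine-readable JSON report.

The pipeline is configured by a TOML file with ``[run]``, ``[synth]``,
``[conditioning]`` and ``[plasticity]`` tables whose keys mirror the
corresponding dataclass fields; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bh
from . import classification as cl
from . import conditioning as cond
from . import plasticity as pl
from . import readout as ro
from .synthetic_data import Session, SynthConfig, save_session, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "analyze_session"]

REPORT_SCHEMA = {
    "seed", "config", "behavior", "classification", "plasticity", "readout",
    "decoding",
}


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    conditioning_grc: cond.ConditioningParams = field(
        default_factory=lambda: cond.GRC_PARAMS)
    conditioning_cf: cond.ConditioningParams = field(
        default_factory=lambda: cond.CF_PARAMS)
    plasticity: pl.PlasticityParams = field(default_factory=pl.PlasticityParams)
    seed: int = 0
    outdir: Path | None = None

    def normalized(self) -> dict:
        d = {
            "run": {"seed": self.seed,
                    "outdir": str(self.outdir) if self.outdir else ""},
            "synth": dataclasses.asdict(self.synth),
            "conditioning": dataclasses.asdict(self.conditioning_grc),
            "conditioning_cf": dataclasses.asdict(self.conditioning_cf),
            "plasticity": dataclasses.asdict(self.plasticity),
        }
        return d


def _build(cls, table: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    coerced = {}
    for k, v in table.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def validate_config(path: str | Path) -> RunConfig:
    """Read and normalize a TOML run configuration.

    Missing tables and keys take their defaults; unknown tables or keys are
    rejected.  An empty file yields the all-defaults configuration.
    """
    path = Path(path)
    with open(path, "rb") as f:
        data = tomllib.load(f)
    known = {"run", "synth", "conditioning", "conditioning_cf", "plasticity"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config tables: {sorted(unknown)}")
    run = data.get("run", {})
    bad = set(run) - {"seed", "outdir"}
    if bad:
        raise ValueError(f"unknown keys in [run]: {sorted(bad)}")
    synth = _build(SynthConfig, data.get("synth", {}), "synth")
    grc_p = _build(cond.ConditioningParams, data.get("conditioning", {}),
                   "conditioning")
    cf_table = data.get("conditioning_cf",
                        {"detrend_window_s": 5.0, "median_window_s": 60.0})
    cf_p = _build(cond.ConditioningParams, cf_table, "conditioning_cf")
    plast = _build(pl.PlasticityParams, data.get("plasticity", {}), "plasticity")
    seed = int(run.get("seed", synth.seed))
    if seed != synth.seed:
        synth = dataclasses.replace(synth, seed=seed)
    outdir = Path(run["outdir"]) if run.get("outdir") else None
    return RunConfig(synth=synth, conditioning_grc=grc_p, conditioning_cf=cf_p,
                     plasticity=plast, seed=seed, outdir=outdir)


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig back to TOML (round-trips with validate_config)."""
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, (tuple, list)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return json.dumps(str(v))

    lines = []
    for table, values in config.normalized().items():
        lines.append(f"[{table}]")
        for k, v in values.items():
            if v is None:
                continue
            lines.append(f"{k} = {fmt(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def analyze_session(session: Session,
                    run_config: RunConfig | None = None,
                    control_seeds: tuple[int, ...] | None = None) -> dict:
    """Run the full analysis chain on one session and return the report dict.

    The report aggregates lick-timing metrics, classification fractions, the
    LTD-weight vs anticipatory-center-time correlation, readout timing
    metrics for every weight provenance, and cross-validated time decoding.
    """
    rc = run_config or RunConfig(synth=session.config, seed=session.config.seed)
    cfg = session.config
    fs = cfg.frame_rate_hz
    report: dict = {"seed": rc.seed, "config": dataclasses.asdict(cfg)}

    # --- stage: conditioning -------------------------------------------------
    logger.info("stage conditioning: %d GrCs, %d CFs", cfg.n_grc, cfg.n_cf)
    grc_z = cond.condition_traces(session.grc_raw, session.frame_times,
                                  rc.conditioning_grc)
    cf_z, cf_trains, cf_rates = cond.condition_cf(
        session.cf_raw, session.frame_times, rc.conditioning_cf)

    # --- stage: behavior -----------------------------------------------------
    t = session.behav["t"].to_numpy()
    reaches = bh.detect_reaches(t, session.behav["y"].to_numpy())
    pulse_idx = np.flatnonzero(np.diff(
        (session.behav["reward"].to_numpy() > 0.5).astype(int)) == 1) + 1
    pulses = t[pulse_idx]
    trials = bh.build_trial_table(reaches, pulses, cfg.delay_s)
    trials["valid"] = bh.lick_validity_mask(
        t, session.behav["lick"].to_numpy(), trials)
    lick_rate = bh.lick_rate_trace(t, session.behav["lick"].to_numpy())
    lick_tensor = cl.align_to_trials(
        lick_rate[None, :], t, trials[trials["valid"]],
        alignment="reward", window=(-1.0, 2.0))
    rewarded_lick = cl.align_to_trials(
        lick_rate[None, :], t, trials[trials["valid"]],
        alignment="reward", window=(-1.0, 2.0), subset="rewarded")
    avg_lick = rewarded_lick.trial_average()[0]
    pref = bh.lick_preference(rewarded_lick.time, avg_lick)
    offt = bh.lick_offtime(rewarded_lick.time, avg_lick)
    report["behavior"] = {
        "n_reaches": len(reaches),
        "n_trials": int(len(trials)),
        "n_valid": int(trials["valid"].sum()),
        "n_omitted": int(trials["omitted"].sum()),
        "lick_preference": pref,
        "lick_offtime_s": offt,
    }

    # --- stage: classification ----------------------------------------------
    pre = -max(1.5, cfg.delay_s + 0.4)
    grc_reward = cl.align_to_trials(grc_z, session.frame_times, trials,
                                    alignment="reward", window=(pre, 0.5),
                                    subset="rewarded")
    ant_flags = cl.classify_anticipatory_grcs(grc_reward)
    cf_rate_z = cl.align_to_trials(cl.standardize_rates(cf_rates),
                                   session.frame_times, trials,
                                   alignment="reward",
                                   window=(-1.0, 0.5), subset="rewarded")
    cf_flags = cl.classify_reward_cfs(cf_rate_z)
    avg = grc_reward.trial_average()
    centers = np.array([
        cl.anticipatory_center_time(grc_reward.time, avg[i],
                                    (-cfg.delay_s, 0.0))
        for i in range(avg.shape[0])])
    report["classification"] = {
        "frac_anticipatory_grc": float(ant_flags.mean()),
        "frac_reward_cf": float(cf_flags.mean()),
    }

    # --- stage: plasticity ---------------------------------------------------
    included = pl.select_included_cfs(cf_rate_z, rc.plasticity)
    rewarded = trials[~trials["omitted"]]
    spikes = pl.reward_spike_events(
        [cf_trains[i] for i in np.flatnonzero(included)],
        rewarded["reward_s"].to_numpy(), rc.plasticity)
    weights = pl.compute_session_weights(grc_z, session.frame_times, spikes,
                                         rc.plasticity)
    ltp_ws = pl.compute_ltp_adjusted_weights(
        grc_z, session.frame_times, spikes,
        cf_rates[np.flatnonzero(included)], trials, rc.plasticity,
        seed=rc.seed)
    shuffled = pl.control_weights(grc_z, session.frame_times, spikes, trials,
                                  "time_shuffled", seed=rc.seed,
                                  params=rc.plasticity)
    reordered = pl.control_weights(grc_z, session.frame_times, spikes, trials,
                                   "reordered", seed=rc.seed,
                                   params=rc.plasticity,
                                   true_weights=weights)
    uniform = pl.control_weights(grc_z, session.frame_times, spikes, trials,
                                 "uniform", seed=rc.seed, params=rc.plasticity)
    sets = {"true": weights, "ltp_adjusted": ltp_ws,
            "time_shuffled": shuffled, "reordered": reordered,
            "uniform": uniform}

    ok = np.isfinite(centers) & ant_flags
    if ok.sum() >= 3:
        rho = float(stats.spearmanr(weights.raw_ltd[ok], centers[ok])[0])
        rho_shuf = float(stats.spearmanr(shuffled.raw_ltd[ok], centers[ok])[0])
    else:
        rho = rho_shuf = float("nan")
    report["plasticity"] = {
        "n_included_cf": int(included.sum()),
        "ltd_center_time_spearman": rho,
        "shuffled_center_time_spearman": rho_shuf,
    }

    # --- stage: readout & decoding ------------------------------------------
    delay_tensor = cl.align_to_trials(grc_z, session.frame_times, trials,
                                      alignment="reward",
                                      window=(-cfg.delay_s, 0.0),
                                      subset="rewarded")
    table = ro.compare_readouts(delay_tensor, sets, decode_seed=rc.seed)
    report["readout"] = {
        row["provenance"]: {"abs_r": _clean(row["abs_r"]),
                            "r2": _clean(row["r2"])}
        for _, row in table.iterrows()}
    try:
        dec = ro.decode_time_cv(delay_tensor, seed=rc.seed)
        report["decoding"] = {"r2": dec.r2, "mae_ms": dec.mae_ms}
    except ValueError as err:
        logger.warning("decoding skipped: %s", err)
        report["decoding"] = {"r2": None, "mae_ms": None}

    report["_intermediates"] = {
        "grc_z": grc_z, "cf_z": cf_z, "cf_trains": cf_trains,
        "cf_rates": cf_rates, "trials": trials, "weights": sets,
        "centers": centers, "anticipatory": ant_flags, "reward_cf": cf_flags,
        "included_cf": included,
    }
    return report


def _clean(x) -> float | None:
    x = float(x)
    return None if not np.isfinite(x) else x


def run_pipeline(run_config: RunConfig) -> dict:
    """Execute all stages on a synthetic session and persist every
    intermediate under ``run_config.outdir`` (if set).  Returns the report.

    Stage failures raise with a stage-tagged message; outputs written by
    completed stages are retained.
    """
    outdir = run_config.outdir
    stage = "simulate"
    try:
        session = simulate_session(run_config.synth)
        if outdir:
            save_session(session, Path(outdir) / "session")
        stage = "analyze"
        report = analyze_session(session, run_config)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    inter = report.pop("_intermediates")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inter["trials"].to_csv(outdir / "trials_detected.csv", index=False)
        events = pd.DataFrame(
            [(i, t) for i, tr in enumerate(inter["cf_trains"]) for t in tr],
            columns=["cell_id", "time_s"])
        events.to_csv(outdir / "cf_events.csv", index=False)
        pd.concat([ws.to_frame() for ws in inter["weights"].values()]) \
            .to_csv(outdir / "weights.csv", index=False)
        labels = pd.DataFrame({
            "cell": np.arange(inter["anticipatory"].size),
            "anticipatory_grc": inter["anticipatory"],
            "center_time_s": inter["centers"],
        })
        labels.to_csv(outdir / "grc_labels.csv", index=False)
        (outdir / "params.json").write_text(json.dumps(
            run_config.normalized(), indent=2, sort_keys=True, default=str))
        (outdir / "report.json").write_text(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable under fixed seed) JSON serialization."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, indent=2, sort_keys=True, default=str)
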