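"""I/O, session configuration and the end-to-end synthetic protocol.

The protocol mirrors the experimental session: a quasi-static calibration
recording, a PRTS pre-measurement at three amplitudes, 75 learning trials
and a PRTS post-measurement, all on a simulated cohort whose trial-to-trial
parameter drift is known ground truth.  ``run_protocol`` executes

    simulate cohort -> calibrate -> FRF/coherence + bootstrap CIs ->
    learning metrics -> hierarchical trends

and writes results plus a manifest (config hash, per-stage seeds, file
hashes) so identical (config, seed) reproduce identical outputs.

File formats: recordings are CSV with unit-bearing headers
``time_s, platform_tilt_deg, hip_x_m, shoulder_x_m, cop_x_m[, com_deg_truth]``;
stimuli are CSV ``time_s, tilt_deg`` with a JSON sidecar carrying the cycle
structure and generator configuration.
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

from . import __version__
from .boot import BootstrapConfig, bootstrap_statistic
from .calibrate import fit_calibration
from .frf import (
    CycleSet,
    concat_cycle_sets,
    estimate_coherence,
    estimate_frf,
    mean_sway_response,
    segment_cycles,
)
from .learning import METRIC_COLUMNS, metrics_table
from .simulate import (
    DEFAULT_GEOMETRY,
    BalanceModelParams,
    LearningCohortConfig,
    SwayRecording,
    simulate_calibration_recording,
    simulate_learning_cohort,
    simulate_sway,
)
from .stimuli import (
    PP_VELOCITIES,
    StimulusSequence,
    TernaryDesign,
    build_learning_sequence,
    build_prts,
)
from .trend import SamplerConfig, TrendPriors, fit_trend

__all__ = [
    "SessionConfig",
    "ProtocolResults",
    "SchemaError",
    "run_protocol",
    "read_recording",
    "write_recording",
    "read_stimulus",
    "write_stimulus",
]

log = logging.getLogger("posturolab")

RECORDING_COLUMNS = ["time_s", "platform_tilt_deg", "hip_x_m", "shoulder_x_m", "cop_x_m"]
TRUTH_COLUMN = "com_deg_truth"


class SchemaError(ValueError):
    """A data file does not match the expected column schema."""


# ---------------------------------------------------------------------------
# recording / stimulus file round-trips

def write_recording(rec: SwayRecording, path) -> None:
    data = {
        "time_s": rec.time,
        "platform_tilt_deg": rec.platform_tilt,
        "hip_x_m": rec.hip_x,
        "shoulder_x_m": rec.shoulder_x,
        "cop_x_m": rec.cop_x,
    }
    if rec.com_angle is not None:
        data[TRUTH_COLUMN] = rec.com_angle
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_recording(path, subject_id: str = "", trial_label: str = "") -> SwayRecording:
    """Read a recording CSV with strict header validation.

    Raises :class:`SchemaError` on missing columns and on NaN runs longer
    than 1 s in any channel.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise SchemaError(f"{path}: fewer than two samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        raise SchemaError(f"{path}: time_s is not uniformly sampled")
    fs = 1.0 / dt[0]
    for col in df.columns:
        nan = df[col].isna().to_numpy()
        if nan.any():
            run = np.max(
                np.diff(np.flatnonzero(np.diff(np.concatenate([[0], nan, [0]]))))[::2]
            )
            if run > fs:  # longer than 1 s
                raise SchemaError(
                    f"{path}: column {col} has a NaN run of {run / fs:.2f} s (> 1 s)"
                )
    return SwayRecording(
        time=t,
        platform_tilt=df["platform_tilt_deg"].to_numpy(float),
        hip_x=df["hip_x_m"].to_numpy(float),
        shoulder_x=df["shoulder_x_m"].to_numpy(float),
        cop_x=df["cop_x_m"].to_numpy(float),
        sample_rate=float(round(fs, 6)),
        com_angle=df[TRUTH_COLUMN].to_numpy(float) if TRUTH_COLUMN in df else None,
        subject_id=subject_id,
        trial_label=trial_label,
    )


def write_stimulus(stim: StimulusSequence, path, design: TernaryDesign | None = None):
    path = Path(path)
    pd.DataFrame({"time_s": stim.time, "tilt_deg": stim.samples}).to_csv(
        path, index=False, float_format="%.10g"
    )
    sidecar = {
        "label": stim.label,
        "sample_rate": stim.sample_rate,
        "cycle_duration": stim.cycle_duration,
        "n_cycles": stim.n_cycles,
        "excited_frequencies": np.asarray(stim.excited_frequencies).tolist(),
        "velocity_magnitude": stim.velocity_magnitude,
    }
    if design is not None:
        sidecar["design"] = dataclasses.asdict(design)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stimulus(path) -> StimulusSequence:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "tilt_deg"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column(s) ['{col}']")
    meta = json.loads(path.with_suffix(".json").read_text())
    return StimulusSequence(
        samples=df["tilt_deg"].to_numpy(float),
        sample_rate=meta["sample_rate"],
        cycle_duration=meta["cycle_duration"],
        n_cycles=meta["n_cycles"],
        excited_frequencies=np.asarray(meta["excited_frequencies"], float),
        label=meta["label"],
        velocity_magnitude=meta.get("velocity_magnitude"),
    )


# ---------------------------------------------------------------------------
# session configuration

@dataclass
class SessionConfig:
    """Fully serializable description of one synthetic session.

    A run is reproducible bit-for-bit from (config, seed): every stage draws
    its seed from ``seed`` via a splittable seed sequence.
    """

    seed: int = 0
    sample_rate: float = 100.0
    prts_cycles: int = 18
    discard_first: bool = True
    n_boot: int = 400
    ci_level: float = 0.95
    cohort: LearningCohortConfig = field(default_factory=LearningCohortConfig)
    params: BalanceModelParams = field(default_factory=BalanceModelParams)
    # pre -> post controller change applied to the PRTS measurements: the
    # post-measurement uses the cohort's end-of-learning set-point/weight
    post_from_learning_end: bool = True
    trend_sampler: SamplerConfig = field(default_factory=SamplerConfig)
    trend_priors: TrendPriors = field(default_factory=TrendPriors)
    trend_metrics: tuple[str, ...] = tuple(METRIC_COLUMNS)
    substeps: int = 10
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain_dict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["cohort"] = LearningCohortConfig(**raw.get("cohort", {}))
        raw["params"] = BalanceModelParams(**raw.get("params", {}))
        raw["trend_sampler"] = SamplerConfig(**raw.get("trend_sampler", {}))
        raw["trend_priors"] = TrendPriors(**raw.get("trend_priors", {}))
        raw["trend_metrics"] = tuple(raw.get("trend_metrics", METRIC_COLUMNS))
        return cls(**raw)


def _as_plain_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_plain_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _config_dump(cfg: SessionConfig) -> dict:
    d = _as_plain_dict(cfg)
    d.pop("output_dir", None)  # where results land does not identify the run
    return d


def _config_hash(cfg: SessionConfig) -> str:
    return hashlib.sha256(
        json.dumps(_config_dump(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# protocol

@dataclass
class ProtocolResults:
    config: SessionConfig
    calibration: object
    frf_pre: dict
    frf_post: dict
    metrics: pd.DataFrame
    trends: dict
    manifest: dict


def _prts_block(
    cfg: SessionConfig,
    design: TernaryDesign,
    params_by_subject: list[BalanceModelParams],
    seeds,
    condition: str,
):
    """Simulate the three PRTS amplitudes for every subject and pool cycles."""
    out = {}
    for lab, v in PP_VELOCITIES.items():
        stim = build_prts(design, v, cfg.prts_cycles, cfg.sample_rate, label=lab)
        sets = []
        for i, p in enumerate(params_by_subject):
            rec = simulate_sway(
                stim,
                p,
                seed=seeds[(condition, lab, i)],
                substeps=cfg.substeps,
                subject_id=f"S{i:02d}",
                trial_label=f"{condition}_{lab}",
            )
            sets.append(segment_cycles(rec, stim.cycle_duration, cfg.discard_first))
        pool = concat_cycle_sets(sets)
        excited = stim.excited_frequencies

        def statistic(cs: CycleSet, _e=excited):
            fr = estimate_frf(cs, _e)
            coh = estimate_coherence(cs, _e)
            return np.concatenate([fr.gain, fr.phase, coh, mean_sway_response(cs)])

        bres = bootstrap_statistic(
            pool,
            statistic,
            BootstrapConfig(cfg.n_boot, cfg.ci_level, seed=seeds[(condition, lab, "boot")]),
        )
        nf = len(excited)
        fr = estimate_frf(pool, excited)
        fr.coherence = estimate_coherence(pool, excited)
        for name, sl in [
            ("gain", slice(0, nf)),
            ("phase", slice(nf, 2 * nf)),
            ("coherence", slice(2 * nf, 3 * nf)),
            ("mean_response", slice(3 * nf, None)),
        ]:
            fr.ci_low[name] = bres.ci_low[sl]
            fr.ci_high[name] = bres.ci_high[sl]
        out[lab] = {"frf": fr, "pool_cycles": pool.n_cycles, "mean_response": bres.point[3 * nf :]}
    return out


def run_protocol(cfg: SessionConfig) -> ProtocolResults:
    """Execute the full synthetic session; see the module docstring."""
    design = TernaryDesign()
    ss = np.random.SeedSequence(cfg.seed)
    stage = {name: s for name, s in zip(
        ["calibration", "pre", "learning", "post", "boot"], ss.spawn(5)
    )}

    log.info("stage 1/5: calibration")
    cal_rec = simulate_calibration_recording(
        DEFAULT_GEOMETRY, seed=stage["calibration"],
        cop_noise_sd=cfg.cohort.cop_noise_sd,
    )
    calibration = fit_calibration(cal_rec, DEFAULT_GEOMETRY.com_height)

    # per-subject parameter draws shared between pre, learning and post
    cohort = cfg.cohort
    sub_ss = np.random.SeedSequence(cohort.seed).spawn(cohort.n_subjects)
    pre_params, post_params = [], []
    for sseed in sub_ss:
        srng = np.random.default_rng(sseed)
        sp0 = cohort.setpoint_start + srng.normal(0, cohort.setpoint_subject_sd)
        sp1 = cohort.setpoint_end + srng.normal(0, cohort.setpoint_subject_sd)
        w0 = float(np.clip(
            cfg.params.w_prop + srng.normal(0, cohort.wprop_subject_sd), 0.05, 0.95
        ))
        kp = cfg.params.Kp * (1 + srng.normal(0, cohort.kp_subject_frac_sd))
        base = dataclasses.replace(
            cfg.params, Kp=kp, noise_sd=cohort.noise_sd, cop_noise_sd=cohort.cop_noise_sd
        )
        pre_params.append(dataclasses.replace(base, lean_setpoint=sp0, w_prop=w0))
        if cfg.post_from_learning_end and cohort.drift_enabled:
            post_params.append(dataclasses.replace(
                base, lean_setpoint=sp1, w_prop=w0 * cohort.wprop_end_ratio
            ))
        else:
            post_params.append(dataclasses.replace(base, lean_setpoint=sp0, w_prop=w0))

    seed_pool = {}
    pre_seeds = np.random.SeedSequence(int(stage["pre"].generate_state(1)[0] >> 1))
    post_seeds = np.random.SeedSequence(int(stage["post"].generate_state(1)[0] >> 1))
    for cond, sseq in [("pre", pre_seeds), ("post", post_seeds)]:
        children = sseq.spawn(3 * (cohort.n_subjects + 1))
        i = 0
        for lab in PP_VELOCITIES:
            for s in range(cohort.n_subjects):
                seed_pool[(cond, lab, s)] = children[i]
                i += 1
            seed_pool[(cond, lab, "boot")] = int(children[i].generate_state(1)[0] >> 1)
            i += 1

    log.info("stage 2/5: pre-measurement PRTS block")
    frf_pre = _prts_block(cfg, design, pre_params, seed_pool, "pre")

    log.info("stage 3/5: learning phase (%d subjects x %d trials)",
             cohort.n_subjects, cohort.n_trials)
    learn_stim = build_learning_sequence(sample_rate=cfg.sample_rate)
    learn_recs = simulate_learning_cohort(
        cohort, learn_stim, base_params=cfg.params, substeps=cfg.substeps
    )
    metrics = metrics_table(learn_recs, learn_stim)

    log.info("stage 4/5: post-measurement PRTS block")
    frf_post = _prts_block(cfg, design, post_params, seed_pool, "post")

    log.info("stage 5/5: hierarchical trends")
    trends = {}
    trend_seed_root = np.random.SeedSequence(cfg.seed + 7919)
    for metric, mseed in zip(
        cfg.trend_metrics, trend_seed_root.spawn(len(cfg.trend_metrics))
    ):
        trends[metric] = fit_trend(
            metrics, metric,
            priors=cfg.trend_priors, sampler=cfg.trend_sampler,
            seed=int(mseed.generate_state(1)[0] >> 1),
        )

    manifest = {
        "posturolab_version": __version__,
        "config_hash": _config_hash(cfg),
        "config": _config_dump(cfg),
        "calibration": {
            "coef_hip": calibration.coef_hip,
            "coef_shoulder": calibration.coef_shoulder,
            "intercept": calibration.intercept,
            "r_squared": calibration.r_squared,
        },
        "n_learning_recordings": len(learn_recs),
        "pool_cycles": {lab: frf_pre[lab]["pool_cycles"] for lab in frf_pre},
        "trend_slopes": {
            m: {
                "mean": t.beta1.mean,
                "ci_low": t.beta1.ci_low,
                "ci_high": t.beta1.ci_high,
                "significant": t.slope_significant,
            }
            for m, t in trends.items()
        },
    }
    results = ProtocolResults(
        config=cfg,
        calibration=calibration,
        frf_pre=frf_pre,
        frf_post=frf_post,
        metrics=metrics,
        trends=trends,
        manifest=manifest,
    )
    if cfg.output_dir:
        _write_results(results, Path(cfg.output_dir))
    return results


def _frf_frame(fr) -> pd.DataFrame:
    df = pd.DataFrame(
        {"freq_hz": fr.freqs, "gain": fr.gain, "phase_deg": fr.phase,
         "coherence": fr.coherence}
    )
    for name in ("gain", "phase", "coherence"):
        if name in fr.ci_low:
            df[f"{name}_ci_low"] = fr.ci_low[name]
            df[f"{name}_ci_high"] = fr.ci_high[name]
    return df


def _write_results(res: ProtocolResults, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for cond, block in [("pre", res.frf_pre), ("post", res.frf_post)]:
        for lab, d in block.items():
            p = outdir / f"frf_{cond}_{lab}.csv"
            _frf_frame(d["frf"]).to_csv(p, index=False, float_format="%.10g")
            written.append(p)
    p = outdir / "learning_metrics.csv"
    res.metrics.to_csv(p, index=False, float_format="%.10g")
    written.append(p)
    p = outdir / "trends.csv"
    pd.concat(
        [t.summary_frame().assign(metric=m) for m, t in res.trends.items()]
    ).to_csv(p, index=False, float_format="%.10g")
    written.append(p)
    res.manifest["files"] = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in written
    }
    (outdir / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))
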