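"""End-to-end experiment orchestration.

Runs the full synthetic study for one acquisition model: cohort and BOLD
simulation, optional volumetric GLM + VOI extraction, per-session DCM
inversion, the three pairwise polarity-by-time PEB interaction analyses
with BMR/BMA, joystick kinematics with the repeated-measures ANOVA, and
the blinding McNemar test.  Every stage is seeded from the config and
re-running with the same config and seed reproduces identical numbers.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth, motion as motion_mod, peb as peb_mod
from .schedule import generate_schedule
from .dcm.model import DCMStructure, PriorSpec, HemodynamicConstants, build_inputs
from .dcm.invert import invert, PosteriorEstimate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "glm", "voi", "dcm", "peb", "motion", "blinding",
          "report")


class ConfigError(ValueError):
    """Invalid or contradictory experiment configuration."""


@dataclass
class ExperimentConfig:
    """Settings for one synthetic experiment run."""

    experiment: str = "exp1"
    TR: float = None
    n_volumes: int = None
    n_subjects: int = 21
    effects: dict = None            # polarity -> {connection: shift}; None -> defaults
    noise_fraction: float = 0.10    # observation noise as fraction of signal sd
    drift_amplitude: float = 0.0
    use_volumes: bool = False       # embed volumes and run the GLM/VOI stages
    pp_threshold: float = 0.95
    glm_p_threshold: float = 1e-4
    free_hemo: bool = True
    dcm_max_iter: int = 64
    joystick_miss_rate: float = 0.0
    dropped_motion_runs: int = 0
    blinding_p_active: float = 0.5
    blinding_p_sham: float = 0.5
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self):
        if self.experiment not in synth.ACQUISITION:
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        tr_default, nvol_default = synth.ACQUISITION[self.experiment]
        if self.TR is None:
            self.TR = tr_default
        if self.n_volumes is None:
            self.n_volumes = nvol_default
        if self.TR <= 0 or self.n_volumes <= 0:
            raise ConfigError("TR and n_volumes must be positive")
        if self.n_volumes * self.TR < 320.0:
            raise ConfigError("n_volumes x TR is shorter than the task (320 s)")
        for name in ("pp_threshold", "glm_p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if not 0 <= self.joystick_miss_rate < 1:
            raise ConfigError("joystick_miss_rate must lie in [0, 1)")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def ground_truth_effects(self) -> synth.GroundTruthEffects:
        if self.effects is None:
            return synth.GroundTruthEffects.default(self.experiment)
        return synth.GroundTruthEffects(shifts=self.effects)


@dataclass
class RunManifest:
    """Record of artefacts, seeds and per-stage status of one run."""

    config: dict
    stages: dict = field(default_factory=dict)
    artefacts: dict = field(default_factory=dict)

    def mark(self, stage: str, status: str, wall: float, **info):
        self.stages[stage] = {"status": status, "wall_seconds": round(wall, 3),
                              **info}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages,
                       "artefacts": self.artefacts}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], stages=d["stages"],
                   artefacts=d["artefacts"])


def _session_iter(cfg):
    for s in range(cfg.n_subjects):
        for pol in synth.POLARITIES:
            for t in synth.TIMES:
                yield s, pol, t


def _session_seed(cfg, s, pol, t):
    return (cfg.seed * 1000003 + s * 101
            + synth.POLARITIES.index(pol) * 11 + synth.TIMES.index(t)) % (2 ** 31)


def run_pipeline(config: ExperimentConfig, stages=None,
                 resume: bool = False) -> RunManifest:
    """Execute the pipeline stages in order; returns the run manifest.

    A stage failure halts the run with the partial manifest saved.
    ``resume=True`` skips stages already marked complete in an existing
    manifest in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
    else:
        manifest = RunManifest(config=asdict(config))
    config.to_yaml(out / "config.yaml")
    stages = list(stages or STAGES)
    state = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        if resume and manifest.stages.get(stage, {}).get("status") == "complete":
            logger.info("stage %s already complete; skipping", stage)
            continue
        if stage in ("glm", "voi") and not config.use_volumes:
            manifest.mark(stage, "skipped", 0.0,
                          reason="use_volumes disabled")
            continue
        fn = globals()[f"_stage_{stage}"]
        logger.info("running stage %s", stage)
        t0 = _time.time()
        try:
            info = fn(config, out, manifest, state) or {}
        except Exception as exc:
            manifest.mark(stage, "failed", _time.time() - t0, error=str(exc))
            manifest.save(manifest_path)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.mark(stage, "complete", _time.time() - t0, **info)
        manifest.save(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg, out, manifest, state):
    schedule = generate_schedule(cfg.seed)
    schedule.write_events(out / "events.tsv")
    effects = cfg.ground_truth_effects()
    cohort = synth.generate_cohort(
        synth.CohortSpec(n_subjects=cfg.n_subjects, seed=cfg.seed), effects)
    with open(out / "cohort.json", "w") as fh:
        json.dump(cohort, fh, indent=2)
    runs = {}
    for s, pol, t in _session_iter(cfg):
        model = synth.session_model(cohort, s, pol, t)
        runs[(s, pol, t)] = synth.simulate_session_bold(
            model, schedule, cfg.TR, cfg.n_volumes,
            noise_sd=cfg.noise_fraction, relative_noise=True,
            drift_amplitude=cfg.drift_amplitude,
            seed=_session_seed(cfg, s, pol, t))
    state.update(schedule=schedule, cohort=cohort, runs=runs)
    manifest.artefacts["events"] = str(out / "events.tsv")
    manifest.artefacts["cohort"] = str(out / "cohort.json")
    return {"n_sessions": len(runs)}


def _require(state, key, stage):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} requires the simulate stage in "
                           "the same invocation")
    return state[key]


def _stage_glm(cfg, out, manifest, state):
    from . import glm as glm_mod
    runs = _require(state, "runs", "glm")
    schedule = state["schedule"]
    coords = synth.GROUP_COORDINATES[cfg.experiment]
    effect_maps, labels = [], []
    design = glm_mod.build_design(schedule, cfg.TR, cfg.n_volumes,
                                  motion=np.zeros((cfg.n_volumes, 0)))
    affine = synth.grid_affine()
    state["volumes"] = {}
    for (s, pol, t), run in runs.items():
        img = synth.embed_volumes(run, coords, smooth_noise_sd=0.05,
                                  seed=_session_seed(cfg, s, pol, t) + 7)
        state["volumes"][(s, pol, t)] = img
        _tmap, eff = glm_mod.fit_glm(img, design)
        effect_maps.append(eff)
        labels.append((s, pol, t))
    fmap, supra, clusters = glm_mod.factorial_interaction(
        effect_maps, [l[1] for l in labels], [l[2] for l in labels],
        [l[0] for l in labels], p_threshold=cfg.glm_p_threshold)
    clusters.to_csv(out / "interaction_clusters.csv", index=False)
    state["glm"] = {"design": design, "fmap": fmap, "affine": affine,
                    "effect_maps": effect_maps, "labels": labels}
    manifest.artefacts["interaction_clusters"] = str(out / "interaction_clusters.csv")
    return {"n_clusters": int(clusters.shape[0])}


def _stage_voi(cfg, out, manifest, state):
    from . import glm as glm_mod
    from .voi import PeakSearchPolicy, find_voi_peak, extract_voi
    volumes = _require(state, "volumes", "voi")
    schedule = state["schedule"]
    coords = synth.GROUP_COORDINATES[cfg.experiment]
    policy = PeakSearchPolicy()
    affine = synth.grid_affine()
    mask = np.zeros(synth.DEFAULT_GRID_SHAPE, bool)
    mask[:] = True
    design = state["glm"]["design"]
    rows = []
    state["voi_series"] = {}
    for (s, pol, t), img in volumes.items():
        tmap, _eff = glm_mod.fit_glm(img, design)
        series = {}
        for region, coord in coords.items():
            res = find_voi_peak(tmap, mask, coord, region, policy)
            series[region] = extract_voi(img, res["coord"],
                                         radius=policy.voi_radius,
                                         affine=affine)
            rows.append({"subject": s, "polarity": pol, "time": t,
                         "region": region, "x": res["coord"][0],
                         "y": res["coord"][1], "z": res["coord"][2],
                         "threshold_used": res["threshold_used"],
                         "fallback": res["fallback"]})
        state["voi_series"][(s, pol, t)] = series
    pd.DataFrame(rows).to_csv(out / "voi_peaks.csv", index=False)
    manifest.artefacts["voi_peaks"] = str(out / "voi_peaks.csv")
    return {"n_vois": len(rows)}


def _stage_dcm(cfg, out, manifest, state):
    runs = _require(state, "runs", "dcm")
    schedule = state["schedule"]
    structure = DCMStructure.full(free_hemo=cfg.free_hemo)
    priors = PriorSpec.default(structure)
    inputs = build_inputs(schedule, dt=cfg.TR / 16.0,
                          duration=max(320.0, cfg.n_volumes * cfg.TR))
    posteriors = {}
    for (s, pol, t), run in runs.items():
        if "voi_series" in state:
            regions = list(synth.GROUP_COORDINATES[cfg.experiment])
            Y = np.column_stack([state["voi_series"][(s, pol, t)][r]
                                 for r in regions])
        else:
            Y = run.node_timeseries
        post = invert(Y, structure, priors, inputs, cfg.TR,
                      max_iter=cfg.dcm_max_iter)
        posteriors[(s, pol, t)] = post
    state["posteriors"] = posteriors
    state["structure"] = structure
    state["priors"] = priors
    dump = {f"{s}_{pol}_{t}": p.to_dict()
            for (s, pol, t), p in posteriors.items()}
    with open(out / "dcm_posteriors.json", "w") as fh:
        json.dump(dump, fh)
    manifest.artefacts["dcm_posteriors"] = str(out / "dcm_posteriors.json")
    return {"n_inverted": len(posteriors),
            "n_converged": sum(p.converged for p in posteriors.values())}


def connectivity_field_mask(structure):
    """Boolean mask selecting the A- and B-parameters (connections and
    task modulations) within the free-parameter vector."""
    sl = structure.block_slices()
    mask = np.zeros(structure.n_free, bool)
    for name in ("a_off", "a_self", "b_self"):
        mask[sl[name]] = True
    return mask


def analyse_interactions(posteriors, covariates, structure,
                         param_prior_var=None, pp_threshold=0.95):
    """Three pairwise polarity-by-time PEB ANOVAs with BMR/BMA.

    ``posteriors`` maps (subject, polarity, time) -> PosteriorEstimate.
    Returns {contrast: {"peb": group PEBModel, "bma": BMAResult}}.
    """
    mask = connectivity_field_mask(structure)
    if param_prior_var is None:
        param_prior_var = PriorSpec.default(structure).variance[mask]
    subjects = sorted({k[0] for k in posteriors})
    results = {}
    for contrast, (p1, p2) in peb_mod.CONTRASTS.items():
        subject_level = []
        for s in subjects:
            sessions = [(p, t) for p in (p1, p2) for t in ("pre", "post")]
            X = peb_mod.build_interaction_design(sessions, contrast)
            firsts = [posteriors[(s, p, t)] for p, t in sessions]
            m = peb_mod.fit_peb(firsts, X, field_mask=mask,
                                param_prior_var=param_prior_var * 16,
                                between_var=param_prior_var / 16.0)
            subject_level.append(m.marginal("interaction"))
        Xg = peb_mod.build_group_design(covariates)
        if len(Xg) <= Xg.shape[1]:
            # too few subjects to estimate covariate effects
            Xg = Xg[["mean"]]
        group = peb_mod.fit_peb(subject_level, Xg,
                                param_prior_var=param_prior_var)
        bma = peb_mod.search_and_average(group, search_columns=["mean"],
                                         threshold=pp_threshold)
        results[contrast] = {"peb": group, "bma": bma}
    return results


def _stage_peb(cfg, out, manifest, state):
    posteriors = _require(state, "posteriors", "peb")
    cov = synth.cohort_covariates(state["cohort"])
    results = analyse_interactions(posteriors, cov, state["structure"],
                                   pp_threshold=cfg.pp_threshold)
    state["peb_results"] = results
    info = {}
    for contrast, res in results.items():
        path = out / f"bma_{contrast}.csv"
        res["bma"].to_csv(path)
        manifest.artefacts[f"bma_{contrast}"] = str(path)
        info[contrast] = int(res["bma"].table.flagged.sum())
    return {"flagged_per_contrast": info}


def _stage_motion(cfg, out, manifest, state):
    schedule = _require(state, "schedule", "motion")
    summaries = []
    dropped = 0
    for s, pol, t in _session_iter(cfg):
        if dropped < cfg.dropped_motion_runs:
            dropped += 1
            continue
        seed = _session_seed(cfg, s, pol, t) + 31
        trace, _gt = synth.simulate_joystick(
            schedule, miss_rate=cfg.joystick_miss_rate, seed=seed)
        filt = motion_mod.preprocess_trace(trace)
        trials = motion_mod.extract_trials(filt, schedule, trace.rate)
        summaries.append(motion_mod.summarize_run(
            trials, subject=f"sub-{s + 1:02d}", polarity=pol, time=t).__dict__)
    df = pd.DataFrame(summaries)
    df.to_csv(out / "run_summaries.csv", index=False)
    anova = motion_mod.rm_anova(df) if len(df) else {}
    with open(out / "kinematics_anova.json", "w") as fh:
        json.dump(anova, fh, indent=2)
    state["motion"] = {"summaries": df, "anova": anova}
    manifest.artefacts["run_summaries"] = str(out / "run_summaries.csv")
    manifest.artefacts["kinematics_anova"] = str(out / "kinematics_anova.json")
    return {"n_runs": len(df), "n_dropped": dropped}


def _stage_blinding(cfg, out, manifest, state):
    _df, table = synth.simulate_blinding(
        cfg.n_subjects, cfg.blinding_p_active, cfg.blinding_p_sham,
        seed=cfg.seed + 97)
    res = motion_mod.mcnemar(table)
    payload = {"table": table.tolist(), **res}
    with open(out / "blinding.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    state["blinding"] = payload
    manifest.artefacts["blinding"] = str(out / "blinding.json")
    return {"p": res["p"]}


def _stage_report(cfg, out, manifest, state):
    report_dict = build_report(cfg, state)
    with open(out / "report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        fh.write(format_report(report_dict))
    manifest.artefacts["report_json"] = str(out / "report.json")
    manifest.artefacts["report_txt"] = str(out / "report.txt")
    return {}


# ---------------------------------------------------------------------------
# reporting

def build_report(cfg, state) -> dict:
    """Machine-readable summary comparing recovered and true effects."""
    report = {"experiment": cfg.experiment, "seed": cfg.seed,
              "n_subjects": cfg.n_subjects, "sections": {}}
    effects = cfg.ground_truth_effects()
    if "peb_results" in state:
        rows = []
        for contrast, res in state["peb_results"].items():
            p1, p2 = peb_mod.CONTRASTS[contrast]
            tab = res["bma"].table
            true_shift = {}
            for pol, sign in ((p1, +0.5), (p2, -0.5)):
                for name, val in effects.shifts.get(pol, {}).items():
                    true_shift[name] = true_shift.get(name, 0.0) + sign * val
            for _, r in tab.iterrows():
                name = r.parameter.split(":", 1)[1]
                truth = true_shift.get(name, 0.0)
                rows.append({
                    "contrast": contrast, "parameter": name,
                    "true_effect": truth, "recovered_effect": float(r.effect),
                    "pp": float(r.pp), "flagged": bool(r.flagged),
                    "sign_recovered": bool(truth != 0 and r.flagged
                                           and np.sign(r.effect) == np.sign(truth)),
                })
        report["sections"]["connectivity"] = rows
    if "motion" in state:
        report["sections"]["kinematics"] = state["motion"]["anova"]
    else:
        report["sections"]["kinematics"] = {"status": "skipped"}
    if "blinding" in state:
        report["sections"]["blinding"] = state["blinding"]
    return report


def format_report(report: dict) -> str:
    lines = [f"Synthetic experiment report ({report['experiment']}, "
             f"seed {report['seed']}, n={report['n_subjects']})", ""]
    conn = report["sections"].get("connectivity")
    if conn:
        lines.append("Polarity x time connectivity effects (BMA):")
        lines.append(f"  {'contrast':22s} {'parameter':16s} {'true':>7s} "
                     f"{'recovered':>10s} {'Pp':>6s} flag")
        for r in conn:
            if r["true_effect"] == 0 and not r["flagged"]:
                continue
            lines.append(f"  {r['contrast']:22s} {r['parameter']:16s} "
                         f"{r['true_effect']:+7.2f} "
                         f"{r['recovered_effect']:+10.3f} {r['pp']:6.2f} "
                         f"{'*' if r['flagged'] else ''}")
        lines.append("")
    kin = report["sections"].get("kinematics")
    if kin and "status" not in kin:
        lines.append("Kinematics 2x3 repeated-measures ANOVA:")
        for metric, effectsd in kin.items():
            for eff, v in effectsd.items():
                lines.append(f"  {metric:18s} {eff:12s} F={v['F']:.2f} "
                             f"p={v['p']:.3f} np2={v['partial_eta_sq']:.2f}")
        lines.append("")
    elif kin:
        lines.append("Kinematics: skipped")
    bl = report["sections"].get("blinding")
    if bl:
        lines.append(f"Blinding McNemar: b={bl['b']} c={bl['c']} p={bl['p']:.3f}")
    return "\n".join(lines) + "\n"


_field_mask = connectivity_field_mask
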