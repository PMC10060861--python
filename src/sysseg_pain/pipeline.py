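"""End-to-end orchestration: synthesis -> segregation -> scoring -> inference.

A run is driven by a serializable :class:`RunConfig` (YAML on disk). Stages
execute in order, every intermediate artifact is written to the output
directory, and a :class:`RunManifest` records artifact hashes, subject
inclusion/exclusion decisions with machine-readable reasons, and stage
timings. Re-running the same config and seed reproduces the results bundle
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import yaml

from . import __version__
from .atlas import PartitionAtlas, default_partition
from .connectivity import (
    dct_drift_basis,
    compute_fc,
    compute_segregation,
    exclude_high_motion,
    framewise_displacement,
    motion_regressors,
    nuisance_regress,
)
from .io import (
    read_motion_par,
    read_partition,
    read_timeseries,
    write_motion_par,
    write_partition,
    write_timeseries_tsv,
)
from .moderation import ModerationModel
from .scores import score_phenotypes
from .simulate import SimulationConfig, simulate_cohort
from .stats import ancova_group_compare, chi2_from_proportions, ols_standardized, welch_t


@dataclass
class RunConfig:
    """Archivable description of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    synthetic: bool = True
    # synthetic-mode knobs (forwarded to SimulationConfig)
    n_subjects: int = 60
    n_volumes: int = 740
    simulation_overrides: dict = field(default_factory=dict)
    # real-data inputs (used when synthetic=False)
    atlas_path: str | None = None
    timeseries_glob: str | None = None
    motion_glob: str | None = None
    phenotypes_path: str | None = None
    # QC thresholds
    fd_threshold_mm: float = 0.5
    fd_prop_threshold: float = 0.5
    dummy_scans: int = 0
    motion_translations_first: bool = False
    # inference
    pain_experience_variant: str = "mean"
    moderation_focal: str = "sys_default"
    moderation_moderator: str = "pcs_helplessness"
    moderation_covariates: tuple = (
        "age", "sex_female", "fd_mean", "delay_t1_mri_days",
    )
    n_boot: int = 5000
    ci_level: float = 0.95

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["moderation_covariates"] = list(d["moderation_covariates"])
        pathlib.Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(pathlib.Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "moderation_covariates" in data:
            data["moderation_covariates"] = tuple(data["moderation_covariates"])
        return cls(**data)


@dataclass
class RunManifest:
    """Provenance record of a completed run."""

    version: str
    seed: int
    started_utc: str
    stages: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    n_subjects_in: int = 0
    n_subjects_analyzed: int = 0

    def add_artifact(self, name: str, path: pathlib.Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and subject context."""

    def __init__(self, stage: str, message: str, subject: str | None = None):
        self.stage, self.subject = stage, subject
        ctx = f" [subject {subject}]" if subject else ""
        super().__init__(f"stage {stage!r}{ctx}: {message}")


def _simulation_config(config: RunConfig) -> SimulationConfig:
    kwargs = dict(
        n_subjects=config.n_subjects,
        n_volumes=config.n_volumes,
        seed=config.seed,
    )
    kwargs.update(config.simulation_overrides)
    return SimulationConfig(**kwargs)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, write artifacts under ``config.out_dir``, and
    return the manifest. Deterministic for a fixed config."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        started_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    config.to_yaml(out / "config.yaml")
    manifest.add_artifact("config", out / "config.yaml")

    # --- stage: inputs -----------------------------------------------------
    t0 = time.perf_counter()
    if config.synthetic:
        sim = _simulation_config(config)
        cohort = simulate_cohort(sim)
        atlas = sim.partition
        phenotypes = cohort.phenotypes
        ts_map, motion_map = cohort.timeseries, cohort.motion
        syn = out / "synthetic"
        (syn / "timeseries").mkdir(parents=True, exist_ok=True)
        (syn / "motion").mkdir(parents=True, exist_ok=True)
        for sid in phenotypes["subject_id"]:
            write_timeseries_tsv(ts_map[sid], syn / "timeseries" / f"{sid}.tsv")
            write_motion_par(motion_map[sid], syn / "motion" / f"{sid}.par")
        phenotypes.to_csv(syn / "phenotypes.csv", index=False)
        (syn / "ground_truth.json").write_text(cohort.ground_truth.to_json())
        write_partition(atlas, syn / "partition.tsv")
        manifest.add_artifact("phenotypes", syn / "phenotypes.csv")
        manifest.add_artifact("ground_truth", syn / "ground_truth.json")
    else:
        for name, value in (
            ("atlas_path", config.atlas_path),
            ("timeseries_glob", config.timeseries_glob),
            ("motion_glob", config.motion_glob),
            ("phenotypes_path", config.phenotypes_path),
        ):
            if not value:
                raise PipelineError("inputs", f"{name} is required when synthetic=False")
        atlas = read_partition(config.atlas_path)
        phenotypes = pd.read_csv(config.phenotypes_path)
        import glob as _glob

        ts_paths = sorted(pathlib.Path(p) for p in _glob.glob(config.timeseries_glob))
        mot_paths = sorted(pathlib.Path(p) for p in _glob.glob(config.motion_glob))
        ts_map = {p.stem: read_timeseries(p) for p in ts_paths}
        motion_map = {
            p.stem: read_motion_par(p, config.motion_translations_first) for p in mot_paths
        }
    manifest.n_subjects_in = len(phenotypes)
    manifest.stages.append({"stage": "inputs", "seconds": round(time.perf_counter() - t0, 3)})

    # --- stage: motion QC + segregation ------------------------------------
    t0 = time.perf_counter()
    fd_rows, seg_frames = [], []
    for sid in phenotypes["subject_id"]:
        if sid not in ts_map or sid not in motion_map:
            raise PipelineError("segregate", "missing time series or motion trace", sid)
        ts, trace = ts_map[sid], motion_map[sid]
        if config.dummy_scans:
            from .connectivity import MotionTrace, RoiTimeSeries

            k = config.dummy_scans
            ts = RoiTimeSeries(ts.values[k:], ts.tr_seconds, ts.node_labels)
            trace = MotionTrace(trace.rotations[k:], trace.translations[k:])
        if trace.n_volumes != ts.n_volumes:
            raise PipelineError(
                "segregate",
                f"motion has {trace.n_volumes} volumes, series has {ts.n_volumes}",
                sid,
            )
        summary = framewise_displacement(trace, fd_threshold_mm=config.fd_threshold_mm)
        excluded = exclude_high_motion(
            summary, config.fd_threshold_mm, config.fd_prop_threshold
        )
        fd_rows.append(
            {
                "subject_id": sid,
                "fd_mean": summary.fd_mean,
                "prop_above_threshold": summary.prop_above_threshold,
                "excluded": excluded,
            }
        )
        if excluded:
            manifest.exclusions.append(
                {
                    "subject_id": sid,
                    "reason": "high_motion",
                    "detail": (
                        f"{summary.prop_above_threshold:.0%} of frame transitions "
                        f"exceeded {config.fd_threshold_mm} mm "
                        f"(rule: >= {config.fd_prop_threshold:.0%})"
                    ),
                }
            )
            continue
        confounds = np.hstack(
            [motion_regressors(trace), dct_drift_basis(ts.n_volumes, ts.tr_seconds)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean = nuisance_regress(ts, confounds)
            profile = compute_segregation(compute_fc(clean), atlas)
        frame = profile.to_frame()
        frame.insert(0, "subject_id", sid)
        seg_frames.append(frame)
    fd_summary = pd.DataFrame(fd_rows)
    fd_summary.to_csv(out / "fd_summary.csv", index=False)
    manifest.add_artifact("fd_summary", out / "fd_summary.csv")
    if not seg_frames:
        raise PipelineError("segregate", "no subjects survived motion QC")
    segregation = pd.concat(seg_frames, ignore_index=True)
    segregation.to_csv(out / "segregation.csv", index=False)
    manifest.add_artifact("segregation", out / "segregation.csv")
    manifest.stages.append(
        {"stage": "segregate", "seconds": round(time.perf_counter() - t0, 3)}
    )

    # --- stage: scoring -----------------------------------------------------
    t0 = time.perf_counter()
    scored = score_phenotypes(phenotypes, variant=config.pain_experience_variant)
    sys_wide = segregation.pivot(index="subject_id", columns="network", values="sys")
    sys_wide.columns = [f"sys_{c}" for c in sys_wide.columns]
    scored = scored.merge(sys_wide, on="subject_id", how="inner")
    scored = scored.merge(
        fd_summary[["subject_id", "fd_mean"]], on="subject_id", how="left"
    )
    scored.to_csv(out / "scored.csv", index=False)
    manifest.add_artifact("scored", out / "scored.csv")
    manifest.n_subjects_analyzed = len(scored)
    manifest.stages.append({"stage": "scores", "seconds": round(time.perf_counter() - t0, 3)})

    # --- stage: inference ---------------------------------------------------
    t0 = time.perf_counter()
    results = analyze(scored, config, atlas)
    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    manifest.add_artifact("results", out / "results.json")
    manifest.stages.append(
        {"stage": "analyze", "seconds": round(time.perf_counter() - t0, 3)}
    )

    report = make_report(manifest, results, atlas)
    (out / "report.md").write_text(report)
    manifest.add_artifact("report", out / "report.md")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Inference over a scored table
# ---------------------------------------------------------------------------

def analyze(scored: pd.DataFrame, config: RunConfig, atlas: PartitionAtlas) -> dict:
    """Run the inferential chain on the scored per-subject table.

    Returns a JSON-serializable bundle: group comparisons (Welch t and the
    sex chi-square; covariate-adjusted segregation contrasts), partial
    correlations, the two-timepoint pain comparisons, the standardized
    regression with VIFs, and the moderation model with its bootstrap CI and
    Johnson-Neyman region.
    """
    results: dict = {"n_analyzed": int(len(scored))}
    pain = scored[scored["group"] == "pain"]
    nopain = scored[scored["group"] == "no_pain"]
    results["n_pain"], results["n_no_pain"] = int(len(pain)), int(len(nopain))
    if len(pain) < 8 or len(nopain) < 8:
        results["note"] = "groups too small for inference"
        return results

    # group comparisons --------------------------------------------------
    comparisons = {}
    for var in ("age", "bmi", "phq4", "promis_cognitive", "whoqol_age", "fd_mean"):
        x, y = nopain[var].dropna(), pain[var].dropna()
        t, df, p = welch_t(x, y)
        comparisons[var] = {
            "no_pain_mean": float(x.mean()), "no_pain_sd": float(x.std(ddof=1)),
            "pain_mean": float(y.mean()), "pain_sd": float(y.std(ddof=1)),
            "welch_t": t, "df": df, "p": p,
        }
    chi2, p = chi2_from_proportions(
        nopain["sex_female"].mean(), len(nopain), pain["sex_female"].mean(), len(pain)
    )
    comparisons["sex_female"] = {
        "no_pain_prop": float(nopain["sex_female"].mean()),
        "pain_prop": float(pain["sex_female"].mean()),
        "chi2": chi2, "p": p,
    }
    results["group_comparisons"] = comparisons

    cov_cols = ["delay_t1_mri_days", "fd_mean", "age", "sex_female"]
    seg_compare = {}
    for net in atlas.network_names:
        col = f"sys_{net}"
        sub = scored.dropna(subset=[col] + cov_cols)
        f, p, adj = ancova_group_compare(sub[col], sub["group"], sub[cov_cols])
        seg_compare[net] = {"F": f, "p": p, "adjusted_means": adj}
    results["segregation_group_compare"] = seg_compare

    # partial correlations (pain group) ----------------------------------
    from .stats import partial_correlation

    pc = {}
    pcov = pain[["age", "sex_female", "fd_mean"]]
    for net in atlas.network_names:
        row = {}
        for var in ("intensity_t1", "total_interference_t1", "n_pain_sites"):
            sub = pain.dropna(subset=[f"sys_{net}", var])
            r, p = partial_correlation(
                sub[f"sys_{net}"], sub[var], sub[["age", "sex_female", "fd_mean"]]
            )
            row[var] = {"r": r, "p": p}
        pc[net] = row
    _ = pcov
    results["partial_correlations"] = pc

    # two-timepoint comparisons ------------------------------------------
    longitudinal = {}
    for var in ("intensity", "total_interference", "affective_interference",
                "activity_interference"):
        a = pain[f"{var}_t1"].astype(float)
        b = pain[f"{var}_t2"].astype(float)
        t, p = sps.ttest_rel(a, b, nan_policy="omit")
        longitudinal[var] = {
            "t1_mean": float(a.mean()), "t2_mean": float(b.mean()),
            "t": float(t), "p": float(p),
        }
    chi2, p = chi2_from_proportions(
        pain["medication_t1"].astype(float).mean(), len(pain),
        pain["medication_t2"].astype(float).mean(), len(pain),
    )
    longitudinal["medication"] = {"chi2": chi2, "p": p}
    longitudinal["pct_worsening"] = float(
        (pain["pain_experience_longitudinal"] > 0).mean() * 100
    )
    results["longitudinal"] = longitudinal

    # standardized regression --------------------------------------------
    reg_cols = [
        "pcs_helplessness", "sys_default", "sys_dorsoattention",
        "intensity_t1", "affective_interference_t1", "activity_interference_t1",
    ]
    sub = pain.dropna(subset=["pain_experience_longitudinal"] + reg_cols + cov_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg = ols_standardized(
            sub["pain_experience_longitudinal"], sub[reg_cols], sub[cov_cols]
        )
    results["regression"] = {
        "standardized_betas": {k: float(v) for k, v in reg.standardized_betas.items()},
        "p_values": {k: float(v) for k, v in reg.p_values.items()},
        "vif": {k: float(v) for k, v in reg.vif.items()},
        "r_squared": reg.r_squared,
        "n": reg.n_obs,
    }

    # moderation ----------------------------------------------------------
    model = ModerationModel.from_dataframe(
        pain.dropna(subset=["pain_experience_longitudinal"]),
        outcome="pain_experience_longitudinal",
        focal=config.moderation_focal,
        moderator=config.moderation_moderator,
        covariates=[c for c in config.moderation_covariates if c in pain.columns],
    )
    fit = model.fit(n_boot=config.n_boot, ci_level=config.ci_level, seed=config.seed)
    jn = fit.johnson_neyman()
    results["moderation"] = {
        "focal": config.moderation_focal,
        "moderator": config.moderation_moderator,
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "p_values": {k: float(v) for k, v in fit.pvalues.items()},
        "interaction_bootstrap_ci": list(fit.bootstrap_ci),
        "n_boot": fit.n_boot,
        "jn_boundaries": list(jn.boundaries),
        "jn_segments": list(jn.segment_significance),
        "jn_effect_signs": list(jn.segment_effect_sign),
        "jn_moderator_range": list(jn.moderator_range),
    }
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def make_report(manifest: RunManifest, results: dict, atlas: PartitionAtlas) -> str:
    """Human-readable report; every number is taken verbatim from the results
    bundle so the two cannot disagree."""
    lines = [
        "# System segregation & pain progression — run report",
        "",
        f"- pipeline version: {manifest.version}",
        f"- seed: {manifest.seed}",
        f"- subjects in: {manifest.n_subjects_in}; analyzed: {manifest.n_subjects_analyzed}; "
        f"excluded: {len(manifest.exclusions)}",
    ]
    for ex in manifest.exclusions:
        lines.append(f"  - excluded {ex['subject_id']}: {ex['reason']} ({ex['detail']})")
    if results.get("note"):
        lines += ["", f"**{results['note']}**", ""]
        return "\n".join(lines)

    lines += ["", "## Group comparisons (no pain vs pain)", ""]
    lines.append("| variable | no pain mean (SD) | pain mean (SD) | statistic | p |")
    lines.append("|---|---|---|---|---|")
    for var, row in results["group_comparisons"].items():
        if "welch_t" in row:
            lines.append(
                f"| {var} | {row['no_pain_mean']:.2f} ({row['no_pain_sd']:.2f}) "
                f"| {row['pain_mean']:.2f} ({row['pain_sd']:.2f}) "
                f"| t = {row['welch_t']:.3f} | {row['p']:.4g} |"
            )
        else:
            lines.append(
                f"| {var} | {row['no_pain_prop']:.1%} | {row['pain_prop']:.1%} "
                f"| chi2 = {row['chi2']:.3f} | {row['p']:.4g} |"
            )

    lines += ["", "## Segregation by group (covariate-adjusted)", ""]
    lines.append("| network | F | p |")
    lines.append("|---|---|---|")
    for net in atlas.network_names:
        row = results["segregation_group_compare"][net]
        lines.append(f"| {net} | {row['F']:.3f} | {row['p']:.4g} |")

    lines += ["", "## Longitudinal pain comparisons (pain group)", ""]
    lines.append("| variable | T1 mean | T2 mean | t | p |")
    lines.append("|---|---|---|---|---|")
    for var, row in results["longitudinal"].items():
        if isinstance(row, dict) and "t" in row:
            lines.append(
                f"| {var} | {row['t1_mean']:.2f} | {row['t2_mean']:.2f} "
                f"| {row['t']:.3f} | {row['p']:.4g} |"
            )
    med = results["longitudinal"]["medication"]
    lines.append(f"| medication | — | — | chi2 = {med['chi2']:.3f} | {med['p']:.4g} |")
    lines.append(
        f"\n{results['longitudinal']['pct_worsening']:.1f}% of the pain group worsened "
        "(positive pain-experience change)."
    )

    lines += ["", "## Standardized regression on pain-experience change", ""]
    reg = results["regression"]
    lines.append("| regressor | beta | p | VIF |")
    lines.append("|---|---|---|---|")
    for k in reg["standardized_betas"]:
        lines.append(
            f"| {k} | {reg['standardized_betas'][k]:.3f} | {reg['p_values'][k]:.4g} "
            f"| {reg['vif'][k]:.2f} |"
        )
    lines.append(f"\nR^2 = {reg['r_squared']:.3f} (n = {reg['n']})")

    mod = results["moderation"]
    lo, hi = mod["interaction_bootstrap_ci"]
    lines += [
        "",
        "## Moderation",
        "",
        f"Focal {mod['focal']}, moderator {mod['moderator']}: interaction "
        f"b3 = {mod['coefficients']['interaction']:.4f} "
        f"(p = {mod['p_values']['interaction']:.4g}; "
        f"{mod['n_boot']}-resample bootstrap 95% CI [{lo:.4f}, {hi:.4f}])",
        "",
        f"Johnson-Neyman boundaries within {mod['jn_moderator_range']}: "
        f"{mod['jn_boundaries'] or 'none in range'}; segments: {mod['jn_segments']}",
    ]
    return "\n".join(lines) + "\n"
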