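"""Synthetic resting-state chronic-pain cohort generator.

Everything downstream — connectivity, segregation, scoring, inference — is
exercised against cohorts produced here, with full ground truth. A cohort
consists of

* parcel time series per subject, drawn from a zero-mean Gaussian whose
  block covariance has correlation ``r_within[net]`` inside each network and
  ``r_between`` across networks (the segregated structure the segregation
  ratio quantifies; the analytic value is
  ``1 - arctanh(r_between) / arctanh(r_within)``),
* rigid-body motion traces (AR(1) positions) rescaled so every subject's mean
  framewise displacement hits a per-subject target,
* an item-level phenotype table in which pain-experience change is generated
  by a planted linear + interaction model on z-scored predictors, and the
  instrument items are generated *consistently with* the target composites so
  the scoring layer is exercised end to end.

Defaults emulate a middle-aged community cohort of 347 (133 chronic pain /
214 pain free), 100 nodes, 7 networks, 740 volumes at TR = 0.8 s, and the
planted standardized effects of the motivating analysis (helplessness 0.325,
default-mode segregation 0.193, dorsal-attention segregation -0.215, baseline
intensity -0.428, affective interference -0.678, activity interference 0.255).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import PartitionAtlas, default_partition
from .connectivity import MotionTrace, RoiTimeSeries, framewise_displacement

#: Planted standardized effects on pain-experience change (pain group).
DEFAULT_BEHAVIORAL_BETAS = {
    "helplessness": 0.325,
    "sys_default": 0.193,
    "sys_dorsoattention": -0.215,
    "intensity_t1": -0.428,
    "affective_interference_t1": -0.678,
    "activity_interference_t1": 0.255,
    "interaction": 0.25,  # helplessness x default-mode segregation
}

#: Within-network correlations chosen so the analytic segregation
#: 1 - arctanh(r_between)/arctanh(r_within) matches typical per-network means.
DEFAULT_R_WITHIN = {
    "default": 0.27,
    "somatomotor": 0.33,
    "control": 0.26,
    "dorsoattention": 0.28,
    "salience_ventral_attention": 0.28,
    "limbic": 0.27,
    "visual": 0.32,
}

#: Group mean framewise-displacement targets (mm) and chronic-pain prevalence.
DEFAULT_FD_TARGET_MM = {"no_pain": 0.163, "pain": 0.179}
DEFAULT_PAIN_PREVALENCE = 133 / 347


def analytic_sys(r_within: float, r_between: float) -> float:
    """Population segregation ratio for the block-correlation model."""
    zw, zb = np.arctanh(r_within), np.arctanh(max(r_between, 0.0))
    return (zw - zb) / zw


@dataclass
class SimulationConfig:
    """Study-condition knobs of the synthetic cohort."""

    n_subjects: int = 347
    partition: PartitionAtlas = field(default_factory=default_partition)
    n_volumes: int = 740          # 750 acquired minus 10 dummy scans
    tr_seconds: float = 0.8
    r_within: dict = field(default_factory=lambda: dict(DEFAULT_R_WITHIN))
    r_between: float = 0.20
    #: between-subject SD of the within-network Fisher-z level (SyS variance)
    sys_z_sd: float = 0.10
    motion_sd_mm: float = 0.05
    fd_target_mm: dict = field(default_factory=lambda: dict(DEFAULT_FD_TARGET_MM))
    fd_target_sd_mm: float = 0.05
    pain_prevalence: float = DEFAULT_PAIN_PREVALENCE
    behavioral_betas: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIORAL_BETAS))
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.partition.n_nodes

    def __post_init__(self):
        nets = set(self.partition.network_names)
        missing = nets - set(self.r_within)
        if missing:
            raise ValueError(f"r_within missing networks: {sorted(missing)}")
        rw_min = min(self.r_within[n] for n in nets)
        if not 0 <= self.r_between < rw_min:
            raise ValueError(
                f"r_between={self.r_between} must lie in [0, min(r_within)={rw_min})"
                " for a segregated ground truth"
            )
        for net, r in self.r_within.items():
            if not 0 < r < 1:
                raise ValueError(f"r_within[{net!r}]={r} outside (0, 1)")
        if self.tr_seconds <= 0 or self.noise_sd < 0 or self.motion_sd_mm < 0:
            raise ValueError("tr_seconds must be positive; SDs nonnegative")
        if self.n_volumes < 2 * self.n_nodes:
            warnings.warn(
                f"n_volumes={self.n_volumes} < 2 x n_nodes={self.n_nodes}; "
                "connectivity estimates may be unstable",
                stacklevel=2,
            )
        # fail early on a non-positive-definite combination
        make_block_covariance(self.partition, self.r_within, self.r_between)


@dataclass
class GroundTruth:
    """Per-subject truths recorded at generation time."""

    seed: int
    groups: list
    true_sys: pd.DataFrame = field(repr=False)
    behavioral_betas: dict = field(default_factory=dict)
    planted_change: pd.Series | None = field(default=None, repr=False)
    clip_rate: float = 0.0

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "groups": list(self.groups),
            "true_sys": self.true_sys.to_dict(orient="list"),
            "behavioral_betas": self.behavioral_betas,
            "planted_change": None
            if self.planted_change is None
            else self.planted_change.where(self.planted_change.notna(), None).tolist(),
            "clip_rate": self.clip_rate,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def make_block_covariance(partition: PartitionAtlas, r_within, r_between: float) -> np.ndarray:
    """Block correlation matrix: 1 on the diagonal, ``r_within[net]`` inside
    each network block, ``r_between`` everywhere else.

    Raises if the combination is not positive definite (it cannot then be a
    correlation matrix of any process).
    """
    if np.isscalar(r_within):
        r_within = {net: float(r_within) for net in partition.network_names}
    for net, r in r_within.items():
        if not 0 <= r < 1:
            raise ValueError(f"r_within[{net!r}]={r} outside [0, 1)")
    if not 0 <= r_between < 1:
        raise ValueError(f"r_between={r_between} outside [0, 1)")
    n = partition.n_nodes
    cov = np.full((n, n), float(r_between))
    for net in partition.network_names:
        idx = partition.nodes_of(net)
        cov[np.ix_(idx, idx)] = r_within[net]
    np.fill_diagonal(cov, 1.0)
    lam_min = np.linalg.eigvalsh(cov)[0]
    if lam_min <= 0:
        raise ValueError(
            "block covariance is not positive definite "
            f"(smallest eigenvalue {lam_min:.3g}); lower r_between or the "
            "spread of r_within values"
        )
    return cov


def simulate_timeseries(config: SimulationConfig, subject_seed, r_within=None) -> RoiTimeSeries:
    """One subject's T x N Gaussian series with the block covariance.

    ``r_within`` overrides the config map (used for per-subject variation);
    identical seeds reproduce identical matrices.
    """
    rw = config.r_within if r_within is None else r_within
    cov = make_block_covariance(config.partition, rw, config.r_between)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(subject_seed)
    white = rng.standard_normal((config.n_volumes, config.n_nodes))
    return RoiTimeSeries(
        white @ chol.T,
        tr_seconds=config.tr_seconds,
        node_labels=config.partition.node_labels,
    )


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def simulate_motion(
    n_volumes: int,
    motion_sd_mm: float,
    seed,
    target_mean_fd: float | None = None,
    ar_coeff: float = 0.95,
) -> MotionTrace:
    """AR(1) rigid-body motion trace (3 rotations rad, 3 translations mm).

    Positions follow an AR(1) random walk with innovation SD ``motion_sd_mm``
    (rotations use the equivalent angle ``motion_sd_mm / 50`` so both
    contribute comparably to displacement on a 50 mm sphere). When
    ``target_mean_fd`` is given the whole trace is rescaled so the realized
    mean framewise displacement equals the target exactly.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(seed)
    if motion_sd_mm == 0:
        return MotionTrace(np.zeros((n_volumes, 3)), np.zeros((n_volumes, 3)))
    innov = rng.standard_normal((n_volumes, 6))
    pos = np.empty_like(innov)
    pos[0] = innov[0]
    for t in range(1, n_volumes):
        pos[t] = ar_coeff * pos[t - 1] + innov[t]
    pos *= motion_sd_mm
    rot, trans = pos[:, :3] / 50.0, pos[:, 3:]
    trace = MotionTrace(rot, trans)
    if target_mean_fd is not None:
        realized = framewise_displacement(trace).fd_mean
        scale = target_mean_fd / realized
        trace = MotionTrace(rot * scale, trans * scale)
    return trace


# ---------------------------------------------------------------------------
# Segregation ground truth
# ---------------------------------------------------------------------------

def simulate_sys_profiles(config: SimulationConfig, rng) -> tuple:
    """Per-subject true within-network correlations and segregation values.

    Subjects vary around the config's within-network Fisher-z level with SD
    ``sys_z_sd``; the between-network correlation is common. Returns
    (r_within_per_subject: list of dict, true_sys: DataFrame).
    """
    nets = config.partition.network_names
    zb = np.arctanh(config.r_between)
    rws, rows = [], []
    for _ in range(config.n_subjects):
        rw, sys_row = {}, {}
        for net in nets:
            zw = np.arctanh(config.r_within[net]) + config.sys_z_sd * rng.standard_normal()
            zw = max(zw, zb + 0.02)  # keep the segregated ordering
            rw[net] = float(np.tanh(zw))
            sys_row[net] = (zw - zb) / zw
        rws.append(rw)
        rows.append(sys_row)
    return rws, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _split_sum(total: float, n_items: int, upper: float, rng) -> np.ndarray:
    """Random nonnegative items with the exact target sum, each <= upper.

    Draws a uniform simplex composition of ``total`` and redistributes any
    excess above ``upper`` among unsaturated items. Requires
    ``0 <= total <= n_items * upper``.
    """
    if not 0 <= total <= n_items * upper + 1e-9:
        raise ValueError("infeasible item split")
    w = rng.dirichlet(np.ones(n_items)) * total
    for _ in range(100):
        over = np.clip(w - upper, 0, None)
        if over.sum() <= 1e-12:
            break
        w = np.minimum(w, upper)
        room = w < upper
        w[room] += over.sum() * rng.dirichlet(np.ones(room.sum()))
    w = np.minimum(w, upper)
    # final exactness correction into whichever item has room
    deficit = total - w.sum()
    for i in np.argsort(-(upper - w)):
        take = np.clip(deficit, -w[i], upper - w[i])
        w[i] += take
        deficit -= take
        if abs(deficit) < 1e-12:
            break
    return w


def _split_sum_int(total: int, n_items: int, upper: int, rng) -> np.ndarray:
    """Random integer items with the exact target sum, each in [0, upper]."""
    total = int(round(total))
    items = np.zeros(n_items, dtype=int)
    remaining = total
    for i in range(n_items):
        slots_left = n_items - i - 1
        lo = max(0, remaining - upper * slots_left)
        hi = min(upper, remaining)
        items[i] = rng.integers(lo, hi + 1)
        remaining -= items[i]
    return rng.permutation(items)


class _ClipCounter:
    def __init__(self):
        self.clipped = 0
        self.total = 0

    def clip(self, values, lo, hi):
        values = np.asarray(values, dtype=float)
        out = np.clip(values, lo, hi)
        self.clipped += int(np.sum((values < lo) | (values > hi)))
        self.total += values.size
        return out

    @property
    def rate(self) -> float:
        return self.clipped / self.total if self.total else 0.0


def simulate_phenotypes(
    config: SimulationConfig,
    true_sys: pd.DataFrame,
    groups,
    rng,
) -> tuple:
    """Item-level phenotype table with a planted pain-progression model.

    For pain-group subjects, the change in the pain-experience composite is

        Delta PE = sum_j beta_j * z_j + beta_int * z_help * z_dmn + noise

    with every predictor z-scored within the pain group, after which
    timepoint-2 instrument items are constructed so that scoring them
    reproduces exactly that change (up to instrument-bound clipping, whose
    rate is reported). Returns (phenotypes, planted_change, clip_rate).
    """
    n = config.n_subjects
    groups = list(groups)
    clip = _ClipCounter()
    is_pain = np.array([g == "pain" for g in groups])
    df = pd.DataFrame({"subject_id": [f"sub-{i:04d}" for i in range(n)]})
    df["cp_t1"] = np.where(is_pain, "yes", "no")
    df["cp_t2"] = np.where(is_pain, "yes", "no")

    # demographics (plausibility-clipped, not instrument bounds)
    df["age"] = np.clip(
        np.where(is_pain, 54.81, 52.87) + 7.0 * rng.standard_normal(n), 40, 65
    )
    df["sex_female"] = (
        rng.random(n) < np.where(is_pain, 0.632, 0.472)
    ).astype(int)
    df["bmi"] = np.clip(
        np.where(is_pain, 26.86, 25.36)
        + np.where(is_pain, 5.40, 3.72) * rng.standard_normal(n),
        15, 50,
    )
    # health questionnaires (instrument-bounded scales)
    df["phq4"] = clip.clip(
        np.where(is_pain, 2.18, 1.21) + np.where(is_pain, 2.02, 1.59)
        * rng.standard_normal(n), 0, 12
    )
    df["promis_cognitive"] = clip.clip(
        np.where(is_pain, 48.41, 53.26) + np.where(is_pain, 9.28, 6.54)
        * rng.standard_normal(n), 20, 80
    )
    df["whoqol_age"] = clip.clip(
        np.where(is_pain, 34.32, 39.90) + 7.93 * rng.standard_normal(n), 13, 65
    )
    df["delay_t1_mri_days"] = np.clip(120 + 45 * rng.standard_normal(n), 30, 400)
    fd_mu = np.where(
        is_pain, config.fd_target_mm["pain"], config.fd_target_mm["no_pain"]
    )
    df["fd_target_mm"] = np.clip(
        fd_mu + config.fd_target_sd_mm * rng.standard_normal(n), 0.02, 1.5
    )

    pain_cols = []
    for t in (1, 2):
        pain_cols += [f"bpi_intensity_t{t}"] + [
            f"bpi_{it}_t{t}"
            for it in ("relations", "enjoyment", "sleep", "mood",
                       "walking", "general_activity", "work")
        ]
    pain_cols += [f"pcs_item_{k}" for k in range(1, 14)]
    for c in pain_cols:
        df[c] = np.nan
    for c in ("n_pain_sites", "duration_category", "medication_t1", "medication_t2"):
        df[c] = pd.Series([None] * n, dtype=object)

    idx = np.flatnonzero(is_pain)
    n_pain = idx.size
    planted = pd.Series(np.nan, index=df.index)
    if 0 < n_pain < 3:
        raise ValueError(
            f"only {n_pain} pain-group subject(s); the planted progression model "
            "needs at least 3 — increase n_subjects or pain_prevalence"
        )
    if n_pain >= 3:
        # --- baseline (T1) targets, clipped to the instrument range first so
        # the planted model sees the realized predictor values
        intensity1 = clip.clip(4.17 + 1.89 * rng.standard_normal(n_pain), 0, 10)
        affective1 = clip.clip(2.59 + 2.37 * rng.standard_normal(n_pain), 0, 10)
        activity1 = clip.clip(2.76 + 2.36 * rng.standard_normal(n_pain), 0, 10)

        # catastrophizing: integer subscale targets -> integer items
        helpless = np.rint(clip.clip(6.41 + 4.19 * rng.standard_normal(n_pain), 0, 24))
        rumin = np.rint(clip.clip(6.44 + 3.37 * rng.standard_normal(n_pain), 0, 16))
        magnif = np.rint(clip.clip(3.60 + 2.26 * rng.standard_normal(n_pain), 0, 12))
        pcs_items = np.zeros((n_pain, 13))
        from .scores import PCS_KEYING

        for s in range(n_pain):
            for name, target in (
                ("helplessness", helpless[s]),
                ("rumination", rumin[s]),
                ("magnification", magnif[s]),
            ):
                nums = np.asarray(PCS_KEYING[name]) - 1
                pcs_items[s, nums] = _split_sum_int(target, len(nums), 4, rng)

        # --- planted progression model on z-scored predictors
        def z(a):
            a = np.asarray(a, dtype=float)
            return (a - a.mean()) / a.std(ddof=1)

        betas = config.behavioral_betas
        nets = list(true_sys.columns)
        dmn_col = "default" if "default" in nets else nets[0]
        dan_col = "dorsoattention" if "dorsoattention" in nets else nets[-1]
        z_help = z(helpless)
        z_dmn = z(true_sys[dmn_col].values[idx])
        z_dan = z(true_sys[dan_col].values[idx])
        lin = (
            betas.get("helplessness", 0.0) * z_help
            + betas.get("sys_default", 0.0) * z_dmn
            + betas.get("sys_dorsoattention", 0.0) * z_dan
            + betas.get("intensity_t1", 0.0) * z(intensity1)
            + betas.get("affective_interference_t1", 0.0) * z(affective1)
            + betas.get("activity_interference_t1", 0.0) * z(activity1)
            + betas.get("interaction", 0.0) * z_help * z_dmn
        )
        change = lin + config.noise_sd * rng.standard_normal(n_pain)
        planted.iloc[idx] = change

        pe1 = (intensity1 + affective1) / 2.0
        pe2 = clip.clip(pe1 + change, 0, 10)
        # split PE2 into intensity and affective staying near their T1 levels
        delta_want = (intensity1 - affective1) / 2.0 + 0.3 * rng.standard_normal(n_pain)
        d_lo = np.maximum(-pe2, pe2 - 10)
        d_hi = np.minimum(pe2, 10 - pe2)
        delta = np.clip(delta_want, d_lo, d_hi)
        clip.clipped += int(np.sum((delta_want < d_lo) | (delta_want > d_hi)))
        clip.total += delta.size
        intensity2, affective2 = pe2 + delta, pe2 - delta
        activity2 = clip.clip(activity1 + 0.5 * rng.standard_normal(n_pain) - 0.3, 0, 10)

        # --- items consistent with the composites
        for t, (inten, aff, act) in (
            (1, (intensity1, affective1, activity1)),
            (2, (intensity2, affective2, activity2)),
        ):
            df.loc[idx, f"bpi_intensity_t{t}"] = inten
            aff_items = np.vstack([_split_sum(4 * a, 4, 10.0, rng) for a in aff])
            act_items = np.vstack([_split_sum(3 * a, 3, 10.0, rng) for a in act])
            for j, it in enumerate(("relations", "enjoyment", "sleep", "mood")):
                df.loc[idx, f"bpi_{it}_t{t}"] = aff_items[:, j]
            for j, it in enumerate(("walking", "general_activity", "work")):
                df.loc[idx, f"bpi_{it}_t{t}"] = act_items[:, j]
        for k in range(13):
            df.loc[idx, f"pcs_item_{k + 1}"] = pcs_items[:, k]

        df.loc[idx, "n_pain_sites"] = rng.choice(
            [1, 2, 3, 4], size=n_pain, p=[0.248, 0.30, 0.20, 0.252]
        )
        df.loc[idx, "duration_category"] = rng.choice(
            ["<3y", "3-9y", ">9y"], size=n_pain, p=[0.413, 0.36, 0.227]
        )
        df.loc[idx, "medication_t1"] = rng.random(n_pain) < 0.316
        df.loc[idx, "medication_t2"] = rng.random(n_pain) < 0.429

    if clip.rate > 0.20:
        warnings.warn(
            f"{clip.rate:.1%} of generated values hit instrument bounds; "
            "planted effects will be attenuated",
            stacklevel=2,
        )
    return df, planted, clip.rate


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A fully generated cohort with its ground truth."""

    config: SimulationConfig
    phenotypes: pd.DataFrame = field(repr=False)
    ground_truth: GroundTruth
    timeseries: dict = field(default_factory=dict, repr=False)
    motion: dict = field(default_factory=dict, repr=False)


def assign_groups(n_subjects: int, prevalence: float, rng) -> list:
    """Random pain / no-pain labels at the configured prevalence."""
    return ["pain" if u < prevalence else "no_pain" for u in rng.random(n_subjects)]


def simulate_cohort(config: SimulationConfig, include_imaging: bool = True) -> SyntheticCohort:
    """Generate a full cohort (phenotypes always; time series and motion
    unless ``include_imaging`` is False). Bit-reproducible for a fixed config."""
    root = np.random.SeedSequence(config.seed)
    pheno_seq, imaging_seq = root.spawn(2)
    rng = np.random.default_rng(pheno_seq)
    groups = assign_groups(config.n_subjects, config.pain_prevalence, rng)
    rw_subjects, true_sys = simulate_sys_profiles(config, rng)
    phenotypes, planted, clip_rate = simulate_phenotypes(config, true_sys, groups, rng)
    gt = GroundTruth(
        seed=config.seed,
        groups=groups,
        true_sys=true_sys,
        behavioral_betas=dict(config.behavioral_betas),
        planted_change=planted,
        clip_rate=clip_rate,
    )
    cohort = SyntheticCohort(config=config, phenotypes=phenotypes, ground_truth=gt)
    if include_imaging:
        subject_seqs = imaging_seq.spawn(config.n_subjects)
        for i, (sid, seq) in enumerate(zip(phenotypes["subject_id"], subject_seqs)):
            ts_seq, mot_seq = seq.spawn(2)
            cohort.timeseries[sid] = simulate_timeseries(config, ts_seq, rw_subjects[i])
            cohort.motion[sid] = simulate_motion(
                config.n_volumes,
                config.motion_sd_mm,
                mot_seq,
                target_mean_fd=float(phenotypes["fd_target_mm"].iloc[i]),
            )
    return cohort
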