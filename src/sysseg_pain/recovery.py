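"""Simulation-based recovery and calibration diagnostics.

Utilities that measure how well the pipeline recovers known ground truth from
its own synthetic cohorts: analytic segregation recovery from simulated time
series, oracle-equivalence deviations for the segregation and partial-
correlation estimators, Johnson-Neyman boundary agreement with a dense grid
scan, and bootstrap-CI coverage / type-I calibration of the moderation test.
These are the checks a user should rerun after modifying the generator or the
estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as sps

from .atlas import PartitionAtlas, default_partition
from .connectivity import ConnectivityMatrix, compute_fc, compute_segregation
from .moderation import ModerationModel, fit_moderation
from .simulate import (
    DEFAULT_BEHAVIORAL_BETAS,
    SimulationConfig,
    analytic_sys,
    simulate_phenotypes,
    simulate_sys_profiles,
    simulate_timeseries,
)
from .stats import partial_correlation


def sys_analytic_recovery(
    n_subjects: int = 50,
    n_volumes: int = 740,
    r_within: float = 0.5,
    r_between: float = 0.1,
    seed: int = 0,
    partition: PartitionAtlas | None = None,
) -> pd.DataFrame:
    """Mean estimated segregation per network vs the analytic value.

    Simulates ``n_subjects`` block-covariance series with fixed correlations,
    runs the connectivity + segregation estimators, and returns per-network
    columns ``mean_sys``, ``analytic`` and ``abs_error``.
    """
    partition = partition or default_partition()
    config = SimulationConfig(
        n_subjects=n_subjects,
        partition=partition,
        n_volumes=n_volumes,
        r_within={net: r_within for net in partition.network_names},
        r_between=r_between,
        sys_z_sd=0.0,
        seed=seed,
    )
    seqs = np.random.SeedSequence(seed).spawn(n_subjects)
    estimates = []
    for seq in seqs:
        ts = simulate_timeseries(config, seq)
        prof = compute_segregation(compute_fc(ts), partition)
        estimates.append(prof.to_frame().set_index("network")["sys"])
    mean_sys = pd.concat(estimates, axis=1).mean(axis=1)
    target = analytic_sys(r_within, r_between)
    return pd.DataFrame(
        {"mean_sys": mean_sys, "analytic": target, "abs_error": (mean_sys - target).abs()}
    )


def segregation_oracle_max_dev(n_instances: int = 100, seed: int = 0) -> float:
    """Max |difference| between the vectorized segregation estimator and a
    brute-force double loop over node pairs, across random 10-node instances."""
    rng = np.random.default_rng(seed)
    nets = ("A",) * 4 + ("B",) * 3 + ("C",) * 3
    atlas = PartitionAtlas(tuple(f"n{i}" for i in range(10)), nets)
    worst = 0.0
    for _ in range(n_instances):
        z = np.abs(rng.normal(0.3, 0.2, size=(10, 10)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        prof = compute_segregation(ConnectivityMatrix(z), atlas).to_frame()
        for _, row in prof.iterrows():
            inside = set(atlas.nodes_of(row["network"]))
            w = np.mean([z[i, j] for i in inside for j in inside if i < j])
            b = np.mean([z[i, j] for i in inside for j in range(10) if j not in inside])
            worst = max(
                worst,
                abs(row["w_net"] - w),
                abs(row["b_net"] - b),
                abs(row["sys"] - (w - b) / w),
            )
    return worst


def partial_corr_oracle_max_dev(n_instances: int = 100, seed: int = 0) -> float:
    """Max |difference| between the residual-method partial correlation and
    the precision-matrix identity on random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(1, 4))
        data = rng.standard_normal((50, 2 + k))
        data[:, 0] += 0.5 * data[:, 2]
        data[:, 1] += 0.5 * data[:, 2]
        r, _ = partial_correlation(data[:, 0], data[:, 1], data[:, 2:])
        prec = np.linalg.inv(np.corrcoef(data, rowvar=False))
        worst = max(worst, abs(r - (-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))))
    return worst


def jn_grid_max_dev(n_models: int = 50, seed: int = 0, n_grid: int = 20001) -> float:
    """Max |boundary difference| between the Johnson-Neyman quadratic roots
    and a dense grid scan of conditional-effect t tests, in grid steps."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_models):
        n = int(rng.integers(40, 120))
        f = rng.standard_normal(n)
        m = rng.normal(2.0, 1.5, n)
        y = (
            rng.normal(0, 1) * f
            + 0.3 * m
            + rng.normal(0, 0.6) * f * m
            + rng.uniform(0.5, 2.0) * rng.standard_normal(n)
        )
        res = fit_moderation(y, f, m, n_boot=10, seed=k)
        lo, hi = float(m.min()), float(m.max())
        w = np.linspace(lo, hi, n_grid)
        t = res.conditional_effect(w) / res.conditional_effect_se(w)
        crit = sps.t.ppf(0.975, res.df_resid)
        sig = np.abs(t) > crit
        flips = np.flatnonzero(sig[1:] != sig[:-1])
        oracle = [(w[i] + w[i + 1]) / 2 for i in flips]
        boundaries = res.johnson_neyman(moderator_range=(lo, hi)).boundaries
        if len(boundaries) != len(oracle):
            return np.inf
        step = (hi - lo) / (n_grid - 1)
        for a, b in zip(boundaries, oracle):
            worst = max(worst, abs(a - b) / step)
    return worst


def planted_phenotype_cohort(n_subjects: int, interaction: float, noise_sd: float, seed: int):
    """One phenotype-level cohort (all chronic pain) with planted effects."""
    betas = dict(DEFAULT_BEHAVIORAL_BETAS)
    betas["interaction"] = interaction
    config = SimulationConfig(
        n_subjects=n_subjects,
        pain_prevalence=1.0,
        behavioral_betas=betas,
        noise_sd=noise_sd,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    groups = ["pain"] * n_subjects
    _, true_sys = simulate_sys_profiles(config, rng)
    pheno, _, _ = simulate_phenotypes(config, true_sys, groups, rng)
    from .scores import score_phenotypes

    scored = score_phenotypes(pheno)
    scored["sys_default"] = true_sys["default"].values
    scored["sys_dorsoattention"] = true_sys["dorsoattention"].values
    return scored


def _refit_interaction_ci(scored: pd.DataFrame, n_boot: int, seed: int):
    """Moderation refit matching the generator's z-scored planted design."""
    covs = scored[
        ["sys_dorsoattention", "intensity_t1", "affective_interference_t1",
         "activity_interference_t1"]
    ].apply(lambda a: (a - a.mean()) / a.std(ddof=1))
    model = ModerationModel(
        scored["pain_experience_longitudinal"],
        scored["pcs_helplessness"],
        scored["sys_default"],
        covariates=covs,
        standardize=True,
    )
    res = model.fit(n_boot=n_boot, seed=seed)
    return res.bootstrap_ci, res.interaction


def moderation_coverage(
    n_reps: int = 100,
    interaction: float = 0.4,
    n_subjects: int = 300,
    noise_sd: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> float:
    """Fraction of replicates whose 95% percentile-bootstrap CI covers the
    planted interaction coefficient."""
    base = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    hits = 0
    for k in range(n_reps):
        scored = planted_phenotype_cohort(n_subjects, interaction, noise_sd, int(base[k]) % 2**31)
        (lo, hi), _ = _refit_interaction_ci(scored, n_boot, int(base[k]) % 2**31)
        hits += lo <= interaction <= hi
    return hits / n_reps


def null_rejection_rate(
    n_reps: int = 200,
    n_subjects: int = 300,
    noise_sd: float = 1.0,
    n_boot: int = 5000,
    seed: int = 1,
) -> float:
    """Fraction of null (zero-interaction) replicates whose bootstrap CI
    excludes zero — the moderation test's empirical type-I error."""
    base = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    rejections = 0
    for k in range(n_reps):
        scored = planted_phenotype_cohort(n_subjects, 0.0, noise_sd, int(base[k]) % 2**31)
        (lo, hi), _ = _refit_interaction_ci(scored, n_boot, int(base[k]) % 2**31)
        rejections += not (lo <= 0.0 <= hi)
    return rejections / n_reps
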