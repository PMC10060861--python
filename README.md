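# sysseg-pain

Brain-network **system segregation** and **pain-catastrophizing** analysis for
longitudinal chronic-pain cohorts — with a fully ground-truthed synthetic
cohort generator, so the whole pipeline is testable without any participant
data.

The package is aimed at researchers studying how resting-state network
organization relates to the progression of chronic pain: it takes parcellated
BOLD time series, rigid-body motion traces, and an item-level phenotype table,
and produces per-network segregation values, scored pain instruments, and the
full inferential chain (group contrasts, partial correlations, standardized
regressions with collinearity diagnostics, and moderation models with
bootstrap confidence intervals and Johnson–Neyman regions).

## The core quantities

For a node→network partition (default: 100 nodes, 7 canonical networks) and
Fisher-z connectivity `z_ij = arctanh(r_ij)` (negatives truncated to zero,
self-connections excluded), each network's segregation is

```
SyS_net = (W_net − B_net) / W_net
```

with `W_net` the mean z over node pairs inside the network and `B_net` the
mean z over pairs connecting it to the rest of the cortex. Higher values mean
a more segregated (functionally distinct) network.

The behavioral outcome is the **pain experience** composite — the mean of
pain intensity and affective interference (both 0–10) at each timepoint —
and its T2 − T1 change (positive = worsening). The moderation model

```
ΔPE = b0 + b1·SyS + b2·helplessness + b3·(SyS × helplessness) + covariates
```

asks whether catastrophizing's helplessness subscale changes the brain–pain
relationship; the Johnson–Neyman region gives the helplessness scores at
which the conditional effect of segregation is significant.

## Worked example

Segregation recovery from one simulated subject (100 nodes, 7 networks,
740 volumes, within-network correlation 0.5, between 0.1):

```python
from sysseg_pain import (SimulationConfig, simulate_timeseries, compute_fc,
                         compute_segregation, default_partition, analytic_sys)

atlas = default_partition()
cfg = SimulationConfig(n_subjects=1, seed=0, sys_z_sd=0.0,
                       r_within={n: 0.5 for n in atlas.network_names},
                       r_between=0.1)
ts = simulate_timeseries(cfg, 0)
profile = compute_segregation(compute_fc(ts), atlas)
print(profile.to_frame().round(4).to_string(index=False))
print("analytic:", round(analytic_sys(0.5, 0.1), 4))
```

```
                   network  w_net  b_net    sys  undefined
                   default 0.5488 0.1087 0.8019      False
               somatomotor 0.5387 0.1101 0.7956      False
                   control 0.5807 0.1187 0.7956      False
            dorsoattention 0.5344 0.1164 0.7822      False
salience_ventral_attention 0.5616 0.1158 0.7937      False
                    limbic 0.6217 0.0922 0.8518      False
                    visual 0.5706 0.1066 0.8131      False
analytic: 0.8173
```

Each network's estimated segregation sits near the population value
`1 − arctanh(0.1)/arctanh(0.5) ≈ 0.8173`; the scatter is finite-scan noise.

Moderation on a synthetic pain cohort (n = 300) with a planted interaction of
0.4 between helplessness and default-mode segregation (both z-scored):

```python
from sysseg_pain.moderation import ModerationModel
from sysseg_pain.recovery import planted_phenotype_cohort

scored = planted_phenotype_cohort(300, interaction=0.4, noise_sd=1.0, seed=42)
covs = scored[["sys_dorsoattention", "intensity_t1",
               "affective_interference_t1", "activity_interference_t1"]]
covs = covs.apply(lambda a: (a - a.mean()) / a.std(ddof=1))
res = ModerationModel(scored["pain_experience_longitudinal"],
                      scored["sys_default"], scored["pcs_helplessness"],
                      covariates=covs, standardize=True).fit(n_boot=5000, seed=42)
print(res.summary())
```

```
Moderation model (OLS with focal x moderator interaction)
n = 300, R^2 = 0.5093, df_resid = 292

term                          coef          se           p
const                      -0.1140      0.0597     0.05704
focal                       0.2003      0.0602   0.0009837
moderator                   0.2153      0.0603   0.0004151
interaction                 0.4716      0.0612   2.107e-13
...
interaction 95% percentile bootstrap CI (5000 resamples): [0.3543, 0.5848]
Johnson-Neyman: [0, 3.62]: significant; [3.62, 5.77]: not significant; [5.77, 17]: significant
```

The bootstrap CI covers the planted 0.4, and the Johnson–Neyman region says
the segregation–pain association is significant for helplessness scores
above ≈5.8 (and, with opposite sign, at the very bottom of the scale).
`res.plot_johnson_neyman()` draws the conditional-effect band.

## Command line

```
sysseg-pain run --out run1 --seed 1          # full synthetic end-to-end run
sysseg-pain synthesize --out data --seed 1   # cohort only
sysseg-pain segregate --timeseries 'data/timeseries/*.tsv' \
    --atlas data/partition.tsv --motion 'data/motion/*.par' --out seg
sysseg-pain scores --phenotypes data/phenotypes.csv --out scored.csv
sysseg-pain analyze --input scored.csv --seed 1 --out results
```

A run writes every intermediate artifact (FD summary, segregation profiles,
scored table, results bundle, report) plus a manifest with artifact hashes
and per-subject exclusion reasons; reruns of an archived config reproduce the
results bundle byte for byte.

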