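# normdev

Normative modeling of regional cortical thickness for heterogeneity
analysis in neurodegenerative disease.

Case-control comparisons describe the *average* patient and hide how
differently atrophy is distributed across individuals. Neuroanatomical
normative modeling takes the opposite view: a large healthy reference
cohort defines, for every cortical region, the range of thickness
expected given a person's age and sex, and each patient is then
expressed as a map of deviations from that expectation. `normdev`
implements this workflow end to end for the 148-region Destrieux
parcellation (74 gyral/sulcal parcels per hemisphere):

- **Hierarchical Bayesian normative model.** Per region *j*, thickness
  follows

  *y*<sub>ij</sub> = *x*<sub>i</sub><sup>T</sup>β<sub>j</sub> + *u*<sub>s(i),j</sub> + ε<sub>ij</sub>,  ε<sub>ij</sub> ~ N(0, σ²<sub>s,j</sub>),  *u*<sub>s,j</sub> ~ N(0, τ²<sub>j</sub>),

  with covariates *x* = (1, age, sex), site random intercepts
  *u*<sub>s,j</sub>, per-site noise variances σ²<sub>s,j</sub> pooled through a shared
  inverse-gamma hyperprior, fitted independently for each of the 148
  regions. Inference is a deterministic conjugate empirical-Bayes
  scheme by default, with a seeded blocked Gibbs sampler as an
  alternative backend behind the same interface.
- **Site transfer.** A new scanner/site is calibrated from a small
  local control sample (default n = 20): the fixed effects transfer
  unchanged while the new site's intercept offset and noise variance
  get posteriors that use the reference hyperposterior as prior,
  including a scanner-wide noise-scale factor pooled across regions.
- **Deviation z-scores.** *z*<sub>ij</sub> = (*y*<sub>ij</sub> − μ̂<sub>ij</sub>)/σ̂<sub>ij</sub> with
  posterior-predictive mean and SD (parameter uncertainty included).
  Regions with *z* < −1.96 (bottom 2.5% of the normative range) are
  *outliers*; only negative deviations are flagged. The per-subject
  **total outlier count** (TOC, 0–148), per-region prevalence maps,
  superior-temporal-sulcus (STS) status and temporal/extratemporal
  summaries follow.
- **Heterogeneity.** Pairwise Hamming distances (number of discordant
  outlier flags) quantify how dissimilar patients' atrophy patterns
  are; groups are compared on per-subject median distances with a
  seeded permutation test.
- **Group statistics.** Case-control ANCOVA and region-wise Welch
  t-tests with Benjamini–Hochberg FDR, ANCOVAs on log(TOC+1),
  Mann–Whitney and Shapiro–Wilk companions, Pearson TOC–age
  correlation, location × phenotype two-way ANOVA, amyloid-SUVR
  regressions and median-split labels.
- **Synthetic cohorts.** A deterministic multi-site generator emulates
  the reference / adaptation / clinical study layout, with
  heterogeneous atrophy concentrated in (but not limited to) the
  temporal lobe, so every stage is testable without clinical data.

## Worked example

```python
from normdev import (CohortSimulator, GeneratorConfig,
                     HierarchicalNormativeModel, flag_outliers,
                     load_atlas, summarize_outliers)
from normdev.dissimilarity import hamming_matrix, group_dissimilarity

sim = CohortSimulator(GeneratorConfig(seed=1))        # 2000 controls, 10 sites
model = HierarchicalNormativeModel().fit(*sim.reference())
model.adapt(*sim.adaptation())                        # 20 controls, new site

cohort, thickness = sim.clinical()                    # 86 patients
z = model.deviation_scores(cohort.set_index("subject_id"), thickness).z
flags = flag_outliers(z)                              # z < -1.96
summary = summarize_outliers(flags, load_atlas())

toc = summary.total_outlier_count
print(f"median total outlier count: {toc.median():.1f} "
      f"(range {toc.min()}-{toc.max()})")
sts = summary.prevalence.loc[["lh_S_temporal_sup", "rh_S_temporal_sup"],
                             "prevalence_pct"]
print(f"STS outlier prevalence: lh {sts.iloc[0]:.0f}%, rh {sts.iloc[1]:.0f}%")

H = hamming_matrix(flags)
for stage, s in group_dissimilarity(H, cohort["stage"]).items():
    print(f"{stage}: median Hamming {s.median:.2f} (IQR {s.iqr:.2f}, n={s.n})")
```

Output:

```
median total outlier count: 31.0 (range 14-54)
STS outlier prevalence: lh 67%, rh 66%
MCI: median Hamming 41.50 (IQR 6.25, n=28)
dementia: median Hamming 51.00 (IQR 7.00, n=58)
```

Reading this: the simulated patients deviate in a median of 31 of 148
regions; the bilateral superior temporal sulci — the generator's core
atrophy site — are the most frequently outlying regions; and the
dementia-stage subgroup shows more heterogeneous outlier patterns
(higher median Hamming distance) than the MCI subgroup, because its
idiosyncratic atrophy rate is higher by construction.

The same pipeline is available from the shell:

```bash
normdev run --seed 1 --out results/demo          # simulate+fit+adapt+score+analyze
normdev simulate --seed 1 --out data/            # or stage by stage:
normdev fit --cohort data/cohort.csv --thickness data/thickness.csv --out model.json
normdev adapt --model model.json --cohort data/cohort.csv --thickness data/thickness.csv --out model_ad.json
normdev score --model model_ad.json --cohort data/cohort.csv --thickness data/thickness.csv --out z.csv
normdev analyze --zscores z.csv --cohort data/cohort.csv --out analysis/
```

Every `run` writes a `manifest.json` (versions, seed, input checksums,
output list) from which all outputs are re-derivable.

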