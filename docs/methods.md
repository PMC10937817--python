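# Methods

## The normative model

For each of the 148 Destrieux regions *j* independently, thickness of
subject *i* at site *s(i)* is modelled as

    y_ij = beta_j0 + beta_j1 (age_i - age_ref) + beta_j2 female_i
           + u_{s(i),j} + eps_ij
    eps_ij ~ N(0, sigma^2_{s,j})      site-specific noise
    u_{s,j} ~ N(0, tau^2_j)           site random intercept
    sigma^2_{s,j} ~ InvGamma(a_j, b_j)   pooled across sites

Age is centred at the reference-cohort mean (numerical stability; this
changes the reported intercept, not predictions). Sex is coded
female = 1, male = 0. Regions are fitted independently: this mirrors
the usual practice for regional normative models and is a known
limitation — regions covary structurally, so outlier maps and Hamming
distances should be interpreted with that dependence in mind.

### Inference backends

Both backends satisfy one contract (same fitted attributes, same
downstream behaviour, same calibration suite):

- **`eb` (default).** A deterministic blocked conjugate scheme. Each
  outer iteration: (1) fixed effects by marginal GLS with the site
  intercepts integrated out (Woodbury closed form on per-site
  sufficient statistics, so the fit touches the data once and scales
  as O(sites × regions)); (2) conjugate normal posteriors for each
  site offset; (3) per-site noise variances shrunk through an
  inverse-gamma hyperprior whose (a, b) are method-of-moments
  estimates across sites, with the within-site sampling variance of
  the raw estimates subtracted; (4) tau^2 by method of moments on the
  site residual means, floored at `tau2_floor`. Convergence is the
  relative change of the coefficient matrix (tol 1e-9, max 200
  iterations); non-convergence flags all regions and warns, never
  drops.
- **`gibbs`.** A seeded blocked Gibbs sampler with the same conjugate
  updates (beta | u, sigma; u | beta, sigma, tau; sigma | beta, u;
  tau | u), vectorised across regions, initialised at the EB solution
  and using the EB (a, b) as the fixed noise hyperprior. Two chains of
  500 warmup + 500 kept draws by default; a split-chain R-hat on the
  age slope is recorded per region and regions exceeding 1.05 are
  flagged (reported, never dropped). Posterior summaries (means,
  covariances) feed the same scoring path as EB.

### Site adaptation

Transferring to an unseen site uses a small local control sample
(n = 20 in the intended design, n >= 2 enforced). Fixed effects are
held at the reference posterior — the transfer recalibrates the
intercept and the noise, not the covariate slopes. The new site's
offset gets a conjugate normal posterior with prior N(0, tau^2_j); its
noise variance gets an inverse-gamma posterior whose prior is the
reference hyperprior *recentred by a scanner-wide scale factor kappa*
estimated by pooling all n × 148 standardized residuals. Rationale:
scanner or field-strength differences move the noise level of all
regions together, and n = 20 subjects per region alone cannot pin a
per-region variance — pooling across regions gives the shared
component ~3000 effective degrees of freedom, after which the
per-region inverse-gamma update absorbs residual regional deviation.
Without this pooling the lower-tail calibration of the z-scores
fluctuates across simulated sites by more than a percentage point;
with it the null outlier rate stays within a few tenths of the nominal
2.5%.

If the "new" site is already a reference site, adaptation warns and
reuses that site's posterior.

### Deviation scores

    z_ij = (y_ij - mu_ij) / sd_ij
    mu_ij = x_i' beta_j + E[u_new,j]
    sd_ij^2 = E[sigma^2_new,j] + Var[u_new,j] + x_i' Cov[beta_j] x_i

The predictive SD is posterior-predictive: it includes the posterior
uncertainty of the site offset and the fixed effects, not only the
residual noise. With 20 adaptation controls the offset uncertainty
term is ~sigma^2/20, i.e. 5% of the variance — dropping it visibly
inflates the outlier rate above nominal. A `predictive="plugin"`
option reports the residual-only denominator for comparison. Subjects
whose age falls outside the reference support are scored but flagged
as extrapolated.

Outliers are z < -1.96, strictly: a score exactly at the threshold is
not an outlier, and positive deviations are never flagged (the target
phenomenon is thinning). The threshold is configurable but must be
negative; z-scores are always exported in full so other thresholds
need no refit.

## Synthetic cohorts

The generator emulates the study layout the analysis assumes: a large
multi-site healthy reference cohort, a 20-control adaptation set at a
new site, and an 86-patient clinical cohort at that same site.
Defaults (all configurable, chosen once as field-plausible values):

| parameter | default | units / note |
|---|---|---|
| reference size / sites | 2000 / 10 | reduced desk scale; full-scale n is a config choice |
| reference ages | U(18, 90) | years |
| clinical ages | U(49.1, 87.4) | years; clinical sex ratio 42/86 female |
| regional baseline | U(2.0, 3.0) | mm |
| age slope | U(-0.008, -0.002) | mm/year, thinning |
| sex effect | U(-0.05, 0.05) | mm |
| residual SD sigma_j | U(0.08, 0.18) | mm |
| site intercept SD | 0.05 | mm |
| site noise scale | lognormal, sd(log) 0.15 | multiplies sigma_j per site |
| core atrophy | bilateral STS, penetrance 0.6 | effect U(2, 5) x sigma_j |
| idiosyncratic atrophy | rate 0.15 per region | binomial region set |
| stage multipliers | dementia 1.5 / MCI 1.0 (rate), 1.15 / 0.85 (core) | |
| phenotype multipliers | non-amnestic 1.4 rate, 1.5 extratemporal weight | |
| depression multipliers | ongoing 0.6, past 0.9, none 1.0 | |
| SUVR | mean 1.4, sd 0.2, slope -0.06 per SD burden | implies R^2 ~ 0.09 |

Clinical subgroup label frequencies follow the intended cohort
composition (dementia 48/86, amnestic 64/86, depression 24/7/51). The
multipliers are set so the qualitative group orderings hold by
construction: dementia > MCI burden and heterogeneity, non-amnestic >
amnestic spread, ongoing depression < none. Affected regions are
shifted down by exactly effect x sigma_j, and the truth record (region
sets, effect sizes, generative parameters) is returned for recovery
tests.

Determinism: all randomness descends from one seed through fixed
per-cohort child streams, so generating one cohort never perturbs
another and repeated runs are bit-identical.

What the generator does **not** emulate: spatial covariance between
regions (real atrophy and measurement noise are correlated across
neighbouring and homotopic parcels), non-Gaussian thickness
distributions, age-by-disease interactions, longitudinal structure,
segmentation failures, and missing data beyond an MCAR mask. Passing
tests therefore demonstrate the *method's* correctness and calibration
under its stated assumptions, not performance on real clinical data —
in particular, real Hamming distances will be smaller and more
structured than independent-region simulation suggests.

## Statistical contrasts

- Case-control: ANCOVA (age + sex) on mean-over-regions thickness;
  per-region Welch t-tests (no homogeneity assumption) with
  Benjamini–Hochberg FDR at 0.05; zero-variance regions reported NA
  and excluded from the BH step.
- Outlier counts: ANCOVA on log(count + 1) — counts of 0 are
  attainable, so the offset keeps the transform finite — with
  age + sex (plus disease stage for phenotype/depression contrasts);
  Mann–Whitney U companion (exact enumeration below combined n = 20
  without ties, otherwise normal approximation with tie correction);
  Shapiro–Wilk normality check reported alongside.
- Heterogeneity: per-subject median Hamming distance to same-group
  peers; group medians and IQRs on the raw count scale (0–148).
  Groups are compared by regressing the per-subject medians on group
  (equivalently a one-way ANOVA). Because pairwise distances are
  mutually dependent, the parametric F null is badly anti-conservative
  (empirically ~35% type-I at nominal 5%), so the reported p-value
  comes from a seeded label-permutation null (default 1000
  permutations); the parametric p is retained in the result for
  transparency. Whether such group comparisons should use per-subject
  medians or pooled pairwise distances is genuinely ambiguous; the
  per-subject-median choice is implemented, and the pooled
  off-diagonal distribution is exported for sensitivity analysis.
- Location x phenotype: per-region prevalence computed within each
  phenotype, two-way ANOVA with factors lobe (temporal 30 regions vs
  extratemporal 118) and phenotype over region-level observations;
  full tables are reported so any df convention can be read off.
- SUVR: OLS of TOC and of mean thickness on SUVR, with and without age
  adjustment; high/low labels by strict median split (ties to low).
- STS status (none / unilateral / bilateral): one-way ANOVA with
  Bonferroni-adjusted pairwise Welch t-tests for continuous variables;
  chi-squared without continuity correction for categorical ones.

Type-I calibration of every group test is verified at 1000 null
simulations in the acceptance suite ([3%, 7%] at nominal 5%; the
permutation p keeps the Hamming comparison inside that band).

## Numerical choices and edge cases

- Variance floors: sigma^2 >= 1e-12, tau^2 >= `tau2_floor` (1e-12) —
  degenerate noiseless or site-free inputs stay finite and reduce to
  ordinary weighted least squares.
- The inverse-gamma method-of-moments fit caps the shape parameter at
  1e4 (sites with indistinguishable variances would otherwise send it
  to infinity); between-site variance is floored at (mean/100)^2.
- Region matching is tolerant of label dialects (dots vs underscores,
  `&` vs `and`, `_thickness` suffixes) and reports every unmatched
  name; the temporal-lobe roster ships as data (15 labels per
  hemisphere, every `a2009s` label containing "temp": the temporal
  gyri/sulci proper plus the occipito-temporal fusiform, lingual and
  parahippocampal labels). The assignment of border parcels to
  "temporal" is a convention; the packaged table is the reviewable
  statement of it.
- Scores are computed for one site per call; mixing sites in a scoring
  batch raises rather than silently mixing posteriors.
- Group tests refuse groups below their minimum size (ANCOVA 3,
  dissimilarity 2 with singletons skipped and warned about).

## Problem sizes

Default experiment sizes (reference n = 2000 over 10 sites, 20
adaptation controls, 86 patients, 200 held-out calibration subjects,
1000-replicate null calibration, 100-seed direction checks) were
chosen so the whole verification suite runs on a laptop-class single
core in a couple of minutes while keeping Monte-Carlo error well
inside the asserted tolerances; all are configuration values, not
constants.
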