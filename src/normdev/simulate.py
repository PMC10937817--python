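"""Synthetic multi-site cohort generator.

Emulates the data layout of a multi-site normative-modeling study of
regional cortical thickness: a large healthy *reference* cohort spread
over several acquisition sites, a small healthy *adaptation* set scanned
at a new (clinical) site, and a *clinical* cohort at that same site with
heterogeneous regional atrophy concentrated in — but not limited to —
the temporal lobe.

Generative model for thickness of subject i in region j at site s (mm):

    y_ij = b_j + m_j * age_i + f_j * 1[female_i] + u_{s,j} + eps_ij
    eps_ij ~ Normal(0, (sigma_j * lambda_s)^2)

with per-region baselines b_j, (negative) age slopes m_j, sex effects
f_j and residual scales sigma_j drawn once per configuration; per-site
random intercepts u_{s,j} ~ Normal(0, site_intercept_sd^2) and log-normal
noise-scale multipliers lambda_s.  Clinical subjects additionally receive
atrophy: each *core* region (default: bilateral superior temporal
sulcus) is atrophied with probability ``core_penetrance``, and an
idiosyncratic random region set is atrophied at a per-region rate; an
affected region is shifted down by ``effect * sigma_j`` with the effect
size drawn from ``effect_size_range`` (units of residual SD).  Clinical
subgroup labels (disease stage, presenting phenotype, depression
history) modulate the rates so that group orderings seen in clinical
cohorts (dementia > MCI burden, non-amnestic > amnestic spread, ongoing
depression < no depression) hold by construction.

Everything is deterministic under a fixed ``seed``; each cohort draws
from its own child stream, so generating one cohort never perturbs
another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import load_atlas, region_mask

CLINICAL_SITE = "site_clinical"


@dataclass
class AtrophySpec:
    """Where and how strongly clinical subjects lose thickness."""

    core_regions: tuple[str, ...] = ("lh_S_temporal_sup", "rh_S_temporal_sup")
    core_penetrance: float = 0.6
    idiosyncratic_rate: float = 0.15
    effect_size_range: tuple[float, float] = (2.0, 5.0)  # units of sigma_j


@dataclass
class SubgroupSpec:
    """Clinical label frequencies and label-dependent rate modifiers."""

    p_dementia: float = 48 / 86
    p_amnestic: float = 64 / 86
    p_depression: tuple[float, float, float] = (24 / 82, 7 / 82, 51 / 82)  # ongoing, past, none
    stage_rate_mult: dict = field(
        default_factory=lambda: {"dementia": 1.5, "MCI": 1.0}
    )
    stage_core_mult: dict = field(
        default_factory=lambda: {"dementia": 1.15, "MCI": 0.85}
    )
    phenotype_rate_mult: dict = field(
        default_factory=lambda: {"non-amnestic": 1.4, "amnestic": 1.0}
    )
    # sampling weight of extratemporal regions in the idiosyncratic draw
    phenotype_extratemporal_weight: dict = field(
        default_factory=lambda: {"non-amnestic": 1.5, "amnestic": 1.0}
    )
    depression_rate_mult: dict = field(
        default_factory=lambda: {"ongoing": 0.6, "past": 0.9, "none": 1.0}
    )


@dataclass
class SuvrSpec:
    """Per-subject amyloid SUVR scalar: mean + slope * z(burden) + noise."""

    mean: float = 1.4
    sd: float = 0.2
    slope: float = -0.06  # per SD of atrophy burden; sign configurable


@dataclass
class GeneratorConfig:
    n_reference: int = 2000
    n_sites: int = 10
    n_adaptation: int = 20
    n_clinical: int = 86
    age_range_reference: tuple[float, float] = (18.0, 90.0)
    age_range_clinical: tuple[float, float] = (49.1, 87.4)
    sex_ratio: float = 0.5  # fraction female, reference/adaptation
    clinical_sex_ratio: float = 42 / 86
    baseline_range: tuple[float, float] = (2.0, 3.0)  # mm
    age_slope_range: tuple[float, float] = (-0.008, -0.002)  # mm / year
    sex_effect_range: tuple[float, float] = (-0.05, 0.05)  # mm
    residual_sd_range: tuple[float, float] = (0.08, 0.18)  # mm
    site_intercept_sd: float = 0.05  # mm
    site_log_scale_sd: float = 0.15  # sd of log lambda_s
    atrophy: AtrophySpec = field(default_factory=AtrophySpec)
    subgroups: SubgroupSpec = field(default_factory=SubgroupSpec)
    suvr: SuvrSpec = field(default_factory=SuvrSpec)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_reference", "n_sites", "n_adaptation", "n_clinical"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 (site hierarchy unidentifiable)")
        if self.n_adaptation < 2:
            raise ValueError("n_adaptation must be >= 2 (site variance unestimable)")
        for rng_name in ("age_range_reference", "age_range_clinical"):
            lo, hi = getattr(self, rng_name)
            if not lo < hi:
                raise ValueError(f"{rng_name} must be a well-ordered interval")
        for p in (self.sex_ratio, self.clinical_sex_ratio,
                  self.atrophy.core_penetrance, self.atrophy.idiosyncratic_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions/penetrances/rates must lie in [0, 1]")
        if self.residual_sd_range[0] <= 0:
            raise ValueError("residual sd must be positive")
        if self.atrophy.effect_size_range[0] < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.site_intercept_sd < 0 or self.site_log_scale_sd < 0:
            raise ValueError("site effect scales must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth echoed by the generator for recovery tests."""

    baseline: np.ndarray  # (148,)
    age_slope: np.ndarray
    sex_effect: np.ndarray
    residual_sd: np.ndarray
    site_offsets: np.ndarray  # (n_sites, 148), reference sites
    site_scales: np.ndarray  # (n_sites,)
    clinical_site_offset: np.ndarray  # (148,)
    clinical_site_scale: float
    atrophied_regions: dict = field(default_factory=dict)  # subject_id -> {region: effect}
    config: GeneratorConfig | None = None

    def burden(self, subject_ids) -> np.ndarray:
        """Number of truly atrophied regions per subject."""
        return np.array([len(self.atrophied_regions.get(s, {})) for s in subject_ids])

    def to_json(self) -> str:
        d = {
            "baseline": self.baseline.tolist(),
            "age_slope": self.age_slope.tolist(),
            "sex_effect": self.sex_effect.tolist(),
            "residual_sd": self.residual_sd.tolist(),
            "site_offsets": self.site_offsets.tolist(),
            "site_scales": self.site_scales.tolist(),
            "clinical_site_offset": self.clinical_site_offset.tolist(),
            "clinical_site_scale": self.clinical_site_scale,
            "atrophied_regions": self.atrophied_regions,
            "config": dataclasses.asdict(self.config) if self.config else None,
        }
        return json.dumps(d, indent=1)


class CohortSimulator:
    """Deterministic simulator for reference / adaptation / clinical cohorts.

    Parameters are fixed by a :class:`GeneratorConfig`; all randomness
    descends from ``config.seed`` through per-cohort child streams.
    """

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or GeneratorConfig()
        self.config.validate()
        self.atlas = load_atlas()
        self.region_names = list(self.atlas["name"])
        self._temporal_mask = region_mask(self.atlas, lobe_group="temporal")
        # fixed fan-out: params, reference, adaptation, clinical, suvr, holdout
        ss = np.random.SeedSequence(self.config.seed)
        self._children = ss.spawn(6)
        self.truth = self._draw_truth()

    # -- truth ---------------------------------------------------------
    def _draw_truth(self) -> TruthRecord:
        cfg = self.config
        rng = np.random.default_rng(self._children[0])
        R = len(self.region_names)
        baseline = rng.uniform(*cfg.baseline_range, R)
        age_slope = rng.uniform(*cfg.age_slope_range, R)
        sex_effect = rng.uniform(*cfg.sex_effect_range, R)
        residual_sd = rng.uniform(*cfg.residual_sd_range, R)
        site_offsets = rng.normal(0.0, cfg.site_intercept_sd, (cfg.n_sites, R))
        site_scales = np.exp(rng.normal(0.0, cfg.site_log_scale_sd, cfg.n_sites))
        clin_offset = rng.normal(0.0, cfg.site_intercept_sd, R)
        clin_scale = float(np.exp(rng.normal(0.0, cfg.site_log_scale_sd)))
        missing = [r for r in cfg.atrophy.core_regions if r not in self.region_names]
        if missing:
            raise ValueError(f"core atrophy regions not in atlas: {missing}")
        return TruthRecord(
            baseline=baseline, age_slope=age_slope, sex_effect=sex_effect,
            residual_sd=residual_sd, site_offsets=site_offsets,
            site_scales=site_scales, clinical_site_offset=clin_offset,
            clinical_site_scale=clin_scale, config=cfg,
        )

    # -- helpers -------------------------------------------------------
    def _healthy_thickness(self, rng, age, female, site_offset, site_scale):
        t = self.truth
        mu = (t.baseline[None, :]
              + np.outer(age, t.age_slope)
              + np.outer(female.astype(float), t.sex_effect)
              + site_offset[None, :])
        noise = rng.normal(0.0, 1.0, mu.shape) * (t.residual_sd[None, :] * site_scale)
        return np.maximum(mu + noise, 0.05)

    def _cohort_frame(self, ids, age, female, site, role):
        return pd.DataFrame({
            "subject_id": ids,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "site": site,
            "role": role,
        })

    def _thickness_frame(self, ids, values):
        return pd.DataFrame(values, index=pd.Index(ids, name="subject_id"),
                            columns=self.region_names)

    # -- cohorts -------------------------------------------------------
    def reference(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        rng = np.random.default_rng(self._children[1])
        n = cfg.n_reference
        ids = [f"ref_{i:05d}" for i in range(n)]
        age = rng.uniform(*cfg.age_range_reference, n)
        female = rng.random(n) < cfg.sex_ratio
        site_idx = rng.integers(0, cfg.n_sites, n)
        sites = np.array([f"site_{s:02d}" for s in site_idx])
        thick = np.empty((n, len(self.region_names)))
        for s in range(cfg.n_sites):
            m = site_idx == s
            thick[m] = self._healthy_thickness(
                rng, age[m], female[m],
                self.truth.site_offsets[s], self.truth.site_scales[s])
        cohort = self._cohort_frame(ids, age, female, sites, "reference")
        return cohort, self._thickness_frame(ids, thick)

    def adaptation(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        rng = np.random.default_rng(self._children[2])
        n = cfg.n_adaptation
        ids = [f"adapt_{i:03d}" for i in range(n)]
        age = rng.uniform(*cfg.age_range_clinical, n)
        female = rng.random(n) < cfg.sex_ratio
        thick = self._healthy_thickness(
            rng, age, female, self.truth.clinical_site_offset,
            self.truth.clinical_site_scale)
        cohort = self._cohort_frame(ids, age, female, CLINICAL_SITE, "adaptation")
        return cohort, self._thickness_frame(ids, thick)

    def holdout(self, n: int = 200) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Extra healthy subjects at the clinical site (calibration checks)."""
        cfg = self.config
        rng = np.random.default_rng(self._children[5])
        ids = [f"hold_{i:04d}" for i in range(n)]
        age = rng.uniform(*cfg.age_range_clinical, n)
        female = rng.random(n) < cfg.sex_ratio
        thick = self._healthy_thickness(
            rng, age, female, self.truth.clinical_site_offset,
            self.truth.clinical_site_scale)
        cohort = self._cohort_frame(ids, age, female, CLINICAL_SITE, "adaptation")
        return cohort, self._thickness_frame(ids, thick)

    def clinical(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        sub = cfg.subgroups
        atr = cfg.atrophy
        rng = np.random.default_rng(self._children[3])
        n = cfg.n_clinical
        R = len(self.region_names)
        ids = [f"clin_{i:03d}" for i in range(n)]
        age = rng.uniform(*cfg.age_range_clinical, n)
        female = rng.random(n) < cfg.clinical_sex_ratio
        thick = self._healthy_thickness(
            rng, age, female, self.truth.clinical_site_offset,
            self.truth.clinical_site_scale)

        stage = np.where(rng.random(n) < sub.p_dementia, "dementia", "MCI")
        phenotype = np.where(rng.random(n) < sub.p_amnestic, "amnestic", "non-amnestic")
        dep_p = np.asarray(sub.p_depression, dtype=float)
        dep_p = dep_p / dep_p.sum()
        depression = rng.choice(["ongoing", "past", "none"], size=n, p=dep_p)

        core_idx = [self.region_names.index(r) for r in atr.core_regions]
        lo, hi = atr.effect_size_range
        self.truth.atrophied_regions = {}
        for i in range(n):
            effects: dict[str, float] = {}
            p_core = min(atr.core_penetrance * sub.stage_core_mult[stage[i]], 1.0)
            if rng.random() < p_core:
                for j in core_idx:
                    effects[self.region_names[j]] = float(rng.uniform(lo, hi))
            rate = (atr.idiosyncratic_rate
                    * sub.stage_rate_mult[stage[i]]
                    * sub.phenotype_rate_mult[phenotype[i]]
                    * sub.depression_rate_mult[depression[i]])
            w = np.where(self._temporal_mask, 1.0,
                         sub.phenotype_extratemporal_weight[phenotype[i]])
            p_j = np.minimum(rate * w / w.mean(), 1.0)
            hit = rng.random(R) < p_j
            for j in np.flatnonzero(hit):
                effects.setdefault(self.region_names[j], float(rng.uniform(lo, hi)))
            for name, e in effects.items():
                j = self.region_names.index(name)
                thick[i, j] -= e * self.truth.residual_sd[j]
            self.truth.atrophied_regions[ids[i]] = effects
        thick = np.maximum(thick, 0.05)

        cohort = self._cohort_frame(ids, age, female, CLINICAL_SITE, "clinical")
        cohort["phenotype"] = phenotype
        cohort["stage"] = stage
        cohort["depression"] = depression
        burden = self.truth.burden(ids)
        cohort["suvr"] = self.suvr(burden)
        return cohort, self._thickness_frame(ids, thick)

    def suvr(self, burden: np.ndarray) -> np.ndarray:
        """SUVR scalar correlated (sign per config) with atrophy burden."""
        spec = self.config.suvr
        rng = np.random.default_rng(self._children[4])
        burden = np.asarray(burden, dtype=float)
        sd_b = burden.std()
        z = (burden - burden.mean()) / sd_b if sd_b > 0 else np.zeros_like(burden)
        noise_sd = np.sqrt(max(spec.sd**2 - spec.slope**2, 0.0))
        vals = spec.mean + spec.slope * z + rng.normal(0.0, noise_sd, burden.shape)
        return np.maximum(vals, 0.05)


# -- thin functional wrappers (spec-level operations) ------------------

def generate_reference(config: GeneratorConfig | None = None):
    sim = CohortSimulator(config)
    cohort, thick = sim.reference()
    return cohort, thick, sim.truth


def generate_adaptation(config: GeneratorConfig | None = None, truth: TruthRecord | None = None):
    sim = CohortSimulator(config if config is not None else (truth.config if truth else None))
    if truth is not None:
        sim.truth = truth
    return sim.adaptation()


def generate_clinical(config: GeneratorConfig | None = None, truth: TruthRecord | None = None):
    sim = CohortSimulator(config if config is not None else (truth.config if truth else None))
    if truth is not None:
        for f in ("baseline", "age_slope", "sex_effect", "residual_sd",
                  "clinical_site_offset", "clinical_site_scale"):
            setattr(sim.truth, f, getattr(truth, f))
    cohort, thick = sim.clinical()
    return cohort, thick, sim.truth


def generate_suvr(config: GeneratorConfig, truth: TruthRecord, counts) -> np.ndarray:
    sim = CohortSimulator(config)
    sim.truth = truth
    return sim.suvr(np.asarray(counts))


# -- writers -----------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_thickness_csv(thickness: pd.DataFrame, path) -> None:
    thickness.to_csv(path)


def write_truth_json(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
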