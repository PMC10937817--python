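"""End-to-end pipeline: simulate -> fit -> adapt -> score -> analyze.

Stages read and write plain CSV/JSON with stable headers; a manifest
JSON records package/library versions, the seed, SHA-256 checksums of
every input and the list of every output, so any result file can be
re-derived from the manifest alone.  A stage failure leaves partial
outputs in place alongside a ``FAILED`` marker file and a nonzero exit
status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import load_atlas, resolve_region_columns
from .dissimilarity import compare_group_dissimilarity, group_dissimilarity, hamming_matrix
from .model import HierarchicalNormativeModel
from .outliers import DEFAULT_THRESHOLD, flag_outliers, summarize_outliers
from .simulate import CohortSimulator, GeneratorConfig
from .stats import (age_correlation, location_phenotype_interaction,
                    outliercount_group_test, results_frame, suvr_association)

log = logging.getLogger("normdev")


@dataclass
class PipelineConfig:
    output_dir: str = "normdev_out"
    cohort_csv: str | None = None      # None -> simulate
    thickness_csv: str | None = None
    model_json: str | None = None      # None -> fit from the (simulated) reference
    threshold: float = DEFAULT_THRESHOLD
    transform: str = "log1p"
    group_by: tuple[str, ...] = ("stage", "phenotype", "depression")
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.threshold < 0:
            raise ValueError("threshold must be negative")
        if self.transform not in ("log1p", "none"):
            raise ValueError("transform must be 'log1p' or 'none'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "age", "sex", "site", "role") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {missing}")
    return df


def read_thickness_csv(path, validate_regions=True) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if validate_regions:
        order = resolve_region_columns(df.columns)
        df = df[order]
        df.columns = load_atlas()["name"]
    return df


def run_pipeline(config: PipelineConfig) -> tuple[int, Path]:
    """Execute all configured stages; return (exit status, manifest path)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    manifest: dict = {
        "normdev_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "settings": _jsonable(dataclasses.asdict(config)),
        "inputs": {}, "outputs": [],
    }
    failed_marker = out / "FAILED"

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    try:
        if failed_marker.exists():
            failed_marker.unlink()
        atlas = load_atlas()
        cfg = dataclasses.replace(config.generator, seed=config.seed)
        sim = CohortSimulator(cfg)

        if config.cohort_csv is None:
            log.info("simulating cohorts (seed=%d)", config.seed)
            ref_c, ref_t = sim.reference()
            ad_c, ad_t = sim.adaptation()
            cl_c, cl_t = sim.clinical()
            cohort = pd.concat([ref_c, ad_c, cl_c], ignore_index=True)
            thickness = pd.concat([ref_t, ad_t, cl_t])
            emit("cohort.csv", lambda p: cohort.to_csv(p, index=False))
            emit("thickness.csv", thickness.to_csv)
            emit("truth.json", lambda p: Path(p).write_text(sim.truth.to_json()))
        else:
            for key, p in (("cohort_csv", config.cohort_csv),
                           ("thickness_csv", config.thickness_csv)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{key} not found: {p}")
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
            cohort = read_cohort_csv(config.cohort_csv)
            thickness = read_thickness_csv(config.thickness_csv)
            thickness.index = cohort["subject_id"]

        roles = cohort["role"]
        covs = cohort.set_index("subject_id")
        thickness.index.name = "subject_id"

        if config.model_json is not None:
            p = Path(config.model_json)
            if not p.exists():
                raise FileNotFoundError(f"model_json not found: {p}")
            manifest["inputs"]["model_json"] = {"path": str(p), "sha256": _sha256(p)}
            est = HierarchicalNormativeModel.from_json(p.read_text())
        else:
            log.info("fitting reference model")
            mask = (roles == "reference").to_numpy()
            est = HierarchicalNormativeModel(random_state=config.seed)
            est.fit(cohort[mask], thickness.iloc[mask])
        flagged = est.diagnostics_.get("flagged_regions", [])
        if flagged:
            log.warning("non-converged regions: %s", flagged)

        mask_ad = (roles == "adaptation").to_numpy()
        if mask_ad.any():
            log.info("adapting to site of %d controls", mask_ad.sum())
            est.adapt(cohort[mask_ad], thickness.iloc[mask_ad])
        emit("model.json", lambda p: Path(p).write_text(est.to_json()))

        mask_cl = (roles == "clinical").to_numpy()
        clinical = cohort[mask_cl].set_index("subject_id")
        res = est.deviation_scores(cohort[mask_cl].set_index("subject_id"),
                                   thickness.iloc[mask_cl])
        emit("zscores.csv", res.z.to_csv)

        flags = flag_outliers(res.z, config.threshold)
        summary = summarize_outliers(flags, atlas)
        emit("outliers.csv", flags.to_csv)
        emit("prevalence.csv", lambda p: summary.prevalence.join(
            atlas.set_index("name")[["hemisphere", "lobe_group"]]).to_csv(p))
        subj = pd.DataFrame({
            "total_outlier_count": summary.total_outlier_count,
            "sts_status": summary.sts_status,
        })
        emit("subjects.csv", subj.to_csv)

        log.info("analyzing")
        H = hamming_matrix(flags)
        emit("hamming.csv", H.to_csv)
        all_results = {}
        toc = summary.total_outlier_count
        all_results["toc_age"] = age_correlation(toc, clinical["age"])
        for grouping in config.group_by:
            if grouping not in clinical.columns:
                continue
            labels = clinical[grouping]
            keep = labels.notna().to_numpy()
            if pd.unique(labels[keep]).size < 2:
                continue
            covariates = clinical.loc[keep, ["age", "sex"]]
            if grouping in ("phenotype", "depression") and "stage" in clinical:
                covariates = clinical.loc[keep, ["age", "sex", "stage"]]
            try:
                all_results[f"toc_{grouping}"] = outliercount_group_test(
                    toc[keep], labels[keep], covariates, config.transform)
            except ValueError as exc:
                log.warning("skipping TOC test for %s: %s", grouping, exc)
            try:
                ids = labels.index[keep]
                all_results[f"hamming_{grouping}"] = compare_group_dissimilarity(
                    H.loc[ids, ids], labels[keep], seed=config.seed)
            except ValueError as exc:
                log.warning("skipping dissimilarity test for %s: %s", grouping, exc)
        if "phenotype" in clinical.columns:
            all_results["location_phenotype"] = location_phenotype_interaction(
                flags, clinical["phenotype"], atlas)
        if "suvr" in clinical.columns and clinical["suvr"].notna().all():
            assoc = suvr_association(toc, thickness.iloc[mask_cl].mean(axis=1),
                                     clinical["suvr"], clinical["age"])
            all_results["suvr"] = assoc["results"]
            try:
                all_results["hamming_suvr_split"] = compare_group_dissimilarity(
                    H, assoc["split"], seed=config.seed)
            except ValueError as exc:
                log.warning("skipping SUVR-split dissimilarity: %s", exc)
        emit("stats.tsv", lambda p: results_frame(all_results).to_csv(p, sep="\t", index=False))

        hsum = group_dissimilarity(H, pd.Series("all", index=H.index))["all"]
        manifest["summary"] = {
            "n_clinical": int(mask_cl.sum()),
            "toc_median": float(toc.median()),
            "hamming_median": hsum.median, "hamming_iqr": hsum.iqr,
        }
    except Exception as exc:  # stage failure: marker + nonzero status
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("pipeline failed: %s", exc)
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return 1, out / "manifest.json"

    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return 0, path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
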