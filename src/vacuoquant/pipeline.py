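"""End-to-end synthetic pipeline: simulate -> smear -> gate -> image -> model.

``run_pipeline`` chains the package stages in the order of the underlying
assay workflow: a longitudinal smear cohort is generated and scored; per
sampling occasion a flow sample is generated, gated with NK-anchored LAMP-1
and perforin gates and summarised into per-subset affected percentages;
batches of single-cell images are segmented and quantified; and finally the
longitudinal mixed model is fitted to the percentage of vacuolated
lymphocytes and to the per-subset affected percentages.  Everything is
deterministic given the seed (stage seeds are spawned from it), all outputs
carry the version and parameter set, and a manifest records which stages
completed so partial failures leave finished outputs intact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, imaging, io, severity, smear, synth
from .synth import CohortConfig, SeverityClass

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass
class PipelineConfig:
    """Configuration of the full synthetic pipeline."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    flow_events_per_sample: int = 4000
    nk_quantile: float = 0.05
    min_nk: int = 50
    images_per_class: int = 40
    image_classes: tuple = (SeverityClass.CONTROL, SeverityClass.CLASSICAL)
    image_size: tuple = (64, 64)
    connectivity: int = 2
    hole_fill: bool = True
    severity_outcomes: tuple = severity.OUTCOME_NAMES
    alpha: float = 0.05
    save_images: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = io.load_yaml(path)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "image_classes" in kwargs:
            kwargs["image_classes"] = tuple(
                SeverityClass.from_label(c) for c in kwargs["image_classes"]
            )
        for key in ("image_size", "severity_outcomes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return io.jsonable(dataclasses.asdict(self))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages into ``out_dir``; return (and write) the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict()}
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": []}

    def _record(stage: str, status: str, outputs: list[str] | None = None):
        manifest["stages"][stage] = status
        manifest["outputs"].extend(outputs or [])
        io.write_json(
            {k: manifest[k] for k in ("stages", "outputs")},
            out_dir / "manifest.json",
            meta=meta,
        )

    (seed_cohort, seed_flow, seed_img) = _spawn_seeds(config.seed, 3)

    # stage 1: synthetic cohort + smear scoring
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seed_cohort)
        cohort_df, patients = synth.generate_cohort(cohort_cfg)
        io.write_table(cohort_df, out_dir / "cohort.csv", meta)
        patients_df = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "class": p.severity_class.value,
                    "genotype": p.genotype_string,
                    "random_intercept": p.random_intercept,
                    "random_slope": p.random_slope,
                }
                for p in patients
            ]
        )
        io.write_table(patients_df, out_dir / "patients.csv", meta)
        scores = smear.score_cohort(cohort_df)
        io.write_table(scores, out_dir / "smear_scores.csv", meta)
        io.write_table(
            smear.two_axis_summary(scores), out_dir / "two_axis_summary.csv", meta
        )
        _record("smear", "ok",
                ["cohort.csv", "patients.csv", "smear_scores.csv",
                 "two_axis_summary.csv"])
    except Exception as exc:
        _record("smear", f"failed: {exc}")
        raise PipelineError(f"smear stage failed: {exc}") from exc

    # stage 2: flow samples + gating, one sample per sampling occasion
    try:
        by_id = {p.patient_id: p for p in patients}
        sample_keys = (
            scores[["sample_id", "patient_id", "severity_class", "age_years"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )
        flow_seeds = _spawn_seeds(seed_flow, len(sample_keys))
        rows = []
        for i, rec in sample_keys.iterrows():
            p = by_id[rec["patient_id"]]
            offset = p.random_intercept + p.random_slope * rec["age_years"]
            events = synth.generate_flow_sample(
                rec["severity_class"],
                config.flow_events_per_sample,
                cohort_cfg,
                seed=flow_seeds[i],
                affected_logit_offset=offset,
            )
            gates = gating.auto_marker_gates(events)
            labeled = gating.assign_subsets(events, gates)
            gates = gating.derive_lamp1_gate(
                labeled, gates, quantile=config.nk_quantile, min_nk=config.min_nk
            )
            report = gating.affected_fractions(
                labeled, gates, sample_id=rec["sample_id"]
            )
            row = {
                "sample_id": rec["sample_id"],
                "patient_id": rec["patient_id"],
                "severity_class": rec["severity_class"],
                "age_years": rec["age_years"],
            }
            for name in ("T4", "T8", "B", "NK"):
                row[f"pct_affected_{name}"] = report.subsets[name]["pct_affected"]
                row[f"n_events_{name}"] = report.subsets[name]["n_events"]
            rows.append(row)
        affected_df = pd.DataFrame(rows)
        io.write_table(affected_df, out_dir / "affected_fractions.csv", meta)
        _record("gating", "ok", ["affected_fractions.csv"])
    except Exception as exc:
        _record("gating", f"failed: {exc}")
        raise PipelineError(f"gating stage failed: {exc}") from exc

    # stage 3: single-cell imaging quantification
    try:
        rng = np.random.default_rng(seed_img)
        quants_rows = []
        curves_by_class = {}
        quants_by_class = {}
        for cls in config.image_classes:
            cls = SeverityClass.from_label(cls)
            pmf = synth.DEFAULT_VACUOLE_PMF[cls]
            vals = sorted(pmf)
            probs = np.array([pmf[v] for v in vals])
            vac_p = float(
                cohort_cfg.normalized().vac_fraction_by_class[cls]
            )
            curves, quants = [], []
            for j in range(config.images_per_class):
                vacuolated = rng.random() < vac_p
                n_vac = int(rng.choice(vals, p=probs)) if vacuolated else 0
                pair = synth.generate_cell_image(
                    cls,
                    n_vac,
                    image_size=config.image_size,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    cell_id=f"{cls.value}_{j:04d}",
                )
                if config.save_images:
                    io.save_image_pair(pair, out_dir / "images")
                mask = imaging.segment_cell(
                    pair, connectivity=config.connectivity,
                    fill_holes=config.hole_fill,
                )
                quant, curve = imaging.quantify_cell(pair, mask)
                quants.append(quant)
                curves.append(curve)
                quants_rows.append(
                    {
                        "cell_id": quant.cell_id,
                        "class": cls.value,
                        "n_vacuoles_true": n_vac,
                        "mean_lamp1": quant.mean_lamp1,
                        "area_px": quant.area_px,
                        "otsu_threshold": mask.otsu_threshold,
                        "true_mean_lamp1": pair.true_mean_lamp1,
                    }
                )
            curves_by_class[cls.value] = curves
            quants_by_class[cls.value] = quants
        io.write_table(
            pd.DataFrame(quants_rows), out_dir / "imaging_quants.csv", meta
        )
        band_frames = []
        for cls_name, curves in curves_by_class.items():
            bands = imaging.population_bands(curves)
            band_frames.append(
                pd.DataFrame(
                    {
                        "class": cls_name,
                        "level": bands.levels,
                        "p2_5": bands.p2_5,
                        "q25": bands.q25,
                        "median": bands.median,
                        "q75": bands.q75,
                        "p97_5": bands.p97_5,
                    }
                )
            )
        io.write_table(
            pd.concat(band_frames, ignore_index=True),
            out_dir / "imaging_bands.csv",
            meta,
        )
        io.write_table(
            imaging.compare_classes(quants_by_class),
            out_dir / "imaging_summary.csv",
            meta,
        )
        _record("imaging", "ok",
                ["imaging_quants.csv", "imaging_bands.csv", "imaging_summary.csv"])
    except Exception as exc:
        _record("imaging", f"failed: {exc}")
        raise PipelineError(f"imaging stage failed: {exc}") from exc

    # stage 4: longitudinal severity model per outcome
    try:
        merged = scores.merge(
            affected_df.drop(columns=["severity_class", "age_years"]),
            on=["sample_id", "patient_id"],
            how="left",
        )
        io.write_table(merged, out_dir / "merged_outcomes.csv", meta)
        fits = {}
        for outcome in config.severity_outcomes:
            fits[outcome] = severity.fit_severity_model(merged, outcome)
        io.write_json(
            {name: fit.to_dict() for name, fit in fits.items()},
            out_dir / "severity_fits.json",
            meta,
        )
        io.write_json(
            severity.severity_trend_report(fits, alpha=config.alpha),
            out_dir / "severity_report.json",
            meta,
        )
        _record("severity", "ok",
                ["merged_outcomes.csv", "severity_fits.json",
                 "severity_report.json"])
    except Exception as exc:
        _record("severity", f"failed: {exc}")
        raise PipelineError(f"severity stage failed: {exc}") from exc

    return manifest
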