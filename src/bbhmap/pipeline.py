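"""Configuration-driven end-to-end hemorrhage-mapping run.

Stages: cohort (generate or load) -> trajectory rasterization + hemispheric
flip -> hemorrhage masks (generate or load) -> target classification ->
cohort statistics + logistic risk model -> VLSM (trajectories vs hemorrhage;
hemorrhage vs symptoms; hemorrhage vs sensorimotor deficit) -> standardized
trajectory profile. All tables, maps and figures land in the output
directory together with a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axisprofile import axial_profile, cross_section_map
from .grids import VolumeGrid, flip_to_right, read_volume, write_volume
from .segmentation import SegmentationParams
from .stats import HemorrhageRiskModel, chi_squared, cohort_summary, kruskal_wallis
from .synthetic import (
    CohortSpec,
    generate_cohort,
    generate_hemorrhage_mask,
    generate_template,
    read_cohort_csv,
    records_to_frame,
    write_cohort_csv,
)
from .trajectories import (
    classify_target,
    overlap_frequency_map,
    rasterize_trajectory,
)
from .vlsm import VoxelLesionSymptomMapper, threshold_map

log = logging.getLogger("bbhmap")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name, partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    ``cohort_csv``/``masks_dir`` switch the run from synthetic generation to
    loading an existing cohort; the template is generated unless paths are
    given.
    """

    seed: int = 0
    outdir: str = "bbhmap_out"
    cohort_spec: CohortSpec | None = None
    cohort_csv: str | None = None
    masks_dir: str | None = None
    template_path: str | None = None
    atlas_path: str | None = None
    template_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    min_coverage: int = 5
    tail: str = "greater"
    alpha: float = 0.05
    correction: str = "bonferroni"
    profile_bins: int = 24
    radial_cap_mm: float = 20.0
    write_figures: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "cohort_spec" in raw and isinstance(raw["cohort_spec"], dict):
            raw["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
        if "segmentation" in raw and isinstance(raw["segmentation"], dict):
            raw["segmentation"] = SegmentationParams(**raw["segmentation"])
        if "template_shape" in raw:
            raw["template_shape"] = tuple(raw["template_shape"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                out = fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, e) from e
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _run_vlsm(masks, outcome, covariates, cfg, outdir, tag):
    mapper = VoxelLesionSymptomMapper(
        tail=cfg.tail, alpha=cfg.alpha, correction=cfg.correction,
        min_coverage=cfg.min_coverage,
    )
    mapper.fit(masks, outcome, covariates=covariates)
    res = mapper.result_
    for name, grid in (
        ("t", res.t_map), ("z", res.z_map), ("p", res.p_map),
        ("analyzed", res.analyzed_mask),
    ):
        g = grid if name == "analyzed" else grid.with_data(grid.data.astype(np.float32))
        write_volume(g, outdir / f"vlsm_{tag}_{name}.nii.gz")
    supra_corr = threshold_map(res)
    supra_unc = threshold_map(res, correction="none")
    write_volume(supra_corr, outdir / f"vlsm_{tag}_suprathreshold.nii.gz")
    write_volume(supra_unc, outdir / f"vlsm_{tag}_suprathreshold_uncorrected.nii.gz")
    return res, {
        "n_analyzed_voxels": res.n_analyzed_voxels,
        "alpha": res.alpha,
        "correction": res.correction,
        "corrected_threshold": res.corrected_threshold,
        "df": res.df,
        "n_degenerate_voxels": res.n_degenerate,
        "n_suprathreshold_corrected": int(supra_corr.data.sum()),
        "n_suprathreshold_uncorrected": int(supra_unc.data.sum()),
        "max_z": float(np.nanmax(res.z_map.data)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"software": {"name": "bbhmap", "version": __version__}}

    @_stage("template")
    def stage_template():
        if config.template_path and config.atlas_path:
            return (read_volume(config.template_path), read_volume(config.atlas_path))
        return generate_template(config.template_shape, config.voxel_size_mm)

    template, atlas = stage_template()
    write_volume(template, outdir / "template.nii.gz")
    write_volume(atlas, outdir / "atlas.nii.gz")

    @_stage("cohort")
    def stage_cohort():
        if config.cohort_csv:
            return read_cohort_csv(config.cohort_csv)
        spec = config.cohort_spec or CohortSpec(seed=config.seed)
        if config.cohort_spec is None or spec.seed != config.seed:
            spec = CohortSpec(**{**spec.__dict__, "seed": config.seed})
        return generate_cohort(spec, atlas)

    records = stage_cohort()
    write_cohort_csv(records, outdir / "cohort.csv")
    df = records_to_frame(records)

    @_stage("trajectories")
    def stage_trajectories():
        masks = []
        for r in records:
            masks.append(flip_to_right(rasterize_trajectory(r.trajectory, atlas)))
        return masks

    traj_masks = stage_trajectories()
    freq_traj = overlap_frequency_map(traj_masks)
    write_volume(freq_traj, outdir / "trajectory_frequency.nii.gz")

    @_stage("hemorrhage_masks")
    def stage_masks():
        masks = {}
        if config.masks_dir:
            for r in records:
                if r.bbh:
                    masks[r.patient_id] = read_volume(
                        Path(config.masks_dir) / f"{r.patient_id}_bbh.nii.gz"
                    )
        else:
            for i, r in enumerate(records):
                if r.bbh:
                    masks[r.patient_id] = generate_hemorrhage_mask(
                        r, template, seed=(config.seed * 100_003 + i) % (2**31 - 1)
                    )
        return masks

    bbh_masks = stage_masks()
    empty = VolumeGrid(
        np.zeros(template.shape, dtype=np.uint8), template.affine, template.space_tag
    )
    flipped_bbh = {
        pid: flip_to_right(m) for pid, m in bbh_masks.items()
    }
    bbh_stack = [flipped_bbh.get(r.patient_id, empty) for r in records]
    if flipped_bbh:
        freq_bbh = overlap_frequency_map(list(flipped_bbh.values()))
        write_volume(freq_bbh, outdir / "bbh_frequency.nii.gz")

    @_stage("target_classification")
    def stage_classify():
        return [classify_target(r.target_mm, atlas) for r in records]

    df["classified_label"] = stage_classify()
    report["target_classification"] = {
        "n_unclassified": int((df["classified_label"] == "unclassified").sum()),
    }

    @_stage("cohort_stats")
    def stage_stats():
        summary = cohort_summary(df)
        summary["patients"].to_csv(outdir / "table_patients.tsv", sep="\t", index=False)
        summary["hemorrhage"].to_csv(outdir / "table_hemorrhage.tsv", sep="\t", index=False)
        stats_block = {
            "n": len(df),
            "bbh_rate": float(df["bbh"].mean()),
            "symptomatic_rate": float(df["symptomatic"].mean()),
            "diagnostic_yield": summary["diagnostic_yield"],
            "notes": summary["notes"],
        }
        bbh = df["bbh"].astype(bool)
        if bbh.any() and (~bbh).any():
            bg = (df["target_region"] == "basal_ganglia").astype(int)
            tab = pd.crosstab(bg, bbh).to_numpy()[::-1, ::-1]
            x2, _, p = chi_squared(tab)
            stats_block["chi2_bg"] = {"statistic": x2, "p": p}
            h, p = kruskal_wallis([df.loc[bbh, "age"], df.loc[~bbh, "age"]])
            stats_block["kruskal_age"] = {"H": h, "p": p}
            model = HemorrhageRiskModel().fit(
                pd.DataFrame(
                    {
                        "age": df["age"],
                        "bg": bg,
                        "hgg": (df["histology"] == "HGG").astype(int),
                        "lgg": (df["histology"] == "LGG").astype(int),
                    }
                ),
                bbh.astype(int),
            )
            stats_block["logistic"] = {
                "coefficients": model.fit_.coefficients,
                "p_values": model.fit_.p_values,
                "model_chi2": model.model_chi2_,
                "nagelkerke_r2": model.nagelkerke_r2_,
                "converged": model.converged_,
            }
        return stats_block

    report["cohort_stats"] = stage_stats()

    @_stage("vlsm")
    def stage_vlsm():
        out = {}
        _, out["trajectory_vs_bbh"] = _run_vlsm(
            traj_masks, df["bbh"].astype(float).to_numpy(), None,
            config, outdir, "trajectory_bbh",
        )
        for tag, outcome_col in (
            ("bbh_vs_symptomatic", "symptomatic"),
            ("bbh_vs_sensorimotor", "sensorimotor_deficit"),
        ):
            outcome = df[outcome_col].astype(float).to_numpy()
            if outcome.sum() == 0 or len(flipped_bbh) < config.min_coverage:
                out[tag] = {"skipped": "too few hemorrhages or outcomes"}
                continue
            try:
                _, out[tag] = _run_vlsm(
                    bbh_stack, outcome, None, config, outdir,
                    tag.replace("bbh_vs_", "bbh_"),
                )
            except ValueError as e:
                # small cohorts can leave no voxel with enough mask coverage
                out[tag] = {"skipped": str(e)}
        return out

    report["vlsm"] = stage_vlsm()

    @_stage("axis_profile")
    def stage_profile():
        with_bbh = [r for r in records if r.patient_id in flipped_bbh]
        masks = [bbh_masks[r.patient_id] for r in with_bbh]
        specs = [r.trajectory for r in with_bbh]
        prof = axial_profile(masks, specs, config.profile_bins, config.radial_cap_mm)
        prof.to_frame().to_csv(outdir / "axis_profile.tsv", sep="\t", index=False)
        xsec, edges = cross_section_map(masks, specs, at_axial_fraction=1.0,
                                        half_thickness=0.1)
        np.savetxt(outdir / "cross_section.tsv", xsec, fmt="%d", delimiter="\t")
        block = {
            "n_subjects": len(masks),
            "argmax_axial_fraction": prof.argmax_fraction() if len(masks) else None,
            "total_voxels": int(prof.counts_per_bin.sum()),
            "excluded_radial": prof.n_excluded_radial,
            "excluded_axial": prof.n_excluded_axial,
        }
        if config.write_figures:
            _write_figures(outdir, freq_traj, prof, xsec, edges)
        return block

    report["axis_profile"] = stage_profile()

    report["config"] = _config_echo(config)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _config_echo(config: RunConfig) -> dict:
    d = dict(config.__dict__)
    d["segmentation"] = dict(config.segmentation.__dict__)
    if config.cohort_spec is not None:
        cs = dict(config.cohort_spec.__dict__)
        for k in ("volume_lognormal_params", "eloquent_labels", "location_probs"):
            cs[k] = list(cs[k])
        d["cohort_spec"] = cs
    d["template_shape"] = list(config.template_shape)
    return d


def _write_figures(outdir, freq_traj, prof, xsec, edges) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, axis_i, name in zip(axes, (0, 1, 2), ("sagittal", "coronal", "axial")):
        ax.imshow(freq_traj.data.max(axis=axis_i).T, origin="lower", cmap="hot")
        ax.set_title(f"trajectory frequency ({name} MIP)")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(outdir / "trajectory_frequency.png", dpi=110)
    plt.close(fig)

    fig, (a1, a2) = plt.subplots(1, 2, figsize=(10, 4))
    a1.bar(prof.centers, prof.counts_per_bin, width=np.diff(prof.edges), color="firebrick")
    a1.axvline(1.0, ls="--", c="k", lw=1)
    a1.set_xlabel("axial fraction (0 = entry, 1 = target)")
    a1.set_ylabel("hemorrhage voxels")
    a1.set_title("hemorrhage along standardized trajectory")
    a2.imshow(xsec.T, origin="lower", cmap="hot",
              extent=[edges[0], edges[-1], edges[0], edges[-1]])
    a2.set_title("cross-section at target")
    a2.set_xlabel("mm")
    fig.tight_layout()
    fig.savefig(outdir / "axis_profile.png", dpi=110)
    plt.close(fig)
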