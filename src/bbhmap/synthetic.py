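"""Synthetic cohorts, template space, atlas, trajectories and hemorrhage masks.

This module generates ground-truth data with the statistical structure the
downstream analyses assume: a midline-symmetric template grid with an
anatomical label volume; patients with age/sex/histology and a biopsy
trajectory whose target is drawn from a configurable regional distribution;
hemorrhage occurrence from a binary logistic model (age, basal-ganglia
target, high-grade-glioma effects); lognormal hemorrhage volumes; and
symptom flags driven by volume and by eloquent (posterior basal-ganglia)
location. Deep targets (basal ganglia, insula) are approached through
frontal entry points, cerebellar and brainstem targets through
posterior-inferior ones, cortical targets roughly radially — so hemorrhages
concentrate at the distal (target) end of the trajectories.

Everything is a pure function of (spec, seed): identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .grids import VolumeGrid
from .trajectories import TrajectorySpec, trajectory_length_mm

__all__ = [
    "CohortSpec",
    "PatientRecord",
    "ATLAS_LABELS",
    "REGION_LABELS",
    "generate_template",
    "generate_cohort",
    "generate_hemorrhage_mask",
    "calibrate_baseline_logit",
    "records_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]

# integer atlas labels of the synthetic anatomy
ATLAS_LABELS = {
    "frontal": 1,
    "parietal": 2,
    "temporal": 3,
    "occipital": 4,
    "insular": 5,
    "cerebellum": 6,
    "brainstem": 7,
    "basal_ganglia_anterior": 8,
    "basal_ganglia_posterior": 9,
}
_NAME_OF_LABEL = {v: k for k, v in ATLAS_LABELS.items()}

# target-region categories -> atlas labels they may occupy
REGION_LABELS = {
    "frontal": (1,),
    "parietal": (2,),
    "temporal": (3,),
    "occipital": (4,),
    "insular": (5,),
    "cerebellum": (6,),
    "brainstem": (7,),
    "basal_ganglia": (8, 9),
}

# cohort marginals of a 450-patient biopsy series: region and histology mix
DEFAULT_REGION_PROBS = {
    "frontal": 0.28,
    "parietal": 0.14,
    "temporal": 0.14,
    "occipital": 0.02,
    "insular": 0.05,
    "cerebellum": 0.09,
    "brainstem": 0.03,
    "basal_ganglia": 0.25,
}
DEFAULT_HISTOLOGY_PROBS = {
    "HGG": 0.476,
    "LGG": 0.193,
    "metastasis": 0.040,
    "lymphoma": 0.138,
    "inflammation": 0.100,
    "abscess": 0.018,
    "other": 0.026,
    "inconclusive": 0.009,
}

_BRAIN_AXES = np.array([55.0, 62.0, 50.0])  # mm semi-axes of the head surrogate


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; the defaults encode the emulated cohort.

    ``baseline_logit=None`` means: calibrate the intercept numerically so the
    marginal hemorrhage rate equals ``target_bbh_rate`` under the covariate
    distribution implied by the other fields.
    """

    n_patients: int = 450
    seed: int = 0
    age_mean: float = 58.3
    age_sd: float = 19.2
    histology_probs: dict = field(default_factory=lambda: dict(DEFAULT_HISTOLOGY_PROBS))
    region_probs: dict = field(default_factory=lambda: dict(DEFAULT_REGION_PROBS))
    beta_age: float = 0.022
    beta_bg: float = 0.749
    beta_hgg: float = 0.45
    baseline_logit: float | None = None
    target_bbh_rate: float = 0.18
    volume_lognormal_params: tuple[float, float] = (-0.60, 1.20)
    min_volume_ml: float = 0.5
    symptom_volume_threshold: float = 5.0
    eloquent_labels: tuple[int, ...] = (ATLAS_LABELS["basal_ganglia_posterior"],)
    p_female: float = 210 / 450
    p_robot: float = 230 / 450
    location_probs: tuple[float, float, float] = (51 / 80, 10 / 80, 19 / 80)
    couple_hgg_deep: bool = False  # stress-test flag: make HGG prefer deep targets

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, probs in (("histology_probs", self.histology_probs),
                            ("region_probs", self.region_probs)):
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{name} must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {vals.sum():.12f})")
        if not 0 <= self.target_bbh_rate <= 1:
            raise ValueError("target_bbh_rate must lie in [0, 1]")
        if abs(sum(self.location_probs) - 1.0) > 1e-9:
            raise ValueError("location_probs must sum to 1")


@dataclass
class PatientRecord:
    """One subject: covariates, trajectory endpoints, hemorrhage outcomes."""

    patient_id: str
    age: float
    sex: str
    system: str
    histology: str
    entry_mm: tuple[float, float, float]
    target_mm: tuple[float, float, float]
    target_label: str
    bbh: bool
    bbh_volume_ml: float
    bbh_location: str
    symptomatic: bool
    sensorimotor_deficit: bool
    reduced_vigilance: bool
    aphasia: bool
    revision: bool
    persistent_deficit: bool

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not self.bbh:
            if self.bbh_volume_ml != 0 or self.symptomatic or self.bbh_location != "none":
                raise ValueError(
                    "bbh=False requires zero volume, no symptoms, location 'none'"
                )
        if self.symptomatic and not self.bbh:
            raise ValueError("symptomatic requires bbh")

    @property
    def trajectory(self) -> TrajectorySpec:
        return TrajectorySpec(self.entry_mm, self.target_mm)


# ---------------------------------------------------------------------------
# template and atlas


def _centre_affine(shape, voxel_size_mm: float) -> np.ndarray:
    """Affine with isotropic spacing and world origin at the grid centre."""
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size_mm
    return aff


def generate_template(
    shape: tuple[int, int, int] = (64, 64, 64), voxel_size_mm: float = 2.0
) -> tuple[VolumeGrid, VolumeGrid]:
    """Synthetic brain-like template plus an integer atlas, symmetric in x.

    The x extent must be even so voxel centres pair off symmetrically about
    the world plane x=0 (no voxel centre sits exactly on the midline) and a
    hemispheric flip is an exact array reversal.
    """
    shape = tuple(int(s) for s in shape)
    if shape[0] % 2 != 0:
        raise ValueError(
            "x extent must be even: the grid has to be mirror-symmetric about "
            "the midsagittal plane x=0"
        )
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be > 0")
    aff = _centre_affine(shape, voxel_size_mm)
    grid = VolumeGrid(np.zeros(shape, dtype=np.int16), aff)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    w = grid.voxel_to_world(idx.reshape(-1, 3)).reshape(shape + (3,))
    x, y, z = w[..., 0], w[..., 1], w[..., 2]
    ax, ay, az = _BRAIN_AXES
    r2 = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2
    brain = r2 <= 1.0

    atlas = np.zeros(shape, dtype=np.int16)
    # deep structures first, cortex fills the rest
    bstem = brain & (np.abs(x) < 12) & (np.abs(y + 8) < 16) & (z < -18)
    cereb = brain & (y < -22) & (z < -12) & ~bstem
    bg = (
        ((np.abs(x) - 18) / 13) ** 2 + (y / 22) ** 2 + ((z - 2) / 14) ** 2 <= 1.0
    ) & brain & ~bstem & ~cereb
    bg_post = bg & (y < 0)
    insula = (
        brain & ~bg & ~bstem & ~cereb
        & (np.abs(x) >= 32) & (np.abs(x) <= 42) & (np.abs(y) < 24) & (np.abs(z - 2) < 16)
    )
    cortex = brain & ~bg & ~bstem & ~cereb & ~insula
    frontal = cortex & (y >= 16)
    occipital = cortex & (y <= -38)
    parietal = cortex & (y < 16) & (y > -38) & (z >= 16)
    temporal = cortex & (y < 16) & (y > -38) & (z < 16) & (np.abs(x) >= 22)

    atlas[frontal] = ATLAS_LABELS["frontal"]
    atlas[parietal] = ATLAS_LABELS["parietal"]
    atlas[temporal] = ATLAS_LABELS["temporal"]
    atlas[occipital] = ATLAS_LABELS["occipital"]
    atlas[insula] = ATLAS_LABELS["insular"]
    atlas[cereb] = ATLAS_LABELS["cerebellum"]
    atlas[bstem] = ATLAS_LABELS["brainstem"]
    atlas[bg & ~bg_post] = ATLAS_LABELS["basal_ganglia_anterior"]
    atlas[bg_post] = ATLAS_LABELS["basal_ganglia_posterior"]

    # smooth, symmetric T1-like intensity: bright brain, darker deep nuclei
    template = np.where(brain, 100.0 * (1.0 - 0.5 * r2), 0.0)
    template[bg] *= 0.85
    template = template.astype(np.float32)

    return (
        VolumeGrid(template, aff, "template"),
        VolumeGrid(atlas, aff, "template"),
    )


# ---------------------------------------------------------------------------
# cohort


# burr-hole zones on the scalp surrogate, as directions from the head centre:
# a precoronal site serving the frontal corridor (frontal lobe, basal ganglia,
# insula), a parietal-boss site for the parietal/temporal/occipital corridor,
# and a paramedian suboccipital site for the transcerebellar corridor
_ENTRY_ZONES = {
    "frontal": np.array([0.35, 0.62, 0.70]),
    "parietal": np.array([0.45, -0.35, 0.82]),
    "cerebellar": np.array([0.30, -0.85, -0.42]),
}
_CORRIDOR_OF_REGION = {
    "frontal": "frontal",
    "basal_ganglia": "frontal",
    "insular": "frontal",
    "parietal": "parietal",
    "temporal": "parietal",
    "occipital": "parietal",
    "cerebellum": "cerebellar",
    "brainstem": "cerebellar",
}
_SCALP_SCALE = 1.02        # shell sits just outside the brain surrogate
_CORTICAL_DEPTH_CAP = 0.85  # cortical targets stay parenchymal (not pial)


def _shell_point(direction: np.ndarray, scale: float = _SCALP_SCALE) -> np.ndarray:
    """Point on the scalp-surrogate ellipsoid along a direction from centre."""
    d = direction / np.linalg.norm(direction)
    t = 1.0 / np.linalg.norm(d / (_BRAIN_AXES * scale))
    return t * d


def _entry_point(region: str, target: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Entry on the scalp shell: the corridor burr-hole zone, jittered,
    in the target's hemisphere."""
    sign = 1.0 if target[0] >= 0 else -1.0
    zone = _ENTRY_ZONES[_CORRIDOR_OF_REGION[region]].copy()
    zone[0] *= sign
    return _shell_point(zone + rng.normal(0, 0.08, 3))


def _expected_rate(b0: float, age: np.ndarray, bg: np.ndarray, hgg: np.ndarray,
                   spec: CohortSpec) -> float:
    logit = b0 + spec.beta_age * age + spec.beta_bg * bg + spec.beta_hgg * hgg
    return float(np.mean(1.0 / (1.0 + np.exp(-logit))))


def calibrate_baseline_logit(spec: CohortSpec, n_mc: int = 200_000) -> float:
    """Intercept giving the requested marginal hemorrhage rate.

    Solved by bisection against a large fixed-seed Monte-Carlo draw of the
    covariates, so the result is a deterministic function of the spec alone.
    """
    rng = np.random.default_rng(961_748_927)
    age = _draw_ages(spec, rng, n_mc)
    bg = (rng.random(n_mc) < spec.region_probs.get("basal_ganglia", 0.0)).astype(float)
    hgg = (rng.random(n_mc) < spec.histology_probs.get("HGG", 0.0)).astype(float)
    lo, hi = -30.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _expected_rate(mid, age, bg, hgg, spec) < spec.target_bbh_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_ages(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    bad = (age < 1) | (age > 100)
    while bad.any():
        age[bad] = rng.normal(spec.age_mean, spec.age_sd, int(bad.sum()))
        bad = (age < 1) | (age > 100)
    return age


def _draw_volumes(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Lognormal hemorrhage volumes truncated below the significance cutoff."""
    mu, sigma = spec.volume_lognormal_params
    v = rng.lognormal(mu, sigma, n)
    bad = v < spec.min_volume_ml
    while bad.any():
        v[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
        bad = v < spec.min_volume_ml
    return v


def generate_cohort(spec: CohortSpec, atlas: VolumeGrid) -> list[PatientRecord]:
    """Draw a full synthetic cohort on the given atlas.

    Raises if a region in ``region_probs`` has no voxels in the atlas.
    """
    rng = np.random.default_rng(spec.seed)
    idx = np.indices(atlas.shape).reshape(3, -1).T
    world = atlas.voxel_to_world(idx)
    depth_r2 = ((world / _BRAIN_AXES) ** 2).sum(axis=1).reshape(atlas.shape)
    label_voxels: dict[str, np.ndarray] = {}
    for region in spec.region_probs:
        if region not in REGION_LABELS:
            raise ValueError(f"unknown target region '{region}'")
        sel = np.isin(atlas.data, REGION_LABELS[region])
        if region in ("frontal", "parietal", "temporal", "occipital"):
            sel &= depth_r2 <= _CORTICAL_DEPTH_CAP
        vox = np.argwhere(sel)
        if vox.size == 0:
            raise ValueError(f"atlas contains no voxels for region '{region}'")
        label_voxels[region] = vox

    b0 = spec.baseline_logit
    if b0 is None:
        b0 = calibrate_baseline_logit(spec)

    regions = list(spec.region_probs)
    region_p = np.array([spec.region_probs[r] for r in regions])
    hists = list(spec.histology_probs)
    hist_p = np.array([spec.histology_probs[h] for h in hists])
    locations = ("intralesional", "extralesional", "both")
    voxel_size = float(np.linalg.norm(atlas.affine[:3, 0]))

    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        # two decimals keep the CSV round-trip lossless
        age = round(float(_draw_ages(spec, rng, 1)[0]), 2)
        sex = "f" if rng.random() < spec.p_female else "m"
        system = "robot" if rng.random() < spec.p_robot else "frame"
        histology = hists[rng.choice(len(hists), p=hist_p)]
        region = regions[rng.choice(len(regions), p=region_p)]
        if spec.couple_hgg_deep and histology == "HGG" and rng.random() < 0.5:
            region = "basal_ganglia"

        vox = label_voxels[region]
        v = vox[rng.integers(len(vox))]
        jitter = rng.uniform(-0.5, 0.5, 3)
        target = atlas.voxel_to_world(v + jitter)
        vox_label = int(atlas.data[tuple(v)])
        eloquent = vox_label in spec.eloquent_labels
        entry = _entry_point(region, target, rng)

        is_bg = float(region == "basal_ganglia")
        is_hgg = float(histology == "HGG")
        logit = b0 + spec.beta_age * age + spec.beta_bg * is_bg + spec.beta_hgg * is_hgg
        bbh = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))

        volume = 0.0
        location = "none"
        symptomatic = sensorimotor = vigilance = aphasia = revision = persistent = False
        if bbh:
            volume = float(_draw_volumes(spec, rng, 1)[0])
            location = locations[rng.choice(3, p=np.array(spec.location_probs))]
            eloquent_bleed = eloquent and location in ("intralesional", "both")
            symptomatic = volume > spec.symptom_volume_threshold or eloquent_bleed
            sensorimotor = symptomatic and eloquent_bleed
            vigilance = symptomatic and volume > 2 * spec.symptom_volume_threshold
            aphasia = symptomatic and region == "insular"
            revision = symptomatic and volume > 1.1 * spec.symptom_volume_threshold
            persistent = sensorimotor or revision

        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                age=age,
                sex=sex,
                system=system,
                histology=histology,
                entry_mm=tuple(np.round(entry, 3)),
                target_mm=tuple(np.round(target, 3)),
                target_label=region,
                bbh=bbh,
                bbh_volume_ml=round(volume, 4),
                bbh_location=location,
                symptomatic=symptomatic,
                sensorimotor_deficit=sensorimotor,
                reduced_vigilance=vigilance,
                aphasia=aphasia,
                revision=revision,
                persistent_deficit=persistent,
            )
        )
    return records


# ---------------------------------------------------------------------------
# hemorrhage masks


def _take_nearest(score: np.ndarray, candidates: np.ndarray, n: int) -> np.ndarray:
    order = np.argsort(score, kind="stable")
    return candidates[order[:n]]


def generate_hemorrhage_mask(
    record: PatientRecord, template: VolumeGrid, seed: int
) -> VolumeGrid:
    """Binary hemorrhage mask matching the record's volume and location class.

    Intralesional content is an ellipsoidal blob centred on the target;
    extralesional content hugs the trajectory just proximal to the target.
    The voxel count is matched exactly to round(volume / voxel volume), so the
    mask volume agrees with ``bbh_volume_ml`` within one voxel volume.
    """
    if not record.bbh:
        raise ValueError("record has no hemorrhage (bbh=False): no mask to generate")
    rng = np.random.default_rng(seed)
    vox_ml = template.voxel_volume_mm3 / 1000.0
    n_total = max(int(round(record.bbh_volume_ml / vox_ml)), 1)

    target = np.asarray(record.target_mm, float)
    entry = np.asarray(record.entry_mm, float)
    axis = (target - entry) / np.linalg.norm(target - entry)
    length = float(np.linalg.norm(target - entry))

    # candidate voxels near the distal trajectory
    reach_mm = max(2.0 * (n_total * template.voxel_volume_mm3) ** (1 / 3), 15.0)
    lo_w = np.minimum(target, target - axis * 0.35 * length) - reach_mm
    hi_w = np.maximum(target, target - axis * 0.35 * length) + reach_mm
    lo = np.maximum(np.floor(template.world_to_voxel(lo_w)).astype(int), 0)
    hi = np.minimum(
        np.ceil(template.world_to_voxel(hi_w)).astype(int) + 1, np.array(template.shape)
    )
    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    cand = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    centres = template.voxel_to_world(cand)

    # mildly anisotropic ellipsoidal metric around the target (intralesional)
    axes = 1.0 + rng.uniform(-0.25, 0.25, 3)
    d_intra = np.linalg.norm((centres - target) / axes, axis=1)
    # extralesional: along-axis band proximal to the target
    rel = centres - target
    ax_mm = rel @ axis  # 0 at target, negative towards entry
    radial = np.linalg.norm(rel - np.outer(ax_mm, axis), axis=1)
    d_extra = np.sqrt((0.35 * (ax_mm + 0.18 * length)) ** 2 + radial**2)

    out = np.zeros(template.shape, dtype=np.uint8)
    if record.bbh_location == "intralesional":
        chosen = _take_nearest(d_intra, cand, n_total)
    elif record.bbh_location == "extralesional":
        chosen = _take_nearest(d_extra, cand, n_total)
    else:  # both
        n1 = max(int(round(0.7 * n_total)), 1)
        first = _take_nearest(d_intra, cand, n1)
        out[tuple(first.T)] = 1
        rest = np.flatnonzero(out[tuple(cand.T)] == 0)
        second = _take_nearest(d_extra[rest], cand[rest], n_total - n1)
        chosen = np.vstack([first, second]) if len(second) else first
    out[tuple(chosen.T)] = 1
    return VolumeGrid(out, template.affine, template.space_tag)


# ---------------------------------------------------------------------------
# IO

_COORD_COLS = [f"{p}_{c}" for p in ("entry", "target") for c in "xyz"]


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records to a table; coordinates become three columns each.

    Adds derived ``trajectory_length_mm`` and ``target_region`` columns used
    by the summary statistics.
    """
    rows = []
    for r in records:
        d = asdict(r)
        entry = d.pop("entry_mm")
        target = d.pop("target_mm")
        for c, v in zip(_COORD_COLS, list(entry) + list(target)):
            d[c] = v
        d["trajectory_length_mm"] = trajectory_length_mm(r.trajectory)
        d["target_region"] = r.target_label
        rows.append(d)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                system=str(row["system"]),
                histology=str(row["histology"]),
                entry_mm=tuple(float(row[f"entry_{c}"]) for c in "xyz"),
                target_mm=tuple(float(row[f"target_{c}"]) for c in "xyz"),
                target_label=str(row["target_label"]),
                bbh=bool(row["bbh"]),
                bbh_volume_ml=float(row["bbh_volume_ml"]),
                bbh_location=str(row["bbh_location"]),
                symptomatic=bool(row["symptomatic"]),
                sensorimotor_deficit=bool(row["sensorimotor_deficit"]),
                reduced_vigilance=bool(row["reduced_vigilance"]),
                aphasia=bool(row["aphasia"]),
                revision=bool(row["revision"]),
                persistent_deficit=bool(row["persistent_deficit"]),
            )
        )
    return records


def spec_to_yaml(spec: CohortSpec, path) -> None:
    d = asdict(spec)
    d["volume_lognormal_params"] = list(spec.volume_lognormal_params)
    d["eloquent_labels"] = list(spec.eloquent_labels)
    d["location_probs"] = list(spec.location_probs)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("volume_lognormal_params", "eloquent_labels", "location_probs"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return CohortSpec(**d)
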