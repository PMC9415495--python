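"""Synthetic multi-reader delineation studies.

No patient images ship with this package, so validation runs on generated
studies that reproduce the statistical structure the analysis assumes:

* a 3D brain-like phantom — an ellipsoidal "brain" of uniform tracer
  uptake, an ellipsoidal tumor at a configurable true tumor-to-brain
  ratio, optional hot "physiological" distractors near the volume
  boundary (scalp/vessel stand-ins), Gaussian point-spread blurring and
  additive Gaussian noise;
* per-sequence truth masks derived deterministically from the tumor
  geometry (contrast-enhancing core, edema-expanded FLAIR extent, eroded
  functional-map subregions);
* an observer model that perturbs a truth mask with a smooth random
  boundary-displacement field (amplitude = the per-sequence severity, in
  mm) plus a per-reader systematic over/under-contouring bias, and may
  decline to delineate with a per-sequence probability.

Severity is the single dial controlling expected Dice: 0 mm reproduces
the truth exactly and agreement falls monotonically as severity grows.
Default severities are calibrated so the generated study reproduces the
qualitative ordering seen in clinical multi-sequence delineation studies
(PET and contrast T1 most reproducible, FLAIR close behind, perfusion and
diffusion maps far less, ADC worst). All randomness is split per
(patient, sequence, reader), so enlarging the study never perturbs
existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io_masks import BinaryMask, ImageVolume, ManifestEntry, StudyManifest, SEQUENCES
from .pet_segmentation import N_BACKGROUND_ROIS


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic patient phantom.

    Geometry is in world mm on a grid of ``shape`` voxels at ``spacing``;
    the default 96^3 grid at 2 mm spacing covers a 192 mm cube, enough for
    an adult head. ``true_tbr`` is the tumor-to-background uptake ratio
    before blurring; 2.0 is a typical avid high-grade lesion. Noise is
    i.i.d. Gaussian with standard deviation ``noise_sigma`` times the
    background uptake, and ``psf_fwhm_mm`` emulates scanner resolution
    (6 mm FWHM is typical of a clinical PET reconstruction).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semi_axes_mm: tuple[float, float, float] = (70.0, 85.0, 65.0)
    tumor_center_mm: tuple[float, float, float] = (35.0, 10.0, 5.0)
    tumor_semi_axes_mm: tuple[float, float, float] = (14.0, 12.0, 11.0)
    background_uptake: float = 1.0
    true_tbr: float = 2.0
    noise_sigma: float = 0.05
    psf_fwhm_mm: float = 6.0
    edema_margin_mm: float = 8.0
    #: (center_mm, radius_mm, uptake multiple of background) hot spots
    distractors: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_tbr <= 0:
            raise ValueError("true_tbr must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


#: How much each functional sequence's truth is eroded (+) or the FLAIR
#: truth dilated relative to the tumor core, in mm. The morphological
#: sequences see the full lesion; functional maps highlight subregions.
_TRUTH_OFFSETS_MM: Mapping[str, float] = {
    "T1-GD": 0.0,
    "FET-PET": 0.0,
    "T2-FLAIR": None,  # special: dilated by edema_margin_mm
    "rCBV": -2.0,
    "K2": -3.0,
    "DWI_b1000": -2.0,
    "ADC": -4.0,
}


def _centered_affine(shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
    """Affine placing the world origin at the grid centre, axes along ijk."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = [-(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    return affine


def _world_grid(shape: Sequence[int], spacing: Sequence[float]) -> tuple[np.ndarray, ...]:
    affine = _centered_affine(shape, spacing)
    axes = [affine[i, i] * np.arange(shape[i]) + affine[i, 3] for i in range(3)]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _ellipsoid(shape, spacing, center, semi_axes) -> np.ndarray:
    X, Y, Z = _world_grid(shape, spacing)
    return (
        ((X - center[0]) / semi_axes[0]) ** 2
        + ((Y - center[1]) / semi_axes[1]) ** 2
        + ((Z - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def _offset_mask(core: np.ndarray, spacing, offset_mm: float) -> np.ndarray:
    """Dilate (offset > 0) or erode (offset < 0) by a metric distance."""
    if offset_mm == 0.0:
        return core.copy()
    if offset_mm > 0:
        dist = ndimage.distance_transform_edt(~core, sampling=spacing)
        return dist <= offset_mm
    dist = ndimage.distance_transform_edt(core, sampling=spacing)
    return dist > -offset_mm


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, dict[str, BinaryMask], np.ndarray]:
    """Build one patient phantom.

    Returns the PET volume, the per-sequence truth masks, and the six
    background-ROI centres (world mm), placed in the hemisphere opposite
    the tumor along a crescent-like arc in normal brain.
    """
    shape, spacing = spec.shape, spec.spacing
    affine = _centered_affine(shape, spacing)

    brain = _ellipsoid(shape, spacing, (0.0, 0.0, 0.0), spec.brain_semi_axes_mm)
    tumor = _ellipsoid(shape, spacing, spec.tumor_center_mm, spec.tumor_semi_axes_mm)
    if not tumor.any():
        raise ValueError("tumor rasterized to zero voxels")
    if (tumor & ~brain).any():
        raise ValueError("tumor extends outside the brain ellipsoid")

    activity = np.zeros(shape, dtype=float)
    activity[brain] = spec.background_uptake
    activity[tumor] = spec.background_uptake * spec.true_tbr
    for center, radius, mult in spec.distractors:
        ball = _ellipsoid(shape, spacing, center, (radius, radius, radius))
        activity[ball] = spec.background_uptake * mult

    if spec.psf_fwhm_mm > 0:
        sigma_mm = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        activity = ndimage.gaussian_filter(
            activity, sigma=[sigma_mm / s for s in spacing]
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xF0)))
        activity = activity + rng.normal(
            0.0, spec.noise_sigma * spec.background_uptake, size=shape
        )

    pet = ImageVolume(data=activity, spacing=spacing, affine=affine,
                      modality_label="FET-PET")

    truths: dict[str, BinaryMask] = {}
    for seq in SEQUENCES:
        offset = _TRUTH_OFFSETS_MM[seq]
        if offset is None:
            data = _offset_mask(tumor, spacing, spec.edema_margin_mm) & brain
        else:
            data = _offset_mask(tumor, spacing, offset)
        truths[seq] = BinaryMask(data=data, grid=pet, label=("", seq, "truth"))

    centers = _background_centers(spec)
    return pet, truths, centers


def _background_centers(spec: PhantomSpec) -> np.ndarray:
    """Six ROI centres on an arc in the hemisphere opposite the tumor.

    The arc sits at 55% of the brain semi-axes (deep enough that 20-25 mm
    ROIs stay inside the brain) with the tumor's x-side mirrored away.
    """
    ax, ay, az = spec.brain_semi_axes_mm
    side = -1.0 if spec.tumor_center_mm[0] >= 0 else 1.0
    angles = np.linspace(-0.9, 0.9, N_BACKGROUND_ROIS)
    centers = np.stack(
        [
            side * 0.55 * ax * np.cos(angles),
            0.55 * ay * np.sin(angles),
            np.full(N_BACKGROUND_ROIS, 0.1 * az),
        ],
        axis=1,
    )
    return centers


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------

#: Default per-sequence boundary-perturbation severity in mm; chosen so
#: the generated study reproduces the ordering PET ~ T1-GD < T2-FLAIR
#: << rCBV ~ K2 ~ DWI << ADC in expected Dice.
DEFAULT_SEVERITY_MM: Mapping[str, float] = {
    "FET-PET": 2.0,
    "T1-GD": 2.2,
    "T2-FLAIR": 3.2,
    "rCBV": 6.5,
    "K2": 6.0,
    "DWI_b1000": 6.5,
    "ADC": 12.0,
}

#: Default probability that a reader declines to delineate the sequence
#: (exam failures and uninterpretable functional maps).
DEFAULT_MISSING_PROB: Mapping[str, float] = {
    "FET-PET": 0.02,
    "T1-GD": 0.0,
    "T2-FLAIR": 0.0,
    "rCBV": 0.06,
    "K2": 0.06,
    "DWI_b1000": 0.04,
    "ADC": 0.12,
}


@dataclass(frozen=True)
class ObserverModel:
    """Stochastic reader behaviour.

    ``severity_mm`` scales the smooth random boundary displacement per
    sequence; ``missing_prob`` is the per-(patient, sequence, reader)
    probability of a non-delineation; ``bias_sd_mm`` is the SD of each
    reader's systematic over/under-contouring margin; ``difficulty_sd``
    is the log-SD of a per-patient lognormal difficulty multiplier shared
    by all readers and sequences — ill-defined lesions are hard for
    everyone, which is what correlates reader pairs across patients. The
    difficulty draws are truncated at +/- 1.5 log-SD (an unbounded tail
    would let a single patient's severity dwarf the rest and dominate
    every outlier-sensitive volume statistic) and centred to geometric
    mean 1 within a study: difficulty is a relative patient effect, and
    the per-sequence severities alone set the study's absolute scale.
    """

    severity_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_MM)
    )
    missing_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_PROB)
    )
    bias_sd_mm: float = 0.5
    difficulty_sd: float = 0.6
    #: spatial correlation length of the boundary displacement field, mm.
    #: Shorter than the tumor radius: disagreement is wiggly contouring,
    #: not near-uniform inflation, so surface errors partly cancel in the
    #: delineated volume.
    field_scale_mm: float = 6.0

    def __post_init__(self) -> None:
        for s, v in self.severity_mm.items():
            if v < 0:
                raise ValueError(f"severity for {s} must be >= 0")
        for s, q in self.missing_prob.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"missing probability for {s} must be in [0,1]")


def _signed_distance(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask boundary, negative inside.

    ``sd <= 0`` holds exactly on the mask voxels, so thresholding the
    signed distance at 0 reproduces the mask bit-for-bit.
    """
    spacing = mask.grid.spacing
    inside = ndimage.distance_transform_edt(mask.data, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask.data, sampling=spacing)
    return outside - inside


def perturb_mask(
    truth: BinaryMask,
    severity_mm: float,
    bias_mm: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    field_scale_mm: float = 6.0,
    signed_distance: np.ndarray | None = None,
) -> BinaryMask:
    """Perturb a truth mask with a smooth random boundary displacement.

    The perturbed contour is the level set  sd(x) <= bias_mm + f(x), where
    sd is the signed Euclidean distance to the truth boundary (negative
    inside) and f is a Gaussian random field of unit variance smoothed at
    ``field_scale_mm`` and scaled by ``severity_mm``. severity 0 and bias 0
    reproduce the truth exactly; positive bias dilates, negative erodes.
    An empty result (erosion consumed the mask) is legal and maps to a
    missing record downstream. Only the connected components touching the
    truth are kept: a reader deforms the lesion boundary but does not
    delineate distant islands where the random field happens to peak.

    ``signed_distance`` may be supplied to amortize the distance transform
    when the same truth is perturbed for several readers.
    """
    if truth.is_empty:
        raise ValueError("truth mask is empty")
    spacing = truth.grid.spacing
    signed = _signed_distance(truth) if signed_distance is None else signed_distance

    displacement = bias_mm
    if severity_mm > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(truth.data.shape)
        sigma_vox = [field_scale_mm / s for s in spacing]
        fld = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        sd = fld.std()
        if sd > 0:
            fld = fld / sd
        displacement = bias_mm + severity_mm * fld

    data = signed <= displacement
    if data.any():
        labels, _ = ndimage.label(data, structure=np.ones((3, 3, 3), dtype=int))
        keep = np.unique(labels[truth.data])
        keep = keep[keep > 0]
        data = np.isin(labels, keep) if keep.size else np.zeros_like(data)
    return BinaryMask(data=data, grid=truth.grid, label=truth.label)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    manifest: StudyManifest
    masks: dict[tuple[str, str, str], BinaryMask | None]
    pet_volumes: dict[str, ImageVolume]
    truths: dict[tuple[str, str], BinaryMask]
    background_centers: dict[str, np.ndarray]


def _patient_spec(template: PhantomSpec, patient_index: int, seed: int) -> PhantomSpec:
    """Jitter tumor size and position around the template, reproducibly."""
    rng = np.random.default_rng(
        np.random.SeedSequence((seed, 0xA0, patient_index))
    )
    semi = np.array(template.tumor_semi_axes_mm) * rng.uniform(0.6, 1.5, size=3)
    ax, ay, az = template.brain_semi_axes_mm
    center = np.array(
        [
            rng.uniform(0.30, 0.55) * ax * rng.choice([-1.0, 1.0]),
            rng.uniform(-0.35, 0.35) * ay,
            rng.uniform(-0.25, 0.25) * az,
        ]
    )
    # shrink until the tumor surely sits inside the brain ellipsoid
    for _ in range(20):
        corner = np.abs(center) + semi
        if (corner[0] / ax) ** 2 + (corner[1] / ay) ** 2 + (corner[2] / az) ** 2 <= 1.0:
            break
        semi *= 0.9
    return replace(
        template,
        tumor_center_mm=tuple(center),
        tumor_semi_axes_mm=tuple(semi),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_study(
    n_patients: int = 30,
    n_readers: int = 3,
    observer: ObserverModel | None = None,
    template: PhantomSpec | None = None,
    seed: int = 0,
    sequences: Sequence[str] = SEQUENCES,
) -> SyntheticStudy:
    """Simulate a complete multi-reader delineation study.

    Per patient: a randomized phantom (tumor size/position jittered around
    the template), then per (sequence, reader) a perturbed mask drawn from
    the observer model, or a missing record with the sequence's
    non-delineation probability. Fully reproducible from ``seed``; random
    streams are split per (patient, sequence, reader).
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    observer = observer or ObserverModel()
    template = template or PhantomSpec()

    readers = [f"r{i + 1}" for i in range(n_readers)]
    entries: list[ManifestEntry] = []
    masks: dict[tuple[str, str, str], BinaryMask | None] = {}
    pets: dict[str, ImageVolume] = {}
    truths: dict[tuple[str, str], BinaryMask] = {}
    bg_centers: dict[str, np.ndarray] = {}

    bias_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB1)))
    reader_bias = {r: float(bias_rng.normal(0.0, observer.bias_sd_mm))
                   for r in readers}

    # truncated, then centred to geometric mean 1 over the study
    sd = observer.difficulty_sd
    log_diff = np.array(
        [
            np.clip(
                np.random.default_rng(
                    np.random.SeedSequence((seed, 0xD1, p))
                ).normal(0.0, sd),
                -1.5 * sd,
                1.5 * sd,
            )
            for p in range(n_patients)
        ]
    )
    difficulties = np.exp(log_diff - log_diff.mean())

    for p_idx in range(n_patients):
        patient = f"p{p_idx + 1:02d}"
        spec = _patient_spec(template, p_idx, seed)
        pet, truth_masks, centers = make_phantom(spec)
        pets[patient] = pet
        bg_centers[patient] = centers
        difficulty = float(difficulties[p_idx])

        for s_idx, seq in enumerate(sequences):
            truth = truth_masks[seq]
            truths[(patient, seq)] = truth
            signed = _signed_distance(truth) if not truth.is_empty else None
            for r_idx, reader in enumerate(readers):
                key = (patient, seq, reader)
                ss = np.random.SeedSequence((seed, 0xC2, p_idx, s_idx, r_idx))
                rng = np.random.default_rng(ss)
                q = observer.missing_prob.get(seq, 0.0)
                if truth.is_empty or rng.random() < q:
                    masks[key] = None
                    entries.append(ManifestEntry(patient, seq, reader, ""))
                    continue
                severity = observer.severity_mm.get(seq, 0.0) * difficulty
                mask = perturb_mask(
                    truth,
                    severity_mm=severity,
                    bias_mm=reader_bias[reader],
                    seed=ss.spawn(1)[0],
                    field_scale_mm=observer.field_scale_mm,
                    signed_distance=signed,
                )
                if mask.is_empty:
                    masks[key] = None
                    entries.append(ManifestEntry(patient, seq, reader, ""))
                    continue
                masks[key] = mask
                entries.append(
                    ManifestEntry(patient, seq, reader,
                                  f"{patient}_{seq}_{reader}.nii.gz")
                )

    manifest = StudyManifest(entries=entries)
    return SyntheticStudy(
        manifest=manifest,
        masks=masks,
        pet_volumes=pets,
        truths=truths,
        background_centers=bg_centers,
    )


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Materialize a simulated study on disk (NIfTI masks + manifest.csv)."""
    from pathlib import Path

    from .io_masks import write_manifest, write_mask, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for patient, pet in study.pet_volumes.items():
        write_volume(pet, out / f"{patient}_FET-PET_activity.nii.gz")
        np.savetxt(
            out / f"{patient}_background_centers.csv",
            study.background_centers[patient],
            delimiter=",",
            header="x_mm,y_mm,z_mm",
            comments="",
        )
    for e in study.manifest.entries:
        if not e.path:
            continue
        mask = study.masks[(e.patient_id, e.sequence, e.reader)]
        write_mask(mask, out / e.path)
    write_manifest(study.manifest, out / "manifest.csv")
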