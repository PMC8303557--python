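"""Synthetic sacroiliac-joint phantom generator.

Real gadolinium-enhanced SIJ MR data of the kind this pipeline targets is not
publicly available, so this module renders simplified slice stacks that keep
the properties the downstream stages depend on:

* two bright lateral bone regions (ilium) flanking a central bright structure
  (sacrum), separated by dark joint lines;
* per-slice bounding-box annotations of the left and right iliac bones;
* hyperintense bone-marrow-edema-like lesions placed at the joint line in
  positive subjects, arranged so the subject satisfies the ASAS positivity
  rule (>=2 lesions on one slice, or lesions on >=2 consecutive slices);
* slice stacks ordered lower -> upper pelvis with smooth slice-to-slice
  anatomy and lesion drift (<=2 px between adjacent slices);
* optional Rician-like acquisition noise.

Slice counts default to 4-23 per positive subject and 18-25 per control,
matching the clinical cohort the pipeline emulates.  Intensities live in
[0, 1]; 8-bit quantization happens only at PNG export.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .postprocess import asas_label

POSITIVE = "positive"
NEGATIVE = "negative"
SUBJECT_POSITIVE = "active sacroiliitis"
SUBJECT_NEGATIVE = "normal"


@dataclasses.dataclass(frozen=True)
class Box:
    """Axis-aligned box, 0-based half-open: rows [r0, r1), cols [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self):
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError(f"degenerate box {self}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def center_col(self) -> int:
        return (self.c0 + self.c1) // 2

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.r0, self.r1, self.c0, self.c1)


@dataclasses.dataclass(frozen=True)
class PhantomParams:
    """Knobs of the synthetic cohort.

    ``lesion_contrast`` is the relative intensity uplift of lesion over bone
    (lesion = bone * (1 + contrast)).  ``noise_sigma`` is the scale of the
    Rician-like acquisition noise added at render time (set 0 to disable).
    """

    image_size: tuple[int, int] = (96, 96)
    n_slices_range_pos: tuple[int, int] = (4, 23)
    n_slices_range_neg: tuple[int, int] = (18, 25)
    lesion_contrast: float = 0.5
    lesion_radius_range: tuple[int, int] = (2, 4)
    bone_intensity: float = 0.55
    background_intensity: float = 0.08
    noise_sigma: float = 0.015
    seed: int = 0

    def __post_init__(self):
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least 64x64")
        for lo, hi in (self.n_slices_range_pos, self.n_slices_range_neg, self.lesion_radius_range):
            if hi < lo or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be > 0")
        if not (0 <= self.background_intensity < self.bone_intensity <= 1):
            raise ValueError("need 0 <= background < bone intensity <= 1")


@dataclasses.dataclass
class SliceRecord:
    image: np.ndarray
    subject_id: str
    slice_index: int
    left_box: Box
    right_box: Box
    lesion_masks: list[np.ndarray]
    slice_label: str

    @property
    def lesion_count(self) -> int:
        return len(self.lesion_masks)


@dataclasses.dataclass
class SubjectExam:
    subject_id: str
    slices: list[SliceRecord]
    subject_label: str

    @property
    def lesion_counts(self) -> list[int]:
        return [s.lesion_count for s in self.slices]

    def __post_init__(self):
        idx = [s.slice_index for s in self.slices]
        if idx != sorted(set(idx)):
            raise ValueError("slice_index must be strictly increasing")


def _ellipse_mask(shape, center, semi_axes):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    ar, ac = semi_axes
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _render_slice(params: PhantomParams, geom: dict, lesions: list[tuple[tuple[int, int], int]], rng):
    """Render one slice; returns (image, left_box, right_box, lesion_masks)."""
    h, w = params.image_size
    img = np.full((h, w), params.background_intensity)

    sac = _ellipse_mask((h, w), geom["sacrum_center"], geom["sacrum_axes"])
    img[sac] = params.bone_intensity * 0.92

    boxes = []
    for side in ("left", "right"):
        center = geom[f"{side}_center"]
        axes = geom[f"{side}_axes"]
        il = _ellipse_mask((h, w), center, axes)
        img[il] = params.bone_intensity
        r0 = max(int(np.floor(center[0] - axes[0])), 0)
        r1 = min(int(np.ceil(center[0] + axes[0])) + 1, h)
        c0 = max(int(np.floor(center[1] - axes[1])), 0)
        c1 = min(int(np.ceil(center[1] + axes[1])) + 1, w)
        boxes.append(Box(r0, r1, c0, c1))

    masks = []
    lesion_val = min(params.bone_intensity * (1.0 + params.lesion_contrast), 1.0)
    for center, radius in lesions:
        m = _disk_mask((h, w), center, radius)
        img[m] = lesion_val
        masks.append(m)

    if params.noise_sigma > 0:
        # Rician-like magnitude noise: sqrt((x + n1)^2 + n2^2)
        n1 = rng.normal(0.0, params.noise_sigma, size=img.shape)
        n2 = rng.normal(0.0, params.noise_sigma, size=img.shape)
        img = np.sqrt((img + n1) ** 2 + n2**2)

    return np.clip(img, 0.0, 1.0), boxes[0], boxes[1], masks


def _subject_geometry(params: PhantomParams, n_slices: int, rng):
    """Smoothly varying per-slice ellipse geometry for one subject."""
    h, w = params.image_size
    cr = h / 2 + rng.integers(-3, 4)
    cc = w / 2 + rng.integers(-2, 3)
    lat = 0.27 * w + rng.integers(-2, 3)  # lateral offset of iliac centers
    geoms = []
    for i in range(n_slices):
        # anatomy tapers toward the ends of the stack
        t = np.sin(np.pi * (i + 1) / (n_slices + 1))
        scale = 0.75 + 0.25 * t
        geoms.append(
            {
                "sacrum_center": (cr, cc),
                "sacrum_axes": (0.28 * h * scale, 0.125 * w * scale),
                "left_center": (cr, cc - lat),
                "left_axes": (0.23 * h * scale, 0.10 * w),
                "right_center": (cr, cc + lat),
                "right_axes": (0.23 * h * scale, 0.10 * w),
            }
        )
    return geoms


def _plan_lesions(params: PhantomParams, geoms: list[dict], n_slices: int, rng):
    """Choose lesioned slices and lesion positions satisfying the ASAS rule.

    Always places a run of >=2 consecutive lesioned slices (when the stack
    allows it); some subjects additionally get a slice with two lesions.
    """
    plans: list[list[tuple[tuple[int, int], int]]] = [[] for _ in range(n_slices)]
    run_len = int(rng.integers(2, min(5, n_slices) + 1)) if n_slices >= 2 else 1
    start = int(rng.integers(0, n_slices - run_len + 1))
    side = "left" if rng.random() < 0.5 else "right"
    radius = int(rng.integers(params.lesion_radius_range[0], params.lesion_radius_range[1] + 1))

    g0 = geoms[start]
    center_r = g0[f"{side}_center"][0] + int(rng.integers(-8, 9))
    # medial edge of the iliac ellipse, i.e. at the joint line
    sign = 1 if side == "left" else -1
    center_c = g0[f"{side}_center"][1] + sign * (g0[f"{side}_axes"][1] - 1)
    center = (int(center_r), int(center_c))

    for k in range(run_len):
        i = start + k
        plans[i].append((center, radius))
        # drift <= 2 px between adjacent slices
        center = (
            int(center[0] + rng.integers(-2, 3)),
            int(center[1] + rng.integers(-1, 2)),
        )
    # occasionally a second lesion on one slice (also satisfies the
    # ">=2 lesions on one slice" clause on its own)
    if rng.random() < 0.5:
        i = start + int(rng.integers(0, run_len))
        g = geoms[i]
        other = "right" if side == "left" else "left"
        sign = 1 if other == "left" else -1
        c2 = (
            int(g[f"{other}_center"][0] + rng.integers(-8, 9)),
            int(g[f"{other}_center"][1] + sign * (g[f"{other}_axes"][1] - 1)),
        )
        plans[i].append((c2, int(rng.integers(*params.lesion_radius_range))))
    return plans


def generate_subject(params: PhantomParams, positive: bool, seed: int) -> SubjectExam:
    """Generate one subject exam; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    lo, hi = params.n_slices_range_pos if positive else params.n_slices_range_neg
    n_slices = int(rng.integers(lo, hi + 1))
    geoms = _subject_geometry(params, n_slices, rng)
    plans = (
        _plan_lesions(params, geoms, n_slices, rng)
        if positive
        else [[] for _ in range(n_slices)]
    )

    subject_id = f"{'P' if positive else 'N'}{seed:06d}"
    slices = []
    for i in range(n_slices):
        img, lbox, rbox, masks = _render_slice(params, geoms[i], plans[i], rng)
        slices.append(
            SliceRecord(
                image=img,
                subject_id=subject_id,
                slice_index=i,
                left_box=lbox,
                right_box=rbox,
                lesion_masks=masks,
                slice_label=POSITIVE if masks else NEGATIVE,
            )
        )
    counts = [len(p) for p in plans]
    label = SUBJECT_POSITIVE if asas_label(counts) == POSITIVE else SUBJECT_NEGATIVE
    if positive and label != SUBJECT_POSITIVE:
        raise RuntimeError("positive phantom failed the ASAS rule (generator bug)")
    return SubjectExam(subject_id=subject_id, slices=slices, subject_label=label)


def generate_cohort(
    n_pos: int, n_neg: int, params: PhantomParams, seed: int | None = None
) -> tuple[list[SubjectExam], pd.DataFrame]:
    """Generate a cohort and its per-slice manifest."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("subject counts must be non-negative")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    exams = []
    for _ in range(n_pos):
        exams.append(generate_subject(params, True, int(rng.integers(0, 2**31 - 1))))
    for _ in range(n_neg):
        exams.append(generate_subject(params, False, int(rng.integers(0, 2**31 - 1))))
    return exams, build_manifest(exams)


def build_manifest(exams: list[SubjectExam]) -> pd.DataFrame:
    rows = []
    for exam in exams:
        for s in exam.slices:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "slice_index": s.slice_index,
                    "slice_label": s.slice_label,
                    "subject_label": exam.subject_label,
                    "n_lesions": s.lesion_count,
                    "left_r0": s.left_box.r0,
                    "left_r1": s.left_box.r1,
                    "left_c0": s.left_box.c0,
                    "left_c1": s.left_box.c1,
                    "right_r0": s.right_box.r0,
                    "right_r1": s.right_box.r1,
                    "right_c0": s.right_box.c0,
                    "right_c1": s.right_box.c1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk round-trip


def write_cohort(exams: list[SubjectExam], outdir: str | Path) -> Path:
    """Write slices as 8-bit grayscale PNG plus a CSV manifest and params JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(exams)
    paths = []
    for exam in exams:
        sdir = outdir / exam.subject_id
        sdir.mkdir(exist_ok=True)
        for s in exam.slices:
            p = sdir / f"slice_{s.slice_index:03d}.png"
            Image.fromarray(np.round(s.image * 255).astype(np.uint8), mode="L").save(p)
            paths.append(str(p.relative_to(outdir)))
            for j, m in enumerate(s.lesion_masks):
                mp = sdir / f"slice_{s.slice_index:03d}_lesion{j}.png"
                Image.fromarray((m * 255).astype(np.uint8), mode="L").save(mp)
    manifest = manifest.assign(image_path=paths)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"


def read_cohort(outdir: str | Path) -> tuple[list[SubjectExam], pd.DataFrame]:
    """Reload a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    exams = []
    for sid, g in manifest.groupby("subject_id", sort=False):
        slices = []
        for _, row in g.sort_values("slice_index").iterrows():
            img = np.asarray(Image.open(outdir / row["image_path"]), dtype=np.float64) / 255.0
            masks = []
            j = 0
            while True:
                mp = outdir / sid / f"slice_{row['slice_index']:03d}_lesion{j}.png"
                if not mp.exists():
                    break
                masks.append(np.asarray(Image.open(mp)) > 127)
                j += 1
            slices.append(
                SliceRecord(
                    image=img,
                    subject_id=sid,
                    slice_index=int(row["slice_index"]),
                    left_box=Box(row["left_r0"], row["left_r1"], row["left_c0"], row["left_c1"]),
                    right_box=Box(
                        row["right_r0"], row["right_r1"], row["right_c0"], row["right_c1"]
                    ),
                    lesion_masks=masks,
                    slice_label=row["slice_label"],
                )
            )
        exams.append(SubjectExam(sid, slices, g["subject_label"].iloc[0]))
    return exams, manifest


def export_nifti(exam: SubjectExam, path: str | Path) -> None:
    """Export one subject's stack as a NIfTI volume (slices along axis 2)."""
    import nibabel as nib

    vol = np.stack([s.image for s in exam.slices], axis=2)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), str(path))
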