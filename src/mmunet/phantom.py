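"""Synthetic multimodal brain-tumor phantoms.

The generator emulates exactly the statistical structure the network and
the evaluation protocol consume, without claiming MRI physics: four
co-registered single-channel images (T1, T1c, T2, FLAIR) over a common
grid, a label map with three nested tumor regions (enhancing core inside
a necrotic shell inside an edema shell, so ET <= TC <= WT holds by
construction), class- and modality-dependent mean intensities, and
additive Gaussian noise.  A surrounding elliptical "brain" of normal
tissue sits on a zero background, mirroring skull-stripped data.

Default contrasts make each region most conspicuous in a different
modality (the enhancing core in T1c, the whole edema extent in FLAIR),
mirroring the clinical reading; the values are free parameters of the
phantom, not physical claims.

Everything is reproducible bit-for-bit from the spec seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MODALITIES = ("t1", "t1ce", "t2", "flair")
TISSUES = ("background", "brain", "ncr", "edema", "enhancing")

# label codes used internally (the remapped {0,1,2,3} convention)
LABEL_BG, LABEL_NCR, LABEL_EDEMA, LABEL_ENH = 0, 1, 2, 3
_TISSUE_OF_LABEL = {LABEL_BG: "background", LABEL_NCR: "ncr", LABEL_EDEMA: "edema", LABEL_ENH: "enhancing"}

DEFAULT_CONTRAST: dict[tuple[str, str], float] = {
    ("t1", "background"): 0.0,
    ("t1", "brain"): 100.0,
    ("t1", "ncr"): 60.0,
    ("t1", "edema"): 80.0,
    ("t1", "enhancing"): 90.0,
    ("t1ce", "background"): 0.0,
    ("t1ce", "brain"): 100.0,
    ("t1ce", "ncr"): 50.0,
    ("t1ce", "edema"): 90.0,
    ("t1ce", "enhancing"): 200.0,
    ("t2", "background"): 0.0,
    ("t2", "brain"): 100.0,
    ("t2", "ncr"): 140.0,
    ("t2", "edema"): 160.0,
    ("t2", "enhancing"): 120.0,
    ("flair", "background"): 0.0,
    ("flair", "brain"): 100.0,
    ("flair", "ncr"): 120.0,
    ("flair", "edema"): 180.0,
    ("flair", "enhancing"): 130.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case."""

    image_size: int = 160
    tumor_center: tuple[float, float] | None = None  # defaults to the grid center
    # WT > TC > ET, pixels; None scales the (30, 18, 8)-at-160 defaults to image_size
    region_radii: tuple[float, float, float] | None = None
    axis_ratio: float = 1.0  # semi-minor/semi-major of the tumor ellipses
    brain_radius: float | None = None  # defaults to 0.42 * image_size
    contrast_table: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.region_radii is None:
            scale = self.image_size / 160.0
            object.__setattr__(
                self, "region_radii", (30.0 * scale, 18.0 * scale, 8.0 * scale)
            )
        wt, tc, et = self.region_radii
        if not (wt > tc > et >= 0):
            raise ValueError(
                f"region_radii must be strictly decreasing WT > TC > ET >= 0, got {self.region_radii}"
            )
        if wt >= self.image_size / 2:
            raise ValueError("whole-tumor radius must be smaller than image_size / 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16 (network requirement)")
        if not 0 < self.axis_ratio <= 1:
            raise ValueError("axis_ratio must lie in (0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return (self.image_size / 2.0, self.image_size / 2.0)

    @property
    def effective_brain_radius(self) -> float:
        return self.brain_radius if self.brain_radius is not None else 0.42 * self.image_size


@dataclass(frozen=True)
class PhantomCase:
    """One generated case: a four-modality stack and its label map."""

    case_id: str
    images: np.ndarray  # (4, H, W) float32, modality order MODALITIES
    labels: np.ndarray  # (H, W) uint8 in {0,1,2,3}
    spec: PhantomSpec


def _elliptic_distance(spec: PhantomSpec) -> np.ndarray:
    """Pseudo-radius grid: contours are ellipses around the tumor center."""
    n = spec.image_size
    cy, cx = spec.center
    yy, xx = np.mgrid[0:n, 0:n]
    return np.sqrt((yy - cy) ** 2 + ((xx - cx) / spec.axis_ratio) ** 2)


def generate_case(spec: PhantomSpec, case_id: str = "phantom_000") -> PhantomCase:
    """Build one case deterministically from the spec."""
    n = spec.image_size
    dist = _elliptic_distance(spec)
    wt_r, tc_r, et_r = spec.region_radii

    labels = np.zeros((n, n), dtype=np.uint8)
    labels[dist <= wt_r] = LABEL_EDEMA
    labels[dist <= tc_r] = LABEL_NCR
    if et_r > 0:
        labels[dist <= et_r] = LABEL_ENH

    cy, cx = n / 2.0, n / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    brain = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) <= spec.effective_brain_radius

    rng = np.random.default_rng(spec.seed)
    images = np.zeros((len(MODALITIES), n, n), dtype=np.float32)
    for mi, mod in enumerate(MODALITIES):
        mean = np.full((n, n), spec.contrast_table[(mod, "background")], dtype=np.float32)
        mean[brain] = spec.contrast_table[(mod, "brain")]
        for lab, tissue in _TISSUE_OF_LABEL.items():
            if lab == LABEL_BG:
                continue
            mean[labels == lab] = spec.contrast_table[(mod, tissue)]
        img = mean.copy()
        if spec.noise_sd > 0:
            # noise only where tissue is present; true background stays 0
            noisy = mean > 0
            img[noisy] += rng.normal(0.0, spec.noise_sd, size=int(noisy.sum())).astype(np.float32)
        images[mi] = img
    return PhantomCase(case_id=case_id, images=images, labels=labels, spec=spec)


@dataclass(frozen=True)
class JitterSpec:
    """Per-case perturbation ranges for dataset generation (uniform draws)."""

    center_px: float = 10.0  # +- offset of the tumor center, per axis
    radius_frac: float = 0.2  # +- fractional perturbation of each radius
    contrast_frac: float = 0.05  # +- fractional perturbation of tissue means
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)


def generate_dataset(
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    jitter: JitterSpec | None = None,
    empty_et_fraction: float = 0.25,
    seed: int | None = None,
) -> list[PhantomCase]:
    """A seeded collection of jittered cases.

    A fixed fraction of cases (rounded to the nearest count, chosen by the
    seeded stream) has an empty enhancing region to exercise the special
    scoring rule.  Jitter draws that would break the WT > TC > ET nesting
    are resampled, never emitted.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_spec or PhantomSpec()
    jit = jitter or JitterSpec()
    rng = np.random.default_rng(base.seed if seed is None else seed)
    n_empty = int(round(empty_et_fraction * n_cases))
    empty_idx = set(rng.choice(n_cases, size=n_empty, replace=False).tolist())

    cases = []
    for i in range(n_cases):
        for _attempt in range(100):
            cy = base.center[0] + rng.uniform(-jit.center_px, jit.center_px)
            cx = base.center[1] + rng.uniform(-jit.center_px, jit.center_px)
            radii = tuple(
                r * (1.0 + rng.uniform(-jit.radius_frac, jit.radius_frac))
                for r in base.region_radii
            )
            if i in empty_idx:
                radii = (radii[0], radii[1], 0.0)
            contrast = {
                key: val * (1.0 + rng.uniform(-jit.contrast_frac, jit.contrast_frac))
                if val > 0
                else val
                for key, val in base.contrast_table.items()
            }
            ratio = rng.uniform(*jit.axis_ratio_range)
            try:
                spec = replace(
                    base,
                    tumor_center=(cy, cx),
                    region_radii=radii,
                    contrast_table=contrast,
                    axis_ratio=ratio,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                break
            except ValueError:
                continue
        else:  # pragma: no cover - jitter ranges keep this unreachable
            raise RuntimeError("could not draw a valid jittered spec")
        cases.append(generate_case(spec, case_id=f"phantom_{i:03d}"))
    return cases


# -- BraTS-style on-disk layout -------------------------------------------

_BRATS_FROM_INTERNAL = np.array([0, 1, 2, 4], dtype=np.uint8)  # {0,1,2,3} -> {0,1,2,4}


def write_brats_layout(cases: list[PhantomCase], directory) -> list[Path]:
    """One subdirectory per case with five NIfTI files (t1/t1ce/t2/flair/seg).

    Segmentation files use the on-disk label values {0, 1, 2, 4}; images are
    stored as (H, W, 1) volumes so the reader's slicing path applies.
    """
    import nibabel as nib

    if not cases:
        raise ValueError("no cases to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    written = []
    for case in cases:
        case_dir = directory / case.case_id
        case_dir.mkdir(exist_ok=True)
        for mi, mod in enumerate(MODALITIES):
            vol = case.images[mi][:, :, None].astype(np.float32)
            nib.save(nib.Nifti1Image(vol, affine), case_dir / f"{case.case_id}_{mod}.nii.gz")
        seg = _BRATS_FROM_INTERNAL[case.labels][:, :, None]
        nib.save(nib.Nifti1Image(seg, affine), case_dir / f"{case.case_id}_seg.nii.gz")
        written.append(case_dir)
    manifest = directory / "manifest.txt"
    manifest.write_text("\n".join(c.case_id for c in cases) + "\n")
    return written


def dataset_digest(cases: list[PhantomCase]) -> str:
    """Deterministic content digest of a generated dataset."""
    h = hashlib.sha256()
    for case in cases:
        h.update(case.case_id.encode())
        h.update(np.ascontiguousarray(case.images).tobytes())
        h.update(np.ascontiguousarray(case.labels).tobytes())
    return h.hexdigest()
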