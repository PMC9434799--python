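"""Reading BraTS-layout cases and the preprocessing pipeline.

A case directory holds five NIfTI volumes sharing one grid: the four
modalities (t1, t1ce, t2, flair) and a segmentation with label values
{0, 1, 2, 4}.  Preprocessing follows the training protocol: a center crop
to a 16-divisible target (the source grid only needs to be at least as
large; the original shape is recorded), axial 2-D slice extraction along
the last axis, remapping of the sparse on-disk labels {0,1,2,4} to the
dense {0,1,2,3} used by the network, and per-modality z-score
normalization over nonzero (brain) voxels with the zero background left
untouched.

Arrays are (height, width, depth); slices are taken along depth with
0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantom import MODALITIES

BRATS_LABELS = (0, 1, 2, 4)

# {0,1,2,4} <-> {0,1,2,3}
_TO_INTERNAL = np.zeros(5, dtype=np.uint8)
_TO_INTERNAL[[0, 1, 2, 4]] = [0, 1, 2, 3]
_FROM_INTERNAL = np.array([0, 1, 2, 4], dtype=np.uint8)


def remap_labels(seg: np.ndarray) -> np.ndarray:
    """On-disk {0,1,2,4} -> dense {0,1,2,3}."""
    seg = np.asarray(seg)
    bad = np.setdiff1d(np.unique(seg), BRATS_LABELS)
    if bad.size:
        raise ValueError(f"segmentation contains non-BraTS label values {bad.tolist()}")
    return _TO_INTERNAL[seg.astype(np.intp)]


def unmap_labels(labels: np.ndarray) -> np.ndarray:
    """Dense {0,1,2,3} -> on-disk {0,1,2,4}."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 3:
        raise ValueError("internal labels must lie in {0,1,2,3}")
    return _FROM_INTERNAL[labels.astype(np.intp)]


@dataclass
class CaseVolumes:
    """Per-case multimodal volumes plus the raw-label segmentation."""

    case_id: str
    images: dict[str, np.ndarray]  # modality -> (H, W, D) float32
    seg: np.ndarray  # (H, W, D), values in {0,1,2,4}
    source_shape: tuple[int, int, int] | None = None  # pre-crop shape, for the log

    def __post_init__(self):
        shapes = {mod: img.shape for mod, img in self.images.items()}
        ref = self.seg.shape
        for mod, shp in shapes.items():
            if shp != ref:
                raise ValueError(
                    f"shape mismatch in case {self.case_id}: {mod} {shp} vs seg {ref}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.seg.shape


@dataclass(frozen=True)
class SlicePair:
    """One training/inference example: a four-modality slice and its labels."""

    images: np.ndarray  # (4, H, W) float32, modality order MODALITIES
    labels: np.ndarray  # (H, W) uint8, values in {0,1,2,3}
    case_id: str = ""
    slice_index: int = 0


def load_case(case_directory) -> CaseVolumes:
    """Read the five expected NIfTI files of one case directory."""
    import nibabel as nib

    case_dir = Path(case_directory)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"case directory not found: {case_dir}")
    case_id = case_dir.name

    def find(suffix: str) -> Path:
        matches = sorted(case_dir.glob(f"*_{suffix}.nii*"))
        if not matches:
            raise FileNotFoundError(
                f"case {case_id}: missing {suffix} file (expected *_{suffix}.nii[.gz])"
            )
        return matches[0]

    images = {}
    for mod in MODALITIES:
        vol = np.asarray(nib.load(find(mod)).dataobj, dtype=np.float32)
        if vol.ndim != 3:
            raise ValueError(f"case {case_id}: {mod} volume is not 3-D (shape {vol.shape})")
        images[mod] = vol
    seg = np.asarray(nib.load(find("seg")).dataobj).astype(np.int16)
    remap_labels(seg)  # validates the label alphabet
    return CaseVolumes(case_id=case_id, images=images, seg=seg, source_shape=seg.shape)


def crop_volume(vol: CaseVolumes, target: tuple[int, int, int] = (160, 160, 128)) -> CaseVolumes:
    """Center crop all five volumes to ``target`` (source must be >= target).

    The crop keeps the central region: start index ``(n - t) // 2`` per
    axis, so a voxel at the source center index ``n // 2`` maps to the new
    center index ``t // 2`` whenever ``n`` and ``t`` have equal parity.
    """
    src = vol.shape
    if any(s < t for s, t in zip(src, target)):
        raise ValueError(f"source shape {src} smaller than crop target {target}")
    slices = tuple(slice((s - t) // 2, (s - t) // 2 + t) for s, t in zip(src, target))
    return CaseVolumes(
        case_id=vol.case_id,
        images={mod: img[slices] for mod, img in vol.images.items()},
        seg=vol.seg[slices],
        source_shape=vol.source_shape or src,
    )


def extract_slices(vol: CaseVolumes, policy: str = "tumor-bearing") -> list[SlicePair]:
    """Axial slices as SlicePairs.

    ``policy='all'`` emits every slice; ``policy='tumor-bearing'`` keeps
    only slices whose label plane contains tumor (the training default; an
    empty result is legal for tumor-free volumes).
    """
    if policy not in ("all", "tumor-bearing"):
        raise ValueError(f"unknown slice policy {policy!r}; expected 'all' or 'tumor-bearing'")
    labels3d = remap_labels(vol.seg)
    pairs = []
    for k in range(vol.shape[2]):
        lab = labels3d[:, :, k]
        if policy == "tumor-bearing" and not lab.any():
            continue
        stack = np.stack([vol.images[mod][:, :, k] for mod in MODALITIES]).astype(np.float32)
        pairs.append(
            SlicePair(images=stack, labels=lab.astype(np.uint8), case_id=vol.case_id, slice_index=k)
        )
    return pairs


def normalize(images: np.ndarray, method: str = "zscore_nonzero") -> np.ndarray:
    """Per-modality intensity normalization of a (4, H, W) stack.

    Default: z-score over nonzero (brain) pixels per modality; zero
    background stays exactly zero; a zero-variance foreground is guarded
    with sd = 1 (so a constant foreground maps to 0).  ``method='none'``
    returns the input unchanged.
    """
    if method == "none":
        return np.asarray(images, dtype=np.float32)
    if method != "zscore_nonzero":
        raise ValueError(f"unknown normalization method {method!r}")
    images = np.asarray(images, dtype=np.float32)
    out = np.zeros_like(images)
    for m in range(images.shape[0]):
        plane = images[m]
        mask = plane != 0
        if not mask.any():
            continue
        vals = plane[mask]
        sd = float(vals.std())
        if sd == 0.0:
            sd = 1.0
        out[m, mask] = (vals - float(vals.mean())) / sd
    return out


def load_dataset(directory, policy: str = "tumor-bearing", *, crop: tuple[int, int, int] | None = None,
                 normalization: str = "zscore_nonzero") -> list[SlicePair]:
    """Read every case under ``directory`` and run the full pipeline."""
    directory = Path(directory)
    case_dirs = sorted(p for p in directory.iterdir() if p.is_dir())
    if not case_dirs:
        raise FileNotFoundError(f"no case directories under {directory}")
    pairs: list[SlicePair] = []
    for case_dir in case_dirs:
        vol = load_case(case_dir)
        if crop is not None:
            vol = crop_volume(vol, crop)
        for pair in extract_slices(vol, policy):
            pairs.append(
                SlicePair(
                    images=normalize(pair.images, normalization),
                    labels=pair.labels,
                    case_id=pair.case_id,
                    slice_index=pair.slice_index,
                )
            )
    return pairs
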