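"""Evaluation protocol: nested tumor regions, Dice, HD95, and aggregation.

Predicted and ground-truth label maps (values 0..3 after remapping) are
reduced to the three nested binary regions used for glioma scoring:

* WT (whole tumor)      = labels {1, 2, 3}
* TC (tumor core)       = labels {1, 3}
* ET (enhancing tumor)  = label {3}

Per case and region the Dice similarity coefficient ``2TP/(2TP+FP+FN)`` and
the 95th-percentile symmetric Hausdorff boundary distance are computed.
When the ground-truth enhancing region is empty the special scoring rule
applies: the ET Dice is 0 if the prediction contains enhancing pixels and 1
if it is also empty, and the record is flagged so that aggregation can drop
these special values before averaging (their all-or-nothing nature would
otherwise dominate the mean).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

REGIONS = ("ET", "TC", "WT")

_REGION_LABELS = {"WT": (1, 2, 3), "TC": (1, 3), "ET": (3,)}


@dataclass(frozen=True)
class RegionMasks:
    """The three nested evaluation masks."""

    et: np.ndarray
    tc: np.ndarray
    wt: np.ndarray

    def __getitem__(self, region: str) -> np.ndarray:
        return {"ET": self.et, "TC": self.tc, "WT": self.wt}[region]


@dataclass
class EvalRecord:
    """Per-case scores: DSC and HD95 per region, plus special-case flags."""

    case_id: str
    dsc: dict[str, float] = field(default_factory=dict)
    hd95: dict[str, float | None] = field(default_factory=dict)
    hd95_reason: dict[str, str] = field(default_factory=dict)
    special: dict[str, bool] = field(default_factory=dict)


def extract_regions(labels: np.ndarray) -> RegionMasks:
    """Build the nested region masks from a {0,1,2,3} label map."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2, 3])
    if bad.size:
        raise ValueError(f"label map contains out-of-range values {bad.tolist()}")
    masks = {
        name: np.isin(labels, _REGION_LABELS[name]) for name in REGIONS
    }
    return RegionMasks(et=masks["ET"], tc=masks["TC"], wt=masks["WT"])


def dsc(pred: np.ndarray, gt: np.ndarray, *, both_empty: float = 1.0) -> float:
    """Dice similarity coefficient ``2TP / (2TP + FP + FN)``.

    ``both_empty`` is returned when neither mask has any pixel (the ratio
    is 0/0); 1.0 reflects a correctly predicted absence.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.logical_and(pred, gt).sum())
    denom = 2 * tp + int(np.logical_and(pred, ~gt).sum()) + int(np.logical_and(~pred, gt).sum())
    if denom == 0:
        return float(both_empty)
    return 2.0 * tp / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Surface pixels: set pixels with at least one unset 4-neighbor."""
    footprint = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=footprint, border_value=0)
    return mask & ~eroded


def hd95(
    pred: np.ndarray,
    gt: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    *,
    symmetrize: str = "max",
) -> float:
    """95th-percentile Hausdorff distance between mask boundaries.

    Euclidean distances between boundary pixel centers, scaled by
    ``spacing``.  ``symmetrize='max'`` (default) takes the larger of the
    two directed 95th percentiles; ``'pooled'`` takes the 95th percentile
    of the pooled directed distances.  Raises on an empty mask -- callers
    record the reason instead of scoring.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    if not pred.any() or not gt.any():
        raise ValueError("hd95 undefined for an empty mask")
    sp = np.asarray(spacing, dtype=float)
    a = np.argwhere(_boundary(pred)) * sp
    b = np.argwhere(_boundary(gt)) * sp
    d_ab = cKDTree(b).query(a)[0]  # each pred-boundary pixel to nearest gt boundary
    d_ba = cKDTree(a).query(b)[0]
    if symmetrize == "max":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    if symmetrize == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    raise ValueError(f"unknown symmetrization {symmetrize!r}")


def score_case(
    pred_labels: np.ndarray,
    gt_labels: np.ndarray,
    case_id: str = "",
    spacing: tuple[float, float] = (1.0, 1.0),
) -> EvalRecord:
    """Score one case: per-region DSC/HD95 with the enhancing special rule."""
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError(
            f"prediction/ground-truth shape mismatch: {pred_labels.shape} vs {gt_labels.shape}"
        )
    pred = extract_regions(pred_labels)
    gt = extract_regions(gt_labels)
    rec = EvalRecord(case_id=case_id)
    for region in REGIONS:
        p, g = pred[region], gt[region]
        if region == "ET" and not g.any():
            # special rule: empty ground-truth enhancing tumor scores
            # all-or-nothing and is flagged for removal before averaging
            rec.dsc[region] = 0.0 if p.any() else 1.0
            rec.special[region] = True
        else:
            rec.dsc[region] = dsc(p, g)
            rec.special[region] = False
        if p.any() and g.any():
            rec.hd95[region] = hd95(p, g, spacing)
        else:
            rec.hd95[region] = None
            empty = [s for s, m in (("pred", p), ("gt", g)) if not m.any()]
            rec.hd95_reason[region] = f"empty {'+'.join(empty)} mask"
    return rec


def aggregate(records: list[EvalRecord]) -> dict:
    """Per-region and overall means, excluding special and undefined values.

    The overall means are the arithmetic means of the three per-region
    means.  A region with no remaining values is reported as None, never
    as 0.
    """
    if not records:
        raise ValueError("no records to aggregate")
    summary: dict = {"per_region": {}, "n_cases": len(records)}
    for region in REGIONS:
        ds = [
            r.dsc[region]
            for r in records
            if region in r.dsc and not r.special.get(region, False)
        ]
        hs = [r.hd95[region] for r in records if r.hd95.get(region) is not None]
        summary["per_region"][region] = {
            "dsc_mean": float(np.mean(ds)) if ds else None,
            "hd95_mean": float(np.mean(hs)) if hs else None,
            "n_dsc": len(ds),
            "n_hd95": len(hs),
        }
    dsc_means = [v["dsc_mean"] for v in summary["per_region"].values() if v["dsc_mean"] is not None]
    hd_means = [v["hd95_mean"] for v in summary["per_region"].values() if v["hd95_mean"] is not None]
    summary["mean_dsc"] = float(np.mean(dsc_means)) if dsc_means else None
    summary["mean_hd95"] = float(np.mean(hd_means)) if hd_means else None
    return summary


# -- CSV round trip (consumed by the command-line summarize step) ---------


def write_records_csv(records: list[EvalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "region", "dsc", "hd95", "special"])
        for rec in records:
            for region in REGIONS:
                hd = rec.hd95.get(region)
                writer.writerow(
                    [
                        rec.case_id,
                        region,
                        f"{rec.dsc[region]:.6f}",
                        "" if hd is None else f"{hd:.6f}",
                        int(rec.special.get(region, False)),
                    ]
                )


def read_records_csv(path) -> list[EvalRecord]:
    by_case: dict[str, EvalRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = by_case.setdefault(row["case"], EvalRecord(case_id=row["case"]))
            region = row["region"]
            rec.dsc[region] = float(row["dsc"])
            rec.hd95[region] = float(row["hd95"]) if row["hd95"] else None
            rec.special[region] = bool(int(row.get("special", 0) or 0))
    return list(by_case.values())
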