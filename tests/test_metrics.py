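"""Region extraction, DSC, HD95 and aggregation against exhaustive oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mmunet import metrics
from mmunet.metrics import EvalRecord, aggregate, dsc, extract_regions, hd95, score_case


def test_extract_regions_union_counts():
    lab = np.zeros((10, 10), dtype=int)
    lab.flat[:5] = 1
    lab.flat[5:12] = 2
    lab.flat[12:15] = 3
    masks = extract_regions(lab)
    assert masks.et.sum() == 3
    assert masks.tc.sum() == 8  # labels {1, 3}
    assert masks.wt.sum() == 15  # labels {1, 2, 3}


def test_extract_regions_nested_and_empty():
    empty = extract_regions(np.zeros((4, 4), dtype=int))
    assert not empty.wt.any()
    lab = np.random.default_rng(0).integers(0, 4, size=(12, 12))
    masks = extract_regions(lab)
    assert (masks.et <= masks.tc).all() and (masks.tc <= masks.wt).all()


def test_extract_regions_rejects_out_of_range():
    with pytest.raises(ValueError, match=r"\[4\]"):
        extract_regions(np.array([[4]]))


def test_dsc_examples_and_symmetry():
    a = np.zeros((5, 5), bool)
    b = np.zeros((5, 5), bool)
    a[1:3, 1:3] = True
    assert dsc(a, a) == 1.0
    b[3:5, 3:5] = True
    assert dsc(a, b) == 0.0
    # TP=2, FP=1, FN=1 -> 4/6
    p = np.array([1, 1, 1, 0], bool)
    g = np.array([1, 1, 0, 1], bool)
    assert dsc(p, g) == pytest.approx(2 / 3)
    assert dsc(p, g) == dsc(g, p)


def test_dsc_false_positive_growth_never_increases_score():
    g = np.zeros((16, 16), bool)
    g[4:8, 4:8] = True
    prev = 1.0
    pred = g.copy()
    for grow in range(1, 5):
        pred[8 : 8 + grow, 4:8] = True  # enlarge a pure false-positive margin
        score = dsc(pred, g)
        assert score <= prev
        prev = score


def brute_hd95(a, b):
    """All-pairs boundary-distance oracle."""
    pa = np.argwhere(metrics._boundary(a)).astype(float)
    pb = np.argwhere(metrics._boundary(b)).astype(float)
    d = cdist(pa, pb)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


def test_hd95_identical_masks_zero():
    m = np.zeros((8, 8), bool)
    m[2:6, 2:6] = True
    assert hd95(m, m) == 0.0


def test_hd95_single_pixel_offset_is_euclidean():
    a = np.zeros((10, 10), bool)
    b = np.zeros((10, 10), bool)
    a[1, 1] = True
    b[4, 5] = True
    assert hd95(a, b) == pytest.approx(5.0)


@pytest.mark.parametrize("seed", range(8))
def test_hd95_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(16, 16)) > 0.6
    b = rng.uniform(size=(16, 16)) > 0.6
    if not a.any():
        a[3, 3] = True
    if not b.any():
        b[9, 9] = True
    assert hd95(a, b) == pytest.approx(brute_hd95(a, b), abs=1e-9)
    assert hd95(a, b) == pytest.approx(hd95(b, a))


def test_hd95_not_exceeding_full_hausdorff():
    rng = np.random.default_rng(99)
    a = rng.uniform(size=(16, 16)) > 0.7
    b = rng.uniform(size=(16, 16)) > 0.7
    pa = np.argwhere(metrics._boundary(a)).astype(float)
    pb = np.argwhere(metrics._boundary(b)).astype(float)
    d = cdist(pa, pb)
    hd100 = max(d.min(axis=1).max(), d.min(axis=0).max())
    assert hd95(a, b) <= hd100 + 1e-12


def test_hd95_spacing_scales_distances():
    a = np.zeros((6, 6), bool)
    b = np.zeros((6, 6), bool)
    a[1, 1] = True
    b[1, 3] = True
    assert hd95(a, b, spacing=(1.0, 2.5)) == pytest.approx(5.0)


def test_hd95_empty_mask_raises():
    m = np.zeros((4, 4), bool)
    full = ~m
    with pytest.raises(ValueError, match="empty"):
        hd95(m, full)


def test_score_case_special_rules():
    gt = np.zeros((8, 8), dtype=int)
    gt[2:5, 2:5] = 2  # edema only: ET empty in ground truth
    pred_fp = gt.copy()
    pred_fp[3, 3] = 3
    rec = score_case(pred_fp, gt, "fp")
    assert rec.dsc["ET"] == 0.0 and rec.special["ET"]
    rec2 = score_case(gt, gt, "tn")
    assert rec2.dsc["ET"] == 1.0 and rec2.special["ET"]
    assert rec2.hd95["ET"] is None and "empty" in rec2.hd95_reason["ET"]

    gt[4, 4] = 3  # nonempty ET: the regular path, flag unset
    rec3 = score_case(gt, gt, "reg")
    assert not rec3.special["ET"]
    assert rec3.dsc["ET"] == 1.0 and rec3.hd95["ET"] == 0.0


def test_score_case_self_is_perfect(small_cases):
    case = next(c for c in small_cases if (c.labels == 3).any())
    rec = score_case(case.labels, case.labels, case.case_id)
    for region in metrics.REGIONS:
        assert rec.dsc[region] == 1.0
        assert rec.hd95[region] == 0.0


def _record(case_id, et, wt, tc, special_et=False):
    return EvalRecord(
        case_id,
        dsc={"ET": et, "WT": wt, "TC": tc},
        hd95={"ET": None, "WT": None, "TC": None},
        special={"ET": special_et, "WT": False, "TC": False},
    )


def test_aggregate_excludes_special_values_like_hand_filtering():
    records = [
        _record("a", 0.8, 0.9, 0.7),
        _record("b", 1.0, 0.8, 0.6, special_et=True),  # special ET must be dropped
        _record("c", 0.0, 0.7, 0.5, special_et=True),
        _record("d", 0.6, 0.6, 0.4),
    ]
    s = aggregate(records)
    assert s["per_region"]["ET"]["dsc_mean"] == pytest.approx(np.mean([0.8, 0.6]))
    assert s["per_region"]["ET"]["n_dsc"] == 2
    assert s["per_region"]["WT"]["dsc_mean"] == pytest.approx(np.mean([0.9, 0.8, 0.7, 0.6]))
    assert s["per_region"]["WT"]["hd95_mean"] is None  # all undefined -> None, never 0


def test_aggregate_single_record_echoes_it():
    rec = _record("only", 0.5, 0.6, 0.7)
    s = aggregate([rec])
    assert s["per_region"]["ET"]["dsc_mean"] == 0.5
    assert s["mean_dsc"] == pytest.approx((0.5 + 0.6 + 0.7) / 3)


def test_headline_means_from_per_region_values():
    rec = EvalRecord(
        "published",
        dsc={"ET": 0.762, "WT": 0.850, "TC": 0.765},
        hd95={"ET": 6.389, "WT": 8.243, "TC": 10.766},
        special={},
    )
    s = aggregate([rec])
    assert round(100 * s["mean_dsc"], 1) == 79.2
    assert round(s["mean_hd95"], 3) == 8.466


def test_records_csv_round_trip(tmp_path):
    records = [_record("a", 0.8, 0.9, 0.7), _record("b", 1.0, 0.8, 0.6, special_et=True)]
    records[0].hd95["WT"] = 3.5
    path = tmp_path / "records.csv"
    metrics.write_records_csv(records, path)
    back = metrics.read_records_csv(path)
    assert aggregate(back)["per_region"]["ET"]["dsc_mean"] == pytest.approx(0.8)
    assert back[0].hd95["WT"] == pytest.approx(3.5)
    assert back[1].special["ET"]
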