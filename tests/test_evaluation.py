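import numpy as np
import pytest
from PIL import Image

from blastoseg.dataio import CLASS_MAP, ImageSample
from blastoseg.evaluation import (
    ConfusionCounts,
    JaccardReport,
    confusion_counts,
    evaluate,
    export_result_masks,
    jaccard_index,
    mean_ji,
    write_report_csv,
)
from blastoseg.losses import one_hot


def _loop_oracle(pred, gt):
    """Independent per-pixel double-loop TP/FP/FN tally."""
    tp = np.zeros(5, dtype=int)
    fp = np.zeros(5, dtype=int)
    fn = np.zeros(5, dtype=int)
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = pred[i, j], gt[i, j]
            if p == g:
                tp[p] += 1
            else:
                fp[p] += 1
                fn[g] += 1
    return tp, fp, fn


class _OracleNet:
    """Stand-in predictor that decodes the label encoded in the image.

    Synthetic: stands in for a trained network in evaluation tests, scoring
    class round(image * 4) at every pixel.
    """

    def forward(self, x, training=False):
        labels = np.round(x[:, 0] * 4).astype(int)
        return one_hot(labels, dtype=np.float32) * 10.0


class TestConfusionCounts:
    def test_identical_maps_have_no_errors(self, rng):
        m = rng.integers(0, 5, (16, 16))
        c = confusion_counts(m, m)
        assert (c.fp == 0).all() and (c.fn == 0).all()
        assert c.tp.sum() == m.size

    def test_all_bg_prediction_against_all_te_truth(self):
        pred = np.zeros((2, 2), dtype=int)
        gt = np.full((2, 2), 1)
        c = confusion_counts(pred, gt)
        assert c.tp[1] == 0 and c.fn[1] == 4
        assert c.fp[0] == 4 and c.tp[0] == 0

    def test_matches_pixel_loop_oracle_on_random_masks(self, rng):
        pred = rng.integers(0, 5, (8, 8))
        gt = rng.integers(0, 5, (8, 8))
        c = confusion_counts(pred, gt)
        tp, fp, fn = _loop_oracle(pred, gt)
        np.testing.assert_array_equal(c.tp, tp)
        np.testing.assert_array_equal(c.fp, fp)
        np.testing.assert_array_equal(c.fn, fn)

    def test_total_tp_equals_correct_pixels(self, rng):
        pred = rng.integers(0, 5, (12, 12))
        gt = rng.integers(0, 5, (12, 12))
        assert confusion_counts(pred, gt).tp.sum() == (pred == gt).sum()

    def test_shape_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2), dtype=int), np.zeros((3, 3), dtype=int))


class TestJaccardIndex:
    def test_perfect_class_is_100(self):
        c = ConfusionCounts()
        c.tp[1] = 5
        assert jaccard_index(c, 1) == (100.0, False)

    def test_three_tp_one_fp_two_fn_is_50(self):
        c = ConfusionCounts()
        c.tp[2], c.fp[2], c.fn[2] = 3, 1, 2
        assert jaccard_index(c, 2)[0] == pytest.approx(50.0)

    def test_no_tp_with_fp_is_0(self):
        c = ConfusionCounts()
        c.fp[3] = 7
        assert jaccard_index(c, 3) == (0.0, False)

    def test_class_absent_from_both_is_flagged_100(self):
        ji, flagged = jaccard_index(ConfusionCounts(), 4)
        assert ji == 100.0 and flagged

    def test_equals_set_operation_oracle(self, rng):
        # |A intersection B| / |A union B| over pixel index sets
        pred = rng.integers(0, 5, (16, 16))
        gt = rng.integers(0, 5, (16, 16))
        counts = confusion_counts(pred, gt)
        for c in range(5):
            a = set(zip(*np.nonzero(pred == c)))
            b = set(zip(*np.nonzero(gt == c)))
            if a | b:
                expected = 100.0 * len(a & b) / len(a | b)
                assert jaccard_index(counts, c)[0] == pytest.approx(expected)

    def test_symmetric_under_pred_truth_swap(self, rng):
        pred = rng.integers(0, 5, (10, 10))
        gt = rng.integers(0, 5, (10, 10))
        for c in range(5):
            assert jaccard_index(confusion_counts(pred, gt), c)[0] == pytest.approx(
                jaccard_index(confusion_counts(gt, pred), c)[0]
            )


class TestReport:
    def test_mean_is_arithmetic_mean_of_five_classes(self):
        rep = JaccardReport(
            per_class={"TE": 80.0, "ZP": 85.0, "ICM": 90.0, "BL": 95.0, "BG": 100.0},
            n_images=1,
        )
        assert rep.mean == pytest.approx(90.0)

    def test_published_row_arithmetic(self):
        # the tabulated per-class values must average to the tabulated mean
        assert mean_ji([79.08, 84.69, 85.88, 89.28, 96.07]) == 87.00

    def test_mean_ji_requires_five_values(self):
        with pytest.raises(ValueError):
            mean_ji([1.0, 2.0])

    def test_csv_layout(self, tmp_path):
        rep = JaccardReport(
            per_class={"TE": 79.08, "ZP": 84.69, "ICM": 85.88, "BL": 89.28, "BG": 96.07},
            n_images=35,
            params_millions=2.15,
        )
        write_report_csv(tmp_path / "r.csv", [("tvl_with_fbb", rep)])
        lines = (tmp_path / "r.csv").read_text().strip().splitlines()
        assert lines[0] == "method,TE,ZP,ICM,BL,BG,MeanJI,params_millions"
        assert lines[1].startswith("tvl_with_fbb,79.08,84.69,85.88,89.28,96.07,87.00")


class TestEvaluate:
    def _encoded_samples(self, rng, n=3, size=8):
        out = []
        for k in range(n):
            mask = rng.integers(0, 5, (size, size))
            out.append(ImageSample(image=mask / 4.0, mask=mask, sample_id=f"s{k}"))
        return out

    def test_perfect_predictor_scores_100_everywhere(self, rng):
        report = evaluate(_OracleNet(), self._encoded_samples(rng))
        assert report.row() == [100.0] * 5 + [100.0]

    def test_pooled_report_matches_loop_oracle(self, rng):
        samples = self._encoded_samples(rng, n=2)
        # corrupt the ground truth so the predictor is imperfect
        samples[0].mask = (samples[0].mask + 1) % 5
        report = evaluate(_OracleNet(), samples)
        tp = np.zeros(5, dtype=int)
        fp = np.zeros(5, dtype=int)
        fn = np.zeros(5, dtype=int)
        for smp in samples:
            pred = np.round(smp.image * 4).astype(int)
            a, b, c = _loop_oracle(pred, smp.mask)
            tp += a
            fp += b
            fn += c
        for name in ("TE", "ZP", "ICM", "BL", "BG"):
            idx = CLASS_MAP.index_of(name)
            expected = 100.0 * tp[idx] / (tp[idx] + fp[idx] + fn[idx])
            assert report.per_class[name] == pytest.approx(expected)

    def test_per_image_mode_averages_images(self, rng):
        samples = self._encoded_samples(rng, n=2)
        pooled = evaluate(_OracleNet(), samples, mode="pooled")
        per_image = evaluate(_OracleNet(), samples, mode="per_image")
        assert pooled.row() == per_image.row() == [100.0] * 6

    def test_empty_test_set_is_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_OracleNet(), [])

    def test_detail_json_written(self, rng, tmp_path):
        evaluate(_OracleNet(), self._encoded_samples(rng), detail_path=tmp_path / "d.json")
        import json

        detail = json.loads((tmp_path / "d.json").read_text())
        assert len(detail) == 3 and "ji" in detail[0]


class TestExportMasks:
    def test_all_bl_prediction(self, tmp_path):
        label_map = np.full((8, 8), CLASS_MAP.index_of("BL"))
        files = export_result_masks(label_map, tmp_path, stem="p")
        assert len(files) == 6
        bl = np.asarray(Image.open(tmp_path / "p_BL.png"))
        te = np.asarray(Image.open(tmp_path / "p_TE.png"))
        assert (bl == 255).all() and (te == 0).all()

    def test_binary_masks_partition_every_pixel(self, tmp_path, rng):
        label_map = rng.integers(0, 5, (8, 8))
        export_result_masks(label_map, tmp_path, stem="q")
        total = np.zeros((8, 8), dtype=int)
        for name in ("TE", "ZP", "ICM", "BL", "BG"):
            total += np.asarray(Image.open(tmp_path / f"q_{name}.png")) // 255
        assert (total == 1).all()

    def test_combined_mask_uses_canonical_colors(self, tmp_path):
        label_map = np.full((4, 4), CLASS_MAP.index_of("ICM"))
        export_result_masks(label_map, tmp_path, stem="c")
        rgb = np.asarray(Image.open(tmp_path / "c_combined.png"))
        assert tuple(rgb[0, 0]) == (0, 0, 255)
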