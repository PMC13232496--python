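"""Damage quantification from images: threshold rules, median cut, batch runs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from PIL import Image

import damageqtl as dq
from damageqtl.images import (
    GREEN,
    NECROTIC,
    UNCLASSIFIED,
    YELLOW,
    DamageUndefinedError,
    EmptyMaskError,
    TissueCounts,
)
from damageqtl.simulate import ImageTruth, generate_plant_image, write_image_fixture


def _one_pixel(rgb):
    return dq.RGBImage(
        pixels=np.array(rgb, dtype=float).reshape(1, 1, 3),
        mask=np.ones((1, 1), dtype=bool),
    )


class TestThresholdClassification:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((0.20, 0.60, 0.30), GREEN),  # R < 0.9G, B < 0.9G, 2G large
            ((150 / 255, 150 / 255, 100 / 255), YELLOW),  # fails green, in yellow box
            ((0.40, 0.40, 0.05), NECROTIC),  # fails green/yellow, in necrotic box
            ((1.0, 1.0, 1.0), UNCLASSIFIED),  # white: matches no rule
            ((0.0, 0.0, 0.0), UNCLASSIFIED),  # black: strict inequalities fail
        ],
    )
    def test_single_pixel_labels(self, rgb, expected):
        counts, labels = dq.classify_pixels_dtr(_one_pixel(rgb))
        assert labels[0, 0] == expected
        assert counts.total == 1

    def test_precedence_green_wins_over_yellow(self):
        # inside the yellow box but also satisfying the green rule
        rgb = (100 / 255, 150 / 255, 60 / 255)
        _, labels = dq.classify_pixels_dtr(_one_pixel(rgb))
        assert labels[0, 0] == GREEN

    def test_requires_mask(self):
        img = dq.RGBImage(pixels=np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="mask"):
            dq.classify_pixels_dtr(img)

    def test_labels_partition_masked_pixels(self, rng):
        pix = rng.random((20, 20, 3))
        mask = rng.random((20, 20)) < 0.6
        counts, labels = dq.classify_pixels_dtr(dq.RGBImage(pixels=pix, mask=mask))
        assert counts.total == mask.sum()
        assert (labels[~mask] == -1).all()
        assert (labels[mask] >= 0).all()


class TestLoadAndMask:
    def test_normalisation_endpoints(self, tmp_path):
        arr = np.zeros((2, 2, 3), dtype=np.uint8)
        arr[0, 0] = (255, 255, 255)
        Image.fromarray(arr).save(tmp_path / "a.png")
        img = dq.load_image(tmp_path / "a.png")
        assert img.pixels[0, 0].tolist() == [1.0, 1.0, 1.0]
        assert img.pixels[1, 1].tolist() == [0.0, 0.0, 0.0]

    def test_mask_shape_mismatch_rejected(self, tmp_path):
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(tmp_path / "a.png")
        Image.fromarray(np.zeros((2, 2), dtype=np.uint8)).save(tmp_path / "m.png")
        with pytest.raises(ValueError, match="shape"):
            dq.load_image(tmp_path / "a.png", tmp_path / "m.png")

    def test_background_rule_recovers_planted_mask(self):
        truth = ImageTruth(proportions=(0.5, 0.3, 0.2), n_plant_pixels=300, seed=5)
        img, truth = generate_plant_image(truth, 30, 30)
        unmasked = dq.RGBImage(pixels=img.pixels)
        recovered = dq.mask_background(unmasked, (1.0, 1.0, 1.0), tol=0.0)
        assert (recovered.mask == truth.mask).all()

    def test_tol_one_leaves_nothing(self):
        img = dq.RGBImage(pixels=np.random.default_rng(1).random((5, 5, 3)))
        with pytest.raises(EmptyMaskError):
            dq.mask_background(img, (0.5, 0.5, 0.5), tol=1.0)

    def test_background_count_monotone_in_tol(self, rng):
        img = dq.RGBImage(pixels=rng.random((30, 30, 3)))
        bg = (0.5, 0.5, 0.5)
        n_bg = []
        for tol in np.linspace(0.45, 0.01, 15):
            masked = dq.mask_background(img, bg, tol=float(tol))
            n_bg.append(int((~masked.mask).sum()))
        assert all(a >= b for a, b in zip(n_bg, n_bg[1:]))


class TestMedianCut:
    def test_three_distinct_colors_recovered(self):
        colors = np.array([[0.1, 0.8, 0.2], [0.7, 0.6, 0.3], [0.4, 0.3, 0.05]])
        reps = [50, 30, 20]
        pix = np.vstack([np.tile(c, (r, 1)) for c, r in zip(colors, reps)])
        img = dq.RGBImage(
            pixels=pix.reshape(10, 10, 3), mask=np.ones((10, 10), dtype=bool)
        )
        q = dq.median_cut_quantize(img, n_clusters=3)
        assert len(q.centroids) == 3
        got = sorted(zip(q.cluster_sizes.tolist(),
                         [tuple(np.round(c, 6)) for c in q.centroids]))
        want = sorted(zip(reps, [tuple(np.round(c, 6)) for c in colors]))
        assert got == want

    def test_single_color_is_unsplittable(self):
        img = dq.RGBImage(
            pixels=np.full((4, 4, 3), 0.3), mask=np.ones((4, 4), dtype=bool)
        )
        q = dq.median_cut_quantize(img, n_clusters=3)
        assert len(q.centroids) == 1
        assert q.cluster_sizes.tolist() == [16]

    def test_cluster_sizes_partition_mask(self, rng):
        pix = rng.random((15, 15, 3))
        mask = rng.random((15, 15)) < 0.7
        q = dq.median_cut_quantize(dq.RGBImage(pixels=pix, mask=mask), 3)
        assert q.cluster_sizes.sum() == mask.sum()
        assert (q.labels[mask] >= 0).all() and (q.labels[~mask] == -1).all()

    def test_deterministic(self, rng):
        pix = rng.random((12, 12, 3))
        img = dq.RGBImage(pixels=pix, mask=np.ones((12, 12), dtype=bool))
        q1 = dq.median_cut_quantize(img, 3)
        q2 = dq.median_cut_quantize(img, 3)
        assert np.array_equal(q1.labels, q2.labels)
        assert np.array_equal(q1.centroids, q2.centroids)


class TestClusterClassAssignment:
    def test_rule_matching_centroids(self):
        truth = ImageTruth(proportions=(0.85, 0.10, 0.05), n_plant_pixels=1000, seed=3)
        img, truth = generate_plant_image(truth, 40, 40, jitter=False)
        q = dq.median_cut_quantize(img, 3)
        counts = dq.assign_clusters_to_classes(q)
        assert (counts.green, counts.yellow, counts.necrotic) == truth.class_counts
        assert counts.unclassified == 0

    def test_equidistant_tie_breaks_to_green(self):
        # centroid at (0.5, 0, 0) matches no threshold rule and is equidistant
        # from the two custom prototypes; fixed class order wins
        img = dq.RGBImage(
            pixels=np.full((2, 2, 3), (0.5, 0.0, 0.0)),
            mask=np.ones((2, 2), dtype=bool),
        )
        q = dq.median_cut_quantize(img, 3)
        protos = {GREEN: (0.0, 0.0, 0.0), YELLOW: (1.0, 0.0, 0.0)}
        counts = dq.assign_clusters_to_classes(q, prototypes=protos)
        assert counts.green == 4 and counts.yellow == 0


class TestDamageScore:
    def test_printed_formula(self):
        assert dq.damage_score(TissueCounts(850, 100, 50)) == pytest.approx(0.15)

    def test_boundaries(self):
        assert dq.damage_score(TissueCounts(green=10)) == 0.0
        assert dq.damage_score(TissueCounts(yellow=3, necrotic=2)) == 1.0

    def test_unclassified_excluded_from_denominator(self):
        assert dq.damage_score(TissueCounts(50, 25, 25, unclassified=900)) == 0.5

    def test_no_classified_pixels_is_undefined(self):
        with pytest.raises(DamageUndefinedError):
            dq.damage_score(TissueCounts(unclassified=10))

    @given(
        st.integers(1, 10**6), st.integers(0, 10**6), st.integers(0, 10**6),
        st.integers(2, 50),
    )
    def test_scale_invariance(self, g, y, n, k):
        d1 = dq.damage_score(TissueCounts(g, y, n))
        d2 = dq.damage_score(TissueCounts(g * k, y * k, n * k))
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestMethodConcordance:
    def test_dqu_equals_dtr_on_separable_fixtures(self, rng):
        for _ in range(10):
            u = float(rng.uniform(0.05, 0.9))
            s = float(rng.uniform(0.2, 0.8))
            truth = ImageTruth(
                proportions=(1 - u, u * s, u * (1 - s)),
                n_plant_pixels=600,
                seed=int(rng.integers(2**31)),
            )
            img, truth = generate_plant_image(truth, 30, 30, jitter=False)
            dtr, _ = dq.classify_pixels_dtr(img)
            dqu = dq.assign_clusters_to_classes(dq.median_cut_quantize(img, 3))
            assert dq.damage_score(dtr) == dq.damage_score(dqu)
            assert dq.damage_score(dtr) == pytest.approx(truth.damage)

    def test_dqu_dtr_correlation_on_jittered_fixtures(self):
        # wide, segregating-population-like damage spread; the quantisation
        # method mixes classes for mid-range compositions, so agreement is
        # correlation-level, not exact
        rng = np.random.default_rng(0)
        dtr, dqu = [], []
        for _ in range(60):
            u = 0.02 + 0.93 * float(rng.beta(0.5, 0.5))
            s = float(rng.uniform(0.2, 0.8))
            truth = ImageTruth(
                proportions=(1 - u, u * s, u * (1 - s)),
                n_plant_pixels=1200,
                seed=int(rng.integers(2**31)),
            )
            img, _ = generate_plant_image(truth, 45, 45, jitter=True)
            c1, _ = dq.classify_pixels_dtr(img)
            c2 = dq.assign_clusters_to_classes(dq.median_cut_quantize(img, 3))
            dtr.append(dq.damage_score(c1))
            dqu.append(dq.damage_score(c2))
        assert np.corrcoef(dtr, dqu)[0, 1] >= 0.9


class TestBatchQuantify:
    def test_damages_match_planted_truth(self, image_set):
        out, truths = image_set
        table = dq.batch_quantify(out, method="dtr", mask_dir=out)
        assert len(table) == len(truths)
        for row in table.itertuples():
            assert row.damage == pytest.approx(truths[row.image_id].damage)

    def test_both_methods_give_two_rows_per_image(self, image_set):
        out, truths = image_set
        table = dq.batch_quantify(out, method="both", mask_dir=out)
        assert len(table) == 2 * len(truths)
        assert set(table["method"]) == {"dtr", "dqu"}

    def test_corrupt_file_is_skipped_not_fatal(self, tmp_path, caplog):
        truth = ImageTruth(proportions=(0.7, 0.2, 0.1), n_plant_pixels=300, seed=1)
        img, truth = generate_plant_image(truth, 25, 25)
        write_image_fixture(img, truth, tmp_path, "good")
        (tmp_path / "broken.png").write_bytes(b"not a png at all")
        table = dq.batch_quantify(tmp_path, method="dtr", mask_dir=tmp_path)
        assert table["image_id"].tolist() == ["good"]
        assert "broken" in caplog.text

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no decodable images"):
            dq.batch_quantify(tmp_path, method="dtr")
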