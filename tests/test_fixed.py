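"""Fixed-cell assays: foci filters, pRb split, background subtraction,
DNA content, and phase gating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial import cKDTree
from scipy.stats import binom

from zincycle import (
    SyntheticConfig,
    analyze_foci_fields,
    block_background_subtract,
    classify_phase,
    classify_prb,
    damage_fraction,
    detect_foci,
    dna_gates,
    generate_foci_image,
    integrated_dna,
    p21_vs_cdk2,
)
from zincycle.segmentation import LabelMask


def nucleus_mask(radius=10, shape=(160, 160), center=(80, 80)):
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    labels[(xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2] = 1
    return LabelMask.from_labels(labels)


def gauss_spot(img, cx, cy, sa, sb=None, amp=150.0, theta=0.0):
    sb = sa if sb is None else sb
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    u = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    v = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    img += amp * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))


class TestDetectFoci:
    def test_uniform_nucleus_no_foci(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(0, 2.0, (160, 160)), 0, None)
        foci = detect_foci(img, nucleus_mask())
        assert foci.empty

    def test_planted_circular_focus_detected(self):
        rng = np.random.default_rng(1)
        img = np.clip(rng.normal(0, 2.0, (160, 160)), 0, None)
        sa = math.sqrt(50.0 / (math.pi * 2 * math.log(2)))  # half-max area 50
        gauss_spot(img, 80, 80, sa)
        foci = detect_foci(img, nucleus_mask())
        assert len(foci) == 1
        assert foci["area"].iloc[0] == pytest.approx(50.0, rel=0.25)
        assert np.hypot(foci["x"].iloc[0] - 80, foci["y"].iloc[0] - 80) < 2

    def test_elongated_object_rejected(self):
        """Eccentricity 0.85 at valid area fails the shape filter."""
        rng = np.random.default_rng(2)
        img = np.clip(rng.normal(0, 2.0, (160, 160)), 0, None)
        ecc = 0.85
        q = math.sqrt(1 - ecc**2)
        sa = math.sqrt(50.0 / (math.pi * 2 * math.log(2) * q))
        gauss_spot(img, 80, 80, sa, sa * q)
        foci = detect_foci(img, nucleus_mask())
        assert foci.empty

    def test_out_of_area_objects_rejected(self):
        rng = np.random.default_rng(3)
        img = np.clip(rng.normal(0, 2.0, (160, 160)), 0, None)
        gauss_spot(img, 80, 80, 12.0)  # half-max area ~627 px^2
        assert detect_foci(img, nucleus_mask(radius=30)).empty

    def test_focus_outside_nucleus_ignored(self):
        rng = np.random.default_rng(4)
        img = np.clip(rng.normal(0, 2.0, (160, 160)), 0, None)
        sa = math.sqrt(50.0 / (math.pi * 2 * math.log(2)))
        gauss_spot(img, 130, 130, sa)  # far from the radius-10 nucleus at 80,80
        assert detect_foci(img, nucleus_mask()).empty

    def test_recall_precision_on_rendered_fields(self):
        """Planted in-filter foci: recall and precision both >= 0.95."""
        fields, truth = generate_foci_image(150, 1.0,
                                            config=SyntheticConfig(seed=17))
        _, foci_table = analyze_foci_fields(fields)
        hits = 0
        claimed_ok = 0
        for fi in range(len(fields)):
            tf = truth.foci[truth.foci["field"] == fi]
            df = foci_table[foci_table["field"] == fi]
            if len(tf) == 0 or len(df) == 0:
                continue
            t_tree = cKDTree(tf[["x", "y"]].to_numpy())
            d, _ = t_tree.query(df[["x", "y"]].to_numpy())
            claimed_ok += int((d < 3).sum())
            d_tree = cKDTree(df[["x", "y"]].to_numpy())
            d2, _ = d_tree.query(tf[["x", "y"]].to_numpy())
            hits += int((d2 < 3).sum())
        assert hits / len(truth.foci) >= 0.95
        assert claimed_ok / len(foci_table) >= 0.95


class TestDamageFraction:
    def test_all_negative(self):
        recs = pd.DataFrame({"prb_class": ["hypo"] * 5, "foci_count": [0] * 5})
        out = damage_fraction(recs)
        assert out["fraction_positive"].tolist() == [0.0]

    def test_planted_strata_recovered(self):
        """50% positive planted in each stratum recovers within binomial CI."""
        fields, truth = generate_foci_image(
            200, {"hypo": 0.5, "hyper": 0.5}, config=SyntheticConfig(seed=19)
        )
        records, _ = analyze_foci_fields(fields)
        out = damage_fraction(records).set_index("prb_class")
        for cls in ("hypo", "hyper"):
            n = int(out.loc[cls, "n"])
            lo, hi = binom.interval(0.95, n, 0.5)
            assert lo / n <= out.loc[cls, "fraction_positive"] <= hi / n

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        recs = pd.DataFrame(
            {"prb_class": rng.choice(["hypo", "hyper"], 50),
             "foci_count": rng.integers(0, 3, 50)}
        )
        a = damage_fraction(recs)
        b = damage_fraction(recs.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )


class TestClassifyPrb:
    def test_separated_modes_low_error(self):
        rng = np.random.default_rng(6)
        true = np.array(["hypo"] * 300 + ["hyper"] * 200)
        vals = np.where(
            true == "hypo",
            rng.lognormal(math.log(50), 0.25, 500),
            rng.lognormal(math.log(400), 0.25, 500),
        )
        labels, boundary = classify_prb(vals)
        assert (labels != true).mean() < 0.02
        assert 50 < boundary < 400

    def test_constant_input_single_class(self):
        with pytest.warns(UserWarning, match="unimodal"):
            labels, boundary = classify_prb(np.full(30, 10.0))
        assert boundary is None
        assert len(set(labels)) == 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.lognormal(math.log(50), 0.2, 100),
             rng.lognormal(math.log(500), 0.2, 100)]
        )
        a, _ = classify_prb(vals)
        b, _ = classify_prb(vals * 10.0)
        assert np.array_equal(a, b)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="20 cells"):
            classify_prb(np.ones(5))


class TestBlockBackgroundSubtract:
    def test_constant_image_zeroed(self):
        img = np.full((44, 44), 7.3)
        assert np.allclose(block_background_subtract(img), 0.0)

    def test_spots_on_gradient_recovered(self):
        """Planted spot amplitudes on a linear gradient survive within 5%."""
        yy, xx = np.mgrid[0:220, 0:220].astype(float)
        grad = 30.0 * (xx / 220)
        img = grad.copy()
        spots = [(40, 40), (110, 170), (180, 80)]
        for cx, cy in spots:
            gauss_spot(img, cx, cy, 3.0, amp=200.0)
        corrected = block_background_subtract(img)
        for cx, cy in spots:
            assert corrected[cy, cx] == pytest.approx(200.0, rel=0.05)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            block_background_subtract(np.ones((8, 8)))

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(np.float64, (33, 33),
               elements=st.floats(0, 1000, allow_nan=False))
    )
    def test_idempotent_up_to_clip(self, img):
        """Applying the subtraction twice changes no pixel by more than the
        per-block 5th percentile of the once-corrected image."""
        once = block_background_subtract(img)
        twice = block_background_subtract(once)
        row_edges = np.linspace(0, 33, 12).astype(int)
        col_edges = np.linspace(0, 33, 12).astype(int)
        for r0, r1 in zip(row_edges, row_edges[1:]):
            for c0, c1 in zip(col_edges, col_edges[1:]):
                bound = np.percentile(once[r0:r1, c0:c1], 5)
                delta = np.abs(once[r0:r1, c0:c1] - twice[r0:r1, c0:c1])
                assert np.all(delta <= bound + 1e-9)


class TestDnaContent:
    def test_integrated_equals_sum(self):
        mask = nucleus_mask(radius=8)
        img = np.where(mask.labels == 1, 3.5, 0.0)
        out = integrated_dna(mask, img)
        area = (mask.labels == 1).sum()
        assert out["dna_integrated"].iloc[0] == pytest.approx(3.5 * area)

    def test_bimodal_centers(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(2e4, 1e3, 300), rng.normal(4e4, 2e3, 150)]
        )
        gates = dna_gates(vals)
        assert not gates.single_mode
        assert gates.center_4n / gates.center_2n == pytest.approx(2.0, rel=0.05)
        assert gates.classify(2e4) == "2N"
        assert gates.classify(3e4) == "intermediate"
        assert gates.classify(4e4) == "4N"

    def test_all_2n_flagged(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning, match="single DNA mode"):
            gates = dna_gates(rng.normal(2e4, 1e3, 200))
        assert gates.single_mode
        assert gates.center_4n is None


class TestClassifyPhase:
    def test_rule_table(self):
        phases = classify_phase(
            np.array([5.0, 5.0, 150.0, 5.0]),
            np.array(["2N", "4N", "intermediate", "intermediate"]),
            edu_threshold=50.0,
        )
        assert phases.tolist() == ["G0/G1", "G2/M", "S", "unclassified"]

    def test_planted_mixture_recovered(self):
        """Planted (0.5, 0.3, 0.2) phase mixture recovered within CIs."""
        from zincycle import analyze_edu_fields, generate_edu_pi_population

        mix = {"G0/G1": 0.5, "S": 0.3, "G2/M": 0.2}
        fields, _ = generate_edu_pi_population(400, mix,
                                               config=SyntheticConfig(seed=23))
        records = analyze_edu_fields(fields)
        frac = records["phase"].value_counts(normalize=True)
        n = len(records)
        for phase, p in mix.items():
            lo, hi = binom.interval(0.95, n, p)
            assert lo / n <= frac.get(phase, 0.0) <= hi / n

    def test_phase_fractions_partition(self):
        rng = np.random.default_rng(10)
        edu = rng.uniform(0, 200, 100)
        dna = rng.choice(["2N", "intermediate", "4N"], 100)
        phases = classify_phase(edu, dna, edu_threshold=100.0)
        counts = pd.Series(phases).value_counts(normalize=True)
        assert counts.sum() == pytest.approx(1.0)


class TestP21VsCdk2:
    def test_anticorrelated(self):
        rng = np.random.default_rng(11)
        ratio = rng.uniform(0.3, 2.0, 200)
        p21 = 100.0 / ratio + rng.normal(0, 2.0, 200)
        recs = pd.DataFrame(
            {"cell_id": np.arange(200), "cdk2_ratio": ratio, "p21_mean": p21}
        )
        table, dropped, rho = p21_vs_cdk2(recs)
        assert dropped == 0
        assert rho < -0.8

    def test_empty_input(self):
        table, dropped, rho = p21_vs_cdk2(pd.DataFrame())
        assert table.empty and dropped == 0 and rho is None

    def test_missing_channel_dropped_and_constant_undefined(self):
        recs = pd.DataFrame(
            {"cell_id": [0, 1, 2, 3], "cdk2_ratio": [1.0, 2.0, np.nan, 1.5],
             "p21_mean": [5.0, 5.0, 5.0, 5.0]}
        )
        table, dropped, rho = p21_vs_cdk2(recs)
        assert dropped == 1
        assert rho is None
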