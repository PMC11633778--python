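"""Background correction, segmentation, cell QC and focus QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import notchscreen as ns
from notchscreen import imaging as im
from notchscreen import synthdata as sd


def quadrant_means(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    return np.array(
        [
            a[: h // 2, : w // 2].mean(),
            a[: h // 2, w // 2 :].mean(),
            a[h // 2 :, : w // 2].mean(),
            a[h // 2 :, w // 2 :].mean(),
        ]
    )


class TestBackgroundCorrection:
    def test_flat_image_corrects_to_zero(self):
        img = im.FieldImage(channels={"x": np.full((128, 128), 300.0)})
        out = im.correct_background(img)
        assert out.channels["x"].max() == 0.0

    def test_unknown_method_rejected(self):
        img = im.FieldImage(channels={"x": np.zeros((128, 128))})
        with pytest.raises(ValueError, match="unknown"):
            im.correct_background(img, method="wavelet")

    def test_linear_gradient_removed(self):
        # quadrant means of the corrected gradient image must match those of
        # the corrected clean image (phalloidin channel drives segmentation)
        fld = sd.render_field(sd.NT_LIKE, 30, seed=3)
        img = ns.FieldImage.from_synthetic(fld)
        h, w = img.shape
        grad = np.linspace(0, 1, w)[None, :] * np.ones((h, 1)) * 500.0
        img_g = im.FieldImage(
            channels={k: v.astype(float) + grad for k, v in img.channels.items()}
        )
        q_before = quadrant_means(img_g.channels["phalloidin"])
        q_clean = quadrant_means(img.channels["phalloidin"].astype(float))
        assert np.max(np.abs(q_before - q_clean) / q_clean) > 0.20
        c = im.correct_background(img).channels["phalloidin"]
        cg = im.correct_background(img_g).channels["phalloidin"]
        assert np.max(np.abs(quadrant_means(cg) - quadrant_means(c)) / quadrant_means(c)) < 0.05

    def test_idempotent(self):
        fld = sd.render_field(sd.NT_LIKE, 20, seed=4)
        c1 = im.correct_background(ns.FieldImage.from_synthetic(fld))
        c2 = im.correct_background(c1)
        t1 = sum(v.sum() for v in c1.channels.values())
        t2 = sum(v.sum() for v in c2.channels.values())
        assert abs(t1 - t2) <= 0.01 * t1


class TestSegmentNuclei:
    def test_blank_field_yields_no_nuclei(self):
        rng = np.random.default_rng(0)
        blank = rng.normal(100, 10, (128, 128)).clip(0)
        assert im.segment_nuclei(blank).max() == 0

    def test_recovers_count_and_centroids(self, segmented_field):
        fld, img, seg, _ = segmented_field
        truth = fld.truth.nucleus_labels
        rec = seg.nucleus_labels
        assert rec.max() == truth.max()
        # centroid error < 2 px for each matched nucleus
        from scipy import ndimage as ndi

        t_cent = ndi.center_of_mass(truth > 0, truth, range(1, truth.max() + 1))
        r_cent = ndi.center_of_mass(rec > 0, rec, range(1, rec.max() + 1))
        for tc in t_cent:
            d = min(np.hypot(tc[0] - rc[0], tc[1] - rc[1]) for rc in r_cent)
            assert d < 2.0

    def test_two_nuclei_with_gap_not_merged(self):
        img = np.full((128, 128), 100.0)
        rr, cc = np.mgrid[0:128, 0:128]
        for cy, cx in ((60, 55), (60, 73)):  # 18 px apart, radius 7 -> 4 px gap
            img += 2500.0 * ((rr - cy) ** 2 + (cc - cx) ** 2 <= 49)
        labels = im.segment_nuclei(img)
        assert labels.max() == 2


class TestSegmentCells:
    def test_single_nucleus_uniform_phalloidin_claims_foreground(self):
        phal = np.full((128, 128), 500.0)
        nuclei = np.zeros((128, 128), np.int32)
        nuclei[60:68, 60:68] = 1
        seg = im.segment_cells(phal, nuclei)
        assert (seg.cell_labels == 1).sum() == 128 * 128
        assert not seg.excluded_region_mask.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            im.segment_cells(np.zeros((64, 64)), np.zeros((32, 32), np.int32))

    def test_cell_free_region_excluded(self):
        fld = sd.render_field(sd.NT_LIKE, 8, seed=2)
        seg, _ = ns.segment_field(ns.FieldImage.from_synthetic(fld))
        truth_bg = fld.truth.cell_labels == 0
        overlap = (seg.excluded_region_mask & truth_bg).sum() / truth_bg.sum()
        assert overlap >= 0.95

    def test_every_cell_has_exactly_one_nucleus(self, segmented_field):
        fld, img, seg, _ = segmented_field
        for cid in seg.cell_ids():
            nuc_ids = set(seg.nucleus_labels[seg.cell_labels == cid]) - {0}
            assert len(nuc_ids) == 1


class TestCompartments:
    def test_partition_identity(self, segmented_field):
        _, _, seg, _ = segmented_field
        for cid, comp in seg.compartments.items():
            cell = seg.cell_labels == cid
            union = comp["nucleus"] | comp["membrane_ring"] | comp["cytosol"]
            assert (union == cell).all()
            assert not (comp["nucleus"] & comp["membrane_ring"]).any()
            assert not (comp["nucleus"] & comp["cytosol"]).any()
            assert not (comp["membrane_ring"] & comp["cytosol"]).any()

    def test_zero_ring_width_means_cytosol_is_cell_minus_nucleus(self):
        fld = sd.render_field(sd.NT_LIKE, 6, seed=3, shape=(128, 128))
        img = ns.FieldImage.from_synthetic(fld)
        c = im.correct_background(img)
        nuclei = im.segment_nuclei(c.channels["DAPI"])
        seg = im.segment_cells(c.channels["phalloidin"], nuclei)
        seg = im.derive_compartments(seg, ring_width_px=0)
        for cid, comp in seg.compartments.items():
            cell = seg.cell_labels == cid
            assert not comp["membrane_ring"].any()
            assert (comp["cytosol"] == (cell & ~comp["nucleus"])).all()

    def test_membrane_phenotype_signal_lands_in_ring(self):
        ph = sd.PhenotypeSpec(1.0, 0.0, 0.0, spot_rate=0.0)
        fld = sd.render_field(ph, 8, seed=6)
        img = ns.FieldImage.from_synthetic(fld)
        seg, flags = ns.segment_field(img)
        notch = img.channels["NOTCH1"].astype(float)
        fracs = []
        for cid, comp in seg.compartments.items():
            if not flags[cid].passed:
                continue
            cell = seg.cell_labels == cid
            fracs.append(notch[comp["membrane_ring"]].sum() / notch[cell].sum())
        assert np.median(fracs) >= 0.80


class TestCellQC:
    def test_border_cells_flagged(self, segmented_field):
        _, img, seg, flags = segmented_field
        edge_ids = set(
            np.unique(
                np.concatenate(
                    [
                        seg.cell_labels[0, :],
                        seg.cell_labels[-1, :],
                        seg.cell_labels[:, 0],
                        seg.cell_labels[:, -1],
                    ]
                )
            )
        ) - {0}
        for cid in seg.cell_ids():
            assert flags[cid].border == (cid in edge_ids)

    def test_interior_cells_pass(self, segmented_field):
        _, _, seg, flags = segmented_field
        interior = [f for f in flags.values() if not f.border]
        assert any(f.passed for f in interior)

    def test_planted_saturated_cell_flagged(self, default_field):
        img = ns.FieldImage.from_synthetic(default_field)
        seg, flags0 = ns.segment_field(img)
        target = next(c for c in seg.cell_ids() if flags0[c].passed)
        notch = img.channels["NOTCH1"].copy()
        notch[seg.cell_labels == target] = 2**16 - 1
        img2 = im.FieldImage(channels={**img.channels, "NOTCH1": notch})
        flags = im.qc_cells(seg, img2)
        assert flags[target].saturated
        others = [c for c in seg.cell_ids() if c != target]
        assert not any(flags[c].saturated for c in others)

    def test_passed_means_no_flag(self, segmented_field):
        _, _, _, flags = segmented_field
        for f in flags.values():
            assert f.passed == not_any_flag(f)


def not_any_flag(f):
    return not (f.border or f.too_small or f.too_big or f.saturated or f.malformed)


class TestNucleusContrast:
    def test_constant_region_zero(self):
        img = np.full((32, 32), 77.0)
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        assert im.nucleus_contrast(img, mask) == 0.0

    def test_scale_invariance(self, default_field):
        dapi = default_field.channels["DAPI"].astype(float)
        mask = default_field.truth.nucleus_labels == 1
        c1 = im.nucleus_contrast(dapi, mask)
        c2 = im.nucleus_contrast(dapi * 3.7, mask)
        assert c1 == pytest.approx(c2, rel=1e-9)

    def test_blur_strictly_reduces_contrast(self):
        sharp = sd.render_field(sd.NT_LIKE, 10, seed=8)
        blurred = sd.render_field(sd.NT_LIKE, 10, seed=8, blur_sigma=4.0)
        d_s = sharp.channels["DAPI"].astype(float)
        d_b = blurred.channels["DAPI"].astype(float)
        for nid in range(1, 11):
            mask = sharp.truth.nucleus_labels == nid
            assert im.nucleus_contrast(d_b, mask) < im.nucleus_contrast(d_s, mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            im.nucleus_contrast(np.ones((8, 8)), np.zeros((8, 8), bool))


def oracle_fence(values, k=1.5):
    """Brute-force sort-and-interpolate quantiles."""
    xs = sorted(values)
    n = len(xs)

    def quant(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    q1, q3 = quant(0.25), quant(0.75)
    return q1, q3, q1 - k * (q3 - q1)


class TestLowerInnerFence:
    def test_constant_sequence(self):
        q1, q3, lif = im.lower_inner_fence([5.0] * 10)
        assert q1 == q3 == lif == 5.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            vals = rng.normal(size=rng.integers(4, 60)).tolist()
            got = im.lower_inner_fence(vals)
            want = oracle_fence(vals)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=50)
    )
    def test_oracle_equivalence_property(self, vals):
        got = im.lower_inner_fence(vals)
        want = oracle_fence(vals)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-6 * max(1.0, abs(w)))

    def test_high_outlier_lowers_fence(self):
        base = list(range(1, 21))
        _, _, lif0 = im.lower_inner_fence(base)
        _, _, lif1 = im.lower_inner_fence(base + [1000.0])
        assert lif1 < lif0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            im.lower_inner_fence([1.0, 2.0, 3.0])


class TestFocusClassification:
    def test_strict_majority_rule(self):
        # pooled distribution is dominated by values at 1.0 so LIF = 1.0;
        # a field with 6/10 nuclei below is out of focus, one with 5/10 not
        well = {
            0: np.array([1.0] * 40),
            1: np.array([0.5] * 6 + [1.0] * 4),
            2: np.array([0.5] * 5 + [1.0] * 5),
        }
        res = im.classify_fields_focus(well)
        assert res.lif == pytest.approx(1.0)
        assert res.out_of_focus[1]
        assert not res.out_of_focus[2]

    def test_all_sharp_fields_none_flagged(self):
        rng = np.random.default_rng(1)
        well = {f: rng.normal(0.7, 0.02, 20) for f in range(8)}
        res = im.classify_fields_focus(well)
        assert not any(res.out_of_focus.values())

    def test_empty_field_counts_as_out_of_focus(self):
        well = {0: np.full(30, 0.7), 1: np.array([])}
        res = im.classify_fields_focus(well)
        assert res.out_of_focus[1]
        assert res.fraction_below_lif[1] == 1.0

    def test_single_blurred_field_detected(self):
        # one defocused field of eight: contamination stays below the
        # fence's 25% breakdown and the field is caught
        rng = np.random.default_rng(3)
        hits = 0
        trials = 5
        for t in range(trials):
            contrasts = {}
            blur_field = int(rng.integers(8))
            for f in range(8):
                blur = 4.0 if f == blur_field else 0.0
                fld = sd.render_field(
                    sd.NT_LIKE,
                    int(rng.poisson(10)),
                    blur_sigma=blur,
                    seed=int(rng.integers(2**31)),
                    shape=(160, 160),
                    cell_radius_px=18.0,
                )
                img = ns.FieldImage.from_synthetic(fld)
                c = im.correct_background(img)
                nuc = im.segment_nuclei(c.channels["DAPI"])
                contrasts[f] = im.field_nucleus_contrasts(c.channels["DAPI"], nuc)
            res = im.classify_fields_focus(contrasts)
            flagged = {f for f, v in res.out_of_focus.items() if v}
            if flagged == {blur_field}:
                hits += 1
        assert hits >= trials - 1
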