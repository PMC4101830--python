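"""IHC quantification: OD transform, deconvolution, region/nuclear/vessel metrics."""

import numpy as np
import pytest

from prosmark.ihc import (
    RegionMasks,
    StainVectors,
    TISSUE_LABELS,
    deconvolve,
    microvessel_metrics,
    nuclear_metrics,
    od_to_intensity,
    region_metrics,
    rgb_to_od,
)
from prosmark.synthetic import SpotSimConfig, simulate_spot_image


class TestOpticalDensity:
    def test_formula_values(self):
        img = np.array([[[255, 24, 0]]], dtype=np.uint8)
        od = rgb_to_od(img)[0, 0]
        assert od[0] == pytest.approx(0.0)
        assert od[1] == pytest.approx(-np.log10(25 / 256), abs=1e-12)
        assert od[2] == pytest.approx(-np.log10(1 / 256), abs=1e-12)

    def test_monotone_decreasing_in_intensity(self):
        ramp = np.arange(256, dtype=np.uint8).reshape(1, 256, 1)
        od = rgb_to_od(ramp).ravel()
        assert np.all(np.diff(od) < 0)
        assert np.all(od >= 0)

    def test_rejects_non_uint8(self):
        with pytest.raises(ValueError, match="8-bit"):
            rgb_to_od(np.zeros((2, 2, 3), dtype=float))

    def test_round_trip_through_intensity(self):
        # 8-bit quantization keeps OD error < 0.01 over the staining range
        od = np.linspace(0, 1.0, 50)
        back = rgb_to_od(od_to_intensity(od)[..., None].repeat(3, -1))[..., 0]
        assert np.all(np.abs(back - od) < 0.01)


class TestDeconvolution:
    def test_pure_stain_pixel_recovered_exactly(self):
        v = StainVectors()
        c = 0.73
        od = (c * v.dab).reshape(1, 1, 3)
        conc, rmse = deconvolve(od, v, clamp=False)
        assert conc[0, 0, 1] == pytest.approx(c, abs=1e-9)
        assert conc[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert conc[0, 0, 2] == pytest.approx(0.0, abs=1e-9)
        assert rmse < 1e-12

    def test_white_pixel_all_zero(self):
        od = rgb_to_od(np.full((1, 1, 3), 255, dtype=np.uint8))
        conc, _ = deconvolve(od)
        assert np.allclose(conc, 0.0, atol=1e-12)

    def test_compose_then_deconvolve_identity(self):
        """Noise-free two-stain mixtures invert to machine precision."""
        rng = np.random.default_rng(0)
        v = StainVectors()
        ch = rng.uniform(0, 1.2, (5, 5))
        cd = rng.uniform(0, 1.2, (5, 5))
        od = ch[..., None] * v.hematoxylin + cd[..., None] * v.dab
        conc, _ = deconvolve(od, v)
        assert np.allclose(conc[..., 0], ch, atol=1e-10)
        assert np.allclose(conc[..., 1], cd, atol=1e-10)

    def test_collinear_vectors_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            StainVectors(hematoxylin=[1, 0, 0], dab=[1, 0, 0])


class TestRegionMetrics:
    def _masks(self, shape, label="tumor_epithelium"):
        return RegionMasks(
            tissue_class=np.full(shape, TISSUE_LABELS[label], dtype=int)
        )

    def test_all_zero_dab(self):
        m = region_metrics(np.zeros((4, 4)), self._masks((4, 4)), threshold=0.1)
        assert (m.avg_od, m.pct_pos, m.score) == (0.0, 0.0, 0.0)

    def test_half_positive_by_construction(self):
        dab = np.zeros((2, 4))
        dab[:, :2] = 0.8
        m = region_metrics(dab, self._masks((2, 4)), threshold=0.1)
        assert m.avg_od == pytest.approx(0.4)
        assert m.pct_pos == pytest.approx(50.0)
        assert m.score == pytest.approx(20.0)

    def test_empty_region_missing_flagged(self):
        m = region_metrics(np.ones((3, 3)), self._masks((3, 3), "stroma"),
                           region="tumor_epithelium")
        assert m.missing and np.isnan(m.avg_od)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        dab = rng.uniform(0, 1, (6, 6))
        masks = self._masks((6, 6))
        m1 = region_metrics(dab, masks)
        perm = dab.ravel()[rng.permutation(36)].reshape(6, 6)
        m2 = region_metrics(perm, masks)
        assert m1.avg_od == pytest.approx(m2.avg_od)
        assert m1.pct_pos == pytest.approx(m2.pct_pos)

    def test_score_is_product(self):
        rng = np.random.default_rng(1)
        dab = rng.uniform(0, 1.5, (8, 8))
        m = region_metrics(dab, self._masks((8, 8)))
        assert m.score == m.avg_od * m.pct_pos


class TestNuclearMetrics:
    def test_two_nuclei_example(self):
        nuclei = np.array([[1, 1, 0], [2, 2, 0]])
        dab = np.array([[1.0, 1.0, 0.3], [0.0, 0.0, 0.9]])
        masks = RegionMasks(tissue_class=np.ones((2, 3), int), nuclei=nuclei)
        m = nuclear_metrics(dab, masks, threshold=0.5)
        assert m.avg_nuclear_od == pytest.approx(0.5)
        assert m.pct_pos_nuclei == pytest.approx(50.0)
        assert m.score == pytest.approx(25.0)

    def test_uniform_nuclei(self):
        nuclei = np.array([[1, 2, 3]])
        dab = np.full((1, 3), 0.7)
        masks = RegionMasks(tissue_class=np.ones((1, 3), int), nuclei=nuclei)
        m = nuclear_metrics(dab, masks, threshold=0.2)
        assert (m.avg_nuclear_od, m.pct_pos_nuclei) == (pytest.approx(0.7), 100.0)
        assert m.score == pytest.approx(70.0)

    def test_brute_force_loop_agreement(self):
        """Vectorised per-nucleus means agree with an explicit pixel loop."""
        rng = np.random.default_rng(17)
        nuclei = rng.integers(0, 6, size=(12, 12))
        dab = rng.uniform(0, 1.2, (12, 12))
        masks = RegionMasks(tissue_class=np.ones((12, 12), int), nuclei=nuclei)
        m = nuclear_metrics(dab, masks, threshold=0.5)
        means = []
        for nid in sorted(set(nuclei.ravel()) - {0}):
            vals = [dab[i, j] for i in range(12) for j in range(12)
                    if nuclei[i, j] == nid]
            means.append(sum(vals) / len(vals))
        assert m.avg_nuclear_od == pytest.approx(float(np.mean(means)))
        assert m.pct_pos_nuclei == pytest.approx(
            100.0 * np.mean([mu >= 0.5 for mu in means])
        )

    def test_no_nuclei_missing_flagged(self):
        masks = RegionMasks(tissue_class=np.ones((2, 2), int),
                            nuclei=np.zeros((2, 2), int))
        assert nuclear_metrics(np.ones((2, 2)), masks).missing


class TestMicrovesselMetrics:
    def test_square_vessels_no_lumen(self):
        vessels = np.zeros((12, 12), int)
        vessels[1:4, 1:4] = 1    # 3x3
        vessels[5:10, 5:10] = 2  # 5x5
        masks = RegionMasks(tissue_class=np.ones((12, 12), int), vessels=vessels)
        m = microvessel_metrics(masks, tumor_area=144)
        assert m.avg_vessel_area == pytest.approx(17.0)
        assert m.avg_lumen_area == 0.0
        assert m.avg_vessel_perimeter == pytest.approx((12 + 20) / 2)

    def test_lumen_subtraction(self):
        vessels = np.zeros((8, 8), int)
        vessels[2:6, 2:6] = 1  # 16 px
        lumen = np.zeros((8, 8), int)
        lumen[3:5, 3:5] = 1    # 4 px
        masks = RegionMasks(tissue_class=np.ones((8, 8), int), vessels=vessels,
                            lumen=lumen)
        m = microvessel_metrics(masks, tumor_area=64)
        assert m.avg_vascular_area == pytest.approx(12.0)
        assert m.avg_vascular_area <= m.avg_vessel_area

    def test_density(self):
        vessels = np.zeros((50, 20), int)
        for k in range(5):
            vessels[k * 9 + 1, 3] = k + 1
        masks = RegionMasks(tissue_class=np.ones((50, 20), int), vessels=vessels)
        m = microvessel_metrics(masks, tumor_area=1000)
        assert m.microvessel_density == pytest.approx(0.005)

    def test_zero_vessels(self):
        masks = RegionMasks(tissue_class=np.ones((4, 4), int),
                            vessels=np.zeros((4, 4), int))
        m = microvessel_metrics(masks, tumor_area=16)
        assert m.microvessel_density == 0.0
        assert np.isnan(m.avg_vessel_area)


@pytest.mark.parametrize("layout", ["epithelium_only", "epithelium_stroma", "nuclei"])
def test_generator_round_trip_within_one_percent(layout):
    """Quantifying a synthesized spot recovers the generator's truth <1%."""
    cfg = SpotSimConfig(tissue_layout=layout, seed=3)
    rgb, masks, truth = simulate_spot_image(cfg)
    conc, _ = deconvolve(rgb_to_od(rgb))
    dab = conc[..., 1]
    if layout == "nuclei":
        m = nuclear_metrics(dab, masks, truth["threshold"])
        t = truth["nuclear"]
        assert m.score == pytest.approx(t["score"], rel=0.01)
    else:
        m = region_metrics(dab, masks, "tumor_epithelium", truth["threshold"])
        t = truth["tumor_epithelium"]
        assert m.avg_od == pytest.approx(t["avg_od"], rel=0.01)
        assert m.pct_pos == pytest.approx(t["pct_pos"], rel=0.01)
        assert m.score == pytest.approx(t["score"], rel=0.01)
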