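"""Statistical structure and determinism of the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

from dyam.radiomics import dice
from dyam.records import MODALITIES
from dyam.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_ihc_image,
    generate_lesion_volume,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"responder_prevalence": 1.2},
            {"p_segmentable": -0.1},
            {"lesion_count_range": (0, 4)},
            {"median_pfs_months": 0.0},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_scalar_effect_broadcast(self):
        cfg = CohortConfig(effect_sizes=0.0)
        assert set(cfg.effect_sizes.values()) == {0.0}


class TestCohort:
    def test_fixed_seed_byte_identical(self):
        a = generate_cohort(CohortConfig(n_patients=40, seed=3))
        b = generate_cohort(CohortConfig(n_patients=40, seed=3))
        for ra, rb in zip(a, b):
            assert ra.patient_id == rb.patient_id
            assert ra.response == rb.response
            assert ra.pfs_months == rb.pfs_months
            np.testing.assert_array_equal(ra.genomic_features, rb.genomic_features)
            if ra.ihc_features is not None:
                np.testing.assert_array_equal(ra.ihc_features, rb.ihc_features)
            if ra.lesion_bag is not None:
                for la, lb in zip(ra.lesion_bag, rb.lesion_bag):
                    np.testing.assert_array_equal(la.features, lb.features)

    def test_responder_prevalence_within_binomial_noise(self):
        n = 10000
        cohort = generate_cohort(CohortConfig(n_patients=n, seed=0))
        frac = sum(r.response for r in cohort) / n
        sd = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) <= 3 * sd

    def test_full_presence_when_missingness_off(self):
        cohort = generate_cohort(CohortConfig(n_patients=50, p_segmentable=1.0,
                                              p_pdl1_positive=1.0, seed=1))
        for rec in cohort:
            assert rec.lesion_bag is not None
            assert rec.ihc_features is not None and rec.tps is not None
            assert rec.presence_mask["genomics"]

    def test_missingness_rates_bernoulli(self):
        n = 5000
        cohort = generate_cohort(CohortConfig(n_patients=n, seed=5))
        seg = sum(r.lesion_bag is not None for r in cohort)
        pos = sum(r.tps is not None for r in cohort)
        for count, p in ((seg, 0.76), (pos, 0.52)):
            chi2 = stats.chisquare([count, n - count], [n * p, n * (1 - p)])
            assert chi2.pvalue > 0.01

    def test_presence_mask_consistent_with_blocks(self):
        cohort = generate_cohort(CohortConfig(n_patients=60, seed=2))
        for rec in cohort:
            mask = rec.presence_mask
            assert set(mask) == set(MODALITIES)
            assert mask["ihc"] == (rec.ihc_features is not None)
            sites = rec.lesion_bag.sites() if rec.lesion_bag else set()
            assert mask["ct_parenchymal"] == ("parenchymal" in sites)
            assert 1 <= len(rec.lesion_bag) <= 6 if rec.lesion_bag else True

    def test_zero_effect_features_independent_of_label(self):
        """With all effect sizes zero, per-feature distributions match between
        classes (two-sample KS, Bonferroni-corrected)."""
        cohort = generate_cohort(CohortConfig(n_patients=2000, effect_sizes=0.0, seed=7))
        y = np.array([r.response for r in cohort])
        pvals = []
        gen = np.stack([r.genomic_features for r in cohort])
        pvals.append(stats.ks_2samp(gen[y == 1, -1], gen[y == 0, -1]).pvalue)  # TMB
        tps = np.array([r.tps for r in cohort if r.tps is not None])
        ytps = np.array([r.response for r in cohort if r.tps is not None])
        pvals.append(stats.ks_2samp(tps[ytps == 1], tps[ytps == 0]).pvalue)
        ihc = np.stack([r.ihc_features for r in cohort if r.ihc_features is not None])
        for k in range(ihc.shape[1]):
            pvals.append(stats.ks_2samp(ihc[ytps == 1, k], ihc[ytps == 0, k]).pvalue)
        assert min(pvals) > 0.01 / len(pvals)

    def test_nonresponder_pfs_median_calibrated(self):
        cohort = generate_cohort(CohortConfig(n_patients=4000, seed=9, followup_months=1e6))
        t = np.array([r.pfs_months for r in cohort if r.response == 0])
        # uncensored exponential: sample median ~ 2.7 months
        assert np.median(t) == pytest.approx(2.7, rel=0.15)
        t_resp = np.array([r.pfs_months for r in cohort if r.response == 1])
        assert np.median(t_resp) > np.median(t)


class TestLesionVolume:
    def test_deterministic(self):
        v1, m1 = generate_lesion_volume("pleural", seed=8)
        v2, m2 = generate_lesion_volume("pleural", seed=8)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(m1, m2)

    def test_mask_nonempty_within_grid(self):
        for site in ("parenchymal", "pleural", "node"):
            vol, mask = generate_lesion_volume(site, seed=1)
            assert mask.sum() > 0
            assert mask.shape == vol.shape

    def test_mask_connected(self):
        from scipy import ndimage

        _, mask = generate_lesion_volume("node", seed=3)
        _, n_components = ndimage.label(mask)
        assert n_components == 1

    def test_different_seeds_differ(self):
        _, m1 = generate_lesion_volume("parenchymal", seed=1)
        _, m2 = generate_lesion_volume("parenchymal", seed=2)
        assert dice(m1, m2) < 1.0

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            generate_lesion_volume("liver", seed=0)


class TestIHCImage:
    def test_zero_tps_no_stained_pixels(self):
        from dyam.ihc import deconvolve_stain

        img, mask = generate_ihc_image(0.0, seed=4, size=64)
        maps = deconvolve_stain(img, mask)
        # DAB optical density inside the mask stays at counterstain level only
        hema = maps.hematoxylin_intensity[mask]
        dab = maps.dab_intensity[mask]
        assert (dab < hema).mean() > 0.99

    def test_stained_fraction_tracks_tps(self):
        img, mask = generate_ihc_image(0.5, seed=6, size=128)
        # stained cells are browner: red channel well above blue
        stained = (img[..., 0] - img[..., 2] > 0.1) & mask
        blue = (img[..., 2] - img[..., 0] > 0.1) & mask
        frac = stained.sum() / (stained.sum() + blue.sum())
        n_cells = (128 // 8) ** 2
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n_cells)

    def test_deterministic(self):
        i1, m1 = generate_ihc_image(0.3, seed=5, size=48)
        i2, m2 = generate_ihc_image(0.3, seed=5, size=48)
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(m1, m2)

    def test_invalid_tps(self):
        with pytest.raises(ValueError):
            generate_ihc_image(1.5, seed=0)
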