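"""Co-localisation pipeline: filters, threshold rule, Manders, PCC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropletkit import (
    ColocConfig,
    SyntheticParams,
    colocalize,
    compute_threshold,
    manders_coefficients,
    pearson_correlation,
    preprocess_channel,
    render_image,
    sample_droplet_field,
)

# ---------------------------------------------------------------- oracles


def manders_oracle(a, b, t_a, t_b):
    """Naive per-pixel double loop; the reference for M1/M2."""
    num1 = den1 = num2 = den2 = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            in_a = a[i, j] > t_a
            in_b = b[i, j] > t_b
            if in_a:
                den1 += a[i, j]
                if in_b:
                    num1 += a[i, j]
            if in_b:
                den2 += b[i, j]
                if in_a:
                    num2 += b[i, j]
    m1 = num1 / den1 if den1 > 0 else 0.0
    m2 = num2 / den2 if den2 > 0 else 0.0
    return m1, m2


def pcc_oracle(a, b):
    """Definition-level Σ-of-deviations Pearson correlation."""
    am, bm = a.mean(), b.mean()
    num = sa = sb = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            num += (a[i, j] - am) * (b[i, j] - bm)
            sa += (a[i, j] - am) ** 2
            sb += (b[i, j] - bm) ** 2
    return num / np.sqrt(sa * sb)


# ------------------------------------------------------------ preprocess


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 42.0)
        out = preprocess_channel(img, ColocConfig())
        assert np.allclose(out, 42.0)

    def test_impulse_removed_by_median(self):
        img = np.full((15, 15), 10.0)
        img[7, 7] = 250.0
        out = preprocess_channel(img, ColocConfig(wiener_kernel=1))
        assert out[7, 7] == 10.0

    def test_unit_kernels_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (20, 20))
        out = preprocess_channel(img, ColocConfig(median_kernel=1, wiener_kernel=1))
        assert np.allclose(out, img)

    @pytest.mark.parametrize("kw", [{"median_kernel": 2}, {"wiener_kernel": 4}])
    def test_even_kernel_rejected(self, kw):
        with pytest.raises(ValueError):
            ColocConfig(**kw)


# ------------------------------------------------------------- threshold


class TestThreshold:
    def test_hand_computed_value(self):
        img = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
        assert compute_threshold(img, k=2) == pytest.approx(10.0)
        # strict exceedance: the single bright pixel sits AT the threshold
        assert not (img > compute_threshold(img, k=2)).any()

    def test_constant_image_degenerate(self):
        img = np.full((8, 8), 5.0)
        assert compute_threshold(img, k=2) == 5.0
        assert not (img > 5.0).any()

    def test_k_zero_is_mean(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        assert compute_threshold(img, k=0) == pytest.approx(img.mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(np.empty((0,)))

    def test_population_sigma(self):
        img = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_threshold(img, k=1) == pytest.approx(
            img.mean() + img.std(ddof=0)
        )


# --------------------------------------------------------------- manders


class TestManders:
    def test_identical_images(self):
        img = np.array([[10.0, 0.0], [10.0, 0.0]])
        m1, m2, _ = manders_coefficients(img, img, 5.0, 5.0)
        assert (m1, m2) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.array([[10.0, 0.0]])
        b = np.array([[0.0, 10.0]])
        m1, m2, _ = manders_coefficients(a, b, 5.0, 5.0)
        assert (m1, m2) == (0.0, 0.0)

    def test_hand_enumeration(self):
        a = np.array([[10.0, 0.0, 10.0, 0.0]])
        b = np.array([[0.0, 0.0, 10.0, 10.0]])
        m1, m2, det = manders_coefficients(a, b, 5.0, 5.0)
        assert m1 == pytest.approx(0.5)
        assert m2 == pytest.approx(0.5)
        assert det["n_overlap"] == 1

    def test_empty_mask_flagged(self):
        a = np.zeros((4, 4))
        b = np.ones((4, 4)) * 10
        m1, m2, det = manders_coefficients(a, b, 5.0, 5.0)
        assert m1 == 0.0
        assert "empty_mask_A" in det["flags"]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            manders_coefficients(np.zeros((2, 2)), np.zeros((3, 3)), 0, 0)


class TestPearson:
    def test_affine_relation(self):
        a = np.arange(12, dtype=float).reshape(3, 4)
        assert pearson_correlation(a, 2 * a + 3) == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = np.arange(12, dtype=float).reshape(3, 4)
        assert pearson_correlation(a, -a) == pytest.approx(-1.0)

    def test_hand_value(self):
        a = np.array([[1.0, 2.0, 3.0, 4.0]])
        b = np.array([[1.0, 3.0, 2.0, 4.0]])
        assert pearson_correlation(a, b) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones((3, 3)), np.arange(9.0).reshape(3, 3))


# -------------------------------------------------- oracle equivalence


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    rows=st.integers(1, 8),
    cols=st.integers(1, 8),
    seed=st.integers(0, 2**20),
    frac_a=st.floats(0.0, 1.0),
    frac_b=st.floats(0.0, 1.0),
)
def test_manders_matches_double_loop_oracle(rows, cols, seed, frac_a, frac_b):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 256, (rows, cols)).astype(float)
    b = rng.integers(0, 256, (rows, cols)).astype(float)
    t_a = float(np.quantile(a, frac_a))
    t_b = float(np.quantile(b, frac_b))
    m1, m2, _ = manders_coefficients(a, b, t_a, t_b)
    o1, o2 = manders_oracle(a, b, t_a, t_b)
    assert m1 == pytest.approx(o1, abs=1e-12)
    assert m2 == pytest.approx(o2, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(rows=st.integers(2, 8), cols=st.integers(2, 8), seed=st.integers(0, 2**20))
def test_pcc_matches_double_loop_oracle(rows, cols, seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 256, (rows, cols)).astype(float)
    b = rng.integers(0, 256, (rows, cols)).astype(float)
    if a.std() == 0 or b.std() == 0:
        return
    assert pearson_correlation(a, b) == pytest.approx(pcc_oracle(a, b), abs=1e-12)


# ------------------------------------------------------------ invariants


class TestScaleInvariance:
    def test_scaling_one_channel_preserves_scores(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 200, (32, 32))
        b = rng.uniform(0, 200, (32, 32))
        t_a, t_b = compute_threshold(a), compute_threshold(b)
        m1, m2, _ = manders_coefficients(a, b, t_a, t_b)
        c = 3.7
        m1s, m2s, _ = manders_coefficients(c * a, b, compute_threshold(c * a), t_b)
        assert m1s == pytest.approx(m1)
        assert m2s == pytest.approx(m2)
        assert pearson_correlation(c * a, b) == pytest.approx(pearson_correlation(a, b))
        # mask itself is unchanged: μ and σ both scale by c
        assert np.array_equal(a > t_a, c * a > compute_threshold(c * a))


class TestColocalizeEndToEnd:
    def _image(self, coloc_fraction, seed=3):
        p = SyntheticParams(
            image_shape=(192, 192),
            n_droplets=30,
            poisson_counts=False,
            coloc_fraction=coloc_fraction,
            gaussian_sd=2.0,
            shot_noise_scale=0.1,
            n_nuclei=0,
            seed=seed,
        )
        return render_image(sample_droplet_field(p), p)

    def test_full_colocalisation(self):
        res = colocalize(self._image(1.0), "protein", "droplet")
        assert res.M1 >= 0.9 and res.M2 >= 0.9

    def test_no_colocalisation(self):
        res = colocalize(self._image(0.0), "protein", "droplet")
        assert res.M2 <= 0.1

    def test_identity_channels(self):
        res = colocalize(self._image(0.5), "droplet", "droplet")
        assert res.M1 == pytest.approx(1.0)
        assert res.M2 == pytest.approx(1.0)
        assert res.PCC == pytest.approx(1.0)

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            colocalize(self._image(0.5), "droplet", "missing")

    def test_m2_monotone_in_true_fraction(self):
        # M2 with A=protein, B=droplet: fraction of droplet fluorescence
        # at protein signal — the estimator of the true labelled fraction
        estimates = [
            colocalize(self._image(f, seed=9), "protein", "droplet").M2
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert estimates == sorted(estimates)

    def test_overlap_bounded_by_mask_sizes(self):
        res = colocalize(self._image(0.5), "protein", "droplet")
        assert res.n_overlap <= min(res.n_signal_A, res.n_signal_B)

    def test_pcc_union_region_variant(self):
        img = self._image(0.5)
        cfg = ColocConfig(pcc_region="union_of_masks")
        res = colocalize(img, "protein", "droplet", cfg)
        assert -1.0 <= res.PCC <= 1.0
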