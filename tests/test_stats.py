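"""Group statistics: Hotelling T², permutation tests, Levene battery,
discriminant mapping.  Oracles are coded independently inline."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from shapecorr.shapespace import ShapeMatrix, center_and_scale, fit_pca
from shapecorr.stats import (
    group_mean_shape,
    hotelling_t2,
    levene_tests,
    map_discriminant,
    parametric_p,
    permutation_p,
)


def t2_oracle(a, b):
    """Independent direct-formula evaluation of the two-sample T²."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    na, nb = len(a), len(b)
    mu_a, mu_b = a.mean(0), b.mean(0)
    sa = sum(np.outer(r - mu_a, r - mu_a) for r in a)
    sb = sum(np.outer(r - mu_b, r - mu_b) for r in b)
    d = mu_a - mu_b
    w = np.linalg.inv(sa + sb) @ d
    return na * nb * (na + nb - 2) / (na + nb) * d @ w


# ---------------------------------------------------------------- hotelling


def test_t2_zero_for_identical_means():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(6, 3))
    a = a - a.mean(0)  # mean exactly zero
    b = rng.normal(size=(7, 3))
    b = b - b.mean(0)
    t2, w = hotelling_t2(a, b)
    assert t2 == pytest.approx(0.0, abs=1e-18)
    np.testing.assert_allclose(w, 0.0, atol=1e-12)


def test_t2_m1_equals_squared_t():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = rng.normal(size=(rng.integers(4, 10), 1))
        b = rng.normal(loc=0.5, size=(rng.integers(4, 10), 1))
        t2, _ = hotelling_t2(a, b)
        t_stat, _ = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=True)
        assert t2 == pytest.approx(t_stat**2, abs=1e-10)


def test_t2_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = rng.normal(size=(5, 3))
        b = rng.normal(loc=0.3, size=(6, 3))
        t2, _ = hotelling_t2(a, b)
        assert t2 == pytest.approx(t2_oracle(a, b), abs=1e-10)


def test_t2_as_printed_prefactor():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=(5, 2)), rng.normal(size=(6, 2))
    t_std, w_std = hotelling_t2(a, b, prefactor="standard")
    t_p, w_p = hotelling_t2(a, b, prefactor="as_printed")
    na, nb = 5, 6
    assert t_p == pytest.approx(t_std * (na + nb) / (na * nb), rel=1e-12)
    np.testing.assert_allclose(w_p, w_std, atol=0)
    with pytest.raises(ValueError, match="prefactor"):
        hotelling_t2(a, b, prefactor="bogus")


def test_t2_insufficient_samples():
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError, match="reduce the mode count"):
        hotelling_t2(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)))


def test_t2_label_swap_antisymmetry():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=(6, 3)), rng.normal(loc=1.0, size=(7, 3))
    t_ab, w_ab = hotelling_t2(a, b)
    t_ba, w_ba = hotelling_t2(b, a)
    assert t_ab == pytest.approx(t_ba, rel=1e-12)
    np.testing.assert_allclose(w_ba, -w_ab, atol=1e-12)


# --------------------------------------------------------------- parametric


def test_parametric_p_null_statistic():
    assert parametric_p(0.0, 10, 10, 3) == pytest.approx(1.0)


def test_parametric_p_monotone():
    ps = [parametric_p(t2, 10, 12, 3) for t2 in (0.5, 1.0, 2.0, 5.0, 20.0)]
    assert all(b < a for a, b in zip(ps, ps[1:]))


def test_parametric_p_dof_validation():
    with pytest.raises(ValueError):
        parametric_p(1.0, 2, 2, 3)


def test_parametric_type_one_error_calibrated():
    # multivariate normal null: rejection at alpha=.05 must be ~5%
    rng = np.random.default_rng(6)
    m, n = 3, 15
    rejections = 0
    reps = 2000
    for _ in range(reps):
        a = rng.normal(size=(n, m))
        b = rng.normal(size=(n, m))
        t2, _ = hotelling_t2(a, b)
        if parametric_p(t2, n, n, m) < 0.05:
            rejections += 1
    assert 0.035 <= rejections / reps <= 0.065


# -------------------------------------------------------------- permutation


def test_permutation_exhaustive_matches_enumeration():
    rng = np.random.default_rng(7)
    a = rng.normal(size=(3, 2))
    b = rng.normal(loc=1.5, size=(3, 2))
    res = permutation_p(a, b, n_perms=100, seed=0)
    assert res.exhaustive and res.n_perms == 20
    # independent enumeration oracle over all C(6,3)=20 assignments
    x = np.vstack([a, b])
    t_obs = t2_oracle(a, b)
    count = 0
    for combo in itertools.combinations(range(6), 3):
        ia = list(combo)
        ib = [i for i in range(6) if i not in combo]
        if t2_oracle(x[ia], x[ib]) >= t_obs - 1e-12:
            count += 1
    assert res.p == pytest.approx(count / 20, abs=0)


def test_permutation_degenerate_null_p_one():
    base = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
    res = permutation_p(base, base.copy(), n_perms=100, seed=0)
    assert res.p == pytest.approx(1.0)


def test_permutation_extreme_observation_min_p():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(8, 1))
    b = rng.normal(loc=100.0, size=(8, 1))  # separation no permutation matches
    n_perms = 200
    res = permutation_p(a, b, n_perms=n_perms, seed=1)
    assert not res.exhaustive
    assert res.p <= 3 / (1 + n_perms)  # only re-draws of the true split tie


def test_permutation_prefactor_invariance():
    rng = np.random.default_rng(9)
    a = rng.normal(size=(8, 3))
    b = rng.normal(loc=0.5, size=(9, 3))
    p1 = permutation_p(a, b, n_perms=300, seed=5, prefactor="standard").p
    p2 = permutation_p(a, b, n_perms=300, seed=5, prefactor="as_printed").p
    assert p1 == p2  # bit-identical


def test_permutation_label_symmetry():
    rng = np.random.default_rng(10)
    a = rng.normal(size=(3, 2))
    b = rng.normal(loc=1.0, size=(3, 2))
    assert permutation_p(a, b, n_perms=100, seed=0).p == permutation_p(
        b, a, n_perms=100, seed=0
    ).p


def test_permutation_validation():
    rng = np.random.default_rng(11)
    with pytest.raises(ValueError):
        permutation_p(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), n_perms=50)


def test_permutation_parametric_agreement():
    # under multivariate-normal nulls both p-values estimate the same thing
    rng = np.random.default_rng(12)
    m, n, reps = 3, 15, 200
    diffs = []
    for i in range(reps):
        a = rng.normal(size=(n, m))
        b = rng.normal(size=(n, m))
        t2, _ = hotelling_t2(a, b)
        pp = parametric_p(t2, n, n, m)
        pe = permutation_p(a, b, n_perms=2000, seed=i).p
        diffs.append(abs(pp - pe))
    assert np.mean(diffs) < 0.03


# ------------------------------------------------------------- discriminant


def _model_from_components(e):
    d, r = e.shape
    return __import__("shapecorr.shapespace", fromlist=["PCAModel"]).PCAModel(
        mean=np.zeros(d),
        components=e,
        eigenvalues=np.ones(r),
        loadings=np.zeros((3, r)),
        m=r,
    )


def test_map_discriminant_zero():
    e = np.linalg.qr(np.random.default_rng(13).normal(size=(12, 4)))[0]
    w_hat, arrows = map_discriminant(np.zeros(2), _model_from_components(e))
    assert np.all(w_hat == 0) and np.all(arrows == 0)
    assert arrows.shape == (4, 3)


def test_map_discriminant_identity_basis():
    e = np.eye(6)
    w = np.array([1.0, -2.0, 3.0, 0.5, 0.0, 1.5])
    w_hat, _ = map_discriminant(w, _model_from_components(e))
    np.testing.assert_allclose(w_hat, w, atol=0)


def test_map_discriminant_round_trip():
    rng = np.random.default_rng(14)
    e = np.linalg.qr(rng.normal(size=(30, 7)))[0]
    model = _model_from_components(e)
    w = rng.normal(size=4)
    w_hat, arrows = map_discriminant(w, model)
    w_tilde = e.T @ w_hat
    np.testing.assert_allclose(w_tilde[:4], w, atol=1e-12)
    np.testing.assert_allclose(w_tilde[4:], 0.0, atol=1e-12)
    # components beyond the retained subspace vanish
    np.testing.assert_allclose(arrows.ravel(), w_hat, atol=0)


def test_map_discriminant_dimension_mismatch():
    e = np.eye(6)[:, :2]
    with pytest.raises(ValueError):
        map_discriminant(np.ones(3), _model_from_components(e))


# ------------------------------------------------------------------ levene


def test_levene_null_translation_calibrated():
    rng = np.random.default_rng(15)
    rejections = 0
    reps = 1000
    for i in range(reps):
        a = rng.normal(size=(12, 2))
        b = rng.normal(size=(12, 2)) + 5.0  # same spread, shifted
        res = levene_tests(a, b, n_perms=200, seed=i)
        if res.mean_p < 0.05:
            rejections += 1
    assert rejections / reps <= 0.07


def test_levene_detects_dilation():
    rng = np.random.default_rng(16)
    hits = 0
    reps = 40
    for i in range(reps):
        a = rng.normal(size=(50, 2))
        b = 3.0 * rng.normal(size=(50, 2))  # dilated 3x about its center
        res = levene_tests(a, b, n_perms=500, seed=i)
        if res.mean_p < 0.01:
            hits += 1
    assert hits / reps >= 0.95


def test_levene_randomized_exhaustive_tiny_case():
    rng = np.random.default_rng(17)
    a = rng.normal(size=(3, 2))
    b = 2.0 * rng.normal(size=(3, 2))
    res = levene_tests(a, b, n_perms=1000, seed=0)

    # independent enumeration oracle on the pooled deviations
    def dev(x, center):
        c = x.mean(0) if center == "mean" else np.median(x, axis=0)
        return np.linalg.norm(x - c, axis=1)

    for center, got in (("mean", res.randomized_mean_p), ("median", res.randomized_median_p)):
        da, db = dev(a, center), dev(b, center)
        pooled = np.concatenate([da, db])

        def tstat(u, v):
            sp2 = (((u - u.mean()) ** 2).sum() + ((v - v.mean()) ** 2).sum()) / (
                len(u) + len(v) - 2
            )
            return abs(u.mean() - v.mean()) / np.sqrt(sp2 * (1 / len(u) + 1 / len(v)))

        t_obs = tstat(da, db)
        count = sum(
            tstat(pooled[list(c)], pooled[[i for i in range(6) if i not in c]])
            >= t_obs - 1e-12
            for c in itertools.combinations(range(6), 3)
        )
        assert got == pytest.approx(count / 20, abs=0)


def test_levene_all_zero_deviations():
    a = np.ones((4, 2))
    b = np.full((5, 2), 3.0)
    res = levene_tests(a, b, n_perms=200, seed=0)
    assert res.mean_p == 1.0 and res.median_p == 1.0


def test_levene_validation():
    rng = np.random.default_rng(18)
    with pytest.raises(ValueError, match="at least 3"):
        levene_tests(rng.normal(size=(2, 2)), rng.normal(size=(5, 2)))


def test_levene_deterministic_given_seed():
    rng = np.random.default_rng(19)
    a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
    r1 = levene_tests(a, b, n_perms=300, seed=4)
    r2 = levene_tests(a, b, n_perms=300, seed=4)
    assert r1 == r2


# --------------------------------------------------------------- mean shape


def _sm(pos, groups):
    return center_and_scale(pos, groups)


def test_group_mean_single_member():
    pos = np.random.default_rng(20).normal(size=(3, 8, 3))
    sm = _sm(pos, ["a", "b", "b"])
    np.testing.assert_allclose(
        group_mean_shape(sm, "a").ravel(), sm.X[0], atol=0
    )


def test_group_mean_symmetric_pair():
    base = np.random.default_rng(21).normal(size=(8, 3))
    base -= base.mean(0)
    base /= np.sqrt((base**2).sum(-1).mean())
    v = 0.01 * np.random.default_rng(22).normal(size=(8, 3))
    sm = ShapeMatrix(
        X=np.stack([(base + v).ravel(), (base - v).ravel()]),
        groups=np.array(["g", "g"]),
        centroids=np.zeros((2, 3)),
        scales=np.ones(2),
    )
    np.testing.assert_allclose(group_mean_shape(sm, "g"), base, atol=1e-12)


def test_group_mean_everyone_equals_pca_mean():
    pos = np.random.default_rng(23).normal(size=(6, 10, 3))
    sm = _sm(pos, ["g"] * 6)
    model = fit_pca(sm)
    np.testing.assert_allclose(
        group_mean_shape(sm, "g").ravel(), model.mean, atol=1e-12
    )


def test_group_mean_empty_group():
    sm = _sm(np.random.default_rng(24).normal(size=(3, 5, 3)), ["a", "a", "b"])
    with pytest.raises(ValueError, match="empty group"):
        group_mean_shape(sm, "zzz")
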