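import numpy as np
import pytest

from neuromark.aggregate import robust_bounds
from neuromark.cohort import SubjectRecord
from neuromark.harmonize import (
    GrowthCurve,
    GrowthCurveAdjuster,
    MinMaxNormalizer,
    adjust_features,
    adjust_record,
    growth_curve_eval,
    load_growth_curves,
    normalize_matrix,
)


@pytest.fixture(scope="module")
def curves():
    return load_growth_curves()


def test_growth_curve_interpolation_and_clamping(curves):
    c = curves["M"]
    # knot identity
    assert growth_curve_eval(c, c.ages[3]) == c.volumes[3]
    # midpoint linearity
    mid_age = (c.ages[1] + c.ages[2]) / 2
    assert growth_curve_eval(c, mid_age) == pytest.approx((c.volumes[1] + c.volumes[2]) / 2)
    # clamping below the first knot and above the last
    assert growth_curve_eval(c, 0.25) == c.volumes[0]
    assert growth_curve_eval(c, 200.0) == c.volumes[-1]
    with pytest.raises(ValueError):
        growth_curve_eval(c, -1.0)


def test_growth_curve_shape(curves):
    for sex in ("M", "F"):
        v = curves[sex].volumes
        peak = int(np.argmax(v))
        assert 0 < peak < len(v) - 1  # rise then decline
    # male curve sits above female at every common age
    ages = curves["M"].ages
    assert all(
        growth_curve_eval(curves["M"], a) > growth_curve_eval(curves["F"], a) for a in ages
    )
    with pytest.raises(ValueError):
        GrowthCurve("M", [5.0, 5.0], [1.0, 1.0])


def test_adjustment_formulas(reduced_columns):
    curve = GrowthCurve("M", [1.0, 100.0], [1000.0, 1000.0])
    curves = {"M": curve, "F": curve}
    feats = np.full(len(reduced_columns), np.nan)
    morph = {c.morphology for c in reduced_columns}
    assert morph == {"Sa", "V", "Th", "c"}
    for j, col in enumerate(reduced_columns[:8]):
        feats[j] = {"Sa": 50.0, "V": 500.0, "Th": 2.5, "c": 0.12}[col.morphology]
    adj = adjust_features(feats, reduced_columns, age=10.0, sex="M", curves=curves)
    for j, col in enumerate(reduced_columns[:8]):
        if col.morphology == "V":
            assert adj[j] == pytest.approx(0.5)  # 500 / 1000
        elif col.morphology == "Sa":
            assert adj[j] == pytest.approx(0.5)  # 50 / 1000^(2/3) = 50/100
        else:
            assert adj[j] == feats[j]
    # values equal to Vs(a) / Vs(a)^(2/3) adjust to exactly 1
    feats2 = feats.copy()
    feats2[2] = 1000.0  # a V column
    feats2[0] = 100.0   # a Sa column
    adj2 = adjust_features(feats2, reduced_columns, 10.0, "M", curves)
    assert adj2[2] == pytest.approx(1.0)
    assert adj2[0] == pytest.approx(1.0)
    # missing entries stay missing
    assert np.isnan(adj[10:]).all()


def test_adjust_record_preserves_phenotypes(reduced_columns, curves):
    rec = SubjectRecord("s0", "A", 12.0, "F", "ASD", np.ones(64))
    out = adjust_record(rec, curves, reduced_columns)
    assert out.subject_id == "s0" and out.dx == "ASD"
    assert not np.array_equal(out.features, rec.features)


def test_adjustment_commutes_with_robust_bounds(curves):
    # dividing by a positive scalar commutes with median/IQR arithmetic
    rng = np.random.default_rng(11)
    for _ in range(25):
        vals = rng.lognormal(1.0, 0.4, size=int(rng.integers(5, 200)))
        vs = growth_curve_eval(curves["M"], float(rng.uniform(2, 40)))
        lo_after, hi_after = robust_bounds(vals / vs)
        lo_before, hi_before = robust_bounds(vals)
        np.testing.assert_allclose(
            (lo_before / vs, hi_before / vs), (lo_after, hi_after), rtol=1e-10
        )


def test_age_effect_removed_by_adjustment(matrix_factory, reduced_columns, curves):
    # volumes proportional to Vs(age) plus small noise: pre-adjustment the
    # age correlation is strong, post-adjustment it collapses
    # ages restricted to the declining limb of the curve so the age effect
    # is monotone and a linear correlation can see it
    rng = np.random.default_rng(42)
    n = 200
    ages = rng.uniform(15, 40, size=n)
    X = np.ones((n, len(reduced_columns)))
    vs = np.array([growth_curve_eval(curves["M"], a) for a in ages])
    vol_cols = [j for j, c in enumerate(reduced_columns) if c.morphology == "V"]
    for j in vol_cols:
        X[:, j] = 3.0 * vs * (1 + rng.normal(0, 0.01, size=n))
    mat = matrix_factory(X, rng.integers(0, 2, size=n), columns=reduced_columns)
    mat.ages = ages
    adjusted = GrowthCurveAdjuster(curves).fit(mat).transform(mat)
    # mean |r| over the volume columns: single-column correlations carry
    # O(1/sqrt(n)) sampling noise even when the age effect is fully removed
    pre = np.mean([abs(np.corrcoef(mat.values[:, j], ages)[0, 1]) for j in vol_cols])
    post = np.mean(
        [abs(np.corrcoef(adjusted.values[:, j], ages)[0, 1]) for j in vol_cols]
    )
    assert pre > 0.8
    assert post < 0.1


def test_minmax_normalization_examples():
    col = np.array([[2.0], [4.0], [6.0]])
    norm = MinMaxNormalizer().fit(col)
    np.testing.assert_allclose(norm.transform(col).ravel(), [0, 0.5, 1])
    # Eq-style spot value: f=5 with min=1, max=9 -> 0.5
    norm2 = MinMaxNormalizer().fit(np.array([[1.0], [9.0]]))
    assert norm2.transform(np.array([[5.0]]))[0, 0] == pytest.approx(0.5)
    # constant column maps to zeros
    const = np.full((3, 1), 3.0)
    np.testing.assert_array_equal(MinMaxNormalizer().fit_transform(const), 0.0)


def test_normalization_idempotent_and_bounded(matrix_factory, reduced_columns):
    rng = np.random.default_rng(3)
    X = rng.lognormal(size=(50, 64))
    mat = matrix_factory(X, rng.integers(0, 2, size=50), columns=reduced_columns)
    once, mn, mx = normalize_matrix(mat)
    assert once.values.min() == 0.0 and once.values.max() == 1.0
    assert (once.values >= 0).all() and (once.values <= 1).all()
    twice, _, _ = normalize_matrix(once)
    np.testing.assert_array_equal(once.values, twice.values)
    np.testing.assert_array_equal(mn, X.min(axis=0))


def test_leakage_safe_mode_clips_held_out_rows(matrix_factory, reduced_columns):
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 64))
    mat = matrix_factory(X, rng.integers(0, 2, size=30), columns=reduced_columns)
    train = list(range(20))
    out, _, _ = normalize_matrix(mat, fit_scope=train, mode="leakage_safe")
    assert (out.values >= 0).all() and (out.values <= 1).all()
    # paper mode without clipping lets held-out rows exceed the unit box
    out2, _, _ = normalize_matrix(mat, fit_scope=train, mode="paper")
    assert out2.values.max() > 1 or out2.values.min() < 0
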