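import numpy as np

from neuromark.atlas import (
    NeuroAtlas,
    build_scope_atlas,
    common_markers,
    region_rollup,
)
from neuromark.model_select import small_classifier_specs


def _atlas(scope, cols, backend="lg2"):
    return NeuroAtlas(scope, backend, list(cols), 0.8, 0.05)


def test_common_markers_set_enumeration(reduced_columns):
    a, b = reduced_columns[0], reduced_columns[1]
    global_atlas = _atlas("global", [a, b])
    locals_ = [
        _atlas("site:w", [a]),
        _atlas("site:x", [a]),
        _atlas("site:y", [a]),
        _atlas("site:z", [b]),
    ]
    markers = common_markers(global_atlas, locals_, min_local=3, universe=reduced_columns)
    assert markers.markers == [a.token]
    assert markers.mutual_counts == {"site:w": 1, "site:x": 1, "site:y": 1, "site:z": 1}
    row_a = markers.table.set_index("token").loc[a.token]
    assert row_a["global_flag"] == 1 and row_a["local_count"] == 3


def test_common_markers_empty_locals(reduced_columns):
    markers = common_markers(
        _atlas("global", reduced_columns[:4]), [], min_local=3, universe=reduced_columns
    )
    assert markers.markers == []
    assert markers.mutual_counts == {}


def test_common_markers_saturation(reduced_columns):
    cols = reduced_columns[:5]
    locals_ = [_atlas(f"site:{i}", cols) for i in range(4)]
    markers = common_markers(_atlas("global", cols), locals_, 3, reduced_columns)
    assert set(markers.markers) == {c.token for c in cols}
    assert all(v == 5 for v in markers.mutual_counts.values())


def test_marker_set_monotone_in_min_local(reduced_columns):
    rng = np.random.default_rng(0)
    g_cols = list(reduced_columns[:20])
    locals_ = [
        _atlas(f"site:{i}", [c for c in reduced_columns[:30] if rng.uniform() < 0.4])
        for i in range(8)
    ]
    global_atlas = _atlas("global", g_cols)
    prev = None
    for k in range(1, 9):
        cur = set(common_markers(global_atlas, locals_, k, reduced_columns).markers)
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_mutual_count_bounded_by_atlas_sizes(reduced_columns):
    rng = np.random.default_rng(1)
    g = [c for c in reduced_columns if rng.uniform() < 0.3]
    locals_ = [
        _atlas(f"site:{i}", [c for c in reduced_columns if rng.uniform() < 0.3])
        for i in range(5)
    ]
    markers = common_markers(_atlas("global", g), locals_, 3, reduced_columns)
    for atlas in locals_:
        assert markers.mutual_counts[atlas.scope] <= min(len(g), len(atlas.selected))


def test_region_rollup_preserves_and_flags_duplicates(reduced_columns):
    # lower and upper bound of the same (region, morphology) roll up to the
    # same (morphology, hemisphere, region) row -> a preserved duplicate
    pair = [c for c in reduced_columns if c.morphology == "Sa"][:2]
    assert pair[0].region == pair[1].region
    global_atlas = _atlas("global", pair)
    locals_ = [_atlas(f"site:{i}", pair) for i in range(3)]
    markers = common_markers(global_atlas, locals_, 3, reduced_columns)
    rolled = region_rollup(markers)
    assert len(rolled) == 2
    assert rolled["duplicated"].all()


def test_planted_columns_attain_marker_status_across_sites(reduced_columns):
    # the same ten columns are planted in every site (the generator applies
    # ASD shifts uniformly); lg2 selection should recover most of them both
    # globally and in enough local atlases to flag them as markers
    from neuromark.assemble import assemble_cohort, make_local_matrices
    from neuromark.harmonize import GrowthCurveAdjuster, normalize_matrix
    from neuromark.registry import reduced_region_names
    from neuromark.rfecv import rfecv_select
    from neuromark.synthetic import (
        default_planted_effects,
        generate_records,
        reduced_table1_config,
    )

    regions = reduced_region_names()
    effects = default_planted_effects(5, d=1.5, regions=regions)
    cfg = reduced_table1_config(scale=0.5, planted_effects=effects, seed=11)
    mat, _ = assemble_cohort(generate_records(cfg), cfg.columns())
    mat = GrowthCurveAdjuster().fit(mat).transform(mat)
    mat, _, _ = normalize_matrix(mat)
    g = rfecv_select(mat, "lg2", 10, seed=11)
    global_atlas = _atlas("global", g.selected)
    locals_ = [
        _atlas(lm.scope, rfecv_select(lm, "lg2", 10, seed=11).selected)
        for lm in make_local_matrices(mat)
    ]
    markers = common_markers(global_atlas, locals_, 3, cfg.columns())
    planted = {c.token for e in effects for c in e.columns()}
    assert len({c.token for c in g.selected} & planted) > 0
    assert len(set(markers.markers) & planted) >= 5


def test_single_site_local_atlas_equals_global(matrix_factory, reduced_columns):
    rng = np.random.default_rng(6)
    n = 40
    y = np.array([0, 1] * (n // 2))
    X = rng.uniform(size=(n, 16))
    X[:, 5] = y + rng.normal(0, 0.2, n)
    cols = reduced_columns[:16]
    g = matrix_factory(X, y, columns=cols, scope="global", sites=["A"] * n)
    l = matrix_factory(X, y, columns=cols, scope="site:A", sites=["A"] * n)
    specs = small_classifier_specs()[:2]
    ga, _ = build_scope_atlas(g, backends=("lg2",), rfecv_folds=4, model_folds=3,
                              seed=9, specs=specs)
    la, _ = build_scope_atlas(l, backends=("lg2",), rfecv_folds=4, model_folds=3,
                              seed=9, specs=specs)
    assert ga.selected == la.selected
    assert ga.score_mean == la.score_mean
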