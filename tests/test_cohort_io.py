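import numpy as np
import pandas as pd
import pytest

from neuromark.atlas import NeuroAtlas
from neuromark.cohort import (
    CohortTableError,
    RunReport,
    SubjectRecord,
    read_cohort_table,
    read_report,
    write_cohort_table,
    write_report,
)


def _records(columns, n=3, missing_at=None):
    rng = np.random.default_rng(0)
    out = []
    for i in range(n):
        feats = rng.normal(size=len(columns))
        if missing_at is not None and i == 0:
            feats[missing_at] = np.nan
        out.append(
            SubjectRecord(f"s{i}", "SiteA", 10.0 + i, "M", "ASD" if i % 2 else "TD", feats)
        )
    return out


def test_aggregated_tsv_round_trip(tmp_path, reduced_columns):
    records = _records(reduced_columns)
    path = tmp_path / "cohort.tsv"
    write_cohort_table(records, path, columns=reduced_columns)
    back = read_cohort_table(path, columns=reduced_columns)
    assert len(back) == 3
    for a, b in zip(records, back):
        assert a.subject_id == b.subject_id and a.dx == b.dx and a.sex == b.sex
        np.testing.assert_allclose(a.features, b.features, rtol=1e-12)


def test_shuffled_feature_columns_read_identically(tmp_path, reduced_columns):
    records = _records(reduced_columns)
    path = tmp_path / "cohort.tsv"
    write_cohort_table(records, path, columns=reduced_columns)
    frame = pd.read_csv(path, sep="\t")
    pheno = list(frame.columns[:5])
    feats = list(frame.columns[5:])
    shuffled = tmp_path / "shuffled.tsv"
    frame[pheno + feats[::-1]].to_csv(shuffled, sep="\t", index=False)
    a = read_cohort_table(path, columns=reduced_columns)
    b = read_cohort_table(shuffled, columns=reduced_columns)
    for ra, rb in zip(a, b):
        np.testing.assert_allclose(ra.features, rb.features, rtol=1e-12)


def test_na_cell_becomes_single_missing_value(tmp_path, reduced_columns):
    records = _records(reduced_columns, missing_at=7)
    path = tmp_path / "cohort.tsv"
    write_cohort_table(records, path, columns=reduced_columns)
    # NaN was serialised as an empty cell; also check the literal token NA
    text = path.read_text().splitlines()
    header = text[0].split("\t")
    row = text[2].split("\t")
    row[10] = "NA"
    path.write_text("\n".join([text[0], text[1], "\t".join(row), text[3]]) + "\n")
    back = read_cohort_table(path, columns=reduced_columns)
    assert back[0].n_missing == 1
    assert np.isnan(back[0].features[7])
    assert back[1].n_missing == 1
    assert np.isnan(back[1].features[10 - 5])
    assert header[5:] == [c.token for c in reduced_columns]


def test_missing_phenotype_column_is_hard_error(tmp_path, reduced_columns):
    records = _records(reduced_columns)
    path = tmp_path / "cohort.tsv"
    write_cohort_table(records, path, columns=reduced_columns)
    frame = pd.read_csv(path, sep="\t").drop(columns=["sex"])
    frame.to_csv(path, sep="\t", index=False)
    with pytest.raises(CohortTableError, match="sex"):
        read_cohort_table(path, columns=reduced_columns)


def test_unknown_feature_token_is_hard_error(tmp_path, reduced_columns):
    records = _records(reduced_columns)
    path = tmp_path / "cohort.tsv"
    write_cohort_table(records, path, columns=reduced_columns)
    frame = pd.read_csv(path, sep="\t")
    frame["lh_bogusregion_area_lo"] = 1.0
    frame.to_csv(path, sep="\t", index=False)
    with pytest.raises(CohortTableError, match="bogusregion"):
        read_cohort_table(path, columns=reduced_columns)


def test_run_report_round_trip_and_mean(tmp_path):
    report = RunReport("rfecv", {"backend": "lg2"}, [0.7, 0.8, 0.9], seed=42)
    assert abs(report.mean - np.mean([0.7, 0.8, 0.9])) < 1e-12
    path = tmp_path / "report.json"
    write_report(report, path)
    back = read_report(path)
    assert back.stage == report.stage
    assert back.fold_scores == report.fold_scores
    assert back.seed == 42


def test_empty_atlas_serialises_and_writes_are_byte_identical(tmp_path):
    atlas = NeuroAtlas("global", "lg2", [], 0.5, 0.0)
    p1, p2 = tmp_path / "a1.json", tmp_path / "a2.json"
    write_report(atlas, p1)
    write_report(atlas, p2)
    assert p1.read_bytes() == p2.read_bytes()
    back = read_report(p1)
    assert back.selected == []


def test_explanation_and_marker_table_round_trip(tmp_path, reduced_columns):
    import pandas as pd

    from neuromark.atlas import MarkerTable
    from neuromark.explain import ExplanationMap

    emap = ExplanationMap(
        subject_id="s9",
        contributions={reduced_columns[0].token: 0.4, reduced_columns[2].token: -0.1},
        region_scores={reduced_columns[0].region.token: 0.3},
        r2=0.87, n_samples=1000, kernel_width=3.0, seed=5,
    )
    p = tmp_path / "emap.json"
    write_report(emap, p)
    back = read_report(p)
    assert back.contributions == emap.contributions
    assert back.r2 == emap.r2 and back.seed == 5

    table = pd.DataFrame(
        {"token": [c.token for c in reduced_columns[:3]],
         "global_flag": [1, 0, 1], "local_count": [4, 1, 2], "marker": [1, 0, 0]}
    )
    mt = MarkerTable(table=table, mutual_counts={"site:A": 2}, min_local=3)
    p2 = tmp_path / "markers.json"
    write_report(mt, p2)
    back2 = read_report(p2)
    assert back2.markers == mt.markers
    assert back2.mutual_counts == {"site:A": 2}


def test_atlas_round_trip(tmp_path, reduced_columns):
    atlas = NeuroAtlas("site:UM", "rf", list(reduced_columns[:5]), 0.91, 0.02)
    path = tmp_path / "atlas.json"
    write_report(atlas, path)
    back = read_report(path)
    assert back.selected == atlas.selected
    assert back.scope == "site:UM" and back.backend == "rf"
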