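"""Survey data model: validation, I/O round-trip, cover, community matrix."""

import numpy as np
import pandas as pd
import pytest

from reefpulse import survey
from reefpulse.survey import (
    BENTHIC_LABELS,
    SurveyDataset,
    SurveyValidationError,
    build_community_matrix,
    compute_cover,
    live_coral_taxon_counts,
    read_point_counts,
    taxon_summaries,
    write_point_counts,
)

from conftest import make_records, uniform_image


def complete_transect(n_images=25, n_points=50):
    pts = []
    for img in range(1, n_images + 1):
        for p in range(1, n_points + 1):
            pts.append((img, p, "coral", "acropora", "normal"))
    return SurveyDataset(make_records(pts))


class TestValidation:
    def test_row_count_preserved(self):
        ds = SurveyDataset(make_records(uniform_image(1) + uniform_image(2)))
        assert len(ds) == 100

    def test_complete_transect_has_1250_points(self):
        assert len(complete_transect()) == 25 * 50

    def test_unknown_label_rejected_with_name_and_row(self):
        recs = make_records([(1, 1, "coralz", None, None)])
        with pytest.raises(SurveyValidationError, match="coralz"):
            SurveyDataset(recs)

    def test_bleach_state_on_non_coral_rejected(self):
        recs = make_records([(1, 1, "sand", None, "pale")])
        with pytest.raises(SurveyValidationError, match="non-coral"):
            SurveyDataset(recs)

    def test_live_coral_requires_bleach_state_and_taxon(self):
        with pytest.raises(SurveyValidationError, match="bleach_state required"):
            SurveyDataset(make_records([(1, 1, "coral", "acropora", None)]))
        with pytest.raises(SurveyValidationError, match="taxon"):
            SurveyDataset(make_records([(1, 1, "coral", None, "normal")]))

    def test_duplicate_point_index_rejected(self):
        recs = make_records(
            [(1, 1, "sand", None, None), (1, 1, "rubble", None, None)]
        )
        with pytest.raises(SurveyValidationError, match="duplicate"):
            SurveyDataset(recs)

    def test_turf_dead_coral_state_optional(self):
        ds = SurveyDataset(
            make_records([(1, 1, "coral_dead_turf", "acropora", None)])
        )
        assert ds.records["bleach_state"].isna().all()


class TestIO:
    def test_round_trip_identical_records(self, tmp_path, small_survey):
        path = tmp_path / "survey.csv"
        write_point_counts(small_survey, path)
        back = read_point_counts(path)
        pd.testing.assert_frame_equal(back.records, small_survey.records)

    def test_tab_delimiter_sniffed(self, tmp_path, small_survey):
        path = tmp_path / "survey.tsv"
        write_point_counts(small_survey, path, sep="\t")
        back = read_point_counts(path)
        assert len(back) == len(small_survey)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_id,label\nS1,sand\n")
        with pytest.raises(SurveyValidationError, match="missing required columns"):
            read_point_counts(path)

    def test_schema_mapping_renames_columns(self, tmp_path, small_survey):
        path = tmp_path / "renamed.csv"
        df = small_survey.records.rename(columns={"label": "benthic_cat"})
        df.to_csv(path, index=False)
        back = read_point_counts(path, schema={"benthic_cat": "label"})
        assert len(back) == len(small_survey)


class TestCover:
    def test_simple_ratio(self):
        pts = []
        k = 0
        for img in range(1, 11):
            for p in range(1, 51):
                k += 1
                if k <= 120:
                    pts.append((img, p, "coral", "acropora", "normal"))
                else:
                    pts.append((img, p, "sand", None, None))
        cover = compute_cover(SurveyDataset(make_records(pts)))
        row = cover.iloc[0]
        assert row["coral"] == pytest.approx(120 / 500)
        assert row["n_points"] == 500

    def test_all_sand(self):
        cover = compute_cover(SurveyDataset(make_records(uniform_image(1))))
        row = cover.iloc[0]
        assert row["sand"] == 1.0
        assert all(row[c] == 0 for c in BENTHIC_LABELS if c != "sand")

    def test_cover_sums_to_one(self, rng):
        labels = list(BENTHIC_LABELS)
        pts = []
        for img in range(1, 6):
            for p in range(1, 51):
                lab = labels[rng.integers(len(labels))]
                taxon = "acropora" if lab in survey.CORAL_CATEGORIES else None
                state = (
                    "recently_dead" if lab == "coral_recently_dead"
                    else "normal" if lab in ("coral", "coral_bleached") else None
                )
                if lab == "coral_bleached":
                    state = "pale"
                pts.append((img, p, lab, taxon, state))
        cover = compute_cover(SurveyDataset(make_records(pts)))
        total = cover[list(BENTHIC_LABELS)].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_empty_dataset_errors(self):
        ds = SurveyDataset(make_records([]))
        with pytest.raises(ValueError, match="empty"):
            compute_cover(ds)

    def test_point_count_unbiasedness(self, rng):
        # multinomial sampling from known cover: mean estimate within 3 SE
        p_true = 0.3
        n_pts, n_rep = 200, 1000
        est = rng.binomial(n_pts, p_true, size=n_rep) / n_pts
        # the estimator compute_cover applies is the same count/total ratio:
        pts = [(1, i + 1, "coral" if i < 60 else "sand",
                "acropora" if i < 60 else None,
                "normal" if i < 60 else None) for i in range(200)]
        cover = compute_cover(SurveyDataset(make_records(pts)))
        assert cover.iloc[0]["coral"] == pytest.approx(0.3)
        se = np.sqrt(p_true * (1 - p_true) / (n_pts * n_rep))
        assert abs(est.mean() - p_true) < 3 * se


class TestCommunityMatrix:
    def test_two_taxa_shares(self):
        counts = pd.DataFrame({"acropora": [30], "pocillopora": [10]}, index=["S1"])
        mat = build_community_matrix(counts, min_share=0.0)
        assert mat.loc["S1", "acropora"] == pytest.approx(0.75)
        assert mat.loc["S1", "pocillopora"] == pytest.approx(0.25)

    def test_rare_taxon_dropped_on_pooled_share(self):
        # taxon at 0.4% of pooled observations -> dropped at 0.5% threshold
        counts = pd.DataFrame(
            {"acropora": [498, 498], "favia": [4, 0]}, index=["S1", "S2"]
        )
        assert counts.sum().sum() == 1000
        mat = build_community_matrix(counts, min_share=0.005)
        assert "favia" not in mat.columns
        assert np.allclose(mat.sum(axis=1), 1.0)

    def test_zero_threshold_is_identity(self):
        counts = pd.DataFrame(
            {"acropora": [5, 1], "favia": [1, 9]}, index=["S1", "S2"]
        )
        mat = build_community_matrix(counts, min_share=0.0)
        expected = counts.div(counts.sum(axis=1), axis=0)
        pd.testing.assert_frame_equal(mat, expected[sorted(expected.columns)])

    def test_filter_idempotent(self):
        counts = pd.DataFrame(
            {"acropora": [300, 250], "favia": [2, 1], "pavona": [40, 30]},
            index=["S1", "S2"],
        )
        once = build_community_matrix(counts, min_share=0.005)
        twice = build_community_matrix(once * 1000, min_share=0.005)
        pd.testing.assert_frame_equal(once, twice, check_exact=False)

    def test_no_coral_errors(self):
        counts = pd.DataFrame({"acropora": [0]}, index=["S1"])
        with pytest.raises(ValueError, match="no live coral"):
            build_community_matrix(counts)

    def test_matrix_from_survey_counts(self, small_survey):
        counts = live_coral_taxon_counts(small_survey, by_depth=False)
        mat = build_community_matrix(counts)
        assert mat.loc["S1", "acropora"] == 1.0


class TestTaxonSummaries:
    def test_live_fraction(self):
        pts = (
            [(1, p, "coral", "acropora", "normal") for p in range(1, 7)]
            + [(1, p, "coral_dead_turf", "acropora", None) for p in range(7, 11)]
        )
        out = taxon_summaries(SurveyDataset(make_records(pts)))
        assert out.iloc[0]["live_fraction_acropora"] == pytest.approx(0.6)

    def test_ra_por_extremes(self):
        only_rus = make_records([(1, 1, "coral", "porites_rus", "normal")])
        out = taxon_summaries(SurveyDataset(only_rus))
        assert out.iloc[0]["RA_POR"] == 1.0
        no_por = make_records([(1, 1, "coral", "acropora", "normal")])
        out = taxon_summaries(SurveyDataset(no_por))
        assert out.iloc[0]["RA_POR"] == 0.0

    def test_absent_taxon_is_null_not_zero(self):
        pts = [(1, 1, "coral", "acropora", "normal"),
               (1, 2, "coral_dead_cca", "favia", None)]
        out = taxon_summaries(SurveyDataset(make_records(pts)))
        assert out.iloc[0]["live_fraction_favia"] == 0.0  # favia present, all dead
        assert "live_fraction_pavona" not in out.columns  # absent taxa not fabricated
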