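"""Screening rules, exposure coding, design construction, cell counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acescope import (
    DesignError,
    PredictorSpec,
    build_design,
    check_cell_counts,
    code_exposures,
    collapse_to_nine,
    covariate_dummies,
    make_top_coded_scheme,
    screen,
)
from acescope.predictors import ACE_SCORE, exposure_items
from acescope.schema import (
    COVARIATES,
    ITEMS,
    NEVER,
    SEXUAL_ITEMS,
    item_levels,
)
from conftest import make_row


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_screen_toy_table(toy_screening_table):
    """8 of 10 rows retained: the two single-missing rows are imputed, the
    two-missing-items row and the missing-covariate row are dropped."""
    out, log = screen(toy_screening_table)
    assert log.n_input == 10
    assert log.n_retained == 8 and len(out) == 8
    assert log.n_imputed == 2
    assert log.n_missing_covariate_or_outcome == 1
    assert log.n_multiple_missing_items == 1
    assert not out.isna().any().any()


def test_screen_complete_table_is_identity(small_mir_dataset):
    out, log = screen(small_mir_dataset)
    pd.testing.assert_frame_equal(out, small_mir_dataset)
    assert log.n_imputed == 0
    assert log.n_missing_covariate_or_outcome == 0
    assert log.n_multiple_missing_items == 0


def test_screen_imputes_frequency_item_to_never():
    row = make_row(items={"physical_abuse": np.nan})
    out, log = screen(pd.DataFrame([row]))
    assert out["physical_abuse"].iloc[0] == NEVER
    assert log.imputed_by_item == {"physical_abuse": 1}


def test_screen_idempotent(toy_screening_table):
    once, _ = screen(toy_screening_table)
    twice, log2 = screen(once)
    pd.testing.assert_frame_equal(twice, once)
    assert log2.n_imputed == 0


def test_screen_all_rows_excluded_raises():
    rows = [make_row(items={ITEMS[0]: np.nan, ITEMS[1]: np.nan}) for _ in range(3)]
    with pytest.raises(Exception, match="no rows survive"):
        screen(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# exposure coding
# ---------------------------------------------------------------------------

def test_worked_row_scores(worked_exposure_row):
    once = code_exposures(worked_exposure_row, threshold="once")
    more = code_exposures(worked_exposure_row, threshold="more_than_once")
    assert once[ACE_SCORE].iloc[0] == 5
    assert more[ACE_SCORE].iloc[0] == 3


def test_all_unexposed_row_scores_zero():
    exp = code_exposures(pd.DataFrame([make_row()]))
    assert exp[ACE_SCORE].iloc[0] == 0
    assert exp[list(ITEMS)].to_numpy().sum() == 0


def test_unscreened_missing_rejected():
    df = pd.DataFrame([make_row(items={ITEMS[3]: np.nan})])
    with pytest.raises(ValueError, match="unscreened missing"):
        code_exposures(df)


@given(
    levels=st.tuples(*[st.sampled_from(item_levels(item)) for item in ITEMS]),
)
def test_threshold_monotonicity(levels):
    """Exposures under 'more_than_once' are a subset of exposures under
    'once' row-wise, so the stricter score never exceeds the looser one."""
    df = pd.DataFrame([make_row(items=dict(zip(ITEMS, levels)))])
    once = code_exposures(df, threshold="once")
    more = code_exposures(df, threshold="more_than_once")
    assert (more[list(ITEMS)].to_numpy() <= once[list(ITEMS)].to_numpy()).all()
    assert more[ACE_SCORE].iloc[0] <= once[ACE_SCORE].iloc[0]


# ---------------------------------------------------------------------------
# nine-item collapse
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sexual,expected_indicator,score_drop",
    [((0, 1, 0), 1, 0), ((0, 0, 0), 0, 0), ((1, 1, 1), 1, 2)],
)
def test_collapse_to_nine(sexual, expected_indicator, score_drop):
    items = {
        item: ("once" if flag else "never")
        for item, flag in zip(SEXUAL_ITEMS, sexual)
    }
    items["household_mental_illness"] = "yes"
    df = pd.DataFrame([make_row(items=items)])
    eleven = code_exposures(df)
    nine = collapse_to_nine(eleven)
    assert nine["sexual_abuse"].iloc[0] == expected_indicator
    assert nine[ACE_SCORE].iloc[0] == eleven[ACE_SCORE].iloc[0] - score_drop
    assert len(exposure_items(nine)) == 9


def test_collapse_rejects_nine_item_input(small_mir_dataset):
    nine = collapse_to_nine(code_exposures(small_mir_dataset))
    with pytest.raises(ValueError, match="already 9-item"):
        collapse_to_nine(nine)


def test_nine_item_score_never_exceeds_eleven(small_mir_dataset):
    eleven = code_exposures(small_mir_dataset)
    nine = collapse_to_nine(eleven)
    diff = eleven[ACE_SCORE] - nine[ACE_SCORE]
    assert (diff >= 0).all()
    n_sex = eleven[list(SEXUAL_ITEMS)].sum(axis=1)
    assert (diff == np.maximum(n_sex - 1, 0)).all()


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def test_crcat_identity_scheme_dummy_count(small_mir_dataset):
    exp = code_exposures(small_mir_dataset)
    exp[ACE_SCORE] = exp[ACE_SCORE].clip(upper=6)  # force observed scores 0-6
    spec = PredictorSpec("CRCat")
    design = build_design(
        spec, exp, small_mir_dataset, small_mir_dataset["outcome"].astype(int)
    )
    assert len(design.ace_columns) == 6
    assert all(c.startswith("ace[") for c in design.ace_columns)


def test_crcat_top_coded_scheme_four_dummies(small_mir_dataset):
    exp = code_exposures(small_mir_dataset)
    scheme = make_top_coded_scheme(int(exp[ACE_SCORE].max()), 4)
    spec = PredictorSpec("CRCat", category_scheme=scheme)
    design = build_design(
        spec, exp, small_mir_dataset, small_mir_dataset["outcome"].astype(int)
    )
    assert design.ace_columns == ["ace[1]", "ace[2]", "ace[3]", "ace[4+]"]


def test_mir_design_column_names(small_mir_dataset):
    exp = code_exposures(small_mir_dataset)
    design = build_design(
        PredictorSpec("MIR"), exp, small_mir_dataset, small_mir_dataset["outcome"].astype(int)
    )
    assert design.ace_columns == list(ITEMS)
    assert design.k == 1 + sum(len(lv) - 1 for lv in COVARIATES.values()) + 11


def test_quadratic_column_is_centered(small_mir_dataset):
    exp = code_exposures(small_mir_dataset)
    design = build_design(
        PredictorSpec("CRCn", quadratic=True), exp, small_mir_dataset,
        small_mir_dataset["outcome"].astype(int),
    )
    j = design.columns.index("ace_score_sq_c")
    score = exp[ACE_SCORE].to_numpy(float)
    expected = (score - score.mean()) ** 2
    np.testing.assert_allclose(design.X[:, j], expected)


def test_covariate_block_invariant_across_specs(small_mir_dataset):
    """Partially non-nested structure: every spec shares the same covariate
    dummy columns for a given dataset."""
    exp = code_exposures(small_mir_dataset)
    y = small_mir_dataset["outcome"].astype(int)
    designs = [
        build_design(PredictorSpec("CRCn"), exp, small_mir_dataset, y),
        build_design(PredictorSpec("MIR"), exp, small_mir_dataset, y),
        build_design("baseline", None, small_mir_dataset, y),
    ]
    cov_cols = [c for c in designs[0].columns if "[" in c and not c.startswith("ace")]
    for d in designs[1:]:
        for c in cov_cols:
            np.testing.assert_array_equal(
                d.X[:, d.columns.index(c)], designs[0].X[:, designs[0].columns.index(c)]
            )


def test_empty_category_rank_deficiency_error(small_mir_dataset):
    exp = code_exposures(small_mir_dataset)
    max_score = int(exp[ACE_SCORE].max())
    scheme = tuple(
        [(str(s), (s,)) for s in range(max_score + 1)] + [("ghost", (max_score + 5,))]
    )
    with pytest.raises(DesignError, match="ghost"):
        build_design(
            PredictorSpec("CRCat", category_scheme=scheme), exp, small_mir_dataset,
            small_mir_dataset["outcome"].astype(int),
        )


# ---------------------------------------------------------------------------
# cell counts
# ---------------------------------------------------------------------------

def _score_table(score_counts, outcome_split=0.5):
    rows = []
    rng = np.random.default_rng(0)
    for score, count in score_counts.items():
        for i in range(count):
            exposed = {item: "yes" if j < score else "no" for j, item in enumerate(ITEMS[:5])}
            freq = {
                item: "once" if j + 5 < score else "never"
                for j, item in enumerate(ITEMS[5:])
            }
            rows.append(make_row(items={**exposed, **freq}, outcome=int(rng.random() < outcome_split)))
    df = pd.DataFrame(rows)
    df[ACE_SCORE] = code_exposures(df)[ACE_SCORE]
    return df


def test_sparse_top_category_flagged_and_merged():
    df = _score_table({i: 60 for i in range(8)} | {8: 60, 9: 3})
    report = check_cell_counts(df, min_count=20)
    assert not report.compliant
    assert any(t[1] == 9 for t in report.flags)
    labels = [lab for lab, _ in report.proposed_scheme]
    assert labels[-1] == "8+"


def test_compliant_table_has_no_flags():
    df = _score_table({0: 200, 1: 200, 2: 200})
    report = check_cell_counts(df, min_count=20)
    assert report.compliant and report.flags == [] and report.proposed_scheme is None


def test_vacuous_min_count():
    df = _score_table({0: 5, 1: 2})
    report = check_cell_counts(df, min_count=1)
    assert report.compliant
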