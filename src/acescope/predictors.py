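"""Screening and construction of ACE predictor characterizations.

Turns raw per-respondent responses into the three families of adversity
predictor used throughout the package:

* CRCn  — cumulative risk, continuous ACE score (optionally with a
          mean-centered quadratic term);
* CRCat — cumulative risk, reference-cell-coded categorical ACE score
          (reference is a score of 0);
* MIR   — multiple individual risk, one binary indicator per ACE event.

Each characterization is further parameterized by the exposure threshold
applied to the six frequency items ('once' = any occurrence is an
exposure; 'more_than_once' = only repeated occurrence) and by the item
count (all 11 items, or 9 items with the three sexual-adversity items
collapsed into a single indicator by logical OR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .schema import (
    COVARIATES,
    FREQUENCY_ITEMS,
    ITEMS,
    MORE_THAN_ONCE,
    NINE_ITEMS,
    ONCE,
    OUTCOME,
    SEXUAL_ABUSE,
    SEXUAL_ITEMS,
    THRESHOLD_MORE_THAN_ONCE,
    THRESHOLD_ONCE,
    THRESHOLDS,
    YES,
)

ACE_SCORE = "ace_score"

FAMILIES = ("CRCn", "CRCat", "MIR")


class ScreeningError(ValueError):
    """No analyzable rows survive screening."""


class DesignError(ValueError):
    """A requested design matrix cannot be built (rank deficiency etc.)."""


# ---------------------------------------------------------------------------
# predictor specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorSpec:
    """One characterization of the ACE predictor block.

    Parameters
    ----------
    family : {'CRCn', 'CRCat', 'MIR'}
    items : {11, 9}
        9 collapses the three sexual items to one 'sexual_abuse' indicator.
    threshold : {'once', 'more_than_once'}
        Exposure rule for the six frequency items; yes/no items are
        unaffected.
    quadratic : bool
        CRCn only: add a mean-centered squared-score column.
    category_scheme : tuple of (label, scores) pairs, optional
        CRCat only: mapping of score values to categorical levels. The
        level containing score 0 is the reference. ``None`` means the
        identity scheme (one level per observed score).
    """

    family: str
    items: int = 11
    threshold: str = THRESHOLD_ONCE
    quadratic: bool = False
    category_scheme: tuple[tuple[str, tuple[int, ...]], ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.items not in (11, 9):
            raise ValueError("items must be 11 or 9")
        if self.threshold not in THRESHOLDS:
            raise ValueError(f"unknown threshold {self.threshold!r}")
        if self.quadratic and self.family != "CRCn":
            raise ValueError("quadratic term is only defined for CRCn")
        if self.category_scheme is not None and self.family != "CRCat":
            raise ValueError("category_scheme is only defined for CRCat")

    def label(self) -> str:
        """Human-readable description as used in best-fit tables."""
        parts = [f"{self.items} items", f"'{self.threshold.replace('_', ' ')}'"]
        if self.quadratic:
            parts.append("+ quadratic")
        return ", ".join(parts[:2]) + (" + quadratic" if self.quadratic else "")

    def item_names(self) -> tuple[str, ...]:
        return ITEMS if self.items == 11 else NINE_ITEMS


def make_top_coded_scheme(max_score: int, top: int) -> tuple[tuple[str, tuple[int, ...]], ...]:
    """Score→category scheme with all scores >= ``top`` merged into one level.

    ``make_top_coded_scheme(8, 4)`` gives levels 0, 1, 2, 3, 4+ — the most
    common categorical coding in the adversity literature.
    """
    if not 1 <= top <= max_score:
        raise ValueError("need 1 <= top <= max_score")
    scheme = [(str(s), (s,)) for s in range(top)]
    scheme.append((f"{top}+", tuple(range(top, max_score + 1))))
    return tuple(scheme)


def identity_scheme(max_score: int) -> tuple[tuple[str, tuple[int, ...]], ...]:
    return tuple((str(s), (s,)) for s in range(max_score + 1))


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningLog:
    n_input: int = 0
    n_missing_covariate_or_outcome: int = 0
    n_multiple_missing_items: int = 0
    n_imputed: int = 0
    n_retained: int = 0
    imputed_by_item: dict[str, int] = field(default_factory=dict)


def screen(
    data: pd.DataFrame,
    outcomes: str | list[str] = OUTCOME,
    covariates: list[str] | None = None,
    items: tuple[str, ...] = ITEMS,
) -> tuple[pd.DataFrame, ScreeningLog]:
    """Apply the complete-case screening rules.

    Rows with any missing covariate or outcome are dropped; rows with two
    or more missing ACE items are dropped; rows with exactly one missing
    item are retained with that item imputed to its unexposed level
    ('no' for yes/no items, 'never' for frequency items).
    """
    if isinstance(outcomes, str):
        outcomes = [outcomes]
    if covariates is None:
        covariates = [c for c in COVARIATES if c in data.columns]
    missing_cols = [c for c in list(outcomes) + list(covariates) if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns not present in data: {missing_cols}")

    log = ScreeningLog(n_input=len(data))
    keep_cov = ~data[list(outcomes) + list(covariates)].isna().any(axis=1)
    log.n_missing_covariate_or_outcome = int((~keep_cov).sum())

    item_list = [i for i in items if i in data.columns]
    n_missing_items = data[item_list].isna().sum(axis=1)
    keep_items = n_missing_items <= 1
    log.n_multiple_missing_items = int((keep_cov & ~keep_items).sum())

    out = data.loc[keep_cov & keep_items].copy()
    to_impute = out.loc[n_missing_items.loc[out.index] == 1, item_list]
    log.n_imputed = int(len(to_impute))
    for item in item_list:
        mask = out[item].isna()
        cnt = int(mask.sum())
        if cnt:
            out[item] = out[item].astype(object)
            out.loc[mask, item] = schema.unexposed_level(item)
            log.imputed_by_item[item] = cnt
    log.n_retained = int(len(out))

    if log.n_retained == 0 and log.n_input > 0:
        dominant = (
            "missing covariate/outcome"
            if log.n_missing_covariate_or_outcome >= log.n_multiple_missing_items
            else ">=2 missing ACE items"
        )
        raise ScreeningError(
            f"no rows survive screening of {log.n_input} input rows "
            f"(dominant exclusion: {dominant})"
        )
    return out, log


# ---------------------------------------------------------------------------
# exposure coding
# ---------------------------------------------------------------------------

def code_exposures(
    data: pd.DataFrame,
    threshold: str = THRESHOLD_ONCE,
    items: tuple[str, ...] = ITEMS,
) -> pd.DataFrame:
    """Binary exposure indicators plus the cumulative ACE score.

    Yes/no items are exposed iff 'yes' regardless of threshold. Frequency
    items are exposed iff the response meets the threshold: under 'once'
    both 'once' and 'more_than_once' count, under 'more_than_once' only
    the latter.
    """
    if threshold not in THRESHOLDS:
        raise ValueError(f"unknown threshold {threshold!r}")
    out = pd.DataFrame(index=data.index)
    for item in items:
        col = data[item]
        if col.isna().any():
            raise ValueError(f"unscreened missing value in item {item!r}; run screen() first")
        levels = set(schema.item_levels(item))
        bad = set(col.unique()) - levels
        if bad:
            raise ValueError(f"unexpected levels {sorted(bad)} in item {item!r}")
        if item in FREQUENCY_ITEMS:
            if threshold == THRESHOLD_ONCE:
                exposed = col.isin([ONCE, MORE_THAN_ONCE])
            else:
                exposed = col.eq(MORE_THAN_ONCE)
        else:
            exposed = col.eq(YES)
        out[item] = exposed.astype(np.int64)
    out[ACE_SCORE] = out[list(items)].sum(axis=1)
    return out


def exposure_items(exposures: pd.DataFrame) -> list[str]:
    return [c for c in exposures.columns if c != ACE_SCORE]


def collapse_to_nine(exposures: pd.DataFrame) -> pd.DataFrame:
    """Collapse the three sexual-adversity indicators into one by logical OR.

    The score is recomputed, so the 9-item score equals the 11-item score
    minus the number of extra sexual exposures beyond the first.
    """
    cols = exposure_items(exposures)
    if SEXUAL_ABUSE in cols or not all(s in cols for s in SEXUAL_ITEMS):
        raise ValueError("exposure matrix is already 9-item (or lacks the sexual items)")
    out = exposures.drop(columns=[*SEXUAL_ITEMS, ACE_SCORE]).copy()
    out[SEXUAL_ABUSE] = exposures[list(SEXUAL_ITEMS)].max(axis=1)
    out = out[list(NINE_ITEMS)]
    out[ACE_SCORE] = out[list(NINE_ITEMS)].sum(axis=1)
    return out


def exposures_for_spec(data: pd.DataFrame, spec: PredictorSpec) -> pd.DataFrame:
    """Exposure matrix matching a spec's threshold and item count."""
    exp = code_exposures(data, threshold=spec.threshold)
    if spec.items == 9:
        exp = collapse_to_nine(exp)
    return exp


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """A ready-to-fit logistic design: outcome, intercept, covariate dummies
    (reference-cell coded) and the ACE predictor block from a PredictorSpec
    ('baseline' = no ACE block; 'null' = intercept only)."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    spec: PredictorSpec | str
    ace_columns: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def covariate_dummies(
    data: pd.DataFrame, covariates: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Reference-cell dummy block, identical for every PredictorSpec."""
    if covariates is None:
        covariates = {c: lv for c, lv in COVARIATES.items() if c in data.columns}
    blocks = {}
    for cov, levels in covariates.items():
        col = data[cov]
        bad = set(col.dropna().unique()) - set(levels)
        if bad:
            raise ValueError(f"unexpected levels {sorted(bad)} in covariate {cov!r}")
        for level in levels[1:]:  # first level is the reference
            blocks[f"{cov}[{level}]"] = col.eq(level).astype(float)
    return pd.DataFrame(blocks, index=data.index)


def _ace_block(spec: PredictorSpec, exposures: pd.DataFrame) -> pd.DataFrame:
    items = exposure_items(exposures)
    if len(items) != spec.items:
        raise DesignError(
            f"exposure matrix has {len(items)} items but spec requires {spec.items}"
        )
    score = exposures[ACE_SCORE]
    if spec.family == "CRCn":
        block = pd.DataFrame({ACE_SCORE: score.astype(float)})
        if spec.quadratic:
            centered = score - score.mean()
            block["ace_score_sq_c"] = (centered**2).astype(float)
        return block
    if spec.family == "MIR":
        return exposures[items].astype(float)
    # CRCat
    scheme = spec.category_scheme or identity_scheme(int(score.max()))
    covered = sorted(s for _, scores in scheme for s in scores)
    observed = sorted(score.unique())
    if not set(observed) <= set(covered):
        raise DesignError(
            f"category scheme does not cover observed scores {sorted(set(observed) - set(covered))}"
        )
    ref_label = next(lab for lab, scores in scheme if 0 in scores)
    block = {}
    for lab, scores in scheme:
        if lab == ref_label:
            continue
        col = score.isin(scores).astype(float)
        name = f"ace[{lab}]"
        if col.sum() == 0:
            raise DesignError(f"empty ACE score category column {name!r}")
        block[name] = col
    return pd.DataFrame(block, index=exposures.index)


def build_design(
    spec: PredictorSpec | str,
    exposures: pd.DataFrame | None,
    covariates: pd.DataFrame,
    outcome: pd.Series,
) -> DesignMatrix:
    """Assemble the logistic design for one predictor characterization.

    ``spec`` may be 'baseline' (covariates only) or 'null' (intercept
    only). The covariate dummy block is identical across specs for a
    given dataset, which is what makes competing characterizations
    partially non-nested.
    """
    if outcome.isna().any():
        raise ValueError("outcome contains missing values; run screen() first")
    y = outcome.to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    cov_block = covariate_dummies(covariates) if not _is_dummy_block(covariates) else covariates
    parts = [pd.Series(1.0, index=outcome.index, name="intercept").to_frame()]
    if spec != "null":
        parts.append(cov_block)
    if isinstance(spec, PredictorSpec):
        if exposures is None:
            raise ValueError("exposures required for an ACE spec")
        parts.append(_ace_block(spec, exposures))
        ace_cols = list(parts[-1].columns)
    else:
        if spec not in ("baseline", "null"):
            raise ValueError(f"unknown design spec {spec!r}")
        ace_cols = []
    df = pd.concat(parts, axis=1)
    X = df.to_numpy(dtype=float)
    _check_full_rank(X, list(df.columns))
    return DesignMatrix(X=X, y=y, columns=list(df.columns), spec=spec, ace_columns=ace_cols)


def _is_dummy_block(df: pd.DataFrame) -> bool:
    return all("[" in c for c in df.columns) if len(df.columns) else False


def _check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    # pivoted QR names the most nearly dependent column on failure
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = np.where(diag < tol)[0]
    if bad.size:
        name = columns[piv[bad[0]]]
        raise DesignError(f"design matrix is rank deficient; offending column {name!r}")


# ---------------------------------------------------------------------------
# cell-count screening for categorical scores
# ---------------------------------------------------------------------------

@dataclass
class CellCountReport:
    """Cross-tab screening of the ACE score against outcome and covariates.

    ``flags`` lists every sparse cell as (table, score, level, count).
    ``proposed_scheme`` is the minimal top-category collapse restoring
    min_count compliance, or None if the identity coding already complies
    (or no top collapse can fix it, in which case ``compliant`` stays
    False and the most aggressive collapse is proposed).
    """

    flags: list[tuple[str, int, str, int]]
    compliant: bool
    proposed_scheme: tuple[tuple[str, tuple[int, ...]], ...] | None
    min_count: int


def _crosstab_flags(
    score: pd.Series,
    other: pd.Series,
    name: str,
    levels: list,
    score_values: list[int],
    min_count: int,
) -> list[tuple[str, int, str, int]]:
    tab = pd.crosstab(score, other)
    tab = tab.reindex(index=score_values, columns=levels, fill_value=0)
    flags = []
    for s in score_values:
        row_total = int(tab.loc[s].sum())
        if row_total == 0:
            # an entirely absent score level breaks identity coding
            flags.append((name, int(s), "(all)", 0))
            continue
        for lev in levels:
            cnt = int(tab.loc[s, lev])
            if 0 < cnt < min_count:
                flags.append((name, int(s), str(lev), cnt))
    return flags


def check_cell_counts(
    data: pd.DataFrame,
    min_count: int = 20,
    outcome: str = OUTCOME,
    covariates: list[str] | None = None,
    score: str = ACE_SCORE,
) -> CellCountReport:
    """Screen ACE-score cross-tabs for sparse cells (report only).

    Tabulates score x outcome and score x each covariate; every cell
    below ``min_count`` is flagged, and the minimal top-category merge
    (e.g. scores >= 8 pooled into '8+') that restores compliance is
    proposed for categorical coding.
    """
    if covariates is None:
        covariates = [c for c in COVARIATES if c in data.columns]
    s = data[score].astype(int)
    max_score = int(s.max())
    score_values = list(range(max_score + 1))

    def flags_for(grouped: pd.Series, vals: list[int]) -> list[tuple[str, int, str, int]]:
        out = _crosstab_flags(
            grouped, data[outcome], outcome, sorted(data[outcome].unique()), vals, min_count
        )
        for cov in covariates:
            out += _crosstab_flags(
                grouped, data[cov], cov, sorted(data[cov].dropna().unique()),
                vals, min_count,
            )
        return out

    raw_flags = flags_for(s, score_values)
    if min_count <= 0 or not raw_flags:
        return CellCountReport(flags=[], compliant=True, proposed_scheme=None, min_count=min_count)

    # minimal top collapse: largest cut point whose pooled top category complies
    for top in range(max_score, 0, -1):
        pooled = s.clip(upper=top)
        if not flags_for(pooled, list(range(top + 1))):
            return CellCountReport(
                flags=raw_flags,
                compliant=False,
                proposed_scheme=make_top_coded_scheme(max_score, top),
                min_count=min_count,
            )
    return CellCountReport(
        flags=raw_flags,
        compliant=False,
        proposed_scheme=make_top_coded_scheme(max_score, 1) if max_score >= 1 else None,
        min_count=min_count,
    )
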