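"""End-to-end model-selection workflow.

For each binary outcome: enumerate every predictor characterization
within each family (CRCn / CRCat / MIR), fit them on the screened data,
select the best fit within each family by iterative pairwise two-step
comparisons (with the smaller-AIC rule when a pair is statistically
unresolved, a difference > 50 counting as substantial support), then
compare the three family champions and the covariate-only baseline to
each other. The multiple-individual-risk champion additionally gets an
odds-ratio table contrasting jointly adjusted with single-event
("unadjusted for other ACEs, covariate-included") estimates, plus the
range of variance inflation factors across its event indicators.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import predictors, vuong
from .fitting import FitMetrics, ModelFit, compute_metrics, fit_logistic, vif
from .predictors import (
    ACE_SCORE,
    FAMILIES,
    PredictorSpec,
    ScreeningLog,
    build_design,
    check_cell_counts,
    covariate_dummies,
    exposures_for_spec,
    screen,
)
from .schema import DISPLAY_LABELS, OUTCOME, THRESHOLDS
from .vuong import VuongComparison, compare, significance_stars

logger = logging.getLogger("acescope")

AIC_MARGIN = 50.0          # difference treated as substantial support
AIC_TIE_TOL = 1e-6
FAMILY_DISPLAY_ORDER = ("MIR", "CRCat", "CRCn")   # presentation order
CHAMPION_ORDER = ("baseline", "CRCn", "CRCat", "MIR")  # comparison order


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(family: str) -> list[PredictorSpec]:
    """Every characterization within a family, in the declared iteration
    order: 11 items before 9, threshold 'once' before 'more_than_once',
    and (for CRCn) the linear form before its quadratic variant."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    specs = []
    for items in (11, 9):
        for threshold in THRESHOLDS:
            if family == "CRCn":
                for quadratic in (False, True):
                    specs.append(
                        PredictorSpec(family, items=items, threshold=threshold, quadratic=quadratic)
                    )
            else:
                specs.append(PredictorSpec(family, items=items, threshold=threshold))
    return specs


# ---------------------------------------------------------------------------
# within-family selection
# ---------------------------------------------------------------------------

def _resolve_pair(
    cmp: VuongComparison, aic_a: float, aic_b: float, aic_margin: float = AIC_MARGIN
) -> tuple[str, str, bool]:
    """Resolve champion 'a' vs challenger 'b'.

    Returns (winner 'a'|'b', rule, substantial). A significant closeness
    verdict decides; otherwise the smaller AIC does, flagged substantial
    iff the difference exceeds ``aic_margin``; AIC ties within numerical
    tolerance go to the model with fewer parameters — here the champion,
    whose position encodes the earlier (simpler-first) enumeration.
    """
    if cmp.verdict == "a_better":
        return "a", "vuong", True
    if cmp.verdict == "b_better":
        return "b", "vuong", True
    delta = aic_a - aic_b
    if abs(delta) <= AIC_TIE_TOL:
        return "a", "aic_tie", False
    winner = "a" if delta < 0 else "b"
    return winner, "aic", abs(delta) > aic_margin


def select_within(
    fits: list[ModelFit],
    alpha: float = 0.05,
    aic_margin: float = AIC_MARGIN,
    method: str = "mc",
    mc_draws: int = vuong.DEFAULT_MC_DRAWS,
    seed: int = 0,
) -> tuple[ModelFit, list[dict]]:
    """Champion-vs-challenger selection over fits on identical rows.

    Each pairwise decision is logged: a significant two-step verdict
    decides the pair, otherwise the smaller AIC does (the "(by AIC)"
    annotation of best-fit tables), with the substantial-support flag
    recorded for differences beyond ``aic_margin``.
    """
    if not fits:
        raise ValueError("select_within needs at least one fit")
    champion = fits[0]
    trail: list[dict] = []
    for challenger in fits[1:]:
        cmp = compare(
            champion, challenger, alpha=alpha, method=method, mc_draws=mc_draws, seed=seed
        )
        winner, rule, substantial = _resolve_pair(cmp, champion.aic, challenger.aic, aic_margin)
        trail.append(
            {
                "champion": champion.label(),
                "challenger": challenger.label(),
                "omega_stat": cmp.omega_stat,
                "p_omega": cmp.p_omega,
                "z": cmp.z,
                "p_z": cmp.p_z,
                "verdict": cmp.verdict,
                "aic_champion": champion.aic,
                "aic_challenger": challenger.aic,
                "rule": rule,
                "substantial": substantial,
                "winner": champion.label() if winner == "a" else challenger.label(),
            }
        )
        if winner == "b":
            champion = challenger
    return champion, trail


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass
class OutcomeReport:
    outcome: str
    best_fits: dict[str, ModelFit]
    metrics: dict[str, FitMetrics]
    baseline: ModelFit
    comparisons: dict[tuple[str, str], VuongComparison]
    overall_best: str
    mir_table: pd.DataFrame
    vif_range: tuple[float, float]
    trail: list[dict]
    by_aic: dict[str, bool]   # family -> within-family choice fell to AIC only


@dataclass
class SelectionReport:
    outcomes: dict[str, OutcomeReport]
    screening: ScreeningLog
    alpha: float
    n: int = 0

    def best_fit_table(self) -> pd.DataFrame:
        """Best-fit summary: one row per family, per-outcome metric columns."""
        rows = {}
        for fam in FAMILY_DISPLAY_ORDER:
            row = {}
            for name, rep in self.outcomes.items():
                met = rep.metrics[fam]
                fit = rep.best_fits[fam]
                label = fit.spec.label() + (" (by AIC)" if rep.by_aic[fam] else "")
                row[f"{name}:R2"] = round(met.r2_nagelkerke, 3)
                row[f"{name}:AIC"] = round(met.aic, 1)
                row[f"{name}:c-stat"] = round(met.c_stat, 3)
                row[f"{name}:best-fit"] = label
            rows[fam] = row
        return pd.DataFrame(rows).T

    def comparison_matrix(self, outcome: str) -> pd.DataFrame:
        return render_comparison_matrix(self.outcomes[outcome])

    def decision_trail_json(self) -> str:
        payload = {name: rep.trail for name, rep in self.outcomes.items()}
        return json.dumps(payload, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _auto_scheme(exposures: pd.DataFrame, data: pd.DataFrame, outcome: str):
    """Identity categorical coding, top-collapsed only when the sparse-cell
    screen (20+ cases per score x outcome / covariate cell) demands it."""
    tab = data.copy()
    tab[ACE_SCORE] = exposures[ACE_SCORE]
    report = check_cell_counts(tab, outcome=outcome)
    if report.compliant:
        return None
    return report.proposed_scheme


def fit_family(
    family: str,
    data: pd.DataFrame,
    outcome: str,
    cov_block: pd.DataFrame,
) -> list[ModelFit]:
    """Fit every candidate characterization of one family."""
    fits = []
    for spec in enumerate_candidates(family):
        exp = exposures_for_spec(data, spec)
        if family == "CRCat":
            scheme = _auto_scheme(exp, data, outcome)
            if scheme is not None:
                scheme = tuple(
                    (lab, tuple(s for s in scores if s <= int(exp[ACE_SCORE].max())))
                    for lab, scores in scheme
                )
                spec = PredictorSpec(
                    family, items=spec.items, threshold=spec.threshold, category_scheme=scheme
                )
        design = build_design(spec, exp, cov_block, data[outcome])
        fits.append(fit_logistic(design))
        logger.debug("fitted %s for outcome %s (AIC %.1f)", fits[-1].label(), outcome, fits[-1].aic)
    return fits


def mir_or_table(
    best_mir: ModelFit,
    data: pd.DataFrame,
    cov_block: pd.DataFrame,
    outcome: str,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Adjusted (joint MIR) vs single-event odds ratios, plus the VIF range.

    The "unadjusted" column refits each event alone with the full
    covariate block, mirroring how single-adversity associations are
    usually reported.
    """
    items = best_mir.design.ace_columns
    coef = best_mir.coef_table()
    y = data[outcome].astype(int).to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(cov_block)), cov_block.to_numpy(dtype=float)])
    base_cols = ["intercept", *cov_block.columns]
    idx = {name: best_mir.columns.index(name) for name in items}
    rows = []
    for item in items:
        adj_or = float(coef.loc[item, "or"])
        adj_p = float(coef.loc[item, "p"])
        single = predictors.DesignMatrix(
            X=np.column_stack([base, best_mir.design.X[:, idx[item]]]),
            y=y,
            columns=[*base_cols, item],
            spec="baseline",
            ace_columns=[item],
        )
        stab = fit_logistic(single).coef_table()
        rows.append(
            {
                "item": DISPLAY_LABELS.get(item, item),
                "adjusted_or": adj_or,
                "adjusted_p": adj_p,
                "adjusted_sig": significance_stars(adj_p),
                "unadjusted_or": float(stab.loc[item, "or"]),
                "unadjusted_p": float(stab.loc[item, "p"]),
                "unadjusted_sig": significance_stars(float(stab.loc[item, "p"])),
            }
        )
    vifs = vif(best_mir.design)
    vif_range = (min(vifs.values()), max(vifs.values()))
    return pd.DataFrame(rows).set_index("item"), vif_range


def run_full_analysis(
    data: pd.DataFrame,
    outcomes: str | list[str] = OUTCOME,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    aic_margin: float = AIC_MARGIN,
    method: str = "mc",
    mc_draws: int = vuong.DEFAULT_MC_DRAWS,
    seed: int = 0,
) -> SelectionReport:
    """Screen, fit, select and compare — the whole workflow, per outcome.

    Data are screened first (a no-op on already-screened input). Every
    pairwise decision lands in the per-outcome trail, so the selection
    path can be audited afterwards.
    """
    if isinstance(outcomes, str):
        outcomes = [outcomes]
    screened, log = screen(data, outcomes=outcomes, covariates=covariates)
    cov_block = covariate_dummies(
        screened,
        None if covariates is None else {c: predictors.COVARIATES[c] for c in covariates},
    )
    reports: dict[str, OutcomeReport] = {}
    for outcome in outcomes:
        y = screened[outcome].astype(int)
        null_fit = fit_logistic(build_design("null", None, cov_block, y))
        baseline = fit_logistic(build_design("baseline", None, cov_block, y))
        trail: list[dict] = []
        best_fits: dict[str, ModelFit] = {}
        by_aic: dict[str, bool] = {}
        for family in FAMILIES:
            fits = fit_family(family, screened, outcome, cov_block)
            best, fam_trail = select_within(
                fits, alpha=alpha, aic_margin=aic_margin, method=method,
                mc_draws=mc_draws, seed=seed,
            )
            for entry in fam_trail:
                entry["stage"] = f"within:{family}"
            trail += fam_trail
            best_fits[family] = best
            # "(by AIC)": no within-family pair was significantly different
            by_aic[family] = all(e["rule"] != "vuong" for e in fam_trail) and len(fam_trail) > 0

        models = {"baseline": baseline, **{f: best_fits[f] for f in FAMILIES}}
        comparisons: dict[tuple[str, str], VuongComparison] = {}
        for name_a, name_b in itertools.combinations(CHAMPION_ORDER, 2):
            cmp = compare(
                models[name_a], models[name_b], alpha=alpha, method=method,
                mc_draws=mc_draws, seed=seed, label_a=name_a, label_b=name_b,
            )
            comparisons[(name_a, name_b)] = cmp
            trail.append(
                {
                    "stage": "between",
                    "champion": name_a,
                    "challenger": name_b,
                    "omega_stat": cmp.omega_stat,
                    "p_omega": cmp.p_omega,
                    "z": cmp.z,
                    "p_z": cmp.p_z,
                    "verdict": cmp.verdict,
                    "aic_champion": models[name_a].aic,
                    "aic_challenger": models[name_b].aic,
                }
            )

        overall = _overall_best(models, comparisons, aic_margin, trail)
        metrics = {
            fam: compute_metrics(best_fits[fam], null_fit) for fam in FAMILIES
        }
        mir_tab, vif_range = mir_or_table(best_fits["MIR"], screened, cov_block, outcome)
        metrics["MIR"].vif_range = vif_range
        reports[outcome] = OutcomeReport(
            outcome=outcome,
            best_fits=best_fits,
            metrics=metrics,
            baseline=baseline,
            comparisons=comparisons,
            overall_best=overall,
            mir_table=mir_tab,
            vif_range=vif_range,
            trail=trail,
            by_aic=by_aic,
        )
    return SelectionReport(outcomes=reports, screening=log, alpha=alpha, n=len(screened))


def _overall_best(
    models: dict[str, ModelFit],
    comparisons: dict[tuple[str, str], VuongComparison],
    aic_margin: float,
    trail: list[dict],
) -> str:
    """Champion pass over baseline + the three family bests, reusing the
    already-computed pairwise comparisons."""
    champion = CHAMPION_ORDER[0]
    for challenger in CHAMPION_ORDER[1:]:
        key = (champion, challenger)
        cmp = comparisons[key] if key in comparisons else comparisons[(challenger, champion)]
        if key in comparisons:
            winner, rule, substantial = _resolve_pair(
                cmp, models[champion].aic, models[challenger].aic, aic_margin
            )
            new = challenger if winner == "b" else champion
        else:  # comparison stored with roles swapped
            winner, rule, substantial = _resolve_pair(
                cmp, models[challenger].aic, models[champion].aic, aic_margin
            )
            new = challenger if winner == "a" else champion
        trail.append(
            {
                "stage": "overall",
                "champion": champion,
                "challenger": challenger,
                "rule": rule,
                "substantial": substantial,
                "winner": new,
            }
        )
        champion = new
    return champion


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_comparison_matrix(report: OutcomeReport) -> pd.DataFrame:
    """Comparison matrix: per cell the distinguishability statistic ω̂²
    (top) over the closeness z (bottom) with significance stars; NDF marks
    distinguishable pairs of non-different fit. Positive z favours the
    column model."""
    order = [n for n in ("baseline", *FAMILY_DISPLAY_ORDER)]
    mat = pd.DataFrame("", index=order, columns=order)
    for name in order:
        mat.loc[name, name] = "1"
    for (a, b), cmp in report.comparisons.items():
        # row = later model, column = earlier model; z sign follows the
        # convention that positive favours the column model (model_a)
        cell_omega = f"{cmp.omega2_hat:.3f}{significance_stars(cmp.p_omega)}"
        if cmp.verdict == "indistinguishable":
            cell_z = "ND"
        elif cmp.verdict == "distinguishable_equal_fit":
            cell_z = "NDF"
        else:
            cell_z = f"{cmp.z:.2f}{significance_stars(cmp.p_z)}"
        mat.loc[b, a] = f"{cell_omega} / {cell_z}"
    return mat


def write_report(report: SelectionReport, out_dir: str | Path) -> None:
    """Delimited best-fit / comparison / MIR tables plus the JSON trail."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.best_fit_table().to_csv(out / "best_fit_models.csv")
    for name, rep in report.outcomes.items():
        render_comparison_matrix(rep).to_csv(out / f"comparisons_{name}.csv")
        tab = rep.mir_table.copy()
        lo, hi = rep.vif_range
        tab.loc["VIF range"] = [f"{lo:.2f}-{hi:.2f}", "", "", "", "", ""]
        tab.to_csv(out / f"mir_odds_ratios_{name}.csv")
    (out / "decision_trail.json").write_text(report.decision_trail_json())
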