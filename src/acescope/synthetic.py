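"""Seeded synthetic survey data with the structure the analysis assumes.

Item responses are generated from a Gaussian-copula (latent-threshold)
model: each respondent draws one latent multivariate-normal vector over
the 11 ACE items, which is cut at the quantiles implied by the per-item
marginal probabilities. A scalar ``rho`` gives an exchangeable latent
correlation (ACE exposures are strongly positively associated in survey
data; independence would be unrealistic); a full 11x11 matrix is also
accepted. Three-level frequency items use two ordered thresholds, so
higher latent adversity maps to more frequent exposure.

Covariates are drawn independently of the items by default; an optional
``covariate_linkage`` ties them to the shared latent adversity factor
for confounding experiments. Outcomes are Bernoulli draws from a
logistic linear predictor whose adversity part follows one of four
generating truths: ``mir`` (per-event log-ORs), ``cr_linear`` (score,
optionally quadratic), ``cr_categorical`` (per-count step effects), or
``null`` (no adversity effect). Missingness, when requested, is MCAR
per item cell.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import predictors, schema
from .schema import (
    BINARY_ITEMS,
    COVARIATES,
    FREQUENCY_ITEMS,
    ITEMS,
    MORE_THAN_ONCE,
    NEVER,
    NO,
    ONCE,
    OUTCOME,
    THRESHOLD_ONCE,
    YES,
)

TRUTH_MODES = ("mir", "cr_linear", "cr_categorical", "null")


class TruthError(ValueError):
    """TruthSpec fields inconsistent with its declared mode."""


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth for the outcome model.

    Only the adversity fields belonging to ``mode`` may be set:
    ``mir_betas`` (11 or 9 log-ORs) for 'mir', ``score_beta`` /
    ``score_beta2`` for 'cr_linear', ``step_effects`` (log-OR per score
    count vs 0) for 'cr_categorical'; 'null' sets no adversity effect.
    ``covariate_effects`` maps covariate -> {level: log-OR} for
    non-reference levels and applies in every mode. The generative
    exposure rule is the 'once' threshold unless configured otherwise.
    """

    mode: str
    intercept: float = 0.0
    covariate_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mir_betas: tuple[float, ...] | None = None
    score_beta: float | None = None
    score_beta2: float | None = None
    step_effects: Mapping[int, float] | None = None
    exposure_threshold: str = THRESHOLD_ONCE
    items: int = 11

    def __post_init__(self) -> None:
        if self.mode not in TRUTH_MODES:
            raise TruthError(f"unknown truth mode {self.mode!r}")
        if self.items not in (11, 9):
            raise TruthError("items must be 11 or 9")
        used = {
            "mir": ("mir_betas",),
            "cr_linear": ("score_beta", "score_beta2"),
            "cr_categorical": ("step_effects",),
            "null": (),
        }[self.mode]
        for f in ("mir_betas", "score_beta", "score_beta2", "step_effects"):
            val = getattr(self, f)
            if f not in used and val is not None:
                raise TruthError(f"field {f!r} is not used by mode {self.mode!r}")
        if self.mode == "mir":
            if self.mir_betas is None or len(self.mir_betas) != self.items:
                raise TruthError(f"mode 'mir' requires {self.items} mir_betas")
        if self.mode == "cr_linear" and self.score_beta is None:
            raise TruthError("mode 'cr_linear' requires score_beta")
        if self.mode == "cr_categorical" and not self.step_effects:
            raise TruthError("mode 'cr_categorical' requires step_effects")

    def linear_predictor(self, responses: pd.DataFrame) -> np.ndarray:
        """Log-odds of the outcome for each row (deterministic part)."""
        lp = np.full(len(responses), float(self.intercept))
        for cov, effects in self.covariate_effects.items():
            levels = COVARIATES[cov]
            for level, beta in effects.items():
                if level not in levels[1:]:
                    raise TruthError(f"level {level!r} is not a non-reference level of {cov!r}")
                lp += beta * responses[cov].eq(level).to_numpy(dtype=float)
        if self.mode == "null":
            return lp
        exp = predictors.code_exposures(responses, threshold=self.exposure_threshold)
        if self.items == 9:
            exp = predictors.collapse_to_nine(exp)
        score = exp[predictors.ACE_SCORE].to_numpy(dtype=float)
        if self.mode == "mir":
            items = predictors.exposure_items(exp)
            betas = np.asarray(self.mir_betas, dtype=float)
            lp += exp[items].to_numpy(dtype=float) @ betas
        elif self.mode == "cr_linear":
            lp += float(self.score_beta) * score
            if self.score_beta2:
                lp += float(self.score_beta2) * score**2
        else:  # cr_categorical
            effects = {int(k): float(v) for k, v in self.step_effects.items()}
            observed = set(np.unique(score).astype(int)) - {0}
            uncovered = observed - set(effects)
            if uncovered:
                raise TruthError(f"step_effects does not cover observed scores {sorted(uncovered)}")
            lp += np.array([effects.get(int(s), 0.0) for s in score])
        return lp


# package-default truth: heterogeneous per-event log-ORs of realistic size
# (strong household-mental-illness effect, several near-null events), with
# a mental-health-outcome-like base prevalence and mild covariate gradients.
DEFAULT_MIR_BETAS = tuple(
    round(float(np.log(or_)), 4)
    for or_ in (2.89, 1.20, 0.96, 1.04, 0.93, 0.98, 1.29, 1.46, 1.74, 1.13, 1.28)
)
DEFAULT_COVARIATE_EFFECTS = {
    "sex": {"male": -0.35},
    "age": {"30-39": 0.10, "40-49": 0.15, "50-59": 0.15, "60+": -0.10},
    "education": {"hs_grad": -0.05, "some_college": -0.05, "college_grad": -0.20},
    "income": {"15-25k": -0.10, "25-35k": -0.20, "35-50k": -0.30, "50k+": -0.45},
    "insurance": {"uninsured": 0.10},
    "race": {"black": -0.10, "other": 0.05},
    "marital": {"divorced_widowed": 0.25, "never_married": 0.15},
}


def default_truth(mode: str = "mir") -> TruthSpec:
    """Package-default generating truths, one per mode."""
    common = dict(intercept=-1.9, covariate_effects=DEFAULT_COVARIATE_EFFECTS)
    if mode == "mir":
        return TruthSpec(mode="mir", mir_betas=DEFAULT_MIR_BETAS, **common)
    if mode == "cr_linear":
        return TruthSpec(mode="cr_linear", score_beta=0.20, **common)
    if mode == "cr_categorical":
        steps = {s: 0.35 * np.sqrt(s) for s in range(1, 12)}
        return TruthSpec(mode="cr_categorical", step_effects=steps, **common)
    if mode == "null":
        return TruthSpec(mode="null", intercept=0.0)
    raise TruthError(f"unknown truth mode {mode!r}")


# default marginal exposure structure: binary items carry P(yes); frequency
# items carry (P(never), P(once), P(more_than_once)).
DEFAULT_ITEM_MARGINS: dict[str, tuple[float, ...]] = {
    "household_mental_illness": (0.17,),
    "household_alcoholism": (0.24,),
    "household_drug_abuse": (0.11,),
    "household_criminal": (0.07,),
    "divorce": (0.25,),
    "household_violence": (0.84, 0.05, 0.11),
    "physical_abuse": (0.85, 0.06, 0.09),
    "emotional_abuse": (0.70, 0.08, 0.22),
    "sexually_touched": (0.89, 0.04, 0.07),
    "sexual_touching": (0.93, 0.03, 0.04),
    "forced_sex": (0.955, 0.015, 0.03),
}

DEFAULT_COVARIATE_MARGINS: dict[str, tuple[float, ...]] = {
    "sex": (0.52, 0.48),
    "age": (0.18, 0.16, 0.18, 0.22, 0.26),
    "education": (0.08, 0.28, 0.30, 0.34),
    "income": (0.10, 0.14, 0.12, 0.18, 0.46),
    "insurance": (0.88, 0.12),
    "race": (0.78, 0.10, 0.12),
    "marital": (0.58, 0.24, 0.18),
}


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic dataset (deterministic given seed)."""

    n: int
    truth: TruthSpec = field(default_factory=default_truth)
    item_margins: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_MARGINS)
    )
    rho: float | np.ndarray = 0.4
    covariate_margins: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINS)
    )
    missing_rate: float = 0.0
    covariate_linkage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.covariate_linkage < 1.0:
            raise ValueError("covariate_linkage must be in [0, 1)")
        for item in ITEMS:
            m = self.item_margins.get(item)
            if m is None:
                raise ValueError(f"item_margins missing item {item!r}")
            want = 1 if item in BINARY_ITEMS else 3
            if len(m) != want:
                raise ValueError(f"item {item!r} needs {want} margin value(s)")
            if want == 3 and abs(sum(m) - 1.0) > 1e-12:
                raise ValueError(f"level probabilities for {item!r} must sum to 1")
            if any(not 0 < p < 1 for p in m):
                raise ValueError(f"margins for {item!r} must lie strictly in (0, 1)")
        for cov, levels in COVARIATES.items():
            m = self.covariate_margins.get(cov)
            if m is None or len(m) != len(levels):
                raise ValueError(f"covariate_margins for {cov!r} must give {len(levels)} values")
            if abs(sum(m) - 1.0) > 1e-12:
                raise ValueError(f"level probabilities for {cov!r} must sum to 1")

    def correlation_matrix(self) -> np.ndarray:
        p = len(ITEMS)
        if np.isscalar(self.rho):
            r = float(self.rho)
            if not 0.0 <= r < 1.0:
                raise ValueError("exchangeable rho must be in [0, 1)")
            return (1 - r) * np.eye(p) + r * np.ones((p, p))
        R = np.asarray(self.rho, dtype=float)
        if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-12):
            raise ValueError(f"correlation matrix must be symmetric {p}x{p}")
        return R


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _latent_draw(config: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One latent MVN row per respondent, plus the shared factor (for linkage)."""
    R = config.correlation_matrix()
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "latent correlation matrix is not positive definite: "
            + np.array2string(R, precision=3)
        ) from exc
    Z = rng.standard_normal((config.n, len(ITEMS))) @ L.T
    # shared adversity factor: standardized row mean of the latents
    factor = Z.mean(axis=1)
    sd = float(np.sqrt(R.mean()))
    factor = factor / sd if sd > 0 else factor
    return Z, factor


def generate_responses(config: SyntheticConfig) -> pd.DataFrame:
    """Draw item responses and covariates (no outcome, no missingness)."""
    rng = np.random.default_rng(config.seed)
    Z, factor = _latent_draw(config, rng)
    data: dict[str, object] = {}
    for j, item in enumerate(ITEMS):
        m = config.item_margins[item]
        z = Z[:, j]
        if item in BINARY_ITEMS:
            cut = norm.ppf(1.0 - m[0])  # exposed in the upper tail
            data[item] = np.where(z > cut, YES, NO)
        else:
            c0 = norm.ppf(m[0])
            c1 = norm.ppf(m[0] + m[1])
            resp = np.full(config.n, NEVER, dtype=object)
            resp[z >= c0] = ONCE
            resp[z >= c1] = MORE_THAN_ONCE
            data[item] = resp
    lam = config.covariate_linkage
    for cov, levels in COVARIATES.items():
        m = np.asarray(config.covariate_margins[cov], dtype=float)
        latent = rng.standard_normal(config.n)
        if lam > 0:
            latent = lam * factor + np.sqrt(1 - lam**2) * latent
        cuts = norm.ppf(np.clip(np.cumsum(m)[:-1], 1e-12, 1 - 1e-12))
        idx = np.searchsorted(cuts, latent, side="left")
        data[cov] = np.asarray(levels, dtype=object)[idx]
    return pd.DataFrame(data, index=pd.RangeIndex(config.n))


def generate_outcomes(
    responses: pd.DataFrame,
    truth: TruthSpec,
    seed: int,
    name: str = OUTCOME,
) -> pd.DataFrame:
    """Append a Bernoulli(logistic(lp)) outcome column under the given truth."""
    item_cols = [c for c in ITEMS if c in responses.columns]
    if responses[item_cols].isna().any().any():
        raise ValueError("responses must be complete (no missing items) at outcome generation")
    rng = np.random.default_rng(seed)
    lp = truth.linear_predictor(responses)
    out = responses.copy()
    out[name] = (rng.random(len(out)) < expit(lp)).astype(np.int64)
    return out


def apply_missingness(
    responses: pd.DataFrame, missing_rate: float, seed: int
) -> pd.DataFrame:
    """Set each item cell to missing independently with the given probability.

    Covariates and outcomes are untouched (MCAR on items only).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    out = responses.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    item_cols = [c for c in ITEMS if c in out.columns]
    mask = rng.random((len(out), len(item_cols))) < missing_rate
    for j, col in enumerate(item_cols):
        vals = out[col].astype(object)
        vals[mask[:, j]] = np.nan
        out[col] = vals
    return out


def simulate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Responses + outcome + missingness in one deterministic call.

    Sub-seeds for the outcome and missingness stages are derived from
    ``config.seed`` so the three stages stay independent streams.
    """
    responses = generate_responses(config)
    data = generate_outcomes(responses, config.truth, seed=_substream(config.seed, 1))
    if config.missing_rate > 0:
        data = apply_missingness(data, config.missing_rate, seed=_substream(config.seed, 2))
    return data


def _substream(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# dataset I/O: CSV + JSON sidecar recording the generating recipe
# ---------------------------------------------------------------------------

def _truth_to_dict(truth: TruthSpec) -> dict:
    d = dataclasses.asdict(truth)
    if d.get("step_effects") is not None:
        d["step_effects"] = {str(k): v for k, v in d["step_effects"].items()}
    return {k: v for k, v in d.items() if v is not None}


def truth_from_dict(d: Mapping) -> TruthSpec:
    d = dict(d)
    if "step_effects" in d and d["step_effects"] is not None:
        d["step_effects"] = {int(k): float(v) for k, v in d["step_effects"].items()}
    if "mir_betas" in d and d["mir_betas"] is not None:
        d["mir_betas"] = tuple(d["mir_betas"])
    if "covariate_effects" in d:
        d["covariate_effects"] = {k: dict(v) for k, v in d["covariate_effects"].items()}
    return TruthSpec(**d)


def write_dataset(data: pd.DataFrame, config: SyntheticConfig, path: str | Path) -> Path:
    """Write the table as CSV plus a ``<stem>.config.json`` sidecar."""
    path = Path(path)
    data.to_csv(path, index=False)
    rho = config.rho if np.isscalar(config.rho) else np.asarray(config.rho).tolist()
    sidecar = {
        "n": config.n,
        "truth": _truth_to_dict(config.truth),
        "item_margins": {k: list(v) for k, v in config.item_margins.items()},
        "rho": rho,
        "covariate_margins": {k: list(v) for k, v in config.covariate_margins.items()},
        "missing_rate": config.missing_rate,
        "covariate_linkage": config.covariate_linkage,
        "seed": config.seed,
    }
    sidecar_path = path.with_suffix(".config.json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, SyntheticConfig | None]:
    """Read a dataset CSV; return its generating config if a sidecar exists."""
    path = Path(path)
    data = pd.read_csv(path, dtype={c: object for c in ITEMS})
    sidecar_path = path.with_suffix(".config.json")
    config = None
    if sidecar_path.exists():
        raw = json.loads(sidecar_path.read_text())
        raw["truth"] = truth_from_dict(raw["truth"])
        raw["item_margins"] = {k: tuple(v) for k, v in raw["item_margins"].items()}
        raw["covariate_margins"] = {k: tuple(v) for k, v in raw["covariate_margins"].items()}
        if isinstance(raw["rho"], list):
            raw["rho"] = np.asarray(raw["rho"])
        config = SyntheticConfig(**raw)
    return data, config
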