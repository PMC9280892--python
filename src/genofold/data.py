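"""Survey-data ingestion, preprocessing, and synthetic generation.

The expected tabular dialect is a clinical lung-cancer screening survey:
one gender column (M/F), an integer age, thirteen symptom/history columns
coded YES=2 / NO=1, and a YES/NO outcome column.  Preprocessing drops rows
with missing cells, encodes gender (M=2, F=1) and the outcome (YES=+1,
NO=-1), and z-score standardizes every feature with parameters fitted on a
designated training subset only.

The synthetic generator emulates that structure: ages are Gaussian, each
binary feature has configurable class-conditional prevalences, and the
outcome is drawn from a logistic model whose weights are the naive-Bayes
log-odds implied by those prevalences, optionally plus an XOR-style
interaction between a chosen pair of features.  The intercept is calibrated
numerically so the marginal benign (NO) fraction matches the configured
value, which defaults to the 39/309 imbalance typical of this kind of
screening sample.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "FEATURE_COLUMNS",
    "OUTCOME_COLUMN",
    "SurveyError",
    "SurveyTable",
    "Dataset",
    "GeneratorConfig",
    "read_survey_csv",
    "write_survey_csv",
    "preprocess",
    "standardize",
    "synthesize_survey",
    "make_separable_clusters",
    "oversample_minority",
    "dataset_from_arrays",
]

#: Canonical feature columns (normalized names), gender and age first.
FEATURE_COLUMNS: tuple[str, ...] = (
    "GENDER",
    "AGE",
    "SMOKING",
    "YELLOW_FINGERS",
    "ANXIETY",
    "PEER_PRESSURE",
    "CHRONIC_DISEASE",
    "FATIGUE",
    "ALLERGY",
    "WHEEZING",
    "ALCOHOL",
    "COUGHING",
    "SHORTNESS_OF_BREATH",
    "SWALLOWING_DIFFICULTY",
    "CHEST_PAIN",
)
OUTCOME_COLUMN = "LUNG_CANCER"
SYMPTOM_COLUMNS: tuple[str, ...] = FEATURE_COLUMNS[2:]

# Common header variants seen in the wild for this dialect.
_ALIASES = {
    "ALCOHOL_CONSUMING": "ALCOHOL",
    "CHRONIC_DISEASE": "CHRONIC_DISEASE",
    "LUNG_CANCER": OUTCOME_COLUMN,
    "OUT": OUTCOME_COLUMN,
    "OUTCOME": OUTCOME_COLUMN,
}


class SurveyError(ValueError):
    """Raised on malformed survey tables."""


def _normalize_column(name: str) -> str:
    key = re.sub(r"[^A-Z0-9]+", "_", str(name).strip().upper()).strip("_")
    return _ALIASES.get(key, key)


@dataclass
class SurveyTable:
    """A raw (unvalidated-values) survey table with canonical column names."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.rename(columns=_normalize_column)
        missing = [
            c for c in (*FEATURE_COLUMNS, OUTCOME_COLUMN)
            if c not in self.frame.columns
        ]
        if missing:
            raise SurveyError(f"missing required column(s): {', '.join(missing)}")
        if len(self.frame) == 0:
            raise SurveyError("survey table has no data rows")
        # canonical order: features then outcome
        self.frame = self.frame[list(FEATURE_COLUMNS) + [OUTCOME_COLUMN]]

    def __len__(self) -> int:
        return len(self.frame)

    def outcome_counts(self) -> dict[str, int]:
        counts = (
            self.frame[OUTCOME_COLUMN].astype(str).str.strip().str.upper()
            .value_counts().to_dict()
        )
        return {str(k): int(v) for k, v in counts.items()}


def read_survey_csv(path) -> SurveyTable:
    """Read a survey CSV, normalizing headers; values are left raw."""
    try:
        frame = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SurveyError(f"{path}: empty file") from exc
    return SurveyTable(frame)


def write_survey_csv(table: SurveyTable, path) -> None:
    table.frame.to_csv(path, index=False)


@dataclass
class Dataset:
    """Standardized feature matrix with +-1 labels, ready for kernel work."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    scaling_params: tuple[np.ndarray, np.ndarray]  # (mean, sd) per column
    raw: np.ndarray  # encoded but unscaled features
    dropped_rows: int = 0
    zero_variance: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            self.X[idx], self.y[idx], self.feature_names,
            self.scaling_params, self.raw[idx], 0, self.zero_variance,
        )


def dataset_from_arrays(X, y, feature_names: Optional[Sequence[str]] = None) -> Dataset:
    """Wrap already-numeric arrays (assumed scaled) as a Dataset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be coded +-1")
    names = tuple(feature_names) if feature_names else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    return Dataset(X, y.astype(int), names, (mean, sd), X.copy())


def standardize(raw: np.ndarray, fit_idx=None):
    """Z-score columns with moments from ``fit_idx`` rows (default: all).

    Zero-variance columns are scaled by 1 so they become constant zero;
    their indices are returned for reporting.
    """
    raw = np.asarray(raw, dtype=float)
    fit = raw if fit_idx is None else raw[np.asarray(fit_idx)]
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (raw - mean) / sd_safe, (mean, sd_safe), zero


_GENDER_CODES = {"M": 2.0, "F": 1.0}
_OUTCOME_CODES = {"YES": 1, "NO": -1}


def _encode_column(series: pd.Series, name: str) -> np.ndarray:
    """Coerce one feature column to floats, rejecting unknown codings."""
    values = series.to_numpy()
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if name == "GENDER":
            code = _GENDER_CODES.get(str(v).strip().upper())
            if code is None:
                raise SurveyError(f"column GENDER: unknown code {v!r}")
            out[i] = code
        elif name == "AGE":
            try:
                out[i] = float(v)
            except (TypeError, ValueError):
                raise SurveyError(f"column AGE: non-numeric value {v!r}") from None
        else:
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise SurveyError(f"column {name}: unknown code {v!r}") from None
            if fv not in (1.0, 2.0):
                raise SurveyError(f"column {name}: unknown code {v!r}")
            out[i] = fv
    return out


def preprocess(table: SurveyTable, fit_on=None) -> Dataset:
    """Encode and standardize a survey table.

    Rows with any missing cell are dropped (and counted).  Gender maps
    M=2/F=1, the outcome YES=+1/NO=-1.  Standardization moments are fitted
    on the ``fit_on`` row subset (positions after null-dropping; default all
    rows) and applied everywhere, so a train/test split never leaks test
    statistics into the scaler.
    """
    frame = table.frame
    null_mask = frame.isna().any(axis=1) | frame.map(
        lambda v: isinstance(v, str) and not v.strip()
    ).any(axis=1)
    dropped = int(null_mask.sum())
    frame = frame.loc[~null_mask]
    if len(frame) == 0:
        raise SurveyError("all rows dropped: every row has a missing cell")

    columns = [_encode_column(frame[c], c) for c in FEATURE_COLUMNS]
    raw = np.column_stack(columns)

    outcome = frame[OUTCOME_COLUMN].astype(str).str.strip().str.upper()
    unknown = sorted(set(outcome) - set(_OUTCOME_CODES))
    if unknown:
        raise SurveyError(f"column {OUTCOME_COLUMN}: unknown code(s) {unknown}")
    y = outcome.map(_OUTCOME_CODES).to_numpy(dtype=int)

    X, params, zero = standardize(raw, fit_on)
    zero_names = tuple(FEATURE_COLUMNS[i] for i in zero)
    if zero_names:
        warnings.warn(
            f"zero-variance column(s) kept as constant 0: {', '.join(zero_names)}",
            stacklevel=2,
        )
    return Dataset(X, y, FEATURE_COLUMNS, params, raw, dropped, zero_names)


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

# Default class-conditional prevalences P(feature=YES | class), chosen so the
# marginal feature means sit near the survey's typical values (about 1.5 for
# most symptoms, 1.8 for fatigue, 1.6 for coughing / shortness of breath)
# while a handful of symptoms carry a moderate malignant association.
_DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    #               (P(YES | benign), P(YES | malignant))
    "SMOKING": (0.25, 0.55),
    "YELLOW_FINGERS": (0.30, 0.53),
    "ANXIETY": (0.50, 0.50),
    "PEER_PRESSURE": (0.50, 0.50),
    "CHRONIC_DISEASE": (0.50, 0.50),
    "FATIGUE": (0.80, 0.80),
    "ALLERGY": (0.30, 0.53),
    "WHEEZING": (0.50, 0.50),
    "ALCOHOL": (0.50, 0.50),
    "COUGHING": (0.35, 0.64),
    "SHORTNESS_OF_BREATH": (0.60, 0.60),
    "SWALLOWING_DIFFICULTY": (0.50, 0.50),
    "CHEST_PAIN": (0.30, 0.53),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey generator.

    Defaults mirror the clinical screening sample this package targets:
    309 respondents with a 39/309 benign fraction, mean age 62.6 (SD 8),
    and binary symptom features with means around 1.5-1.8.
    ``nonlinear_pair`` plants an XOR-style interaction between two named
    features in the outcome's log-odds, scaled by ``effect_size``.
    """

    n: int = 309
    benign_fraction: float = 39 / 309
    age_mean: float = 62.6
    age_sd: float = 8.0
    male_fraction: float = 0.5
    prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    nonlinear_pair: Optional[tuple[str, str]] = None
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        probs = [self.benign_fraction, self.male_fraction]
        for p_no, p_yes in self.prevalence.values():
            probs.extend((p_no, p_yes))
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.nonlinear_pair is not None:
            bad = [f for f in self.nonlinear_pair if f not in SYMPTOM_COLUMNS]
            if bad:
                raise ValueError(f"nonlinear_pair names unknown feature(s) {bad}")

    @classmethod
    def xor_benchmark(
        cls, n: int = 309, effect_size: float = 3.0, seed: int = 0
    ) -> "GeneratorConfig":
        """Balanced benchmark where the only signal is an XOR interaction.

        All class-conditional prevalences are equalized, so a linear
        decision function carries no information and only interaction-aware
        kernels can beat chance.
        """
        flat = {f: (0.5, 0.5) for f in SYMPTOM_COLUMNS}
        flat["FATIGUE"] = (0.8, 0.8)
        flat["COUGHING"] = (0.6, 0.6)
        flat["SHORTNESS_OF_BREATH"] = (0.6, 0.6)
        return cls(
            n=n,
            benign_fraction=0.5,
            prevalence=flat,
            nonlinear_pair=("ANXIETY", "PEER_PRESSURE"),
            effect_size=effect_size,
            seed=seed,
        )


def _nb_weights(p_no: float, p_yes: float) -> tuple[float, float]:
    """Per-value log-odds contributions log P(v|YES)/P(v|NO), v in {1, 2}."""
    eps = 1e-6
    p_no = min(max(p_no, eps), 1 - eps)
    p_yes = min(max(p_yes, eps), 1 - eps)
    return (
        float(np.log((1 - p_yes) / (1 - p_no))),  # v = 1 (NO)
        float(np.log(p_yes / p_no)),              # v = 2 (YES)
    )


def synthesize_survey(cfg: GeneratorConfig) -> SurveyTable:
    """Draw a synthetic survey table; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    gender = np.where(rng.random(n) < cfg.male_fraction, "M", "F")
    age = np.clip(
        np.rint(rng.normal(cfg.age_mean, cfg.age_sd, size=n)), 21, 90
    ).astype(int)

    marginal_yes_frac = 1.0 - cfg.benign_fraction
    score = np.zeros(n)
    features: dict[str, np.ndarray] = {}
    for name in SYMPTOM_COLUMNS:
        p_no, p_yes = cfg.prevalence.get(name, (0.5, 0.5))
        p_marginal = marginal_yes_frac * p_yes + cfg.benign_fraction * p_no
        v = np.where(rng.random(n) < p_marginal, 2, 1)
        features[name] = v
        w1, w2 = _nb_weights(p_no, p_yes)
        score += np.where(v == 2, w2, w1)

    if cfg.nonlinear_pair is not None:
        a, b = cfg.nonlinear_pair
        # XOR coded +-1: +1 when the two answers disagree
        xor = np.where(features[a] != features[b], 1.0, -1.0)
        score += cfg.effect_size * xor

    def miss(c: float) -> float:
        return float(np.mean(expit(c + score))) - marginal_yes_frac

    intercept = brentq(miss, -40.0, 40.0)
    outcome = np.where(rng.random(n) < expit(intercept + score), "YES", "NO")

    frame = pd.DataFrame({"GENDER": gender, "AGE": age})
    for name in SYMPTOM_COLUMNS:
        frame[name] = features[name]
    frame[OUTCOME_COLUMN] = outcome
    return SurveyTable(frame)


# ---------------------------------------------------------------------------
# Small helpers for benchmarks and tests
# ---------------------------------------------------------------------------


def make_separable_clusters(
    n: int = 60, d: int = 2, margin: float = 4.0, seed: int = 0
) -> Dataset:
    """Two well-separated Gaussian clusters with +-1 labels.

    The class means sit ``margin`` apart along the first axis with unit-free
    spread 0.5, so the classes are linearly separable by construction for
    margin well above ~2.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    center = np.zeros(d)
    center[0] = margin / 2.0
    X_pos = rng.normal(0, 0.5, size=(half, d)) + center
    X_neg = rng.normal(0, 0.5, size=(n - half, d)) - center
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(half, dtype=int), -np.ones(n - half, dtype=int)])
    order = rng.permutation(n)
    return dataset_from_arrays(X[order], y[order])


def oversample_minority(X: np.ndarray, y: np.ndarray, rng=None):
    """Random-oversample the minority class to parity (training split only)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    idx_min = np.flatnonzero(y == minority)
    extra = rng.choice(idx_min, size=int(counts.max() - counts.min()), replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return X[keep], y[keep]
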