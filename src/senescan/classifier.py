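"""The ML Senescence Classifier (MLSC): an LDA "super-feature" over
single-cell features.

Truth populations are built from the S-index: non-senescent truth are
control-sample cells with SI <= 0.8, senescent truth are induced-sample
cells with SI >= 1.2. Candidate features are z-standardized on the pooled
truth, ranked by Fisher's Rd, and those clearing |Rd| >= 0.5 (at most the
top 10) enter a two-class linear discriminant with equal priors and a
shrinkage-regularized pooled covariance. The offset places the
equal-posterior boundary at score 0, so MLSC > 0 calls senescent and
MLSC < 0 non-senescent.

The joint decision with SI uses the two concordant quadrants only:
senescent iff MLSC > 0 and SI > 0, non-senescent iff both < 0, everything
else ambiguous (strict inequalities). A second-pass classifier (MLSC2) is
retrained on the extreme events — the outer deciles of MLSC within each
first-pass class — standing in for a density-based extreme selection.

The clipped-object image classifier of the original instrument pipeline is
replaced by a deterministic rule: an event is clipped when its segmentation
mask touches the crop border.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import (
    AlignmentError,
    CapabilityError,
    NoSignalError,
    SchemaError,
    TrainingError,
    TruthError,
)
from .events import EventTable
from .imaging import CellImage, segment_cell
from .metrics import fisher_rd

DEFAULT_FEATURES = ["af", "diameter", "area", "aspect_ratio", "circularity", "shape_ratio"]

S_TRUTH = "S_TRUTH"
NONS_TRUTH = "NONS_TRUTH"

_CONTROL_CONDITIONS = {"proliferating", "control", "non_senescent", "nonsenescent"}
_INDUCED_CONDITIONS = {"senescent", "induced", "mixed"}


@dataclass(frozen=True)
class TruthConfig:
    """SI thresholds and source constraint for the truth populations."""

    nons_si_ceiling: float = 0.8
    s_si_floor: float = 1.2
    enforce_source: bool = True

    def __post_init__(self) -> None:
        if self.nons_si_ceiling >= self.s_si_floor:
            raise TruthError("non-senescent ceiling must lie below senescent floor")


@dataclass
class LinearClassifier:
    """score(x) = w · standardized(x) + offset, boundary at 0."""

    features: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    offset: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.offset):
            raise TrainingError("classifier weights must be finite")

    def score(self, X: pd.DataFrame) -> np.ndarray:
        z = (X[self.features].to_numpy(float) - self.means) / self.sds
        return z @ self.weights + self.offset

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "weights": self.weights.tolist(),
                    "offset": self.offset,
                    "metadata": self.metadata,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"],
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            weights=np.array(d["weights"]),
            offset=float(d["offset"]),
            metadata=d.get("metadata", {}),
        )


@dataclass
class ClassificationResult:
    mlsc: np.ndarray
    decision: pd.Series  # senescent | non_senescent | ambiguous
    fraction_senescent: float


def build_truth(
    table: EventTable | pd.DataFrame,
    si,
    config: TruthConfig = TruthConfig(),
) -> pd.Series:
    """Label events S_TRUTH / NONS_TRUTH / None from SI and sample condition.

    With ``enforce_source`` (default), non-senescent truth may only come
    from control samples and senescent truth only from induced samples
    (read from the ``condition`` column); events from unknown conditions
    stay unlabelled.
    """
    df = table.data if isinstance(table, EventTable) else table
    si = np.asarray(si, dtype=float)
    if len(si) != len(df):
        raise AlignmentError("SI vector length does not match table")
    if config.enforce_source:
        if "condition" not in df.columns:
            raise SchemaError("truth building needs a 'condition' column")
        cond = df["condition"].astype(str).str.lower()
        from_control = cond.isin(_CONTROL_CONDITIONS).to_numpy()
        from_induced = cond.isin(_INDUCED_CONDITIONS).to_numpy()
    else:
        from_control = from_induced = np.ones(len(df), dtype=bool)
    labels = pd.Series([None] * len(df), index=df.index, dtype=object)
    labels[(si <= config.nons_si_ceiling) & from_control] = NONS_TRUTH
    labels[(si >= config.s_si_floor) & from_induced] = S_TRUTH
    n_s = int((labels == S_TRUTH).sum())
    n_n = int((labels == NONS_TRUTH).sum())
    if n_s == 0 or n_n == 0:
        raise TruthError(f"empty truth set (S={n_s}, NonS={n_n})")
    return labels


def train_mlsc(
    table: EventTable | pd.DataFrame,
    truth_labels,
    feature_set: list[str] | None = None,
    min_abs_rd: float = 0.5,
    max_features: int = 10,
    shrinkage: float = 1e-3,
    min_class_size: int = 20,
) -> LinearClassifier:
    """Train the linear-discriminant super-feature on the truth populations."""
    df = table.data if isinstance(table, EventTable) else table
    features = list(feature_set or DEFAULT_FEATURES)
    missing = [c for c in features if c not in df.columns]
    if missing:
        raise SchemaError(f"missing feature column(s) {missing}")
    labels = pd.Series(truth_labels).reset_index(drop=True)
    dfr = df.reset_index(drop=True)
    is_s = (labels == S_TRUTH).to_numpy()
    is_n = (labels == NONS_TRUTH).to_numpy()
    if is_s.sum() < min_class_size or is_n.sum() < min_class_size:
        raise TrainingError(
            f"each truth class needs >= {min_class_size} events "
            f"(S={int(is_s.sum())}, NonS={int(is_n.sum())})"
        )
    sel = is_s | is_n
    X = dfr.loc[sel, features].to_numpy(float)
    y = is_s[sel].astype(int)  # 1 = senescent

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    usable = sds > 0
    sds_safe = np.where(usable, sds, 1.0)
    Z = (X - means) / sds_safe

    rd = np.zeros(len(features))
    for j, feat in enumerate(features):
        if usable[j]:
            rd[j] = fisher_rd(Z[y == 1, j], Z[y == 0, j])
    order = sorted(
        range(len(features)),
        key=lambda j: (-abs(rd[j]) if np.isfinite(rd[j]) else -np.inf, features[j]),
    )
    keep = [j for j in order if usable[j] and abs(rd[j]) >= min_abs_rd][:max_features]
    if not keep:
        raise NoSignalError("no feature reaches |Rd| >= %g" % min_abs_rd)

    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=shrinkage, priors=[0.5, 0.5]
    )
    lda.fit(Z[:, keep], y)
    weights = lda.coef_[0]
    offset = float(lda.intercept_[0])
    return LinearClassifier(
        features=[features[j] for j in keep],
        means=means[keep],
        sds=sds_safe[keep],
        weights=weights,
        offset=offset,
        metadata={
            "n_senescent": int(is_s.sum()),
            "n_non_senescent": int(is_n.sum()),
            "rd": {features[j]: float(rd[j]) for j in keep},
            "shrinkage": shrinkage,
        },
    )


def score_events(table: EventTable | pd.DataFrame, classifier: LinearClassifier) -> np.ndarray:
    """Deterministic MLSC scores; events with NaN features score NaN (flagged,
    never silently imputed)."""
    df = table.data if isinstance(table, EventTable) else table
    missing = [c for c in classifier.features if c not in df.columns]
    if missing:
        raise SchemaError(f"missing classifier feature(s) {missing}")
    X = df[classifier.features]
    bad = X.isna().any(axis=1).to_numpy()
    scores = classifier.score(X.fillna(0.0))
    scores[bad] = np.nan
    return scores


def classify_joint(si_values, mlsc_values) -> ClassificationResult:
    """Quadrant rule: senescent iff MLSC > 0 and SI > 0; non-senescent iff
    both < 0; everything else (including exact zeros) ambiguous."""
    si = np.asarray(si_values, dtype=float)
    mlsc = np.asarray(mlsc_values, dtype=float)
    if si.shape != mlsc.shape:
        raise AlignmentError(f"length mismatch: SI {si.shape} vs MLSC {mlsc.shape}")
    decision = np.full(si.shape, "ambiguous", dtype=object)
    decision[(mlsc > 0) & (si > 0)] = "senescent"
    decision[(mlsc < 0) & (si < 0)] = "non_senescent"
    frac = float((decision == "senescent").mean()) if si.size else float("nan")
    return ClassificationResult(
        mlsc=mlsc, decision=pd.Series(decision), fraction_senescent=frac
    )


def train_mlsc2(
    table: EventTable | pd.DataFrame,
    mlsc_scores,
    feature_set: list[str] | None = None,
    extreme_fraction: float = 0.1,
    **train_kwargs,
) -> LinearClassifier:
    """Second-pass classifier from the extremes of the first-pass scores.

    New truth sets are the outer deciles of MLSC within each first-pass
    class (top ``extreme_fraction`` of the positive side, bottom of the
    negative side), then training proceeds as in :func:`train_mlsc`.
    """
    if not 0 < extreme_fraction <= 0.5:
        raise TrainingError("extreme_fraction must be in (0, 0.5]")
    df = table.data if isinstance(table, EventTable) else table
    mlsc = np.asarray(mlsc_scores, dtype=float)
    if len(mlsc) != len(df):
        raise AlignmentError("MLSC vector length does not match table")
    pos = np.where(mlsc > 0)[0]
    neg = np.where(mlsc < 0)[0]
    min_class = train_kwargs.get("min_class_size", 20)
    if len(pos) < min_class or len(neg) < min_class:
        raise TrainingError("first-pass classes too small to take extremes from")
    k_pos = max(int(np.ceil(extreme_fraction * len(pos))), 1)
    k_neg = max(int(np.ceil(extreme_fraction * len(neg))), 1)
    top = pos[np.argsort(mlsc[pos])[-k_pos:]]
    bottom = neg[np.argsort(mlsc[neg])[:k_neg]]
    labels = pd.Series([None] * len(df), dtype=object)
    labels.iloc[top] = S_TRUTH
    labels.iloc[bottom] = NONS_TRUTH
    if len(top) < min_class or len(bottom) < min_class:
        raise TrainingError(
            f"extreme sets below minimum size (S={len(top)}, NonS={len(bottom)})"
        )
    return train_mlsc(df.reset_index(drop=True), labels, feature_set, **train_kwargs)


def flag_clipped(
    images: list[CellImage] | None = None,
    table: EventTable | pd.DataFrame | None = None,
    channel: str = "bf",
) -> np.ndarray:
    """Deterministic clipped-object rule.

    With *images*: an event is clipped when its segmentation mask touches
    the crop border (unsegmentable crops are also flagged — they cannot be
    analysed). With a feature *table*: the generator's ``true_structure``
    flag is used. Raises :class:`CapabilityError` when neither is available.
    """
    if images is not None:
        out = np.zeros(len(images), dtype=bool)
        for i, img in enumerate(images):
            try:
                mask = segment_cell(img, channel=channel)
            except Exception:
                out[i] = True
                continue
            out[i] = mask.touches_border()
        return out
    if table is not None:
        df = table.data if isinstance(table, EventTable) else table
        if "true_structure" not in df.columns:
            raise CapabilityError("table carries no 'true_structure' clipped flag")
        return (df["true_structure"] == "clipped").to_numpy()
    raise CapabilityError("flag_clipped needs images or a flagged feature table")
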