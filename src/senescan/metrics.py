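"""Senescence statistics: reference normalization, S-index, LAF, Fisher Rd.

Per-cell autofluorescence AF and diameter D are normalized to the matched
proliferating control of the same cell model:

    nAF = AF / mean AF of the proliferating sample
    nD  = D  / mean D  of the proliferating sample

and combined into the S-index with a weight factor w = 5 on the diameter
term (AF roughly five-fold outpaces D in senescence):

    SI = (nAF − 1) + w (nD − 1)          (default, "reconciled")
    SI = ((nAF − 1) + w (nD − 1)) / 2    ("as_printed")

The halved variant is the formula as printed in the source method, but only
the un-halved sum reproduces its reported per-model SI means (e.g. HUVEC
2.1, MSC 1.6 from the printed population means); both variants are exposed
and the default is the reconciled one. SI ≈ 0 for non-senescent cells by
construction and rises to roughly 1.5–4 in senescent populations.

Large autofluorescent senescent cells (LAFs) are events with nAF >= 1.5 and
nD >= 1.1 (inclusive, same thresholds for every model); %LAF is their
percentage of the scored events.

Fisher's discriminant ratio Rd = (mean₁ − mean₂) / (SD₁ + SD₂) ranks
candidate features; |Rd| >= 1.5 is the usual bar for a feature that
separates two populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    NormalizationError,
    RankingError,
    ReferenceStatsError,
    SchemaError,
    SummaryError,
)
from .events import EventTable
from .gating import GateLabels

#: default minimum events for a reference; override for tiny biopsies
MIN_REFERENCE_EVENTS = 100


@dataclass(frozen=True)
class ReferenceStats:
    """Proliferating-control means used as normalization denominators."""

    mean_af: float
    mean_d: float
    n: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mean_af <= 0 or self.mean_d <= 0:
            raise NormalizationError("reference means must be positive")


@dataclass(frozen=True)
class MetricsConfig:
    laf_naf_threshold: float = 1.5
    laf_nd_threshold: float = 1.1
    si_weight: float = 5.0
    si_variant: str = "reconciled"  # reconciled | as_printed

    def __post_init__(self) -> None:
        if self.laf_naf_threshold <= 1 or self.laf_nd_threshold <= 1:
            raise NormalizationError("LAF thresholds must exceed 1")
        if self.si_weight <= 0:
            raise NormalizationError("SI weight must be positive")
        if self.si_variant not in {"reconciled", "as_printed"}:
            raise NormalizationError(f"unknown SI variant {self.si_variant!r}")


DEFAULT_METRICS = MetricsConfig()


@dataclass
class SenescenceScores:
    """Per-event nAF/nD/SI/LAF plus sample aggregates."""

    per_event: pd.DataFrame  # columns: naf, nd, si, laf
    mean_si: float
    pct_laf: float
    n: int
    config: MetricsConfig = DEFAULT_METRICS


def compute_reference(
    table: EventTable | pd.DataFrame,
    min_events: int = MIN_REFERENCE_EVENTS,
) -> ReferenceStats:
    """Arithmetic means of AF and D over a live-singles proliferating sample.

    The caller restricts the table to live singles first; AF is the working
    (compensated, if a spillover model was applied) autofluorescence.
    """
    df = table.data if isinstance(table, EventTable) else table
    for col in ("af", "diameter"):
        if col not in df.columns:
            raise SchemaError(f"reference table lacks column {col!r}")
    n = len(df)
    if n < min_events:
        raise ReferenceStatsError(f"reference needs >= {min_events} events, got {n}")
    mean_af = float(df["af"].mean())
    mean_d = float(df["diameter"].mean())
    if not (mean_af > 0 and mean_d > 0):
        raise NormalizationError("non-positive reference mean")
    sid = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else ""
    return ReferenceStats(mean_af=mean_af, mean_d=mean_d, n=n, sample_id=sid)


def s_index(naf, nd, weight: float = 5.0, variant: str = "reconciled"):
    """S-index from normalized AF and normalized diameter."""
    naf = np.asarray(naf, dtype=float)
    nd = np.asarray(nd, dtype=float)
    si = (naf - 1.0) + weight * (nd - 1.0)
    if variant == "as_printed":
        si = si / 2.0
    elif variant != "reconciled":
        raise NormalizationError(f"unknown SI variant {variant!r}")
    return si if si.ndim else float(si)


def senescence_scores(
    table: EventTable | pd.DataFrame,
    reference: ReferenceStats,
    config: MetricsConfig = DEFAULT_METRICS,
) -> SenescenceScores:
    """Score every event of *table* against a proliferating reference."""
    df = table.data if isinstance(table, EventTable) else table
    for col in ("af", "diameter"):
        if col not in df.columns:
            raise SchemaError(f"table lacks column {col!r}")
    naf = df["af"].to_numpy(float) / reference.mean_af
    nd = df["diameter"].to_numpy(float) / reference.mean_d
    si = s_index(naf, nd, config.si_weight, config.si_variant)
    laf = (naf >= config.laf_naf_threshold) & (nd >= config.laf_nd_threshold)
    per_event = pd.DataFrame(
        {"naf": naf, "nd": nd, "si": si, "laf": laf}, index=df.index
    )
    n = len(per_event)
    mean_si = float(np.mean(si)) if n else float("nan")
    pct_laf = float(100.0 * laf.mean()) if n else float("nan")
    return SenescenceScores(per_event=per_event, mean_si=mean_si, pct_laf=pct_laf, n=n, config=config)


def fisher_rd(values_a, values_b) -> float:
    """Fisher's discriminant ratio (mean_a − mean_b) / (SD_a + SD_b).

    Sample standard deviations use the n−1 denominator. A zero pooled
    spread returns 0 for equal means and signed infinity (a saturated
    separation) otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise RankingError("each group needs >= 2 values")
    denom = a.std(ddof=1) + b.std(ddof=1)
    delta = a.mean() - b.mean()
    if denom == 0:
        return 0.0 if delta == 0 else float(np.sign(delta) * np.inf)
    return float(delta / denom)


def rank_features(
    table: EventTable | pd.DataFrame,
    truth_labels,
    feature_set: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank features by |Rd| between two truth groups, descending.

    *truth_labels* is a per-event vector with exactly two distinct non-null
    labels; ties in |Rd| break lexicographically on the feature name.
    """
    df = table.data if isinstance(table, EventTable) else table
    labels = pd.Series(truth_labels).reset_index(drop=True)
    mask = labels.notna()
    groups = sorted(labels[mask].unique().tolist())
    if len(groups) != 2:
        raise RankingError(f"need exactly two truth groups, got {groups}")
    if feature_set is None:
        feature_set = [
            c
            for c in df.columns
            if c not in {"event_id", "sample_id"} and pd.api.types.is_numeric_dtype(df[c])
        ]
    missing = [c for c in feature_set if c not in df.columns]
    if missing:
        raise SchemaError(f"missing feature column(s) {missing}")
    in_a = (labels == groups[0]).to_numpy()
    in_b = (labels == groups[1]).to_numpy()
    out = []
    for feat in feature_set:
        vals = df[feat].to_numpy(float)
        rd = fisher_rd(vals[in_a], vals[in_b])
        out.append((feat, rd))
    out.sort(key=lambda kv: (-abs(kv[1]) if np.isfinite(kv[1]) else -np.inf, kv[0]))
    return out


def sample_summary(
    table: EventTable | pd.DataFrame,
    labels: GateLabels,
    scores: SenescenceScores | pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample viability fractions and live-restricted senescence metrics.

    %live / %apoptotic / %dead are fractions of the gated singles; mean SI
    and %LAF are computed on the live events only, per the method.
    """
    df = table.data if isinstance(table, EventTable) else table
    per_event = scores.per_event if isinstance(scores, SenescenceScores) else scores
    rows = []
    for sid, idx in df.groupby("sample_id").groups.items():
        pop = labels.population.loc[idx]
        via = labels.viability.loc[idx]
        singles = pop == "single"
        n_single = int(singles.sum())
        if n_single == 0:
            raise SummaryError(f"sample {sid!r} has zero gated singles")
        live = via == "live"
        live_idx = idx[(singles & live).to_numpy()]
        ev = per_event.loc[per_event.index.intersection(live_idx)]
        rows.append(
            {
                "sample_id": sid,
                "n_singles": n_single,
                "n_live": int(live.sum()),
                "pct_live": 100.0 * float((via == "live").sum()) / n_single,
                "pct_apoptotic": 100.0 * float((via == "apoptotic").sum()) / n_single,
                "pct_dead": 100.0 * float((via == "dead").sum()) / n_single,
                "mean_si": float(ev["si"].mean()) if len(ev) else float("nan"),
                "pct_laf": 100.0 * float(ev["laf"].mean()) if len(ev) else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
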