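"""Gating: multiplet-safe single-cell selection and live/apoptotic/dead
partitioning.

Two single-cell gate modes are provided. The *conventional* gate bounds area
from above (as done for proliferating cells) and requires a high aspect
ratio; it loses the largest senescent cells, which drift into the multiplet
region of the area vs. aspect-ratio plot. The *extended* gate removes the
upper area bound and relaxes the aspect-ratio minimum, then rejects
multiplets with minima on circularity and shape ratio — round large singles
pass, peanut-shaped aggregates do not.

Viability is assigned only to single-gated events from the DAPI and
Annexin-APC channels: DAPI-positive events are dead, Annexin-positive /
DAPI-negative events are apoptotic, double-negative events are live.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EstimationError,
    SchemaError,
    UndefinedLossError,
)
from .events import EventTable

_SINGLE_FEATURES = ("area", "aspect_ratio", "circularity", "shape_ratio")


@dataclass(frozen=True)
class GateConfig:
    """Gate parameters.

    The conventional upper area bound and the circularity/shape-ratio minima
    are data-driven by default: calibrate them with
    :func:`calibrate_area_max` (97.5th percentile of a proliferating
    reference) and :func:`calibrate_morphology` (0.1th percentile of a
    singles calibration sample) or set them as fixed values. Gate
    comparisons are inclusive (>=) at the boundary.
    """

    mode: str = "extended"  # conventional | extended
    area_min: float = 50.0  # µm²; excludes debris
    area_max: float | None = None  # conventional mode only
    ar_min_conventional: float = 0.6
    ar_min_extended: float = 0.3
    circularity_min: float | None = None
    shape_ratio_min: float | None = None
    morphology_percentile: float = 0.001
    dapi_threshold: float | None = None
    annexin_threshold: float | None = None
    threshold_method: str = "otsu"  # otsu | quantile | fixed
    quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.mode not in {"conventional", "extended"}:
            raise ConfigError(f"unknown gate mode {self.mode!r}")
        if self.mode == "extended" and self.area_max is not None:
            raise ConfigError("extended mode must not set a finite area upper bound")


@dataclass
class GateLabels:
    """Per-event population tag ({excluded, single, multiplet}) and viability
    tag ({live, apoptotic, dead, unassigned}); viability is only assigned to
    singles."""

    population: pd.Series
    viability: pd.Series

    def __post_init__(self) -> None:
        if len(self.population) != len(self.viability):
            raise SchemaError("population/viability label lengths differ")

    @property
    def single(self) -> pd.Series:
        return self.population == "single"

    @property
    def live(self) -> pd.Series:
        return self.viability == "live"

    def counts(self) -> dict[str, int]:
        out = self.population.value_counts().to_dict()
        out.update(self.viability.value_counts().to_dict())
        return {str(k): int(v) for k, v in out.items()}


def _otsu_split(values: np.ndarray) -> float:
    """Exact Otsu on the sample values (no histogram binning).

    Maximizes the between-class variance over every split of the sorted
    sample; the threshold is the midpoint between the two neighbouring
    values at the optimal split, which for well-separated modes lands in
    the middle of the gap rather than at a bin edge.
    """
    x = np.sort(values)
    n = x.size
    csum = np.cumsum(x)
    k = np.arange(1, n)
    m0 = csum[:-1] / k
    m1 = (csum[-1] - csum[:-1]) / (n - k)
    w0 = k / n
    score = w0 * (1.0 - w0) * (m0 - m1) ** 2
    j = int(np.argmax(score))
    return float((x[j] + x[j + 1]) / 2.0)


def estimate_threshold(values, method: str = "otsu", param: float | None = None) -> float:
    """Estimate a gating threshold on intensity *values* (returned on the
    original linear scale).

    ``otsu`` runs Otsu's criterion on log10(1+x) (fluorescence intensities
    are log-shaped) and needs >= 20 finite values; ``quantile`` needs
    ``param`` in (0,1); ``fixed`` returns ``param``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if method == "otsu":
        if x.size < 20:
            raise EstimationError(f"otsu needs >= 20 finite values, got {x.size}")
        logx = np.log10(1.0 + x)
        if np.ptp(logx) == 0:
            raise EstimationError("constant input: otsu threshold undefined")
        return float(10.0 ** _otsu_split(logx) - 1.0)
    if method == "quantile":
        if param is None or not 0 < param < 1:
            raise EstimationError("quantile method needs param in (0,1)")
        if x.size == 0:
            raise EstimationError("no finite values")
        return float(np.quantile(x, param))
    if method == "fixed":
        if param is None:
            raise EstimationError("fixed method needs param")
        return float(param)
    raise ConfigError(f"unknown threshold method {method!r}")


def calibrate_morphology(config: GateConfig, singles: EventTable | pd.DataFrame) -> GateConfig:
    """Fill circularity/shape-ratio minima from a singles calibration sample
    (default: its 0.1th percentile, so essentially all true singles pass)."""
    df = singles.data if isinstance(singles, EventTable) else singles
    q = config.morphology_percentile
    return replace(
        config,
        circularity_min=float(np.quantile(df["circularity"], q)),
        shape_ratio_min=float(np.quantile(df["shape_ratio"], q)),
    )


def calibrate_area_max(
    config: GateConfig, reference: EventTable | pd.DataFrame, percentile: float = 0.975
) -> GateConfig:
    """Set the conventional upper area bound from a proliferating reference
    sample (default: its 97.5th percentile)."""
    df = reference.data if isinstance(reference, EventTable) else reference
    return replace(config, area_max=float(np.quantile(df["area"], percentile)))


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing feature column(s) {missing}")


def gate_singles(table: EventTable, config: GateConfig) -> GateLabels:
    """Tag each event excluded / single / multiplet.

    Conventional mode: single iff area in [area_min, area_max] and
    aspect_ratio >= ar_min_conventional. Extended mode: candidate iff
    area >= area_min and aspect_ratio >= ar_min_extended; candidates are
    singles iff circularity and shape ratio clear their minima, multiplets
    otherwise; non-candidates are excluded.
    """
    df = table.data
    _require(df, _SINGLE_FEATURES)
    n = len(df)
    population = pd.Series(["excluded"] * n, index=df.index, dtype=object)
    if n:
        area = df["area"].to_numpy(float)
        ar = df["aspect_ratio"].to_numpy(float)
        if config.mode == "conventional":
            if config.area_max is None:
                raise ConfigError(
                    "conventional mode needs area_max (see calibrate_area_max)"
                )
            single = (area >= config.area_min) & (area <= config.area_max) & (
                ar >= config.ar_min_conventional
            )
            population[single] = "single"
        else:
            if config.circularity_min is None or config.shape_ratio_min is None:
                raise ConfigError(
                    "extended mode needs circularity/shape-ratio minima "
                    "(see calibrate_morphology)"
                )
            candidate = (area >= config.area_min) & (ar >= config.ar_min_extended)
            round_enough = (df["circularity"].to_numpy(float) >= config.circularity_min) & (
                df["shape_ratio"].to_numpy(float) >= config.shape_ratio_min
            )
            population[candidate & round_enough] = "single"
            population[candidate & ~round_enough] = "multiplet"
    viability = pd.Series(["unassigned"] * n, index=df.index, dtype=object)
    return GateLabels(population, viability)


def gate_live(table: EventTable, labels: GateLabels, config: GateConfig) -> GateLabels:
    """Assign live / apoptotic / dead to single-gated events.

    Dead iff DAPI > t_dapi; apoptotic iff Annexin > t_annexin and
    DAPI <= t_dapi; live otherwise. Thresholds default to Otsu on the
    singles' log intensities when not fixed in the config.
    """
    df = table.data
    _require(df, ("dapi", "annexin"))
    single = labels.single
    viability = pd.Series(["unassigned"] * len(df), index=df.index, dtype=object)
    if single.any():
        dapi = df.loc[single, "dapi"].to_numpy(float)
        annexin = df.loc[single, "annexin"].to_numpy(float)
        t_d = (
            config.dapi_threshold
            if config.dapi_threshold is not None
            else estimate_threshold(dapi, config.threshold_method, config.quantile)
        )
        t_a = (
            config.annexin_threshold
            if config.annexin_threshold is not None
            else estimate_threshold(annexin, config.threshold_method, config.quantile)
        )
        tags = np.where(
            dapi > t_d, "dead", np.where(annexin > t_a, "apoptotic", "live")
        )
        viability[single] = tags
    return GateLabels(labels.population.copy(), viability)


def large_cell_loss(
    labels_conventional: GateLabels,
    labels_reference: GateLabels,
    large_mask,
) -> float:
    """Fraction of large events kept by the reference gate but lost by the
    conventional gate.

    ``large_mask`` is a caller-defined boolean vector over the common event
    universe (e.g. top size decile, or true senescent labels). Raises
    :class:`UndefinedLossError` when the reference gate holds no large
    events.
    """
    large = np.asarray(large_mask, dtype=bool)
    ref = labels_reference.single.to_numpy()
    conv = labels_conventional.single.to_numpy()
    if not (len(large) == len(ref) == len(conv)):
        raise SchemaError("label sets and large_mask must share one event universe")
    denom = large & ref
    if denom.sum() == 0:
        raise UndefinedLossError("no large events in the reference gate")
    lost = denom & ~conv
    return float(lost.sum() / denom.sum())
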