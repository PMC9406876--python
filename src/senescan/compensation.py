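"""Spillover of drug fluorescence into the autofluorescence channel.

Doxorubicin is itself fluorescent (maximum in Ch04) and can leak into the
autofluorescence band (Ch02). The correction is a single-coefficient
subtraction: the coefficient is estimated from a control sample saturated
with the drug (so the target channel is spill-dominated) and then
AF_corrected = max(0, AF − s·DOX) is applied per event. Negative corrected
values are unphysical and clamped at zero; the count of clamped events is
logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EstimationError, SchemaError
from .events import EventTable

logger = logging.getLogger(__name__)

MIN_CONTROL_EVENTS = 20


@dataclass(frozen=True)
class SpilloverModel:
    """Single-coefficient spillover: ``target`` receives ``s``·``source``."""

    source: str = "dox"
    target: str = "af"
    coefficient: float = 0.0
    n: int = 0
    method: str = "ratio"

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient) or self.coefficient < 0:
            raise EstimationError("spillover coefficient must be finite and >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpilloverModel":
        return cls(**json.loads(Path(path).read_text()))


def estimate_spillover(
    control: EventTable | pd.DataFrame,
    source: str = "dox",
    target: str = "af",
    method: str = "ratio",
    signal_quantile: float = 0.5,
) -> SpilloverModel:
    """Estimate the spillover coefficient from a drug-saturated control.

    Events with source intensity above ``signal_quantile`` of the positive
    events are used, ensuring spill dominance over the cells' own background.
    ``method='ratio'`` takes the median of target/source (robust to residual
    background); ``method='regression'`` fits a zero-intercept least-squares
    slope. A negative fit is clamped to 0 with a warning.
    """
    df = control.data if isinstance(control, EventTable) else control
    for col in (source, target):
        if col not in df.columns:
            raise SchemaError(f"control table lacks channel column {col!r}")
    x = df[source].to_numpy(float)
    y = df[target].to_numpy(float)
    pos = x > 0
    if not pos.any():
        raise EstimationError("source channel is all zero in the control")
    cut = np.quantile(x[pos], signal_quantile)
    sel = x >= cut
    if sel.sum() < MIN_CONTROL_EVENTS:
        raise EstimationError(
            f"only {int(sel.sum())} qualifying control events (< {MIN_CONTROL_EVENTS})"
        )
    xs, ys = x[sel], y[sel]
    if method == "ratio":
        s = float(np.median(ys / xs))
    elif method == "regression":
        s = float(np.sum(xs * ys) / np.sum(xs * xs))
    else:
        raise EstimationError(f"unknown estimation method {method!r}")
    if s < 0:
        logger.warning("fitted spillover %g < 0; clamped to 0", s)
        s = 0.0
    return SpilloverModel(source=source, target=target, coefficient=s, n=int(sel.sum()), method=method)


def apply_compensation(table: EventTable, model: SpilloverModel) -> EventTable:
    """Subtract the fitted spill from the target channel.

    The corrected values replace the working ``target`` column (downstream
    scoring always uses the working autofluorescence); the original is
    retained as ``<target>_raw``. Corrected intensities are clamped at 0.
    """
    df = table.data
    for col in (model.source, model.target):
        if col not in df.columns:
            raise SchemaError(f"table lacks channel column {col!r} required by the model")
    corrected = df[model.target].to_numpy(float) - model.coefficient * df[
        model.source
    ].to_numpy(float)
    clamped = int((corrected < 0).sum())
    if clamped:
        logger.info("compensation clamped %d negative event(s) to 0", clamped)
    out = df.copy()
    raw_col = f"{model.target}_raw"
    if raw_col not in out.columns:
        out[raw_col] = df[model.target]
    out[model.target] = np.maximum(corrected, 0.0)
    return EventTable(out, meta=table.meta)
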