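"""Convenience composition of the standard analysis chain.

These helpers wire the individual stages together the way a routine run
uses them: clipped-object removal, extended single-cell gating, viability
gating, then reference normalization and scoring. Each stage remains
available separately for non-standard workflows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import flag_clipped
from .errors import CapabilityError
from .events import EventTable
from .gating import GateConfig, GateLabels, calibrate_morphology, gate_live, gate_singles
from .metrics import (
    MetricsConfig,
    DEFAULT_METRICS,
    ReferenceStats,
    SenescenceScores,
    compute_reference,
    senescence_scores,
)


def live_singles(
    table: EventTable,
    config: GateConfig | None = None,
    calibration: EventTable | pd.DataFrame | None = None,
    drop_clipped: bool = True,
) -> tuple[EventTable, GateLabels]:
    """Return the live single-cell population of *table* and its labels.

    ``calibration`` is the singles sample used to set the circularity /
    shape-ratio minima when the config has none (defaults to the input's
    own high-aspect-ratio events, a self-calibration adequate for samples
    dominated by singles).
    """
    clipped = np.zeros(len(table), dtype=bool)
    if drop_clipped:
        try:
            clipped = flag_clipped(table=table)
        except CapabilityError:
            pass  # no clipped flags available; proceed on all events
    config = config or GateConfig()
    if config.mode == "extended" and (
        config.circularity_min is None or config.shape_ratio_min is None
    ):
        if calibration is None:
            df = table.data.loc[~clipped]
            calibration = df[df["aspect_ratio"] >= np.quantile(df["aspect_ratio"], 0.5)]
        config = calibrate_morphology(config, calibration)
    labels = gate_singles(table, config)
    # clipped objects cannot be analysed; exclude them before viability gating
    labels.population[clipped] = "excluded"
    labels = gate_live(table, labels, config)
    keep = (labels.population == "single") & (labels.viability == "live")
    subset = EventTable(table.data.loc[keep].reset_index(drop=True), meta=table.meta)
    return subset, labels


def score_against_reference(
    sample_live: EventTable,
    reference_live: EventTable,
    config: MetricsConfig = DEFAULT_METRICS,
    min_reference_events: int | None = None,
) -> tuple[SenescenceScores, ReferenceStats]:
    """Compute ReferenceStats on the proliferating live singles and score the
    sample's live singles against them."""
    kwargs = {} if min_reference_events is None else {"min_events": min_reference_events}
    ref = compute_reference(reference_live, **kwargs)
    scores = senescence_scores(sample_live, ref, config)
    return scores, ref
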