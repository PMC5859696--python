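"""End-to-end orchestration: velocity field -> component results.

Thin glue over the module stages in their canonical order (trace,
classify, time the diastasis, split E/A, compute energetics, QC); it
adds no science of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .energetics import ComponentResult, component_curves
from .flow_components import (
    ComponentLabels,
    QcReport,
    TimingError,
    classify,
    find_mid_diastasis,
    qc_inflow_outflow,
    split_e_a,
)
from .flow_io import CardiacTiming, LvSegmentation, RHO_BLOOD, VelocityField
from .pathline_engine import PathlineSet, emit_all

logger = logging.getLogger("ventriflow")


@dataclass
class AnalysisOutput:
    paths: PathlineSet
    labels: ComponentLabels
    timing: CardiacTiming
    results: dict[str, ComponentResult]
    qc: QcReport


def analyze(
    field: VelocityField,
    seg: LvSegmentation,
    timing: CardiacTiming,
    rho: float = RHO_BLOOD,
    step_fraction: float = 0.25,
    qc_threshold_pct: float = 15.0,
    speed_source: str = "field",
) -> AnalysisOutput:
    """Run the full flow-component analysis on a preprocessed dataset.

    If the E/A split is impossible (no inflow pathlines), the four
    primary components are still reported and the subvolumes stay
    empty; the condition is logged and reflected in the QC report.
    """
    paths = emit_all(field, seg, timing, step_fraction=step_fraction)
    labels = classify(paths, seg)
    try:
        find_mid_diastasis(paths, labels, seg, timing)
        labels = split_e_a(paths, labels, seg, timing)
    except TimingError as exc:
        logger.warning("E/A split skipped: %s", exc)
    results = component_curves(paths, labels, timing, rho=rho, speed_source=speed_source)
    qc = qc_inflow_outflow(labels, paths.voxel_volume_ml,
                           threshold_pct=qc_threshold_pct, paths=paths)
    return AnalysisOutput(paths=paths, labels=labels, timing=timing,
                          results=results, qc=qc)
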