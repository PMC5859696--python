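"""Simple static plots of component kinetic-energy curves."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .energetics import ComponentResult
from .flow_components import DISPLAY_NAMES


def plot_ke_curves(
    results: Mapping[str, ComponentResult],
    path: str | Path,
    components: tuple[str, ...] = ("direct_flow_e", "direct_flow_a",
                                   "retained_inflow_e", "retained_inflow_a"),
) -> Path:
    """KE-over-the-cycle panel for the selected components."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for name in components:
        res = results[name]
        ax.plot(res.frame_times, res.ke_curve_mj, label=DISPLAY_NAMES.get(name, name))
    ax.set_xlabel("time in cycle (s)")
    ax.set_ylabel("kinetic energy (mJ)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
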