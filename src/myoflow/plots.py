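"""Optional figures: rose diagrams and correlogram curves."""

from __future__ import annotations

import numpy as np

from .angular import rose_histogram
from .pulses import Correlogram


def rose_diagram(angles, bin_width: float = 20.0, ax=None, color="C0"):
    """Polar rose diagram of movement angles (0 = anterior, 90 = Up).

    Returns the matplotlib axes (created on demand as a polar axes).
    """
    import matplotlib.pyplot as plt

    rose = rose_histogram(angles, bin_width)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians(np.arange(len(rose)) * bin_width + bin_width / 2)
    ax.bar(centers, rose.to_numpy(), width=np.radians(bin_width),
           color=color, edgecolor="black", linewidth=0.5, alpha=0.8)
    ax.set_theta_zero_location("E")  # 0 deg (anterior) to the right
    ax.set_theta_direction(1)        # angles grow toward Up
    ax.set_xticks(np.radians([0, 90, 180, 270]))
    ax.set_xticklabels(["A", "Up", "P", "Down"])
    return ax


def correlogram_plot(correlogram: Correlogram, ax=None, color="C3",
                     label=None):
    """Cross-correlation vs. time offset, with the peak marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(correlogram.offsets_s, correlogram.R, color=color, label=label)
    if correlogram.R_sem is not None:
        ax.fill_between(correlogram.offsets_s,
                        correlogram.R - correlogram.R_sem,
                        correlogram.R + correlogram.R_sem,
                        color=color, alpha=0.2, linewidth=0)
    ax.axvline(correlogram.peak_offset_s, color=color, linestyle=":",
               linewidth=1)
    ax.axvline(0.0, color="grey", linewidth=0.5)
    ax.set_xlabel("offset (s); positive = intensity precedes area reduction")
    ax.set_ylabel("cross-correlation R")
    return ax
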