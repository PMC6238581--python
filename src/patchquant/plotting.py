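"""Plot helpers for aligned curves and bleach diagnostics."""

from __future__ import annotations

import numpy as np

from .alignment import AlignedCurve
from .photobleach import BleachModel


def plot_aligned_curve(curve: AlignedCurve, ax=None, label=None, color=None):
    """Mean ± SD ribbon of an aligned patch curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    good = np.isfinite(curve.mean)
    (line,) = ax.plot(curve.time[good], curve.mean[good], label=label, color=color)
    ax.fill_between(
        curve.time[good],
        curve.mean[good] - curve.sd[good],
        curve.mean[good] + curve.sd[good],
        alpha=0.3,
        color=line.get_color(),
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"patch intensity ({curve.units})")
    return ax


def plot_bleach_fit(times, trace, model: BleachModel, ax=None):
    """Median intracellular trace with the fitted double-exponential decay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(times, trace, "o", ms=3, label="median intracellular")
    ax.plot(times, model.normalization * model.decay(times), "-", label="double-exponential fit")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("brightness (ADU)")
    ax.legend()
    return ax
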