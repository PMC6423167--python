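"""Report plots (optional; requires matplotlib).

Latency distributions are conventionally drawn with a log-scaled count
axis so rare near-deadline events remain visible next to the bulk of
sub-microsecond wakes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_latency_histogram", "plot_hybrid_trace"]


def plot_latency_histogram(summary, ax=None, threshold_label: bool = True):
    """Latency histogram from a :class:`LatencySummary`, log-scaled counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = np.asarray(summary.hist_edges) * 1e6
    counts = np.asarray(summary.hist_counts)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="tab:blue", edgecolor="none")
    ax.set_yscale("log")
    ax.set_xlabel("latency (µs)")
    ax.set_ylabel("intervals")
    if threshold_label:
        ax.axvline(summary.fail_threshold * 1e6, color="red", lw=1,
                   label=f"real-time limit ({summary.fail_threshold*1e6:.0f} µs)")
        ax.legend(frameon=False)
    return ax


def plot_hybrid_trace(trace, t_from: float | None = None,
                      t_to: float | None = None, axes=None):
    """Membrane potentials and synaptic currents of a hybrid run."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(9, 5))
    seg = trace
    if t_from is not None:
        seg = seg[seg.time_s >= t_from]
    if t_to is not None:
        seg = seg[seg.time_s <= t_to]
    axes[0].plot(seg.time_s, seg.live_mV, lw=0.6, label="living")
    axes[0].plot(seg.time_s, seg.model_mV, lw=0.6, label="model (mapped)")
    axes[0].set_ylabel("V (mV)")
    axes[0].legend(frameon=False, ncol=2)
    axes[1].plot(seg.time_s, seg.i_model_to_live_nA, lw=0.6,
                 label="model→live")
    axes[1].plot(seg.time_s, seg.i_live_to_model_nA, lw=0.6,
                 label="live→model")
    axes[1].set_ylabel("I (nA)")
    axes[1].set_xlabel("time (s)")
    axes[1].legend(frameon=False, ncol=2)
    return axes
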