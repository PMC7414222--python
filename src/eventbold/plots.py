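"""Optional diagnostic plots (requires matplotlib).

Currently a single figure: boundary-locked FIR timecourses overlaid by age
group, the standard visual check that an age effect reflects a change in
response amplitude rather than shape or latency.
"""

from __future__ import annotations

import numpy as np

from .glm import FirTimecourse


def plot_fir_timecourses(
    timecourses: dict[str, FirTimecourse],
    tr_s: float,
    path: str,
    title: str = "Boundary-locked FIR timecourse",
) -> None:
    """Write a PNG of FIR amplitude vs peristimulus time, one line per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, fir in timecourses.items():
        ax.plot(np.asarray(fir.lags) * tr_s, fir.amplitudes, marker="o", label=label)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("time from boundary (s)")
    ax.set_ylabel("amplitude (% signal)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
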