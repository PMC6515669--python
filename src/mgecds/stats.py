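"""Descriptive length statistics for output sequence sets (.stats / .png)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import numpy as np

from ._types import LengthStats, MgecdsError


def compute_stats(lengths: Iterable[int]) -> LengthStats:
    """n / min / max / mean / median / sample sd plus a text histogram.

    The sd uses the n-1 denominator; for a single observation it is
    reported as 0 with a note rather than omitted, keeping the file schema
    stable. Histogram bin width follows a Freedman-Diaconis-style rule with
    integer bins.
    """
    values = np.asarray(sorted(lengths), dtype=np.int64)
    if values.size == 0:
        return LengthStats(n=0)
    if np.any(values <= 0):
        raise MgecdsError("sequence lengths must be positive")
    n = int(values.size)
    if n == 1:
        v = int(values[0])
        return LengthStats(
            n=1, min=v, max=v, mean=float(v), median=float(v),
            sd=0.0, sd_note="single observation; sd undefined, reported as 0",
            histogram=[(v, v + 1, 1)],
        )
    stats = LengthStats(
        n=n,
        min=int(values.min()),
        max=int(values.max()),
        mean=float(values.mean()),
        median=float(np.median(values)),
        sd=float(values.std(ddof=1)),
    )
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    width = 2.0 * iqr / (n ** (1.0 / 3.0))
    bin_width = max(1, int(round(width)))
    lo = int(values.min())
    edges = np.arange(lo, int(values.max()) + bin_width + 1, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    stats.histogram = [
        (int(edges[i]), int(edges[i + 1]), int(counts[i])) for i in range(len(counts))
    ]
    return stats


def write_stats(stats: LengthStats, path: Union[str, Path], label: str = "") -> None:
    """Write a plain-text .stats file; histogram counts are always text."""
    with open(path, "w") as fh:
        if label:
            fh.write(f"# {label}\n")
        if stats.n == 0:
            fh.write("0 sequences\n")
            return
        fh.write(f"n\t{stats.n}\n")
        fh.write(f"min\t{stats.min}\n")
        fh.write(f"max\t{stats.max}\n")
        fh.write(f"mean\t{stats.mean:.2f}\n")
        fh.write(f"median\t{stats.median:.1f}\n")
        fh.write(f"sd\t{stats.sd:.2f}\n")
        if stats.sd_note:
            fh.write(f"# {stats.sd_note}\n")
        fh.write("# histogram: bin_start\tbin_end\tcount\n")
        for lo, hi, c in stats.histogram:
            fh.write(f"{lo}\t{hi}\t{c}\n")


def plot_histogram(stats: LengthStats, path: Union[str, Path], title: str = "") -> None:
    """Optional PNG histogram; tests and the pipeline default never require it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if stats.histogram:
        lefts = [b[0] for b in stats.histogram]
        widths = [b[1] - b[0] for b in stats.histogram]
        counts = [b[2] for b in stats.histogram]
        ax.bar(lefts, counts, width=widths, align="edge", edgecolor="black")
    ax.set_xlabel("sequence length (bp)")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
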