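"""Minimal rearrangement plot: SV arcs over a total/minor CN step track.

A convenience figure, never an interface: plotting does not affect calls.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Arc

from .caller import ChromothripsisCall
from .genome import CNSegment

CLASS_COLORS = {
    "DEL": "#1f77b4",
    "DUP": "#d62728",
    "h2hINV": "#2ca02c",
    "t2tINV": "#9467bd",
    "TRA": "#7f7f7f",
}


def plot_call(
    call: ChromothripsisCall,
    cn: list[CNSegment],
    path: str | os.PathLike,
    pad_frac: float = 0.05,
) -> None:
    """Render one cluster: junction arcs on top, CN steps below."""
    cluster = call.cluster
    span = cluster.span_end - cluster.span_start
    lo = cluster.span_start - pad_frac * span
    hi = cluster.span_end + pad_frac * span

    fig, (ax_sv, ax_cn) = plt.subplots(
        2, 1, figsize=(9, 4.5), sharex=True,
        gridspec_kw={"height_ratios": [2, 1], "hspace": 0.08},
    )
    for sv in cluster.members:
        x1, x2 = sv.bnd1.pos, sv.bnd2.pos
        center, width = (x1 + x2) / 2, max(abs(x2 - x1), span * 0.002)
        ax_sv.add_patch(
            Arc((center, 0), width, 1.0, theta1=0, theta2=180,
                color=CLASS_COLORS.get(sv.sv_class, "black"), lw=1.2)
        )
    ax_sv.set_ylim(0, 0.65)
    ax_sv.set_yticks([])
    ax_sv.set_title(
        f"{cluster.chrom}:{cluster.span_start:,}-{cluster.span_end:,}  "
        f"{call.classification} (n={cluster.n_intra})"
    )
    handles = [
        plt.Line2D([], [], color=c, label=k)
        for k, c in CLASS_COLORS.items() if k != "TRA"
    ]
    ax_sv.legend(handles=handles, loc="upper right", fontsize=7, frameon=False)

    segs = [s for s in cn if s.chrom == cluster.chrom]
    for seg in segs:
        ax_cn.hlines(seg.total_cn, seg.start, seg.end, color="black", lw=2)
        if seg.minor_cn is not None:
            ax_cn.hlines(seg.minor_cn, seg.start, seg.end, color="orange", lw=1.2)
    max_cn = max((s.total_cn for s in segs), default=2)
    ax_cn.set_ylim(-0.3, max_cn + 0.7)
    ax_cn.set_ylabel("copy number")
    ax_cn.set_xlabel(f"{cluster.chrom} position (bp)")
    ax_cn.set_xlim(lo, hi)
    fig.savefig(os.fspath(path), bbox_inches="tight")
    plt.close(fig)


__all__ = ["plot_call"]
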