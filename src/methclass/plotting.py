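"""Figure output: embedding scatter, per-sample CNV profile, summary tracks.

Uses Agg figure objects directly (no pyplot state) so plotting works in
headless pipelines.
"""

from __future__ import annotations

import numpy as np

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .containers import ClusterAssignment, CNVProfile, CohortSummaryTrack, NOISE_LABEL

GAIN_COLOR = "#2ca02c"  # green
LOSS_COLOR = "#d62728"  # red


def _save(fig: Figure, path) -> None:
    FigureCanvasAgg(fig)
    fig.savefig(path, dpi=150, bbox_inches="tight")


def _genome_axis(bins):
    """Cumulative x-coordinates per bin plus chromosome boundary ticks."""
    chroms, offsets, xs = [], {}, []
    cursor = 0
    for b in bins:
        if b.chrom not in offsets:
            chrom_end = max(x.end for x in bins if x.chrom == b.chrom)
            offsets[b.chrom] = cursor
            chroms.append((b.chrom, cursor, cursor + chrom_end))
            cursor += chrom_end
        xs.append(offsets[b.chrom] + (b.start + b.end) / 2)
    widths = [b.end - b.start for b in bins]
    return np.array(xs), np.array(widths), chroms


def plot_embedding(
    assignment: ClusterAssignment,
    mapping: dict[int, str] | None,
    path,
    title: str = "UMAP of methylation beta values",
) -> None:
    """Scatter of the 2-D embedding, colored by cluster, noise in grey."""
    fig = Figure(figsize=(7, 6))
    ax = fig.add_subplot(111)
    labels = assignment.labels
    cmap = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]
    for k, cid in enumerate(assignment.cluster_ids):
        pts = assignment.embedding[labels == cid]
        name = f"cluster {cid}"
        if mapping is not None and cid in mapping:
            name = f"{mapping[cid]} ({cid})"
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=cmap[k % len(cmap)], label=name)
    noise = assignment.embedding[labels == NOISE_LABEL]
    if len(noise):
        ax.scatter(noise[:, 0], noise[:, 1], s=10, color="lightgrey", label="noise")
    if assignment.reference_flag is not None and assignment.reference_flag.any():
        refs = assignment.embedding[assignment.reference_flag]
        ax.scatter(refs[:, 0], refs[:, 1], s=60, facecolors="none",
                   edgecolors="black", label="reference cohort")
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    ax.set_title(title)
    ax.legend(fontsize=8, loc="best")
    _save(fig, path)


def plot_cnv_profile(profile: CNVProfile, path) -> None:
    """Per-sample binned log2 ratios with segment means along the genome."""
    xs, _, chroms = _genome_axis(profile.bins)
    fig = Figure(figsize=(11, 3.2))
    ax = fig.add_subplot(111)
    colors = np.where(
        profile.calls == "gain", GAIN_COLOR,
        np.where(profile.calls == "loss", LOSS_COLOR, "#555555"),
    )
    ax.scatter(xs, profile.log2_ratio, s=8, c=colors)
    for seg in profile.segments.itertuples(index=False):
        b0, b1 = seg.start_bin, seg.end_bin - 1
        chrom_off = xs[b0] - (profile.bins[b0].start + profile.bins[b0].end) / 2
        ax.hlines(seg.seg_mean, chrom_off + seg.start, chrom_off + seg.end,
                  colors="black", linewidth=2)
    _decorate_genome_axis(ax, chroms)
    ax.axhline(0, color="grey", linewidth=0.5)
    ax.set_ylabel("log2 ratio")
    ax.set_title(f"CNV profile — {profile.sample_id}")
    _save(fig, path)


def plot_summary_track(track: CohortSummaryTrack, path) -> None:
    """Cohort summary: % gained upward in green, % lost downward in red."""
    xs, widths, chroms = _genome_axis(track.bins)
    fig = Figure(figsize=(11, 3.2))
    ax = fig.add_subplot(111)
    ax.bar(xs, track.pct_gain, width=widths, color=GAIN_COLOR, label="gain")
    ax.bar(xs, -track.pct_loss, width=widths, color=LOSS_COLOR, label="loss")
    _decorate_genome_axis(ax, chroms)
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_ylim(-100, 100)
    ax.set_ylabel("% of samples altered")
    ax.set_title(f"CNV summary — {track.group} (n = {track.n_samples})")
    ax.legend(fontsize=8, loc="upper right")
    _save(fig, path)


def _decorate_genome_axis(ax, chroms) -> None:
    for name, start, end in chroms:
        if start > 0:
            ax.axvline(start, color="lightgrey", linewidth=0.6)
    ax.set_xticks([(s + e) / 2 for _, s, e in chroms])
    ax.set_xticklabels([name for name, _, _ in chroms], fontsize=8)
    ax.set_xlim(0, chroms[-1][2])
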