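"""Cohort-level CNV frequency summary tracks.

Aggregates the discrete per-bin gain/loss calls of a sample group into a
per-bin percentage-altered track — the group-level view in which a
CNV-rich tumor class stands out against classes with flat profiles.
Frequencies are computed from discrete segment-derived calls, not from
averaged log2 ratios, so the y-axis reads directly as "percentage of
samples showing an alteration".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CNVProfile, CohortSummaryTrack, GAIN, LOSS


def _check_shared_bins(profiles: list[CNVProfile]) -> None:
    first = profiles[0].bins
    for p in profiles[1:]:
        if len(p.bins) != len(first) or any(
            (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end)
            for a, b in zip(p.bins, first)
        ):
            raise ValueError("profiles do not share one bin set")


def summarize_group(
    profiles: list[CNVProfile],
    group_members,
    group: str = "group",
) -> CohortSummaryTrack:
    """Per-bin gain/loss percentages across a group of sample profiles.

    ``pct_gain`` in a bin is ``100 * #(members called gain) / n_members``
    and ``pct_loss`` analogously; neutral is the complement.
    """
    members = list(group_members)
    if not members:
        raise ValueError("empty group")
    by_id = {p.sample_id: p for p in profiles}
    missing = [m for m in members if m not in by_id]
    if missing:
        raise ValueError(f"no CNV profile for group members: {missing}")
    selected = [by_id[m] for m in members]
    _check_shared_bins(selected)
    calls = np.array([p.calls for p in selected])  # members x bins
    n = len(selected)
    pct_gain = 100.0 * (calls == GAIN).sum(axis=0) / n
    pct_loss = 100.0 * (calls == LOSS).sum(axis=0) / n
    return CohortSummaryTrack(group, selected[0].bins, n, pct_gain, pct_loss)


def compare_tracks(track_a: CohortSummaryTrack, track_b: CohortSummaryTrack) -> pd.DataFrame:
    """Per-bin frequency differences between two group tracks.

    Returns a DataFrame with ``delta_pct_gain`` / ``delta_pct_loss``
    (a minus b), sorted by descending ``abs_delta`` — the larger of the
    two absolute differences per bin.
    """
    if len(track_a.bins) != len(track_b.bins) or any(
        (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end)
        for a, b in zip(track_a.bins, track_b.bins)
    ):
        raise ValueError("tracks are on different bin sets")
    df = track_a.to_frame()[["chrom", "start", "end"]].copy()
    df["delta_pct_gain"] = track_a.pct_gain - track_b.pct_gain
    df["delta_pct_loss"] = track_a.pct_loss - track_b.pct_loss
    df["abs_delta"] = np.maximum(
        np.abs(df["delta_pct_gain"]), np.abs(df["delta_pct_loss"])
    )
    return df.sort_values("abs_delta", ascending=False, kind="stable")


def render_summary(track: CohortSummaryTrack, path) -> None:
    """Genome-axis summary plot: gains upward in green, losses downward in red."""
    from .plotting import plot_summary_track

    plot_summary_track(track, path)
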