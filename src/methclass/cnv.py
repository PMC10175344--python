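"""Intensity-based copy-number calling against copy-neutral references.

The approach follows the conumee tradition for methylation arrays:

1. total log2 intensity per probe, ``log2(M + U + 1)``;
2. per-sample baseline fit — ordinary least squares of the query's
   probe vector on the copy-neutral reference samples (plus intercept);
   the residuals, median-centered, are the per-probe log2 ratios;
3. aggregation into genomic bins (tiling windows merged until each bin
   holds a minimum number of probes), per-bin value = median ratio;
4. circular binary segmentation (CBS) with a seeded permutation test;
5. discrete gain / neutral / loss calls by thresholding segment means.

The intercept in step 2 together with the median-centering makes the
profile invariant to global intensity scaling, so raw and normalized
intensities give the same ratios up to the pseudo-count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    IntensityMatrix,
    GenomicBin,
    CNVProfile,
    GAIN,
    NEUTRAL,
    LOSS,
    validate_manifest,
)
from .preprocess import _chrom_key

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNVParams:
    """Binning, segmentation and calling thresholds.

    ``target_bin_size`` defaults to the 50 kb used on real-scale
    manifests; synthetic genomes with sparser probes use larger windows
    via configuration.  ``call_threshold`` is the |log2 ratio| above
    which a segment is called gained or lost.
    """

    min_probes_per_bin: int = 15
    target_bin_size: int = 50_000
    seg_alpha: float = 0.01
    seg_permutations: int = 100
    min_seg_bins: int = 2
    call_threshold: float = 0.15
    non_negative_fit: bool = False  # constrain reference coefficients >= 0

    def __post_init__(self) -> None:
        if min(self.min_probes_per_bin, self.target_bin_size,
               self.seg_permutations, self.min_seg_bins) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.seg_alpha < 1.0:
            raise ValueError("seg_alpha must be in (0, 1)")
        if self.call_threshold <= 0:
            raise ValueError("call_threshold must be positive")


def total_log_intensity(matrix: IntensityMatrix) -> pd.DataFrame:
    """``log2(meth + unmeth + 1)`` per probe/sample (pseudo-count guards zeros)."""
    return np.log2(matrix.total() + 1.0)


def fit_reference(query, references, non_negative: bool = False) -> np.ndarray:
    """Per-probe log2 ratio of a query against copy-neutral references.

    Ordinary least squares of the query's total log intensities on the
    reference matrix plus an intercept; the returned ratio is the
    residual vector, median-centered so the genome-wide median is zero.
    Negative reference coefficients are permitted by default;
    ``non_negative=True`` constrains them to be >= 0 (the intercept
    stays free).

    Parameters
    ----------
    query : (n_probes,) vector
    references : (n_probes, n_ref) matrix, n_ref >= 2
    """
    y = np.asarray(query, dtype=float).ravel()
    r = np.asarray(references, dtype=float)
    if r.ndim != 2 or r.shape[0] != y.shape[0]:
        raise ValueError("references must be probes x n_ref matching the query length")
    if r.shape[1] < 2:
        raise ValueError("need at least 2 reference samples")
    x = np.column_stack([np.ones_like(y), r])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("reference matrix is rank-deficient (collinear references); "
                      "using a minimum-norm least-squares fit")
    if non_negative:
        from scipy.optimize import lsq_linear

        lower = np.r_[-np.inf, np.zeros(r.shape[1])]
        coef = lsq_linear(x, y, bounds=(lower, np.inf)).x
    else:
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return resid - np.median(resid)


def bin_genome(manifest: pd.DataFrame, params: CNVParams) -> list[GenomicBin]:
    """Tile chromosomes into windows and merge until each bin is populated.

    Windows of ``target_bin_size`` (0-based half-open) are merged
    left-to-right until every bin holds at least ``min_probes_per_bin``
    probes; a trailing deficient bin merges into its left neighbor.
    Chromosomes with fewer than ``min_probes_per_bin`` probes in total
    are excluded with a warning.
    """
    validate_manifest(manifest)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    bins: list[GenomicBin] = []
    chroms = sorted(manifest["chrom"].unique(), key=_chrom_key)
    for chrom in chroms:
        sub = manifest[manifest["chrom"] == chrom].sort_values(["pos", "probe_id"])
        if len(sub) < params.min_probes_per_bin:
            log.warning("chromosome %s has %d probes (< %d); excluded from binning",
                        chrom, len(sub), params.min_probes_per_bin)
            continue
        pos0 = sub["pos"].to_numpy() - 1  # to 0-based
        ids = sub["probe_id"].to_numpy()
        size = params.target_bin_size
        n_windows = int(pos0.max() // size) + 1
        window_of_probe = pos0 // size
        chrom_bins: list[GenomicBin] = []
        cur_start = 0
        cur_probes: list[str] = []
        for w in range(n_windows):
            cur_probes.extend(ids[window_of_probe == w])
            w_end = (w + 1) * size
            if len(cur_probes) >= params.min_probes_per_bin:
                chrom_bins.append(GenomicBin(chrom, cur_start, w_end, tuple(cur_probes)))
                cur_start = w_end
                cur_probes = []
        if cur_probes:  # trailing deficient window merges into its left neighbor
            last = chrom_bins[-1]
            chrom_bins[-1] = GenomicBin(
                chrom, last.start, n_windows * size, last.probe_ids + tuple(cur_probes)
            )
        bins.extend(chrom_bins)
    if not bins:
        raise ValueError("no chromosome had enough probes to form a bin")
    return bins


def bin_ratios(probe_ratios: pd.Series, bins: list[GenomicBin]) -> np.ndarray:
    """Per-bin median of member-probe log2 ratios."""
    return np.array([float(np.median(probe_ratios.loc[list(b.probe_ids)])) for b in bins])


# ---------------------------------------------------------------------------
# circular binary segmentation


def _max_circular_t(x: np.ndarray, min_seg_bins: int) -> tuple[float, int, int]:
    """Maximal two-segment |t| over all circular splits of ``x``.

    A circular two-arc partition is equivalent to a linear arc ``x[i:j]``
    versus its complement, so all pairs ``1 <= i < j <= n`` with both
    sides holding at least ``min_seg_bins`` bins are scanned (arcs
    starting at 0 are excluded: ``x[0:k]`` describes the same partition
    as ``x[k:n]``, so each partition is visited exactly once).  Returns
    ``(|t|, i, j)``; ties resolve to the smallest ``(i, j)``.  When the
    pooled within-variance is zero but the means differ, |t| is +inf.
    """
    n = x.shape[0]
    m = min_seg_bins
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    total = prefix[-1]
    total2 = float(np.sum(x * x))
    # all (i, j) with i >= 1 and m <= j - i <= n - m
    length_ok = (
        np.triu(np.ones((n + 1, n + 1), dtype=bool), k=m)
        & ~np.triu(np.ones((n + 1, n + 1), dtype=bool), k=n - m + 1)
    )
    length_ok[0, :] = False
    i_idx, j_idx = np.nonzero(length_ok)
    n1 = (j_idx - i_idx).astype(float)
    n2 = n - n1
    s1 = prefix[j_idx] - prefix[i_idx]
    s2 = total - s1
    mean1 = s1 / n1
    mean2 = s2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        within = total2 - n1 * mean1**2 - n2 * mean2**2
        within = np.maximum(within, 0.0)
        s2pool = within / max(n - 2, 1)
        denom = np.sqrt(s2pool * (1.0 / n1 + 1.0 / n2))
        t = np.abs(mean1 - mean2) / denom
    t[np.isnan(t)] = 0.0
    # zero pooled variance with distinct means -> perfect split
    t[(denom == 0) & (np.abs(mean1 - mean2) > 0)] = np.inf
    k = int(np.argmax(t))  # argmax returns the first maximum: smallest (i, j)
    return float(t[k]), int(i_idx[k]), int(j_idx[k])


def segment_cbs(
    bin_values: np.ndarray,
    params: CNVParams,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[int, int, float]]:
    """Circular binary segmentation of one chromosome's bin values.

    Recursively finds the circular split maximizing the two-segment
    |t|-statistic, accepts it if its permutation p-value (based on
    ``seg_permutations`` seeded shuffles) is at most ``seg_alpha`` and
    both arcs hold at least ``min_seg_bins`` bins, then recurses on the
    resulting linear sub-segments.

    Returns ``[(start, end, mean), ...]`` with 0-based half-open bin
    index ranges, sorted by start.
    """
    x = np.asarray(bin_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no bins to segment")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    segments: list[tuple[int, int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * params.min_seg_bins or np.ptp(seg) == 0.0:
            segments.append((lo, hi, float(seg.mean())))
            return
        t_obs, i, j = _max_circular_t(seg, params.min_seg_bins)
        exceed = 0
        for _ in range(params.seg_permutations):
            t_perm, _, _ = _max_circular_t(rng.permutation(seg), params.min_seg_bins)
            if t_perm >= t_obs:
                exceed += 1
        p = (exceed + 1) / (params.seg_permutations + 1)
        if p > params.seg_alpha:
            segments.append((lo, hi, float(seg.mean())))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, x.size)
    segments.sort(key=lambda s: s[0])
    return segments


def call_states(
    segments: list[tuple[int, int, float]], params: CNVParams, n_bins: int
) -> np.ndarray:
    """Discrete per-bin calls from segment means.

    Bins of a segment with mean >= ``call_threshold`` are gains, those
    <= -threshold losses, everything else neutral.
    """
    calls = np.full(n_bins, NEUTRAL, dtype=object)
    for start, end, mean in segments:
        if mean >= params.call_threshold:
            calls[start:end] = GAIN
        elif mean <= -params.call_threshold:
            calls[start:end] = LOSS
    return calls


def call_cnv(
    sample_id: str,
    query_log_intensity: pd.Series,
    reference_log_intensity: pd.DataFrame,
    bins: list[GenomicBin],
    params: CNVParams,
    rng: np.random.Generator | int | None = None,
) -> CNVProfile:
    """Full per-sample CNV profile: fit, bin, segment, call.

    ``query_log_intensity`` and ``reference_log_intensity`` are indexed
    by probe id (references as columns); segmentation runs per
    chromosome with the supplied random generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ratios = pd.Series(
        fit_reference(query_log_intensity.to_numpy(), reference_log_intensity.to_numpy(),
                      non_negative=params.non_negative_fit),
        index=query_log_intensity.index,
    )
    values = bin_ratios(ratios, bins)
    chrom_of_bin = np.array([b.chrom for b in bins])
    seg_rows = []
    calls = np.full(len(bins), NEUTRAL, dtype=object)
    for chrom in pd.unique(chrom_of_bin):
        idx = np.flatnonzero(chrom_of_bin == chrom)
        segs = segment_cbs(values[idx], params, rng)
        chrom_calls = call_states(segs, params, idx.size)
        calls[idx] = chrom_calls
        for start, end, mean in segs:
            seg_rows.append(
                {
                    "chrom": chrom,
                    "start_bin": int(idx[start]),
                    "end_bin": int(idx[end - 1]) + 1,
                    "start": bins[idx[start]].start,
                    "end": bins[idx[end - 1]].end,
                    "n_bins": end - start,
                    "seg_mean": mean,
                }
            )
    segments = pd.DataFrame(
        seg_rows,
        columns=["chrom", "start_bin", "end_bin", "start", "end", "n_bins", "seg_mean"],
    )
    return CNVProfile(sample_id, bins, values, segments, calls)
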