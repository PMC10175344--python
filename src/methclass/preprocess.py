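"""Virtual-array construction, probe filtering and normalization.

The processing order mirrors standard mixed-platform practice: matrices
from the 450K and 850K designs are first intersected into a *virtual
array*, the combined matrix is stratified-quantile normalized, and only
then are blacklisted probes (sex chromosomes, SNP-overlapping,
non-unique, cross-reactive) removed before beta values are computed.

The normalization here maps, within each probe-type stratum and each
channel separately, every sample's empirical distribution onto the
cross-sample mean quantile distribution: sort each sample's values,
average the order statistics across samples, and assign the averaged
order statistics back by rank (ties receive the mean of the order
statistics they span).  This is a deliberate, exactly testable
simplification of the fixed-quantile interpolation that full array
pipelines perform; background correction and sex-chromosome handling
are out of scope (sex probes are removed anyway).
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    IntensityMatrix,
    BLACKLIST_FLAGS,
    STRATA,
    validate_manifest,
)

log = logging.getLogger(__name__)


def _chrom_key(chrom: str) -> tuple:
    """Natural chromosome ordering: numeric names first, then lexicographic."""
    m = re.fullmatch(r"(?:chr)?(\d+)", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


def canonical_probe_order(manifest: pd.DataFrame) -> pd.Index:
    """Probe ids sorted by (chromosome natural order, position, probe_id)."""
    key = manifest.assign(_ck=[_chrom_key(c) for c in manifest["chrom"]])
    ordered = key.sort_values(["_ck", "pos", "probe_id"], kind="stable")
    return pd.Index(ordered["probe_id"].to_numpy())


def combine_arrays(
    matrices: list[IntensityMatrix], manifest: pd.DataFrame
) -> IntensityMatrix:
    """Intersect probe sets across array designs into one virtual array.

    Samples from all input matrices are concatenated; only probes present
    in every contributing matrix are retained, reordered canonically by
    genomic position.
    """
    validate_manifest(manifest)
    if not matrices:
        raise ValueError("no input matrices")
    all_samples = np.concatenate([m.sample_ids.to_numpy() for m in matrices])
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample_ids across input matrices")
    shared = matrices[0].probe_ids
    for m in matrices[1:]:
        shared = shared.intersection(m.probe_ids)
    if len(shared) == 0:
        raise ValueError(
            "empty probe intersection across designs — the inputs share no probes"
        )
    order = canonical_probe_order(manifest[manifest["probe_id"].isin(shared)])
    meth = pd.concat([m.meth.loc[order] for m in matrices], axis=1)
    unmeth = pd.concat([m.unmeth.loc[order] for m in matrices], axis=1)
    log.info(
        "virtual array: %d probes shared across %d matrices, %d samples",
        len(order), len(matrices), meth.shape[1],
    )
    return IntensityMatrix(meth, unmeth)


def filter_probes(matrix: IntensityMatrix, manifest: pd.DataFrame) -> IntensityMatrix:
    """Remove probes with any blacklist flag (sex, SNP, cross-reactive, non-unique).

    Probe order is preserved.  Every probe in the matrix must be
    annotated in the manifest.
    """
    validate_manifest(manifest)
    ann = manifest.set_index("probe_id")
    missing = matrix.probe_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes missing from manifest, e.g. {missing[0]!r}")
    flags = ann.loc[matrix.probe_ids, list(BLACKLIST_FLAGS)].to_numpy().astype(bool)
    keep = ~flags.any(axis=1)
    out = matrix.subset_probes(matrix.probe_ids[keep])
    log.info("probe filter: retained %d of %d probes", out.n_probes, matrix.n_probes)
    return out


def tie_breaking_rank(values) -> np.ndarray:
    """1-based ranks; ties receive the average of the ranks they span."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    return rankdata(values, method="average")


def _normalize_block(block: np.ndarray) -> np.ndarray:
    """Quantile-normalize one (n_values x n_samples) block in place-free form."""
    n, s = block.shape
    order = np.argsort(block, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(block, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(block)
    for j in range(s):
        col_sorted = sorted_vals[:, j]
        assigned = np.empty(n)
        # tie groups get the mean of the target order statistics they span
        start = 0
        for k in range(1, n + 1):
            if k == n or col_sorted[k] != col_sorted[start]:
                assigned[start:k] = target[start:k].mean()
                start = k
        out[order[:, j], j] = assigned
    return out


def stratified_quantile_normalize(
    matrix: IntensityMatrix, manifest: pd.DataFrame
) -> IntensityMatrix:
    """Quantile-normalize each channel within each probe-type stratum.

    Within every stratum/channel, each sample's distribution is mapped
    onto the cross-sample mean of the order statistics; within-sample
    value orderings are preserved up to ties.  With a single sample the
    matrix is returned unchanged with a warning.
    """
    validate_manifest(manifest)
    if matrix.n_samples < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        return matrix
    strata = manifest.set_index("probe_id").loc[matrix.probe_ids, "stratum"]
    meth = matrix.meth.to_numpy(copy=True)
    unmeth = matrix.unmeth.to_numpy(copy=True)
    for stratum in STRATA:
        rows = np.flatnonzero((strata == stratum).to_numpy())
        if rows.size == 0:
            continue
        meth[rows, :] = _normalize_block(meth[rows, :])
        unmeth[rows, :] = _normalize_block(unmeth[rows, :])
    return IntensityMatrix(
        meth=pd.DataFrame(meth, index=matrix.probe_ids, columns=matrix.sample_ids),
        unmeth=pd.DataFrame(unmeth, index=matrix.probe_ids, columns=matrix.sample_ids),
    )


def compute_beta(matrix: IntensityMatrix, offset: float = 100.0) -> pd.DataFrame:
    """Beta values ``M / (M + U + offset)`` (probes x samples, in [0, 1]).

    The default offset of 100 is the community convention; it guards the
    zero-intensity case.  With ``offset == 0`` a probe with both
    channels at zero is defined as beta 0 (and logged).
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    m = matrix.meth.to_numpy()
    u = matrix.unmeth.to_numpy()
    denom = m + u + offset
    if offset == 0:
        zero = denom == 0
        if zero.any():
            log.info("compute_beta: %d probe/sample pairs with M=U=0 set to beta 0", int(zero.sum()))
        denom = np.where(zero, 1.0, denom)
        beta = np.where(zero, 0.0, m / denom)
    else:
        beta = m / denom
    return pd.DataFrame(beta, index=matrix.probe_ids, columns=matrix.sample_ids)
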