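"""UMAP embedding, HDBSCAN cluster confirmation and reference matching.

The embedding uses UMAP with ``init="random"``, ``min_dist=0.0`` and
``spread=3.0`` by default (the remaining knobs stay at the community
defaults of 15 neighbors and 2 output components); clusters are then
confirmed by running HDBSCAN (``min_samples=4``, ``min_cluster_size=4``)
on the embedding coordinates.  Discovered clusters are matched to
previously published methylation-class labels by majority vote among
their labeled members; clusters without labeled members, or below a
purity threshold, are reported as NOVEL — the logic by which a new
tumor methylation class is recognized against a reference cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ClusterAssignment, NOISE_LABEL

log = logging.getLogger(__name__)

NOVEL = "NOVEL"


@dataclass(frozen=True)
class UMAPParams:
    """UMAP settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    init: str = "random"
    min_dist: float = 0.0
    spread: float = 3.0
    n_neighbors: int = 15
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.init not in ("random", "spectral"):
            raise ValueError("init must be 'random' or 'spectral'")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


@dataclass(frozen=True)
class HDBSCANParams:
    min_samples: int = 4
    min_cluster_size: int = 4

    def __post_init__(self) -> None:
        if self.min_samples < 2 or self.min_cluster_size < 2:
            raise ValueError("min_samples and min_cluster_size must be >= 2")


def embed_umap(
    betas: pd.DataFrame, params: UMAPParams, top_variance: int | None = None
) -> pd.DataFrame:
    """Embed samples into ``n_components`` dimensions with UMAP.

    Parameters
    ----------
    betas
        Beta matrix, probes as rows and samples as columns (the
        pipeline's on-disk orientation); samples are embedded.
    top_variance
        If set, restrict to the ``top_variance`` most variable probes
        before embedding (default: use all retained probes).

    Returns a DataFrame indexed by sample id with columns ``UMAP1..k``.
    Deterministic for a fixed seed.
    """
    import umap  # deferred: numba compilation makes this import heavy

    if top_variance is not None and top_variance < betas.shape[0]:
        order = np.argsort(betas.to_numpy().var(axis=1))[::-1][:top_variance]
        betas = betas.iloc[np.sort(order)]
    x = betas.to_numpy().T  # samples x probes
    if np.isnan(x).any():
        raise ValueError("beta matrix contains missing values")
    n_samples = x.shape[0]
    if n_samples < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {params.n_neighbors + 1} samples, "
            f"got {n_samples}; lower n_neighbors or add samples"
        )
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        n_components=params.n_components,
        min_dist=params.min_dist,
        spread=params.spread,
        init=params.init,
        random_state=params.seed,
    )
    coords = reducer.fit_transform(x)
    return pd.DataFrame(
        coords,
        index=betas.columns,
        columns=[f"UMAP{i + 1}" for i in range(params.n_components)],
    )


def cluster_hdbscan(
    embedding: pd.DataFrame,
    params: HDBSCANParams,
    reference_flag: np.ndarray | None = None,
) -> ClusterAssignment:
    """Density-cluster the embedding; noise points get label -1.

    Clusters are relabeled ``0..K-1`` in order of first appearance so the
    labeling is deterministic.  Degenerate inputs are handled explicitly:
    fewer points than ``min_cluster_size`` are all noise, and a set of
    identical points is a single cluster.
    """
    from sklearn.cluster import HDBSCAN  # local import keeps module load light

    coords = embedding.to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("embedding contains non-finite coordinates")
    n = coords.shape[0]
    if n < params.min_cluster_size:
        labels = np.full(n, NOISE_LABEL)
        log.warning("fewer points (%d) than min_cluster_size; all labeled noise", n)
    elif np.allclose(coords, coords[0]):
        labels = np.zeros(n, dtype=int)
    else:
        raw = HDBSCAN(
            min_cluster_size=params.min_cluster_size,
            min_samples=params.min_samples,
            copy=True,
        ).fit_predict(coords)
        labels = _relabel_in_order(raw)
    if (labels == NOISE_LABEL).all():
        log.warning("HDBSCAN classified every sample as noise")
    return ClusterAssignment(
        sample_ids=embedding.index,
        embedding=coords,
        labels=labels,
        reference_flag=reference_flag,
    )


def _relabel_in_order(labels: np.ndarray) -> np.ndarray:
    """Map cluster ids to 0..K-1 by order of first appearance; keep -1."""
    out = np.full(labels.shape, NOISE_LABEL, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE_LABEL:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def match_clusters_to_reference(
    assignment: ClusterAssignment,
    reference_labels: Mapping[str, str],
    purity_threshold: float = 0.5,
) -> tuple[dict[int, str], dict]:
    """Map discovered clusters to known class labels; flag NOVEL clusters.

    Each cluster is assigned the majority label among its members that
    appear in ``reference_labels``.  Clusters with no labeled member, or
    whose majority label holds at most ``purity_threshold`` of the
    labeled members, are reported as NOVEL.  Noise (-1) is never mapped.

    Returns ``(mapping, report)`` where ``mapping`` is cluster id ->
    label or ``"NOVEL"`` and ``report`` carries per-cluster sizes,
    labeled counts and purities.
    """
    labels_by_sample = dict(reference_labels)
    if not labels_by_sample:
        log.warning("no reference labels supplied: every cluster is NOVEL")
    mapping: dict[int, str] = {}
    per_cluster = {}
    for cid in assignment.cluster_ids:
        members = assignment.sample_ids[assignment.labels == cid]
        ref = [labels_by_sample[s] for s in members if s in labels_by_sample]
        if not ref:
            mapping[cid] = NOVEL
            per_cluster[cid] = {"size": len(members), "n_labeled": 0, "purity": None,
                                "majority": None, "call": NOVEL}
            continue
        counts = pd.Series(ref).value_counts()
        majority = str(counts.index[0])
        purity = float(counts.iloc[0] / len(ref))
        call = majority if purity > purity_threshold else NOVEL
        mapping[cid] = call
        per_cluster[cid] = {
            "size": int(len(members)),
            "n_labeled": int(len(ref)),
            "purity": purity,
            "majority": majority,
            "call": call,
        }
    report = {
        "clusters": per_cluster,
        "n_novel": sum(1 for v in mapping.values() if v == NOVEL),
        "n_noise": int((assignment.labels == NOISE_LABEL).sum()),
        "no_reference_labels": not labels_by_sample,
    }
    return mapping, report


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement via the contingency-table form.

    Returns 1.0 iff the partitions are identical up to relabeling; 0 is
    the expectation under random labeling.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons or one cluster)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
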