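"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* A *manifest* is a :class:`pandas.DataFrame` with columns
  ``probe_id, chrom, pos, stratum, in_450k, in_850k, flag_sex, flag_snp,
  flag_crossreactive, flag_nonunique`` (``pos`` is 1-based; flags and
  design membership are 0/1 integers; ``stratum`` is one of
  ``I-red``, ``I-green``, ``II``).
* A *sample sheet* is a DataFrame with columns
  ``sample_id, array_design, true_class, known_class, group,
  seizure_free, is_reference``.
* Intensity and beta matrices are probes-as-rows DataFrames indexed by
  ``probe_id`` with one column per sample, mirroring the on-disk layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRATA = ("I-red", "I-green", "II")
BLACKLIST_FLAGS = ("flag_sex", "flag_snp", "flag_crossreactive", "flag_nonunique")

MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "stratum",
    "in_450k",
    "in_850k",
) + BLACKLIST_FLAGS

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "array_design",
    "true_class",
    "known_class",
    "group",
    "seizure_free",
    "is_reference",
)


@dataclass
class IntensityMatrix:
    """Two-channel probe intensities for a set of samples.

    Parameters
    ----------
    meth, unmeth
        Non-negative DataFrames of identical shape, indexed by probe id
        with sample ids as columns (methylated and unmethylated channel).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index):
            raise ValueError("meth and unmeth probe indices differ")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise ValueError("meth and unmeth sample columns differ")
        if self.meth.index.has_duplicates:
            raise ValueError("duplicate probe_ids in intensity matrix")
        if self.meth.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in intensity matrix")
        if (self.meth.to_numpy() < 0).any() or (self.unmeth.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    @property
    def n_probes(self) -> int:
        return self.meth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def total(self) -> pd.DataFrame:
        """Total intensity per probe/sample (meth + unmeth)."""
        return self.meth + self.unmeth

    def subset_probes(self, probe_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.meth.loc[probe_ids], self.unmeth.loc[probe_ids])

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.meth[list(sample_ids)], self.unmeth[list(sample_ids)])


NOISE_LABEL = -1


@dataclass
class ClusterAssignment:
    """Embedding coordinates and density-cluster label per sample.

    ``labels`` uses non-negative integers for clusters and ``-1`` for
    noise points that HDBSCAN declined to assign.
    """

    sample_ids: pd.Index
    embedding: np.ndarray  # n_samples x n_components
    labels: np.ndarray  # int per sample, -1 = noise
    reference_flag: np.ndarray | None = None  # bool per sample

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids)
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.sample_ids)
        if self.embedding.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("sample_ids, embedding and labels lengths differ")
        if self.reference_flag is not None:
            self.reference_flag = np.asarray(self.reference_flag, dtype=bool)
            if self.reference_flag.shape[0] != n:
                raise ValueError("reference_flag length mismatch")

    @property
    def cluster_ids(self) -> list[int]:
        """Sorted non-noise cluster ids."""
        return sorted(int(c) for c in np.unique(self.labels) if c != NOISE_LABEL)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"UMAP{i + 1}": self.embedding[:, i] for i in range(self.embedding.shape[1])}
        cols["cluster"] = self.labels
        if self.reference_flag is not None:
            cols["is_reference"] = self.reference_flag
        return pd.DataFrame(cols, index=self.sample_ids)


@dataclass(frozen=True)
class GenomicBin:
    """A genomic window with the probes it contains (0-based half-open)."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def bins_to_frame(bins: list[GenomicBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "n_probes": [b.n_probes for b in bins],
        }
    )


GAIN, NEUTRAL, LOSS = "gain", "neutral", "loss"


@dataclass
class CNVProfile:
    """Per-sample binned copy-number profile.

    ``segments`` has columns ``chrom, start_bin, end_bin, start, end,
    n_bins, seg_mean`` where bin indices are positions in ``bins`` and
    genomic ``start``/``end`` are 0-based half-open.  ``calls`` holds one
    of ``gain``/``neutral``/``loss`` per bin.
    """

    sample_id: str
    bins: list[GenomicBin]
    log2_ratio: np.ndarray  # per bin
    segments: pd.DataFrame
    calls: np.ndarray  # str per bin

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        self.calls = np.asarray(self.calls, dtype=object)
        if len(self.bins) != self.log2_ratio.shape[0] or len(self.bins) != self.calls.shape[0]:
            raise ValueError("bins, log2_ratio and calls lengths differ")


@dataclass
class CohortSummaryTrack:
    """Per-bin percentage of a sample group called gained / lost."""

    group: str
    bins: list[GenomicBin]
    n_samples: int
    pct_gain: np.ndarray
    pct_loss: np.ndarray

    def __post_init__(self) -> None:
        self.pct_gain = np.asarray(self.pct_gain, dtype=float)
        self.pct_loss = np.asarray(self.pct_loss, dtype=float)
        nb = len(self.bins)
        if self.pct_gain.shape[0] != nb or self.pct_loss.shape[0] != nb:
            raise ValueError("track length does not match bin count")
        if ((self.pct_gain + self.pct_loss) > 100.0 + 1e-9).any():
            raise ValueError("pct_gain + pct_loss exceeds 100 in some bin")

    def to_frame(self) -> pd.DataFrame:
        df = bins_to_frame(self.bins)[["chrom", "start", "end"]]
        df["n"] = self.n_samples
        df["pct_gain"] = self.pct_gain
        df["pct_loss"] = self.pct_loss
        return df


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest structure and invariants; returns the input."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        raise ValueError("manifest probe_ids are not unique")
    if (manifest["pos"] < 1).any():
        raise ValueError("manifest positions must be 1-based (>= 1)")
    bad = set(manifest["stratum"]) - set(STRATA)
    if bad:
        raise ValueError(f"unknown probe strata: {sorted(bad)}")
    return manifest


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample_ids are not unique")
    non_ref = sheet[~sheet["is_reference"].astype(bool)]
    if non_ref["true_class"].isna().any():
        raise ValueError("every non-reference sample needs a true_class")
    return sheet
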