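"""Delimited-text readers and writers for manifests, intensities and results.

All files are plain TSV.  Intensity matrices are written probes-as-rows
with ``probe_id`` as the first column; values use Python float ``repr``
so a write → read → write cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    IntensityMatrix,
    CohortSummaryTrack,
    CNVProfile,
    MANIFEST_COLUMNS,
    SAMPLE_SHEET_COLUMNS,
    validate_manifest,
    validate_sample_sheet,
    bins_to_frame,
)

MANIFEST_FILE = "manifest.tsv"
METH_FILE = "meth.tsv"
UNMETH_FILE = "unmeth.tsv"
SAMPLE_SHEET_FILE = "samples.tsv"
TRUTH_FILE = "truth.json"


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)
    manifest.to_csv(path, sep="\t", index=False, columns=list(MANIFEST_COLUMNS))


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    return validate_manifest(manifest)


def _write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.insert(0, "probe_id", df.index)
    # repr-formatted floats round-trip losslessly through float64
    out.to_csv(path, sep="\t", index=False, float_format=None)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str}, float_precision="round_trip")
    df = df.set_index("probe_id")
    df.index.name = None
    return df.astype(float)


def write_intensities(matrix: IntensityMatrix, directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meth_path = directory / METH_FILE
    unmeth_path = directory / UNMETH_FILE
    _write_matrix(matrix.meth, meth_path)
    _write_matrix(matrix.unmeth, unmeth_path)
    return meth_path, unmeth_path


def read_intensities(directory: str | Path) -> IntensityMatrix:
    directory = Path(directory)
    return IntensityMatrix(
        meth=_read_matrix(directory / METH_FILE),
        unmeth=_read_matrix(directory / UNMETH_FILE),
    )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet)
    out = sheet.copy()
    out["is_reference"] = out["is_reference"].astype(int)
    # seizure_free: 0/1 with blank for missing
    sf = out["seizure_free"]
    out["seizure_free"] = [
        "" if pd.isna(v) else str(int(bool(v))) for v in sf
    ]
    out.to_csv(path, sep="\t", index=False, columns=list(SAMPLE_SHEET_COLUMNS))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "array_design": str, "group": str},
        keep_default_na=False,
        na_values=[""],
    )
    sheet["is_reference"] = sheet["is_reference"].astype(bool)
    sheet["seizure_free"] = sheet["seizure_free"].astype("float").astype("boolean")
    return validate_sample_sheet(sheet)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_seg(profiles: list[CNVProfile], path: str | Path) -> None:
    """Export per-sample segments in SEG format (1-based inclusive)."""
    rows = []
    for p in profiles:
        for seg in p.segments.itertuples(index=False):
            rows.append(
                {
                    "sample": p.sample_id,
                    "chrom": seg.chrom,
                    "loc.start": int(seg.start) + 1,
                    "loc.end": int(seg.end),
                    "num.mark": int(seg.n_bins),
                    "seg.mean": float(seg.seg_mean),
                }
            )
    pd.DataFrame(
        rows, columns=["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def write_calls(profiles: list[CNVProfile], path: str | Path) -> None:
    """Export per-bin calls as BED-like text (0-based half-open)."""
    rows = []
    for p in profiles:
        frame = bins_to_frame(p.bins)
        for i, b in enumerate(frame.itertuples(index=False)):
            rows.append(
                {
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "sample": p.sample_id,
                    "log2_ratio": p.log2_ratio[i],
                    "call": p.calls[i],
                }
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sample", "log2_ratio", "call"]
    ).to_csv(path, sep="\t", index=False)


def write_track(track: CohortSummaryTrack, path: str | Path) -> None:
    """Export a cohort summary track as BED-like text (0-based half-open)."""
    track.to_frame().to_csv(path, sep="\t", index=False)


def read_track_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
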