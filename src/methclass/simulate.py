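"""Synthetic methylation-array cohort generator.

Emulates the statistical structure the downstream analysis assumes:
mixed 450K/850K probe sets with partial overlap, class-specific
methylation signatures at a subset of probes, chromosome-arm-level
copy-number events expressed as multiplicative shifts of total probe
intensity, logit-scale beta noise, and a set of copy-neutral reference
samples.  Everything is driven by a single integer seed and is
byte-reproducible.

The beta baseline is bimodal (modes near 0.1 and 0.85, 50/50 mix),
mimicking the unmethylated/methylated peaks of real methylomes.  Copy
number acts on total intensity ``T`` only; the beta ratio is unchanged,
so intensity-based copy-number calling is possible while beta values
remain interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import IntensityMatrix, STRATA, validate_manifest, validate_sample_sheet
from . import array_io

log = logging.getLogger(__name__)

BETA_MODES = (0.1, 0.85)  # unmethylated / methylated peaks
BETA_CLIP = (0.001, 0.999)
# rough real-array proportions of Infinium I-red / I-green / II probes
STRATUM_PROBS = (0.15, 0.13, 0.72)


@dataclass(frozen=True)
class CNVEvent:
    """A planted copy-number event (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" or "loss"
    log2_effect: float
    penetrance: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start > end")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain or loss, got {self.direction!r}")
        if self.log2_effect <= 0:
            raise ValueError("log2_effect must be positive (direction carries the sign)")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")

    @property
    def signed_log2(self) -> float:
        return self.log2_effect if self.direction == "gain" else -self.log2_effect


@dataclass(frozen=True)
class ClassSpec:
    """One tumor methylation class in the simulation."""

    name: str
    n_samples: int
    n_signature_probes: int
    signature_beta_shift: float
    cnv_events: tuple[CNVEvent, ...] = ()
    outcome_seizure_free_prob: float = 0.7
    labeled: bool = True  # part of the published reference cohort?

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not -1.0 <= self.signature_beta_shift <= 1.0:
            raise ValueError("signature_beta_shift must be in [-1, 1]")
        if not 0.0 <= self.outcome_seizure_free_prob <= 1.0:
            raise ValueError("outcome_seizure_free_prob must be in [0, 1]")
        object.__setattr__(self, "cnv_events", tuple(self.cnv_events))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort."""

    n_probes_per_array: int = 6000
    overlap_fraction: float = 0.7
    n_chromosomes: int = 8
    chrom_length: int = 30_000_000
    classes: tuple[ClassSpec, ...] = ()
    n_reference_samples: int = 8
    beta_noise_sd: float = 0.3
    baseline_intensity: float = 5000.0
    intensity_dispersion: float = 0.15
    seed: int = 0
    # fraction of probes carrying each blacklist flag, drawn independently
    flag_fractions: tuple[float, float, float, float] = (0.04, 0.05, 0.05, 0.01)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_probes_per_array < 1 or self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_reference_samples < 0:
            raise ValueError("n_reference_samples must be >= 0")
        if self.beta_noise_sd < 0:
            raise ValueError("beta_noise_sd must be >= 0")
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.classes) + self.n_reference_samples


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a probe manifest for two overlapping array designs.

    Probes are placed uniformly at random along ``n_chromosomes``
    chromosomes of equal length.  Exactly
    ``round(overlap_fraction * n_probes_per_array)`` probes belong to
    both designs; each design holds ``n_probes_per_array`` probes in
    total.  Blacklist flags are independent Bernoulli draws with the
    configured per-category fractions.
    """
    rng = np.random.default_rng(config.seed)
    n_shared = int(round(config.overlap_fraction * config.n_probes_per_array))
    if n_shared > config.n_probes_per_array:
        raise ValueError("overlap larger than either design")
    n_only = config.n_probes_per_array - n_shared
    n_total = n_shared + 2 * n_only

    chrom_idx = rng.integers(0, config.n_chromosomes, size=n_total)
    pos = rng.integers(1, config.chrom_length + 1, size=n_total)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]

    membership = np.concatenate(
        [np.repeat("both", n_shared), np.repeat("a450", n_only), np.repeat("a850", n_only)]
    )
    rng.shuffle(membership)

    stratum = rng.choice(STRATA, size=n_total, p=STRATUM_PROBS)
    flags = {
        name: (rng.random(n_total) < frac).astype(int)
        for name, frac in zip(
            ("flag_sex", "flag_snp", "flag_crossreactive", "flag_nonunique"),
            config.flag_fractions,
        )
    }

    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_total)],
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": pos,
            "stratum": stratum,
            "in_450k": np.isin(membership, ("both", "a450")).astype(int),
            "in_850k": np.isin(membership, ("both", "a850")).astype(int),
            **flags,
        }
    )
    return validate_manifest(manifest)


def _eligible_signature_probes(manifest: pd.DataFrame) -> pd.DataFrame:
    """Probes usable as class signatures: shared between designs and unflagged,
    so the signal survives virtual-array intersection and probe filtering."""
    mask = (manifest["in_450k"] == 1) & (manifest["in_850k"] == 1)
    for flag in ("flag_sex", "flag_snp", "flag_crossreactive", "flag_nonunique"):
        mask &= manifest[flag] == 0
    return manifest[mask]


def simulate_cohort(
    config: SimulationConfig, manifest: pd.DataFrame
) -> tuple[IntensityMatrix, pd.DataFrame, dict]:
    """Simulate intensities, a sample sheet and a ground-truth record.

    Per sample: each probe starts at its bimodal baseline beta, class
    signature probes are shifted away from their baseline mode by
    ``signature_beta_shift``, logit-normal noise is added and the result
    clipped to (0, 1).  Total intensity ``T`` is log-normal around
    ``baseline_intensity`` with CV ``intensity_dispersion``; probes
    inside a carried CNV event have ``T`` multiplied by
    ``2**(±log2_effect)``.  Channels are ``M = beta * T`` and
    ``U = T - M`` so that ``M + U == T`` exactly.
    """
    validate_manifest(manifest)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_probes = len(manifest)
    probe_ids = manifest["probe_id"].to_numpy()
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()

    # per-probe baseline mode, shared across samples
    mode_is_high = rng.random(n_probes) < 0.5
    baseline_beta = np.where(mode_is_high, BETA_MODES[1], BETA_MODES[0])

    eligible = _eligible_signature_probes(manifest)
    n_sig_needed = sum(c.n_signature_probes for c in config.classes)
    if n_sig_needed > len(eligible):
        raise ValueError(
            f"need {n_sig_needed} signature probes but only {len(eligible)} "
            "shared unflagged probes are available"
        )
    sig_pool = rng.permutation(eligible.index.to_numpy())
    signature_probes: dict[str, np.ndarray] = {}
    offset = 0
    for cls in config.classes:
        signature_probes[cls.name] = np.sort(sig_pool[offset : offset + cls.n_signature_probes])
        offset += cls.n_signature_probes

    samples: list[dict] = []
    meth_cols: dict[str, np.ndarray] = {}
    unmeth_cols: dict[str, np.ndarray] = {}
    carriers: dict[str, dict[str, list[str]]] = {
        cls.name: {_event_key(e): [] for e in cls.cnv_events} for cls in config.classes
    }
    n_clipped = 0
    sigma_ln = np.sqrt(np.log1p(config.intensity_dispersion**2))
    counter = 0

    def _draw_sample(sample_id: str, cls: ClassSpec | None) -> None:
        nonlocal n_clipped
        beta = baseline_beta.copy()
        if cls is not None and cls.n_signature_probes > 0:
            idx = signature_probes[cls.name]
            # push signature probes away from their baseline mode
            direction = np.where(mode_is_high[idx], -1.0, 1.0)
            beta[idx] = beta[idx] + direction * cls.signature_beta_shift
        clipped = (beta < BETA_CLIP[0]) | (beta > BETA_CLIP[1])
        n_clipped += int(clipped.sum())
        beta = np.clip(beta, *BETA_CLIP)
        if config.beta_noise_sd > 0:
            beta = expit(logit(beta) + rng.normal(0.0, config.beta_noise_sd, n_probes))
        beta = np.clip(beta, *BETA_CLIP)

        # mean-preserving log-normal total intensity
        t = config.baseline_intensity * np.exp(
            rng.normal(-0.5 * sigma_ln**2, sigma_ln, n_probes)
        )
        if cls is not None:
            for event in cls.cnv_events:
                carried = rng.random() < event.penetrance
                if carried:
                    in_event = (chrom == event.chrom) & (pos >= event.start) & (pos <= event.end)
                    t = np.where(in_event, t * 2.0**event.signed_log2, t)
                    carriers[cls.name][_event_key(event)].append(sample_id)
        meth = beta * t
        meth_cols[sample_id] = meth
        unmeth_cols[sample_id] = t - meth  # exact channel conservation

    for cls in config.classes:
        for _ in range(cls.n_samples):
            counter += 1
            sample_id = f"S{counter:03d}"
            _draw_sample(sample_id, cls)
            seizure_free = bool(rng.random() < cls.outcome_seizure_free_prob)
            samples.append(
                {
                    "sample_id": sample_id,
                    "array_design": "A450" if rng.random() < 0.5 else "A850",
                    "true_class": cls.name,
                    "known_class": cls.name if cls.labeled else np.nan,
                    "group": cls.name,
                    "seizure_free": seizure_free,
                    "is_reference": False,
                }
            )
    for r in range(config.n_reference_samples):
        sample_id = f"REF{r + 1:02d}"
        _draw_sample(sample_id, None)
        samples.append(
            {
                "sample_id": sample_id,
                "array_design": "A450" if rng.random() < 0.5 else "A850",
                "true_class": np.nan,
                "known_class": np.nan,
                "group": "reference",
                "seizure_free": np.nan,
                "is_reference": True,
            }
        )

    if n_clipped:
        log.info("clipped %d out-of-range beta values into [%g, %g]", n_clipped, *BETA_CLIP)

    index = pd.Index(probe_ids)
    matrix = IntensityMatrix(
        meth=pd.DataFrame(meth_cols, index=index),
        unmeth=pd.DataFrame(unmeth_cols, index=index),
    )
    sheet = validate_sample_sheet(pd.DataFrame(samples))
    truth = {
        "class_of_sample": {
            s["sample_id"]: s["true_class"]
            for s in samples
            if not s["is_reference"]
        },
        "signature_probes": {
            name: probe_ids[idx].tolist() for name, idx in signature_probes.items()
        },
        "events": {
            cls.name: [
                {
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "direction": e.direction,
                    "log2_effect": e.log2_effect,
                    "penetrance": e.penetrance,
                    "carriers": carriers[cls.name][_event_key(e)],
                }
                for e in cls.cnv_events
            ]
            for cls in config.classes
        },
        "n_clipped_betas": n_clipped,
    }
    return matrix, sheet, truth


def _event_key(event: CNVEvent) -> str:
    return f"{event.chrom}:{event.start}-{event.end}:{event.direction}"


def split_by_design(
    matrix: IntensityMatrix, sheet: pd.DataFrame, manifest: pd.DataFrame
) -> list[IntensityMatrix]:
    """Split a full cohort matrix into per-design matrices.

    Each output matrix contains only the probes on that design and only
    the samples run on it, mimicking real mixed-platform cohorts.
    Designs with no samples are omitted.
    """
    out = []
    for design, col in (("A450", "in_450k"), ("A850", "in_850k")):
        sample_ids = sheet.loc[sheet["array_design"] == design, "sample_id"].tolist()
        if not sample_ids:
            continue
        probes = manifest.loc[manifest[col] == 1, "probe_id"]
        out.append(matrix.subset_probes(probes).subset_samples(sample_ids))
    return out


def write_fixture(
    directory: str | Path,
    matrix: IntensityMatrix,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: dict | None = None,
) -> Path:
    """Write a cohort to delimited-text files that round-trip losslessly."""
    if not matrix.probe_ids.isin(manifest["probe_id"]).all():
        raise ValueError("matrix contains probes absent from the manifest")
    if not pd.Index(sheet["sample_id"]).equals(pd.Index(matrix.sample_ids)):
        raise ValueError("sample sheet and matrix sample ids are inconsistent")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    array_io.write_manifest(manifest, directory / array_io.MANIFEST_FILE)
    array_io.write_intensities(matrix, directory)
    array_io.write_sample_sheet(sheet, directory / array_io.SAMPLE_SHEET_FILE)
    if truth is not None:
        array_io.write_truth(truth, directory / array_io.TRUTH_FILE)
    return directory


def demo_config(seed: int = 0) -> SimulationConfig:
    """The packaged demonstration cohort.

    Five tumor methylation classes: four labeled reference classes with
    essentially flat copy-number profiles (one with a marginal
    low-penetrance gain) and one unlabeled class rich in chromosome-arm
    gains and losses with an adverse postsurgical outcome profile
    (seizure-free probability 0.38 versus 0.72-0.76 elsewhere), plus
    eight copy-neutral reference samples.  Class sizes are a scaled-down
    sketch of a mixed published-reference / new-cases cohort.
    """
    L = 30_000_000
    arm = L // 2
    novel_events = (
        CNVEvent("chr1", 1, L, "gain", 0.4, 0.55),
        CNVEvent("chr3", 1, L, "gain", 0.4, 0.4),
        CNVEvent("chr5", arm + 1, L, "gain", 0.4, 0.5),
        CNVEvent("chr2", 1, L, "loss", 0.4, 0.4),
        CNVEvent("chr4", 1, arm, "loss", 0.4, 0.3),
    )
    classes = (
        ClassSpec("LGG-GG", 9, 350, 0.4, (CNVEvent("chr3", 1, L, "gain", 0.3, 0.12),), 0.76, True),
        ClassSpec("LGG-DNT", 14, 350, 0.4, (), 0.72, True),
        ClassSpec("LGG-PXA", 16, 350, 0.4, (), 0.72, True),
        ClassSpec("LGG-MYB", 11, 350, 0.4, (), 0.72, True),
        ClassSpec("GG-NOVEL", 21, 350, 0.4, novel_events, 0.38, False),
    )
    return SimulationConfig(
        n_probes_per_array=6000,
        overlap_fraction=0.7,
        n_chromosomes=8,
        chrom_length=L,
        classes=classes,
        n_reference_samples=8,
        beta_noise_sd=0.3,
        baseline_intensity=5000.0,
        intensity_dispersion=0.15,
        seed=seed,
    )
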