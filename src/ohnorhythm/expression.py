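"""Library-size normalization and expression filtering.

Raw gene-level read counts are normalized to counts per million
(cpm = counts / library size * 1e6), replicates are averaged per
(organ, zeitgeber time), each gene's profile is rescaled to relative
expression (per-timepoint mean divided by the across-timepoint mean, so
an expressed gene averages exactly 1 over the day), and genes are
flagged as expressed when the replicate-averaged cpm exceeds 1 at two or
more timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

SAMPLE_COLUMNS = ("sample_id", "organ", "zt", "replicate")

__all__ = [
    "CountMatrix",
    "OrganProfile",
    "compute_cpm",
    "average_replicates",
    "relative_expression",
    "expressed_filter",
    "organ_profiles",
]


@dataclass
class CountMatrix:
    """Gene x sample integer read counts plus per-sample metadata.

    ``counts`` has gene ids as the index and sample ids as columns.
    ``samples`` is indexed by sample id with columns ``organ``, ``zt``,
    ``replicate`` and, optionally, ``library_size`` (an explicit
    override; when absent the per-sample column total is used).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" in self.samples.columns:
            self.samples = self.samples.set_index("sample_id")
        missing = [c for c in ("organ", "zt", "replicate") if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample sheet is missing columns: {missing}")
        unknown = [s for s in self.counts.columns if s not in self.samples.index]
        if unknown:
            raise InputError(f"samples absent from the sample sheet: {unknown[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("read counts must be non-negative")

    @property
    def organs(self) -> list[str]:
        return sorted(self.samples["organ"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.samples["zt"].unique())

    def library_sizes(self) -> pd.Series:
        """Library size per sample: explicit override column if present,
        otherwise the column total."""
        totals = self.counts.sum(axis=0).astype(float)
        if "library_size" in self.samples.columns:
            override = self.samples.loc[self.counts.columns, "library_size"]
            totals = override.astype(float).where(override.notna(), totals)
        return totals

    def organ_samples(self, organ: str) -> pd.DataFrame:
        meta = self.samples[self.samples["organ"] == organ]
        if meta.empty:
            raise InputError(f"no samples for organ {organ!r}")
        return meta.sort_values(["zt", "replicate"])


@dataclass
class OrganProfile:
    """Replicate-averaged cpm, relative expression and expressed flags
    for one organ. Frames are genes x zeitgeber timepoints."""

    organ: str
    mean_cpm: pd.DataFrame
    relative: pd.DataFrame
    expressed: pd.Series
    degenerate: pd.Series = field(default=None)


def compute_cpm(counts, library_size=None):
    """Counts-per-million normalization: cpm = counts / library size * 1e6.

    ``counts`` may be a vector (one sample) with scalar ``library_size``
    or a genes x samples frame with a per-sample Series. When
    ``library_size`` is omitted the per-sample column total is used, in
    which case each cpm column sums to 1e6.
    """
    if isinstance(counts, pd.DataFrame):
        if library_size is None:
            library_size = counts.sum(axis=0).astype(float)
        else:
            library_size = pd.Series(library_size, index=counts.columns).astype(float)
        if (library_size <= 0).any():
            bad = library_size[library_size <= 0].index.tolist()
            raise InputError(f"non-positive library size for samples {bad[:5]}")
        return counts.div(library_size, axis=1) * 1e6
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise InputError("counts must be non-negative")
    if library_size is None:
        library_size = arr.sum()
    if library_size <= 0:
        raise InputError("library size must be positive")
    return arr / float(library_size) * 1e6


def average_replicates(cpm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of cpm over biological replicates.

    Returns a genes x (organ, zt) frame with MultiIndex columns; every
    (organ, zt) group must contain at least one sample.
    """
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id")
    missing = [s for s in cpm.columns if s not in samples.index]
    if missing:
        raise InputError(f"samples missing from metadata: {missing[:5]}")
    meta = samples.loc[cpm.columns]
    grouper = pd.MultiIndex.from_frame(meta[["organ", "zt"]])
    out = cpm.T.groupby(grouper).mean().T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["organ", "zt"])
    return out.sort_index(axis=1)


def relative_expression(mean_cpm):
    """Per-timepoint mean cpm divided by the across-timepoint mean.

    Returns ``(relative, degenerate)``: all-zero profiles cannot be
    rescaled and come back as zeros with the degenerate flag set.
    """
    if isinstance(mean_cpm, pd.DataFrame):
        arr = mean_cpm.to_numpy(dtype=float)
        if (arr < 0).any():
            raise InputError("cpm values must be non-negative")
        daily = arr.mean(axis=1)
        degenerate = daily == 0
        safe = np.where(degenerate, 1.0, daily)
        rel = arr / safe[:, None]
        rel[degenerate] = 0.0
        return (
            pd.DataFrame(rel, index=mean_cpm.index, columns=mean_cpm.columns),
            pd.Series(degenerate, index=mean_cpm.index),
        )
    arr = np.asarray(mean_cpm, dtype=float)
    if (arr < 0).any():
        raise InputError("cpm values must be non-negative")
    daily = arr.mean()
    if daily == 0:
        return np.zeros_like(arr), True
    return arr / daily, False


def expressed_filter(mean_cpm, min_cpm: float = 1.0, min_timepoints: int = 2):
    """Expressed iff replicate-averaged cpm is strictly above ``min_cpm``
    at ``min_timepoints`` or more timepoints."""
    if isinstance(mean_cpm, pd.DataFrame):
        return (mean_cpm > min_cpm).sum(axis=1) >= min_timepoints
    arr = np.asarray(mean_cpm, dtype=float)
    return bool((arr > min_cpm).sum() >= min_timepoints)


def organ_profiles(
    cm: CountMatrix,
    min_cpm: float = 1.0,
    min_timepoints: int = 2,
) -> dict[str, OrganProfile]:
    """Run the normalization chain per organ: cpm, replicate averaging,
    relative expression, expressed flag."""
    cpm = compute_cpm(cm.counts, cm.library_sizes())
    averaged = average_replicates(cpm, cm.samples)
    profiles: dict[str, OrganProfile] = {}
    for organ in cm.organs:
        mean_cpm = averaged[organ]
        rel, degenerate = relative_expression(mean_cpm)
        expressed = expressed_filter(mean_cpm, min_cpm, min_timepoints)
        profiles[organ] = OrganProfile(organ, mean_cpm, rel, expressed, degenerate)
    return profiles
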