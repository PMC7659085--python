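"""NanoString nCounter probe-count normalization.

The chain mirrors standard nCounter practice: (1) a per-sample scaling
factor from the built-in positive-control probes (cohort mean of
positive-probe means divided by the sample's positive-probe mean);
samples with a factor outside [0.3, 3] are disqualified; (2) scaled
counts are normalized to the geometric mean of the housekeeping probes,
re-centered on the cohort geometric mean so an average sample passes
through unchanged; (3) background, estimated as the mean of the
negative-control probes, is subtracted and floored at zero.

Cohort reference statistics are fit once (``NCounterNormalizer.fit``)
and then applied per sample, so normalizing a sample is invariant to
rescaling all of its counts by a constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import InputError

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")
QUALIFICATION_RANGE = (0.3, 3.0)

__all__ = [
    "NCounterNormalizer",
    "scaling_factor",
    "normalize_counts",
    "subtract_background",
]


def _check_classes(counts: pd.DataFrame, classes: pd.Series) -> None:
    missing = [p for p in counts.index if p not in classes.index]
    if missing:
        raise InputError(f"probes without a class label: {missing[:5]}")
    unknown = set(classes.unique()) - set(PROBE_CLASSES)
    if unknown:
        raise InputError(f"unknown probe classes: {sorted(unknown)}")


class NCounterNormalizer:
    """Positive-control scaling + housekeeping normalization + background
    removal against a fixed reference cohort.

    ``counts``: probes x samples frame of raw counts. ``classes``: probe
    class per probe (endogenous / positive / negative / housekeeping).
    """

    def __init__(self, classes: pd.Series):
        self.classes = classes
        self._pos = classes.index[classes == "positive"]
        self._hk = classes.index[classes == "housekeeping"]
        self._neg = classes.index[classes == "negative"]
        self.ref_positive_mean: float | None = None
        self.ref_hk_geomean: float | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, cohort: pd.DataFrame) -> "NCounterNormalizer":
        """Fix the cohort references: the across-sample mean of
        positive-probe means, and the geometric mean over samples of the
        scaled housekeeping geometric means."""
        _check_classes(cohort, self.classes)
        if len(self._pos) == 0:
            raise InputError("at least one positive-control probe is required")
        pos_means = cohort.loc[self._pos].mean(axis=0)
        if (pos_means <= 0).any():
            bad = pos_means.index[pos_means <= 0].tolist()
            raise InputError(f"zero positive-control signal in samples {bad}")
        self.ref_positive_mean = float(pos_means.mean())
        if len(self._hk):
            hk = cohort.loc[self._hk]
            if (hk.to_numpy() <= 0).any():
                raise InputError("housekeeping counts must be positive to fit")
            factors = self.ref_positive_mean / pos_means
            hk_geo = gmean(hk.mul(factors, axis=1), axis=0)
            self.ref_hk_geomean = float(gmean(hk_geo))
        return self

    def _require_fit(self) -> None:
        if self.ref_positive_mean is None:
            raise InputError("normalizer must be fit on a cohort first")

    # -- per-sample operations --------------------------------------------

    def scaling_factor(self, sample: pd.Series) -> tuple[float, bool]:
        """(factor, qualified): factor = cohort positive mean / sample
        positive mean; qualified iff 0.3 <= factor <= 3."""
        self._require_fit()
        pos_mean = float(sample.loc[self._pos].mean())
        if pos_mean <= 0:
            return float("inf"), False
        factor = self.ref_positive_mean / pos_mean
        lo, hi = QUALIFICATION_RANGE
        return factor, lo <= factor <= hi

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Scale every sample by its positive-control factor, then
        normalize to the housekeeping geometric mean re-centered on the
        cohort reference. Raises if a housekeeping count is zero."""
        self._require_fit()
        _check_classes(counts, self.classes)
        factors = pd.Series(
            [self.scaling_factor(counts[s])[0] for s in counts.columns],
            index=counts.columns,
        )
        scaled = counts.mul(factors, axis=1)
        if len(self._hk) and self.ref_hk_geomean is not None:
            hk = scaled.loc[self._hk]
            if (hk.to_numpy() <= 0).any():
                raise InputError("housekeeping counts must be positive")
            hk_geo = pd.Series(gmean(hk, axis=0), index=scaled.columns)
            scaled = scaled.div(hk_geo, axis=1) * self.ref_hk_geomean
        return scaled

    def background_correct(self, normalized: pd.DataFrame) -> pd.DataFrame:
        """Subtract the per-sample mean of the normalized negative
        controls from every probe, floored at zero."""
        if len(self._neg) == 0:
            return normalized
        background = normalized.loc[self._neg].mean(axis=0)
        return normalized.sub(background, axis=1).clip(lower=0.0)

    def qualified_samples(self, counts: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {s: self.scaling_factor(counts[s])[1] for s in counts.columns}
        )


# ---------------------------------------------------------------------------
# functional wrappers over a single cohort


def scaling_factor(sample: pd.Series, cohort: pd.DataFrame, classes: pd.Series):
    """Per-sample positive-control scaling factor against a cohort,
    with its qualification flag."""
    return NCounterNormalizer(classes).fit(cohort).scaling_factor(sample)


def normalize_counts(counts: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Full scaling + housekeeping normalization of a cohort against its
    own references."""
    return NCounterNormalizer(classes).fit(counts).transform(counts)


def subtract_background(normalized: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Remove the negative-control mean from normalized counts, floored
    at zero."""
    norm = NCounterNormalizer(classes)
    return norm.background_correct(normalized)
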