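"""Nonparametric detection of 24 h cyclic expression.

The test groups each gene's cpm values by zeitgeber time and scores an
umbrella alternative: a monotone rise from a trough timepoint to a peak
timepoint followed by a monotone fall back to the trough, on the
circular 24 h axis. Each arc is scored by summing Mann-Whitney U counts
over all ordered group pairs within the arc (the Jonckheere-Terpstra
construction for a monotone alternative), with ties counted as half a
concordance. Every (peak, trough) placement on the sampled grid is
tested; the per-hypothesis right-tail permutation p-values are combined
by Bonferroni across the hypotheses, and a gene is called cyclic when
the combined p-value is below 0.01.

The permutation null is computed exactly (full enumeration of the N!
position permutations) for up to 10 observations, and by seeded
Monte-Carlo permutation otherwise. Because the statistic is a rank
statistic, the null depends only on the group sizes and the tie
structure of the pooled values, so null distributions are cached and
shared across genes.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, InputError
from .expression import CountMatrix, organ_profiles

EXACT_MAX_OBS = 10  # full enumeration bound: 10! permutations
_CHUNK = 40320

__all__ = [
    "RhythmResult",
    "RhythmTester",
    "umbrella_statistic",
    "rhythm_test",
    "peak_statistics",
    "detect_rhythms",
]


# ---------------------------------------------------------------------------
# statistic construction


def _pair_list(k: int):
    return [(a, b) for a in range(k) for b in range(a + 1, k)]


def _arc(start: int, end: int, k: int) -> list[int]:
    """Circular inclusive run of group indices from start to end."""
    out = [start]
    i = start
    while i != end:
        i = (i + 1) % k
        out.append(i)
    return out


@dataclass(frozen=True)
class _Hypothesis:
    peak: int
    trough: int
    coeff: np.ndarray  # weights on the upper-triangle pairwise U vector
    const: float
    s_max: float


def _build_hypothesis(sizes, peak: int, trough: int, pair_index) -> _Hypothesis:
    k = len(sizes)
    coeff = np.zeros(len(pair_index), dtype=float)
    const = 0.0
    s_max = 0.0
    rising = _arc(trough, peak, k)
    falling = _arc(peak, trough, k)
    for arc, rising_arc in ((rising, True), (falling, False)):
        for x in range(len(arc)):
            for y in range(x + 1, len(arc)):
                e, l = arc[x], arc[y]  # e strictly earlier than l within the arc
                n_el = sizes[e] * sizes[l]
                s_max += n_el
                # U[a,b] for a<b counts (value in b) > (value in a), ties 1/2;
                # the complementary direction is n_a*n_b - U[a,b].
                if rising_arc:  # count later-beats-earlier
                    if e < l:
                        coeff[pair_index[(e, l)]] += 1.0
                    else:
                        coeff[pair_index[(l, e)]] -= 1.0
                        const += n_el
                else:  # falling: count earlier-beats-later
                    if e < l:
                        coeff[pair_index[(e, l)]] -= 1.0
                        const += n_el
                    else:
                        coeff[pair_index[(l, e)]] += 1.0
    return _Hypothesis(peak, trough, coeff, const, s_max)


def _build_hypotheses(sizes):
    k = len(sizes)
    pairs = _pair_list(k)
    pair_index = {p: i for i, p in enumerate(pairs)}
    hyps = [
        _build_hypothesis(sizes, peak, trough, pair_index)
        for peak in range(k)
        for trough in range(k)
        if trough != peak
    ]
    return pairs, pair_index, hyps


def _group_bounds(sizes):
    b = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(b[i]), int(b[i + 1])) for i in range(len(sizes))]


def _pairwise_u(values: np.ndarray, sizes, pairs) -> np.ndarray:
    """Mann-Whitney U counts (ties as 1/2) for every group pair a<b.

    ``values`` is (M, N) with pooled observations laid out group by
    group; returns (M, P).
    """
    bounds = _group_bounds(sizes)
    out = np.empty((values.shape[0], len(pairs)), dtype=float)
    for p, (a, b) in enumerate(pairs):
        va = values[:, bounds[a][0] : bounds[a][1]][:, :, None]
        vb = values[:, bounds[b][0] : bounds[b][1]][:, None, :]
        gt = (vb > va).sum(axis=(1, 2))
        eq = (vb == va).sum(axis=(1, 2))
        out[:, p] = gt + 0.5 * eq
    return out


def umbrella_statistic(groups, peak_index: int, trough_index: int):
    """Umbrella rank statistic S and its maximum for one (peak, trough).

    ``groups`` is a sequence of per-timepoint value arrays in circular
    time order. S sums, over all ordered group pairs within the rising
    arc (trough -> peak) and the falling arc (peak -> trough), the count
    of concordant value pairs, ties counted as 1/2. Returns (S, S_max).
    """
    if peak_index == trough_index:
        raise InputError("peak and trough indices must differ")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise InputError("every timepoint group must be non-empty")
    sizes = tuple(g.size for g in groups)
    pairs = _pair_list(len(sizes))
    pair_index = {p: i for i, p in enumerate(pairs)}
    hyp = _build_hypothesis(sizes, peak_index, trough_index, pair_index)
    pooled = np.concatenate(groups)[None, :]
    u = _pairwise_u(pooled, sizes, pairs)[0]
    return float(u @ hyp.coeff + hyp.const), float(hyp.s_max)


# ---------------------------------------------------------------------------
# permutation null


def _tie_key(pooled: np.ndarray):
    _, counts = np.unique(pooled, return_counts=True)
    return tuple(sorted(counts.tolist()))


class _NullDistribution:
    """Right-tail lookup over the permutation distribution of S for
    every hypothesis, stored as suffix counts on the half-integer grid."""

    def __init__(self, tail: np.ndarray, n_perm: int, exact: bool):
        self.tail = tail  # (H, nbins): #permutations with S >= bin/2
        self.n_perm = n_perm
        self.exact = exact

    def pvalues(self, s_obs: np.ndarray) -> np.ndarray:
        idx = np.rint(2.0 * s_obs).astype(int)
        idx = np.clip(idx, 0, self.tail.shape[1] - 1)
        counts = self.tail[np.arange(self.tail.shape[0]), idx]
        if self.exact:
            return counts / self.n_perm
        return (counts + 1.0) / (self.n_perm + 1.0)


def _accumulate(hist: np.ndarray, s_block: np.ndarray) -> None:
    nbins = hist.shape[1]
    idx = np.rint(2.0 * s_block).astype(np.int64)
    np.clip(idx, 0, nbins - 1, out=idx)
    for h in range(hist.shape[0]):
        hist[h] += np.bincount(idx[:, h], minlength=nbins)


class RhythmTester:
    """Umbrella permutation test for a fixed timepoint design.

    Builds the (peak, trough) hypothesis set once for the given group
    sizes and caches permutation nulls per tie pattern, so batches of
    genes sharing the design are tested efficiently.
    """

    def __init__(
        self,
        sizes,
        alpha: float = 0.01,
        method: str = "auto",
        n_perm: int = 10_000,
        seed: int | None = None,
    ):
        sizes = tuple(int(s) for s in sizes)
        if len(sizes) < 3:
            raise ConfigurationError("need at least 3 timepoint groups")
        if any(s < 1 for s in sizes):
            raise ConfigurationError("every timepoint group must be non-empty")
        if method not in ("auto", "exact", "monte_carlo"):
            raise ConfigurationError(f"unknown method {method!r}")
        if method == "monte_carlo" and n_perm < 100:
            raise ConfigurationError("n_perm must be at least 100 for monte_carlo")
        self.sizes = sizes
        self.n_obs = int(sum(sizes))
        self.alpha = alpha
        self.n_perm = int(n_perm)
        self.seed = 0 if seed is None else int(seed)
        if method == "auto":
            method = "exact" if self.n_obs <= EXACT_MAX_OBS else "monte_carlo"
        if method == "exact" and self.n_obs > EXACT_MAX_OBS:
            raise ConfigurationError(
                f"exact enumeration supports at most {EXACT_MAX_OBS} observations"
            )
        if method == "monte_carlo" and n_perm < 100:
            raise ConfigurationError("n_perm must be at least 100 for monte_carlo")
        self.method = method
        self.pairs, self._pair_index, self.hyps = _build_hypotheses(sizes)
        self._coeff = np.stack([h.coeff for h in self.hyps])  # (H, P)
        self._const = np.array([h.const for h in self.hyps])
        self._smax = np.array([h.s_max for h in self.hyps])
        self._nbins = int(np.rint(2.0 * self._smax.max())) + 1
        self._null_cache: dict[tuple, _NullDistribution] = {}

    @property
    def n_hypotheses(self) -> int:
        return len(self.hyps)

    # -- null machinery ----------------------------------------------------

    def _statistics(self, values: np.ndarray) -> np.ndarray:
        u = _pairwise_u(values, self.sizes, self.pairs)
        return u @ self._coeff.T + self._const

    def _null_for(self, pooled: np.ndarray) -> _NullDistribution:
        key = _tie_key(pooled)
        null = self._null_cache.get(key)
        if null is not None:
            return null
        # the null depends only on the midrank multiset, i.e. on the key
        canonical = rankdata(pooled)
        hist = np.zeros((len(self.hyps), self._nbins), dtype=np.int64)
        if self.method == "exact":
            n_total = 0
            it = itertools.permutations(canonical)
            while True:
                block = list(itertools.islice(it, _CHUNK))
                if not block:
                    break
                arr = np.asarray(block, dtype=float)
                n_total += arr.shape[0]
                _accumulate(hist, self._statistics(arr))
            null = _NullDistribution(self._suffix(hist), n_total, exact=True)
        else:
            child = np.random.default_rng(
                [self.seed, zlib.crc32(repr((self.sizes, key)).encode())]
            )
            done = 0
            while done < self.n_perm:
                b = min(_CHUNK, self.n_perm - done)
                arr = child.permuted(np.tile(canonical, (b, 1)), axis=1)
                _accumulate(hist, self._statistics(arr))
                done += b
            null = _NullDistribution(self._suffix(hist), self.n_perm, exact=False)
        self._null_cache[key] = null
        return null

    @staticmethod
    def _suffix(hist: np.ndarray) -> np.ndarray:
        return np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]

    # -- testing -----------------------------------------------------------

    def hypothesis_pvalues(self, values) -> np.ndarray:
        """Right-tail permutation p-value of every (peak, trough)
        hypothesis for one pooled observation vector."""
        values = np.asarray(values, dtype=float).ravel()
        if values.size != self.n_obs:
            raise InputError(f"expected {self.n_obs} pooled observations")
        s = self._statistics(values[None, :])[0]
        return self._null_for(values).pvalues(s)

    def test_many(self, values: np.ndarray) -> pd.DataFrame:
        """Test each row of ``values`` (pooled observations, group by
        group in circular time order). Returns one result row per gene."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != self.n_obs:
            raise InputError(f"expected (n_genes, {self.n_obs}) value matrix")
        s_all = self._statistics(values)  # (G, H)
        rows = []
        for g in range(values.shape[0]):
            null = self._null_for(values[g])
            p_h = null.pvalues(s_all[g])
            best = int(np.argmin(p_h))
            p_comb = min(1.0, float(p_h[best]) * self.n_hypotheses)
            rows.append(
                (
                    float(s_all[g, best]),
                    float(self._smax[best]),
                    p_comb,
                    float(p_h[best]),
                    self.hyps[best].peak,
                    self.hyps[best].trough,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "statistic",
                "s_max",
                "p_value",
                "p_best_raw",
                "peak_index",
                "trough_index",
            ],
        )

    def test_one(self, groups):
        groups = [np.asarray(g, dtype=float) for g in groups]
        if tuple(g.size for g in groups) != self.sizes:
            raise InputError("group sizes do not match this tester")
        row = self.test_many(np.concatenate(groups)[None, :]).iloc[0]
        return row


@dataclass
class RhythmResult:
    """Outcome of the umbrella test for one gene in one organ."""

    gene_id: str
    organ: str
    statistic: float
    s_max: float
    p_value: float
    is_cyclic: bool
    peak_zt: float
    peak_shape: float
    amplitude: float
    degenerate: bool = False


def rhythm_test(
    groups,
    alpha: float = 0.01,
    method: str = "auto",
    n_perm: int = 10_000,
    seed: int | None = None,
):
    """Combined umbrella permutation p-value for one gene.

    ``groups``: per-timepoint replicate values in circular time order.
    Returns a Series with statistic, s_max, p_value (Bonferroni-combined
    across (peak, trough) hypotheses), the best hypothesis indices, and
    the cyclic call at ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    tester = RhythmTester(
        [g.size for g in groups], alpha=alpha, method=method, n_perm=n_perm, seed=seed
    )
    row = tester.test_one(groups).copy()
    row["is_cyclic"] = bool(row["p_value"] < alpha)
    row["n_hypotheses"] = tester.n_hypotheses
    row["method"] = tester.method
    return row


def peak_statistics(relative, timepoints):
    """Peak Zt, peak shape and amplitude from a relative-expression profile.

    peak_zt is the timepoint of maximum relative expression; peak_shape
    the circular forward distance (hours) from the maximum to the
    minimum; amplitude the max-minus-min range in relative units. An
    all-equal profile is degenerate: amplitude 0, peak undefined (NaN).
    """
    rel = np.asarray(relative, dtype=float)
    zts = np.asarray(timepoints, dtype=float)
    if rel.shape != zts.shape:
        raise InputError("profile and timepoint vectors differ in length")
    if np.all(rel == rel[0]):
        return float("nan"), float("nan"), 0.0, True
    i_max = int(np.argmax(rel))
    i_min = int(np.argmin(rel))
    peak_zt = float(zts[i_max])
    shape = float((zts[i_min] - zts[i_max]) % 24.0)
    amplitude = float(rel[i_max] - rel[i_min])
    return peak_zt, shape, amplitude, False


def detect_rhythms(
    cm: CountMatrix,
    alpha: float = 0.01,
    method: str = "auto",
    n_perm: int = 10_000,
    seed: int | None = None,
    min_cpm: float = 1.0,
    min_timepoints: int = 2,
    bh_correct: bool = False,
    organs=None,
) -> pd.DataFrame:
    """Run the umbrella test per organ over all expressed genes.

    Returns a tidy frame (gene_id, organ, expressed, statistic, s_max,
    p_value, is_cyclic, peak_zt, peak_shape, amplitude, degenerate);
    unexpressed genes carry NaN test fields and is_cyclic False. With
    ``bh_correct`` a Benjamini-Hochberg adjusted column is added and
    used for the cyclic call (off by default: the raw p < alpha rule).
    """
    from .expression import compute_cpm  # local alias for clarity

    profiles = organ_profiles(cm, min_cpm=min_cpm, min_timepoints=min_timepoints)
    cpm = compute_cpm(cm.counts, cm.library_sizes())
    testers: dict[tuple, RhythmTester] = {}
    frames = []
    for organ in organs if organs is not None else cm.organs:
        prof = profiles[organ]
        meta = cm.organ_samples(organ)
        zts = sorted(meta["zt"].unique())
        ordered_cols = []
        sizes = []
        for zt in zts:
            cols = meta.index[meta["zt"] == zt].tolist()
            ordered_cols.extend(cols)
            sizes.append(len(cols))
        sizes = tuple(sizes)
        if sizes not in testers:
            testers[sizes] = RhythmTester(
                sizes, alpha=alpha, method=method, n_perm=n_perm, seed=seed
            )
        tester = testers[sizes]
        expressed = prof.expressed
        genes = expressed.index[expressed].tolist()
        base = pd.DataFrame(
            {
                "gene_id": expressed.index,
                "organ": organ,
                "expressed": expressed.to_numpy(),
            }
        ).set_index("gene_id")
        for col in ("statistic", "s_max", "p_value", "peak_zt", "peak_shape", "amplitude"):
            base[col] = np.nan
        base["is_cyclic"] = False
        base["degenerate"] = False
        if genes:
            values = cpm.loc[genes, ordered_cols].to_numpy(dtype=float)
            res = tester.test_many(values)
            res.index = pd.Index(genes, name="gene_id")
            base.loc[genes, ["statistic", "s_max", "p_value"]] = res[
                ["statistic", "s_max", "p_value"]
            ].to_numpy()
            peaks = [
                peak_statistics(prof.relative.loc[g].to_numpy(), zts) for g in genes
            ]
            peak_df = pd.DataFrame(
                peaks,
                index=genes,
                columns=["peak_zt", "peak_shape", "amplitude", "degenerate"],
            )
            base.loc[genes, ["peak_zt", "peak_shape", "amplitude"]] = peak_df[
                ["peak_zt", "peak_shape", "amplitude"]
            ].to_numpy()
            base.loc[genes, "degenerate"] = peak_df["degenerate"].astype(bool).to_numpy()
            if bh_correct:
                from statsmodels.stats.multitest import multipletests

                adj = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
                base.loc[genes, "p_adjusted"] = adj
                base.loc[genes, "is_cyclic"] = adj < alpha
            else:
                base.loc[genes, "is_cyclic"] = res["p_value"].to_numpy() < alpha
        frames.append(base.reset_index())
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["organ", "gene_id"], ignore_index=True)
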