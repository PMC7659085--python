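"""Functional-divergence classification of cyclic gene duplicates.

After a whole-genome duplication a pair of retained duplicates
(ohnologs) may partition the ancestral expression pattern between
organs or phases (sub-functionalization), acquire a pattern the partner
lacks (neo-functionalization), or both keep the identical cyclic
pattern (super-functionalization). Operationally the classifier looks
only at which (gene, organ) combinations were called cyclic and at
their peak zeitgeber times:

* intra-organ scope (all cyclic calls in one organ): ONE_CYCLIC,
  BOTH_CYCLIC_SAME (equal peaks), BOTH_CYCLIC_DIFFERENT;
* inter-organ scope (cyclic calls span several organs):
  ONE_CYCLIC_MULTI (only one gene ever cyclic), SYNCHRONIZED_MULTI
  (both cyclic with equal peaks in every shared cyclic organ),
  DIFFERENT_BY_ORGAN otherwise;
* multi-organ singletons: SYNCHRONIZED (one common peak across all
  cyclic organs) or DIFFERENT.

"Same pattern" means identical peak Zt at the 3 h sampling resolution;
``peak_tolerance`` (hours, circular, default 0) relaxes the equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError

# intra-organ categories
ONE_CYCLIC = "ONE_CYCLIC"
BOTH_CYCLIC_SAME = "BOTH_CYCLIC_SAME"
BOTH_CYCLIC_DIFFERENT = "BOTH_CYCLIC_DIFFERENT"
# inter-organ categories
ONE_CYCLIC_MULTI = "ONE_CYCLIC_MULTI"
DIFFERENT_BY_ORGAN = "DIFFERENT_BY_ORGAN"
SYNCHRONIZED_MULTI = "SYNCHRONIZED_MULTI"
# singleton categories
SYNCHRONIZED = "SYNCHRONIZED"
DIFFERENT = "DIFFERENT"

NOT_CYCLIC = "NOT_CYCLIC"

INTRA_CATEGORIES = (ONE_CYCLIC, BOTH_CYCLIC_DIFFERENT, BOTH_CYCLIC_SAME)
INTER_CATEGORIES = (ONE_CYCLIC_MULTI, DIFFERENT_BY_ORGAN, SYNCHRONIZED_MULTI)
SINGLETON_CATEGORIES = (SYNCHRONIZED, DIFFERENT)

__all__ = [
    "DivergenceCall",
    "ScopeError",
    "peaks_from_rhythm",
    "classify_intra_organ",
    "classify_inter_organ",
    "classify_singleton_multi_organ",
    "classify_pair",
    "classify_all",
    "summarize_divergence",
]


class ScopeError(InputError):
    """The pair/gene does not satisfy the precondition of this scope."""


@dataclass(frozen=True)
class DivergenceCall:
    unit_id: str
    scope: str  # intra_organ | inter_organ | singleton_multi_organ | not_cyclic
    category: str
    organs: tuple[str, ...]


def peaks_from_rhythm(rhythm: pd.DataFrame) -> dict[tuple[str, str], float]:
    """(gene, organ) -> peak Zt for every cyclic call in a rhythm table."""
    cyc = rhythm[rhythm["is_cyclic"].astype(bool)]
    return {
        (r.gene_id, r.organ): float(r.peak_zt) for r in cyc.itertuples(index=False)
    }


def _peaks_equal(p1: float, p2: float, tol: float) -> bool:
    d = abs(p1 - p2) % 24.0
    return min(d, 24.0 - d) <= tol


def _pair_calls(gene_a, gene_b, peaks):
    calls_a = {o: p for (g, o), p in peaks.items() if g == gene_a}
    calls_b = {o: p for (g, o), p in peaks.items() if g == gene_b}
    return calls_a, calls_b


def classify_intra_organ(
    gene_a: str,
    gene_b: str,
    peaks: Mapping[tuple[str, str], float],
    peak_tolerance: float = 0.0,
) -> str:
    """Category for a pair whose cyclic calls sit in exactly one organ."""
    calls_a, calls_b = _pair_calls(gene_a, gene_b, peaks)
    organs = set(calls_a) | set(calls_b)
    if len(organs) != 1:
        raise ScopeError(
            f"pair ({gene_a}, {gene_b}) has cyclic calls in {len(organs)} organs; "
            "intra-organ scope requires exactly one"
        )
    organ = next(iter(organs))
    if (organ in calls_a) != (organ in calls_b):
        return ONE_CYCLIC
    if _peaks_equal(calls_a[organ], calls_b[organ], peak_tolerance):
        return BOTH_CYCLIC_SAME
    return BOTH_CYCLIC_DIFFERENT


def classify_inter_organ(
    gene_a: str,
    gene_b: str,
    peaks: Mapping[tuple[str, str], float],
    peak_tolerance: float = 0.0,
) -> str:
    """Category for a pair whose cyclic calls span two or more organs."""
    calls_a, calls_b = _pair_calls(gene_a, gene_b, peaks)
    organs = set(calls_a) | set(calls_b)
    if len(organs) < 2:
        raise ScopeError(
            f"pair ({gene_a}, {gene_b}) has cyclic calls in {len(organs)} organ(s); "
            "inter-organ scope requires at least two"
        )
    if not calls_a or not calls_b:
        return ONE_CYCLIC_MULTI
    shared = set(calls_a) & set(calls_b)
    if shared and all(
        _peaks_equal(calls_a[o], calls_b[o], peak_tolerance) for o in shared
    ):
        return SYNCHRONIZED_MULTI
    return DIFFERENT_BY_ORGAN


def classify_singleton_multi_organ(
    gene: str,
    peaks: Mapping[tuple[str, str], float],
    peak_tolerance: float = 0.0,
) -> str:
    """SYNCHRONIZED iff the singleton peaks at the same Zt in every organ
    where it is cyclic (requires cyclic calls in >= 2 organs)."""
    calls = {o: p for (g, o), p in peaks.items() if g == gene}
    if len(calls) < 2:
        raise ScopeError(f"{gene} is cyclic in {len(calls)} organ(s); need >= 2")
    values = list(calls.values())
    if all(_peaks_equal(values[0], p, peak_tolerance) for p in values[1:]):
        return SYNCHRONIZED
    return DIFFERENT


def classify_pair(
    unit_id: str,
    gene_a: str,
    gene_b: str,
    peaks: Mapping[tuple[str, str], float],
    peak_tolerance: float = 0.0,
) -> DivergenceCall:
    """Route a pair to its scope and classify it; symmetric in
    (gene_a, gene_b)."""
    calls_a, calls_b = _pair_calls(gene_a, gene_b, peaks)
    organs = tuple(sorted(set(calls_a) | set(calls_b)))
    if not organs:
        return DivergenceCall(unit_id, "not_cyclic", NOT_CYCLIC, ())
    if len(organs) == 1:
        cat = classify_intra_organ(gene_a, gene_b, peaks, peak_tolerance)
        return DivergenceCall(unit_id, "intra_organ", cat, organs)
    cat = classify_inter_organ(gene_a, gene_b, peaks, peak_tolerance)
    return DivergenceCall(unit_id, "inter_organ", cat, organs)


def classify_all(
    pairs: Iterable[tuple[str, str, str]],
    peaks: Mapping[tuple[str, str], float],
    singletons: Sequence[str] = (),
    peak_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Classify every (pair_id, gene_a, gene_b) plus every singleton that
    is cyclic in two or more organs. Returns a tidy call table."""
    rows = []
    for unit_id, a, b in pairs:
        call = classify_pair(unit_id, a, b, peaks, peak_tolerance)
        rows.append(
            {
                "unit_id": call.unit_id,
                "scope": call.scope,
                "category": call.category,
                "n_organs": len(call.organs),
                "organs": ",".join(call.organs),
            }
        )
    for gene in singletons:
        calls = {o: p for (g, o), p in peaks.items() if g == gene}
        if len(calls) < 2:
            continue
        cat = classify_singleton_multi_organ(gene, peaks, peak_tolerance)
        rows.append(
            {
                "unit_id": gene,
                "scope": "singleton_multi_organ",
                "category": cat,
                "n_organs": len(calls),
                "organs": ",".join(sorted(calls)),
            }
        )
    return pd.DataFrame(
        rows, columns=["unit_id", "scope", "category", "n_organs", "organs"]
    )


def summarize_divergence(calls: pd.DataFrame) -> dict:
    """Counts and derived percentages per scope and category.

    ``single_organ_pair_percent`` is the share of intra-organ pairs
    among all pairs with at least one cyclic call (one decimal place,
    following the source arithmetic).
    """
    def scope_counts(scope: str, categories) -> dict[str, int]:
        sub = calls[calls["scope"] == scope]
        return {c: int((sub["category"] == c).sum()) for c in categories}

    intra = scope_counts("intra_organ", INTRA_CATEGORIES)
    inter = scope_counts("inter_organ", INTER_CATEGORIES)
    singleton = scope_counts("singleton_multi_organ", SINGLETON_CATEGORIES)
    n_intra = sum(intra.values())
    n_inter = sum(inter.values())
    total = n_intra + n_inter
    return {
        "intra_organ": intra,
        "inter_organ": inter,
        "singleton_multi_organ": singleton,
        "not_cyclic_pairs": int((calls["scope"] == "not_cyclic").sum()),
        "intra_organ_pairs": n_intra,
        "inter_organ_pairs": n_inter,
        "total_cyclic_pairs": total,
        "single_organ_pair_percent": (
            round(100.0 * n_intra / total, 1) if total else 0.0
        ),
    }
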