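"""Ohnolog and singleton identification with synteny scoring.

A teleost whole-genome-duplication (TGD) ohnolog pair is a pair of
within-species paralogs in 2:1 orthology with the pre-duplication
outgroup, spotted gar. Candidate paralog pairs from a Biomart-style
export are reduced by five conjunctive filters:

1. drop pairs whose duplication-ancestor label is "Clupeocephala";
2. drop pairs exhibiting more than one distinct gar ortholog;
3. drop every pair containing a gene that appears in more than one
   candidate pair;
4. drop pairs with a gene not annotated to a chromosome (unanchored
   contigs, mitochondrion);
5. drop pairs less than 5 Mbp apart on the same chromosome (likely
   tandem duplicates rather than whole-genome duplicates).

Singletons (post-duplication genes resolved back to a single copy) are
genes with no paralog row carrying a TGD or post-TGD lineage
duplication-ancestor label, no "Neopterygii" ancestor (an Ensembl tree
artifact node), no "one of many" gene-name marker, and a one-to-one gar
ortholog.

Synteny co-linearization scores the fraction of a gene's 2n chromosomal
neighbors whose gar orthologs fall within the candidate gar gene's own
2n-gene neighborhood; when a fish gene has several candidate gar
orthologs the highest-scoring pair wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeneLookupError, InputError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "ensembl_gene_id",
    "paralog_gene_id",
    "paralog_subtype",
    "gar_ortholog_id",
    "gar_orthology_type",
    "chromosome_name",
    "start_position",
    "end_position",
    "external_gene_name",
)

# duplication-ancestor labels marking TGD or post-TGD lineage-specific
# duplication; the three misspelled variants appear verbatim in public
# tables, so both spellings are matched
POST_TGD_ANCESTORS = (
    "Clupeocephala",
    "Euteleosteomorpha",
    "Percomorphaceae",
    "Ovalentaria",
    "Atherinomorphae",
    "Cyprinodontlformes",
    "Cyprinodontiformes",
    "Cyprinodontoldel",
    "Cyprinodontoidei",
    "Poecllilnae",
    "Poeciliinae",
    "Xiphophorus",
)

OHNOLOG_EXCLUDED_ANCESTOR = "Clupeocephala"
TREE_ARTIFACT_ANCESTOR = "Neopterygii"
MIN_SEPARATION_BP = 5_000_000
ONE2ONE = "ortholog_one2one"
OHNOLOG_FILTERS = (
    "clupeocephala_ancestor",
    "multi_gar_ortholog",
    "repeated_gene",
    "unanchored_contig",
    "tandem_lt_5Mbp",
)
SINGLETON_FILTERS = (
    "post_tgd_ancestor",
    "neopterygii_ancestor",
    "one_of_many_name",
    "non_one2one_ortholog",
)

__all__ = [
    "OhnologPair",
    "SyntenyWindow",
    "GenomeOrder",
    "identify_ohnolog_pairs",
    "identify_singletons",
    "ohnolog_filter_report",
    "singleton_filter_report",
    "synteny_score",
    "assign_best_ortholog",
    "ortholog_map_from_table",
]


@dataclass(frozen=True)
class OhnologPair:
    """A resolved 2:1 relationship: two fish paralogs, one gar ortholog."""

    gene_a: str
    gene_b: str
    gar_id: str
    chrom_a: str = ""
    start_a: int = 0
    chrom_b: str = ""
    start_b: int = 0


@dataclass(frozen=True)
class SyntenyWindow:
    """Neighborhood of a focal gene and of a candidate gar ortholog.

    ``neighbors``/``gar_neighbors`` exclude the focal genes themselves
    and may be shorter than 2n at chromosome ends.
    """

    focal_gene: str
    neighbors: tuple[str, ...]
    gar_gene: str
    gar_neighbors: tuple[str, ...]
    n: int


def _check_schema(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"homology table is missing required column {col!r}")


def _default_anchored(names: Iterable[str]) -> set[str]:
    """Heuristic chromosome list: plain numbers or chr-prefixed numbers.

    Scaffold/contig accessions and the mitochondrion fall through; pass
    an explicit ``chromosomes`` list to override.
    """
    anchored = set()
    for name in names:
        s = str(name)
        body = s[3:] if s.lower().startswith("chr") else s
        if body.isdigit():
            anchored.add(s)
    return anchored


def _gene_info(table: pd.DataFrame):
    """Per-gene gar-ortholog sets and coordinates."""
    gar_sets: dict[str, set[str]] = {}
    coords: dict[str, tuple[str, int]] = {}
    for row in table.itertuples(index=False):
        g = row.ensembl_gene_id
        gar_sets.setdefault(g, set())
        if isinstance(row.gar_ortholog_id, str) and row.gar_ortholog_id:
            gar_sets[g].add(row.gar_ortholog_id)
        if g not in coords and pd.notna(row.start_position):
            coords[g] = (str(row.chromosome_name), int(row.start_position))
    return gar_sets, coords


def _candidate_pairs(table: pd.DataFrame):
    """Unordered paralog pairs and the ancestor labels on their rows."""
    pairs: dict[tuple[str, str], set[str]] = {}
    para = table[table["paralog_gene_id"].notna() & (table["paralog_gene_id"] != "")]
    for row in para.itertuples(index=False):
        key = tuple(sorted((row.ensembl_gene_id, row.paralog_gene_id)))
        subtypes = pairs.setdefault(key, set())
        if isinstance(row.paralog_subtype, str) and row.paralog_subtype:
            subtypes.add(row.paralog_subtype)
    return pairs


def _ohnolog_failures(
    pair,
    subtypes,
    gar_sets,
    coords,
    anchored,
    counts,
) -> list[str]:
    """Names of the predicates this candidate pair violates."""
    a, b = pair
    failures = []
    if OHNOLOG_EXCLUDED_ANCESTOR in subtypes:
        failures.append("clupeocephala_ancestor")
    union = gar_sets.get(a, set()) | gar_sets.get(b, set())
    if len(union) != 1:
        failures.append("multi_gar_ortholog")
    if counts[a] > 1 or counts[b] > 1:
        failures.append("repeated_gene")
    ca, cb = coords.get(a), coords.get(b)
    if ca is None or cb is None or ca[0] not in anchored or cb[0] not in anchored:
        failures.append("unanchored_contig")
    elif ca[0] == cb[0] and abs(ca[1] - cb[1]) < MIN_SEPARATION_BP:
        failures.append("tandem_lt_5Mbp")
    return failures


def ohnolog_filter_report(
    table: pd.DataFrame, chromosomes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per candidate pair, which of the five predicates it fails
    (each evaluated against the full candidate set)."""
    _check_schema(table)
    pairs = _candidate_pairs(table)
    gar_sets, coords = _gene_info(table)
    anchored = (
        set(map(str, chromosomes))
        if chromosomes is not None
        else _default_anchored(table["chromosome_name"].dropna().unique())
    )
    counts: dict[str, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    rows = []
    for pair in sorted(pairs):
        failures = _ohnolog_failures(
            pair, pairs[pair], gar_sets, coords, anchored, counts
        )
        rows.append(
            {
                "gene_a": pair[0],
                "gene_b": pair[1],
                "failed_filters": tuple(failures),
                "passes": not failures,
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "failed_filters", "passes"])


def identify_ohnolog_pairs(
    table: pd.DataFrame,
    chromosomes: Sequence[str] | None = None,
    filter_order: Sequence[str] = OHNOLOG_FILTERS,
) -> list[OhnologPair]:
    """Apply the five-step ohnolog filter chain.

    ``filter_order`` exists so the conjunctive predicates can be applied
    in any order (the result is order-invariant on consistent tables);
    the default is the canonical order. Output is sorted by gene_a.
    """
    _check_schema(table)
    if set(filter_order) != set(OHNOLOG_FILTERS):
        raise InputError(f"filter_order must be a permutation of {OHNOLOG_FILTERS}")
    pairs = _candidate_pairs(table)
    gar_sets, coords = _gene_info(table)
    anchored = (
        set(map(str, chromosomes))
        if chromosomes is not None
        else _default_anchored(table["chromosome_name"].dropna().unique())
    )
    surviving = set(pairs)
    for name in filter_order:
        if name == "repeated_gene":
            counts: dict[str, int] = {}
            for a, b in surviving:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            surviving = {p for p in surviving if counts[p[0]] == 1 and counts[p[1]] == 1}
            continue
        keep = set()
        for pair in surviving:
            a, b = pair
            if name == "clupeocephala_ancestor":
                ok = OHNOLOG_EXCLUDED_ANCESTOR not in pairs[pair]
            elif name == "multi_gar_ortholog":
                ok = len(gar_sets.get(a, set()) | gar_sets.get(b, set())) == 1
            elif name == "unanchored_contig":
                ca, cb = coords.get(a), coords.get(b)
                ok = (
                    ca is not None
                    and cb is not None
                    and ca[0] in anchored
                    and cb[0] in anchored
                )
            else:  # tandem_lt_5Mbp
                ca, cb = coords.get(a), coords.get(b)
                ok = (
                    ca is None
                    or cb is None
                    or ca[0] != cb[0]
                    or abs(ca[1] - cb[1]) >= MIN_SEPARATION_BP
                )
            if ok:
                keep.add(pair)
        surviving = keep
    out = []
    for a, b in sorted(surviving):
        gar = next(iter(gar_sets.get(a, set()) | gar_sets.get(b, set())))
        ca = coords.get(a, ("", 0))
        cb = coords.get(b, ("", 0))
        out.append(OhnologPair(a, b, gar, ca[0], ca[1], cb[0], cb[1]))
    return out


def _singleton_failures(gene_rows: pd.DataFrame, name: str) -> list[str]:
    failures = []
    subtypes = set(gene_rows["paralog_subtype"].dropna())
    if subtypes & set(POST_TGD_ANCESTORS):
        failures.append("post_tgd_ancestor")
    if TREE_ARTIFACT_ANCESTOR in subtypes:
        failures.append("neopterygii_ancestor")
    lowered = (name or "").lower()
    if "one of many" in lowered or "1 of many" in lowered:
        failures.append("one_of_many_name")
    gar_ids = set(gene_rows["gar_ortholog_id"].dropna()) - {""}
    gar_types = set(gene_rows["gar_orthology_type"].dropna()) - {""}
    if len(gar_ids) != 1 or gar_types != {ONE2ONE}:
        failures.append("non_one2one_ortholog")
    return failures


def singleton_filter_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per gene, which of the four singleton predicates it fails."""
    _check_schema(table)
    rows = []
    for gene, grp in table.groupby("ensembl_gene_id", sort=True):
        name = next(iter(grp["external_gene_name"].dropna()), "")
        failures = _singleton_failures(grp, name)
        rows.append(
            {"gene_id": gene, "failed_filters": tuple(failures), "passes": not failures}
        )
    return pd.DataFrame(rows, columns=["gene_id", "failed_filters", "passes"])


def identify_singletons(
    table: pd.DataFrame, chromosomes: Sequence[str] | None = None
) -> list[str]:
    """Genes in 1:1 orthology with gar that survive the four exclusions.

    A final consistency guard removes any gene that the ohnolog chain
    resolved into a pair, so the two calls are disjoint even on tables
    whose orthology-type labels contradict the id mapping.
    """
    report = singleton_filter_report(table)
    singles = set(report.loc[report["passes"], "gene_id"])
    in_pairs = {
        g
        for p in identify_ohnolog_pairs(table, chromosomes=chromosomes)
        for g in (p.gene_a, p.gene_b)
    }
    return sorted(singles - in_pairs)


# ---------------------------------------------------------------------------
# synteny


class GenomeOrder:
    """Coordinate-sorted gene order per chromosome, for window lookups."""

    def __init__(self, table: pd.DataFrame):
        """``table`` needs gene id, chromosome and start columns; the
        first matching column names among (ensembl_gene_id | gene_id),
        (chromosome_name | chromosome), (start_position | start) are used."""
        gene_col = "ensembl_gene_id" if "ensembl_gene_id" in table.columns else "gene_id"
        chrom_col = (
            "chromosome_name" if "chromosome_name" in table.columns else "chromosome"
        )
        start_col = "start_position" if "start_position" in table.columns else "start"
        sub = (
            table[[gene_col, chrom_col, start_col]]
            .dropna()
            .drop_duplicates(subset=gene_col)
            .sort_values([chrom_col, start_col])
        )
        self._position: dict[str, tuple[str, int]] = {}
        self._order: dict[str, list[str]] = {}
        for chrom, grp in sub.groupby(chrom_col, sort=True):
            genes = grp[gene_col].tolist()
            self._order[str(chrom)] = genes
            for i, g in enumerate(genes):
                self._position[g] = (str(chrom), i)

    def __contains__(self, gene: str) -> bool:
        return gene in self._position

    def neighbors(self, gene: str, n: int) -> tuple[str, ...]:
        """Up to n genes on each side of ``gene`` on its chromosome,
        truncated at chromosome ends, focal gene excluded."""
        if gene not in self._position:
            raise GeneLookupError(gene)
        chrom, i = self._position[gene]
        order = self._order[chrom]
        lo = max(0, i - n)
        return tuple(order[lo:i] + order[i + 1 : i + 1 + n])

    def window(self, focal: str, gar_gene: str, gar_order: "GenomeOrder", n: int) -> SyntenyWindow:
        return SyntenyWindow(
            focal_gene=focal,
            neighbors=self.neighbors(focal, n),
            gar_gene=gar_gene,
            gar_neighbors=gar_order.neighbors(gar_gene, n),
            n=n,
        )


def ortholog_map_from_table(table: pd.DataFrame) -> dict[str, set[str]]:
    """gene id -> set of gar ortholog ids, from a homology table."""
    _check_schema(table)
    out: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        if isinstance(row.gar_ortholog_id, str) and row.gar_ortholog_id:
            out.setdefault(row.ensembl_gene_id, set()).add(row.gar_ortholog_id)
    return out


def synteny_score(
    window: SyntenyWindow, orthology: Mapping[str, set[str]]
) -> tuple[float, bool]:
    """Fraction of the focal gene's neighbors with a gar ortholog inside
    the gar-side window.

    The denominator is the number of neighbors actually considered
    (2n for a full window, fewer when truncated at a chromosome end).
    Returns ``(score, degenerate)``; an empty window scores 0, flagged.
    """
    if window.n < 1:
        raise InputError("window size n must be >= 1")
    if not window.neighbors:
        return 0.0, True
    gar_set = set(window.gar_neighbors)
    hits = sum(
        1
        for g in window.neighbors
        if orthology.get(g) and (orthology[g] & gar_set)
    )
    return hits / len(window.neighbors), False


def assign_best_ortholog(
    gene: str,
    candidates: Sequence[str],
    focal_order: GenomeOrder,
    gar_order: GenomeOrder,
    orthology: Mapping[str, set[str]],
    n: int = 10,
) -> tuple[str, float]:
    """Pick the gar candidate with the highest synteny score.

    Ties break to the lexicographically smallest gar id, with a logged
    warning. Raises on an empty candidate list.
    """
    if not candidates:
        raise GeneLookupError(f"no candidate gar orthologs for {gene}")
    scored = []
    for gar in candidates:
        window = focal_order.window(gene, gar, gar_order, n)
        score, _ = synteny_score(window, orthology)
        scored.append((gar, score))
    best_score = max(s for _, s in scored)
    winners = sorted(g for g, s in scored if s == best_score)
    if len(winners) > 1:
        logger.warning(
            "synteny tie for %s among %s (score %.3f); keeping %s",
            gene,
            winners,
            best_score,
            winners[0],
        )
    return winners[0], best_score
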