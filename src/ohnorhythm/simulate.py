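"""Synthetic data generators with known ground truth.

Two generators emulate the study design end to end without any
download:

* ``simulate_counts`` — negative-binomial read counts for 9 organs x 8
  zeitgeber timepoints (Zt 0.5 ... 21.5, 3 h apart) x 2 replicates, with
  a planted fraction of cosine-rhythmic genes per organ. For a cyclic
  gene the per-timepoint mean is b * (1 + A * cos(2*pi*(t - phi)/24));
  phases are drawn on the sampled Zt grid so planted peaks are
  recoverable at the sampling resolution. Library-size variation is
  introduced by multinomial thinning of an oversampled matrix, which
  preserves relative means while making cpm normalization non-trivial.

* ``simulate_homology`` — a Biomart-style homology table with planted
  ohnolog pairs (two genes sharing one gar ortholog, >= 5 Mbp apart or
  on different chromosomes), planted singletons (1:1 to gar), and one
  decoy unit per requested decoy class, each constructed to violate
  exactly the filter it is named for.

Ground-truth labels are returned as sidecar tables, never encoded in
gene identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import CountMatrix

DEFAULT_ORGANS = (
    "brain",
    "eye",
    "gills",
    "ovary",
    "testis",
    "heart",
    "liver",
    "muscle",
    "skin",
)
DEFAULT_TIMEPOINTS = (0.5, 3.5, 6.5, 9.5, 12.5, 15.5, 18.5, 21.5)

HOMOLOGY_COLUMNS = (
    "ensembl_gene_id",
    "paralog_gene_id",
    "paralog_subtype",
    "paralog_orthology_type",
    "gar_ortholog_id",
    "gar_orthology_type",
    "chromosome_name",
    "start_position",
    "end_position",
    "external_gene_name",
)

DECOY_CLASSES = (
    "clupeocephala_ancestor",
    "multi_gar_ortholog",
    "repeated_gene",
    "unanchored_contig",
    "tandem_lt_5Mbp",
    "neopterygii_ancestor",
    "one_of_many_name",
    "non_one2one_ortholog",
)

# duplication-ancestor label carried by planted whole-genome-duplication pairs
TGD_ANCESTOR = "Osteoglossocephalai"
ANCIENT_ANCESTOR = "Vertebrata"

_GENE_SPACING = 250_000  # bp between gene starts on a simulated chromosome
_GENE_LENGTH = 10_000
_TANDEM_OFFSET = 12  # 12 * 250 kb = 3 Mbp, inside the 5 Mbp exclusion radius

__all__ = [
    "SimulationConfig",
    "HomologySimConfig",
    "simulate_counts",
    "simulate_homology",
    "simulate_probe_counts",
    "DEFAULT_ORGANS",
    "DEFAULT_TIMEPOINTS",
    "HOMOLOGY_COLUMNS",
    "DECOY_CLASSES",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the expression simulator.

    Defaults mirror the study layout: 9 organs, 8 timepoints 3 h apart
    starting at Zt 0.5, 2 biological replicates, roughly one gene in
    five cyclic per organ, relative amplitudes 0.3-1.0, log-uniform
    baseline means of 20-500 counts, a shared negative-binomial
    dispersion of 0.1 (variance = mu + 0.1 mu^2) and per-sample library
    sizes drawn uniformly from 150k-250k reads.
    """

    n_genes: int = 1000
    organs: Sequence[str] = DEFAULT_ORGANS
    timepoints_zt: Sequence[float] = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    cyclic_fraction: float = 0.2
    amplitude_range: tuple[float, float] = (0.3, 1.0)
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (150_000, 250_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if not self.organs:
            raise ConfigurationError("organ list must be non-empty")
        zts = list(self.timepoints_zt)
        if not zts:
            raise ConfigurationError("timepoint list must be non-empty")
        if any(not (0 <= t < 24) for t in zts):
            raise ConfigurationError("timepoints must lie in [0, 24)")
        if any(b <= a for a, b in zip(zts, zts[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not 0.0 <= self.cyclic_fraction <= 1.0:
            raise ConfigurationError("cyclic_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.amplitude_range[0] < 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise ConfigurationError("invalid amplitude_range")
        if self.baseline_mean_range[0] <= 0 or (
            self.baseline_mean_range[1] < self.baseline_mean_range[0]
        ):
            raise ConfigurationError("invalid baseline_mean_range")
        if self.library_size_range[0] <= 0 or (
            self.library_size_range[1] < self.library_size_range[0]
        ):
            raise ConfigurationError("invalid library_size_range")


def negative_binomial(rng, mean, dispersion):
    """Negative-binomial draws parameterized by mean and dispersion.

    Variance is mu + dispersion * mu^2 (the gamma-Poisson mixture used
    throughout RNA-seq modeling); dispersion is shared across genes.
    """
    inv = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = inv / (inv + mean)
    return rng.negative_binomial(inv, p, size=mean.shape)


def _draw_range(rng, lo, hi, size, log=False):
    if lo == hi:
        return np.full(size, float(lo))
    if log:
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size))
    return rng.uniform(lo, hi, size)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a count matrix plus a per-(gene, organ) truth table.

    Exactly round(cyclic_fraction * n_genes) genes are planted cyclic in
    each organ (planting, not sampling). Identical configs give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    zts = np.asarray(config.timepoints_zt, dtype=float)
    n_cyc = int(round(config.cyclic_fraction * config.n_genes))
    lib_lo, lib_hi = config.library_size_range

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    truth_rows = []
    for organ in config.organs:
        baseline = _draw_range(rng, *config.baseline_mean_range, config.n_genes, log=True)
        cyclic_idx = np.sort(rng.choice(config.n_genes, size=n_cyc, replace=False))
        amp = _draw_range(rng, *config.amplitude_range, n_cyc)
        phase = rng.choice(zts, size=n_cyc)
        mean = np.tile(baseline[:, None], (1, zts.size))
        if n_cyc:
            wave = 1.0 + amp[:, None] * np.cos(
                2.0 * np.pi * (zts[None, :] - phase[:, None]) / 24.0
            )
            mean[cyclic_idx] = baseline[cyclic_idx, None] * np.clip(wave, 0.0, None)

        is_cyc = np.zeros(config.n_genes, dtype=bool)
        is_cyc[cyclic_idx] = True
        true_peak = np.full(config.n_genes, np.nan)
        true_peak[cyclic_idx] = phase
        true_amp = np.zeros(config.n_genes)
        true_amp[cyclic_idx] = amp
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "organ": organ,
                    "is_cyclic": is_cyc,
                    "true_peak_zt": true_peak,
                    "true_amplitude": true_amp,
                }
            )
        )

        # oversample then thin: guarantees enough raw reads per column
        col_totals = mean.sum(axis=0)
        factor = max(2.0, 2.0 * lib_hi / float(col_totals.min()))
        for t, zt in enumerate(zts):
            for rep in range(1, config.n_replicates + 1):
                target = int(rng.integers(lib_lo, lib_hi + 1))
                raw = negative_binomial(rng, mean[:, t] * factor, config.dispersion)
                total = int(raw.sum())
                if total < target:  # pragma: no cover - oversampling guard
                    raise ConfigurationError(
                        "library_size_range exceeds simulated sequencing depth; "
                        "lower it or raise baseline_mean_range/n_genes"
                    )
                thinned = rng.multinomial(target, raw / total)
                sid = f"{organ}_zt{zt:g}_r{rep}"
                columns[sid] = thinned
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "organ": organ,
                        "zt": float(zt),
                        "replicate": rep,
                        "library_size": target,
                    }
                )

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(sample_rows)
    truth = pd.concat(truth_rows, ignore_index=True)
    return CountMatrix(counts, samples), truth


# ---------------------------------------------------------------------------
# homology simulation


@dataclass(frozen=True)
class HomologySimConfig:
    """Layout of the planted homology table.

    ``decoy_counts`` maps decoy class to the number of decoy units
    (a unit is a gene pair for the pair-level decoys, a gene triplet for
    ``repeated_gene`` and a single gene for the singleton-chain
    decoys). Every decoy violates exactly the filter it is named for.
    """

    n_ohnolog_pairs: int = 50
    n_singletons: int = 100
    decoy_counts: Mapping[str, int] = field(
        default_factory=lambda: {c: 2 for c in DECOY_CLASSES}
    )
    n_chromosomes: int = 24
    genes_per_chromosome: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ohnolog_pairs < 0 or self.n_singletons < 0:
            raise ConfigurationError("counts must be non-negative")
        for cls, n in self.decoy_counts.items():
            if cls not in DECOY_CLASSES:
                raise ConfigurationError(f"unknown decoy class {cls!r}")
            if n < 0:
                raise ConfigurationError("decoy counts must be non-negative")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigurationError("chromosome layout must be positive")


class _Genome:
    """Deterministic slot allocator over the simulated karyotype."""

    def __init__(self, cfg: HomologySimConfig, rng):
        self.cfg = cfg
        slots = [
            (f"chr{c + 1}", i)
            for c in range(cfg.n_chromosomes)
            for i in range(cfg.genes_per_chromosome)
        ]
        rng.shuffle(slots)
        self.free = slots
        self.rng = rng
        self.n_scaffold = 0

    def take(self):
        if not self.free:
            raise ConfigurationError(
                "karyotype too small for the requested gene count; "
                "increase n_chromosomes or genes_per_chromosome"
            )
        return self.free.pop()

    def take_far_pair(self):
        """Two slots on different chromosomes or >= 5 Mbp apart."""
        a = self.take()
        for i, b in enumerate(self.free):
            if b[0] != a[0] or abs(b[1] - a[1]) * _GENE_SPACING >= 5_000_000:
                return a, self.free.pop(i)
        raise ConfigurationError("no well-separated slot pair available")

    def take_tandem_pair(self):
        """Two slots on one chromosome exactly 3 Mbp apart."""
        by_chrom: dict[str, set[int]] = {}
        for c, i in self.free:
            by_chrom.setdefault(c, set()).add(i)
        for c in sorted(by_chrom):
            for i in sorted(by_chrom[c]):
                if i + _TANDEM_OFFSET in by_chrom[c]:
                    a, b = (c, i), (c, i + _TANDEM_OFFSET)
                    self.free.remove(a)
                    self.free.remove(b)
                    return a, b
        raise ConfigurationError("no tandem slot pair available")

    def take_scaffold(self):
        self.n_scaffold += 1
        return (f"Scaffold_{self.n_scaffold}", 0)

    @staticmethod
    def coords(slot):
        chrom, i = slot
        start = i * _GENE_SPACING + 1
        return chrom, start, start + _GENE_LENGTH - 1


def simulate_homology(config: HomologySimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a Biomart-style homology table plus per-gene truth labels.

    Returns ``(table, truth)`` where truth has columns gene_id, label
    (``ohnolog`` / ``singleton`` / decoy class) and unit_id (pair or
    decoy-unit identifier, empty for lone genes).
    """
    rng = np.random.default_rng(config.seed)
    genome = _Genome(config, rng)
    rows: list[dict] = []
    truth: list[dict] = []
    counter = {"gene": 0, "gar": 0, "unit": 0}

    def new_gene():
        counter["gene"] += 1
        return f"XMAG{counter['gene']:05d}"

    def new_gar():
        counter["gar"] += 1
        return f"GARG{counter['gar']:05d}"

    def new_unit(prefix):
        counter["unit"] += 1
        return f"{prefix}{counter['unit']:04d}"

    def add_row(gene, slot, name, paralog=None, subtype=None, gar=None, gar_type=None):
        chrom, start, end = _Genome.coords(slot)
        rows.append(
            {
                "ensembl_gene_id": gene,
                "paralog_gene_id": paralog,
                "paralog_subtype": subtype,
                "paralog_orthology_type": (
                    "within_species_paralog" if paralog else None
                ),
                "gar_ortholog_id": gar,
                "gar_orthology_type": gar_type,
                "chromosome_name": chrom,
                "start_position": start,
                "end_position": end,
                "external_gene_name": name,
            }
        )

    def add_pair(subtype, gar_ids_a, gar_ids_b, slots=None, unit=None, label="ohnolog"):
        a, b = new_gene(), new_gene()
        slot_a, slot_b = slots if slots is not None else genome.take_far_pair()
        unit = unit or new_unit("P")
        for gid in gar_ids_a:
            add_row(a, slot_a, f"gene-{a[-5:]}", paralog=b, subtype=subtype,
                    gar=gid, gar_type="ortholog_one2many" if gid else None)
        for gid in gar_ids_b:
            add_row(b, slot_b, f"gene-{b[-5:]}", paralog=a, subtype=subtype,
                    gar=gid, gar_type="ortholog_one2many" if gid else None)
        truth.append({"gene_id": a, "label": label, "unit_id": unit})
        truth.append({"gene_id": b, "label": label, "unit_id": unit})
        return a, b

    # planted ohnolog pairs: TGD-era ancestor, one shared gar ortholog,
    # well separated, each gene in exactly one pair
    for _ in range(config.n_ohnolog_pairs):
        gar = new_gar()
        add_pair(TGD_ANCESTOR, [gar], [gar])

    # planted singletons: 1:1 to gar; half carry an ancient (pre-TGD)
    # paralog row to exercise the no-TGD-era-rows inclusion path
    singleton_ids = [new_gene() for _ in range(config.n_singletons)]
    for i, gene in enumerate(singleton_ids):
        slot = genome.take()
        gar = new_gar()
        partner = None
        if i % 4 == 0 and i + 1 < config.n_singletons:
            partner = singleton_ids[i + 1]
        elif i % 4 == 1:
            partner = singleton_ids[i - 1]
        if partner is not None:
            add_row(gene, slot, f"gene-{gene[-5:]}", paralog=partner,
                    subtype=ANCIENT_ANCESTOR, gar=gar, gar_type="ortholog_one2one")
        else:
            add_row(gene, slot, f"gene-{gene[-5:]}", gar=gar,
                    gar_type="ortholog_one2one")
        truth.append({"gene_id": gene, "label": "singleton", "unit_id": ""})

    decoys = dict(config.decoy_counts)
    for _ in range(decoys.get("clupeocephala_ancestor", 0)):
        gar = new_gar()
        add_pair("Clupeocephala", [gar], [gar],
                 unit=new_unit("D"), label="clupeocephala_ancestor")
    for _ in range(decoys.get("multi_gar_ortholog", 0)):
        g1, g2 = new_gar(), new_gar()
        add_pair(TGD_ANCESTOR, [g1, g2], [g1],
                 unit=new_unit("D"), label="multi_gar_ortholog")
    for _ in range(decoys.get("repeated_gene", 0)):
        gar = new_gar()
        unit = new_unit("D")
        x, y, z = new_gene(), new_gene(), new_gene()
        slot_x = genome.take()

        # place y and z far from x so only the repetition rule fires
        def far_from(ref):
            for i, s in enumerate(genome.free):
                if s[0] != ref[0] or abs(s[1] - ref[1]) * _GENE_SPACING >= 5_000_000:
                    return genome.free.pop(i)
            raise ConfigurationError("no well-separated slot available")

        slot_y = far_from(slot_x)
        slot_z = far_from(slot_x)
        if slot_y[0] == slot_z[0] and abs(slot_y[1] - slot_z[1]) * _GENE_SPACING < 5_000_000:
            genome.free.append(slot_z)
            slot_z = far_from(slot_y)
        add_row(x, slot_x, f"gene-{x[-5:]}", paralog=y, subtype=TGD_ANCESTOR,
                gar=gar, gar_type="ortholog_one2many")
        add_row(x, slot_x, f"gene-{x[-5:]}", paralog=z, subtype=TGD_ANCESTOR,
                gar=gar, gar_type="ortholog_one2many")
        add_row(y, slot_y, f"gene-{y[-5:]}", paralog=x, subtype=TGD_ANCESTOR,
                gar=gar, gar_type="ortholog_one2many")
        add_row(z, slot_z, f"gene-{z[-5:]}", paralog=x, subtype=TGD_ANCESTOR,
                gar=gar, gar_type="ortholog_one2many")
        for gene in (x, y, z):
            truth.append({"gene_id": gene, "label": "repeated_gene", "unit_id": unit})
    for _ in range(decoys.get("unanchored_contig", 0)):
        gar = new_gar()
        slots = (genome.take(), genome.take_scaffold())
        add_pair(TGD_ANCESTOR, [gar], [gar], slots=slots,
                 unit=new_unit("D"), label="unanchored_contig")
    for _ in range(decoys.get("tandem_lt_5Mbp", 0)):
        gar = new_gar()
        add_pair(TGD_ANCESTOR, [gar], [gar], slots=genome.take_tandem_pair(),
                 unit=new_unit("D"), label="tandem_lt_5Mbp")
    for _ in range(decoys.get("neopterygii_ancestor", 0)):
        # a pair of genes whose duplication node is the tree-artifact
        # label; each keeps its own 1:1 gar ortholog
        unit = new_unit("D")
        a, b = new_gene(), new_gene()
        slot_a, slot_b = genome.take_far_pair()
        add_row(a, slot_a, f"gene-{a[-5:]}", paralog=b, subtype="Neopterygii",
                gar=new_gar(), gar_type="ortholog_one2one")
        add_row(b, slot_b, f"gene-{b[-5:]}", paralog=a, subtype="Neopterygii",
                gar=new_gar(), gar_type="ortholog_one2one")
        truth.append({"gene_id": a, "label": "neopterygii_ancestor", "unit_id": unit})
        truth.append({"gene_id": b, "label": "neopterygii_ancestor", "unit_id": unit})
    for _ in range(decoys.get("one_of_many_name", 0)):
        gene = new_gene()
        add_row(gene, genome.take(), f"sox{counter['gene']} (1 of many)",
                gar=new_gar(), gar_type="ortholog_one2one")
        truth.append({"gene_id": gene, "label": "one_of_many_name", "unit_id": ""})
    for _ in range(decoys.get("non_one2one_ortholog", 0)):
        gene = new_gene()
        add_row(gene, genome.take(), f"gene-{gene[-5:]}",
                gar=new_gar(), gar_type="ortholog_one2many")
        truth.append({"gene_id": gene, "label": "non_one2one_ortholog", "unit_id": ""})

    table = pd.DataFrame(rows, columns=list(HOMOLOGY_COLUMNS))
    truth_df = pd.DataFrame(truth, columns=["gene_id", "label", "unit_id"])
    table = table.sort_values(
        ["ensembl_gene_id", "paralog_gene_id", "gar_ortholog_id"],
        ignore_index=True,
        na_position="last",
    )
    truth_df = truth_df.sort_values("gene_id", ignore_index=True)
    return table, truth_df


# ---------------------------------------------------------------------------
# NanoString-style probe counts


def simulate_probe_counts(
    truth: pd.DataFrame,
    organ: str,
    gene_ids: Sequence[str],
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    baseline: float = 2000.0,
    n_housekeeping: int = 3,
    n_positive: int = 6,
    n_negative: int = 8,
    background: float = 15.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Probe counts for selected genes driven by their planted rhythms.

    Endogenous probe means follow the planted cosine relative-expression
    curves scaled by ``baseline``; every sample has a random hybridization
    efficiency and RNA-input factor so the normalization chain has work
    to do. Returns (counts probes x samples, probe class Series).
    """
    rng = np.random.default_rng(seed)
    zts = np.asarray(timepoints, dtype=float)
    sub = truth[(truth["organ"] == organ) & (truth["gene_id"].isin(gene_ids))]
    sub = sub.set_index("gene_id").loc[list(gene_ids)]
    probes = (
        [f"endo_{g}" for g in gene_ids]
        + [f"hk_{i}" for i in range(n_housekeeping)]
        + [f"pos_{i}" for i in range(n_positive)]
        + [f"neg_{i}" for i in range(n_negative)]
    )
    classes = pd.Series(
        ["endogenous"] * len(gene_ids)
        + ["housekeeping"] * n_housekeeping
        + ["positive"] * n_positive
        + ["negative"] * n_negative,
        index=pd.Index(probes, name="probe"),
        name="probe_class",
    )
    pos_levels = np.geomspace(128, 4096, n_positive)
    hk_levels = rng.uniform(500, 5000, n_housekeeping)
    cols = {}
    for zt in zts:
        efficiency = rng.uniform(0.6, 1.6)
        rna_input = rng.uniform(0.6, 1.6)
        mean = []
        for g in gene_ids:
            row = sub.loc[g]
            if bool(row["is_cyclic"]):
                rel = 1.0 + row["true_amplitude"] * np.cos(
                    2 * np.pi * (zt - row["true_peak_zt"]) / 24.0
                )
            else:
                rel = 1.0
            mean.append(baseline * max(rel, 0.0) * rna_input)
        mean.extend(hk_levels * rna_input)
        mean.extend(pos_levels)  # positives are RNA-independent
        mean.extend([background] * n_negative)
        mu = np.asarray(mean) * efficiency
        cols[f"{organ}_zt{zt:g}"] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=classes.index)
    return counts, classes
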