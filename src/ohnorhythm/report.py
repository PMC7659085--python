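"""Pipeline orchestration, per-gene queries and summary tables.

``run_pipeline`` chains normalization -> rhythm detection -> (optional)
ohnolog/singleton identification -> divergence classification, writing
one TSV per stage plus a JSON summary. ``query_gene`` reproduces the
expression-browser view for one gene: a per-organ summary table (daily
mean cpm, expressed and cyclic flags, p-value, peak Zt, peak shape,
amplitude) and the 24 h relative-expression series, with optional plot
panels (mean cpm per organ bar chart; relative expression over the day).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence as dv
from . import homology as hm
from .errors import GeneLookupError, InputError
from .expression import CountMatrix, organ_profiles
from .rhythm import detect_rhythms

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "query_gene",
    "search_gene_names",
    "summarize_counts",
    "cyclic_percentage",
    "tracked_gene_percentage",
    "plot_gene",
]


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run."""

    counts_path: str | Path
    samples_path: str | Path
    out_dir: str | Path
    homology_path: str | Path | None = None
    alpha: float = 0.01
    n_perm: int = 10_000
    seed: int = 0
    min_cpm: float = 1.0
    min_timepoints: int = 2
    peak_tolerance: float = 0.0
    window_n: int = 10
    chromosomes: list[str] | None = None
    method: str = "auto"


@dataclass
class PipelineResult:
    profiles: dict
    rhythm: pd.DataFrame
    pairs: list = field(default_factory=list)
    singletons: list = field(default_factory=list)
    calls: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _timed(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; deterministic for a given seed."""
    from .io import read_count_matrix, read_homology, write_table

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm = read_count_matrix(config.counts_path, config.samples_path)
    profiles = _timed(
        "expression", organ_profiles, cm, config.min_cpm, config.min_timepoints
    )
    rhythm = _timed(
        "rhythm",
        detect_rhythms,
        cm,
        alpha=config.alpha,
        method=config.method,
        n_perm=config.n_perm,
        seed=config.seed,
        min_cpm=config.min_cpm,
        min_timepoints=config.min_timepoints,
    )
    result = PipelineResult(profiles=profiles, rhythm=rhythm)
    result.outputs["rhythm"] = write_table(rhythm, out_dir / "rhythm_results.tsv")

    if config.homology_path is not None:
        table = read_homology(config.homology_path)
        pairs = _timed(
            "ohnologs", hm.identify_ohnolog_pairs, table, config.chromosomes
        )
        singletons = _timed(
            "singletons", hm.identify_singletons, table, config.chromosomes
        )
        peaks = dv.peaks_from_rhythm(rhythm)
        calls = _timed(
            "divergence",
            dv.classify_all,
            [(f"P{i:04d}", p.gene_a, p.gene_b) for i, p in enumerate(pairs)],
            peaks,
            singletons,
            config.peak_tolerance,
        )
        result.pairs = pairs
        result.singletons = singletons
        result.calls = calls
        result.outputs["ohnolog_pairs"] = write_table(
            pd.DataFrame(
                [
                    {
                        "gene_a": p.gene_a,
                        "gene_b": p.gene_b,
                        "gar_id": p.gar_id,
                        "chrom_a": p.chrom_a,
                        "start_a": p.start_a,
                        "chrom_b": p.chrom_b,
                        "start_b": p.start_b,
                    }
                    for p in pairs
                ]
            ),
            out_dir / "ohnolog_pairs.tsv",
        )
        result.outputs["singletons"] = write_table(
            pd.DataFrame({"gene_id": singletons}), out_dir / "singletons.tsv"
        )
        result.outputs["divergence"] = write_table(
            calls, out_dir / "divergence_calls.tsv"
        )
    else:
        logger.info("no homology table supplied; divergence stage skipped")

    n_pairs = len(result.pairs)
    n_singletons = len(result.singletons)
    total_genes = cm.counts.shape[0]
    result.summary = summarize_counts(
        rhythm,
        result.calls,
        n_pairs=n_pairs,
        n_singletons=n_singletons,
        total_genes=total_genes,
    )
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(result.summary, indent=2, sort_keys=True))
    result.outputs["summary"] = summary_path
    return result


# ---------------------------------------------------------------------------
# summaries


def cyclic_percentage(n_expressed: int, n_cyclic: int) -> float:
    """Share of expressed genes called cyclic, one decimal place."""
    if n_expressed <= 0:
        return 0.0
    return round(100.0 * n_cyclic / n_expressed, 1)


def tracked_gene_percentage(n_pairs: int, n_singletons: int, total_genes: int) -> float:
    """Share of the genome traceable through the duplication via gar:
    (2 * pairs + singletons) / total, to the nearest percent."""
    if total_genes <= 0:
        return 0.0
    return round(100.0 * (2 * n_pairs + n_singletons) / total_genes)


def summarize_counts(
    rhythm: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    n_pairs: int = 0,
    n_singletons: int = 0,
    total_genes: int = 0,
) -> dict:
    """Machine-readable run summary: per-organ expressed/cyclic counts
    with percentages, homology tallies and divergence tables."""
    per_organ = {}
    for organ, grp in rhythm.groupby("organ"):
        n_exp = int(grp["expressed"].sum())
        n_cyc = int(grp["is_cyclic"].sum())
        per_organ[organ] = {
            "expressed": n_exp,
            "cyclic": n_cyc,
            "cyclic_percent": cyclic_percentage(n_exp, n_cyc),
        }
    summary = {
        "per_organ": per_organ,
        "ohnolog_pairs": int(n_pairs),
        "singletons": int(n_singletons),
        "total_genes": int(total_genes),
        "tracked_gene_percent": tracked_gene_percentage(
            n_pairs, n_singletons, total_genes
        ),
    }
    if calls is not None and len(calls):
        summary["divergence"] = dv.summarize_divergence(calls)
    return summary


# ---------------------------------------------------------------------------
# per-gene query (the browser view)


def search_gene_names(keyword: str, names: pd.DataFrame) -> list[str]:
    """Case-insensitive substring search over external gene names;
    mirrors the browser's common-name -> gene-id converter."""
    if "external_gene_name" not in names.columns:
        raise InputError("name table needs an external_gene_name column")
    gene_col = "ensembl_gene_id" if "ensembl_gene_id" in names.columns else "gene_id"
    mask = (
        names["external_gene_name"]
        .fillna("")
        .str.lower()
        .str.contains(keyword.lower(), regex=False)
    )
    return sorted(names.loc[mask, gene_col].unique())


def query_gene(gene_id: str, result: PipelineResult):
    """Per-organ summary row plus the relative-expression series for one
    gene, as the expression browser would display them."""
    rhythm = result.rhythm
    if gene_id not in set(rhythm["gene_id"]):
        raise GeneLookupError(
            f"{gene_id} not found; use search_gene_names() to resolve a common name"
        )
    rows = []
    series = {}
    for organ, prof in result.profiles.items():
        sub = rhythm[(rhythm["gene_id"] == gene_id) & (rhythm["organ"] == organ)]
        rec = sub.iloc[0]
        rows.append(
            {
                "organ": organ,
                "mean_cpm": float(prof.mean_cpm.loc[gene_id].mean()),
                "expressed": bool(rec["expressed"]),
                "is_cyclic": bool(rec["is_cyclic"]),
                "p_value": rec["p_value"],
                "peak_zt": rec["peak_zt"],
                "peak_shape": rec["peak_shape"],
                "amplitude": rec["amplitude"],
            }
        )
        series[organ] = prof.relative.loc[gene_id]
    summary = pd.DataFrame(rows).set_index("organ")
    return summary, series


def plot_gene(gene_id: str, result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write the two browser panels as SVG: (a) daily mean cpm per organ;
    (b) relative expression across the day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary, series = query_gene(gene_id, result)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(summary.index, summary["mean_cpm"], color="#4878d0")
    ax.set_ylabel("mean cpm over the day")
    ax.set_title(gene_id)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    paths["mean_cpm"] = out_dir / f"{gene_id}_mean_cpm.svg"
    fig.savefig(paths["mean_cpm"])
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for organ, rel in series.items():
        ax.plot(rel.index.to_numpy(dtype=float), rel.to_numpy(), label=organ)
    ax.set_xlabel("zeitgeber time (h)")
    ax.set_ylabel("relative expression")
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    paths["relative"] = out_dir / f"{gene_id}_relative_expression.svg"
    fig.savefig(paths["relative"])
    plt.close(fig)
    return paths
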