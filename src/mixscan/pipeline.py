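"""End-to-end orchestration: mask -> coverage -> intervals -> intermixing ->
assignment -> fractionation (-> gene steps when inputs are given), with
tabular outputs, a machine-readable run summary and optional plots.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import assign as assign_mod
from . import homology as homology_mod
from .coverage import (
    CoverageTrack,
    Thresholds,
    load_alignments_coverage,
    load_bedgraph_coverage,
    normalization_factor,
)
from .fractionation import ContingencyResult, fractionation_test
from .intermix import add_intermixing, genome_intermixing_summary
from .intervals import featured_fraction, interval_table
from .regions import RegionSet, assembly_gaps_from_fasta, build_informative_mask

log = logging.getLogger("mixscan")


def setup_logging(verbosity: int = 1) -> None:
    level = logging.WARNING if verbosity == 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Exactly two parental inputs (SAM/BAM alignments or bedGraph tracks)
    against the hybrid assembly. The include BED lists regions to analyse
    (typically non-repetitive coordinates); assembly N-gaps are removed from
    it when the assembly FASTA is given.
    """

    assembly_fasta: str | None = None
    parent1_input: str | None = None
    parent2_input: str | None = None
    input_format: str = "bam"           # "bam" (SAM/BAM) or "bedgraph"
    include_bed: str | None = None
    genes_path: str | None = None       # BED or GFF3 gene models
    genes_format: str = "bed"
    hits_path: str | None = None        # 12-column tabular hits
    parent_map_path: str | None = None  # subject id -> parent label
    parent_labels: tuple[str, str] = ("parent1", "parent2")
    parental_sizes: tuple[float, float] | None = None  # bp
    fractionation_unit_bp: float = 1e6  # counting unit of the retention table
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: str = "mixscan_out"
    seed: int = 0
    verbosity: int = 1
    plots: bool = False


@dataclass
class RunResult:
    """Bundle of everything a run computed."""

    intervals: pd.DataFrame
    summary: dict
    sizes: assign_mod.SubgenomeSizeEstimate
    contingency: ContingencyResult | None = None
    genes: pd.DataFrame | None = None
    homology_genes: pd.DataFrame | None = None
    reconciliation: homology_mod.ReconciliationReport | None = None


def _load_mask(config: RunConfig, lengths: dict[str, int]) -> RegionSet:
    if config.include_bed is None:
        raise ValueError("an include BED (informative positions) is required")
    include = RegionSet.from_bed(config.include_bed, lengths)
    if config.assembly_fasta is not None:
        gaps = assembly_gaps_from_fasta(config.assembly_fasta)
        # informative = include minus gaps
        include = build_informative_mask(
            include.complement(lengths), gaps, lengths
        )
    return include


def run_pipeline(
    config: RunConfig,
    mask: RegionSet | None = None,
    track1: CoverageTrack | None = None,
    track2: CoverageTrack | None = None,
) -> RunResult:
    """Execute the full analysis.

    File inputs are taken from ``config``; alternatively pre-built in-memory
    mask/tracks (e.g. from the simulator) can be passed directly. Any stage
    failure aborts with a stage-labelled error.
    """
    t0 = time.time()
    th = config.thresholds
    stage = "inputs"
    try:
        if track1 is None or track2 is None or mask is None:
            if config.assembly_fasta is not None:
                from .regions import read_fasta

                lengths = {c: len(s) for c, s in read_fasta(config.assembly_fasta).items()}
            else:
                raise ValueError("assembly FASTA required when tracks not supplied")
            stage = "mask"
            mask = _load_mask(config, lengths)
            stage = "coverage"
            loader = (
                load_bedgraph_coverage
                if config.input_format == "bedgraph"
                else load_alignments_coverage
            )
            track1 = loader(config.parent1_input, mask, th, config.parent_labels[0])
            track2 = loader(config.parent2_input, mask, th, config.parent_labels[1])
        assembly_size = sum(mask.lengths.values())
        log.info("mask: %d informative of %d bp", mask.total_length(), assembly_size)

        stage = "intervals"
        table = interval_table(mask, track1, track2, th)
        fractions = featured_fraction(table, assembly_size)

        stage = "intermixing"
        summary: dict = {
            "assembly_bp": assembly_size,
            "informative_positions": mask.total_length(),
            **fractions,
            "parent_labels": list(config.parent_labels),
            "thresholds": asdict(th),
            "seed": config.seed,
        }
        if table["sufficient"].any() and track1.n_covered and track2.n_covered:
            norm = normalization_factor(track1, track2)
            table = add_intermixing(table, mask, track1, track2, norm, th)
            summary["mean_depth"] = {
                config.parent_labels[0]: norm.mean1,
                config.parent_labels[1]: norm.mean2,
            }
            summary["normalization_ratio"] = norm.ratio
        else:
            log.warning("no sufficient interval or empty track; Jaccard all NA")
            table = table.copy()
            table["jaccard"] = float("nan")
            table["n_intersection"] = 0
            table["n_union_bins"] = 0
        summary.update(genome_intermixing_summary(table))

        stage = "assignment"
        table["assignment"] = assign_mod.assign_intervals(
            table, th, rule="fractionation", labels=config.parent_labels
        )
        table["assignment_gene_rule"] = assign_mod.assign_intervals(
            table, th, rule="gene", labels=config.parent_labels
        )
        sizes = assign_mod.estimate_subgenome_sizes(table, config.parent_labels)
        summary["subgenome_bp"] = {
            config.parent_labels[0]: sizes.s1,
            config.parent_labels[1]: sizes.s2,
        }

        stage = "fractionation"
        contingency = None
        if config.parental_sizes is not None:
            contingency = fractionation_test(
                sizes, config.parental_sizes,
                unit_bp=config.fractionation_unit_bp,
            )
            if contingency is not None:
                summary["fractionation"] = {
                    "table": contingency.table,
                    "p_value": contingency.p_value,
                    "biased": contingency.biased,
                }

        stage = "genes"
        genes = homology_genes = reconciliation = None
        if config.genes_path is not None:
            reader = (
                assign_mod.read_genes_gff
                if config.genes_format == "gff"
                else assign_mod.read_genes_bed
            )
            genes = assign_mod.assign_genes_by_interval(
                reader(config.genes_path), table, th,
                column="assignment_gene_rule",
            )
            summary["genes_assigned"] = int(
                (genes["label"] != assign_mod.UNASSIGNED).sum()
            )
            summary["genes_total"] = int(len(genes))
        if config.hits_path is not None and config.parent_map_path is not None:
            hits = homology_mod.read_blast_tab(config.hits_path)
            pmap = homology_mod.read_parent_map(config.parent_map_path)
            homology_genes = homology_mod.assign_genes_by_homology(hits, pmap)
            if genes is not None:
                reconciliation = homology_mod.reconcile_assignments(
                    homology_genes, genes
                )
                summary["gene_agreement"] = reconciliation.agreement
        summary["runtime_s"] = round(time.time() - t0, 2)
        return RunResult(
            table, summary, sizes, contingency, genes, homology_genes, reconciliation
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def write_reports(result: RunResult, outdir, plots: bool = False) -> list[Path]:
    """Write the deterministic TSV/JSON file set (and optional plots)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "intervals.tsv"
    result.intervals.to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    if result.contingency is not None:
        c = result.contingency
        p = out / "fractionation.tsv"
        pd.DataFrame(
            [{
                "S1": c.s1, "S2": c.s2, "G1": c.g1, "G2": c.g2,
                "S1/G1(%)": round(c.retention1, 2),
                "S2/G2(%)": round(c.retention2, 2),
                "p": c.p_value,
                "verdict": "biased" if c.biased else "not_biased",
            }]
        ).to_csv(p, sep="\t", index=False)
        written.append(p)

    if result.genes is not None:
        p = out / "genes_by_interval.tsv"
        result.genes.to_csv(p, sep="\t", index=False)
        written.append(p)
    if result.homology_genes is not None:
        p = out / "genes_by_homology.tsv"
        result.homology_genes.to_csv(p, sep="\t", index=False)
        written.append(p)

    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    written.append(p)

    if plots:
        written.extend(_write_plots(result, out))
    return written


def _write_plots(result: RunResult, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    table = result.intervals
    fig, ax = plt.subplots(figsize=(5, 3.5))
    j = table["jaccard"].dropna()
    ax.hist(j, bins=20, range=(0, 1), color="firebrick")
    if len(j):
        ax.axvline(j.mean(), color="purple", lw=2, label=f"mean J = {j.mean():.3f}")
        ax.legend()
    ax.set_xlabel("Jaccard intermixing index")
    ax.set_ylabel("intervals")
    fig.tight_layout()
    p = out / "jaccard_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=False)
    for ax, (mean_col, frac_col, lab) in zip(
        axes,
        [("mean_cov1", "frac_cov1", "parent 1"), ("mean_cov2", "frac_cov2", "parent 2")],
    ):
        sub = table[table["sufficient"]]
        ax.scatter(sub[mean_col], sub[frac_col], s=4, alpha=0.5)
        ax.set_xlabel(f"{lab} mean coverage (x)")
        ax.set_ylabel("covered fraction")
        ax.set_ylim(0, 1)
    fig.tight_layout()
    p = out / "coverage_profiles.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
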