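"""Assignment of windows and genes to parental subgenomes; subgenome sizes.

Two selectable rules:

fractionation rule
    A window belongs to parent *i* when its Jaccard index is defined and
    <= 0.2 and parent *i* exclusively covers more than 50% of the window's
    mask positions (covered by *i* at >= min_coverage and not by the other).
    Used for subgenome-size estimation; the entire window width is credited.

gene rule
    A window belongs to parent *i* when J <= 0.5 and parent *i*'s plain
    covered fraction exceeds 50% while the other parent's does not. Used to
    hand gene models the label of their containing window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import Thresholds

UNASSIGNED = "unassigned"


@dataclass
class SubgenomeSizeEstimate:
    """Summed widths (bp) of the windows assigned to each parent."""

    s1: int
    s2: int


def assign_intervals(
    table: pd.DataFrame,
    thresholds: Thresholds,
    rule: str = "fractionation",
    labels: tuple[str, str] = ("parent1", "parent2"),
) -> pd.Series:
    """Per-window assignment labels under the chosen rule."""
    if rule not in ("fractionation", "gene"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    j = table["jaccard"].to_numpy(dtype=float)
    n_mask = table["n_mask"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if rule == "fractionation":
            max_j = thresholds.assign_max_jaccard
            f1 = np.where(n_mask > 0, table["n_excl1"] / np.maximum(n_mask, 1), 0.0)
            f2 = np.where(n_mask > 0, table["n_excl2"] / np.maximum(n_mask, 1), 0.0)
        else:
            max_j = thresholds.gene_assign_max_jaccard
            f1 = table["frac_cov1"].to_numpy(dtype=float)
            f2 = table["frac_cov2"].to_numpy(dtype=float)
        ok = ~np.isnan(j) & (j <= max_j)
        hit1 = ok & (f1 > thresholds.assign_min_frac)
        hit2 = ok & (f2 > thresholds.assign_min_frac)
    out = np.full(len(table), UNASSIGNED, dtype=object)
    out[hit1 & ~hit2] = labels[0]
    out[hit2 & ~hit1] = labels[1]  # both-hit ties stay unassigned
    return pd.Series(out, index=table.index, name="assignment")


def estimate_subgenome_sizes(
    table: pd.DataFrame,
    labels: tuple[str, str] = ("parent1", "parent2"),
    column: str = "assignment",
) -> SubgenomeSizeEstimate:
    """Sum full window widths (end - start) per assigned parent."""
    widths = (table["end"] - table["start"]).to_numpy(dtype=np.int64)
    lab = table[column].to_numpy()
    return SubgenomeSizeEstimate(
        s1=int(widths[lab == labels[0]].sum()),
        s2=int(widths[lab == labels[1]].sum()),
    )


def read_genes_bed(path) -> pd.DataFrame:
    """Gene models from BED (>=3 columns; column 4, if present, is the id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    genes = df.iloc[:, :3].copy()
    genes.columns = ["chrom", "start", "end"]
    genes["gene_id"] = (
        df.iloc[:, 3].astype(str)
        if df.shape[1] > 3
        else [f"gene{i}" for i in range(len(df))]
    )
    return genes[["gene_id", "chrom", "start", "end"]]


def read_genes_gff(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene models from GFF3 (1-based closed converted to half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end",
               "score", "strand", "frame", "attr"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == feature_type].reset_index(drop=True)
    ids = df["attr"].str.extract(r"ID=([^;]+)", expand=False)
    ids = ids.fillna(pd.Series([f"gene{i}" for i in range(len(df))]))
    return pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) - 1,
            "end": df["end"].astype(np.int64),
        }
    )


def assign_genes_by_interval(
    genes: pd.DataFrame,
    table: pd.DataFrame,
    thresholds: Thresholds,
    column: str = "assignment",
) -> pd.DataFrame:
    """Genes inherit the label of their containing window.

    A gene spanning windows with differing labels (including an unassigned
    window next to an assigned one) stays unassigned. Genes outside assembly
    bounds raise.
    """
    w = thresholds.interval_size
    # window index per (chrom, k) for bounds checks and label lookup
    lab_map: dict[tuple[str, int], str] = {}
    interval_id: dict[tuple[str, int], int] = {}
    for idx, row in enumerate(table.itertuples(index=False)):
        k = row.start // w
        lab_map[(row.chrom, k)] = getattr(row, column)
        interval_id[(row.chrom, k)] = idx
    chrom_len = {
        c: int(sub["end"].max()) for c, sub in table.groupby("chrom", sort=False)
    }
    labels, ivals = [], []
    for g in genes.itertuples(index=False):
        if g.chrom not in chrom_len or g.start < 0 or g.end > chrom_len[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id} at {g.chrom}:{g.start}-{g.end} outside assembly"
            )
        ks = range(g.start // w, (g.end - 1) // w + 1)
        labs = {lab_map[(g.chrom, k)] for k in ks}
        ivals.append(",".join(str(interval_id[(g.chrom, k)]) for k in ks))
        labels.append(labs.pop() if len(labs) == 1 else UNASSIGNED)
    out = genes.copy()
    out["label"] = labels
    out["intervals"] = ivals
    return out
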