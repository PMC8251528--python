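"""Gene-to-parent assignment from tabular pairwise-alignment hits.

Consumes precomputed 12-column tabular hits (blastn outfmt-6 dialect:
qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend, sstart,
send, evalue, bitscore) of hybrid transcripts against the two parental
transcript sets, plus a subject-to-parent map. Hits below 70% identity or
above e-value 0.01 are discarded; the best surviving hit is selected by
priority lowest e-value, then highest identity, then highest bit score.
Queries whose best hits to the two parents tie exactly on all three keys
stay unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .assign import UNASSIGNED

log = logging.getLogger("mixscan")

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

MIN_IDENTITY = 70.0
MAX_EVALUE = 0.01


def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column tabular hit file; malformed rows are dropped with a warning."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#",
        dtype={"qseqid": str, "sseqid": str},
    )
    for col in ("pident", "evalue", "bitscore"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["pident", "evalue", "bitscore"]].isna().any(axis=1)
    bad |= (df["pident"] < 0) | (df["pident"] > 100) | (df["evalue"] < 0)
    if bad.any():
        log.warning("rejecting %d malformed hit rows", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def read_parent_map(path) -> dict[str, str]:
    """Two-column TSV mapping subject id -> parent label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sseqid", "parent"],
                     dtype=str)
    return dict(zip(df["sseqid"], df["parent"]))


def select_best_hit(hits: pd.DataFrame) -> str:
    """Parent label for one query's hits (rows must carry a 'parent' column).

    Returns UNASSIGNED when no hit survives the identity/e-value filters or
    when the best hits to both parents are of identical quality.
    """
    ok = hits[(hits["pident"] >= MIN_IDENTITY) & (hits["evalue"] <= MAX_EVALUE)]
    if ok.empty:
        return UNASSIGNED
    # total order: e-value ascending, identity descending, score descending
    ranked = ok.sort_values(
        ["evalue", "pident", "bitscore"], ascending=[True, False, False],
        kind="mergesort",
    )
    best = ranked.iloc[0]
    rival = ranked[ranked["parent"] != best["parent"]]
    if not rival.empty:
        other = rival.iloc[0]
        if (
            other["evalue"] == best["evalue"]
            and other["pident"] == best["pident"]
            and other["bitscore"] == best["bitscore"]
        ):
            return UNASSIGNED
    return str(best["parent"])


def assign_genes_by_homology(
    hits: pd.DataFrame, parent_map: dict[str, str]
) -> pd.DataFrame:
    """Best-hit parent label per query (gene_id, label)."""
    hits = hits.copy()
    hits["parent"] = hits["sseqid"].map(parent_map)
    missing = hits["parent"].isna()
    if missing.any():
        log.warning("%d hits to subjects absent from the parent map dropped",
                    int(missing.sum()))
        hits = hits[~missing]
    rows = [
        {"gene_id": q, "label": select_best_hit(sub)}
        for q, sub in hits.groupby("qseqid", sort=True)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "label"])


@dataclass
class ReconciliationReport:
    """Agreement between homology-based and interval-based gene labels."""

    n_compared: int
    n_agreeing: int
    discordant: pd.DataFrame  # gene_id, interval_label, homology_label[, chrom_match]

    @property
    def agreement(self) -> float:
        return self.n_agreeing / self.n_compared if self.n_compared else float("nan")


def reconcile_assignments(
    homology_labels: pd.DataFrame,
    interval_labels: pd.DataFrame,
    chrom_subgenome_map: dict[str, str] | None = None,
) -> ReconciliationReport:
    """Compare the two gene-assignment routes over their shared labelled genes.

    Agreement is computed over genes assigned (not UNASSIGNED) by both
    methods. For discordant genes, when a chromosome-to-subgenome map is
    supplied, reports whether the interval-based label matches the label of
    the whole chromosome.
    """
    merged = interval_labels.merge(
        homology_labels, on="gene_id", suffixes=("_interval", "_homology")
    )
    both = merged[
        (merged["label_interval"] != UNASSIGNED)
        & (merged["label_homology"] != UNASSIGNED)
    ]
    agree = both["label_interval"] == both["label_homology"]
    discordant = both[~agree].copy()
    if chrom_subgenome_map is not None and "chrom" in discordant.columns:
        discordant["chrom_label"] = discordant["chrom"].map(chrom_subgenome_map)
        discordant["chrom_match"] = (
            discordant["label_interval"] == discordant["chrom_label"]
        )
    return ReconciliationReport(
        n_compared=int(len(both)),
        n_agreeing=int(agree.sum()),
        discordant=discordant.reset_index(drop=True),
    )
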