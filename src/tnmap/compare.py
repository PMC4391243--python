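"""Two-pool comparison: shared-site proportion ratios, Z-scores and flags.

A selection experiment sequences a mutant pool before ("input") and after
("output") a condition.  Insertion positions are partitioned into
input-only, output-only and shared.  For each shared position the share of
reads it receives in each pool is compared as

    proportion ratio = (input depth / input total) / (output depth / output total)

The natural log of this ratio is approximately normally distributed across
shared positions within an experiment, so each position is scored against
the population itself:

    Zscore = (ln(proportion ratio) - shared mean) / (shared sd)

with shared mean/sd taken over all shared positions (sample sd, n-1).  By
construction the Z-score population has mean 0 and sd 1.  Positions are
flagged by fixed two-sided normal bands: |Z| >= 3.291 "***" (~p 0.001),
3.291 > |Z| >= 2.579 "**" (~p 0.01), 2.579 > |Z| >= 1.960 "*" (~p 0.05).
The middle band edge is 2.579 by convention of this flagging scheme (the
textbook 0.995 normal quantile is 2.576); the band between the two values
is vanishingly thin and flags essentially no additional sites.  These
flags approximate statistical importance — they are not
multiplicity-corrected p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneAnnotation, assign_sites
from .samfilter import InsertionTable

logger = logging.getLogger(__name__)

#: (|Z| lower bound, flag) in decreasing order of stringency
FLAG_BANDS = ((3.291, "***"), (2.579, "**"), (1.960, "*"))


def flag(zscore: float) -> str:
    """Significance flag for one Z-score (inclusive lower band edges)."""
    a = abs(zscore)
    for bound, stars in FLAG_BANDS:
        if a >= bound:
            return stars
    return ""


@dataclass
class SharedStats:
    """Mean and sample sd of ln(proportion ratio) over shared positions."""

    shared_mean: float
    shared_sd: float
    n_shared: int


def partition(
    input_table: InsertionTable, output_table: InsertionTable
) -> tuple[list[tuple[str, int]], list[tuple[str, int]], list[tuple[str, int]]]:
    """Split site keys into (input_only, output_only, shared), each sorted."""
    if not input_table.sites or not output_table.sites:
        raise ValueError("both pools must contain at least one insertion site")
    in_keys = set(input_table.sites)
    out_keys = set(output_table.sites)
    return (
        sorted(in_keys - out_keys),
        sorted(out_keys - in_keys),
        sorted(in_keys & out_keys),
    )


def proportion_ratio(
    key: tuple[str, int],
    input_table: InsertionTable,
    output_table: InsertionTable,
    input_total: int | None = None,
    output_total: int | None = None,
) -> float:
    """Input/output ratio of the read share at one shared position.

    Totals default to each pool's total mapped reads; they can be overridden
    to use shared-positions-only totals instead (see ``compare_pools``).
    """
    it = input_total if input_total is not None else input_table.total_mapped_reads
    ot = output_total if output_total is not None else output_table.total_mapped_reads
    return (input_table.sites[key] / it) / (output_table.sites[key] / ot)


@dataclass
class CompareResult:
    input_only: pd.DataFrame
    output_only: pd.DataFrame
    shared: pd.DataFrame
    stats: SharedStats | None


def _gene_lookup(
    table: InsertionTable, genes: list[GeneAnnotation] | None
) -> dict[tuple[str, int], str]:
    if not genes:
        return {}
    per_gene, _ = assign_sites(table, genes)
    lookup: dict[tuple[str, int], str] = {}
    by_id = {g.gene_id: g for g in genes}
    for gene_id, gene_sites in per_gene.items():
        ref = by_id[gene_id].reference_name
        for pos, _ in gene_sites:
            # overlapping genes: first assignment wins for the label column
            lookup.setdefault((ref, pos), gene_id)
    return lookup


def compare_pools(
    input_table: InsertionTable,
    output_table: InsertionTable,
    genes: list[GeneAnnotation] | None = None,
    shared_totals_only: bool = False,
) -> CompareResult:
    """Full two-pool comparison.

    Returns the three tables.  The "only" tables carry depths and gene
    labels but no Z-score (undefined off the shared population).  With
    ``shared_totals_only`` the read-share denominators are the totals over
    shared positions instead of whole-pool totals (the default, which is
    logged so users can audit the choice).
    """
    input_only, output_only, shared = partition(input_table, output_table)

    if shared_totals_only:
        in_total = sum(input_table.sites[k] for k in shared)
        out_total = sum(output_table.sites[k] for k in shared)
    else:
        in_total = input_table.total_mapped_reads
        out_total = output_table.total_mapped_reads
    logger.info(
        "proportion denominators: input=%d output=%d (%s totals)",
        in_total,
        out_total,
        "shared-position" if shared_totals_only else "pool",
    )

    union_genes = _gene_lookup(
        InsertionTable({**output_table.sites, **input_table.sites}), genes
    )

    def only_frame(keys: list[tuple[str, int]], table: InsertionTable) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reference": ref,
                    "position": pos,
                    "depth": table.sites[(ref, pos)],
                    "gene_id": union_genes.get((ref, pos), ""),
                }
                for ref, pos in keys
            ],
            columns=["reference", "position", "depth", "gene_id"],
        )

    stats: SharedStats | None = None
    shared_rows = []
    if shared:
        log_ratios = np.array(
            [
                math.log(
                    proportion_ratio(
                        k, input_table, output_table, in_total, out_total
                    )
                )
                for k in shared
            ]
        )
        mean = float(log_ratios.mean())
        sd = float(log_ratios.std(ddof=1)) if len(log_ratios) >= 2 else 0.0
        if sd == 0.0:
            logger.warning(
                "shared log-ratio sd is 0 (n=%d); all Z-scores set to 0", len(shared)
            )
            zs = np.zeros_like(log_ratios)
        else:
            zs = (log_ratios - mean) / sd
        stats = SharedStats(shared_mean=mean, shared_sd=sd, n_shared=len(shared))
        for (ref, pos), lr, z in zip(shared, log_ratios, zs):
            d_in = input_table.sites[(ref, pos)]
            d_out = output_table.sites[(ref, pos)]
            shared_rows.append(
                {
                    "reference": ref,
                    "position": pos,
                    "input_depth": d_in,
                    "output_depth": d_out,
                    "input_share": d_in / in_total,
                    "output_share": d_out / out_total,
                    "proportion_ratio": math.exp(lr),
                    "log_ratio": lr,
                    "zscore": float(z),
                    "flag": flag(float(z)),
                    "gene_id": union_genes.get((ref, pos), ""),
                }
            )
    else:
        logger.warning("no shared positions between pools; Z-score stage skipped")

    shared_df = pd.DataFrame(
        shared_rows,
        columns=[
            "reference",
            "position",
            "input_depth",
            "output_depth",
            "input_share",
            "output_share",
            "proportion_ratio",
            "log_ratio",
            "zscore",
            "flag",
            "gene_id",
        ],
    )
    return CompareResult(
        input_only=only_frame(input_only, input_table),
        output_only=only_frame(output_only, output_table),
        shared=shared_df,
        stats=stats,
    )


def write_compare_outputs(result: CompareResult, out_dir: str | Path) -> dict[str, Path]:
    """Write ``input_only.tsv``, ``output_only.tsv`` and ``shared.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "input_only": out_dir / "input_only.tsv",
        "output_only": out_dir / "output_only.tsv",
        "shared": out_dir / "shared.tsv",
    }
    result.input_only.to_csv(paths["input_only"], sep="\t", index=False)
    result.output_only.to_csv(paths["output_only"], sep="\t", index=False)
    result.shared.to_csv(paths["shared"], sep="\t", index=False)
    return paths
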