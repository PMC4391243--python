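"""Per-gene insertion statistics: counts, NRM/NIM, centiles and NIindex.

Joining insertion positions to a GFF annotation yields, per coding
sequence: the number of unique insertion positions, the total read depth
over them, insertions per kb, the percentile position of the first and last
insert within the coding sequence (5'→3' in coding orientation), and two
library-size- and length-normalised scores,

    NRM = (gene reads   / gene length kb) / (pool mapped reads      / 1e6)
    NIM = (gene unique insertions / gene length kb) / (pool unique insertions / 1e6)

NRM and NIM make disruption comparable across genes and across experiments
of different depth.  A gene whose insertions are strongly depleted relative
to the pool — the working threshold is NIM < 2 — is a candidate (conditionally)
essential gene.

The genome-wide NIindex assigns each insertion position the deviation of
its observed read count from the single pool-wide expectation
(total mapped reads / unique positions); by construction these deviations
sum to zero, and a smoothed profile of them exposes insertion hot and cold
spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .samfilter import InsertionTable

logger = logging.getLogger(__name__)

#: attribute keys tried, in order, to name a feature
_ID_KEYS = ("ID", "locus_tag", "gene_id")

#: genes with NIM below this are called (conditionally) essential
NIM_ESSENTIAL_THRESHOLD = 2.0

#: smoothing window (consecutive sites) for the NIindex profile
NIINDEX_WINDOW = 201


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated coding sequence (1-based inclusive coordinates)."""

    gene_id: str
    reference_name: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def load_gff(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models from a GFF3 or GFF2 file.

    CDS features are preferred; if none are present, ``gene`` features are
    used.  The feature identifier is taken from the first of the ID,
    locus_tag or gene_id attributes that is present.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = list(db.features_of_type("CDS"))
    if not feats:
        feats = list(db.features_of_type("gene"))
    if not feats:
        raise ValueError(f"{path}: no CDS or gene features found")
    genes = []
    for f in feats:
        gene_id = next(
            (f.attributes[k][0] for k in _ID_KEYS if k in f.attributes), f.id
        )
        product = f.attributes.get("product", [""])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                reference_name=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                product=product,
            )
        )
    return genes


def assign_sites(
    sites: InsertionTable, genes: list[GeneAnnotation]
) -> tuple[dict[str, list[tuple[int, int]]], list[tuple[str, int, int]]]:
    """Assign each insertion site to every gene whose span contains it.

    Returns ``(per_gene, intergenic)`` where per_gene maps gene_id to a list
    of (position, depth) and intergenic lists (reference, position, depth)
    for unassigned sites.  Boundaries are inclusive.  A site inside
    overlapping genes is counted in each of them (and the overlap logged),
    rather than silently dropped from either.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    site_refs = {ref for ref, _ in sites.sites}
    gene_refs = {g.reference_name for g in genes}
    if sites.sites and not (site_refs & gene_refs):
        raise ValueError(
            "no shared reference names between insertion table and annotation: "
            f"sites use {sorted(site_refs)}, annotation uses {sorted(gene_refs)}"
        )
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the gene end inclusive
        trees.setdefault(g.reference_name, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id
        )
    per_gene: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    intergenic: list[tuple[str, int, int]] = []
    n_overlap = 0
    for (ref, pos), depth in sorted(sites.sites.items()):
        hits = trees[ref][pos] if ref in trees else set()
        if not hits:
            intergenic.append((ref, pos, depth))
            continue
        if len(hits) > 1:
            n_overlap += 1
        for iv in hits:
            per_gene[iv.data].append((pos, depth))
    if n_overlap:
        logger.info("%d site(s) fell in overlapping genes (counted in each)", n_overlap)
    return per_gene, intergenic


def nrm(gene_reads: int, gene_len_kb: float, total_mapped_reads: int) -> float:
    """Normalized Reads Mapped: (reads/kb) per million pool reads."""
    if gene_len_kb <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("empty pool: total mapped reads must be positive")
    return (gene_reads / gene_len_kb) / (total_mapped_reads / 1e6)


def nim(
    gene_unique_insertions: int, gene_len_kb: float, total_unique_insertions: int
) -> float:
    """Normalized Insertions Mapped: (unique insertions/kb) per million pool insertions."""
    if gene_len_kb <= 0:
        raise ValueError("gene length must be positive")
    if total_unique_insertions <= 0:
        raise ValueError("empty pool: total unique insertions must be positive")
    return (gene_unique_insertions / gene_len_kb) / (total_unique_insertions / 1e6)


def centile(gene: GeneAnnotation, position: int) -> float:
    """Percent position of an insertion within the coding sequence, 5'→3'.

    Base 1 of a gene of length L scores 100*1/L and the last coding base
    scores 100, in coding orientation: on the - strand the gene's first
    coding base is its highest chromosomal coordinate.
    """
    if gene.strand == "-":
        offset = gene.end - position
    else:
        offset = position - gene.start
    return 100.0 * (offset + 1) / gene.length_bp


def centiles(gene: GeneAnnotation, positions: list[int]) -> tuple[float, float, list[float]]:
    """(first, last, all) insertion centiles for one gene (requires >= 1 site)."""
    values = [centile(gene, p) for p in positions]
    return min(values), max(values), values


def essential_call(nim_value: float, threshold: float = NIM_ESSENTIAL_THRESHOLD) -> bool:
    """Essentiality call: strictly below the NIM threshold."""
    return nim_value < threshold


def summarize_genes(
    sites: InsertionTable, genes: list[GeneAnnotation]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene summary table plus the all-insertions centile table.

    Genes with zero insertions stay in the table with NIM = 0 and absent
    centiles — they are exactly the essential candidates.  The centile table
    has one row per (gene, insertion) for histogramming.
    """
    per_gene, _ = assign_sites(sites, genes)
    total_reads = sites.total_mapped_reads
    total_ins = sites.total_unique_positions
    rows = []
    centile_rows = []
    for g in genes:
        gene_sites = per_gene[g.gene_id]
        n_ins = len(gene_sites)
        n_reads = sum(depth for _, depth in gene_sites)
        if n_ins:
            first, last, values = centiles(g, [p for p, _ in gene_sites])
            centile_rows.extend(
                {"gene_id": g.gene_id, "position": p, "centile": c}
                for (p, _), c in zip(gene_sites, values)
            )
        else:
            first = last = np.nan
        row_nim = nim(n_ins, g.length_kb, total_ins) if total_ins else 0.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "reference": g.reference_name,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
                "length_kb": g.length_kb,
                "unique_insertions": n_ins,
                "total_reads": n_reads,
                "insertions_per_kb": n_ins / g.length_kb,
                "first_insert_centile": first,
                "last_insert_centile": last,
                "NRM": nrm(n_reads, g.length_kb, total_reads) if total_reads else 0.0,
                "NIM": row_nim,
                "essential": essential_call(row_nim),
            }
        )
    summary = pd.DataFrame(rows)
    centile_df = pd.DataFrame(
        centile_rows, columns=["gene_id", "position", "centile"]
    )
    return summary, centile_df


def niindex_profile(
    sites: InsertionTable, window: int = NIINDEX_WINDOW
) -> pd.DataFrame:
    """Observed-minus-expected read count per insertion position.

    expected = total mapped reads / unique positions (one pool-wide
    constant), so Σ niindex = 0 exactly; the ``smoothed`` column is a
    centred running mean over ``window`` consecutive sites in genome order,
    for visualisation only.
    """
    if not sites.sites:
        raise ValueError("NIindex requires at least one insertion site")
    expected = sites.total_mapped_reads / sites.total_unique_positions
    df = sites.to_frame()
    df["observed"] = df["depth"]
    df["expected"] = expected
    df["niindex"] = df["observed"] - expected
    df["smoothed"] = (
        df.groupby("reference")["niindex"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return df.drop(columns=["depth"])


def write_counts_outputs(
    sites: InsertionTable,
    genes: list[GeneAnnotation],
    out_dir: str | Path,
    pool_name: str = "pool",
) -> dict[str, Path]:
    """Write ``<pool>.summary.table``, ``niindex.tsv`` and ``centiles.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary, centile_df = summarize_genes(sites, genes)
    paths = {
        "summary": out_dir / f"{pool_name}.summary.table",
        "niindex": out_dir / "niindex.tsv",
        "centiles": out_dir / "centiles.tsv",
    }
    summary.to_csv(paths["summary"], sep="\t", index=False)
    niindex_profile(sites).to_csv(paths["niindex"], sep="\t", index=False)
    centile_df.to_csv(paths["centiles"], sep="\t", index=False)
    return paths
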