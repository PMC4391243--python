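"""Synthetic mutant-library generator with a known truth table.

Generates a random genome with non-overlapping gene models, plants unique
insertion sites, and writes junction reads of the exact structure the read
preparation stage expects: ``[filler] + terminal motif + genomic sequence``
starting at the junction, in either read orientation.  Elements that create
a target-site duplication are emulated faithfully: reads from the reverse
junction of an insertion planted at position p call position p + tsd, so
collapsing at exactly the duplication length restores one site per
insertion.

The truth table records every planted site with its forward/reverse read
depths, which makes every downstream stage verifiable without external
data: with error rate 0 the full pipeline must recover the truth exactly.

All randomness flows from a single seeded generator; per-base sequencing
errors are applied only to the genomic part of a read, never to the motif,
so motif recovery is exact by construction (robustness to motif errors is
out of scope).  After assembly every read is checked to ensure the motif
search will recover the intended junction (a random filler or error could
otherwise create a spurious earlier motif match); reads failing the check
are re-drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneAnnotation
from .readprep import MotifSpec, ReadRecord, find_motif, reverse_complement
from .samfilter import InsertionTable

REFERENCE_NAME = "sim_chr"

_DEFAULT_MOTIF = "TCAGACGTGGTT"  # 12 bp, non-palindromic

_BASE_ARRAY = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Conditions of one simulated library.

    Defaults describe a desk-scale bacterial screen: a 500 kb genome with
    one gene per ~1.1 kb, 5,000 independent insertions (one per mutant, as
    in a pooled-colony library), an 8 bp target-site duplication, 50 bp
    reads whose per-insertion count is geometric with mean 5, and both
    junction orientations sequenced equally.  The error rate default is 0
    so that truth recovery is exact; set it positive to exercise the
    mismatch filter.
    """

    seed: int
    genome_length: int = 500_000
    n_genes: int = 450
    n_insertions: int = 5_000
    tsd_length: int = 8
    motif: MotifSpec = field(
        default_factory=lambda: MotifSpec(label="tn_end", sequence=_DEFAULT_MOTIF)
    )
    read_length: int = 50
    mean_reads_per_insertion: float = 5.0
    fraction_reverse: float = 0.5
    base_error_rate: float = 0.0
    max_filler: int = 6

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_genes", "n_insertions", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tsd_length < 0 or self.max_filler < 0:
            raise ValueError("tsd_length and max_filler must be >= 0")
        if not 0 <= self.fraction_reverse <= 1:
            raise ValueError("fraction_reverse must be in [0,1]")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0,1)")


def simulate_genome(cfg: SimConfig) -> tuple[str, list[GeneAnnotation]]:
    """Uniform-random genome plus non-overlapping genes on alternating strands."""
    rng = np.random.default_rng(cfg.seed)
    genome = "".join(_BASE_ARRAY[rng.integers(0, 4, cfg.genome_length)])
    slot = cfg.genome_length // cfg.n_genes
    gene_len = int(slot * 0.75)
    if gene_len < 30:
        raise ValueError(
            f"cannot fit {cfg.n_genes} genes of useful size in {cfg.genome_length} bp"
        )
    genes = []
    for i in range(cfg.n_genes):
        start = i * slot + slot // 8 + 1  # 1-based
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i + 1:04d}",
                reference_name=REFERENCE_NAME,
                start=start,
                end=start + gene_len - 1,
                strand="+" if i % 2 == 0 else "-",
                product="hypothetical protein",
            )
        )
    return genome, genes


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    if hits.any():
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASE_ARRAY[rng.integers(0, 4, n)]) if n else ""


def plant_insertions_and_reads(
    cfg: SimConfig, genome: str
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Plant unique insertion sites and emit junction reads plus the truth table.

    Each insertion at position p yields a geometric number of reads, split
    between the forward junction (called site p, read written motif-forward)
    and the reverse junction (called site p + tsd, read written in
    reverse-complement form so the motif appears as its reverse complement).
    The truth table columns are reference, position, depth_fwd, depth_rev.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    motif = cfg.motif
    margin = cfg.read_length + cfg.tsd_length + 2
    # Minimum spacing keeps planted insertions distinguishable: two junction
    # sites from *different* insertions must never sit exactly tsd apart, or
    # collapsing would merge them.  Spacing of 2*tsd+1 rules that out.
    spacing = 2 * cfg.tsd_length
    lo, hi = margin, cfg.genome_length - margin
    span = hi - lo - (cfg.n_insertions - 1) * spacing
    if cfg.n_insertions > span:
        raise ValueError("more insertions requested than available genome positions")
    base = np.sort(rng.choice(np.arange(span), cfg.n_insertions, replace=False))
    positions = base + lo + np.arange(cfg.n_insertions) * spacing

    reads: list[ReadRecord] = []
    truth_rows = []
    serial = 0

    def build_read(p: int, reverse_junction: bool) -> ReadRecord:
        nonlocal serial
        serial += 1
        for attempt in range(10):
            filler_len = int(rng.integers(0, cfg.max_filler + 1)) if attempt < 9 else 0
            glen = cfg.read_length - filler_len - len(motif.sequence)
            if not reverse_junction:
                genomic = genome[p - 1 : p - 1 + glen]
            else:
                q = p + cfg.tsd_length
                genomic = reverse_complement(genome[q - glen : q])
            genomic = _mutate(rng, genomic, cfg.base_error_rate)
            filler = _random_bases(rng, filler_len)
            template = filler + motif.sequence + genomic
            seq = template if not reverse_junction else reverse_complement(template)
            quality = "".join(
                chr(33 + q) for q in rng.integers(32, 41, len(seq))
            )
            read = ReadRecord(
                id=f"sim{serial:07d}:p{p}:{'rev' if reverse_junction else 'fwd'}",
                sequence=seq,
                quality=quality,
                mate=0,
            )
            m = find_motif(read, motif)
            want_orient = "revcomp" if reverse_junction else "forward"
            want_offset = (
                filler_len + len(motif.sequence) if not reverse_junction else glen
            )
            if m.found and m.orientation == want_orient and m.offset == want_offset:
                return read
        raise RuntimeError(
            f"could not build an unambiguous junction read at position {p}"
        )

    for p in positions:
        depth = int(rng.geometric(1.0 / cfg.mean_reads_per_insertion))
        n_rev = int(rng.binomial(depth, cfg.fraction_reverse))
        n_fwd = depth - n_rev
        for _ in range(n_fwd):
            reads.append(build_read(int(p), reverse_junction=False))
        for _ in range(n_rev):
            reads.append(build_read(int(p), reverse_junction=True))
        truth_rows.append(
            {
                "reference": REFERENCE_NAME,
                "position": int(p),
                "depth_fwd": n_fwd,
                "depth_rev": n_rev,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def truth_to_insertion_table(truth: pd.DataFrame, tsd_length: int = 0) -> InsertionTable:
    """Expected post-collapse insertion table implied by a truth table.

    One site per planted insertion with depth = fwd + rev reads.  An
    insertion sequenced *only* from its reverse junction leaves evidence
    only at position p + tsd — there is no forward-junction site to collapse
    it into — so that is the position any correct pipeline reports for it.
    """
    table = InsertionTable()
    for row in truth.itertuples():
        pos = int(row.position)
        if row.depth_fwd == 0:
            pos += tsd_length
        table.add(row.reference, pos, int(row.depth_fwd + row.depth_rev))
    return table


def write_gff3(genes: list[GeneAnnotation], path: str | Path, seed: int) -> None:
    with open(path, "wt") as out:
        out.write("##gff-version 3\n")
        out.write(f"# simulation seed: {seed}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id};product={g.product}"
            out.write(
                f"{g.reference_name}\ttnmap-sim\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


def write_fasta(genome: str, path: str | Path, seed: int) -> None:
    with open(path, "wt") as out:
        out.write(f">{REFERENCE_NAME} simulation seed: {seed}\n")
        for i in range(0, len(genome), 80):
            out.write(genome[i : i + 80] + "\n")


def simulate_library(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fasta, genes.gff3, reads.fastq and truth.tsv for one library."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(cfg)
    reads, truth = plant_insertions_and_reads(cfg, genome)
    paths = {
        "fasta": out_dir / "genome.fasta",
        "gff": out_dir / "genes.gff3",
        "fastq": out_dir / "reads.fastq",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(genome, paths["fasta"], cfg.seed)
    write_gff3(genes, paths["gff"], cfg.seed)
    with open(paths["fastq"], "wt") as out:
        for r in reads:
            out.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
    with open(paths["truth"], "wt") as out:
        out.write(f"# simulation seed: {cfg.seed}\n")
        truth.to_csv(out, sep="\t", index=False)
    return paths


def simulate_paired_pools(
    n_shared: int = 2_000,
    n_unique_each: int = 50,
    seed: int = 0,
    mean_log_depth: float = 2.0,
    sigma_log_depth: float = 0.8,
) -> tuple[InsertionTable, InsertionTable]:
    """Two pools re-sequenced from one library with no selection (null model).

    Shared positions receive independent log-normal read depths in each pool
    (rounded, minimum 1): per-site read shares in real pools are roughly
    log-normal, which is what makes the shared log-proportion-ratio
    approximately normal and the ~5% null flag rate meaningful.  Each pool
    additionally gets ``n_unique_each`` private positions.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(
            np.arange(100, 100 + 10 * (n_shared + 2 * n_unique_each)),
            n_shared + 2 * n_unique_each,
            replace=False,
        )
    )
    shared = positions[: n_shared]
    uniq_a = positions[n_shared : n_shared + n_unique_each]
    uniq_b = positions[n_shared + n_unique_each :]

    def depths(n: int) -> np.ndarray:
        return np.maximum(
            1, np.round(rng.lognormal(mean_log_depth, sigma_log_depth, n))
        ).astype(int)

    pool_a, pool_b = InsertionTable(), InsertionTable()
    for p, d in zip(shared, depths(n_shared)):
        pool_a.add(REFERENCE_NAME, int(p), int(d))
    for p, d in zip(shared, depths(n_shared)):
        pool_b.add(REFERENCE_NAME, int(p), int(d))
    for p, d in zip(uniq_a, depths(n_unique_each)):
        pool_a.add(REFERENCE_NAME, int(p), int(d))
    for p, d in zip(uniq_b, depths(n_unique_each)):
        pool_b.add(REFERENCE_NAME, int(p), int(d))
    return pool_a, pool_b
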