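"""Alignment post-filtering and insertion-site calling from SAM.

Each primary alignment of a junction fragment is screened on two axes:
the number of substituted bases (decoded from the SAM MD tag) and the
aligner-reported alignment score (AS tag).  For surviving records the
position of the *initial* base of the alignment — the base immediately
adjacent to the inserted element — is recorded as the insertion site.
Because the trimmed fragment always reads away from the transposon, that
base is the leftmost reference position for a forward-strand alignment and
the rightmost for a reverse-strand alignment.

Insertion elements that create a target-site duplication (an exact 8 bp
repeat for pGhost9::ISS1) make the two ends of one insertion map a fixed
distance apart; sites exactly that distance apart can therefore be
collapsed into one.  A depth (coverage) filter removes positions supported
by a single read, which are enriched for artifacts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


@dataclass
class FilterConfig:
    """Alignment acceptance thresholds.

    ``max_mismatch`` is either an integer count of substituted bases or a
    fraction strictly between 0 and 1, interpreted as a fraction of the read
    length (floor, i.e. an upper bound).  ``min_align_score`` is on the
    aligner's own scale, so negative values are meaningful for bowtie2.
    ``collapse_distance`` of 0 disables target-site-duplication collapsing;
    use 8 for pGhost9::ISS1.
    """

    max_mismatch: float = 0
    min_align_score: int = 50
    collapse_distance: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if 0 < self.max_mismatch < 1:
            pass  # fractional form
        elif self.max_mismatch != int(self.max_mismatch):
            raise ValueError(
                "max_mismatch must be an integer count or a fraction in (0,1)"
            )
        if self.collapse_distance < 0:
            raise ValueError("collapse_distance must be >= 0")

    def mismatch_threshold(self, read_len: int) -> int:
        if 0 < self.max_mismatch < 1:
            return math.floor(self.max_mismatch * read_len)
        return int(self.max_mismatch)


@dataclass
class InsertionTable:
    """Unique insertion positions with read depth, keyed by (reference, 1-based pos)."""

    sites: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def total_mapped_reads(self) -> int:
        return sum(self.sites.values())

    @property
    def total_unique_positions(self) -> int:
        return len(self.sites)

    def add(self, reference: str, position: int, depth: int = 1) -> None:
        key = (reference, position)
        self.sites[key] = self.sites.get(key, 0) + depth

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.sites.items())
        return pd.DataFrame(
            [(ref, pos, depth) for (ref, pos), depth in rows],
            columns=["reference", "position", "depth"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InsertionTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"reference", "position", "depth"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        table = cls()
        for ref, pos, depth in zip(df["reference"], df["position"], df["depth"]):
            table.add(str(ref), int(pos), int(depth))
        return table


def count_mismatches(md_tag: str, read_id: str | None = None) -> int:
    """Number of substituted bases encoded by a SAM MD tag.

    Letters inside a ``^``-prefixed run describe deleted reference bases and
    are not substitutions; insertions are invisible to the MD tag.  Indels
    are therefore never counted — only true base substitutions are.
    """
    consumed = 0
    n = 0
    for m in _MD_TOKEN.finditer(md_tag):
        if m.start() != consumed:
            break
        consumed = m.end()
        if m.group(3):
            n += 1
    if consumed != len(md_tag) or not md_tag:
        who = f" (read {read_id})" if read_id else ""
        raise ValueError(f"malformed MD tag {md_tag!r}{who}")
    return n


def reference_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M/D/N/=/X; clips do not count)."""
    span = 0
    consumed = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != consumed:
            break
        consumed = m.end()
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
    if consumed != len(cigar) or not cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return span


def insertion_position(
    reference_name: str, pos: int, cigar: str, strand: str
) -> tuple[str, int]:
    """Insertion site of an aligned junction fragment.

    ``pos`` is the 1-based leftmost mapping position.  The junction-adjacent
    base is the fragment's 5' end: leftmost base on the + strand, rightmost
    (pos + reference span - 1) on the - strand.
    """
    if strand == "+":
        return reference_name, pos
    if strand == "-":
        return reference_name, pos + reference_span(cigar) - 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def passes_filters(
    mismatches: int, align_score: int | None, cfg: FilterConfig, read_len: int
) -> bool:
    """True iff mismatches and alignment score both meet the thresholds.

    A missing AS tag fails the score test (counted separately in the run
    stats so the loss is visible).
    """
    if align_score is None:
        return False
    return (
        mismatches <= cfg.mismatch_threshold(read_len)
        and align_score >= cfg.min_align_score
    )


@dataclass
class AlignmentSummary:
    """Minimal per-record view used by filtering and the parameter sweep."""

    read_id: str
    reference_name: str
    site: int  # called insertion position, 1-based
    strand: str
    read_len: int
    mismatches: int | None  # None when the MD tag is absent
    align_score: int | None


def iter_alignments(sam_path: str | Path) -> Iterator[tuple[str, AlignmentSummary | None]]:
    """Yield ``(category, summary)`` for every record in a SAM file.

    category is one of ``unmapped``, ``secondary`` (includes supplementary)
    or ``candidate``; only candidates carry a summary.  Secondary and
    supplementary records are ignored so each read is counted at most once.
    """
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                yield "unmapped", None
                continue
            if rec.is_secondary or rec.is_supplementary:
                yield "secondary", None
                continue
            strand = "-" if rec.is_reverse else "+"
            site = (
                rec.reference_start + 1 if strand == "+" else rec.reference_end
            )
            md = rec.get_tag("MD") if rec.has_tag("MD") else None
            mismatches = (
                count_mismatches(md, read_id=rec.query_name) if md is not None else None
            )
            yield "candidate", AlignmentSummary(
                read_id=rec.query_name,
                reference_name=rec.reference_name,
                site=int(site),
                strand=strand,
                read_len=rec.query_length or len(rec.query_sequence or ""),
                mismatches=mismatches,
                align_score=int(rec.get_tag("AS")) if rec.has_tag("AS") else None,
            )


@dataclass
class ProcessStats:
    """Conservation counts: every SAM record lands in exactly one bucket."""

    total_records: int = 0
    unmapped: int = 0
    secondary: int = 0
    passed: int = 0
    failed_mismatch: int = 0
    failed_score: int = 0
    missing_md: int = 0
    missing_as: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def call_insertions(
    sam_path: str | Path, cfg: FilterConfig
) -> tuple[InsertionTable, ProcessStats]:
    """Filter a SAM file and tabulate insertion positions with read depth.

    Applies the mismatch and score filters, calls the strand-aware junction
    position per read, then collapses sites exactly ``cfg.collapse_distance``
    apart (when nonzero).
    """
    table = InsertionTable()
    stats = ProcessStats()
    for category, summ in iter_alignments(sam_path):
        stats.total_records += 1
        if category == "unmapped":
            stats.unmapped += 1
            continue
        if category == "secondary":
            stats.secondary += 1
            continue
        assert summ is not None
        if summ.mismatches is None:
            stats.missing_md += 1
            stats.failed_mismatch += 1
            continue
        if summ.align_score is None:
            stats.missing_as += 1
            stats.failed_score += 1
            continue
        if summ.mismatches > cfg.mismatch_threshold(summ.read_len):
            stats.failed_mismatch += 1
            continue
        if summ.align_score < cfg.min_align_score:
            stats.failed_score += 1
            continue
        stats.passed += 1
        table.add(summ.reference_name, summ.site)
    if cfg.collapse_distance:
        table = collapse(table, cfg.collapse_distance)
    return table, stats


def collapse(sites: InsertionTable, d: int) -> InsertionTable:
    """Merge sites exactly ``d`` bp apart into the lower position, summing depth.

    Single left-to-right pass without re-chaining: a position consumed as the
    right-hand partner of a merge cannot seed a further merge.  This matches
    the geometry of a target-site duplication, which produces exactly one
    partner site per insertion.  ``d=0`` is the identity.
    """
    if d < 0:
        raise ValueError("collapse distance must be >= 0")
    if d == 0:
        return InsertionTable(dict(sites.sites))
    merged = InsertionTable()
    by_ref: dict[str, dict[int, int]] = {}
    for (ref, pos), depth in sites.sites.items():
        by_ref.setdefault(ref, {})[pos] = depth
    for ref in sorted(by_ref):
        positions = by_ref[ref]
        consumed: set[int] = set()
        for pos in sorted(positions):
            if pos in consumed:
                continue
            depth = positions[pos]
            partner = pos + d
            if partner in positions and partner not in consumed:
                depth += positions[partner]
                consumed.add(partner)
            merged.add(ref, pos, depth)
    return merged


def coverage_filter(sites: InsertionTable, min_depth: int) -> InsertionTable:
    """Keep sites with depth >= ``min_depth`` (totals recomputed)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    kept = InsertionTable(
        {key: depth for key, depth in sites.sites.items() if depth >= min_depth}
    )
    if not kept.sites and sites.sites:
        logger.warning("coverage_filter(min_depth=%d) removed every site", min_depth)
    return kept


def parameter_sweep(
    sam_path: str | Path,
    mismatch_grid: Iterable[float],
    score_grid: Iterable[int],
    collapse_distance: int = 0,
) -> pd.DataFrame:
    """Unique positions and mean depth over a grid of filter thresholds.

    One SAM pass extracts per-read summaries; each grid cell is then
    evaluated in memory.  Unique positions are non-increasing as either
    threshold tightens (records can only be lost, never gained).
    """
    candidates = [s for cat, s in iter_alignments(sam_path) if cat == "candidate"]
    rows = []
    for mis in mismatch_grid:
        for score in score_grid:
            cfg = FilterConfig(
                max_mismatch=mis,
                min_align_score=score,
                collapse_distance=collapse_distance,
            )
            table = InsertionTable()
            for s in candidates:
                if s.mismatches is None or s.align_score is None:
                    continue
                if passes_filters(s.mismatches, s.align_score, cfg, s.read_len):
                    table.add(s.reference_name, s.site)
            if collapse_distance:
                table = collapse(table, collapse_distance)
            n = table.total_unique_positions
            rows.append(
                {
                    "max_mismatch": mis,
                    "min_align_score": score,
                    "unique_positions": n,
                    "mean_depth": (table.total_mapped_reads / n) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
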