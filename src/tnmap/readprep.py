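"""Transposon-junction read extraction from raw FASTQ.

Mutant libraries built by random insertional mutagenesis are typically
sequenced by inverse PCR outward from the inserted element, so each raw read
is a chimera: part transposon, part flanking chromosome.  Such reads do not
map faithfully to the reference, so the first pipeline stage scans every read
for a user-supplied terminal motif of the transposon (both the motif and its
automatically generated reverse complement are searched) and emits only the
genomic fragment immediately downstream of the junction, re-oriented so that
it always reads *away* from the transposon.  Fragment length is bounded:
short fragments carry too little information to map confidently, and long
fragments risk re-entering the transposon when the PCR template was a small
circle.

The stage also produces per-position QC tables (base composition and quality
quartiles) for both raw and trimmed reads, and a run log with exact
conservation counts so that every input read is accounted for.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_MOTIF_BASES = frozenset("ACGT")

#: rejection reasons used throughout the run log
NO_MOTIF = "no_motif"
TOO_SHORT = "too_short"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A transposon terminal motif together with its reverse complement.

    The reverse complement is derived, never user-supplied: reads from the
    opposite strand of the junction carry the motif in reverse-complement
    form, and both forms are searched.
    """

    label: str
    sequence: str
    revcomp: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("motif sequence must be non-empty")
        bad = set(seq) - _VALID_MOTIF_BASES
        if bad:
            raise ValueError(
                f"motif {self.label!r} contains non-DNA character(s): "
                f"{','.join(sorted(bad))}"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "revcomp", reverse_complement(seq))


@dataclass
class ReadRecord:
    """One FASTQ record. ``mate`` is 1 or 2 for paired data, 0 if unpaired."""

    id: str
    sequence: str
    quality: str
    mate: int = 0


@dataclass
class TrimmedRead:
    """The genomic fragment downstream of a transposon junction.

    ``orientation`` records whether the motif was found as given ("forward")
    or as its reverse complement ("revcomp"); in the latter case the emitted
    sequence has already been reverse-complemented (and the quality string
    reversed) so that base 1 is always the junction-adjacent genomic base.
    """

    id: str
    sequence: str
    quality: str
    source_motif: str
    orientation: str
    original_read_id: str


@dataclass
class TrimConfig:
    """Motifs plus fragment length bounds (bp). Defaults: keep 20-50 bp."""

    motifs: list[MotifSpec]
    min_len: int = 20
    max_len: int = 50

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("at least one motif is required")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")


@dataclass(frozen=True)
class MotifMatch:
    found: bool
    orientation: str | None = None
    offset: int = -1  # forward: 0-based index one past the motif; revcomp: 0-based start


def find_motif(read: ReadRecord, motif: MotifSpec) -> MotifMatch:
    """Locate ``motif`` in a read, searching both orientations.

    Exact substring search (an N never matches).  If both orientations occur
    the forward match wins; within an orientation the leftmost occurrence
    wins.  Both tie-breaks are deterministic by design.
    """
    seq = read.sequence.upper()
    i = seq.find(motif.sequence)
    if i != -1:
        return MotifMatch(True, "forward", i + len(motif.sequence))
    i = seq.find(motif.revcomp)
    if i != -1:
        return MotifMatch(True, "revcomp", i)
    return MotifMatch(False)


def extract_fragment(
    read: ReadRecord, cfg: TrimConfig
) -> tuple[TrimmedRead | None, str | None]:
    """Extract the junction-adjacent genomic fragment from one read.

    Returns ``(TrimmedRead, None)`` on success or ``(None, reason)`` where
    reason is ``"no_motif"`` or ``"too_short"``.  Motifs are tried in config
    order; the first that matches is used.

    Forward match: the bases after the motif are kept.  Reverse-complement
    match: the bases *before* the match are reverse-complemented (qualities
    reversed) so the fragment reads away from the transposon either way.
    Truncation to ``max_len`` always keeps the bases closest to the junction,
    since the junction-proximal base defines the insertion site.
    """
    if len(read.sequence) != len(read.quality):
        raise ValueError(
            f"malformed FASTQ record {read.id!r}: sequence length "
            f"{len(read.sequence)} != quality length {len(read.quality)}"
        )
    seq = read.sequence.upper()
    for motif in cfg.motifs:
        m = find_motif(read, motif)
        if not m.found:
            continue
        if m.orientation == "forward":
            frag = seq[m.offset : m.offset + cfg.max_len]
            qual = read.quality[m.offset : m.offset + cfg.max_len]
        else:
            left = max(0, m.offset - cfg.max_len)
            frag = reverse_complement(seq[left : m.offset])
            qual = read.quality[left : m.offset][::-1]
        if len(frag) < cfg.min_len:
            return None, TOO_SHORT
        return (
            TrimmedRead(
                id=read.id,
                sequence=frag,
                quality=qual,
                source_motif=motif.label,
                orientation=m.orientation,
                original_read_id=read.id,
            ),
            None,
        )
    return None, NO_MOTIF


def dedup_pairs(
    pairs: Iterable[tuple[TrimmedRead | None, TrimmedRead | None]],
) -> Iterator[tuple[TrimmedRead, bool]]:
    """Collapse mate pairs that both yielded a fragment.

    When both ends of one insertion are sequenced the two mates describe the
    same junction, so counting both would double-count the insertion: if both
    mates survive trimming only mate 1 is emitted.  Yields
    ``(fragment, mate2_discarded)``.
    """
    for r1, r2 in pairs:
        if r1 is not None and r2 is not None:
            yield r1, True
        elif r1 is not None:
            yield r1, False
        elif r2 is not None:
            yield r2, False


# ---------------------------------------------------------------------------
# QC summaries
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T", "N")
_MAX_PHRED = 94


class QCAccumulator:
    """Streaming per-position base composition and quality quartiles."""

    def __init__(self) -> None:
        self._base_counts: np.ndarray = np.zeros((0, len(_BASES)), dtype=np.int64)
        self._qual_counts: np.ndarray = np.zeros((0, _MAX_PHRED), dtype=np.int64)
        self.n_reads = 0

    def _grow(self, length: int) -> None:
        if length > self._base_counts.shape[0]:
            extra = length - self._base_counts.shape[0]
            self._base_counts = np.vstack(
                [self._base_counts, np.zeros((extra, len(_BASES)), dtype=np.int64)]
            )
            self._qual_counts = np.vstack(
                [self._qual_counts, np.zeros((extra, _MAX_PHRED), dtype=np.int64)]
            )

    def add(self, sequence: str, quality: str) -> None:
        self.n_reads += 1
        self._grow(len(sequence))
        for i, (b, q) in enumerate(zip(sequence.upper(), quality)):
            j = _BASES.index(b) if b in _BASES else len(_BASES) - 1
            self._base_counts[i, j] += 1
            self._qual_counts[i, min(ord(q) - 33, _MAX_PHRED - 1)] += 1

    def base_composition(self) -> pd.DataFrame:
        """Percent of A/C/G/T/N at each 1-based read position (rows sum to 100)."""
        totals = self._base_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self._base_counts / totals
        df = pd.DataFrame(pct, columns=[f"pct_{b}" for b in _BASES])
        df.insert(0, "position", np.arange(1, len(df) + 1))
        return df

    def quality_quartiles(self) -> pd.DataFrame:
        """Q1/median/Q3 of phred scores at each 1-based read position."""
        rows = []
        for i in range(self._qual_counts.shape[0]):
            counts = self._qual_counts[i]
            n = counts.sum()
            if n == 0:
                rows.append((i + 1, np.nan, np.nan, np.nan))
                continue
            values = np.repeat(np.arange(_MAX_PHRED), counts)
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            rows.append((i + 1, q1, med, q3))
        return pd.DataFrame(rows, columns=["position", "q1", "median", "q3"])


def qc_summaries(
    reads: Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Base-composition and quality-quartile tables for (sequence, quality) pairs."""
    acc = QCAccumulator()
    for seq, qual in reads:
        acc.add(seq, qual)
    if acc.n_reads == 0:
        logger.warning("qc_summaries: empty input, emitting empty tables")
    return acc.base_composition(), acc.quality_quartiles()


# ---------------------------------------------------------------------------
# FASTQ streaming driver
# ---------------------------------------------------------------------------


def open_maybe_gzip(path: str | Path) -> IO[str]:
    """Open text or gzip FASTQ, auto-detected from the magic bytes."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_stream(path: str | Path, mate: int) -> Iterator[ReadRecord]:
    with open_maybe_gzip(path) as handle:
        for rid, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(id=rid.split()[0], sequence=seq, quality=qual, mate=mate)


def _core_id(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def write_fastq(reads: Iterable[TrimmedRead | ReadRecord], handle: IO[str]) -> int:
    n = 0
    for r in reads:
        handle.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
        n += 1
    return n


@dataclass
class ReadPrepResult:
    """Conservation counts from one trimming run.

    Invariant: total_reads == emitted + no_motif + too_short + mate2_discarded
    (for paired input, counts are over read *pairs* plus the discarded mates).
    """

    total_reads: int = 0
    emitted: int = 0
    no_motif: int = 0
    too_short: int = 0
    mate2_discarded: int = 0
    fragments_path: str = ""

    def as_dict(self) -> dict[str, int | str]:
        return {
            "total_reads": self.total_reads,
            "emitted": self.emitted,
            "no_motif": self.no_motif,
            "too_short": self.too_short,
            "mate2_discarded": self.mate2_discarded,
        }


def process_fastq(
    fastq: str | Path,
    cfg: TrimConfig,
    out_fastq: str | Path,
    fastq2: str | Path | None = None,
    qc_prefix: str | Path | None = None,
) -> ReadPrepResult:
    """Run motif trimming over one FASTQ file (or a mate pair of files).

    Writes the fragment FASTQ and, when ``qc_prefix`` is given, four QC
    tables: ``<prefix>.raw.basecomp.tsv``, ``<prefix>.raw.qualquartile.tsv``
    and the same pair for the processed fragments.
    """
    res = ReadPrepResult()
    raw_qc = QCAccumulator() if qc_prefix else None
    out_qc = QCAccumulator() if qc_prefix else None

    def account(read: ReadRecord) -> TrimmedRead | None:
        res.total_reads += 1
        if raw_qc is not None:
            raw_qc.add(read.sequence, read.quality)
        trimmed, reason = extract_fragment(read, cfg)
        if reason == NO_MOTIF:
            res.no_motif += 1
        elif reason == TOO_SHORT:
            res.too_short += 1
        return trimmed

    def emit(trimmed: TrimmedRead, out: IO[str]) -> None:
        res.emitted += write_fastq([trimmed], out)
        if out_qc is not None:
            out_qc.add(trimmed.sequence, trimmed.quality)

    with open(out_fastq, "wt") as out:
        if fastq2 is None:
            for read in _read_stream(fastq, mate=0):
                trimmed = account(read)
                if trimmed is not None:
                    emit(trimmed, out)
        else:
            stream1 = _read_stream(fastq, mate=1)
            stream2 = _read_stream(fastq2, mate=2)
            for r1, r2 in zip(stream1, stream2, strict=True):
                if _core_id(r1.id) != _core_id(r2.id):
                    raise ValueError(
                        f"desynchronized pair files: {r1.id!r} vs {r2.id!r}"
                    )
                t1, t2 = account(r1), account(r2)
                for keep, discarded in dedup_pairs([(t1, t2)]):
                    if discarded:
                        res.mate2_discarded += 1
                    emit(keep, out)
    res.fragments_path = str(out_fastq)

    if qc_prefix is not None:
        prefix = str(qc_prefix)
        assert raw_qc is not None and out_qc is not None
        raw_qc.base_composition().to_csv(
            f"{prefix}.raw.basecomp.tsv", sep="\t", index=False
        )
        raw_qc.quality_quartiles().to_csv(
            f"{prefix}.raw.qualquartile.tsv", sep="\t", index=False
        )
        out_qc.base_composition().to_csv(
            f"{prefix}.processed.basecomp.tsv", sep="\t", index=False
        )
        out_qc.quality_quartiles().to_csv(
            f"{prefix}.processed.qualquartile.tsv", sep="\t", index=False
        )
    return res
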