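"""External aligner invocation and a built-in exact-match oracle aligner.

The pipeline treats alignment as a pluggable external step: by default
``bwa mem -t 2`` is run on the fragment FASTQ, with ``bowtie2`` (preset
``--end-to-end --very-sensitive``) as the supported alternative, and any SAM
produced elsewhere can be fed to the downstream stages directly.  Programs
other than the two supported ones require an explicit opt-in flag, to guard
against typos silently producing nonsense alignments.

Downstream filtering needs MD and AS tags.  If the chosen aligner omitted
the MD tag it is recomputed from the reference (``samtools calmd``) rather
than treated as zero mismatches, which would make the mismatch filter
vacuous.

``oracle_align`` is a deterministic exhaustive-search aligner used as an
independent reference in tests and simulations: fragments that occur exactly
once in the reference (on either strand) are placed with a full-match CIGAR,
MD equal to the fragment length and AS equal to the fragment length;
everything else is reported unmapped.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .readprep import open_maybe_gzip, reverse_complement

KNOWN_ALIGNERS = ("bwa", "bowtie2")
DEFAULT_BWA_OPTIONS = ["mem", "-t", "2"]
BOWTIE2_SENSITIVE_PRESET = ["--end-to-end", "--very-sensitive"]


@dataclass
class AlignerCommand:
    """An aligner invocation: program, option list and reference path."""

    program: str = "bwa"
    options: list[str] = field(default_factory=lambda: list(DEFAULT_BWA_OPTIONS))
    reference: str | Path = ""
    declared_nonstandard: bool = False

    def __post_init__(self) -> None:
        if not self.program:
            raise ValueError("aligner program must be non-empty")


def build_command(cmd: AlignerCommand, fragments: str | Path) -> list[str]:
    """Assemble the argv for one aligner run (SAM goes to stdout)."""
    if cmd.program == "bowtie2":
        return [
            cmd.program,
            *cmd.options,
            "-x",
            str(cmd.reference),
            "-U",
            str(fragments),
        ]
    # bwa-style positional interface; also used for nonstandard programs
    return [cmd.program, *cmd.options, str(cmd.reference), str(fragments)]


def _ensure_bwa_index(reference: str | Path) -> None:
    if not Path(f"{reference}.bwt").exists():
        subprocess.run(
            ["bwa", "index", str(reference)], check=True, capture_output=True
        )


def _sam_has_md(sam_path: str | Path) -> bool:
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            return rec.has_tag("MD")
    return True  # nothing mapped, nothing to repair


def ensure_md_tags(sam_path: str | Path, reference: str | Path) -> None:
    """Recompute MD tags in place (via ``samtools calmd``) when absent."""
    if _sam_has_md(sam_path):
        return
    repaired = subprocess.run(
        ["samtools", "calmd", "-S", str(sam_path), str(reference)],
        check=True,
        capture_output=True,
    )
    Path(sam_path).write_bytes(repaired.stdout)


def run_aligner(
    cmd: AlignerCommand, fragments: str | Path, out_sam: str | Path
) -> Path:
    """Align the fragment FASTQ against the reference, writing SAM.

    Indexes the reference first when needed (bwa only).  Unknown programs
    are refused unless ``declared_nonstandard`` is set.  Raises with the
    captured stderr when the aligner exits nonzero.
    """
    if cmd.program not in KNOWN_ALIGNERS and not cmd.declared_nonstandard:
        raise ValueError(
            f"aligner {cmd.program!r} is not one of {KNOWN_ALIGNERS}; pass "
            "declared_nonstandard=True (--allow-nonstandard) to run it anyway"
        )
    if shutil.which(cmd.program) is None:
        raise FileNotFoundError(
            f"aligner executable {cmd.program!r} not found on PATH"
        )
    if cmd.program == "bwa":
        _ensure_bwa_index(cmd.reference)
    argv = build_command(cmd, fragments)
    proc = subprocess.run(argv, capture_output=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"aligner failed ({' '.join(argv)}):\n{proc.stderr.decode(errors='replace')}"
        )
    out_sam = Path(out_sam)
    out_sam.write_bytes(proc.stdout)
    ensure_md_tags(out_sam, cmd.reference)
    return out_sam


# ---------------------------------------------------------------------------
# exact-match oracle aligner
# ---------------------------------------------------------------------------


def _load_reference(reference_fasta: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(reference_fasta), "fasta")
    }


_SEED_K = 16


def _build_seed_index(refs: dict[str, str]) -> dict[str, list[tuple[str, int]]]:
    """k-mer -> occurrence list over all references (exact-search accelerator)."""
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in refs.items():
        for i in range(len(seq) - _SEED_K + 1):
            index.setdefault(seq[i : i + _SEED_K], []).append((name, i))
    return index


def _occurrences(
    refs: dict[str, str],
    index: dict[str, list[tuple[str, int]]],
    probe: str,
    limit: int,
) -> list[tuple[str, int]]:
    """Up to ``limit`` occurrences of probe over all references (forward only)."""
    hits: list[tuple[str, int]] = []
    if len(probe) >= _SEED_K:
        for name, i in index.get(probe[: _SEED_K], ()):
            if refs[name][i : i + len(probe)] == probe:
                hits.append((name, i))
                if len(hits) >= limit:
                    return hits
        return hits
    for name, seq in refs.items():  # short probes: rare, fall back to scan
        start = seq.find(probe)
        while start != -1:
            hits.append((name, start))
            if len(hits) >= limit:
                return hits
            start = seq.find(probe, start + 1)
    return hits


def _place_unique(
    refs: dict[str, str],
    index: dict[str, list[tuple[str, int]]],
    frag: str,
) -> tuple[str, int, str] | None:
    """Unique placement of ``frag`` over all references/strands, else None."""
    fwd = _occurrences(refs, index, frag, limit=2)
    if len(fwd) > 1:
        return None
    rev = _occurrences(refs, index, reverse_complement(frag), limit=2)
    if len(fwd) + len(rev) != 1:
        return None  # absent, or ambiguous across strands/positions
    if fwd:
        name, start = fwd[0]
        return name, start, "+"
    name, start = rev[0]
    return name, start, "-"


def oracle_align(
    fragments: str | Path, reference_fasta: str | Path, out_sam: str | Path
) -> Path:
    """Place fragments by exhaustive exact-substring search, writing SAM.

    A fragment is mapped only when it occurs exactly once in the reference
    (counting both strands); ambiguous or absent fragments are written as
    unmapped records.  Mapped records get CIGAR ``<L>M``, MD ``<L>``,
    ``AS = L`` and ``NM = 0`` — the scoring a gapless perfect match earns.
    """
    refs = _load_reference(reference_fasta)
    seed_index = _build_seed_index(refs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in refs.items()],
            "PG": [{"ID": "oracle", "PN": "tnmap-oracle"}],
        }
    )
    tid = {name: i for i, name in enumerate(refs)}
    cache: dict[str, tuple[str, int, str] | None] = {}
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        with open_maybe_gzip(fragments) as handle:
            for rid, seq, qual in FastqGeneralIterator(handle):
                seq = seq.upper()
                if seq not in cache:
                    cache[seq] = _place_unique(refs, seed_index, seq)
                hit = cache[seq]
                rec = pysam.AlignedSegment(header)
                rec.query_name = rid.split()[0]
                if hit is None:
                    rec.is_unmapped = True
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array(qual)
                else:
                    name, start, strand = hit
                    rec.reference_id = tid[name]
                    rec.reference_start = start
                    rec.cigarstring = f"{len(seq)}M"
                    if strand == "-":
                        rec.is_reverse = True
                        rec.query_sequence = reverse_complement(seq)
                        rec.query_qualities = pysam.qualitystring_to_array(qual[::-1])
                    else:
                        rec.query_sequence = seq
                        rec.query_qualities = pysam.qualitystring_to_array(qual)
                    rec.mapping_quality = 60
                    rec.set_tag("AS", len(seq))
                    rec.set_tag("MD", str(len(seq)))
                    rec.set_tag("NM", 0)
                out.write(rec)
    return out_sam
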