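import pandas as pd
import pysam
import pytest
from hypothesis import HealthCheck, settings

from tnmap.aligner import oracle_align
from tnmap.readprep import TrimConfig, process_fastq
from tnmap.samfilter import FilterConfig, call_insertions
from tnmap.simulate import SimConfig, simulate_library, truth_to_insertion_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_library(tmp_path_factory):
    """A small simulated mutant library: 400 insertions on 60 kb, tsd 8."""
    out = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(
        seed=11, genome_length=60_000, n_genes=50, n_insertions=400, tsd_length=8
    )
    paths = simulate_library(cfg, out)
    truth = pd.read_csv(paths["truth"], sep="\t", comment="#")
    return {"cfg": cfg, "paths": paths, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def small_pipeline(small_library):
    """readprep + oracle alignment + insertion calling on the small library."""
    cfg = small_library["cfg"]
    d = small_library["dir"]
    paths = small_library["paths"]
    prep = process_fastq(
        paths["fastq"], TrimConfig(motifs=[cfg.motif]), d / "fragments.fastq"
    )
    sam = oracle_align(d / "fragments.fastq", paths["fasta"], d / "oracle.sam")
    table, stats = call_insertions(
        sam, FilterConfig(max_mismatch=0, min_align_score=30, collapse_distance=8)
    )
    expected = truth_to_insertion_table(small_library["truth"], tsd_length=8)
    return {
        "prep": prep,
        "sam": sam,
        "table": table,
        "stats": stats,
        "expected": expected,
    }


def write_sam(path, records, reference_name="chr1", reference_length=100_000):
    """Write a SAM file from (name, pos0, cigar, reverse, md, as_score) tuples.

    md/as_score may be None to omit the tag; pos0 of None means unmapped.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": reference_name, "LN": reference_length}],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, pos0, cigar, reverse, md, as_score in records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            if pos0 is None:
                rec.is_unmapped = True
                rec.query_sequence = "ACGT"
                out.write(rec)
                continue
            rec.reference_id = 0
            rec.reference_start = pos0
            rec.cigarstring = cigar
            rec.is_reverse = reverse
            length = sum(
                n for n, op in _cigar_tuples(cigar) if op in "MIS=X"
            )
            rec.query_sequence = "A" * length
            rec.mapping_quality = 60
            if md is not None:
                rec.set_tag("MD", md)
            if as_score is not None:
                rec.set_tag("AS", as_score)
            out.write(rec)
    return path


def _cigar_tuples(cigar):
    import re

    return [(int(n), op) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]
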