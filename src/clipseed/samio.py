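"""Reading and writing the pipeline's on-disk formats.

SAM (via pysam) carries the alignments; MD and NM tags are always emitted
so that mismatches and deletions survive a round trip without the reference.
The UMI travels in the read name as a ``#<umi>`` suffix.  FASTA (via
Biopython) carries reference transcripts and miRNA sequences, BED6 the
region annotation (name = ``transcriptid|region``), and TSV the truth
table and count tables.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .process import AlignedRead

logger = logging.getLogger(__name__)

_DNA_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def _comp(base: str) -> str:
    return _DNA_COMP[base]


def _revcomp(seq: str) -> str:
    return "".join(_DNA_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _cigar_and_md(read: AlignedRead) -> tuple[list[tuple[int, int]], str]:
    """CIGAR tuples and MD tag from the block/mismatch/deletion records."""
    # genome-sense base identities for the MD tag
    if read.strand == "-":
        mm = {p: _comp(ref) for p, ref, _ in read.mismatches}
        dels = {p: _comp(ref) for p, ref in read.deletions}
    else:
        mm = {p: ref for p, ref, _ in read.mismatches}
        dels = {p: ref for p, ref in read.deletions}
    cigar: list[tuple[int, int]] = []
    md_parts: list[str] = []
    run = 0  # matched/mismatched bases since last MD event

    def flush_match(n):
        if n > 0:
            if cigar and cigar[-1][0] == 0:
                cigar[-1] = (0, cigar[-1][1] + n)
            else:
                cigar.append((0, n))

    prev_end = None
    match_run = 0
    in_del = False
    for bs, be in read.blocks:
        if prev_end is not None and bs > prev_end:
            flush_match(match_run)
            match_run = 0
            cigar.append((3, bs - prev_end))  # N
        prev_end = be
        for p in range(bs, be):
            if p in dels:
                flush_match(match_run)
                match_run = 0
                if cigar and cigar[-1][0] == 2:
                    cigar[-1] = (2, cigar[-1][1] + 1)
                else:
                    cigar.append((2, 1))
                if in_del:
                    md_parts.append(dels[p])
                else:
                    md_parts.append(f"{run}^{dels[p]}")
                run = 0
                in_del = True
            elif p in mm:
                match_run += 1
                md_parts.append(f"{run}{mm[p]}")
                run = 0
                in_del = False
            else:
                match_run += 1
                run += 1
                in_del = False
    flush_match(match_run)
    md_parts.append(str(run))
    return cigar, "".join(md_parts)


def write_sam(
    reads: Sequence[AlignedRead],
    reference_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write reads as coordinate-sorted SAM with MD/NM tags.

    The header carries only @HD and @SQ lines so that identical inputs
    produce byte-identical files.
    """
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(reference_lengths[n])} for n in names],
    }
    ref_idx = {n: i for i, n in enumerate(names)}
    ordered = sorted(reads, key=lambda r: (ref_idx[r.reference], r.start, r.name))
    with pysam.AlignmentFile(path, "w", header=header, add_sam_header=True) as fh:
        for read in ordered:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"{read.name}#{read.umi}" if read.umi else read.name
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = ref_idx[read.reference]
            a.reference_start = read.start
            a.mapping_quality = 255
            cigar, md = _cigar_and_md(read)
            a.cigartuples = cigar
            seq = read.sequence
            if seq is not None and read.strand == "-":
                seq = _revcomp(seq)  # SAM stores reference-forward orientation
            a.query_sequence = seq
            nm = len(read.mismatches) + len(read.deletions)
            tags = [("NM", nm), ("MD", md)]
            if read.copy_number != 1:
                tags.append(("XC", int(read.copy_number)))
            a.set_tags(tags)
            fh.write(a)


def sam_reference_lengths(path: str) -> dict[str, int]:
    """Reference name -> length map from the SAM @SQ header."""
    with pysam.AlignmentFile(path, "r") as fh:
        return dict(zip(fh.references, fh.lengths))


def read_sam(path: str) -> list[AlignedRead]:
    """Parse a SAM file back into :class:`AlignedRead` records.

    Mismatch and deletion identities are reconstructed from the MD tag;
    minus-strand base identities are complemented into transcript sense.
    """
    out = []
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            qname = a.query_name
            if "#" in qname:
                name, umi = qname.rsplit("#", 1)
            else:
                name, umi = qname, None
            strand = "-" if a.is_reverse else "+"
            # blocks: split on N only; deletions stay inside a block
            blocks: list[tuple[int, int]] = []
            pos = a.reference_start
            for op, ln in a.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D advance the reference
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], pos + ln)
                    else:
                        blocks.append((pos, pos + ln))
                    pos += ln
                elif op == 3:  # N
                    pos += ln
            qseq = a.query_sequence
            mismatches = []
            deletions = []
            for qpos, rpos, refbase in a.get_aligned_pairs(with_seq=True):
                if rpos is None:
                    continue
                if qpos is None:
                    b = refbase.upper()
                    deletions.append((rpos, _comp(b) if strand == "-" else b))
                elif refbase is not None and refbase.islower():
                    ref = refbase.upper()
                    obs = qseq[qpos]
                    if strand == "-":
                        ref, obs = _comp(ref), _comp(obs)
                    mismatches.append((rpos, ref, obs))
            seq = qseq
            if seq is not None and strand == "-":
                seq = _revcomp(seq)
            copy_number = a.get_tag("XC") if a.has_tag("XC") else 1
            out.append(
                AlignedRead(
                    name=name,
                    umi=umi,
                    reference=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    strand=strand,
                    blocks=tuple(blocks),
                    sequence=seq,
                    mismatches=tuple(sorted(mismatches)),
                    deletions=tuple(sorted(deletions)),
                    copy_number=int(copy_number),
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / BED / TSV
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_region_bed(reference, path: str) -> None:
    """BED6 of transcript regions; name = ``transcriptid|region``."""
    with open(path, "w") as fh:
        for tx in reference.transcripts:
            for label, (s, e) in (
                ("5'UTR", tx.utr5), ("CDS", tx.cds), ("3'UTR", tx.utr3)
            ):
                fh.write(f"{tx.id}\t{s}\t{e}\t{tx.id}|{label}\t0\t+\n")


def read_region_bed(path: str) -> dict[str, list[tuple[int, int, str]]]:
    regions: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, name = line.split("\t")[:4]
            label = name.rsplit("|", 1)[-1]
            regions.setdefault(chrom, []).append((int(s), int(e), label))
    return regions


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
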