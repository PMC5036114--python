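"""File formats: paired FASTQ, a minimal SAM dialect, and TSV tables.

FASTQ pairs are read/written as synchronized ``_R1``/``_R2`` files
(phred33, gzip transparent).  SAM handling goes through pysam; alignment
records are surfaced as a light dataclass carrying the fields the QC
statistics need (FLAG, RNAME, 1-based POS, PNEXT, TLEN).  Truth SAM
output from the simulator writes two proper-pair records per read pair
with the signed template length on the leftmost mate.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import ReadPairRecord, SimulatedLibrary

__all__ = [
    "AlignmentRecord",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_sam",
    "write_truth_sam",
    "truth_alignments",
    "write_fasta",
]

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal alignment record (positions 1-based as in the SAM text)."""

    qname: str
    flag: int
    reference_name: str | None
    pos: int  # 1-based leftmost; 0 when unmapped
    mate_pos: int
    tlen: int

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PAIRED) and bool(self.flag & FLAG_PROPER)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def start0(self) -> int:
        """0-based leftmost position."""
        return self.pos - 1


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _strip_mate(name: str) -> str:
    name = name.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPairRecord]:
    """Stream synchronized read pairs from two FASTQ files.

    Raises on desynchronized mate ids (with the record index) and on
    truncated/mismatched record counts.
    """
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path_r1 if rec1 is None else path_r2
                raise ValueError(
                    f"paired FASTQ files out of sync: {short} ended at record {index}"
                )
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            if _strip_mate(id1) != _strip_mate(id2):
                raise ValueError(
                    f"mate ids disagree at record {index}: {id1!r} vs {id2!r}"
                )
            yield ReadPairRecord(
                pair_id=_strip_mate(id1),
                fwd_seq=seq1,
                rev_seq=seq2,
                fwd_qual=q1,
                rev_qual=q2,
            )
            index += 1


def write_fastq_pairs(pairs: Iterable[ReadPairRecord], path_r1, path_r2) -> None:
    with _open_text(path_r1, "wt") as h1, _open_text(path_r2, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.pair_id}/1\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            h2.write(f"@{p.pair_id}/2\n{p.rev_seq}\n+\n{p.rev_qual}\n")


def write_fasta(genomes: dict[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in genomes.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file (header with @SQ required)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as handle:
        for rec in handle:
            yield AlignmentRecord(
                qname=rec.query_name,
                flag=rec.flag,
                reference_name=rec.reference_name,
                pos=(rec.reference_start + 1) if rec.reference_start is not None and rec.reference_start >= 0 else 0,
                mate_pos=(rec.next_reference_start + 1) if rec.next_reference_start >= 0 else 0,
                tlen=rec.template_length,
            )


def truth_alignments(sim: SimulatedLibrary) -> Iterator[AlignmentRecord]:
    """Ground-truth proper-pair records for a simulated library.

    Two records per pair; the forward mate carries +fragment_length TLEN,
    the reverse mate -fragment_length.  Coordinates are reduced modulo the
    (circular) genome length.
    """
    ids = sim.member_ids
    glens = {m.member_id: m.genome_length for m in sim.spec.members}
    read_len = sim.read_len
    for i, (m, s, ln) in enumerate(
        zip(sim.member_idx.tolist(), sim.starts.tolist(), sim.lengths.tolist())
    ):
        ref = ids[m]
        L = glens[ref]
        qname = f"p{i:08d}"
        fwd_pos = (s % L) + 1
        rev_start = s + max(ln - read_len, 0)
        rev_pos = (rev_start % L) + 1
        yield AlignmentRecord(
            qname=qname,
            flag=FLAG_PAIRED | FLAG_PROPER | FLAG_MATE_REVERSE | FLAG_READ1,
            reference_name=ref,
            pos=fwd_pos,
            mate_pos=rev_pos,
            tlen=ln,
        )
        yield AlignmentRecord(
            qname=qname,
            flag=FLAG_PAIRED | FLAG_PROPER | FLAG_REVERSE | FLAG_READ2,
            reference_name=ref,
            pos=rev_pos,
            mate_pos=fwd_pos,
            tlen=-ln,
        )


def write_truth_sam(path, sim: SimulatedLibrary) -> None:
    """Write the simulator's ground-truth alignments as SAM text."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": m.member_id, "LN": int(m.genome_length)} for m in sim.spec.members
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {m.member_id: i for i, m in enumerate(sim.spec.members)}
        read_len = sim.read_len
        for rec in truth_alignments(sim):
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = rec.flag
            a.reference_id = tid[rec.reference_name]
            a.reference_start = rec.pos - 1
            a.next_reference_id = tid[rec.reference_name]
            a.next_reference_start = rec.mate_pos - 1
            a.template_length = rec.tlen
            a.mapping_quality = 60
            a.cigarstring = f"{min(read_len, abs(rec.tlen))}M"
            out.write(a)
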