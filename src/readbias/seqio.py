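"""File formats: FASTA references, read-start count tables, optional BAM input.

Internal coordinates are 0-based throughout; every user-facing text format is
1-based, and the writers state so in their header comments. The read-start
table is a simple TSV dialect ``chrom <TAB> pos(1-based) <TAB> count``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """A malformed input file."""


@dataclass
class ReferenceSequence:
    """A named sequence over {A,C,G,T,N}.

    Lowercase letters are uppercased on load; IUPAC ambiguity codes other
    than N are mapped to N.
    """

    name: str
    seq: str

    def __post_init__(self):
        self.seq = _VALID.sub("N", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)

    def window(self, pos: int, halfwidth: int) -> str:
        """Forward-strand substring of length 2*halfwidth+1 centred at pos."""
        if not halfwidth <= pos <= self.length - 1 - halfwidth:
            raise ValueError(f"position {pos} too close to a sequence end")
        return self.seq[pos - halfwidth : pos + halfwidth + 1]


@dataclass
class ReadStartTrack:
    """Sparse per-position counts of reads starting at each 0-based coordinate."""

    name: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        for pos, c in self.counts.items():
            if pos < 0 or c < 1:
                raise ValueError(f"invalid entry pos={pos} count={c}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, pos: int, count: int = 1) -> None:
        if count < 1 or pos < 0:
            raise ValueError(f"invalid entry pos={pos} count={count}")
        self.counts[pos] = self.counts.get(pos, 0) + count

    def freq(self, pos: int) -> int:
        return self.counts.get(pos, 0)


def read_fasta(path) -> list[ReferenceSequence]:
    """Load all records of a FASTA file, normalizing the alphabet."""
    records = [
        ReferenceSequence(name=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(refs: list[ReferenceSequence], path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in refs
    ]
    SeqIO.write(records, str(path), "fasta")  # biopython wraps at 60 columns


def read_starts_tsv(path) -> list[ReadStartTrack]:
    """Parse a ``chrom pos(1-based) count`` table into per-chromosome tracks.

    Lines starting with '#' are ignored; duplicate (chrom, pos) rows are
    summed. Tracks are returned in first-appearance order of the chromosome.
    """
    tracks: dict[str, ReadStartTrack] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            chrom, pos_s, count_s = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position or count"
                ) from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            if count < 1:
                raise FormatError(f"{path}:{lineno}: count must be >= 1")
            track = tracks.setdefault(chrom, ReadStartTrack(name=chrom))
            track.add(pos - 1, count)
    return list(tracks.values())


def write_starts_tsv(tracks: list[ReadStartTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tpos(1-based)\tcount\n")
        for track in tracks:
            for pos in sorted(track.counts):
                fh.write(f"{track.name}\t{pos + 1}\t{track.counts[pos]}\n")


def read_starts_bed(path) -> list[ReadStartTrack]:
    """BED3 alternative input: each row is one read start at the BED start.

    BED starts are already 0-based; every row contributes a count of 1.
    """
    tracks: dict[str, ReadStartTrack] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected BED3 columns")
            try:
                start = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer start") from None
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            track = tracks.setdefault(parts[0], ReadStartTrack(name=parts[0]))
            track.add(start, 1)
    return list(tracks.values())


def starts_from_bam(
    path,
    chrom: str,
    start_mode: str = "leftmost",
    skip_duplicates: bool = True,
) -> ReadStartTrack:
    """Count read starts on one chromosome of a coordinate-sorted, indexed BAM.

    Each mapped, primary, (optionally) non-duplicate alignment contributes one
    count. ``start_mode='leftmost'`` uses the leftmost aligned reference
    coordinate regardless of strand; ``'five-prime'`` uses the 5' end of the
    read (the rightmost coordinate for reverse-strand alignments).
    """
    import pysam

    if start_mode not in ("leftmost", "five-prime"):
        raise ValueError(f"unknown start_mode {start_mode!r}")
    bai = Path(str(path) + ".bai")
    csi = Path(str(path) + ".csi")
    if not bai.exists() and not csi.exists():
        raise FileNotFoundError(f"BAM index not found: {bai} (or {csi})")
    track = ReadStartTrack(name=chrom)
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(chrom):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if skip_duplicates and aln.is_duplicate:
                continue
            if start_mode == "five-prime" and aln.is_reverse:
                pos = aln.reference_end - 1
            else:
                pos = aln.reference_start
            track.add(pos, 1)
    return track
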