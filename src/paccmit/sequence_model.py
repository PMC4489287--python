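"""Core sequence types, seed extraction and seed-match scanning.

A miRNA recognises its target mainly through its *seed*, a short stretch
of 6–8 nucleotides near the 5' end (canonically positions 2–8).  A *seed
match* is the exact reverse complement of the seed occurring on the mRNA
sense strand; this module finds all such matches in a transcript.

Coordinates are 1-based inclusive in every user-facing structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

__all__ = [
    "Alphabet",
    "Region",
    "MicroRNA",
    "SeedSpec",
    "Transcript",
    "SeedMatchSite",
    "normalize_sequence",
    "extract_seed",
    "seed_match_motif",
    "scan_sites",
    "read_mirna_fasta",
    "read_transcript_fasta",
]

_DNA = frozenset("ACGT")
_RNA = frozenset("ACGU")
_ALLOWED_RAW = frozenset("ACGTUacgtu \t\r\n")

_RC_DNA = str.maketrans("ACGT", "TGCA")


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class Region(str, Enum):
    UTR3 = "UTR3"
    CDS = "CDS"


def normalize_sequence(raw: str, target_alphabet: Union[Alphabet, str]) -> str:
    """Uppercase ``raw``, strip whitespace and convert to the target alphabet.

    T and U are interconverted as needed.  Ambiguity codes (N, R, ...) and
    any other non-nucleotide character are rejected with the 1-based
    position of the first offender (counted in the raw string, whitespace
    included).
    """
    target = Alphabet(target_alphabet)
    for i, ch in enumerate(raw, start=1):
        if ch not in _ALLOWED_RAW:
            raise ValueError(
                f"invalid character {ch!r} at position {i}: only A/C/G/T/U "
                "(any case) and whitespace are accepted; ambiguity codes are not"
            )
    seq = "".join(raw.split()).upper()
    if target is Alphabet.DNA:
        return seq.replace("U", "T")
    return seq.replace("T", "U")


@dataclass(frozen=True)
class MicroRNA:
    """An accession-identified small RNA, sequence written 5'->3'."""

    accession: str
    sequence: str
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence, Alphabet.RNA))
        if not self.accession:
            raise ValueError("miRNA accession must be non-empty")
        if len(self.sequence) < 9:
            raise ValueError(
                f"miRNA {self.accession}: sequence length {len(self.sequence)} < 9"
            )


@dataclass(frozen=True)
class SeedSpec:
    """Seed window on the miRNA: 1-based ``start`` from the 5' end, ``length`` in 6..8.

    The default (start=2, length=7) is the canonical 2–8 seed, matched on
    the mRNA as a 7-mer.
    """

    start: int = 2
    length: int = 7

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"seed start must be >= 1, got {self.start}")
        if self.length not in (6, 7, 8):
            raise ValueError(f"seed length must be 6, 7 or 8, got {self.length}")


@dataclass(frozen=True)
class Transcript:
    """A DNA sequence tagged as 3' UTR or CDS; the search space for sites."""

    id: str
    region: Region
    sequence: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence, Alphabet.DNA))
        if not self.id:
            raise ValueError("transcript id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SeedMatchSite:
    """One exact seed match: 1-based inclusive ``start`` on the transcript.

    ``conserved`` and ``accessible`` stay ``None`` until the corresponding
    filter has produced a verdict.
    """

    transcript_id: str
    start: int
    length: int
    conserved: bool | None = None
    accessible: bool | None = None

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1


def extract_seed(mirna: MicroRNA, spec: SeedSpec = SeedSpec()) -> str:
    """Return the seed subsequence at miRNA positions [start, start+length-1]."""
    end = spec.start + spec.length - 1
    if end > len(mirna.sequence):
        raise ValueError(
            f"seed window [{spec.start}, {end}] exceeds miRNA {mirna.accession} "
            f"length {len(mirna.sequence)}"
        )
    return mirna.sequence[spec.start - 1 : end]


def seed_match_motif(seed: str) -> str:
    """Reverse complement of an RNA seed, written 5'->3' in DNA letters.

    This is the exact motif searched on the mRNA sense strand; only
    Watson–Crick pairing is considered (no G:U wobble).
    """
    if not set(seed) <= _RNA:
        raise ValueError(f"seed must be RNA over A/C/G/U, got {seed!r}")
    return seed.replace("U", "T").translate(_RC_DNA)[::-1]


def scan_sites(transcript: Transcript, motif: str) -> list[SeedMatchSite]:
    """All 1-based starts of exact (possibly overlapping) motif occurrences.

    Returns an empty list when the motif is longer than the transcript.
    """
    if not set(motif) <= _DNA:
        raise ValueError(f"motif must be DNA over A/C/G/T, got {motif!r}")
    sites: list[SeedMatchSite] = []
    seq = transcript.sequence
    pos = seq.find(motif)
    while pos != -1:
        sites.append(SeedMatchSite(transcript.id, pos + 1, len(motif)))
        pos = seq.find(motif, pos + 1)
    return sites


def read_mirna_fasta(path: Union[str, Path]) -> list[MicroRNA]:
    """Read miRNAs from FASTA; the first header token is the accession,
    the remainder (if any) the name."""
    mirnas: list[MicroRNA] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description.split(None, 1)[1] if " " in rec.description else None
        if rec.id in seen:
            raise ValueError(f"duplicate miRNA accession in FASTA: {rec.id}")
        seen.add(rec.id)
        mirnas.append(MicroRNA(accession=rec.id, sequence=str(rec.seq), name=name))
    return mirnas


def read_transcript_fasta(path: Union[str, Path], region: Union[Region, str]) -> list[Transcript]:
    """Read transcripts from FASTA, tagging each with ``region``."""
    region = Region(region)
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.description.split(None, 1)[1] if " " in rec.description else None
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id in FASTA: {rec.id}")
        seen.add(rec.id)
        out.append(Transcript(id=rec.id, region=region, sequence=str(rec.seq), gene_name=gene))
    return out
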