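"""Accessibility and conservation verdicts for individual seed-match sites.

Accessibility: a site counts as accessible when a 4-mer inside it is
unpaired (all dots in dot-bracket notation) in at least 20% of the
transcript's sampled secondary structures.  The *loose* policy accepts any
4-mer window inside the site; the *strict* policy requires the window at
the site's 3' end.  Both thresholds are inclusive ("at least 20%").

The 3' end is taken in the mRNA frame: the site is a substring of the
transcript written 5'->3', so its 3' end is its right end (offsets 3..6
of a 7-mer site).

Conservation: a site is conserved when, in at least ``min_other_species``
non-reference rows of an ortholog alignment, the aligned columns of the
site are gap-free and identical to the reference site sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

from Bio import SeqIO

from .sequence_model import SeedMatchSite

__all__ = [
    "AccessibilityMode",
    "AccessibilityPolicy",
    "StructureEnsemble",
    "OrthologAlignment",
    "unpaired_window_fraction",
    "is_accessible",
    "map_reference_window",
    "is_conserved",
    "read_ensemble_file",
    "read_alignment_fasta",
]


class AccessibilityMode(str, Enum):
    OFF = "off"
    LOOSE = "loose"
    STRICT = "strict"


@dataclass(frozen=True)
class AccessibilityPolicy:
    mode: AccessibilityMode = AccessibilityMode.OFF
    window_length: int = 4
    min_fraction: float = 0.20

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", AccessibilityMode(self.mode))
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError(f"min_fraction must be in [0,1], got {self.min_fraction}")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")


def _check_balanced(struct: str) -> bool:
    depth = 0
    for ch in struct:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
    return depth == 0


@dataclass(frozen=True)
class StructureEnsemble:
    """Sampled secondary structures of one transcript, dot-bracket, one per line."""

    transcript_id: str
    structures: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        if not self.structures:
            raise ValueError(f"ensemble for {self.transcript_id} has no structures")
        n = len(self.structures[0])
        for i, s in enumerate(self.structures):
            if len(s) != n:
                raise ValueError(
                    f"ensemble for {self.transcript_id}: structure {i + 1} has length "
                    f"{len(s)} != {n}"
                )
            if not set(s) <= {".", "(", ")"}:
                raise ValueError(
                    f"ensemble for {self.transcript_id}: structure {i + 1} has characters "
                    "outside '.', '(', ')'"
                )
            if not _check_balanced(s):
                raise ValueError(
                    f"ensemble for {self.transcript_id}: structure {i + 1} has "
                    "unbalanced brackets"
                )

    @property
    def length(self) -> int:
        return len(self.structures[0])


def unpaired_window_fraction(
    ensemble: StructureEnsemble, start: int, window_length: int
) -> float:
    """Fraction of structures whose window [start, start+window_length-1]
    (1-based) is entirely unpaired."""
    end = start + window_length - 1
    if start < 1 or end > ensemble.length:
        raise ValueError(
            f"window [{start}, {end}] out of bounds for transcript "
            f"{ensemble.transcript_id} of length {ensemble.length}"
        )
    target = "." * window_length
    hits = sum(1 for s in ensemble.structures if s[start - 1 : end] == target)
    return hits / len(ensemble.structures)


def is_accessible(
    site: SeedMatchSite, ensemble: StructureEnsemble, policy: AccessibilityPolicy
) -> bool:
    """Apply the accessibility policy to one site.

    loose: any ``window_length``-mer fully inside the site reaches
    ``min_fraction``; strict: only the window at the site's 3' end counts.
    """
    if policy.mode is AccessibilityMode.OFF:
        raise ValueError("accessibility policy is off; no verdict to compute")
    if site.transcript_id != ensemble.transcript_id:
        raise ValueError(
            f"site transcript {site.transcript_id!r} does not match ensemble "
            f"{ensemble.transcript_id!r}"
        )
    w = policy.window_length
    if w > site.length:
        raise ValueError("accessibility window longer than the site")
    if policy.mode is AccessibilityMode.STRICT:
        offsets = [site.length - w]
    else:
        offsets = list(range(site.length - w + 1))
    return any(
        unpaired_window_fraction(ensemble, site.start + off, w) >= policy.min_fraction
        for off in offsets
    )


@dataclass(frozen=True)
class OrthologAlignment:
    """Gapped multi-species alignment of one transcript; reference row first."""

    transcript_id: str
    rows: tuple[tuple[str, str], ...]  # (species label, aligned sequence)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple((lab, seq) for lab, seq in self.rows))
        if len(self.rows) < 1:
            raise ValueError("alignment needs at least the reference row")
        width = len(self.rows[0][1])
        for lab, seq in self.rows:
            if len(seq) != width:
                raise ValueError(
                    f"alignment {self.transcript_id}: row {lab!r} has length "
                    f"{len(seq)} != {width}"
                )

    @property
    def reference(self) -> str:
        return self.rows[0][1]

    @property
    def n_other_species(self) -> int:
        return len(self.rows) - 1

    def reference_ungapped(self) -> str:
        return self.reference.replace("-", "")


def map_reference_window(alignment: OrthologAlignment, start: int, length: int) -> list[int]:
    """Alignment-column indices (1-based) of reference positions
    start..start+length-1, walking the reference row and skipping gaps."""
    if start < 1:
        raise ValueError("window start must be >= 1")
    cols: list[int] = []
    ungapped = 0
    last_needed = start + length - 1
    for col, ch in enumerate(alignment.reference, start=1):
        if ch == "-":
            continue
        ungapped += 1
        if ungapped >= start:
            cols.append(col)
        if ungapped == last_needed:
            return cols
    raise ValueError(
        f"window [{start}, {last_needed}] extends beyond the ungapped reference "
        f"length {ungapped} for {alignment.transcript_id}"
    )


def is_conserved(
    site: SeedMatchSite, alignment: OrthologAlignment, min_other_species: int
) -> bool:
    """True iff >= ``min_other_species`` non-reference rows carry the exact,
    gap-free reference site sequence at the mapped alignment columns."""
    if min_other_species < 0:
        raise ValueError("min_other_species must be >= 0")
    if min_other_species > alignment.n_other_species:
        raise ValueError(
            f"min_other_species={min_other_species} exceeds the "
            f"{alignment.n_other_species} non-reference rows of {alignment.transcript_id}"
        )
    if min_other_species == 0:
        return True
    cols = map_reference_window(alignment, site.start, site.length)
    ref_site = "".join(alignment.reference[c - 1] for c in cols)
    n_ok = 0
    for _, seq in alignment.rows[1:]:
        other = "".join(seq[c - 1] for c in cols)
        if "-" not in other and other == ref_site:
            n_ok += 1
    return n_ok >= min_other_species


# -- file formats -------------------------------------------------------------


def read_ensemble_file(path: Union[str, Path]) -> dict[str, StructureEnsemble]:
    """Parse a dot-bracket ensemble file.

    Format: a line ``>transcript_id`` starts each record; every following
    non-empty line is one structure of that transcript.
    """
    ensembles: dict[str, StructureEnsemble] = {}
    current_id: str | None = None
    current: list[str] = []

    def flush() -> None:
        if current_id is not None:
            if current_id in ensembles:
                raise ValueError(f"duplicate ensemble for transcript {current_id}")
            ensembles[current_id] = StructureEnsemble(current_id, tuple(current))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            current_id = line[1:].split()[0]
            current = []
        else:
            if current_id is None:
                raise ValueError("structure line before any '>' header")
            current.append(line)
    flush()
    return ensembles


def read_alignment_fasta(path: Union[str, Path]) -> OrthologAlignment:
    """Read one aligned multi-FASTA; the first record is the reference row and
    its id names the transcript."""
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return OrthologAlignment(transcript_id=rows[0][0], rows=tuple(rows))
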