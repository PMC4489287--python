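"""Empirical null for coding sequences: synonymous-codon shuffling.

Seed matches inside a CDS sit on top of the protein-coding signal, so a
plain Markov background would misstate their expected frequency.  Instead,
the CDS statistic compares the observed seed-match count against
randomized coding sequences that preserve BOTH the amino-acid sequence and
the exact codon multiset (hence codon usage): codons are permuted uniformly
at random within each synonymous group.  The empirical P-value uses the
add-one estimator

    p = (1 + #{null >= observed}) / (1 + n_shuffles),

which is never zero and is super-uniform under the null.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .sequence_model import Region, SeedMatchSite, Transcript, scan_sites
from .site_filters import OrthologAlignment, is_conserved

__all__ = [
    "CodonSequence",
    "EmpiricalTest",
    "codonize",
    "synonymous_shuffle",
    "count_occurrences",
    "transcript_rng",
    "cds_empirical_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodonSequence:
    """A CDS partitioned into codons plus its translation ('*' = stop)."""

    transcript_id: str
    codons: tuple[str, ...]
    protein: str

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


def codonize(cds: Transcript) -> CodonSequence:
    """Partition a CDS into codons and translate with the standard code.

    Internal stop codons are permitted (they form their own synonymous
    group) but logged, since they usually indicate a frame problem.
    """
    if cds.region is not Region.CDS:
        raise ValueError(f"transcript {cds.id} is not tagged as CDS")
    if len(cds.sequence) % 3 != 0:
        raise ValueError(
            f"CDS {cds.id}: length {len(cds.sequence)} is not divisible by 3"
        )
    codons = tuple(cds.sequence[i : i + 3] for i in range(0, len(cds.sequence), 3))
    protein = str(Seq(cds.sequence).translate())
    if "*" in protein[:-1]:
        logger.info("CDS %s contains internal stop codon(s)", cds.id)
    return CodonSequence(transcript_id=cds.id, codons=codons, protein=protein)


def synonymous_shuffle(codons: CodonSequence, rng: np.random.Generator) -> CodonSequence:
    """Permute codons uniformly at random within each synonymous group.

    Positions coding the same amino acid exchange their codons, so the
    protein sequence and the codon multiset are both preserved exactly.
    """
    new = list(codons.codons)
    groups: dict[str, list[int]] = {}
    for i, aa in enumerate(codons.protein):
        groups.setdefault(aa, []).append(i)
    for positions in groups.values():
        if len(positions) < 2:
            continue
        perm = rng.permutation(len(positions))
        pool = [codons.codons[p] for p in positions]
        for dst, src in zip(positions, perm):
            new[dst] = pool[src]
    return CodonSequence(
        transcript_id=codons.transcript_id, codons=tuple(new), protein=codons.protein
    )


def count_occurrences(sequence: str, motif: str) -> int:
    """Number of (possibly overlapping) motif occurrences in ``sequence``."""
    n = 0
    pos = sequence.find(motif)
    while pos != -1:
        n += 1
        pos = sequence.find(motif, pos + 1)
    return n


def transcript_rng(master_seed: int, transcript_id: str) -> np.random.Generator:
    """Independent RNG stream per transcript, derived from the master seed
    and the transcript id, so results do not depend on processing order."""
    digest = hashlib.sha256(transcript_id.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


@dataclass(frozen=True)
class EmpiricalTest:
    """Add-one permutation test result for one miRNA-CDS pair."""

    observed_count: int
    null_counts: tuple[int, ...]
    n_shuffles: int
    p_value: float
    rng_seed: int


def cds_empirical_pvalue(
    cds: Transcript,
    motif: str,
    n_shuffles: int = 999,
    rng_seed: int = 0,
    alignment: Optional[OrthologAlignment] = None,
    min_other_species: int = 0,
) -> EmpiricalTest:
    """Empirical over-representation P-value of ``motif`` in a CDS.

    The observed count is the number of seed-match sites in the real CDS
    (restricted to conserved sites when ``alignment`` is given); the null
    counts are raw occurrences in each synonymous shuffle, which makes the
    conservation-filtered P-value conservative.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    codons = codonize(cds)
    sites: list[SeedMatchSite] = scan_sites(cds, motif)
    if alignment is not None and min_other_species > 0:
        sites = [s for s in sites if is_conserved(s, alignment, min_other_species)]
    observed = len(sites)
    rng = transcript_rng(rng_seed, cds.id)
    null_counts = tuple(
        count_occurrences(synonymous_shuffle(codons, rng).sequence, motif)
        for _ in range(n_shuffles)
    )
    if observed == 0:
        p = 1.0
    else:
        p = (1 + sum(1 for c in null_counts if c >= observed)) / (1 + n_shuffles)
    return EmpiricalTest(
        observed_count=observed,
        null_counts=null_counts,
        n_shuffles=n_shuffles,
        p_value=p,
        rng_seed=rng_seed,
    )
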