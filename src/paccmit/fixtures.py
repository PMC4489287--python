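"""Seeded synthetic-data generator: miRNAs, transcripts with planted seed
matches, structure ensembles with controlled accessibility, and ortholog
alignments with a controlled conservation plan.

Everything is deterministic given ``rng_seed``, and every planted truth is
recorded in a manifest so downstream stages can be checked end to end
without any external data.  Planting overwrites the transcript in place
(lengths stay fixed); incidental background matches elsewhere are allowed,
so the manifest's per-pair expected counts come from re-scanning the final
sequences, not from the plant list.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .sequence_model import (
    MicroRNA,
    Region,
    SeedSpec,
    Transcript,
    extract_seed,
    scan_sites,
    seed_match_motif,
)
from .site_filters import OrthologAlignment, StructureEnsemble

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture", "make_ensemble"]

_BASES = np.array(list("ACGT"))
_RNA_BASES = np.array(list("ACGU"))
_SUBSTITUTE = {"A": "C", "C": "A", "G": "A", "T": "A"}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic data set.

    ``planted_sites`` is a list of (miRNA index, transcript index, 1-based
    position); indices are 0-based into the generated lists.
    ``accessibility_fractions`` maps (transcript index, 1-based window
    start) to the target fraction of structures in which that 4-mer window
    is unpaired; uncontrolled positions are unpaired in every structure.
    ``conservation_plan`` maps planted-site index to a conserved flag
    (sites absent from the map default to conserved when alignments are
    generated at all, i.e. when n_species >= 2).
    """

    n_mirnas: int = 3
    n_transcripts: int = 4
    transcript_length: int = 1000
    region: Region = Region.UTR3
    planted_sites: tuple[tuple[int, int, int], ...] = ()
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_structures: int = 0
    accessibility_fractions: Mapping[tuple[int, int], float] = field(default_factory=dict)
    n_species: int = 0
    conservation_plan: Mapping[int, bool] = field(default_factory=dict)
    mirna_length: int = 22
    seed_spec: SeedSpec = SeedSpec()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "planted_sites", tuple(tuple(p) for p in self.planted_sites))
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.region is Region.CDS and self.transcript_length % 3 != 0:
            raise ValueError("CDS transcript_length must be divisible by 3")
        m = self.seed_spec.length
        occupied: dict[int, list[tuple[int, int]]] = {}
        for mi, ti, pos in self.planted_sites:
            if not (0 <= mi < self.n_mirnas and 0 <= ti < self.n_transcripts):
                raise ValueError(f"planted site ({mi}, {ti}, {pos}) indexes out of range")
            if not (1 <= pos and pos + m - 1 <= self.transcript_length):
                raise ValueError(f"planted position {pos} illegal for seed length {m}")
            for a, b in occupied.get(ti, []):
                if pos <= b and pos + m - 1 >= a:
                    raise ValueError(
                        f"planted sites overlap on transcript index {ti} near position {pos}"
                    )
            occupied.setdefault(ti, []).append((pos, pos + m - 1))
        for (ti, wpos), f in self.accessibility_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"accessibility fraction {f} outside [0, 1]")
            if self.n_structures < 1:
                raise ValueError("accessibility_fractions requires n_structures >= 1")
            if not (1 <= wpos and wpos + 3 <= self.transcript_length):
                raise ValueError(f"controlled window at {wpos} out of transcript bounds")


@dataclass
class Fixture:
    """Generated objects plus the manifest of planted truths."""

    spec: FixtureSpec
    mirnas: list[MicroRNA]
    transcripts: list[Transcript]
    ensembles: dict[str, StructureEnsemble]
    alignments: dict[str, OrthologAlignment]
    manifest: dict[str, str]


def make_ensemble(
    transcript_id: str,
    length: int,
    n_structures: int,
    controlled_windows: Mapping[int, float],
    window_length: int = 4,
) -> StructureEnsemble:
    """Build ``n_structures`` dot-bracket structures of the given length.

    Each controlled window (1-based start -> fraction) is fully unpaired in
    ``round(fraction * n_structures)`` structures and fully base-paired in
    the rest; all other positions are unpaired everywhere.  Paired windows
    are closed by bracket blocks at the 3' tail of the molecule (properly
    nested), so the tail must not overlap any controlled window.
    """
    starts = sorted(controlled_windows)
    for a, b in zip(starts, starts[1:]):
        if a + window_length > b:
            raise ValueError(f"controlled windows at {a} and {b} overlap")
    tail_needed = window_length * len(starts)
    if starts and starts[-1] + window_length - 1 > length - tail_needed:
        raise ValueError(
            "controlled windows collide with the tail region reserved for closing brackets"
        )
    structures = []
    for j in range(n_structures):
        chars = ["."] * length
        paired = [s for s in starts if j >= round(controlled_windows[s] * n_structures)]
        tail = length  # exclusive end of the unused tail
        for s in paired:  # close later-opened windows first: reverse order at the tail
            for off in range(window_length):
                chars[s - 1 + off] = "("
        for s in reversed(paired):
            for off in range(window_length):
                chars[tail - window_length + off] = ")"
            tail -= window_length
        structures.append("".join(chars))
    return StructureEnsemble(transcript_id=transcript_id, structures=tuple(structures))


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate all synthetic inputs described by ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.rng_seed)
    comp = np.asarray(spec.base_composition, dtype=float)

    mirnas = [
        MicroRNA(
            accession=f"MIR{i:04d}",
            sequence="".join(rng.choice(_RNA_BASES, size=spec.mirna_length)),
        )
        for i in range(spec.n_mirnas)
    ]
    motifs = [seed_match_motif(extract_seed(m, spec.seed_spec)) for m in mirnas]

    seqs = [
        list(rng.choice(_BASES, size=spec.transcript_length, p=comp))
        for _ in range(spec.n_transcripts)
    ]
    for mi, ti, pos in spec.planted_sites:
        seqs[ti][pos - 1 : pos - 1 + spec.seed_spec.length] = list(motifs[mi])
    transcripts = [
        Transcript(id=f"TX{i:04d}", region=spec.region, sequence="".join(s))
        for i, s in enumerate(seqs)
    ]

    ensembles: dict[str, StructureEnsemble] = {}
    if spec.n_structures >= 1:
        per_tx: dict[int, dict[int, float]] = {}
        for (ti, wpos), f in spec.accessibility_fractions.items():
            per_tx.setdefault(ti, {})[wpos] = f
        for i, tx in enumerate(transcripts):
            ensembles[tx.id] = make_ensemble(
                tx.id, len(tx), spec.n_structures, per_tx.get(i, {})
            )

    alignments: dict[str, OrthologAlignment] = {}
    if spec.n_species >= 2:
        planted_by_tx: dict[int, list[tuple[int, int]]] = {}
        for site_idx, (_, ti, pos) in enumerate(spec.planted_sites):
            planted_by_tx.setdefault(ti, []).append((site_idx, pos))
        for i, tx in enumerate(transcripts):
            # one insertion column at the front exercises gap mapping
            ref_row = "-" + tx.sequence
            rows = [(tx.id, ref_row)]
            for sp in range(1, spec.n_species):
                other = list("A" + tx.sequence)
                for site_idx, pos in planted_by_tx.get(i, []):
                    if not spec.conservation_plan.get(site_idx, True):
                        mid = pos + spec.seed_spec.length // 2  # column = position + 1
                        other[mid] = _SUBSTITUTE[other[mid]]
                rows.append((f"species{sp}", "".join(other)))
            alignments[tx.id] = OrthologAlignment(transcript_id=tx.id, rows=tuple(rows))

    manifest: dict[str, str] = {
        "rng_seed": str(spec.rng_seed),
        "n_mirnas": str(spec.n_mirnas),
        "n_transcripts": str(spec.n_transcripts),
        "region": spec.region.value,
        "seed_start": str(spec.seed_spec.start),
        "seed_length": str(spec.seed_spec.length),
    }
    for idx, (mi, ti, pos) in enumerate(spec.planted_sites):
        conserved = spec.conservation_plan.get(idx, True) if spec.n_species >= 2 else ""
        manifest[f"planted:{idx}"] = (
            f"{mirnas[mi].accession},{transcripts[ti].id},{pos},conserved={conserved}"
        )
    for (ti, wpos), f in sorted(spec.accessibility_fractions.items()):
        achieved = round(f * spec.n_structures) / spec.n_structures
        manifest[f"accessibility:{transcripts[ti].id}:{wpos}"] = f"{achieved:.6g}"
    # truth = what scanning the final sequences finds, not the plant list
    for m, motif in zip(mirnas, motifs):
        for tx in transcripts:
            sites = scan_sites(tx, motif)
            if sites:
                manifest[f"pair:{m.accession},{tx.id}"] = ";".join(
                    str(s.start) for s in sites
                )
    return Fixture(
        spec=spec,
        mirnas=mirnas,
        transcripts=transcripts,
        ensembles=ensembles,
        alignments=alignments,
        manifest=manifest,
    )


def write_fixture(fixture: Fixture, outdir: Union[str, Path]) -> dict[str, Path]:
    """Dump all fixture files (FASTA, ensembles, alignments, manifest).

    Returns a map of logical name -> written path.  Byte-identical for a
    given spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mirna_path = outdir / "mirnas.fa"
    mirna_path.write_text(
        "".join(f">{m.accession}\n{m.sequence}\n" for m in fixture.mirnas)
    )
    paths["mirnas"] = mirna_path

    tx_path = outdir / "transcripts.fa"
    tx_path.write_text(
        "".join(f">{t.id}\n{t.sequence}\n" for t in fixture.transcripts)
    )
    paths["transcripts"] = tx_path

    if fixture.ensembles:
        ens_path = outdir / "ensembles.txt"
        chunks = []
        for tid in sorted(fixture.ensembles):
            ens = fixture.ensembles[tid]
            chunks.append(f">{tid}\n" + "\n".join(ens.structures) + "\n")
        ens_path.write_text("".join(chunks))
        paths["ensembles"] = ens_path

    if fixture.alignments:
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for tid in sorted(fixture.alignments):
            aln = fixture.alignments[tid]
            p = aln_dir / f"{tid}.fa"
            p.write_text("".join(f">{lab}\n{seq}\n" for lab, seq in aln.rows))
        paths["alignments"] = aln_dir

    manifest_path = outdir / "manifest.txt"
    manifest_path.write_text(
        "".join(f"{k}={v}\n" for k, v in sorted(fixture.manifest.items()))
    )
    paths["manifest"] = manifest_path
    return paths
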