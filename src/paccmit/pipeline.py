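"""End-to-end prediction pipeline: input reconciliation, scanning, filtering,
P-values, FDR ranking and output writing.

Mirrors a four-step workflow: (1) choose the algorithm (UTR Markov-binomial
or CDS codon-shuffle) and the precision filters, (2) select miRNAs,
(3) select transcripts, (4) choose FDR level, pair limit and output format.
The "database" is the pair of user-supplied FASTA files; requested
identifiers are reconciled against them into Used/Discarded groups.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cds_background import cds_empirical_pvalue
from .markov_background import MarkovModel, fit_markov, site_count_pvalue
from .ranking_stats import PredictionRecord, bh_adjust, rank_and_filter
from .sequence_model import (
    MicroRNA,
    Region,
    SeedSpec,
    Transcript,
    extract_seed,
    read_mirna_fasta,
    read_transcript_fasta,
    scan_sites,
    seed_match_motif,
)
from .site_filters import (
    AccessibilityMode,
    AccessibilityPolicy,
    OrthologAlignment,
    StructureEnsemble,
    is_accessible,
    is_conserved,
    read_alignment_fasta,
    read_ensemble_file,
)

__all__ = [
    "Algorithm",
    "OutputFormat",
    "PipelineConfig",
    "InputReconciliation",
    "OutputResult",
    "reconcile_inputs",
    "run_pipeline",
    "predict",
    "write_outputs",
    "read_alignments_dir",
    "PREDICTION_COLUMNS",
]

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = [
    "rank",
    "mirna_accession",
    "transcript_id",
    "gene_name",
    "site_count",
    "positions",
    "p_value",
    "p_adjusted",
]


class Algorithm(str, Enum):
    PACCMIT = "PACCMIT"
    PACCMIT_CDS = "PACCMIT_CDS"


class OutputFormat(str, Enum):
    TABLE = "table"
    CSV = "csv"
    WORKBOOK = "workbook"


@dataclass
class PipelineConfig:
    """Full run configuration; flags mirror these field names."""

    mirna_fasta: Optional[Union[str, Path]] = None
    transcript_fasta: Optional[Union[str, Path]] = None
    algorithm: Algorithm = Algorithm.PACCMIT
    conservation: bool = False
    min_other_species: Optional[int] = None  # None = all non-reference rows
    accessibility: AccessibilityMode = AccessibilityMode.OFF
    accessibility_min_fraction: float = 0.20
    accessibility_window: int = 4
    seed_spec: SeedSpec = field(default_factory=SeedSpec)
    markov_order: int = 1
    pseudocount: float = 1.0
    per_transcript_background: bool = False
    n_shuffles: int = 999
    alpha: float = 0.05
    max_pairs: Optional[int] = None
    rng_seed: int = 0
    inline_display_limit: int = 10000
    output_format: OutputFormat = OutputFormat.TABLE
    output_path: Optional[Union[str, Path]] = None
    ensembles_path: Optional[Union[str, Path]] = None
    alignments_dir: Optional[Union[str, Path]] = None
    requested_mirnas: Sequence[str] = ()
    requested_transcripts: Sequence[str] = ()
    abort_on_missing_ensemble: bool = True

    def __post_init__(self) -> None:
        self.algorithm = Algorithm(self.algorithm)
        self.accessibility = AccessibilityMode(self.accessibility)
        self.output_format = OutputFormat(self.output_format)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if (
            self.accessibility is not AccessibilityMode.OFF
            and self.algorithm is not Algorithm.PACCMIT
        ):
            raise ValueError("the accessibility filter is available for PACCMIT only")

    @property
    def region(self) -> Region:
        return Region.UTR3 if self.algorithm is Algorithm.PACCMIT else Region.CDS


@dataclass
class InputReconciliation:
    """Used/Discarded identifier groups plus the potential-target lists."""

    used_mirnas: list[str] = field(default_factory=list)
    discarded_mirnas: list[str] = field(default_factory=list)
    used_transcripts: list[str] = field(default_factory=list)
    discarded_transcripts: list[str] = field(default_factory=list)
    mirnas_with_targets: list[str] = field(default_factory=list)
    targeted_transcripts: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def reconcile_inputs(
    requested_ids: Sequence[str], available_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Split requested identifiers into (used, discarded) against the
    available set, deduplicating while preserving first occurrence.

    An empty request selects everything available.  A discarded id that
    looks like a version-suffixed form of an available one gets a log hint.
    """
    available_list = list(dict.fromkeys(available_ids))
    available = set(available_list)
    requested = list(dict.fromkeys(requested_ids))
    if not requested:
        return available_list, []
    used = [r for r in requested if r in available]
    discarded = [r for r in requested if r not in available]
    for d in discarded:
        base = d.rsplit(".", 1)[0]
        if "." in d and base in available:
            logger.warning(
                "id %r not found but %r is available: identifiers should not "
                "carry a version suffix",
                d,
                base,
            )
    return used, discarded


def read_alignments_dir(path: Union[str, Path]) -> dict[str, OrthologAlignment]:
    """Read every aligned multi-FASTA under ``path`` (*.fa / *.fasta),
    keyed by each file's reference (first-row) id."""
    out: dict[str, OrthologAlignment] = {}
    p = Path(path)
    files = sorted(list(p.glob("*.fa")) + list(p.glob("*.fasta")))
    for f in files:
        aln = read_alignment_fasta(f)
        out[aln.transcript_id] = aln
    return out


def predict(
    mirnas: Sequence[MicroRNA],
    transcripts: Sequence[Transcript],
    config: PipelineConfig,
    ensembles: Optional[dict[str, StructureEnsemble]] = None,
    alignments: Optional[dict[str, OrthologAlignment]] = None,
) -> tuple[InputReconciliation, list[PredictionRecord]]:
    """Core prediction on in-memory objects (the file-free heart of
    :func:`run_pipeline`)."""
    mirna_by_id = {m.accession: m for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}

    rec = InputReconciliation()
    rec.used_mirnas, rec.discarded_mirnas = reconcile_inputs(
        config.requested_mirnas, [m.accession for m in mirnas]
    )
    rec.used_transcripts, rec.discarded_transcripts = reconcile_inputs(
        config.requested_transcripts, [t.id for t in transcripts]
    )

    used_mirnas = [mirna_by_id[a] for a in rec.used_mirnas]
    used_tx = [tx_by_id[t] for t in rec.used_transcripts]

    accessibility_on = config.accessibility is not AccessibilityMode.OFF
    policy = AccessibilityPolicy(
        mode=config.accessibility,
        window_length=config.accessibility_window,
        min_fraction=config.accessibility_min_fraction,
    )
    if accessibility_on:
        ensembles = ensembles or {}
        missing = [t.id for t in used_tx if t.id not in ensembles]
        if missing and config.abort_on_missing_ensemble:
            raise ValueError(
                f"accessibility filter is on but no structure ensemble was "
                f"supplied for: {', '.join(missing)}"
            )
        for t in used_tx:
            if t.id in ensembles and ensembles[t.id].length != len(t):
                raise ValueError(
                    f"ensemble for {t.id} has structure length "
                    f"{ensembles[t.id].length} != transcript length {len(t)}"
                )
    if config.conservation:
        alignments = alignments or {}
        missing = [t.id for t in used_tx if t.id not in alignments]
        if missing:
            raise ValueError(
                f"conservation filter is on but no ortholog alignment was "
                f"supplied for: {', '.join(missing)}"
            )
        for t in used_tx:
            if alignments[t.id].reference_ungapped() != t.sequence:
                raise ValueError(
                    f"alignment reference row for {t.id} does not match the "
                    "transcript sequence once gaps are removed"
                )

    model: Optional[MarkovModel] = None
    if config.algorithm is Algorithm.PACCMIT and not config.per_transcript_background and used_tx:
        model = fit_markov(
            [t.sequence for t in used_tx],
            order=config.markov_order,
            pseudocount=config.pseudocount,
        )

    records: list[PredictionRecord] = []
    bad_cds: set[str] = set()
    for t in used_tx:
        if config.algorithm is Algorithm.PACCMIT_CDS and len(t) % 3 != 0:
            rec.errors.append(
                f"CDS {t.id}: length {len(t)} is not divisible by 3; skipped"
            )
            bad_cds.add(t.id)
    logger.info(
        "evaluating %d miRNAs x %d transcripts (%s)",
        len(used_mirnas),
        len(used_tx),
        config.algorithm.value,
    )

    min_other = config.min_other_species
    for mirna in used_mirnas:
        motif = seed_match_motif(extract_seed(mirna, config.seed_spec))
        for t in used_tx:
            if t.id in bad_cds:
                continue
            sites = scan_sites(t, motif)
            if not sites:
                continue
            if config.conservation:
                aln = alignments[t.id]
                k = aln.n_other_species if min_other is None else min_other
                for s in sites:
                    s.conserved = is_conserved(s, aln, k)
                sites = [s for s in sites if s.conserved]
            if accessibility_on and t.id in ensembles:
                for s in sites:
                    s.accessible = is_accessible(s, ensembles[t.id], policy)
                sites = [s for s in sites if s.accessible]
            if not sites:
                continue
            if config.algorithm is Algorithm.PACCMIT:
                m = (
                    model
                    if model is not None
                    else fit_markov(
                        [t.sequence],
                        order=config.markov_order,
                        pseudocount=config.pseudocount,
                    )
                )
                test_p = site_count_pvalue(m, len(t), motif, len(sites)).p_value
            else:
                aln = alignments.get(t.id) if config.conservation else None
                k = 0
                if config.conservation:
                    k = aln.n_other_species if min_other is None else min_other
                test_p = cds_empirical_pvalue(
                    t,
                    motif,
                    n_shuffles=config.n_shuffles,
                    rng_seed=config.rng_seed,
                    alignment=aln,
                    min_other_species=k,
                ).p_value
            records.append(
                PredictionRecord(
                    mirna_accession=mirna.accession,
                    transcript_id=t.id,
                    gene_name=t.gene_name,
                    site_count=len(sites),
                    positions=tuple(s.start for s in sites),
                    p_value=test_p,
                )
            )

    if records:
        adjusted = bh_adjust([r.p_value for r in records])
        records = [replace(r, p_adjusted=a) for r, a in zip(records, adjusted)]

    rec.mirnas_with_targets = sorted({r.mirna_accession for r in records})
    rec.targeted_transcripts = sorted({r.transcript_id for r in records})

    ranked = rank_and_filter(records, alpha=config.alpha, max_pairs=config.max_pairs)
    logger.info("%d candidate pairs, %d returned after FDR/ranking", len(records), len(ranked))
    return rec, ranked


def run_pipeline(config: PipelineConfig) -> tuple[InputReconciliation, list[PredictionRecord]]:
    """Load all configured input files and run :func:`predict`."""
    if config.mirna_fasta is None or config.transcript_fasta is None:
        raise ValueError("mirna_fasta and transcript_fasta are required")
    mirnas = read_mirna_fasta(config.mirna_fasta)
    transcripts = read_transcript_fasta(config.transcript_fasta, config.region)
    ensembles = (
        read_ensemble_file(config.ensembles_path) if config.ensembles_path else None
    )
    alignments = (
        read_alignments_dir(config.alignments_dir) if config.alignments_dir else None
    )
    return predict(mirnas, transcripts, config, ensembles=ensembles, alignments=alignments)


# -- output writing -----------------------------------------------------------


def _fmt_p(x: float) -> str:
    return f"{x:.6e}"


def predictions_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Predictions table with all cells pre-formatted as strings
    (floats in scientific notation, 6 significant digits)."""
    rows = [
        {
            "rank": str(r.rank),
            "mirna_accession": r.mirna_accession,
            "transcript_id": r.transcript_id,
            "gene_name": r.gene_name or "",
            "site_count": str(r.site_count),
            "positions": ",".join(str(p) for p in r.positions),
            "p_value": _fmt_p(r.p_value),
            "p_adjusted": _fmt_p(r.p_adjusted),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS, dtype=str)


@dataclass
class OutputResult:
    kind: str  # "table", "csv" or "workbook"
    path: Optional[Path] = None
    text: Optional[str] = None
    forced_csv: bool = False


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _overview_text(rec: InputReconciliation) -> str:
    lines = ["Input overview", "--------------"]
    for label, ids in [
        ("Discarded miRNAs", rec.discarded_mirnas),
        ("Used miRNAs", rec.used_mirnas),
        ("Used miRNAs with at least one potential target", rec.mirnas_with_targets),
        ("Discarded mRNAs", rec.discarded_transcripts),
        ("Used mRNAs", rec.used_transcripts),
        ("Used mRNAs that are potential targets", rec.targeted_transcripts),
    ]:
        lines.append(f"{label} ({len(ids)}): {', '.join(ids) if ids else '-'}")
    for e in rec.errors:
        lines.append(f"ERROR: {e}")
    return "\n".join(lines)


def write_outputs(
    reconciliation: InputReconciliation,
    records: Sequence[PredictionRecord],
    config: PipelineConfig,
) -> OutputResult:
    """Render or write the run output.

    CSV contains only the predictions table; the workbook carries seven
    sheets (three miRNA overviews, three mRNA overviews, predictions); the
    inline table mirrors overview + predictions.  More records than
    ``inline_display_limit`` forces CSV regardless of the requested format.
    """
    frame = predictions_frame(records)
    fmt = config.output_format
    forced = False
    if fmt is OutputFormat.TABLE and len(records) > config.inline_display_limit:
        logger.warning(
            "%d predictions exceed the inline display limit of %d; writing CSV instead",
            len(records),
            config.inline_display_limit,
        )
        fmt = OutputFormat.CSV
        forced = True

    if fmt is OutputFormat.TABLE:
        text = (
            _overview_text(reconciliation)
            + "\n\nPredictions\n-----------\n"
            + (frame.to_string(index=False) if len(frame) else "(none)")
        )
        return OutputResult(kind="table", text=text)

    out = Path(config.output_path) if config.output_path else Path("predictions.csv")
    if fmt is OutputFormat.CSV:
        if out.suffix.lower() != ".csv":
            out = out.with_suffix(".csv")
        _atomic_write_text(out, frame.to_csv(index=False))
        return OutputResult(kind="csv", path=out, forced_csv=forced)

    # workbook: seven sheets, openpyxl backend
    from openpyxl import Workbook

    wb = Workbook()
    sheets = [
        ("Discarded miRNAs", reconciliation.discarded_mirnas),
        ("Used miRNAs", reconciliation.used_mirnas),
        ("miRNAs with targets", reconciliation.mirnas_with_targets),
        ("Discarded mRNAs", reconciliation.discarded_transcripts),
        ("Used mRNAs", reconciliation.used_transcripts),
        ("Targeted mRNAs", reconciliation.targeted_transcripts),
    ]
    wb.remove(wb.active)
    for title, ids in sheets:
        ws = wb.create_sheet(title=title)
        ws.append(["id"])
        for i in ids:
            ws.append([i])
    ws = wb.create_sheet(title="Predictions")
    ws.append(PREDICTION_COLUMNS)
    for _, row in frame.iterrows():
        ws.append(list(row))
    if out.suffix.lower() not in (".xlsx", ".xlsm"):
        out = out.with_suffix(".xlsx")
    fd, tmp = tempfile.mkstemp(dir=out.parent, prefix=out.name, suffix=".tmp")
    os.close(fd)
    try:
        wb.save(tmp)
        os.replace(tmp, out)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return OutputResult(kind="workbook", path=out)
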