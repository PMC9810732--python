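"""Readers and writers for every external format the screen touches.

Coordinate conventions used throughout the package:

* everything lives in *transcript space* — positions are 0-based, intervals
  half-open ``[start, end)``, and the strand is always ``+`` (genome lifting
  is out of scope);
* a transcript's annotated CDS, when present, spans the start codon through
  the stop codon inclusive and its length is a multiple of 3.

Tabular outputs are tab-separated with ``#``-prefixed provenance comment
lines recording parameter values; readers skip those lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lincRNA")
ASSAYS = ("RPF", "RNA")
CONDITIONS = ("control", "case")

#: column order of the alignment TSV interchange format
ALIGNMENT_COLUMNS = [
    "read_id",
    "transcript_id",
    "five_prime_pos",
    "read_length",
    "sample_id",
    "assay",
]

VALID_BASES = frozenset("ACGTN")

# retention window for ribosome-protected fragments; the lower bound encodes
# the library's size selection (fragments of 18 nt and longer are kept)
DEFAULT_RPF_LENGTH_WINDOW = (18, 40)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with its biotype and optional annotated CDS.

    ``cds_start``/``cds_end`` (0-based half-open, spanning start codon
    through stop codon inclusive) are present iff the biotype is
    ``protein_coding``; they define the transcript's main ORF (mORF).
    """

    transcript_id: str
    sequence: str
    biotype: str = "lincRNA"
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if set(self.sequence) - VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValueError(
                f"{self.transcript_id}: invalid characters in sequence: {bad}"
            )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        has_cds = self.cds_start is not None and self.cds_end is not None
        if self.biotype == "protein_coding":
            if not has_cds:
                raise ValueError(
                    f"{self.transcript_id}: protein_coding transcript without CDS"
                )
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                    f"out of bounds for length {len(self.sequence)}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: CDS length not divisible by 3"
                )
        elif has_cds or self.cds_start is not None or self.cds_end is not None:
            raise ValueError(
                f"{self.transcript_id}: CDS coordinates on a non-coding transcript"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignment:
    """One read aligned to a transcript, reduced to its 5' end and length."""

    read_id: str
    transcript_id: str
    five_prime_pos: int
    read_length: int
    sample_id: str
    assay: str

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError(f"{self.read_id}: negative five_prime_pos")
        if self.read_length < 1:
            raise ValueError(f"{self.read_id}: non-positive read_length")
        if self.assay not in ASSAYS:
            raise ValueError(f"{self.read_id}: unknown assay {self.assay!r}")


def _write_provenance(handle, params: Mapping | None) -> None:
    if params:
        for key, value in params.items():
            handle.write(f"# {key}={value}\n")


def transcript_lengths(transcripts: Iterable[TranscriptRecord]) -> dict[str, int]:
    """Map transcript_id -> sequence length."""
    return {t.transcript_id: t.length for t in transcripts}


# ---------------------------------------------------------------------------
# transcripts


def read_transcripts(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> list[TranscriptRecord]:
    """Read transcript sequences, optionally joined with a CDS annotation.

    Without an annotation every entry defaults to biotype ``lincRNA``. With
    one, the annotation and the FASTA must cover exactly the same transcript
    set: annotation rows without a FASTA entry and FASTA entries without an
    annotation row are both errors.

    The annotation is a TSV with columns ``transcript_id``, ``biotype`` and,
    for protein-coding rows, ``cds_start``/``cds_end`` in transcript
    coordinates (0-based half-open).
    """
    fasta_path = Path(fasta_path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA entry {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"malformed FASTA: empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"malformed FASTA: no sequences in {fasta_path}")

    if annotation_path is None:
        return [TranscriptRecord(tid, seq) for tid, seq in seqs.items()]

    ann = pd.read_csv(annotation_path, sep="\t", comment="#", dtype={"transcript_id": str})
    required = {"transcript_id", "biotype"}
    if missing := required - set(ann.columns):
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    unknown = set(ann["transcript_id"]) - set(seqs)
    if unknown:
        raise ValueError(
            f"annotation rows without a FASTA entry: {sorted(unknown)[:5]}"
        )
    unannotated = set(seqs) - set(ann["transcript_id"])
    if unannotated:
        raise ValueError(
            f"FASTA entries without an annotation row: {sorted(unannotated)[:5]}"
        )

    records = []
    for row in ann.itertuples(index=False):
        tid = row.transcript_id
        cds_start = cds_end = None
        if row.biotype == "protein_coding":
            cds_start = int(row.cds_start)
            cds_end = int(row.cds_end)
        records.append(
            TranscriptRecord(tid, seqs[tid], row.biotype, cds_start, cds_end)
        )
    return records


def write_transcripts(
    transcripts: Sequence[TranscriptRecord],
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write transcripts as FASTA plus (optionally) the CDS annotation TSV."""
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, t.length, 80):
                fh.write(t.sequence[i : i + 80] + "\n")
    if annotation_path is not None:
        rows = [
            {
                "transcript_id": t.transcript_id,
                "biotype": t.biotype,
                "cds_start": "" if t.cds_start is None else t.cds_start,
                "cds_end": "" if t.cds_end is None else t.cds_end,
            }
            for t in transcripts
        ]
        pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments


def _validate_alignments(
    df: pd.DataFrame, lengths: Mapping[str, int] | None
) -> None:
    if (df["five_prime_pos"] < 0).any():
        bad = df.loc[df["five_prime_pos"] < 0, "read_id"].iloc[0]
        raise ValueError(f"negative five_prime_pos (first offender: {bad})")
    if lengths is not None:
        unknown = set(df["transcript_id"]) - set(lengths)
        if unknown:
            raise ValueError(f"unknown transcript_id(s): {sorted(unknown)[:5]}")
        tx_len = df["transcript_id"].map(lengths)
        over = df["five_prime_pos"] + df["read_length"] > tx_len
        if over.any():
            bad = df.loc[over, "read_id"].iloc[0]
            raise ValueError(
                f"alignment extends past transcript end (first offender: {bad})"
            )
    bad_assay = set(df["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ValueError(f"unknown assay value(s): {sorted(bad_assay)}")


def read_alignments(
    path: str | Path,
    assay: str | None = None,
    fmt: str | None = None,
    transcript_lengths: Mapping[str, int] | None = None,
    sample_id: str | None = None,
    rpf_length_window: tuple[int, int] = DEFAULT_RPF_LENGTH_WINDOW,
) -> pd.DataFrame:
    """Read read-vs-transcript alignments into the standard alignment table.

    ``fmt`` is ``"tsv"`` or ``"sam"`` (inferred from the extension when
    omitted; ``.sam``/``.bam`` -> SAM). TSV files carry sample_id and assay
    columns; for SAM input both must be supplied as arguments. For SAM, only
    primary, forward-strand, unspliced records are used and the 5' position
    is the leftmost aligned base.

    RPF rows with a read length outside ``rpf_length_window`` (size
    selection: fragments shorter than 18 nt are discarded) are dropped; the
    count of dropped rows is logged and stored in ``df.attrs["n_dropped_short"]``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() in {".sam", ".bam"} else "tsv"

    if fmt == "tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={
                "read_id": str,
                "transcript_id": str,
                "sample_id": str,
                "assay": str,
            },
        )
        if missing := set(ALIGNMENT_COLUMNS) - set(df.columns):
            raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
        df = df[ALIGNMENT_COLUMNS]
    elif fmt == "sam":
        import pysam

        if sample_id is None or assay is None:
            raise ValueError("SAM input requires explicit sample_id and assay")
        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for aln in sam:
                if (
                    aln.is_unmapped
                    or aln.is_secondary
                    or aln.is_supplementary
                    or aln.is_reverse
                ):
                    continue
                # unspliced only: skip reference-skip (N) cigar ops
                if aln.cigartuples and any(op == 3 for op, _ in aln.cigartuples):
                    continue
                length = aln.query_length or aln.infer_query_length()
                rows.append(
                    (
                        aln.query_name,
                        aln.reference_name,
                        aln.reference_start,
                        int(length),
                        sample_id,
                        assay,
                    )
                )
        df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")

    if assay is not None:
        df = df[df["assay"] == assay].reset_index(drop=True)

    _validate_alignments(df, transcript_lengths)

    lo, hi = rpf_length_window
    is_rpf = df["assay"] == "RPF"
    short = is_rpf & ~df["read_length"].between(lo, hi)
    n_dropped = int(short.sum())
    if n_dropped:
        logger.info(
            "dropped %d RPF alignments outside length window [%d, %d] from %s",
            n_dropped,
            lo,
            hi,
            path,
        )
    df = df[~short].reset_index(drop=True)
    df.attrs["n_dropped_short"] = n_dropped
    return df


def write_alignments_tsv(
    df: pd.DataFrame, path: str | Path, params: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        _write_provenance(fh, params)
        df[ALIGNMENT_COLUMNS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ORFs

ORF_TSV_COLUMNS = [
    "orf_id",
    "transcript_id",
    "start",
    "end",
    "start_codon",
    "stop_codon",
    "aa_length",
    "kind",
]


def write_orfs_bed(orfs: Sequence, path: str | Path) -> None:
    """Write ORFs as BED6 in transcript space.

    chrom = transcript_id; the interval spans the start codon through the
    stop codon inclusive (0-based half-open); score 0; strand always ``+``.
    """
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(
                f"{orf.transcript_id}\t{orf.start}\t{orf.end}\t{orf.orf_id}\t0\t+\n"
            )


def write_orfs_tsv(
    orfs: Sequence, path: str | Path, params: Mapping | None = None
) -> None:
    """Write the ORF sidecar TSV (full codon-level detail; round-trippable)."""
    rows = [
        {
            "orf_id": o.orf_id,
            "transcript_id": o.transcript_id,
            "start": o.start,
            "end": o.end,
            "start_codon": o.start_codon,
            "stop_codon": o.stop_codon,
            "aa_length": o.aa_length,
            "kind": o.kind,
        }
        for o in orfs
    ]
    with open(path, "w") as fh:
        _write_provenance(fh, params)
        pd.DataFrame(rows, columns=ORF_TSV_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_orfs_tsv(path: str | Path) -> list:
    from .orfs import OrfCandidate

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    return [
        OrfCandidate(
            transcript_id=row.transcript_id,
            start=int(row.start),
            end=int(row.end),
            start_codon=row.start_codon,
            stop_codon=row.stop_codon,
            kind=row.kind,
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# scores / screen tables


def write_scores_tsv(
    scores: pd.DataFrame, path: str | Path, params: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        _write_provenance(fh, params)
        scores.to_csv(fh, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})


# ---------------------------------------------------------------------------
# sample manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample manifest.

    TSV columns: ``sample_id``, ``condition`` (control/case), ``rpf_path``,
    ``rna_path`` (either path may be empty). Exactly one control sample and
    unique sample ids are required.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    if missing := {"sample_id", "condition"} - set(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition(s): {sorted(bad)}")
    n_control = int((df["condition"] == "control").sum())
    if n_control != 1:
        raise ValueError(f"manifest must have exactly one control sample, got {n_control}")
    if not (df["condition"] == "case").any():
        raise ValueError("manifest must have at least one case sample")
    return df.reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
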