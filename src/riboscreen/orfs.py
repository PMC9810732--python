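"""Candidate small-ORF enumeration and main-ORF materialization.

A candidate ORF runs from an allowed start codon to the first in-frame stop
codon, has no internal in-frame stop, and reports its length in encoded
amino acids *excluding* the stop codon (a "108 aa" peptide has
``aa_length == 108`` and spans ``3 * (108 + 1)`` nucleotides including the
stop).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import TranscriptRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NEAR_COGNATE_STARTS = ("CTG", "GTG", "TTG")


@dataclass(frozen=True)
class OrfCandidate:
    """An ORF interval on a transcript, start codon through stop inclusive."""

    transcript_id: str
    start: int
    end: int  # exclusive; last base of the stop codon + 1
    start_codon: str
    stop_codon: str
    kind: str = "lincORF"  # or "mORF"
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"ORF length not divisible by 3: [{self.start}, {self.end})")
        if self.aa_length < 1:
            raise ValueError(f"ORF shorter than one codon + stop: [{self.start}, {self.end})")
        if self.kind not in ("lincORF", "mORF"):
            raise ValueError(f"unknown ORF kind {self.kind!r}")

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def validate_against(self, sequence: str) -> None:
        """Re-check the codon-level invariants against the actual sequence."""
        if not (0 <= self.start < self.end <= len(sequence)):
            raise ValueError(f"{self.orf_id}: out of sequence bounds")
        if sequence[self.start : self.start + 3] != self.start_codon:
            raise ValueError(f"{self.orf_id}: start codon mismatch")
        if sequence[self.end - 3 : self.end] != self.stop_codon:
            raise ValueError(f"{self.orf_id}: stop codon mismatch")
        for p in range(self.start + 3, self.end - 3, 3):
            if sequence[p : p + 3] in STOP_CODONS:
                raise ValueError(f"{self.orf_id}: internal in-frame stop at {p}")


@dataclass(frozen=True)
class OrfConfig:
    """Enumeration parameters for candidate sORFs."""

    start_codons: tuple[str, ...] = ("ATG",)
    min_aa: int = 10
    max_aa: int = 150
    per_stop: str = "longest_per_stop"  # or "all_starts"

    def __post_init__(self) -> None:
        if not (1 <= self.min_aa <= self.max_aa):
            raise ValueError("require 1 <= min_aa <= max_aa")
        if self.per_stop not in ("longest_per_stop", "all_starts"):
            raise ValueError(f"unknown per_stop policy {self.per_stop!r}")
        for codon in self.start_codons:
            if len(codon) != 3:
                raise ValueError(f"start codon {codon!r} is not a 3-mer")


def find_sorfs(
    transcript: TranscriptRecord,
    config: OrfConfig | None = None,
    allow_coding: bool = False,
) -> list[OrfCandidate]:
    """Enumerate candidate sORFs on a (lincRNA) transcript.

    Under ``longest_per_stop`` only the most 5' start satisfying the length
    bounds is kept for each stop position. Output is sorted by
    ``(start, end)`` and fully deterministic. Codons containing N never
    match start or stop patterns.
    """
    config = config or OrfConfig()
    if transcript.biotype != "lincRNA" and not allow_coding:
        raise ValueError(
            f"{transcript.transcript_id} is {transcript.biotype}; "
            "pass allow_coding=True to scan coding transcripts"
        )
    seq = transcript.sequence
    n = len(seq)

    # in-frame stop lookup: sorted stop-codon positions per frame
    stops_by_frame: list[list[int]] = [[], [], []]
    for p in range(n - 2):
        if seq[p : p + 3] in STOP_CODONS:
            stops_by_frame[p % 3].append(p)

    start_set = set(config.start_codons)
    candidates: list[tuple[int, int]] = []
    for p in range(n - 2):
        if seq[p : p + 3] not in start_set:
            continue
        frame_stops = stops_by_frame[p % 3]
        i = bisect_left(frame_stops, p + 3)
        if i == len(frame_stops):
            continue
        q = frame_stops[i]  # first in-frame stop downstream of the start codon
        aa = (q + 3 - p) // 3 - 1
        if config.min_aa <= aa <= config.max_aa:
            candidates.append((p, q + 3))

    if config.per_stop == "longest_per_stop":
        by_stop: dict[int, int] = {}
        for p, e in candidates:
            if e not in by_stop or p < by_stop[e]:
                by_stop[e] = p
        candidates = [(p, e) for e, p in by_stop.items()]

    candidates.sort()
    return [
        OrfCandidate(
            transcript_id=transcript.transcript_id,
            start=p,
            end=e,
            start_codon=seq[p : p + 3],
            stop_codon=seq[e - 3 : e],
            kind="lincORF",
        )
        for p, e in candidates
    ]


def morf_of(transcript: TranscriptRecord) -> OrfCandidate:
    """Materialize the annotated CDS of a coding transcript as its mORF.

    Non-canonical start/stop codons are flagged in ``warnings`` rather than
    rejected — annotation is taken at face value.
    """
    if transcript.biotype != "protein_coding" or transcript.cds_start is None:
        raise ValueError(
            f"{transcript.transcript_id}: mORF requires a protein_coding "
            "transcript with an annotated CDS"
        )
    start, end = transcript.cds_start, transcript.cds_end
    seq = transcript.sequence
    start_codon = seq[start : start + 3]
    stop_codon = seq[end - 3 : end]
    warnings = []
    if start_codon != "ATG":
        warnings.append("noncanonical_start")
    if stop_codon not in STOP_CODONS:
        warnings.append("noncanonical_stop")
    return OrfCandidate(
        transcript_id=transcript.transcript_id,
        start=start,
        end=end,
        start_codon=start_codon,
        stop_codon=stop_codon,
        kind="mORF",
        warnings=tuple(warnings),
    )


def count_filter(
    orfs: Sequence[OrfCandidate],
    psite_profiles: Mapping[tuple[str, str], "PsiteProfile"],
    min_reads: int = 1,
) -> list[OrfCandidate]:
    """Keep ORFs with at least ``min_reads`` P-site counts summed over samples.

    ``psite_profiles`` is keyed by ``(transcript_id, sample_id)`` as returned
    by :func:`riboscreen.psite.assign_psites`.
    """
    if min_reads <= 0:
        return list(orfs)
    by_tx: dict[str, list] = {}
    for (tx, _sample), prof in psite_profiles.items():
        by_tx.setdefault(tx, []).append(prof)
    kept = []
    for orf in orfs:
        total = sum(
            int(p.counts[orf.start : orf.end].sum()) for p in by_tx.get(orf.transcript_id, [])
        )
        if total >= min_reads:
            kept.append(orf)
    return kept
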