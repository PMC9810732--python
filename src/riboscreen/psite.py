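"""P-site assignment: collapse RPF alignments to per-transcript count vectors.

Each retained footprint contributes one count at ``five_prime_pos +
offset(read_length)``; the classic constant 5'+12 nt rule is the default
offset for all lengths, with a per-length table configurable (offset 0
reproduces raw 5'-end counting). Reads whose length falls outside the
retention window or whose P-site lands outside the transcript are dropped
and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import DEFAULT_RPF_LENGTH_WINDOW


@dataclass(frozen=True)
class OffsetTable:
    """Read-length -> P-site offset (nt from the 5' end) lookup."""

    offsets: Mapping[int, int] = field(default_factory=dict)
    default_offset: int = 12

    def __post_init__(self) -> None:
        if self.default_offset < 0 or any(v < 0 for v in self.offsets.values()):
            raise ValueError("P-site offsets must be non-negative")

    def offset(self, read_length: int) -> int:
        return self.offsets.get(read_length, self.default_offset)

    @classmethod
    def from_tsv(cls, path: str | Path, default_offset: int = 12) -> "OffsetTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            offsets=dict(zip(df["read_length"].astype(int), df["offset"].astype(int))),
            default_offset=default_offset,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.offsets.items()), columns=["read_length", "offset"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PsiteProfile:
    """Per-(transcript, sample) P-site count vector."""

    transcript_id: str
    sample_id: str
    counts: np.ndarray  # int vector, length = transcript length
    n_assigned: int = 0
    n_dropped: int = 0


def zero_profile(transcript_id: str, sample_id: str, length: int) -> PsiteProfile:
    return PsiteProfile(transcript_id, sample_id, np.zeros(length, dtype=np.int64))


def assign_psites(
    alignments: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    offsets: OffsetTable | None = None,
    length_window: tuple[int, int] = DEFAULT_RPF_LENGTH_WINDOW,
    assay: str = "RPF",
) -> dict[tuple[str, str], PsiteProfile]:
    """Build P-site profiles keyed by ``(transcript_id, sample_id)``.

    Only rows with the requested ``assay`` are used. The result covers every
    (transcript, sample) pair present in the input, including pairs whose
    reads were all dropped; pairs with no input rows are simply absent (use
    :func:`get_profile` for zero-filled access). Input row order never
    affects the result.
    """
    offsets = offsets or OffsetTable()
    if "assay" in alignments.columns:
        alignments = alignments[alignments["assay"] == assay]

    tx = alignments["transcript_id"].to_numpy()
    unknown = set(tx) - set(transcript_lengths)
    if unknown:
        raise ValueError(f"alignments reference unknown transcripts: {sorted(unknown)[:5]}")

    fivep = alignments["five_prime_pos"].to_numpy(dtype=np.int64)
    rlen = alignments["read_length"].to_numpy(dtype=np.int64)
    sample = alignments["sample_id"].to_numpy()

    # vectorized per-length offset lookup
    uniq_len, inv = np.unique(rlen, return_inverse=True) if len(rlen) else (np.array([], dtype=np.int64), np.array([], dtype=np.intp))
    off = np.array([offsets.offset(int(l)) for l in uniq_len], dtype=np.int64)[inv] if len(rlen) else np.array([], dtype=np.int64)
    psite = fivep + off

    lo, hi = length_window
    lengths_arr = np.array([transcript_lengths[t] for t in tx], dtype=np.int64) if len(tx) else np.array([], dtype=np.int64)
    keep = (rlen >= lo) & (rlen <= hi) & (psite >= 0) & (psite < lengths_arr)

    profiles: dict[tuple[str, str], PsiteProfile] = {}
    if len(tx) == 0:
        return profiles

    keys = pd.DataFrame({"tx": tx, "sample": sample, "psite": psite, "keep": keep})
    for (t, s), grp in keys.groupby(["tx", "sample"], sort=True):
        length = transcript_lengths[t]
        kept = grp.loc[grp["keep"], "psite"].to_numpy()
        counts = np.bincount(kept, minlength=length).astype(np.int64)
        profiles[(t, s)] = PsiteProfile(
            transcript_id=t,
            sample_id=s,
            counts=counts,
            n_assigned=int(len(kept)),
            n_dropped=int(len(grp) - len(kept)),
        )
    return profiles


def assign_rna_ends(
    alignments: pd.DataFrame, transcript_lengths: Mapping[str, int]
) -> dict[tuple[str, str], PsiteProfile]:
    """Per-(transcript, sample) RNA-seq 5'-end count vectors (no offset)."""
    return assign_psites(
        alignments,
        transcript_lengths,
        offsets=OffsetTable(default_offset=0),
        length_window=(1, np.iinfo(np.int64).max),
        assay="RNA",
    )


def get_profile(
    profiles: Mapping[tuple[str, str], PsiteProfile],
    transcript_id: str,
    sample_id: str,
    transcript_lengths: Mapping[str, int],
) -> PsiteProfile:
    """Fetch a profile, synthesizing an all-zero one for absent pairs."""
    key = (transcript_id, sample_id)
    if key in profiles:
        return profiles[key]
    return zero_profile(transcript_id, sample_id, transcript_lengths[transcript_id])


def library_sizes(
    profiles: Mapping[tuple[str, str], PsiteProfile]
) -> dict[str, int]:
    """Total assigned P-sites per sample across all transcripts."""
    totals: dict[str, int] = {}
    for (_tx, sample), prof in profiles.items():
        totals[sample] = totals.get(sample, 0) + prof.n_assigned
    return totals


def pool_profiles(
    profiles: Mapping[tuple[str, str], PsiteProfile],
    transcript_lengths: Mapping[str, int],
    pooled_id: str = "pooled",
) -> dict[tuple[str, str], PsiteProfile]:
    """Sum counts across samples, yielding one profile per transcript."""
    pooled: dict[tuple[str, str], PsiteProfile] = {}
    for (tx, _sample), prof in sorted(profiles.items()):
        key = (tx, pooled_id)
        if key not in pooled:
            pooled[key] = zero_profile(tx, pooled_id, transcript_lengths[tx])
        pooled[key].counts += prof.counts
        pooled[key].n_assigned += prof.n_assigned
        pooled[key].n_dropped += prof.n_dropped
    return pooled


def region_count(profile: PsiteProfile, start: int, end: int) -> int:
    """Sum of counts over ``[start, end)``."""
    if not (0 <= start <= end <= len(profile.counts)):
        raise ValueError(
            f"region [{start}, {end}) out of range for length {len(profile.counts)}"
        )
    return int(profile.counts[start:end].sum())


def rpf_density(profile: PsiteProfile, orf, library_size: int | float) -> float:
    """RPKM-style P-site density: counts / (ORF kb x library millions)."""
    length_nt = orf.end - orf.start
    if length_nt <= 0:
        raise ValueError(f"zero-length ORF {orf!r}")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    counts = region_count(profile, orf.start, orf.end)
    return counts / ((length_nt / 1000.0) * (library_size / 1e6))
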