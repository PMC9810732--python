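"""Per-ORF translation statistics: the frame-periodicity ORF score and the
ribosome release score (RRS).

The ORF score decomposes in-ORF P-site counts into the three codon
sub-positions (F0, F1, F2) relative to the ORF start and measures how far
they depart from uniformity with a chi-square statistic on 2 degrees of
freedom,

    score = sign * log2(1 + sum_i (Fi - m)^2 / m),    m = (F0+F1+F2)/3,

signed positive only when F0 strictly dominates both other frames; genuine
elongating ribosomes step three nucleotides at a time and pile counts into
frame 0. Zero total counts give score 0 by definition.

The RRS contrasts footprint density inside the ORF with density downstream
of its stop codon, normalized by the same contrast in RNA-seq coverage:

    RRS = ((R_orf + psi) / (R_down + psi)) * ((N_down + psi) / (N_orf + psi))

with pseudocount psi (default 1) on all four counts. Terminating ribosomes
are released at the stop codon, so translated ORFs show high RRS; RNA
normalization cancels coverage trends. Without matched RNA-seq the fallback
is the length-normalized RPF ratio alone, flagged ``zero_rna``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .orfs import OrfCandidate
from .psite import PsiteProfile, get_profile, library_sizes, region_count, rpf_density

FLAG_NO_DOWNSTREAM = "no_downstream_region"
FLAG_ZERO_RNA = "zero_rna"

SCORE_COLUMNS = [
    "orf_id",
    "transcript_id",
    "sample_id",
    "F0",
    "F1",
    "F2",
    "orf_score",
    "rpf_count",
    "rpf_density",
    "rrs",
    "log10_rrs",
    "flags",
    # extra provenance columns (not part of the minimal contract)
    "orf_length",
    "library_size",
    "kind",
]


@dataclass(frozen=True)
class FrameCounts:
    """P-site counts in codon sub-positions 0/1/2 relative to the ORF start."""

    f0: int
    f1: int
    f2: int

    @property
    def total(self) -> int:
        return self.f0 + self.f1 + self.f2


@dataclass(frozen=True)
class ScoringConfig:
    pseudocount: float = 1.0
    exclude_first_codon: bool = False


def frame_counts(
    profile: PsiteProfile, orf: OrfCandidate, exclude_first_codon: bool = False
) -> FrameCounts:
    """Accumulate P-site counts per codon sub-position over the coding codons.

    The counted window is ``[start, end - 3)`` — the stop codon never counts;
    ``exclude_first_codon`` additionally drops the start codon (useful when
    initiation-stalling drugs inflate codon 1).
    """
    lo = orf.start + (3 if exclude_first_codon else 0)
    hi = orf.end - 3
    if not (0 <= orf.start and orf.end <= len(profile.counts)):
        raise ValueError(f"{orf.orf_id} outside profile bounds")
    if lo >= hi:
        return FrameCounts(0, 0, 0)
    window = profile.counts[lo:hi]
    phases = (np.arange(lo, hi) - orf.start) % 3
    f = np.bincount(phases, weights=window, minlength=3)
    return FrameCounts(int(f[0]), int(f[1]), int(f[2]))


def orf_score(fc: FrameCounts) -> float:
    """Signed log2 chi-square periodicity statistic (0 for zero counts)."""
    total = fc.total
    if total == 0:
        return 0.0
    m = total / 3.0
    chi2 = sum((x - m) ** 2 / m for x in (fc.f0, fc.f1, fc.f2))
    s = math.log2(1.0 + chi2)
    if fc.f0 > fc.f1 and fc.f0 > fc.f2:
        return s
    return -s


def compute_rrs(
    rpf_profile: PsiteProfile,
    rna_profile: PsiteProfile | None,
    orf: OrfCandidate,
    pseudocount: float = 1.0,
) -> tuple[float | None, frozenset[str]]:
    """Ribosome release score for one ORF; ``(None, flags)`` when undefined.

    The downstream region is ``[orf.end, transcript_length)``; when it has
    zero length the RRS is undefined and ``no_downstream_region`` is set.
    With ``rna_profile=None`` the RPF-only, length-normalized fallback is
    used and ``zero_rna`` is set.
    """
    psi = pseudocount
    length = len(rpf_profile.counts)
    flags: set[str] = set()
    if orf.end >= length:
        return None, frozenset({FLAG_NO_DOWNSTREAM})
    r_orf = region_count(rpf_profile, orf.start, orf.end)
    r_down = region_count(rpf_profile, orf.end, length)
    if rna_profile is None:
        flags.add(FLAG_ZERO_RNA)
        l_orf = orf.end - orf.start
        l_down = length - orf.end
        rrs = ((r_orf + psi) / l_orf) / ((r_down + psi) / l_down)
    else:
        n_orf = region_count(rna_profile, orf.start, orf.end)
        n_down = region_count(rna_profile, orf.end, length)
        rrs = ((r_orf + psi) / (r_down + psi)) * ((n_down + psi) / (n_orf + psi))
    return rrs, frozenset(flags)


def _score_one(
    orf: OrfCandidate,
    rpf_prof: PsiteProfile,
    rna_prof: PsiteProfile | None,
    library_size: int,
    config: ScoringConfig,
) -> dict:
    fc = frame_counts(rpf_prof, orf, config.exclude_first_codon)
    rrs, flags = compute_rrs(rpf_prof, rna_prof, orf, config.pseudocount)
    count = region_count(rpf_prof, orf.start, orf.end)
    density = rpf_density(rpf_prof, orf, library_size) if library_size > 0 else 0.0
    return {
        "orf_id": orf.orf_id,
        "transcript_id": orf.transcript_id,
        "sample_id": rpf_prof.sample_id,
        "F0": fc.f0,
        "F1": fc.f1,
        "F2": fc.f2,
        "orf_score": orf_score(fc),
        "rpf_count": count,
        "rpf_density": density,
        "rrs": np.nan if rrs is None else rrs,
        "log10_rrs": np.nan if rrs is None else math.log10(rrs),
        "flags": ",".join(sorted(flags)),
        "orf_length": orf.length_nt,
        "library_size": library_size,
        "kind": orf.kind,
    }


def score_all(
    orfs: Sequence[OrfCandidate],
    rpf_profiles: Mapping[tuple[str, str], PsiteProfile],
    rna_profiles: Mapping[tuple[str, str], PsiteProfile] | None = None,
    config: ScoringConfig | None = None,
    transcript_lengths: Mapping[str, int] | None = None,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every (ORF, sample) pair; one row each, canonically sorted.

    Samples default to those present in ``rpf_profiles``. A missing RPF
    profile for a pair is an error unless ``transcript_lengths`` is given,
    in which case a zero profile is substituted (a transcript can simply
    have no reads in a sample). Library sizes are totals over *all* supplied
    profiles per sample.
    """
    config = config or ScoringConfig()
    if samples is None:
        samples = sorted({s for (_t, s) in rpf_profiles})
    lib = library_sizes(rpf_profiles)

    rows = []
    for orf in orfs:
        for sample in samples:
            key = (orf.transcript_id, sample)
            if key in rpf_profiles:
                rpf_prof = rpf_profiles[key]
            elif transcript_lengths is not None:
                rpf_prof = get_profile(rpf_profiles, orf.transcript_id, sample, transcript_lengths)
            else:
                raise KeyError(f"missing RPF profile for {key}")
            rna_prof = None
            if rna_profiles is not None:
                rna_prof = rna_profiles.get(key)
                if rna_prof is None and transcript_lengths is not None:
                    rna_prof = get_profile(
                        rna_profiles, orf.transcript_id, sample, transcript_lengths
                    )
            rows.append(
                _score_one(orf, rpf_prof, rna_prof, lib.get(sample, 0), config)
            )
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return df.sort_values(["orf_id", "sample_id"], kind="mergesort").reset_index(drop=True)
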