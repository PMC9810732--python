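"""The translatome screen: threshold calibration on mORFs, active-lincORF
calling, differential-translation calling against the control sample, and
candidate ranking.

Thresholds are the 95th nearest-rank percentiles of the pooled mORF ORF
score and log10 RRS distributions; a lincORF is called actively translated
only when it strictly exceeds *both*. This is deliberately stringent — the
mORF distribution is the positive reference, and only lincORFs that look
more convincingly translated than 95% of annotated coding ORFs pass.

Differential translation is a deterministic fold-change rule (no replicate
model): per case sample, the log2 ratio of RPF densities (each stabilized
by a pseudocount worth one read) must reach the cutoff with an adequate
read count, and a candidate is retained only when every case sample agrees
in direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptRecord, transcript_lengths as _tx_lengths
from .orfs import OrfCandidate, OrfConfig, count_filter, find_sorfs, morf_of
from .psite import (
    OffsetTable,
    assign_psites,
    assign_rna_ends,
    pool_profiles,
)
from .scoring import ScoringConfig, score_all


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: sorted ascending, 1-based index ceil(p/100*n)."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValueError("empty value list")
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    idx = math.ceil(percentile / 100.0 * n)
    return vals[max(idx, 1) - 1]


@dataclass(frozen=True)
class ThresholdPair:
    """Active-translation thresholds calibrated from pooled mORF scores."""

    rrs_threshold: float  # on the log10 RRS scale
    orfscore_threshold: float
    percentile: float = 95.0
    n_morfs: int = 0


def calibrate_thresholds(
    morf_scores: pd.DataFrame,
    percentile: float = 95.0,
    min_morfs: int = 20,
) -> ThresholdPair:
    """Nearest-rank percentile thresholds from per-mORF pooled scores.

    ``morf_scores`` holds one row per mORF with ``orf_score`` and
    ``log10_rrs`` columns; rows with undefined RRS are excluded from the
    RRS list. Fewer than ``min_morfs`` usable mORFs is an error.
    """
    if len(morf_scores) < min_morfs:
        raise ValueError(
            f"threshold calibration needs >= {min_morfs} mORFs, got {len(morf_scores)}"
        )
    log_rrs = morf_scores["log10_rrs"].dropna().to_numpy()
    if len(log_rrs) < min_morfs:
        raise ValueError(
            f"threshold calibration needs >= {min_morfs} mORFs with defined RRS, "
            f"got {len(log_rrs)}"
        )
    rrs_thr = nearest_rank_percentile(log_rrs, percentile)
    score_thr = nearest_rank_percentile(morf_scores["orf_score"].to_numpy(), percentile)
    if not (np.isfinite(rrs_thr) and np.isfinite(score_thr)):
        raise ValueError("non-finite threshold")
    return ThresholdPair(
        rrs_threshold=float(rrs_thr),
        orfscore_threshold=float(score_thr),
        percentile=float(percentile),
        n_morfs=int(len(morf_scores)),
    )


def call_active(linc_scores: pd.DataFrame, thresholds: ThresholdPair) -> set[str]:
    """lincORFs strictly exceeding both thresholds (undefined RRS never passes)."""
    ok = (
        linc_scores["log10_rrs"].notna()
        & (linc_scores["log10_rrs"] > thresholds.rrs_threshold)
        & (linc_scores["orf_score"] > thresholds.orfscore_threshold)
    )
    return set(linc_scores.loc[ok, "orf_id"])


@dataclass(frozen=True)
class DifferentialCall:
    """Per-ORF differential-translation summary across case samples."""

    orf_id: str
    log2fc: Mapping[str, float]  # case sample -> log2 density fold change
    flagged: Mapping[str, bool]
    rpf_counts: Mapping[str, int]  # all samples, incl. control
    in_all_cases: bool
    direction: str | None  # "up" / "down" / None
    mean_abs_log2fc: float
    total_rpf: int


def differential_translation(
    per_sample_scores: pd.DataFrame,
    manifest: pd.DataFrame,
    min_count: int = 10,
    min_abs_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> list[DifferentialCall]:
    """Fold-change differential calls for each ORF, case samples vs control.

    Per case sample: ``log2fc = log2((d_case + pc*d0_case) / (d_ctrl +
    pc*d0_ctrl))`` where ``d0`` is the density equivalent of a single read
    in that ORF and sample. The sample is flagged when ``|log2fc| >=
    min_abs_log2fc`` and at least one of the two samples has ``rpf_count >=
    min_count``. ``in_all_cases`` requires every case sample flagged with a
    consistent direction.
    """
    control_rows = manifest.loc[manifest["condition"] == "control", "sample_id"]
    if len(control_rows) != 1:
        raise ValueError("exactly one control sample required")
    control = control_rows.iloc[0]
    cases = sorted(manifest.loc[manifest["condition"] == "case", "sample_id"])
    if not cases:
        raise ValueError("at least one case sample required")

    df = per_sample_scores.set_index(["orf_id", "sample_id"])
    calls: list[DifferentialCall] = []
    for orf_id in sorted(per_sample_scores["orf_id"].unique()):
        sub = df.loc[orf_id]

        def _d0(sample: str) -> float:
            row = sub.loc[sample]
            lib = float(row["library_size"])
            length = float(row["orf_length"])
            if lib <= 0:
                return 0.0
            return 1.0 / ((length / 1000.0) * (lib / 1e6))

        ctrl = sub.loc[control]
        log2fc: dict[str, float] = {}
        flagged: dict[str, bool] = {}
        counts = {s: int(sub.loc[s, "rpf_count"]) for s in [control] + cases}
        for case in cases:
            row = sub.loc[case]
            num = float(row["rpf_density"]) + pseudocount * _d0(case)
            den = float(ctrl["rpf_density"]) + pseudocount * _d0(control)
            fc = math.log2(num / den)
            log2fc[case] = fc
            flagged[case] = abs(fc) >= min_abs_log2fc and (
                counts[case] >= min_count or counts[control] >= min_count
            )
        signs = {np.sign(log2fc[c]) for c in cases if flagged[c]}
        in_all = all(flagged.values()) and len(signs) == 1 and 0 not in signs
        direction = None
        if in_all:
            direction = "up" if signs == {1.0} else "down"
        calls.append(
            DifferentialCall(
                orf_id=orf_id,
                log2fc=log2fc,
                flagged=flagged,
                rpf_counts=counts,
                in_all_cases=in_all,
                direction=direction,
                mean_abs_log2fc=float(np.mean([abs(v) for v in log2fc.values()])),
                total_rpf=int(sum(counts.values())),
            )
        )
    return calls


def intersect_and_rank(calls: Sequence[DifferentialCall]) -> list[str]:
    """Keep in-all-cases ORFs, ranked by mean |log2fc| (ties: total RPF, id)."""
    shared = [c for c in calls if c.in_all_cases]
    shared.sort(key=lambda c: (-c.mean_abs_log2fc, -c.total_rpf, c.orf_id))
    return [c.orf_id for c in shared]


@dataclass(frozen=True)
class ScreenConfig:
    """All tunable parameters of the end-to-end screen."""

    orf: OrfConfig = field(default_factory=OrfConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    offsets: OffsetTable = field(default_factory=OffsetTable)
    rpf_length_window: tuple[int, int] = (18, 40)
    min_reads: int = 1  # candidate detection gate (total pooled P-sites)
    percentile: float = 95.0
    min_count: int = 10
    min_abs_log2fc: float = 1.0

    def as_params(self) -> dict:
        return {
            "start_codons": ",".join(self.orf.start_codons),
            "min_aa": self.orf.min_aa,
            "max_aa": self.orf.max_aa,
            "per_stop": self.orf.per_stop,
            "pseudocount": self.scoring.pseudocount,
            "exclude_first_codon": self.scoring.exclude_first_codon,
            "psite_default_offset": self.offsets.default_offset,
            "rpf_length_window": f"{self.rpf_length_window[0]}-{self.rpf_length_window[1]}",
            "min_reads": self.min_reads,
            "percentile": self.percentile,
            "min_count": self.min_count,
            "min_abs_log2fc": self.min_abs_log2fc,
        }


@dataclass
class ScreenResult:
    """Everything the screen produces, with full parameter provenance."""

    thresholds: ThresholdPair
    active: set[str]
    calls: list[DifferentialCall]
    ranking: list[str]
    n_candidate_sorfs: int
    n_detected_sorfs: int
    morf_scores: pd.DataFrame  # pooled, one row per mORF
    linc_scores: pd.DataFrame  # pooled, one row per detected lincORF
    per_sample_scores: pd.DataFrame  # active lincORFs only, one row per sample
    params: dict


def run_screen(
    transcripts: Sequence[TranscriptRecord],
    rpf_alignments: pd.DataFrame,
    manifest: pd.DataFrame,
    rna_alignments: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Run the full screen on in-memory inputs.

    Stages: enumerate candidate sORFs on lincRNAs and materialize mORFs;
    assign P-sites; drop candidates with zero pooled P-site counts; score
    mORFs and candidates on pooled counts; calibrate thresholds from mORFs;
    call active lincORFs; score the active set per sample; call and rank
    differential translation against the control sample.
    """
    config = config or ScreenConfig()
    lengths = _tx_lengths(transcripts)
    samples = sorted(manifest["sample_id"])

    coding = [t for t in transcripts if t.biotype == "protein_coding"]
    lincs = [t for t in transcripts if t.biotype == "lincRNA"]
    morfs = [morf_of(t) for t in coding]
    sorfs = [o for t in lincs for o in find_sorfs(t, config.orf)]
    n_candidates = len(sorfs)

    rpf_profiles = assign_psites(
        rpf_alignments, lengths, config.offsets, config.rpf_length_window
    )
    rna_profiles = (
        assign_rna_ends(rna_alignments, lengths) if rna_alignments is not None else None
    )

    sorfs = count_filter(sorfs, rpf_profiles, config.min_reads)
    n_detected = len(sorfs)

    # pooled (across-sample) scoring: one point per ORF, as plotted
    pooled_rpf = pool_profiles(rpf_profiles, lengths)
    pooled_rna = pool_profiles(rna_profiles, lengths) if rna_profiles is not None else None
    morf_scores = score_all(
        morfs, pooled_rpf, pooled_rna, config.scoring, lengths, samples=["pooled"]
    )
    linc_scores = score_all(
        sorfs, pooled_rpf, pooled_rna, config.scoring, lengths, samples=["pooled"]
    )

    thresholds = calibrate_thresholds(morf_scores, config.percentile)
    active = call_active(linc_scores, thresholds)

    active_orfs = [o for o in sorfs if o.orf_id in active]
    per_sample = score_all(
        active_orfs, rpf_profiles, rna_profiles, config.scoring, lengths, samples=samples
    )
    calls = differential_translation(
        per_sample,
        manifest,
        min_count=config.min_count,
        min_abs_log2fc=config.min_abs_log2fc,
        pseudocount=config.scoring.pseudocount,
    ) if active_orfs else []
    ranking = intersect_and_rank(calls)

    return ScreenResult(
        thresholds=thresholds,
        active=active,
        calls=calls,
        ranking=ranking,
        n_candidate_sorfs=n_candidates,
        n_detected_sorfs=n_detected,
        morf_scores=morf_scores,
        linc_scores=linc_scores,
        per_sample_scores=per_sample,
        params=config.as_params(),
    )


def screen_to_frame(result: ScreenResult) -> pd.DataFrame:
    """Flatten a ScreenResult into one tidy sectioned table."""
    rows: list[dict] = []
    for orf_id in sorted(result.active):
        rows.append({"section": "active", "orf_id": orf_id})
    for call in result.calls:
        for sample, fc in sorted(call.log2fc.items()):
            rows.append(
                {
                    "section": "differential",
                    "orf_id": call.orf_id,
                    "sample_id": sample,
                    "log2fc": fc,
                    "flagged": call.flagged[sample],
                    "in_all_cases": call.in_all_cases,
                    "direction": call.direction or "",
                }
            )
    for rank, orf_id in enumerate(result.ranking, start=1):
        call = next(c for c in result.calls if c.orf_id == orf_id)
        rows.append(
            {
                "section": "ranking",
                "orf_id": orf_id,
                "rank": rank,
                "mean_abs_log2fc": call.mean_abs_log2fc,
                "total_rpf": call.total_rpf,
                "direction": call.direction or "",
            }
        )
    columns = [
        "section",
        "orf_id",
        "sample_id",
        "log2fc",
        "flagged",
        "in_all_cases",
        "direction",
        "rank",
        "mean_abs_log2fc",
        "total_rpf",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


def write_screen_tsv(result: ScreenResult, path, seed=None) -> None:
    """Write the sectioned screen table with full parameter provenance."""
    from .io import write_scores_tsv

    params = dict(result.params)
    params.update(
        {
            "rrs_threshold": result.thresholds.rrs_threshold,
            "orfscore_threshold": result.thresholds.orfscore_threshold,
            "n_morfs": result.thresholds.n_morfs,
            "n_candidate_sorfs": result.n_candidate_sorfs,
            "n_detected_sorfs": result.n_detected_sorfs,
            "n_active": len(result.active),
            "n_shared_differential": len(result.ranking),
        }
    )
    if seed is not None:
        params["seed"] = seed
    write_scores_tsv(screen_to_frame(result), path, params)
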