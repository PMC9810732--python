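"""Synthetic Ribo-seq / RNA-seq generator with ground truth.

Emulates the screen's study design — one normal control plus three tumor
case samples, a mixed transcriptome of protein-coding and lincRNA
transcripts — directly at the alignment level (no sequencer error model, no
FASTQ): the pipeline's contract starts at transcript-space alignments.

Generative model per sample:

* RNA-seq read totals per transcript are multinomial with weights
  proportional to expression (log-normal across transcripts, with a small
  per-sample log-normal jitter); read 5' ends are uniform.
* RPF totals are proportional to expression x (sum of ORF translation
  efficiencies + a frameless background TE). Reads on a translated ORF
  place their P-site on a uniformly chosen coding codon with sub-codon
  position drawn from the frame-fidelity vector (default 0.85/0.10/0.05);
  a small leakage fraction lands uniformly downstream of the stop,
  emulating imperfect ribosome release. Background reads are uniform and
  frameless.
* Planted differentially translated lincORFs multiply their TE by a
  per-ORF fold change in case samples (a geometric ladder starting at the
  4x base, so one standout strongest effect exists, like the screen's
  top-ranked hit).

Reads are emitted with 5' positions consistent with the package's default
P-site convention (constant 5'+12 nt offset). Each (sample, assay) pair has
its own pseudo-random stream derived from the seed, so adding a sample
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    TranscriptRecord,
    write_alignments_tsv,
    write_manifest,
    write_transcripts,
)
from .orfs import STOP_CODONS, OrfCandidate

BASES = np.array(list("ACGT"))
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NONSTOP_CODONS = np.array([c for c in _ALL_CODONS if c not in STOP_CODONS])
STOP_LIST = np.array(sorted(STOP_CODONS))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic screen dataset."""

    n_coding: int = 400
    n_linc: int = 100
    length_range: tuple[int, int] = (300, 1500)
    # expression across transcripts and its per-sample jitter (log scale)
    expr_meanlog: float = 0.0
    expr_sdlog: float = 1.0
    sample_sdlog: float = 0.05
    # lincORF planting
    translated_fraction: float = 0.2
    planted_min_aa: int = 10
    planted_max_aa: int = 150
    # translation model
    frame_fidelity: tuple[float, float, float] = (0.85, 0.10, 0.05)
    downstream_leakage: float = 0.02
    background_te: float = 0.05
    te_range: tuple[float, float] = (2.0, 6.0)  # translated lincORFs, mORF TE = 1
    # transcripts carrying a planted sORF draw expression at or above this
    # value (detected translated lincRNAs are expression-biased by construction)
    translated_expr_floor: float = 1.0
    # differential planting (case vs control)
    n_differential: int = 10
    diff_fold_change: float = 4.0  # base of the geometric fold-change ladder
    diff_fold_ladder_span: float = 1.0  # ladder tops out at base * 2**span
    # the strongest planted effect stands apart from the ladder (one dominant
    # hit, like the screen's top-ranked candidate)
    diff_hero_fold: float = 16.0
    # read model
    rpf_lengths: tuple[int, ...] = (26, 27, 28, 29, 30, 31, 32)
    rpf_length_probs: tuple[float, ...] = (0.05, 0.15, 0.35, 0.20, 0.12, 0.08, 0.05)
    rna_read_length: int = 50
    psite_offset: int = 12
    library_size_rpf: int = 200_000
    library_size_rna: int = 200_000
    # optional initiation spike (harringtonine-like pileup on codon 1)
    start_spike_fraction: float = 0.0
    # sample layout: one control + three cases
    control_sample: str = "control"
    case_samples: tuple[str, ...] = ("case1", "case2", "case3")

    def __post_init__(self) -> None:
        if abs(sum(self.frame_fidelity) - 1.0) > 1e-9:
            raise ValueError("frame_fidelity must sum to 1")
        if abs(sum(self.rpf_length_probs) - 1.0) > 1e-9:
            raise ValueError("rpf_length_probs must sum to 1")
        if not (0 <= self.translated_fraction <= 1):
            raise ValueError("translated_fraction must be in [0, 1]")
        if not (0 <= self.downstream_leakage <= 1):
            raise ValueError("downstream_leakage must be in [0, 1]")
        if self.n_differential > int(round(self.translated_fraction * self.n_linc)):
            raise ValueError("planted differential ORFs must be a subset of translated lincORFs")


def _stream(seed: int, *tokens: str) -> np.random.Generator:
    """Independent child stream for (seed, tokens) — stable across runs."""
    return np.random.default_rng(
        [int(seed) % 2**31] + [zlib.crc32(t.encode()) for t in tokens]
    )


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def _plant_orf(seq: np.ndarray, start: int, aa: int, rng: np.random.Generator) -> int:
    """Overwrite seq[start:end] with ATG + aa non-stop codons... + stop.

    Also writes an in-frame TAA immediately upstream so no earlier in-frame
    start can share the planted stop (keeps the planted orf_id identical to
    what longest-per-stop discovery reports). Returns the exclusive end.
    """
    # aa coding codons = ATG + (aa - 1) random non-stop codons, then a stop
    codons = ["ATG"] + list(rng.choice(NONSTOP_CODONS, aa - 1)) + [str(rng.choice(STOP_LIST))]
    orf = np.array(list("".join(codons)))
    end = start + len(orf)
    seq[start:end] = orf
    seq[start - 3 : start] = np.array(list("TAA"))
    return end


@dataclass
class ScreenDataset:
    """A complete synthetic screen fixture with ground truth."""

    transcripts: list[TranscriptRecord]
    rpf_alignments: pd.DataFrame  # all samples concatenated
    rna_alignments: pd.DataFrame
    manifest: pd.DataFrame
    truth: pd.DataFrame  # one row per planted (translated) lincORF
    config: SimConfig
    seed: int

    def write(self, out_dir: str | Path) -> Path:
        """Materialize the fixture as the on-disk layout the CLI consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_transcripts(self.transcripts, out / "transcripts.fasta", out / "annotation.tsv")
        manifest = self.manifest.copy()
        params = {"seed": self.seed}
        for sample in manifest["sample_id"]:
            rpf = self.rpf_alignments[self.rpf_alignments["sample_id"] == sample]
            rna = self.rna_alignments[self.rna_alignments["sample_id"] == sample]
            rpf_path, rna_path = out / f"{sample}_rpf.tsv", out / f"{sample}_rna.tsv"
            write_alignments_tsv(rpf, rpf_path, params)
            write_alignments_tsv(rna, rna_path, params)
            manifest.loc[manifest["sample_id"] == sample, "rpf_path"] = rpf_path.name
            manifest.loc[manifest["sample_id"] == sample, "rna_path"] = rna_path.name
        write_manifest(manifest, out / "manifest.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return out


def simulate_transcriptome(
    config: SimConfig, seed: int
) -> tuple[list[TranscriptRecord], pd.DataFrame, pd.DataFrame]:
    """Generate transcripts, per-ORF truth, and per-transcript expression.

    Returns ``(transcripts, truth, expression)``. Coding transcripts carry a
    valid in-bounds CDS (ATG..stop, length divisible by 3, no internal
    in-frame stop). Translated lincRNAs carry one planted sORF within the
    configured amino-acid bounds, placed with a leader of at least 20 nt and
    a downstream region of at least max(200 nt, the ORF's own length) so the
    release signature has room to show. Deterministic given the seed.
    """
    rng = _stream(seed, "transcriptome")
    lo, hi = config.length_range
    transcripts: list[TranscriptRecord] = []
    truth_rows: list[dict] = []
    expr_rows: list[dict] = []

    def _expr(floor: float = 0.0) -> float:
        while True:
            x = float(rng.lognormal(config.expr_meanlog, config.expr_sdlog))
            if x >= floor:
                return x

    # --- coding transcripts with a main ORF
    for i in range(config.n_coding):
        tid = f"coding{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        u5 = int(rng.integers(20, 101))
        u3 = int(rng.integers(50, 301))
        u3 = min(u3, length - u5 - 153)  # keep CDS >= ~50 aa
        if u3 < 50:
            u3, u5 = 50, min(u5, length - 203)
        cds_nt = ((length - u5 - u3) // 3) * 3
        aa = cds_nt // 3 - 1
        seq = _random_seq(rng, length)
        end = _plant_orf(seq, u5, aa, rng)
        transcripts.append(
            TranscriptRecord(tid, "".join(seq), "protein_coding", u5, end)
        )
        expr_rows.append({"transcript_id": tid, "expression": _expr()})

    # --- lincRNAs, a fraction carrying a translated sORF
    n_translated = int(round(config.translated_fraction * config.n_linc))
    translated_idx = set(rng.choice(config.n_linc, size=n_translated, replace=False).tolist())
    # planted differential subset and its fold-change ladder (strongest first)
    translated_sorted = sorted(translated_idx)
    diff_idx = set(
        rng.choice(translated_sorted, size=config.n_differential, replace=False).tolist()
    )
    n_diff = max(config.n_differential, 1)
    ladder = config.diff_fold_change * 2.0 ** np.linspace(
        config.diff_fold_ladder_span, 0.0, max(n_diff - 1, 1)
    )
    folds = np.concatenate([[config.diff_hero_fold], ladder])[:n_diff]
    fold_of = dict(zip(sorted(diff_idx), folds))  # deterministic assignment

    for i in range(config.n_linc):
        tid = f"linc{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if i in translated_idx:
            leader = int(rng.integers(20, min(101, length - 200 - 3 * (config.planted_min_aa + 1))))
            max_nt = min(
                3 * (config.planted_max_aa + 1),
                length - leader - 200,
                (length - leader) // 2,
            )
            aa_cap = max_nt // 3 - 1
            if aa_cap < config.planted_min_aa:
                raise ValueError(f"infeasible geometry for planted ORF on {tid}")
            aa = int(rng.integers(config.planted_min_aa, aa_cap + 1))
            end = _plant_orf(seq, leader, aa, rng)
            te = float(rng.uniform(*config.te_range))
            fold = float(fold_of.get(i, 1.0))
            truth_rows.append(
                {
                    "orf_id": f"{tid}:{leader}-{end}",
                    "transcript_id": tid,
                    "start": leader,
                    "end": end,
                    "translated": True,
                    "te": te,
                    "differential": i in diff_idx,
                    "fold_change": fold,
                    "direction": "up" if i in diff_idx else "",
                }
            )
        transcripts.append(TranscriptRecord(tid, "".join(seq), "lincRNA"))
        floor = config.translated_expr_floor if i in translated_idx else 0.0
        expr_rows.append({"transcript_id": tid, "expression": _expr(floor)})

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "orf_id",
            "transcript_id",
            "start",
            "end",
            "translated",
            "te",
            "differential",
            "fold_change",
            "direction",
        ],
    )
    expression = pd.DataFrame(expr_rows)
    return transcripts, truth, expression


def simulate_reads(
    transcripts: Sequence[TranscriptRecord],
    truth: pd.DataFrame,
    expression: pd.DataFrame,
    config: SimConfig,
    seed: int,
    sample_id: str,
    condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit RPF and RNA alignment tables for one sample.

    Exactly ``library_size_rpf`` RPF and ``library_size_rna`` RNA alignments
    are emitted (multinomial allocation across transcripts). Case samples
    multiply the TE of planted differential ORFs by their fold change.
    """
    tx_index = {t.transcript_id: t for t in transcripts}
    order = [t.transcript_id for t in transcripts]
    expr_base = expression.set_index("transcript_id").loc[order, "expression"].to_numpy()

    # per-sample expression jitter shared by both assays
    jitter_rng = _stream(seed, sample_id, "expression")
    expr = expr_base * jitter_rng.lognormal(0.0, config.sample_sdlog, len(order))

    # translated ORFs per transcript with condition-effective TE
    orfs_on: dict[str, list[tuple[int, int, float]]] = {tid: [] for tid in order}
    for t in transcripts:
        if t.biotype == "protein_coding":
            orfs_on[t.transcript_id].append((t.cds_start, t.cds_end, 1.0))
    for row in truth.itertuples(index=False):
        te = row.te * (row.fold_change if (row.differential and condition == "case") else 1.0)
        orfs_on[row.transcript_id].append((int(row.start), int(row.end), float(te)))

    te_sum = np.array([sum(te for *_x, te in orfs_on[tid]) for tid in order])
    lengths = np.array([tx_index[tid].length for tid in order])

    # ---- RPF assay
    rng = _stream(seed, sample_id, "RPF")
    weights = expr * (te_sum + config.background_te)
    n_per_tx = rng.multinomial(config.library_size_rpf, weights / weights.sum())
    psites: list[np.ndarray] = []
    tx_of: list[np.ndarray] = []
    fidelity = np.array(config.frame_fidelity)
    for ti, tid in enumerate(order):
        n = int(n_per_tx[ti])
        if n == 0:
            continue
        L = int(lengths[ti])
        parts = orfs_on[tid]
        comp_w = np.array([te for *_x, te in parts] + [config.background_te])
        comp = rng.choice(len(comp_w), size=n, p=comp_w / comp_w.sum())
        pos = np.empty(n, dtype=np.int64)
        for ci, (start, end, _te) in enumerate(parts):
            mask = comp == ci
            k = int(mask.sum())
            if k == 0:
                continue
            leak = rng.random(k) < config.downstream_leakage
            n_in = int((~leak).sum())
            aa = (end - start) // 3 - 1
            codons = rng.integers(0, aa, n_in)
            if config.start_spike_fraction > 0:
                spike = rng.random(n_in) < config.start_spike_fraction
                codons[spike] = 0
            frames = rng.choice(3, size=n_in, p=fidelity)
            in_pos = start + 3 * codons + frames
            down_pos = rng.integers(end, L - 20, size=k - n_in)
            p = np.empty(k, dtype=np.int64)
            p[~leak] = in_pos
            p[leak] = down_pos
            pos[mask] = p
        bg_mask = comp == len(parts)
        pos[bg_mask] = rng.integers(12, L - 20, size=int(bg_mask.sum()))
        psites.append(pos)
        tx_of.append(np.repeat(ti, n))

    psite_arr = np.concatenate(psites) if psites else np.array([], dtype=np.int64)
    tx_arr = np.concatenate(tx_of) if tx_of else np.array([], dtype=np.int64)
    n_rpf = len(psite_arr)
    rlen = np.asarray(config.rpf_lengths)[
        rng.choice(len(config.rpf_lengths), size=n_rpf, p=config.rpf_length_probs)
    ]
    fivep = psite_arr - config.psite_offset
    rpf = pd.DataFrame(
        {
            "read_id": [f"{sample_id}_rpf_{i}" for i in range(n_rpf)],
            "transcript_id": np.array(order, dtype=object)[tx_arr],
            "five_prime_pos": fivep,
            "read_length": rlen,
            "sample_id": sample_id,
            "assay": "RPF",
        }
    )

    # ---- RNA assay (uniform coverage, expression-proportional totals)
    rng_rna = _stream(seed, sample_id, "RNA")
    n_per_tx_rna = rng_rna.multinomial(config.library_size_rna, expr / expr.sum())
    rna_tx: list[np.ndarray] = []
    rna_pos: list[np.ndarray] = []
    for ti, tid in enumerate(order):
        n = int(n_per_tx_rna[ti])
        if n == 0:
            continue
        L = int(lengths[ti])
        rna_pos.append(rng_rna.integers(0, L - config.rna_read_length + 1, size=n))
        rna_tx.append(np.repeat(ti, n))
    rna_pos_arr = np.concatenate(rna_pos) if rna_pos else np.array([], dtype=np.int64)
    rna_tx_arr = np.concatenate(rna_tx) if rna_tx else np.array([], dtype=np.int64)
    rna = pd.DataFrame(
        {
            "read_id": [f"{sample_id}_rna_{i}" for i in range(len(rna_pos_arr))],
            "transcript_id": np.array(order, dtype=object)[rna_tx_arr],
            "five_prime_pos": rna_pos_arr,
            "read_length": config.rna_read_length,
            "sample_id": sample_id,
            "assay": "RNA",
        }
    )
    return rpf, rna


def make_screen_dataset(
    config: SimConfig | None = None, seed: int = 0
) -> ScreenDataset:
    """Build the full four-sample fixture (1 control + 3 cases) with truth."""
    config = config or SimConfig()
    transcripts, truth, expression = simulate_transcriptome(config, seed)
    samples = [(config.control_sample, "control")] + [
        (s, "case") for s in config.case_samples
    ]
    rpf_frames, rna_frames = [], []
    for sample_id, condition in samples:
        rpf, rna = simulate_reads(
            transcripts, truth, expression, config, seed, sample_id, condition
        )
        rpf_frames.append(rpf)
        rna_frames.append(rna)
    manifest = pd.DataFrame(
        {
            "sample_id": [s for s, _c in samples],
            "condition": [c for _s, c in samples],
            "rpf_path": "",
            "rna_path": "",
        }
    )
    return ScreenDataset(
        transcripts=transcripts,
        rpf_alignments=pd.concat(rpf_frames, ignore_index=True),
        rna_alignments=pd.concat(rna_frames, ignore_index=True),
        manifest=manifest,
        truth=truth,
        config=config,
        seed=seed,
    )
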