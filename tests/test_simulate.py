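"""Generator contracts: determinism, read accounting, planted-signal
statistics, and consistency between truth and what discovery recovers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboscreen import (
    OrfConfig,
    SimConfig,
    find_sorfs,
    frame_counts,
    make_screen_dataset,
    simulate_reads,
    simulate_transcriptome,
)
from riboscreen.psite import assign_psites
from riboscreen.io import transcript_lengths

FAST = SimConfig(
    n_coding=40,
    n_linc=20,
    n_differential=2,
    length_range=(300, 800),
    library_size_rpf=20_000,
    library_size_rna=20_000,
)


class TestTranscriptome:
    def test_deterministic_given_seed(self):
        t1, truth1, e1 = simulate_transcriptome(FAST, seed=17)
        t2, truth2, e2 = simulate_transcriptome(FAST, seed=17)
        assert t1 == t2
        pd.testing.assert_frame_equal(truth1, truth2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_no_lincs_when_requested(self):
        cfg = SimConfig(
            n_coding=25, n_linc=0, translated_fraction=0.0, n_differential=0
        )
        transcripts, truth, _ = simulate_transcriptome(cfg, seed=1)
        assert all(t.biotype == "protein_coding" for t in transcripts)
        assert truth.empty

    def test_coding_cds_is_valid_orf(self):
        transcripts, _, _ = simulate_transcriptome(FAST, seed=3)
        from riboscreen import morf_of

        for t in transcripts:
            if t.biotype == "protein_coding":
                morf = morf_of(t)
                assert morf.warnings == ()
                morf.validate_against(t.sequence)

    def test_planted_orfs_recovered_by_discovery(self):
        transcripts, truth, _ = simulate_transcriptome(FAST, seed=5)
        by_id = {t.transcript_id: t for t in transcripts}
        for row in truth.itertuples(index=False):
            found = {o.orf_id for o in find_sorfs(by_id[row.transcript_id])}
            assert row.orf_id in found

    def test_planted_108aa_orf_found_with_matching_length(self):
        cfg = SimConfig(
            n_coding=2,
            n_linc=2,
            translated_fraction=1.0,
            n_differential=1,
            planted_min_aa=108,
            planted_max_aa=108,
            length_range=(800, 1200),
        )
        transcripts, truth, _ = simulate_transcriptome(cfg, seed=9)
        by_id = {t.transcript_id: t for t in transcripts}
        for row in truth.itertuples(index=False):
            orfs = find_sorfs(by_id[row.transcript_id])
            assert any(o.orf_id == row.orf_id and o.aa_length == 108 for o in orfs)

    def test_differential_subset_of_translated_with_direction(self):
        _, truth, _ = simulate_transcriptome(FAST, seed=7)
        assert truth["translated"].all()
        diff = truth[truth["differential"]]
        assert len(diff) == FAST.n_differential
        assert (diff["direction"] == "up").all()
        assert (diff["fold_change"] >= FAST.diff_fold_change).all()
        assert (truth.loc[~truth["differential"], "fold_change"] == 1.0).all()


@pytest.fixture(scope="module")
def world():
    return simulate_transcriptome(FAST, seed=2)


class TestReads:
    def test_library_size_exact_and_alignments_in_bounds(self, world):
        transcripts, truth, expr = world
        rpf, rna = simulate_reads(transcripts, truth, expr, FAST, 2, "S1", "control")
        assert len(rpf) == FAST.library_size_rpf
        assert len(rna) == FAST.library_size_rna
        lengths = transcript_lengths(transcripts)
        for df in (rpf, rna):
            tx_len = df["transcript_id"].map(lengths)
            assert (df["five_prime_pos"] >= 0).all()
            assert (df["five_prime_pos"] + df["read_length"] <= tx_len).all()
        assert rpf["read_length"].between(26, 32).all()

    def test_zero_leakage_zero_background_leaves_downstream_empty(self, world):
        transcripts, truth, expr = world
        cfg = SimConfig(
            n_coding=FAST.n_coding,
            n_linc=FAST.n_linc,
            n_differential=FAST.n_differential,
            length_range=FAST.length_range,
            library_size_rpf=FAST.library_size_rpf,
            library_size_rna=FAST.library_size_rna,
            downstream_leakage=0.0,
            background_te=1e-12,
        )
        rpf, _ = simulate_reads(transcripts, truth, expr, cfg, 2, "S1", "control")
        lengths = transcript_lengths(transcripts)
        profiles = assign_psites(rpf, lengths)
        for row in truth.itertuples(index=False):
            prof = profiles.get((row.transcript_id, "S1"))
            if prof is not None:
                assert prof.counts[row.end :].sum() == 0

    def test_degenerate_frame_fidelity_concentrates_frame0(self, world):
        transcripts, truth, expr = world
        cfg = SimConfig(
            n_coding=FAST.n_coding,
            n_linc=FAST.n_linc,
            n_differential=FAST.n_differential,
            length_range=FAST.length_range,
            library_size_rpf=FAST.library_size_rpf,
            library_size_rna=FAST.library_size_rna,
            frame_fidelity=(1.0, 0.0, 0.0),
            background_te=1e-12,
            downstream_leakage=0.0,
        )
        rpf, _ = simulate_reads(transcripts, truth, expr, cfg, 2, "S1", "control")
        profiles = assign_psites(rpf, transcript_lengths(transcripts))
        from riboscreen.orfs import OrfCandidate

        for row in truth.itertuples(index=False):
            prof = profiles.get((row.transcript_id, "S1"))
            if prof is None:
                continue
            orf = OrfCandidate(row.transcript_id, int(row.start), int(row.end), "ATG", "TAA")
            fc = frame_counts(prof, orf)
            assert fc.f1 == 0 and fc.f2 == 0

    def test_frame0_fraction_matches_binomial_expectation(self, world):
        """In-ORF P-sites land in frame 0 with the configured probability
        (0.85 +/- 3% at >= 2000 reads, the binomial mean)."""
        transcripts, truth, expr = world
        rpf, _ = simulate_reads(transcripts, truth, expr, FAST, 2, "S1", "control")
        profiles = assign_psites(rpf, transcript_lengths(transcripts))
        from riboscreen.orfs import OrfCandidate

        f0 = total = 0
        for row in truth.itertuples(index=False):
            prof = profiles.get((row.transcript_id, "S1"))
            if prof is None:
                continue
            orf = OrfCandidate(row.transcript_id, int(row.start), int(row.end), "ATG", "TAA")
            fc = frame_counts(prof, orf)
            f0, total = f0 + fc.f0, total + fc.total
        assert total >= 2000
        assert f0 / total == pytest.approx(FAST.frame_fidelity[0], abs=0.03)

    def test_start_spike_lands_on_first_codon_and_is_excludable(self, world):
        """An initiation-inhibitor-style pileup inflates codon 1; scoring
        with exclude_first_codon removes it."""
        transcripts, truth, expr = world
        import dataclasses

        cfg = dataclasses.replace(FAST, start_spike_fraction=0.6,
                                  background_te=1e-12, downstream_leakage=0.0)
        rpf, _ = simulate_reads(transcripts, truth, expr, cfg, 2, "S1", "control")
        profiles = assign_psites(rpf, transcript_lengths(transcripts))
        from riboscreen.orfs import OrfCandidate

        spiked = unspiked = 0
        for row in truth.itertuples(index=False):
            prof = profiles.get((row.transcript_id, "S1"))
            if prof is None or prof.n_assigned < 100:
                continue
            orf = OrfCandidate(row.transcript_id, int(row.start), int(row.end), "ATG", "TAA")
            with_first = frame_counts(prof, orf, exclude_first_codon=False)
            without = frame_counts(prof, orf, exclude_first_codon=True)
            start_codon_counts = int(prof.counts[orf.start : orf.start + 3].sum())
            assert with_first.total - without.total == start_codon_counts
            spiked += start_codon_counts
            unspiked += without.total
        # the spike concentrates a large share of in-ORF reads on codon 1
        assert spiked > 0.4 * (spiked + unspiked)

    def test_rna_shares_follow_expression(self, world):
        """Per-transcript RNA read totals fit the expression multinomial
        (chi-square GOF not rejected at alpha = 0.01, >= 1e5 reads)."""
        transcripts, truth, expr = world
        cfg = SimConfig(
            n_coding=FAST.n_coding,
            n_linc=FAST.n_linc,
            n_differential=FAST.n_differential,
            length_range=FAST.length_range,
            library_size_rna=200_000,
            library_size_rpf=1000,
            sample_sdlog=0.0,  # no per-sample jitter: expected shares are exact
        )
        _, rna = simulate_reads(transcripts, truth, expr, cfg, 2, "S1", "control")
        counts = rna["transcript_id"].value_counts()
        e = expr.set_index("transcript_id")["expression"]
        observed = np.array([counts.get(t, 0) for t in e.index], dtype=float)
        expected = (e / e.sum()).to_numpy() * cfg.library_size_rna
        big = expected >= 5
        if (~big).any():  # pool the low-expectation tail into one bin
            observed = np.append(observed[big], observed[~big].sum())
            expected = np.append(expected[big], expected[~big].sum())
        stat = stats.chisquare(observed, expected)
        assert stat.pvalue > 0.01

    def test_adding_a_sample_never_perturbs_others(self):
        """Per-(sample, assay) streams: a dataset with extra case samples
        still emits byte-identical reads for the samples both share."""
        import dataclasses

        one_case = dataclasses.replace(FAST, case_samples=("case1",))
        small = make_screen_dataset(one_case, seed=6)
        full = make_screen_dataset(FAST, seed=6)
        for df_small, df_full in (
            (small.rpf_alignments, full.rpf_alignments),
            (small.rna_alignments, full.rna_alignments),
        ):
            for sample in ("control", "case1"):
                a = df_small[df_small["sample_id"] == sample].reset_index(drop=True)
                b = df_full[df_full["sample_id"] == sample].reset_index(drop=True)
                pd.testing.assert_frame_equal(a, b)


class TestScreenDataset:
    def test_layout_and_cardinality(self, tmp_path):
        ds = make_screen_dataset(FAST, seed=4)
        out = ds.write(tmp_path / "fix")
        files = sorted(p.name for p in out.iterdir())
        assert "transcripts.fasta" in files and "manifest.tsv" in files
        assert sum(f.endswith("_rpf.tsv") for f in files) == 4
        assert sum(f.endswith("_rna.tsv") for f in files) == 4
        assert len(ds.manifest) == 4
        assert (ds.manifest["condition"] == "case").sum() == 3

    def test_case_condition_boosts_planted_orfs(self):
        ds = make_screen_dataset(FAST, seed=4)
        diff_tx = set(ds.truth.loc[ds.truth["differential"], "transcript_id"])
        rpf = ds.rpf_alignments
        ctrl = rpf[rpf["sample_id"] == "control"]
        case = rpf[rpf["sample_id"] == "case1"]
        ctrl_share = ctrl["transcript_id"].isin(diff_tx).mean()
        case_share = case["transcript_id"].isin(diff_tx).mean()
        assert case_share > 2 * ctrl_share
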