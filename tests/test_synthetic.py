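"""Ground-truth structure of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from hlatarget.pipeline import A2_LIKE_ANCHORS, A3_LIKE_ANCHORS, CANONICAL_LENGTH_DIST
from hlatarget.synthetic import (
    IRT_PEPTIDES,
    make_annotation_fixtures,
    make_motif_model,
    make_psm_dataset,
    predict_tm_helices,
    sample_peptides,
    simulate_lfq_experiment,
    simulate_spectrum_pair,
)


class TestMotifModel:
    def test_anchor_mass_split_equally(self, a2_model):
        # P2: {L, M} at total 0.9 -> 0.45 each
        aa = "ACDEFGHIKLMNPQRSTVWY"
        p2 = a2_model.position_freqs[1]
        assert p2[aa.index("L")] == pytest.approx(0.45)
        assert p2[aa.index("M")] == pytest.approx(0.45)
        assert a2_model.position_freqs.sum(axis=1) == pytest.approx(np.ones(9))

    def test_deterministic_anchor(self):
        m = make_motif_model("X", {2: (("L",), 1.0)}, length=9)
        peps = sample_peptides(m, 50, seed=0)
        assert all(p[1] == "L" for p in peps)

    def test_basic_residue_anchors_at_first_and_last_position(self):
        m = make_motif_model("A*03:01", A3_LIKE_ANCHORS, length=9)
        assert m.anchor_positions == {1, 9}
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for pos in (0, 8):
            assert m.position_freqs[pos][aa.index("K")] == pytest.approx(0.45)
            assert m.position_freqs[pos][aa.index("R")] == pytest.approx(0.45)

    def test_invalid_anchor_probability(self):
        with pytest.raises(ValueError):
            make_motif_model("X", {2: (("L",), 1.5)})


class TestSamplePeptides:
    def test_anchor_frequency_matches_planted_mass(self, a2_model):
        peps = [p for p in sample_peptides(a2_model, 2000, seed=3)]
        p2 = sum(p[1] in "LM" for p in peps) / len(peps)
        assert abs(p2 - 0.9) <= 0.03

    def test_same_seed_is_identical(self, a2_model):
        assert sample_peptides(a2_model, 100, seed=5) == sample_peptides(
            a2_model, 100, seed=5
        )

    def test_length_distribution_respected(self, a2_model):
        peps = sample_peptides(a2_model, 5000, CANONICAL_LENGTH_DIST, seed=1)
        frac9 = sum(len(p) == 9 for p in peps) / len(peps)
        assert 0.63 <= frac9 <= 0.67

    def test_anchors_map_to_cterminus_for_other_lengths(self, a2_model):
        peps = [p for p in sample_peptides(a2_model, 3000, {10: 1.0}, seed=2)]
        last = sum(p[-1] in "LV" for p in peps) / len(peps)
        assert abs(last - 0.9) <= 0.03


class TestPsmDataset:
    def test_truth_labels_partition_the_table(self, a2_model):
        peps = sample_peptides(a2_model, 100, seed=4)
        records, blank, truth = make_psm_dataset(
            peps, n_decoy=20, n_irt=5, n_blank=5, n_modified=10, seed=4
        )
        assert len(records) == 140
        assert len(truth.psm_labels) == 140
        from collections import Counter

        assert Counter(truth.psm_labels) == {
            "true": 100, "decoy": 20, "irt": 5, "blank": 5, "modified": 10,
        }

    def test_zero_contamination_gives_pure_table(self, a2_model):
        peps = sample_peptides(a2_model, 30, seed=4)
        records, blank, truth = make_psm_dataset(peps, seed=4)
        assert [r.sequence for r in records] == peps
        assert blank == frozenset()

    def test_determinism(self, a2_model):
        peps = sample_peptides(a2_model, 50, seed=4)
        a = make_psm_dataset(peps, n_decoy=10, n_blank=3, seed=9)
        b = make_psm_dataset(peps, n_decoy=10, n_blank=3, seed=9)
        assert a[0] == b[0] and a[1] == b[1]

    def test_decoys_are_composition_preserving_shuffles(self, a2_model):
        peps = sample_peptides(a2_model, 50, seed=4)
        records, _, truth = make_psm_dataset(peps, n_decoy=25, seed=0)
        decoys = [r for r, l in zip(records, truth.psm_labels) if l == "decoy"]
        assert all(r.is_decoy for r in decoys)
        pools = {"".join(sorted(p)) for p in peps}
        assert all("".join(sorted(d.sequence)) in pools for d in decoys)

    def test_true_scores_stochastically_dominate_decoys(self, a2_model):
        peps = sample_peptides(a2_model, 300, seed=4)
        records, _, truth = make_psm_dataset(peps, n_decoy=150, seed=1)
        t = [r.score for r, l in zip(records, truth.psm_labels) if l == "true"]
        d = [r.score for r, l in zip(records, truth.psm_labels) if l == "decoy"]
        assert stats.mannwhitneyu(t, d, alternative="greater").pvalue < 1e-6

    def test_contamination_exceeding_truth_is_error(self, a2_model):
        peps = sample_peptides(a2_model, 5, seed=4)
        with pytest.raises(ValueError):
            make_psm_dataset(peps, n_decoy=6, seed=0)
        with pytest.raises(ValueError):
            make_psm_dataset(peps, n_irt=len(IRT_PEPTIDES) + 1, seed=0)


class TestSpectrumPair:
    def test_noiseless_pair_has_identical_intensities(self):
        e, s = simulate_spectrum_pair("IVDPGYLGY", noise_cv=0.0, n_noise_peaks=0, seed=0)
        assert np.allclose(e.peaks, s.peaks)

    def test_contains_all_by_ion_mzs(self):
        from hlatarget.spectra import theoretical_fragments

        e, s = simulate_spectrum_pair("IVDPGYLGY", noise_cv=0.1, n_noise_peaks=5, seed=0)
        frags = theoretical_fragments("IVDPGYLGY")
        assert len(frags) == 16
        for spec in (e, s):
            for f in frags:
                assert np.min(np.abs(spec.peaks[:, 0] - f.mz)) < 1e-9

    def test_rt_shift_applied(self):
        e, s = simulate_spectrum_pair("IVDPGYLGY", rt_shift_min=1.9, seed=0)
        assert s.rt_min - e.rt_min == pytest.approx(1.9)

    def test_rejects_out_of_range_length(self):
        with pytest.raises(ValueError):
            simulate_spectrum_pair("SHORT")


class TestLfqExperiment:
    def test_planted_count_is_exact(self):
        m, truth = simulate_lfq_experiment(n_proteins=2000, frac_de=0.05, seed=0)
        assert len(truth.de_proteins) == 100

    def test_null_experiment_centred_at_zero(self):
        m, truth = simulate_lfq_experiment(
            n_proteins=500, frac_de=0.0, dropout_midpoint=-np.inf, seed=0
        )
        assert truth.de_proteins == frozenset()
        log2 = np.log2(m.data.to_numpy())
        diff = log2[:, :3].mean(axis=1) - log2[:, 3:].mean(axis=1)
        assert abs(diff.mean()) < 0.05

    def test_dropout_midpoint_below_everything_gives_complete_matrix(self):
        m, _ = simulate_lfq_experiment(n_proteins=200, dropout_midpoint=-1e9, seed=0)
        assert not m.data.isna().any().any()

    def test_dropout_is_intensity_dependent(self):
        m, _ = simulate_lfq_experiment(
            n_proteins=3000, dropout_midpoint=24.0, dropout_steepness=1.0, seed=0
        )
        log2mean = np.log2(m.data).mean(axis=1)
        missing = m.data.isna().mean(axis=1)
        low = missing[log2mean < 23].mean()
        high = missing[log2mean > 25].mean()
        assert low > high + 0.1


class TestAnnotationFixtures:
    def test_overlap_counts_match_fractions(self):
        peps = [f"PEPTIDE{i:02d}X" for i in range(100)]
        prots = [f"P{i:03d}" for i in range(50)]
        dbs, truth = make_annotation_fixtures(peps, prots, {"TANTIGEN": 0.1, "CSPA": 0.2}, seed=0)
        by_name = {d.name: d for d in dbs}
        assert len(truth.db_members["TANTIGEN"]) == 10
        assert len(truth.db_members["CSPA"]) == 10  # 0.2 * 50 proteins
        assert truth.db_members["TANTIGEN"] <= by_name["TANTIGEN"].members
        # distractors are present and outside the universe
        assert by_name["TANTIGEN"].members - set(peps)

    def test_fixed_seed_reproducible(self):
        peps = [f"AAAAAAAA{c}" for c in "CDEFGHIKLM"]
        a = make_annotation_fixtures(peps, ["P1"], {"IEDB": 0.5}, seed=3)
        b = make_annotation_fixtures(peps, ["P1"], {"IEDB": 0.5}, seed=3)
        assert a[0] == b[0]


def test_hydropathy_window_stand_in_counts_hydrophobic_stretches():
    soluble = "MKRNSTDEQRKNDESQ" * 10
    membrane = soluble[:40] + "AILVILVAILVAILVILVA" + soluble[40:80] + "LIVALIVALIVALIVALIV"
    assert predict_tm_helices(soluble) == 0
    assert predict_tm_helices(membrane) == 2
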