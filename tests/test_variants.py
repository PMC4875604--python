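"""Score quotients, kernel-density Bayes classification and calibration."""

import numpy as np
import pytest

import oracles
from conftest import consensus_matrix, pfm_from_probs
from motifbench.motifs import MotifError, SequenceRecord
from motifbench.variants import (
    GAIN,
    LOSS,
    CalibrationTable,
    ClassifierBundle,
    KernelDensityClassModel,
    QuotientClassifier,
    TrainedMatrix,
    VariantContext,
    build_context,
    calibrate,
    classify_variant,
    direction_agreement,
    fit_kde_classifier,
    make_training_pairs,
    nrd0_bandwidth,
    score_quotient,
    train_bundle,
)
from motifbench.benchmark import PeakRecord


class TestBuildContext:
    GENOME = {"chr1": "ACGT" * 30}

    def test_snv_window_is_41bp(self):
        ctx = build_context(self.GENOME, "chr1", 50, self.GENOME["chr1"][49], "T"
                            if self.GENOME["chr1"][49] != "T" else "A", flank=20)
        assert len(ctx.wt_seq) == 41
        assert len(ctx.var_seq) == 41

    def test_ref_mismatch_reports_expected_and_found(self):
        found = self.GENOME["chr1"][49]
        wrong = "A" if found != "A" else "C"
        with pytest.raises(ValueError, match=f"expected {wrong}, found {found}"):
            build_context(self.GENOME, "chr1", 50, wrong, "T")

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError, match="not a variant"):
            build_context(self.GENOME, "chr1", 50, "A", "A")

    def test_deletion_shortens_var_window(self):
        g = {"chr1": "G" * 100}
        ctx = build_context(g, "chr1", 40, "GGGG", "G", flank=20)
        assert len(ctx.wt_seq) - len(ctx.var_seq) == 3

    def test_flank_clipped_at_contig_start(self, caplog):
        g = {"chr1": "ACGTACGTAC" * 10}
        with caplog.at_level("WARNING"):
            ctx = build_context(g, "chr1", 3, g["chr1"][2], "T"
                                if g["chr1"][2] != "T" else "A", flank=20)
        assert len(ctx.wt_seq) == 2 + 1 + 20


class TestScoreQuotient:
    def test_ratio_of_best_scores(self):
        m = consensus_matrix("ACGT")
        ctx = VariantContext(wt_seq="GGACGTGG", var_seq="GGACCTGG")
        sq = score_quotient(m, ctx)
        # wt holds the full consensus (400); variant keeps 3 of 4 positions (300)
        assert sq.q == pytest.approx(400.0 / 300.0)

    def test_variant_outside_all_motif_windows_gives_unity(self):
        m = consensus_matrix("AC")
        ctx = VariantContext(wt_seq="ACGGGGGGGT", var_seq="ACGGGGGGGA")
        # best window 'AC' at 0 unchanged; trailing change cannot outscore it
        assert score_quotient(m, ctx).q == pytest.approx(1.0)

    def test_flooring_prevents_zero_division(self):
        m = consensus_matrix("AA")
        ctx = VariantContext(wt_seq="AAGG", var_seq="GGGG")
        sq = score_quotient(m, ctx, floor=2.0)
        assert sq.q == pytest.approx(200.0 / 2.0)

    def test_both_windows_too_short_raises(self):
        m = consensus_matrix("ACGTAC")
        with pytest.raises(MotifError):
            score_quotient(m, VariantContext(wt_seq="AC", var_seq="AG"))

    def test_swapping_sequences_inverts_quotient(self):
        m = consensus_matrix("ACGT")
        ctx = VariantContext(wt_seq="GGACGTGG", var_seq="GGACCTGG")
        q = score_quotient(m, ctx).q
        q_swapped = score_quotient(m, ctx.swapped()).q
        assert q * q_swapped == pytest.approx(1.0, abs=1e-12)


class TestMakeTrainingPairs:
    def test_full_cross_product_size(self):
        lost, gained = make_training_pairs([10, 20], [1, 2, 5], cap=100, seed=0)
        assert lost.size == gained.size == 6

    def test_cap_engaged_exact_size(self):
        pos = list(np.linspace(10, 20, 2000))
        neg = list(np.linspace(1, 2, 2000))
        lost, gained = make_training_pairs(pos, neg, cap=1_000_000, seed=0)
        assert lost.size == gained.size == 1_000_000

    def test_gained_is_elementwise_reciprocal(self):
        lost, gained = make_training_pairs([3, 4], [2, 8], cap=10, seed=0)
        assert np.allclose(gained, 1.0 / lost)

    def test_scores_floored_before_division(self):
        lost, _ = make_training_pairs([10], [0], cap=10, seed=0, floor=2.0)
        assert lost[0] == pytest.approx(5.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            make_training_pairs([], [1.0])


def well_separated_classifier(n=200, seed=0):
    """Lost quotients around 2, gained their reciprocals."""
    rng = np.random.default_rng(seed)
    lost = np.exp(rng.normal(np.log(2.0), 0.15, size=n))
    return fit_kde_classifier(lost, 1.0 / lost), lost


class TestKdeClassifier:
    def test_needs_ten_quotients_per_class(self):
        with pytest.raises(ValueError):
            fit_kde_classifier([2.0] * 9, [0.5] * 9)

    def test_density_integrates_to_one(self):
        clf, _ = well_separated_classifier()
        for model in (clf.lost, clf.gained):
            lo = model.log_points.min() - 10 * model.bandwidth
            hi = model.log_points.max() + 10 * model.bandwidth
            x = np.linspace(lo, hi, 20001)
            integral = np.trapezoid(np.exp(model.log_density(x)), x)
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_density_equals_sum_of_kernels_oracle(self):
        clf, lost = well_separated_classifier(n=50)
        model = clf.lost
        for x in [-1.0, 0.0, 0.5, np.log(2.0), 3.0]:
            expected = oracles.kde_density_oracle(model.log_points, model.bandwidth, x)
            got = float(np.exp(model.log_density(np.array([x]))[0]))
            assert got == pytest.approx(expected, rel=1e-9)

    def test_degenerate_class_bandwidth_floored(self, caplog):
        with caplog.at_level("WARNING"):
            clf = fit_kde_classifier([2.0] * 20, [0.5] * 20)
        assert clf.lost.bandwidth == pytest.approx(1e-3)

    def test_posterior_own_class_dominates_at_training_point(self):
        clf = fit_kde_classifier([2.0] * 20, [0.5] * 20)
        p_lost, _ = clf.posterior_scalar(2.0)
        assert p_lost > 0.5

    def test_posterior_half_at_unity_for_symmetric_training(self):
        clf, _ = well_separated_classifier()
        p_lost, p_gained = clf.posterior_scalar(1.0)
        assert p_lost == pytest.approx(0.5, abs=1e-9)
        assert p_gained == pytest.approx(0.5, abs=1e-9)

    def test_deep_lost_tail_is_confident(self):
        clf, _ = well_separated_classifier()
        p_lost, _ = clf.posterior_scalar(6.0)
        assert p_lost > 0.99

    def test_posteriors_sum_to_one_on_log_grid(self):
        clf, _ = well_separated_classifier()
        qs = np.logspace(-3, 3, 100)
        pl, pg = clf.posterior(qs)
        assert np.allclose(pl + pg, 1.0, atol=1e-9)

    def test_antisymmetry_of_reciprocal_quotients(self):
        clf, _ = well_separated_classifier()
        qs = np.logspace(-2, 2, 100)
        pl, pg = clf.posterior(qs)
        pl_inv, pg_inv = clf.posterior(1.0 / qs)
        assert np.allclose(pl, pg_inv, atol=1e-9)
        assert np.allclose(pg, pl_inv, atol=1e-9)

    def test_nrd0_matches_R_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        sd = np.std(x, ddof=1)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 5 ** (-0.2)
        assert nrd0_bandwidth(x) == pytest.approx(expected)


class TestCalibrate:
    def test_perfectly_separable_gives_unit_predictive_values(self):
        clf, lost = well_separated_classifier()
        table = calibrate(clf, lost, 1.0 / lost)
        assert np.all((table.ppv[~np.isnan(table.ppv)]) == 1.0)
        assert np.all((table.npv[~np.isnan(table.npv)]) == 1.0)

    def test_bin_ratio(self):
        # hand-built classifier: confident everywhere, 8 of 10 loss-calls correct
        clf = fit_kde_classifier([2.0] * 20, [0.5] * 20)
        held_lost = [2.0] * 8
        held_gained = [2.0] * 2  # truly gained but will be called lost
        table = calibrate(clf, held_lost, held_gained)
        occupied = ~np.isnan(table.ppv)
        assert table.ppv[occupied][-1] == pytest.approx(0.8)

    def test_matches_confusion_matrix_per_bin_oracle(self):
        rng = np.random.default_rng(3)
        lost = np.exp(rng.normal(0.4, 0.5, size=150))
        gained = np.exp(rng.normal(-0.4, 0.5, size=150))
        clf = fit_kde_classifier(lost, gained)
        held_lost = np.exp(rng.normal(0.4, 0.5, size=100))
        held_gained = np.exp(rng.normal(-0.4, 0.5, size=100))
        table = calibrate(clf, held_lost, held_gained, n_bins=5)

        edges = np.linspace(0.5, 1.0, 6)
        qs = np.concatenate([held_lost, held_gained])
        truth = np.array([LOSS] * 100 + [GAIN] * 100)
        pl, pg = clf.posterior(qs)
        for b in range(5):
            sel = (np.maximum(pl, pg) >= edges[b]) & (
                (np.maximum(pl, pg) < edges[b + 1]) | ((b == 4) & (np.maximum(pl, pg) <= 1.0))
            )
            called_loss = pl > pg
            n_loss_calls = int((sel & called_loss).sum())
            if n_loss_calls:
                expected_ppv = (truth[sel & called_loss] == LOSS).mean()
                assert table.ppv[b] == pytest.approx(expected_ppv, abs=1e-12)
            else:
                assert np.isnan(table.ppv[b])

    def test_monotone_ppv_on_well_separated_data(self):
        rng = np.random.default_rng(8)
        lost = np.exp(rng.normal(0.8, 0.3, size=500))
        gained = np.exp(rng.normal(-0.8, 0.3, size=500))
        clf = fit_kde_classifier(lost, gained)
        table = calibrate(clf, np.exp(rng.normal(0.8, 0.3, 2000)),
                          np.exp(rng.normal(-0.8, 0.3, 2000)), n_bins=5)
        vals = table.ppv[~np.isnan(table.ppv)]
        assert np.all(np.diff(vals) >= -0.05)  # tolerate small-sample wobble


def trained_matrix_with(pv: float, invert=False, name="m") -> TrainedMatrix:
    """A width-2 'AC' matrix with a crafted classifier and a flat
    calibration table whose every bin reports predictive value ``pv``."""
    pfm = pfm_from_probs([[0.98, 0.01], [0.01, 0.97], [0.005, 0.01], [0.005, 0.01]],
                         name="TFX")
    object.__setattr__(pfm, "matrix_id", name)
    rng = np.random.default_rng(0)
    lost = np.exp(rng.normal(np.log(2), 0.1, 50))
    clf = fit_kde_classifier(lost, 1.0 / lost)
    if invert:
        clf = QuotientClassifier(lost=clf.gained, gained=clf.lost)
    n_bins = 10
    table = CalibrationTable(
        bin_edges=np.linspace(0.5, 1.0, n_bins + 1),
        ppv=np.full(n_bins, pv), npv=np.full(n_bins, pv),
        n_lost_calls=np.ones(n_bins, int), n_gained_calls=np.ones(n_bins, int),
    )
    return TrainedMatrix(pfm=pfm, classifier=clf, calibration=table)


# the substitution leaves no high-scoring window on either strand
DESTROY_CTX = VariantContext(wt_seq="GGGGACGGGG", var_seq="GGGGCCGGGG")


class TestClassifyVariant:
    def test_only_reliable_matrices_contribute(self):
        verdict = classify_variant(
            DESTROY_CTX, [trained_matrix_with(0.9, name="m1"),
                          trained_matrix_with(0.65, name="m2")]
        )
        assert verdict.call == LOSS
        grades = {r.matrix_id: r.grade for r in verdict.per_matrix}
        assert grades["m1"] > grades["m2"]

    def test_disagreeing_reliable_matrices_are_uncertain(self):
        verdict = classify_variant(
            DESTROY_CTX, [trained_matrix_with(0.9, name="m1"),
                          trained_matrix_with(0.9, invert=True, name="m2")]
        )
        assert verdict.call == "uncertain"

    def test_no_reliable_matrix(self):
        verdict = classify_variant(DESTROY_CTX, [trained_matrix_with(0.5)])
        assert verdict.call == "no_reliable_prediction"

    def test_known_site_flag_from_peak_overlap(self):
        ctx = VariantContext(wt_seq=DESTROY_CTX.wt_seq, var_seq=DESTROY_CTX.var_seq,
                             genomic_position=("chr5", 150, "A", "T"))
        peaks = [PeakRecord(chrom="chr5", start=100, end=200, tf_name="TFX",
                            binding_score=900)]
        assert classify_variant(ctx, [trained_matrix_with(0.9)], peak_db=peaks).known_site_flag
        far = [PeakRecord(chrom="chr5", start=300, end=400, tf_name="TFX",
                          binding_score=900)]
        assert not classify_variant(ctx, [trained_matrix_with(0.9)], peak_db=far).known_site_flag

    def test_mixed_tf_matrices_rejected(self):
        a = trained_matrix_with(0.9, name="m1")
        b = trained_matrix_with(0.9, name="m2")
        object.__setattr__(b.pfm, "tf_name", "OTHER")
        with pytest.raises(ValueError):
            classify_variant(DESTROY_CTX, [a, b])


class TestDirectionAgreement:
    def test_fraction_of_matches(self):
        preds = [LOSS, LOSS, GAIN, GAIN, LOSS, GAIN, LOSS, GAIN]
        obs = [LOSS, GAIN, GAIN, LOSS, LOSS, LOSS, GAIN, GAIN]
        assert direction_agreement(preds, obs) == pytest.approx(0.5)

    def test_declined_predictions_ignored(self):
        assert direction_agreement([LOSS, None, None], [LOSS, GAIN, GAIN]) == 1.0

    def test_all_declined_raises(self):
        with pytest.raises(ValueError):
            direction_agreement([None, None], [LOSS, GAIN])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            direction_agreement([], [])


class TestBundleRoundTrip:
    def test_json_round_trip_preserves_predictions(self, tmp_path, rng):
        pfm = pfm_from_probs([[0.97, 0.01], [0.01, 0.96], [0.01, 0.015],
                              [0.01, 0.015]], name="TFY")
        pos = [SequenceRecord(f"p{i}", oracles.random_dna(rng, 20) + "AC"
                              + oracles.random_dna(rng, 20)) for i in range(30)]
        neg = [SequenceRecord(f"n{i}", "".join(rng.choice(list("GT"), 42)))
               for i in range(30)]
        bundle = train_bundle([pfm], pos, neg, cap=500, seed=1)
        path = tmp_path / "bundle.json"
        bundle.save(path)
        loaded = ClassifierBundle.load(path)
        t0 = bundle.matrices["TFY"]
        t1 = loaded.matrices["TFY"]
        qs = np.logspace(-1, 1, 25)
        assert np.allclose(t0.classifier.posterior(qs)[0],
                           t1.classifier.posterior(qs)[0], atol=1e-6)
        assert t1.pfm.source == "SYNTHETIC"

    def test_version_checked(self, tmp_path):
        with pytest.raises(ValueError, match="version"):
            ClassifierBundle.from_dict({"version": 99, "matrices": {}})


class TestCapStability:
    def test_capped_and_full_posteriors_agree(self, rng):
        pos = list(rng.normal(900, 40, size=100))
        neg = list(rng.normal(500, 80, size=100))
        full_l, full_g = make_training_pairs(pos, neg, cap=10**7, seed=0)
        cap_l, cap_g = make_training_pairs(pos, neg, cap=4000, seed=0)
        clf_full = fit_kde_classifier(full_l, full_g)
        clf_cap = fit_kde_classifier(cap_l, cap_g)
        qs = np.logspace(-1, 1, 60)
        assert np.max(np.abs(clf_full.posterior(qs)[0] - clf_cap.posterior(qs)[0])) < 0.05
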