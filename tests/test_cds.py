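"""CDS determination: homology extension, frameshifts, coding model, cutoff."""

import numpy as np
import pytest

from alvinest import cds, simulate
from alvinest.cds import (
    CodingModel,
    HomologyHit,
    cds_from_homology,
    coding_score,
    frame_scores,
    mask_frameshift,
    optimize_cutoff,
    reconcile,
)
from alvinest.cleaning import revcomp


def _hit(query_interval, frame=1, subject_length=100, subject_interval=(0, 90),
         query_id="u1", evalue=1e-20):
    return HomologyHit(
        query_id=query_id, subject_id="s1", evalue=evalue,
        query_interval=query_interval, subject_interval=subject_interval,
        frame=frame, subject_length=subject_length,
    )


def orf_oracle(seq: str, frame: int, hit_interval):
    """Brute-force six-frame ORF scan, independent of the implementation.

    Enumerates every in-frame stop position with a list comprehension, then
    derives the CDS containing the hit by set logic.
    """
    w = seq if frame > 0 else revcomp(seq)
    f = abs(frame) - 1
    hs, he = hit_interval
    stops = [
        p for p in range(f, len(w) - 2, 3) if w[p : p + 3] in cds.STOPS
    ]
    after = [p for p in stops if p >= he]
    end = after[0] + 3 if after else f + 3 * ((len(w) - f) // 3)
    before = [p for p in stops if p < hs]
    if before:
        stop5 = before[-1]
        atgs = [
            p for p in range(stop5 + 3, end - 2, 3) if w[p : p + 3] == "ATG"
        ]
        start = atgs[0] if atgs else stop5 + 3
    else:
        start = f
    return (start, end)


class TestHomologyExtension:
    def test_constructed_stop_atg_hit_stop(self):
        # 5'-(TAG)(6 nt)(ATG ... hit ... )(TGA)-3'
        rng = np.random.default_rng(0)
        inner = simulate._cds_with_gc3(rng, 50, 0.5)  # ATG...stop
        body = inner[:-3]  # strip its stop; we provide our own context
        seq = "TAG" + "ACACAC" + body + "TGA"
        cds_start = 9
        cds_end = len(seq)
        hs, he = cds_start + 9, cds_start + 9 + 3 * 30
        ann = cds_from_homology(
            "u1", seq,
            _hit((hs, he), frame=hs % 3 + 1, subject_interval=(0, 90),
                 subject_length=100),
        )
        assert ann.interval == (cds_start, cds_end)
        assert ann.completeness == cds.COMPLETE
        assert ann.interval == orf_oracle(seq, hs % 3 + 1, (hs, he))

    def test_no_upstream_stop_partial_5p(self):
        rng = np.random.default_rng(1)
        body = simulate._cds_with_gc3(rng, 60, 0.5)[3:-3]  # codons, no ATG/stop
        seq = body + "TGA"
        hs = 30
        ann = cds_from_homology(
            "u1", seq, _hit((hs, hs + 60), frame=hs % 3 + 1)
        )
        assert ann.completeness == cds.PARTIAL_5P
        assert ann.interval[0] == hs % 3
        assert ann.interval == orf_oracle(seq, hs % 3 + 1, (hs, hs + 60))

    def test_low_coverage_downgrades_completeness(self):
        rng = np.random.default_rng(2)
        inner = simulate._cds_with_gc3(rng, 60, 0.5)
        seq = "TAG" + inner
        hs = 3 + 9
        ann = cds_from_homology(
            "u1", seq,
            _hit((hs, hs + 90), subject_interval=(0, 70), subject_length=100,
                 frame=hs % 3 + 1),
        )
        # structurally complete but hit covers only 70% of the subject
        assert ann.coverage_of_best_hit == pytest.approx(0.7)
        assert ann.completeness == cds.PARTIAL_BOTH

    def test_matches_orf_oracle_on_random_constructions(self):
        rng = np.random.default_rng(3)
        mismatches = 0
        for i in range(300):
            tx = simulate.generate_transcriptome(1, seed=5000 + i)[0]
            seq = tx.mrna
            cs, ce = tx.cds_interval
            margin = int(rng.integers(2, 8)) * 3
            hs, he = cs + margin, ce - margin - 3
            if he - hs < 30:
                continue
            frame = hs % 3 + 1
            ann = cds_from_homology("u", seq, _hit((hs, he), frame=frame))
            if ann.interval != orf_oracle(seq, frame, (hs, he)):
                mismatches += 1
        assert mismatches == 0

    def test_reverse_frame(self):
        tx = simulate.generate_transcriptome(1, seed=44)[0]
        w = tx.mrna
        seq = revcomp(w)  # unigene read out on the other strand
        cs, ce = tx.cds_interval
        hs, he = cs + 12, ce - 15
        frame = -(hs % 3 + 1)
        ann = cds_from_homology("u", seq, _hit((hs, he), frame=frame))
        assert ann.strand == "-"
        assert ann.interval == (cs, ce)
        _u5, cseq, _u3 = ann.regions(seq)
        assert cseq == tx.cds_seq

    def test_evalue_gate(self):
        with pytest.raises(ValueError):
            cds_from_homology("u", "ATG" * 50, _hit((0, 30), evalue=1e-3))

    def test_frame_interval_consistency_checked(self):
        with pytest.raises(ValueError):
            cds_from_homology("u", "A" * 120, _hit((1, 31), frame=1))


class TestFrameshiftMasking:
    def test_two_frames_gap_masked(self):
        # +1 then +2: nine junction codons plus the single shifted base
        rng = np.random.default_rng(4)
        a = simulate._random_dna(rng, 60, 0.5)
        gap = simulate._random_dna(rng, 10, 0.5)
        b = simulate._random_dna(rng, 60, 0.5)
        seq = a + gap + b + "C"
        protein = mask_frameshift(
            seq,
            [
                _hit((0, 60), frame=1),
                _hit((70, 130), frame=2),
            ],
        )
        assert "XXX" in protein
        assert protein.count("X") == 3
        assert len(protein) == 20 + 3 + 20

    def test_single_frame_no_mask(self):
        seq = "ATG" + "GCT" * 40
        protein = mask_frameshift(seq, [_hit((0, 60), frame=1)])
        assert "X" not in protein

    def test_same_frame_overlap_merged(self):
        seq = "ATG" + "GCT" * 40
        protein = mask_frameshift(
            seq, [_hit((0, 60), frame=1), _hit((30, 90), frame=1)]
        )
        assert "X" not in protein
        assert len(protein) == 30

    def test_opposite_orientation_rejected(self):
        with pytest.raises(ValueError):
            mask_frameshift(
                "A" * 200, [_hit((0, 60), frame=1), _hit((90, 150), frame=-2)]
            )


@pytest.fixture(scope="module")
def model():
    tx = simulate.generate_transcriptome(80, seed=81)
    return CodingModel.train(
        [t.cds_seq for t in tx],
        [t.utr5_seq + t.utr3_seq for t in tx],
    )


class TestCodingModel:
    def test_coding_scores_higher_in_expectation(self, model):
        rng = np.random.default_rng(5)
        wins = 0
        n = 200
        for _ in range(n):
            coding = model.sample(600, rng, which="coding")
            background = model.sample(600, rng, which="background")
            wins += coding_score(coding, model)[0] > coding_score(background, model)[0]
        assert wins / n > 0.95

    def test_reverse_complement_same_score_set(self, model):
        tx = simulate.generate_transcriptome(1, seed=82)[0]
        fwd = frame_scores(tx.mrna, model)
        rev = frame_scores(revcomp(tx.mrna), model)
        assert sorted(fwd.values()) == pytest.approx(sorted(rev.values()))

    def test_concatenation_additivity(self, model):
        rng = np.random.default_rng(6)
        a = model.sample(300, rng, which="coding")
        b = model.sample(300, rng, which="coding")
        sa = frame_scores(a, model)[1]
        sb = frame_scores(b, model)[1]
        sab = frame_scores(a + b, model)[1]
        # in-frame concatenation only adds the junction hexamers
        assert sab >= sa + sb - 10.0

    def test_too_short_rejected(self, model):
        with pytest.raises(ValueError):
            coding_score("ACGTA", model)


class TestCutoffOptimization:
    def test_perfectly_separated(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [False, False, False, True, True, True]
        roc = optimize_cutoff(scores, labels)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert 3 < roc.cutoff <= 10

    def test_sens_spec_equal_direct_counting(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0, 1, 300), rng.normal(1.5, 1, 300)])
        labels = np.array([False] * 300 + [True] * 300)
        roc = optimize_cutoff(scores, labels)
        c = roc.cutoff
        sens = (scores[labels] >= c).mean()
        spec = (scores[~labels] < c).mean()
        assert roc.sensitivity == pytest.approx(sens)
        assert roc.specificity == pytest.approx(spec)

    def test_roc_monotonicity(self):
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        labels = np.array([False] * 200 + [True] * 200)
        table = optimize_cutoff(scores, labels).table
        assert (np.diff(table["sensitivity"]) <= 1e-12).all()
        assert (np.diff(table["specificity"]) >= -1e-12).all()

    def test_permuted_labels_give_null_j(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, 1000)
        labels = rng.random(1000) < 0.5
        j = optimize_cutoff(scores, labels).table["youden_j"].max()
        # permutation null: max J of a 500/500 split stays small
        assert j < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_cutoff([1, 2, 3], [True, True, True])


class TestReconcile:
    def _ann(self, source):
        return cds.CdsAnnotation(
            unigene_id="u", interval=(0, 30), frame=1, protein="M" * 9,
            completeness=cds.COMPLETE, source=source,
        )

    def test_homology_precedence(self):
        hom, ab = self._ann("homology"), self._ann("ab_initio")
        final = reconcile(hom, ab, ab_initio_score=500, cutoff=200)
        assert final.source == "homology"
        assert final.secondary_evidence == "ab_initio"

    def test_ab_initio_below_cutoff_dropped(self):
        ab = self._ann("ab_initio")
        assert reconcile(None, ab, ab_initio_score=100, cutoff=200) is None

    def test_homology_kept_regardless_of_score(self):
        hom = self._ann("homology")
        final = reconcile(hom, None, ab_initio_score=-1000, cutoff=200)
        assert final is hom
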