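"""Pixel-metric correctness: hand-derived cases, a brute-force oracle, and
symmetry/bound properties."""

import numpy as np
import pytest

from translung.metrics import (
    CohortSummary,
    compare_methods,
    confusion,
    score,
    summarize,
)


def brute_force_score(pred, ref):
    """Independent pixel-enumeration implementation of the five metrics."""
    tp = fp = tn = fn = 0
    for p, r in zip(np.asarray(pred).ravel(), np.asarray(ref).ravel()):
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    total = tp + fp + tn + fn
    acc = (tp + tn) / total
    overlap = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    prec = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
    rec = tp / (tp + fn) if tp + fn else (1.0 if fp == 0 else 0.0)
    f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return acc, overlap, prec, rec, f


def _mask(rows):
    return np.array(rows, dtype=np.uint8)


class TestConfusion:
    def test_identity(self):
        m = _mask([[1, 1, 0, 0]] * 4)  # 8 fg / 8 bg
        c = confusion(m, m)
        assert (c.tp, c.fp, c.tn, c.fn) == (8, 0, 8, 0)

    def test_total_disagreement(self):
        pred = np.ones((4, 4), dtype=np.uint8)
        ref = np.zeros((4, 4), dtype=np.uint8)
        c = confusion(pred, ref)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 16, 0, 0)

    def test_enumerated_case(self):
        # |pred|=6, |ref|=4, |pred∧ref|=3 on a 4x4 grid
        pred = _mask([[1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 0], [0, 0, 0, 0]])
        ref = _mask([[1, 1, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 0]])
        c = confusion(pred, ref)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 3, 1, 9)
        rec = score(pred, ref)
        assert rec.accuracy == 0.75
        assert rec.overlap == pytest.approx(3 / 7)
        assert rec.precision == 0.5
        assert rec.recall == 0.75
        assert rec.f_measure == pytest.approx(0.6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8))


class TestScore:
    def test_perfect_match_scores_one(self):
        m = _mask([[1, 0], [0, 1]])
        r = score(m, m)
        assert (r.accuracy, r.overlap, r.precision, r.recall, r.f_measure) == (1, 1, 1, 1, 1)

    def test_disjoint_nonempty(self):
        pred = _mask([[1, 0], [0, 0]])
        ref = _mask([[0, 0], [0, 1]])
        r = score(pred, ref)
        assert r.overlap == 0.0
        assert r.f_measure == 0.0
        assert r.accuracy == 0.5  # the two tn pixels

    def test_empty_masks_are_perfect(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        r = score(z, z)
        assert (r.overlap, r.precision, r.recall, r.f_measure) == (1, 1, 1, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            pred = (rng.random((16, 16)) < rng.random()).astype(np.uint8)
            ref = (rng.random((16, 16)) < rng.random()).astype(np.uint8)
            r = score(pred, ref)
            acc, ov, p, rc, f = brute_force_score(pred, ref)
            assert (r.accuracy, r.overlap, r.precision, r.recall, r.f_measure) == (acc, ov, p, rc, f)

    def test_symmetry_properties(self, rng):
        for _ in range(25):
            a = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            b = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            ra, rb = score(a, b), score(b, a)
            assert ra.accuracy == rb.accuracy
            assert ra.overlap == rb.overlap
            assert ra.precision == rb.recall

    def test_overlap_bounded_by_precision_and_recall(self, rng):
        for _ in range(25):
            a = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            b = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            r = score(a, b)
            if r.counts.tp + r.counts.fp and r.counts.tp + r.counts.fn:
                assert r.overlap <= min(r.precision, r.recall) + 1e-12


class TestSummarize:
    def test_singleton(self):
        r = score(np.ones((2, 2), dtype=np.uint8), np.ones((2, 2), dtype=np.uint8), "a")
        s = summarize([r], "f_measure")
        assert s.minimum == s.maximum == s.mean == 1.0
        assert s.standard_deviation == 0.0

    def test_population_sd(self):
        recs = []
        for f, pid in [(0.8, "a"), (0.9, "b"), (1.0, "c")]:
            base = score(np.ones((2, 2), dtype=np.uint8), np.ones((2, 2), dtype=np.uint8), pid)
            recs.append(type(base)(pair_id=pid, counts=base.counts, accuracy=f,
                                   overlap=f, precision=f, recall=f, f_measure=f))
        s = summarize(recs, "f_measure")
        assert s.mean == pytest.approx(0.9)
        assert s.minimum == 0.8 and s.maximum == 1.0
        assert s.standard_deviation == pytest.approx(0.081649658, abs=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            summarize([], "f_measure")
        r = score(np.zeros((2, 2), dtype=np.uint8), np.zeros((2, 2), dtype=np.uint8), "a")
        with pytest.raises(ValueError, match="unknown metric"):
            summarize([r], "dice")


class TestCompareMethods:
    def _records(self, rng, n=5):
        out = []
        for i in range(n):
            a = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            b = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            out.append(score(a, b, pair_id=f"p{i}"))
        return out

    def test_identical_records_identical_rows(self, rng):
        recs = self._records(rng)
        rows = compare_methods({"m1": recs, "m2": list(recs)})
        r1 = {k: v for k, v in rows[0].items() if k != "method"}
        r2 = {k: v for k, v in rows[1].items() if k != "method"}
        assert r1 == r2

    def test_rows_match_summarize(self, rng):
        per_method = {m: self._records(rng) for m in ("a", "b", "c")}
        # re-key records to a shared id set
        rows = {r["method"]: r for r in compare_methods(per_method)}
        for m, recs in per_method.items():
            assert rows[m]["f_measure_mean"] == summarize(recs, "f_measure").mean
            assert rows[m]["overlap_sd"] == summarize(recs, "overlap").standard_deviation

    def test_mismatched_ids_raise(self, rng):
        recs = self._records(rng)
        other = self._records(rng)[:3]
        with pytest.raises(ValueError, match="pair_id"):
            compare_methods({"a": recs, "b": other})
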