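import math

import numpy as np
import pytest
from scipy import stats

from d2nnlm import (
    EvalReport,
    auc_variance,
    lpocv_auc,
    lpocv_pairs,
    pairwise_auc,
    percent_error,
    perplexity,
    significance,
)


# -- percent error ----------------------------------------------------------------

def test_percent_error_values():
    assert np.isclose(percent_error(list("aaaaaaaab"), list("aaaaaaaaa")), 100 / 9)
    assert percent_error(["a", "b"], ["a", "b"]) == 0.0
    assert percent_error(["a", "b"], ["b", "a"]) == 100.0
    with pytest.raises(ValueError):
        percent_error([], [])


# -- perplexity -------------------------------------------------------------------

def test_perplexity_closed_forms():
    assert np.isclose(perplexity([0.5, 0.5, 0.5]), 2.0)
    assert np.isclose(perplexity([1.0, 1.0]), 1.0)
    assert np.isclose(perplexity([0.5, 1.0]), math.sqrt(2.0))


def test_perplexity_rejects_invalid():
    with pytest.raises(ValueError):
        perplexity([0.5, 0.0])
    with pytest.raises(ValueError):
        perplexity([1.2])
    with pytest.raises(ValueError):
        perplexity([])


# -- LPOCV round structure --------------------------------------------------------

def test_lpocv_pair_counts():
    P = [f"p{i}" for i in range(19)]
    N = [f"n{i}" for i in range(19)]
    rounds = list(lpocv_pairs(P, N))
    assert len(rounds) == 361
    for (p, n), rest in rounds:
        assert len(rest) == 19 + 19 - 2
        assert p not in rest and n not in rest


def test_lpocv_pairs_exact_enumeration():
    rounds = list(lpocv_pairs(["p1", "p2"], ["n1", "n2", "n3"]))
    assert [pair for pair, _ in rounds] == [
        ("p1", "n1"), ("p1", "n2"), ("p1", "n3"),
        ("p2", "n1"), ("p2", "n2"), ("p2", "n3")]
    (pair, rest) = rounds[0]
    assert rest == ["p2", "n2", "n3"]


def test_lpocv_pairs_degenerate():
    with pytest.raises(ValueError):
        list(lpocv_pairs(["p"], ["n1", "n2"]))


# -- pairwise AUC vs rank statistic -----------------------------------------------

def test_pairwise_auc_equals_mann_whitney():
    rng = np.random.default_rng(0)
    for _ in range(25):
        nP, nN = rng.integers(2, 21, size=2)
        pos, neg = rng.normal(1, 1, nP), rng.normal(0, 1, nN)
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert np.isclose(pairwise_auc(pos, neg), u / (nP * nN))


def test_tie_modes_differ_by_half_tied_fraction():
    pos = np.array([1.0, 2.0, 2.0, 3.0])
    neg = np.array([2.0, 0.0])
    tied = int(((pos[:, None]) == neg[None, :]).sum())
    literal = pairwise_auc(pos, neg, tie_value=0.0)
    half = pairwise_auc(pos, neg, tie_value=0.5)
    assert np.isclose(half - literal, 0.5 * tied / (len(pos) * len(neg)))


def test_label_swap_symmetry():
    rng = np.random.default_rng(3)
    pos, neg = rng.normal(1, 1, 9), rng.normal(0, 1, 7)
    assert np.isclose(pairwise_auc(pos, neg), 1.0 - pairwise_auc(neg, pos))


# -- lpocv_auc with trainer -------------------------------------------------------

def _score_lookup(scores):
    def trainer(train_pos, train_neg, seed):
        return None

    def score_fn(model, example):
        return scores[example]

    return trainer, score_fn


def test_lpocv_auc_matches_direct_counting():
    rng = np.random.default_rng(8)
    pos = [f"p{i}" for i in range(4)]
    neg = [f"n{i}" for i in range(4)]
    scores = {e: float(rng.normal()) for e in pos + neg}
    trainer, score_fn = _score_lookup(scores)
    rep = lpocv_auc(trainer, pos, neg, score_fn=score_fn)
    direct = pairwise_auc([scores[p] for p in pos], [scores[n] for n in neg])
    assert rep.auc == direct
    u = stats.mannwhitneyu([scores[p] for p in pos],
                           [scores[n] for n in neg]).statistic
    assert np.isclose(rep.auc, u / 16)


def test_constant_scores_literal_vs_half_ties():
    pos, neg = ["p1", "p2"], ["n1", "n2"]
    trainer, score_fn = _score_lookup({e: 0.7 for e in pos + neg})
    assert lpocv_auc(trainer, pos, neg, score_fn=score_fn).auc == 0.0
    assert lpocv_auc(trainer, pos, neg, score_fn=score_fn,
                     tie_value=0.5).auc == 0.5


def test_trainer_failure_names_round():
    def trainer(tp, tn, seed):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="round 0"):
        lpocv_auc(trainer, ["p1", "p2"], ["n1", "n2"], score_fn=lambda m, e: 0.0)


def test_lpocv_subsampling_deterministic():
    rng = np.random.default_rng(1)
    pos = [f"p{i}" for i in range(6)]
    neg = [f"n{i}" for i in range(6)]
    scores = {e: float(rng.normal()) for e in pos + neg}
    trainer, score_fn = _score_lookup(scores)
    a = lpocv_auc(trainer, pos, neg, score_fn=score_fn, seed=4, max_rounds=10)
    b = lpocv_auc(trainer, pos, neg, score_fn=score_fn, seed=4, max_rounds=10)
    assert a.auc == b.auc


# -- Hanley-McNeil variance -------------------------------------------------------

def _hanley_mcneil_oracle(A, nP, nN):
    # independent implementation straight from the published formula
    Q1 = A / (2 - A)
    Q2 = 2 * A ** 2 / (1 + A)
    return (A * (1 - A) + (nP - 1) * (Q1 - A ** 2)
            + (nN - 1) * (Q2 - A ** 2)) / (nP * nN)


def test_auc_variance_boundary_cases():
    for nP, nN in ((1, 1), (5, 7), (50, 50)):
        assert auc_variance(1.0, nP, nN) == 0.0
    assert np.isclose(auc_variance(0.5, 1, 1), 0.25)


def test_auc_variance_matches_published_formula():
    for A in np.arange(0.1, 0.95, 0.1):
        for nP in (5, 10, 50):
            for nN in (5, 10, 50):
                assert np.isclose(auc_variance(A, nP, nN),
                                  _hanley_mcneil_oracle(A, nP, nN), atol=1e-12)
                assert auc_variance(A, nP, nN) >= 0.0


def test_auc_variance_rejects_bad_inputs():
    with pytest.raises(ValueError):
        auc_variance(1.2, 5, 5)
    with pytest.raises(ValueError):
        auc_variance(0.5, 0, 5)


# -- significance -----------------------------------------------------------------

def test_null_auc_gives_p_one():
    _, _, p = significance(0.5, 0.04, 10, 10)
    assert p == 1.0


def test_zero_se_degenerate():
    se, (lo, hi), p = significance(0.8, 0.0, 10, 10)
    assert se == 0.0 and lo == hi == 0.8 and p == 0.0


def test_ci_normal_quantile_arithmetic():
    # choose variance so that sd / sqrt(nP + nN) = 0.24 with N = 38
    sd = 0.24 * math.sqrt(38)
    se, (lo, hi), p = significance(0.74, sd ** 2, 19, 19)
    assert np.isclose(se, 0.24)
    assert np.isclose(lo, 0.74 - 1.959963984540054 * 0.24, atol=1e-9)
    assert np.isclose(hi, 0.74 + 1.959963984540054 * 0.24, atol=1e-9)
    assert lo < 0.28 and hi > 1.0  # unclipped, like printed negative/overflow bounds


def test_se_denominator_modes():
    se_total, _, _ = significance(0.7, 1.0, 19, 19, se_denominator="total")
    se_pairs, _, _ = significance(0.7, 1.0, 19, 19, se_denominator="pairs")
    assert np.isclose(se_total, 1 / math.sqrt(38))
    assert np.isclose(se_pairs, 1 / math.sqrt(361))


def test_p_monotone_in_distance_from_half():
    ps = [significance(a, 0.01, 10, 10)[2] for a in (0.55, 0.65, 0.75, 0.9)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_report_round_trip(tmp_path):
    rep = EvalReport(percent_error=11.1, perplexity=1.5, auc=0.74, sd=0.08,
                     se=0.013, ci_low=0.71, ci_high=0.77, p_value=0.001,
                     n_pos=19, n_neg=19)
    rep.to_json(tmp_path / "r.json")
    rep.to_tsv(tmp_path / "r.tsv")
    import json
    back = json.loads((tmp_path / "r.json").read_text())
    assert back["auc"] == 0.74 and back["n_pos"] == 19
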