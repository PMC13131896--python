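"""GMT parsing, GSEA running-sum oracles and permutation null, ORA,
per-sample enrichment, TF-pathway correlation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gg1tx.enrichment import (
    ora_hypergeometric,
    preranked_gsea,
    read_gmt,
    sample_enrichment_scores,
    tf_pathway_correlation,
    write_gmt,
)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def test_gmt_parse_dedupe_roundtrip(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("S\tdesc\tg1\tg2\nD\tdesc\tg1\tg2\tg1\n")
    sets = read_gmt(p)
    assert sets == {"S": ["g1", "g2"], "D": ["g1", "g2"]}
    write_gmt(sets, tmp_path / "out.gmt")
    assert read_gmt(tmp_path / "out.gmt") == sets


def test_gmt_malformed_line_and_empty_file(tmp_path):
    bad = tmp_path / "bad.gmt"
    bad.write_text("S\tonlydesc\n")
    with pytest.raises(ValueError, match=":1:"):
        read_gmt(bad)
    empty = tmp_path / "empty.gmt"
    empty.write_text("")
    assert read_gmt(empty) == {}


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

TOY = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "d": -1.0})


def test_gsea_running_sum_hand_oracles():
    """Set {a} at the top walks straight to ES=1; set {d} at the bottom walks
    to -1 (running sum -1/3, -2/3, -1, then back up)."""
    res = preranked_gsea(TOY, {"top": ["a"], "bottom": ["d"]}, n_perm=100, seed=0, min_size=1)
    res = res.set_index("pathway")
    assert res.loc["top", "es"] == pytest.approx(1.0)
    assert res.loc["top", "leading_edge"] == ["a"]
    assert res.loc["bottom", "es"] == pytest.approx(-1.0)
    assert res.loc["bottom", "leading_edge"] == ["d"]
    assert np.sign(res["nes"]).tolist() == np.sign(res["es"]).tolist()


def test_gsea_degenerate_whole_list_set_skipped():
    res = preranked_gsea(TOY, {"all": ["a", "b", "c", "d"]}, n_perm=10, seed=0)
    assert len(res) == 0


def test_gsea_gene_order_invariance_and_sign_flip():
    rng = np.random.default_rng(4)
    stats = pd.Series(rng.normal(size=30), index=[f"g{i:02d}" for i in range(30)])
    sets = {"s1": [f"g{i:02d}" for i in (0, 3, 7, 11)], "s2": [f"g{i:02d}" for i in (20, 25, 29)]}
    a = preranked_gsea(stats, sets, n_perm=500, seed=1)
    b = preranked_gsea(stats.sample(frac=1.0, random_state=9), sets, n_perm=500, seed=1)
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
    neg = preranked_gsea(-stats, sets, n_perm=500, seed=1)
    merged = a.set_index("pathway").join(neg.set_index("pathway"), rsuffix="_neg")
    assert np.allclose(merged["es"], -merged["es_neg"])
    assert np.allclose(np.sign(merged["nes"]), -np.sign(merged["nes_neg"]))


def _exact_es(positions, a, n):
    """Independent running-sum oracle: explicit walk over the ranked list."""
    pos = set(positions)
    nr = sum(a[i] for i in pos)
    running, best = 0.0, 0.0
    for i in range(n):
        if i in pos:
            running += a[i] / nr
        else:
            running -= 1.0 / (n - len(pos))
        if abs(running) > abs(best):
            best = running
    return best


def test_gsea_permutation_p_matches_exhaustive_enumeration():
    """For C(N, s) small, the permutation p approximates the exact
    enumeration over all same-size subsets."""
    rng = np.random.default_rng(7)
    stats = pd.Series(np.sort(rng.normal(size=10))[::-1], index=[f"g{i}" for i in range(10)])
    a = np.abs(stats.to_numpy())
    n = len(stats)
    set_genes = ["g0", "g1", "g3"]
    res = preranked_gsea(stats, {"s": set_genes}, n_perm=8000, seed=3).iloc[0]
    es_obs = res["es"]
    # exhaustive null over all C(10,3)=120 subsets
    es_all = np.array([_exact_es(c, a, n) for c in combinations(range(n), 3)])
    same = es_all > 0 if es_obs >= 0 else es_all < 0
    p_exact = (1 + (np.abs(es_all[same]) >= abs(es_obs)).sum()) / (1 + same.sum())
    assert comb(10, 3) <= 10_000
    assert res["p"] == pytest.approx(p_exact, abs=0.05)
    # the observed ES agrees with the explicit-walk oracle
    assert es_obs == pytest.approx(_exact_es([0, 1, 3], a, n))


def test_gsea_spiked_down_pathway_negative_nes(default_cohort):
    """A pathway built from genes spiked downward in the test group comes out
    with negative NES and adjusted significance."""
    from gg1tx.de import Contrast, run_de
    from tests.conftest import ancestry_groups

    _, cm, md, truth = default_cohort
    res = run_de(cm, Contrast("European", "African", ancestry_groups(md)))
    gt = truth.gene_truth
    down = list(gt.index[(gt["ancestry_lfc"] < 0)][:30])
    up = list(gt.index[(gt["ancestry_lfc"] > 0)][:30])
    neutral = list(gt.index[~gt[["ancestry_de", "cancer_de", "psa_de"]].any(axis=1)][:40])
    ranking = res["stat"].dropna()
    out = preranked_gsea(ranking, {"down_set": down, "up_set": up, "neutral": neutral},
                         n_perm=2000, seed=5).set_index("pathway")
    assert out.loc["down_set", "nes"] < 0 and out.loc["down_set", "padj"] < 0.05
    assert out.loc["up_set", "nes"] > 0 and out.loc["up_set", "padj"] < 0.05


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------


def test_ora_hypergeometric_enumeration_oracle():
    universe = [f"g{i}" for i in range(20)]
    sets = {"s": universe[:5]}
    res = ora_hypergeometric(universe[:5], universe, sets)
    # drawing all 5 set members in 5 draws: p = 1 / C(20,5)
    assert res.iloc[0]["p"] == pytest.approx(1 / comb(20, 5))
    assert res.iloc[0]["gene_ratio"] == 1.0
    # selected == universe -> p = 1 for every set
    res2 = ora_hypergeometric(universe, universe, sets)
    assert res2.iloc[0]["p"] == pytest.approx(1.0)
    # overlap 0 with min_overlap 0 -> P(X >= 0) = 1
    res3 = ora_hypergeometric(universe[10:12], universe, sets, min_overlap=0)
    assert res3.iloc[0]["p"] == pytest.approx(1.0)


def test_ora_selected_outside_universe_rejected():
    with pytest.raises(ValueError, match="not in universe"):
        ora_hypergeometric(["x"], ["a", "b"], {"s": ["a"]})


# ---------------------------------------------------------------------------
# Per-sample enrichment
# ---------------------------------------------------------------------------


def _ssgsea_oracle(expr, genes, inset, weight):
    """Brute-force per-sample KS walk with rank weights (N - i)^weight."""
    n = len(genes)
    order = sorted(range(n), key=lambda i: (-expr[i], genes[i]))
    hits = [genes[i] in inset for i in order]
    w = [(n - i) ** weight if hits[i] else 0.0 for i in range(n)]
    tot_w, tot_miss = sum(w), n - sum(hits)
    p_in = p_out = 0.0
    acc = 0.0
    cw = cm = 0.0
    for i in range(n):
        cw += w[i]
        cm += 0 if hits[i] else 1
        acc += cw / tot_w - cm / tot_miss
    return acc / n


def test_sample_scores_match_brute_force_walk():
    em = pd.DataFrame(
        {"s1": [5.0, 4.0, 3.0, 1.0], "s2": [1.0, 2.0, 5.0, 6.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    scores = sample_enrichment_scores(em, {"set": ["g1", "g2"]}, weight=0.25)
    for s in em.columns:
        expected = _ssgsea_oracle(em[s].tolist(), list(em.index), {"g1", "g2"}, 0.25)
        assert scores.loc["set", s] == pytest.approx(expected)
    # set at the top of s1 but bottom of s2
    assert scores.loc["set", "s1"] > scores.loc["set", "s2"]


def test_sample_scores_monotone_invariance_and_identical_columns():
    rng = np.random.default_rng(2)
    em = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"g{i:02d}" for i in range(20)],
                      columns=["a", "b", "c"])
    em["b"] = em["a"]
    sets = {"s": [f"g{i:02d}" for i in (0, 4, 9, 13)]}
    sc = sample_enrichment_scores(em, sets)
    assert sc.loc["s", "a"] == sc.loc["s", "b"]
    # strictly increasing transform leaves scores unchanged
    em2 = em.copy()
    em2["c"] = np.exp(em2["c"]) * 3 + 1
    sc2 = sample_enrichment_scores(em2, sets)
    assert sc.loc["s", "c"] == pytest.approx(sc2.loc["s", "c"])


def test_single_gene_set_rank_monotonicity():
    em = pd.DataFrame({"first": [9.0, 1.0, 2.0], "last": [0.0, 5.0, 6.0]},
                      index=["g", "x", "y"])
    sc = sample_enrichment_scores(em, {"solo": ["g"]}, min_size=1)
    assert sc.loc["solo", "first"] > sc.loc["solo", "last"]


# ---------------------------------------------------------------------------
# TF-pathway correlation
# ---------------------------------------------------------------------------


def test_tf_pathway_correlation_per_group():
    idx = [f"s{i}" for i in range(8)]
    tf = pd.Series([1, 2, 3, 4, 4, 3, 2, 1], index=idx, dtype=float)
    path = pd.Series([1, 3, 2, 4, 1, 2, 3, 4], index=idx, dtype=float)
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=idx)
    out = tf_pathway_correlation(tf, path, groups)
    # (1,2,3,4) vs (1,3,2,4): rho = 0.8 by the rank formula
    assert out["A"][0] == pytest.approx(0.8)
    # B is perfectly anti-monotone
    assert out["B"][0] == pytest.approx(-1.0)
    # perfect monotone / constant handling
    out2 = tf_pathway_correlation(tf[:4], tf[:4], pd.Series(["A"] * 4, index=idx[:4]))
    assert out2["A"][0] == pytest.approx(1.0)
    const = pd.Series(1.0, index=idx[:4])
    out3 = tf_pathway_correlation(const, path[:4], pd.Series(["A"] * 4, index=idx[:4]))
    assert np.isnan(out3["A"][0])
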