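"""Gene-set enrichment: preranked GSEA, hypergeometric ORA, per-sample
enrichment scores and TF-pathway correlation.

The preranked GSEA is the classic weighted Kolmogorov-Smirnov statistic:
genes are sorted by a signed ranking statistic (descending), the running sum
gains ``|stat|**weight / sum_set |stat|**weight`` at set members and loses
``1 / (N - set size)`` elsewhere, and the enrichment score (ES) is the
running-sum extremum of largest magnitude.  The null is gene-label
permutation: the same set size placed at random positions of the ranked
list, with one shared pool of permutations across pathways.  The permutation
p-value and the normalised enrichment score (NES) are computed against the
same-sign permutation scores only, with a p floor of ``1/(n_perm + 1)``.

The per-sample scores are a rank-based single-sample enrichment statistic
(an ssGSEA-style substitute for kernel-density GSVA): within each sample the
weighted cumulative distribution of set members down the expression ranking
is compared with that of non-members, and the score is the mean difference.
Because it uses within-sample ranks only, it is invariant to any strictly
increasing transform of a sample's expression.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from gg1tx.de import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>gene1<TAB>...``.

    Duplicate genes within a set are removed (order preserved) with a warning;
    a line with fewer than three fields raises with its line number.
    """
    sets: dict[str, list[str]] = {}
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line has {len(fields)} fields, expected >= 3")
        name, genes = fields[0], fields[2:]
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.warning("gene set %s contains duplicate genes; deduplicated", name)
        sets[name] = deduped
    if not sets:
        logger.warning("GMT file %s is empty", path)
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _running_extremum(positions: np.ndarray, weights: np.ndarray, n_genes: int):
    """ES of one gene set given sorted 0-based hit positions and their
    (non-negative) weights; returns (es, extremum_position)."""
    s = len(positions)
    nr = weights.sum()
    if nr == 0:
        weights = np.ones(s)
        nr = float(s)
    miss = 1.0 / (n_genes - s)
    idx = np.arange(s)
    cum = np.cumsum(weights)
    after = cum / nr - (positions - idx) * miss
    before = (cum - weights) / nr - (positions - idx) * miss
    max_i = int(np.argmax(after))
    min_i = int(np.argmin(before))
    if after[max_i] >= -before[min_i]:
        return float(after[max_i]), int(positions[max_i]), True
    return float(before[min_i]), int(positions[min_i]), False


def _perm_es(pos: np.ndarray, a: np.ndarray, n_genes: int) -> np.ndarray:
    """Vectorised permutation ES: ``pos`` is (n_perm, s) distinct positions,
    ``a`` the weight of each position of the ranked list."""
    s = pos.shape[1]
    ps = np.sort(pos, axis=1)
    w = a[ps]
    nr = w.sum(axis=1)
    flat = nr == 0
    if flat.any():
        w[flat] = 1.0
        nr[flat] = s
    miss = 1.0 / (n_genes - s)
    idx = np.arange(s)[None, :]
    cum = np.cumsum(w, axis=1)
    drop = (ps - idx) * miss
    after = cum / nr[:, None] - drop
    before = (cum - w) / nr[:, None] - drop
    mx = after.max(axis=1)
    mn = before.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def rank_genes(ranking: pd.Series) -> pd.Series:
    """Sort a gene -> statistic Series descending, ties broken by gene ID."""
    if ranking.index.duplicated().any():
        raise ValueError("ranking has duplicate gene IDs")
    if ranking.isna().any():
        ranking = ranking.dropna()
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    return ranking.loc[order]


def preranked_gsea(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
    min_size: int = 2,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    Parameters
    ----------
    ranking
        Gene -> signed ranking statistic (e.g. the DE Wald statistic).
    sets
        Gene-set collection; each set is intersected with the ranked genes
        and kept if its size lies in ``[min_size, max_size]``.
    n_perm, weight, seed
        Permutation count, KS weight exponent, and RNG seed (a shared pool of
        permutations is used for all pathways, so results are reproducible
        for a given seed regardless of pathway order).

    Returns
    -------
    pandas.DataFrame
        One row per retained pathway: ``pathway, es, nes, p, padj, size,
        leading_edge`` (list of genes at or before the extremum for positive
        ES, at or after it for negative ES).
    """
    ranked = rank_genes(ranking)
    genes = list(ranked.index)
    pos_of = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    a = np.abs(ranked.to_numpy()) ** weight

    members: dict[str, np.ndarray] = {}
    for name, gs in sets.items():
        inset = sorted({g for g in gs if g in pos_of})
        if len(inset) < min_size:
            logger.warning("gene set %s has %d genes in the ranking (< %d); skipped", name, len(inset), min_size)
            continue
        if max_size is not None and len(inset) > max_size:
            logger.warning("gene set %s has %d genes (> %d); skipped", name, len(inset), max_size)
            continue
        if len(inset) >= n:
            logger.warning("gene set %s covers the whole ranked list; skipped", name)
            continue
        members[name] = np.array(sorted(pos_of[g] for g in inset))
    if not members:
        return pd.DataFrame(columns=["pathway", "es", "nes", "p", "padj", "size", "leading_edge"])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s_max = max(len(v) for v in members.values())
    # one shared pool: each row is an s_max-subset drawn without replacement;
    # a size-s pathway uses the first s entries of every row
    pool = np.empty((n_perm, s_max), dtype=np.int64)
    for i in range(n_perm):
        pool[i] = rng.choice(n, size=s_max, replace=False)

    rows = []
    for name, positions in members.items():
        es, ext_pos, positive = _running_extremum(positions, a[positions], n)
        es_perm = _perm_es(pool[:, : len(positions)], a, n)
        same_sign = es_perm > 0 if es >= 0 else es_perm < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1 + int((np.abs(es_perm[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / np.abs(es_perm[same_sign]).mean()
        if positive:
            lead = [genes[i] for i in positions if i <= ext_pos]
        else:
            lead = [genes[i] for i in positions if i >= ext_pos]
        rows.append(
            {"pathway": name, "es": es, "nes": nes, "p": p, "size": len(positions), "leading_edge": lead}
        )
    res = pd.DataFrame(rows)
    res["padj"] = bh_adjust(res["p"])
    return res[["pathway", "es", "nes", "p", "padj", "size", "leading_edge"]]


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------


def ora_hypergeometric(
    selected: list[str],
    universe: list[str],
    sets: dict[str, list[str]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """One-sided (upper-tail) hypergeometric over-representation test.

    ``selected`` must be a subset of ``universe``; each gene set is
    intersected with the universe first.  Sets with overlap below
    ``min_overlap`` are excluded before BH adjustment.  Returns one row per
    reported set: ``pathway, overlap, set_size, universe_size, selected_size,
    gene_ratio, p, padj``.
    """
    uni = set(universe)
    sel = set(selected)
    offenders = sorted(sel - uni)
    if offenders:
        raise ValueError(f"selected genes not in universe: {offenders[:10]}")
    rows = []
    for name, gs in sets.items():
        in_uni = {g for g in gs if g in uni}
        if not in_uni:
            continue
        k = len(in_uni & sel)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(in_uni), len(sel)))
        rows.append(
            {
                "pathway": name,
                "overlap": k,
                "set_size": len(in_uni),
                "universe_size": len(uni),
                "selected_size": len(sel),
                "gene_ratio": k / len(sel) if sel else np.nan,
                "p": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows, columns=["pathway", "overlap", "set_size", "universe_size",
                                      "selected_size", "gene_ratio", "p"])
    res["padj"] = bh_adjust(res["p"]) if len(res) else np.nan
    return res


# ---------------------------------------------------------------------------
# Per-sample enrichment (GSVA stand-in)
# ---------------------------------------------------------------------------


def sample_enrichment_scores(
    em: pd.DataFrame,
    sets: dict[str, list[str]],
    weight: float = 0.25,
    min_size: int = 2,
) -> pd.DataFrame:
    """Rank-based per-sample enrichment scores (pathway x sample).

    Within each sample, genes are ordered by expression descending (ties
    broken by gene ID); position ``i`` (0-based) carries rank weight
    ``(N - i) ** weight``.  A set's score is the mean over positions of the
    difference between the weighted cumulative in-set fraction and the
    uniform cumulative out-of-set fraction — positive when the set
    concentrates at the top of the sample's ranking.  Sets with fewer than
    ``min_size`` genes in the matrix are skipped with a warning.
    """
    if em.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    genes = list(em.index)
    keep = {}
    for name, gs in sets.items():
        inset = sorted({g for g in gs if g in em.index})
        if len(inset) < min_size or len(inset) >= len(genes):
            logger.warning("gene set %s skipped for per-sample scoring (size %d)", name, len(inset))
            continue
        keep[name] = inset
    n = len(genes)
    rank_w = (n - np.arange(n, dtype=float)) ** weight
    scores = pd.DataFrame(index=list(keep), columns=em.columns, dtype=float)
    gene_arr = np.array(genes)
    for sample in em.columns:
        expr = em[sample]
        order = sorted(range(n), key=lambda i: (-expr.iloc[i], genes[i]))
        ordered_genes = gene_arr[order]
        for name, inset in keep.items():
            hit = np.isin(ordered_genes, list(inset))
            s = hit.sum()
            w_hit = np.where(hit, rank_w, 0.0)
            p_in = np.cumsum(w_hit) / w_hit.sum()
            p_out = np.cumsum(~hit) / (n - s)
            scores.loc[name, sample] = float(np.mean(p_in - p_out))
    return scores


# ---------------------------------------------------------------------------
# TF <-> pathway correlation
# ---------------------------------------------------------------------------


def tf_pathway_correlation(
    tf_expr: pd.Series,
    pathway_scores: pd.Series,
    groups: pd.Series,
) -> dict[str, tuple[float, float]]:
    """Spearman correlation between a transcription factor's expression and a
    pathway's per-sample enrichment score, computed independently per group
    (e.g. per ancestry).  Returns group -> (rho, two-sided p); rho is NaN when
    either vector is constant within a group, and groups with fewer than 3
    samples get a NaN p-value.
    """
    out: dict[str, tuple[float, float]] = {}
    for label, samples in groups.groupby(groups).groups.items():
        samples = [s for s in samples if s in tf_expr.index and s in pathway_scores.index]
        x = tf_expr.loc[samples].astype(float)
        y = pathway_scores.loc[samples].astype(float)
        if x.nunique() <= 1 or y.nunique() <= 1:
            logger.warning("constant vector in group %s; rho undefined", label)
            out[str(label)] = (np.nan, np.nan)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, y)
        if len(x) < 3:
            p = np.nan
        out[str(label)] = (float(rho), float(p))
    return out
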