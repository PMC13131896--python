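"""Ward/Spearman clustering of cell-type score profiles and composition
summaries, including the occult-disease fraction and the PSA x dominant cell
type x cancer status flow table.

Samples are clustered on the dissimilarity ``1 - Spearman rho`` between
their cell-type score vectors using Ward's minimum-variance agglomeration
(the common heatmap-package practice of running Ward on a non-Euclidean
correlation distance).  Within a PSA-high subset this separates a
stromal/immune-rich "benign-like" profile from a luminal-epithelial
"cancer-like" profile; non-cancer samples falling in the cancer-like
cluster are the operational definition of potential occult disease.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from gg1tx.celltype import PANEL_ORDER

logger = logging.getLogger(__name__)


def spearman_distance_matrix(scores: pd.DataFrame) -> np.ndarray:
    """Pairwise ``1 - Spearman rho`` between sample rows of a sample x
    cell-type score table; samples with a constant score vector get the
    maximum dissimilarity (2) to every other sample, with a warning."""
    X = scores.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, X)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant score vectors for samples %s; dissimilarity set to 2",
            list(scores.index[constant]),
        )
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((centred**2).sum(axis=1))
    denom[constant] = 1.0
    rho = (centred @ centred.T) / np.outer(denom, denom)
    d = 1.0 - rho
    d[constant, :] = 2.0
    d[:, constant] = 2.0
    np.fill_diagonal(d, 0.0)
    return d


def spearman_ward_cluster(
    scores: pd.DataFrame,
    samples: list[str] | None = None,
    k: int = 2,
    standardize: bool = True,
) -> pd.Series:
    """Ward hierarchical clustering on 1 - Spearman dissimilarity, cut at
    ``k`` clusters.

    With ``standardize`` (default) each cell-type score is z-scored across
    the clustered samples first, so that panels with systematically higher
    scores (more or stronger markers) do not dominate every sample's
    within-sample ranking — the profile compared between samples is then
    relative enrichment per cell type, as in heatmap-style clustering of
    standardised score rows.

    Cluster IDs (1..k) are relabelled by first appearance in the input sample
    order, so the assignment is deterministic and invariant to how the tree
    happens to number its leaves.
    """
    sub = scores.loc[samples] if samples is not None else scores
    if k < 2 or len(sub) < k:
        raise ValueError(f"need subset size >= k >= 2 (got n={len(sub)}, k={k})")
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 scored cell types")
    if standardize:
        sd = sub.std(ddof=1).replace(0.0, 1.0)
        sub = (sub - sub.mean()) / sd
    d = spearman_distance_matrix(sub)
    Z = linkage(squareform(d, checks=False), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    return pd.Series([relabel[c] for c in raw], index=sub.index, name="cluster")


def cluster_composition(assign: pd.Series, md: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster sample counts, cancer-status counts and fractions, and
    pathology condition counts (BPH / prostatitis / ASAP).

    Percentages are reported to one decimal, matching how cluster
    compositions are conventionally quoted (e.g. 10 of 16 -> 62.5%).
    """
    missing = [s for s in assign.index if s not in md.index]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:10]}")
    rows = []
    for cluster, members in assign.groupby(assign).groups.items():
        sub = md.loc[list(members)]
        n = len(sub)
        n_pca = int((sub["cancer_status"] == "PCa").sum())
        n_non = n - n_pca
        rows.append(
            {
                "cluster": cluster,
                "n": n,
                "n_pca": n_pca,
                "n_nonpca": n_non,
                "pct_pca": round(100.0 * n_pca / n, 1),
                "pct_nonpca": round(100.0 * n_non / n, 1),
                "n_bph": int(sub["bph"].sum()) if "bph" in sub else 0,
                "n_prostatitis": int(sub["prostatitis"].sum()) if "prostatitis" in sub else 0,
                "n_asap": int(sub["asap"].sum()) if "asap" in sub else 0,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def identify_cancer_like_cluster(assign: pd.Series, scores: pd.DataFrame) -> int:
    """The cancer-like cluster is the one with the higher mean luminal
    z-score (z across the clustered samples)."""
    if "luminal" not in scores.columns:
        raise ValueError("scores must include a 'luminal' column")
    lum = scores.loc[assign.index, "luminal"].astype(float)
    z = (lum - lum.mean()) / (lum.std(ddof=1) or 1.0)
    means = z.groupby(assign).mean()
    return int(means.idxmax())


def occult_fraction(
    assign: pd.Series,
    md: pd.DataFrame,
    cancer_like_cluster: int | None = None,
    scores: pd.DataFrame | None = None,
) -> tuple[float, dict]:
    """Fraction of non-cancer samples that fall in the cancer-like cluster —
    the operational occult-disease rate.

    ``cancer_like_cluster`` may be given explicitly or identified from
    ``scores`` (higher mean luminal z-score).  Returns ``(fraction, detail)``
    where detail holds the counts and the integer-percent report; the
    fraction is NaN when the clustered subset has no non-cancer samples.
    """
    if cancer_like_cluster is None:
        if scores is None:
            raise ValueError("provide cancer_like_cluster or scores to identify it")
        cancer_like_cluster = identify_cancer_like_cluster(assign, scores)
    sub = md.loc[assign.index]
    nonpca = sub.index[sub["cancer_status"] == "non-PCa"]
    detail = {
        "cancer_like_cluster": int(cancer_like_cluster),
        "n_nonpca": len(nonpca),
        "n_nonpca_cancer_like": int((assign.loc[nonpca] == cancer_like_cluster).sum()),
    }
    if len(nonpca) == 0:
        logger.warning("no non-PCa samples in the clustered subset; occult fraction undefined")
        detail["percent"] = None
        return float("nan"), detail
    frac = detail["n_nonpca_cancer_like"] / detail["n_nonpca"]
    detail["percent"] = int(round(100.0 * frac))
    return frac, detail


def dominant_cell_type(scores: pd.DataFrame, order: tuple[str, ...] = PANEL_ORDER) -> pd.Series:
    """Per-sample dominant cell type: argmax over z-scored signature scores
    (z across samples per cell type, so panels of different marker counts are
    comparable); exact ties break by fixed panel order."""
    cols = [c for c in order if c in scores.columns] + [
        c for c in scores.columns if c not in order
    ]
    z = pd.DataFrame(index=scores.index, columns=cols, dtype=float)
    for c in cols:
        x = scores[c].astype(float)
        sd = x.std(ddof=1)
        z[c] = 0.0 if (not np.isfinite(sd) or sd == 0) else (x - x.mean()) / sd
    out = {}
    for s in scores.index:
        row = z.loc[s]
        if row.isna().all():
            logger.warning("sample %s has no scored cell type; dominant unassigned", s)
            out[s] = None
            continue
        out[s] = max(cols, key=lambda c: (0 if pd.isna(row[c]) else 1, row[c] if not pd.isna(row[c]) else -np.inf, -cols.index(c)))
    return pd.Series(out, name="dominant_cell_type")


def flow_table(md: pd.DataFrame, dominant: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-way contingency counts over (PSA group x dominant cell type x
    cancer status) for samples with known PSA group; PSA-unknown samples are
    tallied separately in the second returned table.

    Requires ``psa_group`` in the metadata (see
    :func:`gg1tx.io_qc.assign_psa_groups`) and a dominant cell type for every
    included sample.
    """
    if "psa_group" not in md.columns:
        raise ValueError("metadata needs a 'psa_group' column; run assign_psa_groups first")
    samples = list(dominant.index)
    unassigned = [s for s in samples if dominant[s] is None]
    if unassigned:
        raise ValueError(f"dominant cell type unassigned for: {unassigned[:10]}")
    sub = md.loc[samples].copy()
    sub["dominant"] = dominant.loc[samples]
    known = sub[sub["psa_group"] != "unknown"]
    unknown = sub[sub["psa_group"] == "unknown"]
    counts = (
        known.groupby(["psa_group", "dominant", "cancer_status"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    unknown_counts = (
        unknown.groupby(["dominant", "cancer_status"], observed=True).size().rename("n").reset_index()
    )
    return counts, unknown_counts
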