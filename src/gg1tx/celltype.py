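"""Marker-panel cell-type signature scores and tumour-content estimation.

A cell type's signature score in a sample is the mean log2 expression of its
marker genes — a deliberately simple, deconvolution-free readout of cellular
composition in bulk prostate tissue.  The default panels cover the five
compartments of the prostate microenvironment:

* basal epithelium: KRT5, KRT14, TP63
* luminal epithelium: KLK3, AR, NKX3-1, FOLH1
* stroma: ACTA2, COL1A1, VIM, TAGLN
* immune: CD68, CD3E, TNF, CXCL8, IL6, CCL2
* endothelium: PECAM1, VEGFA, FLT1

The tumour-content estimation score contrasts recognised prostate-tumour
markers against basal markers (tumour glands lose the basal layer):
``score_s = z(mean log2 of {AMACR, PCA3, HOXC4, HOXC6, FOLH1})_s
- z(mean log2 of {TP63, KRT5, KRT14})_s`` with z-scaling across samples.
Higher values indicate more tumour-like expression.  Scores are stratified
into very high / high / moderate / low classes by the quartiles of a
reference (cancer-diagnosed) subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PANELS: dict[str, list[str]] = {
    "basal": ["KRT5", "KRT14", "TP63"],
    "luminal": ["KLK3", "AR", "NKX3-1", "FOLH1"],
    "stromal": ["ACTA2", "COL1A1", "VIM", "TAGLN"],
    "immune": ["CD68", "CD3E", "TNF", "CXCL8", "IL6", "CCL2"],
    "endothelial": ["PECAM1", "VEGFA", "FLT1"],
}
PANEL_ORDER = ("basal", "luminal", "stromal", "immune", "endothelial")

# FOLH1 intentionally appears both in the luminal panel and the tumour score.
TUMOUR_MARKERS = ["AMACR", "PCA3", "HOXC4", "HOXC6", "FOLH1"]
BASAL_MARKERS = ["TP63", "KRT5", "KRT14"]

TUMOUR_CLASSES = ("low", "moderate", "high", "very high")


def signature_scores(
    em: pd.DataFrame,
    panels: dict[str, list[str]] | None = None,
    detection_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x cell-type signature scores (mean log2 expression of markers).

    A marker is used only if it is present in the expression matrix (genes
    removed by QC count as undetected) and, when ``detection_threshold`` is
    given, its mean expression exceeds that threshold; markers failing either
    rule are dropped panel-wide with a logged note.  Returns ``(scores,
    coverage)`` where coverage is the fraction of each panel's markers used;
    a panel with zero detected markers yields NaN scores and a warning.
    """
    if panels is None:
        panels = DEFAULT_PANELS
    scores = pd.DataFrame(index=em.columns, columns=list(panels), dtype=float)
    coverage = pd.DataFrame(index=em.columns, columns=list(panels), dtype=float)
    for ct, markers in panels.items():
        if not markers:
            raise ValueError(f"panel {ct!r} is empty")
        used = [g for g in markers if g in em.index]
        dropped = [g for g in markers if g not in em.index]
        if detection_threshold is not None:
            below = [g for g in used if em.loc[g].mean() <= detection_threshold]
            dropped += below
            used = [g for g in used if g not in below]
        if dropped:
            logger.info("panel %s: markers dropped as undetected: %s", ct, dropped)
        coverage[ct] = len(used) / len(markers)
        if not used:
            logger.warning("panel %s has no detected markers; scores missing", ct)
            scores[ct] = np.nan
        else:
            scores[ct] = em.loc[used].mean(axis=0)
    return scores, coverage


def compare_scores(
    scores: pd.DataFrame,
    groups: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of each cell-type score between
    two groups (exact when combined n <= 20 and there are no ties, normal
    approximation with tie correction otherwise)."""
    labels = [group_a, group_b] if group_a is not None else sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a_ids = groups.index[groups == labels[0]]
    b_ids = groups.index[groups == labels[1]]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError(f"empty group among {labels}")
    rows = []
    for ct in scores.columns:
        x = scores.loc[scores.index.intersection(a_ids), ct].dropna()
        y = scores.loc[scores.index.intersection(b_ids), ct].dropna()
        n = len(x) + len(y)
        ties = pd.concat([x, y]).duplicated().any()
        method = "exact" if (n <= 20 and not ties) else "asymptotic"
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"cell_type": ct, "statistic": float(stat), "p": float(p),
                     "n_a": len(x), "n_b": len(y)})
    return pd.DataFrame(rows).set_index("cell_type")


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def tumour_content_score(
    em: pd.DataFrame,
    tumour_markers: list[str] | None = None,
    basal_markers: list[str] | None = None,
) -> pd.Series:
    """Per-sample tumour-content estimation score (z of tumour-marker mean
    minus z of basal-marker mean; z across samples, sample sd).

    Scores sum to zero over samples whenever both z-vectors are defined; a
    zero-variance marker mean contributes all-zero z-scores.
    """
    tumour_markers = TUMOUR_MARKERS if tumour_markers is None else tumour_markers
    basal_markers = BASAL_MARKERS if basal_markers is None else basal_markers
    if em.shape[1] < 2:
        raise ValueError("tumour content score needs >= 2 samples (z-scaling undefined)")
    t_used = [g for g in tumour_markers if g in em.index]
    b_used = [g for g in basal_markers if g in em.index]
    if not t_used or not b_used:
        raise ValueError(
            f"need >= 1 tumour and >= 1 basal marker present (found {t_used} / {b_used})"
        )
    t = em.loc[t_used].mean(axis=0).to_numpy()
    b = em.loc[b_used].mean(axis=0).to_numpy()
    return pd.Series(_z(t) - _z(b), index=em.columns, name="tumour_content_score")


def classify_tumour_content(
    scores: pd.Series,
    reference_samples: list[str],
) -> tuple[pd.Series, dict[str, float]]:
    """Classify tumour-content scores into quartile classes of a reference
    (cancer-diagnosed) subset.

    Q1/Q2/Q3 are linear-interpolation quantiles of the reference scores;
    classes are ``low`` (< Q1), ``moderate`` ([Q1, Q2)), ``high`` ([Q2, Q3))
    and ``very high`` (>= Q3, boundary inclusive at the top).  Returns the
    per-sample class Series and the thresholds used.
    """
    ref = scores.loc[[s for s in reference_samples if s in scores.index]].dropna()
    if len(ref) < 4:
        raise ValueError(f"reference subset needs >= 4 samples, got {len(ref)}")
    q1, q2, q3 = np.quantile(ref.to_numpy(), [0.25, 0.5, 0.75])
    if q1 == q3:
        logger.warning("all reference quartiles equal (%.4g); every sample classed 'very high'", q1)
    vals = scores.to_numpy()
    classes = np.select(
        [vals >= q3, vals >= q2, vals >= q1],
        ["very high", "high", "moderate"],
        default="low",
    )
    return (
        pd.Series(classes, index=scores.index, name="tumour_content_class"),
        {"q1": float(q1), "q2": float(q2), "q3": float(q3)},
    )
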