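"""Cross-cohort replication of differential-expression and pathway results.

Discovery-significant genes are classified against a validation cohort into
a four-way taxonomy plus an ``absent`` class for genes that did not survive
the validation cohort's expression filtering:

* ``validated`` — same log2FC sign and adjusted p < alpha in both cohorts;
* ``concordant_ns`` — same sign, not significant in validation;
* ``discordant_sig`` — opposite sign, significant in validation;
* ``discordant_ns`` — opposite sign, not significant.

Percentages are reported against the genes present in the validation set
post-filter (with the discovery denominator also reported), log2FC
concordance is summarised by Pearson correlation, and pathway-level
validation requires validation significance with a matching NES sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("validated", "concordant_ns", "discordant_sig", "discordant_ns", "absent")


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded to ``decimals`` — the arithmetic behind
    every composition/validation percentage this package reports."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def classify_concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Classify discovery-significant genes by their behaviour in a
    validation cohort.

    ``discovery`` and ``validation`` are DE result tables (columns ``log2fc``
    and ``padj`` indexed by gene).  Only discovery genes with
    ``padj < alpha`` are classified; genes missing from the validation table
    (or with NaN validation statistics) are ``absent``.  Returns the per-gene
    table (``lfc_a, padj_a, lfc_b, padj_b, category``) and a summary dict
    with counts and percentages (per-category percentages use the
    present-in-validation denominator; ``pct_present`` uses the discovery
    denominator).
    """
    sig = discovery[discovery["padj"] < alpha]
    if (sig["log2fc"].fillna(0.0) == 0).any():
        bad = list(sig.index[sig["log2fc"].fillna(0.0) == 0])
        raise ValueError(
            f"discovery-significant genes with log2fc == 0 (corrupt input?): {bad[:10]}"
        )
    rows = {}
    for g in sig.index:
        lfc_a, padj_a = float(sig.loc[g, "log2fc"]), float(sig.loc[g, "padj"])
        if g not in validation.index or pd.isna(validation.loc[g, "log2fc"]) or pd.isna(
            validation.loc[g, "padj"]
        ):
            rows[g] = (lfc_a, padj_a, np.nan, np.nan, "absent")
            continue
        lfc_b = float(validation.loc[g, "log2fc"])
        padj_b = float(validation.loc[g, "padj"])
        concordant = np.sign(lfc_b) == np.sign(lfc_a) and lfc_b != 0
        sig_b = padj_b < alpha
        if concordant and sig_b:
            cat = "validated"
        elif concordant:
            cat = "concordant_ns"
        elif sig_b:
            cat = "discordant_sig"
        else:
            cat = "discordant_ns"
        rows[g] = (lfc_a, padj_a, lfc_b, padj_b, cat)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["lfc_a", "padj_a", "lfc_b", "padj_b", "category"]
    )
    table.index.name = "gene_id"
    counts = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    n_disc = len(table)
    n_present = n_disc - counts["absent"]
    summary = {
        "alpha": alpha,
        "n_discovery_significant": n_disc,
        "n_present_in_validation": n_present,
        "counts": counts,
        "pct_present": percentage(n_present, n_disc) if n_disc else np.nan,
    }
    if n_present:
        summary["pct"] = {
            c: percentage(counts[c], n_present) for c in CATEGORIES if c != "absent"
        }
    return table, summary


def lfc_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of discovery vs validation log2
    fold changes over non-absent genes; (NaN, NaN) if either side has zero
    variance."""
    sub = table[table["category"] != "absent"]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 non-absent genes, got {len(sub)}")
    x, y = sub["lfc_a"].to_numpy(float), sub["lfc_b"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def validate_pathways(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Pathway-level replication: a discovery pathway is validated iff the
    validation run has adjusted p < alpha **and** the NES signs agree.

    Inputs are GSEA result tables with ``pathway``, ``nes`` and ``padj``
    columns; ``discovery`` should already be restricted to the pathways of
    interest (e.g. its significant ones).  Pathways missing from the
    validation table are flagged ``unmatched`` and count as not validated.
    """
    val = validation.set_index("pathway") if "pathway" in validation.columns else validation
    rows = []
    for _, row in (discovery.reset_index() if "pathway" not in discovery.columns else discovery).iterrows():
        name = row["pathway"]
        rec = {"pathway": name, "nes_a": float(row["nes"]), "padj_a": float(row["padj"]),
               "nes_b": np.nan, "padj_b": np.nan, "unmatched": name not in val.index,
               "validated": False}
        if not rec["unmatched"]:
            rec["nes_b"] = float(val.loc[name, "nes"])
            rec["padj_b"] = float(val.loc[name, "padj"])
            rec["validated"] = bool(
                rec["padj_b"] < alpha and np.sign(rec["nes_b"]) == np.sign(rec["nes_a"])
            )
        rows.append(rec)
    table = pd.DataFrame(rows)
    n = len(table)
    n_val = int(table["validated"].sum())
    summary = {
        "n_discovery_pathways": n,
        "n_validated": n_val,
        "pct_validated": percentage(n_val, n) if n else np.nan,
    }
    return table, summary


@dataclass
class RatioSummary:
    ratio: float
    exceeds_bound: bool | None = None


def deg_ratio_summary(count_a: int, count_b: int, bound: float | None = None) -> RatioSummary:
    """Fold ratio of two DEG counts, rounded to one decimal, optionally with
    an exceeds-``bound`` flag (e.g. 123 vs 25 DEGs -> 4.9-fold)."""
    if count_b == 0:
        raise ValueError("denominator DEG count is zero")
    ratio = round(count_a / count_b, 1)
    return RatioSummary(ratio=ratio, exceeds_bound=None if bound is None else ratio > bound)
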