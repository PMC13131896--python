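"""Negative-binomial Wald differential expression between two sample groups.

Per gene the model is NB with variance ``mu + alpha * mu**2`` on normalised
counts and a log-linear group-indicator mean.  The reported log2 fold change
is the log2 ratio of group mean normalised counts (test group over reference,
with a 0.5 pseudocount only when a group mean is zero); the Wald statistic is
``log2fc / se`` against a two-sided standard normal, and p-values are
Benjamini-Hochberg adjusted across tested genes.

Deliberate deviations from heavier DE machinery, stated as this package's
contract: no fold-change shrinkage, no independent filtering, no outlier
replacement, and method-of-moments dispersion instead of a shrinkage trend.
The behavioural guarantees are calibrated type-I error on null data, high
recovery of spiked effects at cohort-scale n, and exact antisymmetry under
swapping the contrast labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gg1tx.io_qc import size_factors

_ALPHA_FLOOR = 1e-8
_LN2 = float(np.log(2.0))


@dataclass
class Contrast:
    """Two-group contrast: ``test`` over ``reference``.

    ``groups`` maps each sample ID to a label; samples whose label is neither
    ``reference`` nor ``test`` are ignored.  Positive log2fc means higher in
    the test group.
    """

    reference: str
    test: str
    groups: dict[str, str] | pd.Series

    def split(self, sample_ids) -> tuple[list[str], list[str]]:
        g = pd.Series(dict(self.groups) if isinstance(self.groups, dict) else self.groups)
        ref = [s for s in sample_ids if g.get(s) == self.reference]
        tst = [s for s in sample_ids if g.get(s) == self.test]
        if self.reference == self.test or set(ref) & set(tst):
            raise ValueError("contrast groups must be disjoint")
        if len(ref) < 2 or len(tst) < 2:
            raise ValueError(
                f"each contrast group needs >= 2 samples "
                f"(reference {self.reference!r}: {len(ref)}, test {self.test!r}: {len(tst)})"
            )
        return ref, tst

    @classmethod
    def from_metadata(cls, md: pd.DataFrame, column: str, reference: str, test: str) -> "Contrast":
        return cls(reference=reference, test=test, groups=md[column])


def estimate_dispersion(cm: pd.DataFrame, sf: pd.Series | None = None) -> pd.Series:
    """Method-of-moments NB dispersion per gene on normalised counts:
    ``alpha = max((s2 - mean) / mean**2, 1e-8)``.  Genes with zero mean get
    the floor (they are untestable)."""
    if cm.shape[1] < 2:
        raise ValueError("dispersion estimation needs >= 2 samples")
    if sf is None:
        sf = size_factors(cm)
    y = cm.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    m = y.mean(axis=1)
    s2 = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, _ALPHA_FLOOR)
    return pd.Series(np.maximum(alpha, _ALPHA_FLOOR), index=cm.index, name="dispersion")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    NaN entries are excluded from the adjustment and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def run_de(cm: pd.DataFrame, contrast: Contrast, sf: pd.Series | None = None) -> pd.DataFrame:
    """NB Wald test per gene for a two-group contrast.

    Returns a DataFrame indexed by gene with columns ``base_mean`` (mean
    normalised count over both groups), ``log2fc`` (test over reference),
    ``se``, ``stat``, ``p``, ``padj``.  Genes with zero counts in both groups
    are excluded from testing and returned with NaN statistics (reported, not
    silently dropped); BH runs over the tested genes only.

    The per-group dispersion entering the Wald variance is pooled from
    within-group moments (residual variance after removing the group means),
    so a genuine group effect does not inflate its own null variance.
    """
    if sf is None:
        sf = size_factors(cm)
    ref_ids, tst_ids = contrast.split(cm.columns)
    y = cm.to_numpy(dtype=float) / sf.loc[list(cm.columns)].to_numpy()[None, :]
    idx = {s: i for i, s in enumerate(cm.columns)}
    ya = y[:, [idx[s] for s in ref_ids]]
    yb = y[:, [idx[s] for s in tst_ids]]
    na, nb = ya.shape[1], yb.shape[1]

    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    va, vb = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)

    # pooled within-group method-of-moments dispersion
    num = (na - 1) * (va - ma) + (nb - 1) * (vb - mb)
    den = (na - 1) * ma**2 + (nb - 1) * mb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha = np.where(np.isfinite(alpha), alpha, _ALPHA_FLOOR)
    alpha = np.maximum(alpha, _ALPHA_FLOOR)

    zero_mask = (ma == 0) | (mb == 0)
    pc = np.where(zero_mask, 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mb + pc) - np.log2(ma + pc)
        var_ma = (ma + alpha * ma**2) / na
        var_mb = (mb + alpha * mb**2) / nb
        se = np.sqrt(var_ma / (ma + pc) ** 2 + var_mb / (mb + pc) ** 2) / _LN2
        stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    untestable = (ma == 0) & (mb == 0)
    for arr in (log2fc, se, stat, p):
        arr[untestable] = np.nan
    res = pd.DataFrame(
        {
            "base_mean": np.concatenate([ya, yb], axis=1).mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=cm.index,
    )
    return res


def significant_genes(res: pd.DataFrame, alpha: float = 0.05, direction: str | None = None,
                      use_adjusted: bool = True) -> list[str]:
    """Gene IDs significant at the given threshold; ``direction`` ``"up"`` /
    ``"down"`` restricts by log2fc sign (used as ORA input)."""
    col = "padj" if use_adjusted else "p"
    mask = res[col] < alpha
    if direction == "up":
        mask &= res["log2fc"] > 0
    elif direction == "down":
        mask &= res["log2fc"] < 0
    elif direction is not None:
        raise ValueError("direction must be 'up', 'down' or None")
    return list(res.index[mask.fillna(False)])
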