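"""Reading, writing and quality control of count matrices and sample metadata.

Conventions used throughout the package:

* A **count matrix** is a :class:`pandas.DataFrame` of non-negative integers
  with gene IDs as the index and sample IDs as the columns.  Gene IDs are
  unique after Ensembl version suffixes (``.N``) are stripped on ingest.
* **Sample metadata** is a :class:`pandas.DataFrame` indexed by sample ID with
  columns ``ancestry`` (``African``/``European``), ``cancer_status``
  (``PCa``/``non-PCa``), ``psa_ng_ml`` (non-negative float, NaN if missing),
  boolean pathology flags ``bph``, ``prostatitis``, ``asap`` and, once
  derived, ``psa_group`` (``high``/``low``/``unknown``).
* An **expression matrix** is a gene x sample DataFrame of log2-normalised
  values, ``log2(count / sizefactor + 1)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")

METADATA_COLUMNS = ("ancestry", "cancer_status", "psa_ng_ml", "bph", "prostatitis", "asap")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def strip_gene_versions(gene_ids) -> list[str]:
    """Strip trailing Ensembl-style version suffixes (``ENSG...0001.7`` -> ``...0001``)."""
    return [_VERSION_SUFFIX.sub("", str(g)) for g in gene_ids]


def _check_counts_frame(df: pd.DataFrame) -> pd.DataFrame:
    stripped = strip_gene_versions(df.index)
    dupes = pd.Index(stripped)[pd.Index(stripped).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate gene IDs after version stripping: {sorted(dupes)[:10]}")
    df.index = pd.Index(stripped, name="gene_id")
    if df.columns.duplicated().any():
        raise ValueError(
            f"duplicate sample IDs: {sorted(df.columns[df.columns.duplicated()].unique())}"
        )
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) < 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(f"negative or non-finite count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    frac = values.astype(float) - np.round(values.astype(float))
    if np.abs(frac).max() > 1e-9:
        g, s = np.argwhere(np.abs(frac) > 1e-9)[0]
        raise ValueError(f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    return df.astype(np.int64)


def read_counts(path, fmt: str = "tsv", features_path=None, samples_path=None) -> pd.DataFrame:
    """Read a gene x sample raw count matrix.

    Parameters
    ----------
    path
        TSV file (gene IDs in the first column, sample IDs in the header) or a
        MatrixMarket ``.mtx`` triplet file.
    fmt
        ``"tsv"`` or ``"mtx"``.  The MTX variant needs ``features_path`` and
        ``samples_path`` (one ID per line; features may be ``<id>\\t<symbol>``
        as in common single-cell layouts — only the first column is used).

    Returns
    -------
    pandas.DataFrame
        Dense integer count matrix, gene version suffixes stripped, with a
        collision check on the stripped IDs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        if features_path is None or samples_path is None:
            raise ValueError("mtx format requires features_path and samples_path")
        mat = scipy_io.mmread(path)
        genes = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
        samples = pd.read_csv(samples_path, sep="\t", header=None)[0].tolist()
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match {len(genes)} features x {len(samples)} samples"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")
    return _check_counts_frame(df)


def write_counts(cm: pd.DataFrame, path) -> None:
    """Write a count matrix as TSV (genes x samples, header row of sample IDs)."""
    cm.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (mandatory header; first column = sample ID)."""
    md = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in md.columns and c != "psa_ng_ml"]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    for flag in ("bph", "prostatitis", "asap"):
        md[flag] = md[flag].astype(bool)
    if "psa_ng_ml" in md.columns:
        md["psa_ng_ml"] = pd.to_numeric(md["psa_ng_ml"], errors="coerce")
    # ASAP histology is grouped with the cancer class
    if (md["asap"] & (md["cancer_status"] != "PCa")).any():
        raise ValueError("ASAP-flagged samples must carry cancer_status == 'PCa'")
    return md


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


@dataclass
class SampleFilterReport:
    """Per-sample QC removal report.

    ``removed`` maps each removed sample ID to the list of criteria it failed
    (``"library_size"`` and/or ``"expressed_genes"``); a sample failing both is
    removed once.
    """

    removed: dict[str, list[str]] = field(default_factory=dict)
    library_sizes: pd.Series | None = None
    expressed_genes: pd.Series | None = None

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_failed_library(self) -> int:
        return sum("library_size" in v for v in self.removed.values())

    @property
    def n_failed_genes(self) -> int:
        return sum("expressed_genes" in v for v in self.removed.values())

    @property
    def n_failed_both(self) -> int:
        return sum(len(v) == 2 for v in self.removed.values())


def filter_samples(
    cm: pd.DataFrame,
    min_lib_size: int = 15_000_000,
    min_expressed_genes: int = 10_000,
    expressed_threshold: int = 10,
) -> tuple[pd.DataFrame, SampleFilterReport]:
    """Remove low-quality samples.

    A sample is kept when its effective library size (column sum of counts) is
    at least ``min_lib_size`` **and** it has at least ``min_expressed_genes``
    genes with count >= ``expressed_threshold``.  The report lists each removed
    sample with the criterion or criteria it failed, deduplicated so that
    flagged_lib + flagged_genes - both = removed.
    """
    if min(min_lib_size, min_expressed_genes, expressed_threshold) < 0:
        raise ValueError("thresholds must be >= 0")
    libsize = cm.sum(axis=0)
    n_expr = (cm >= expressed_threshold).sum(axis=0)
    report = SampleFilterReport(library_sizes=libsize, expressed_genes=n_expr)
    for s in cm.columns:
        reasons = []
        if libsize[s] < min_lib_size:
            reasons.append("library_size")
        if n_expr[s] < min_expressed_genes:
            reasons.append("expressed_genes")
        if reasons:
            report.removed[s] = reasons
    keep = [s for s in cm.columns if s not in report.removed]
    if not keep:
        raise ValueError(
            "all samples removed by QC; review min_lib_size / min_expressed_genes thresholds"
        )
    for s, reasons in report.removed.items():
        logger.info("QC removed sample %s (%s)", s, ", ".join(reasons))
    return cm[keep], report


def filter_genes_prevalence(
    cm: pd.DataFrame, min_samples: int = 26, expressed_threshold: int = 10
) -> tuple[pd.DataFrame, int]:
    """Remove genes expressed (count >= ``expressed_threshold``) in fewer than
    ``min_samples`` samples; returns the filtered matrix and the removal count.

    The default of 26 mirrors sizing the rule to the smallest biological group
    in the cohort, so a gene private to one group can still survive.
    """
    if min_samples > cm.shape[1]:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {cm.shape[1]}")
    n_expr = (cm >= expressed_threshold).sum(axis=1)
    keep = n_expr >= min_samples
    return cm[keep], int((~keep).sum())


def filter_genes_tcga(
    cm: pd.DataFrame, max_low_samples: int = 13, low_threshold: int = 10
) -> pd.DataFrame:
    """Remove genes with count <= ``low_threshold`` in **more than**
    ``max_low_samples`` samples (the low-expression rule used for small
    validation cohorts)."""
    n_low = (cm <= low_threshold).sum(axis=1)
    return cm[n_low <= max_low_samples]


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def size_factors(cm: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts,
    rescaled to geometric mean 1.

    Falls back to column-sum scaling (with a logged warning) when no gene has
    positive counts in every sample.
    """
    counts = cm.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        logref = np.log(counts[all_pos]).mean(axis=1)  # log geometric mean per gene
        ratios = np.log(counts[all_pos]) - logref[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning(
            "no gene with positive counts in all samples; "
            "falling back to column-sum size factors"
        )
        colsum = counts.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError("sample with zero total counts; cannot compute size factors")
        sf = colsum
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=cm.columns, name="size_factor")


def normalize_log2(cm: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Normalise counts to ``log2(count / sizefactor + 1)``.

    This is the log2 scale that all downstream scoring (signature scores,
    tumour content, per-sample enrichment) consumes.  Monotone per sample:
    within a sample, a larger count always maps to a larger value.
    """
    if sf is None:
        sf = size_factors(cm)
    values = np.log2(cm.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    return pd.DataFrame(values, index=cm.index, columns=cm.columns)


# ---------------------------------------------------------------------------
# PSA groups
# ---------------------------------------------------------------------------


def assign_psa_groups(md: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Split samples into PSA high/low by their own ancestry's median.

    Per ancestry the median is computed over non-missing PSA values; a sample
    is ``high`` iff its PSA is strictly greater than the median, ``low`` iff
    PSA <= median, ``unknown`` iff PSA is missing.  The <=-to-low convention
    gives the odd-n strict-greater split (e.g. 59 values -> 29 high / 30 low).

    Returns the metadata with a ``psa_group`` column plus the per-ancestry
    medians used.
    """
    if md["ancestry"].isna().any():
        raise ValueError("ancestry must be present for every sample")
    md = md.copy()
    md["psa_group"] = "unknown"
    medians: dict[str, float] = {}
    for anc, sub in md.groupby("ancestry"):
        psa = sub["psa_ng_ml"].dropna()
        if psa.empty:
            logger.warning("ancestry %s has no non-missing PSA; all samples unknown", anc)
            medians[anc] = float("nan")
            continue
        med = float(psa.median())
        medians[anc] = med
        known = sub.index[sub["psa_ng_ml"].notna()]
        md.loc[known, "psa_group"] = np.where(md.loc[known, "psa_ng_ml"] > med, "high", "low")
    return md, medians


# ---------------------------------------------------------------------------
# Feature selection and embedding
# ---------------------------------------------------------------------------


def select_top_mad(em: pd.DataFrame, k: int = 1000) -> list[str]:
    """Top-``k`` genes by raw median absolute deviation across samples.

    No consistency constant is applied — only the ranking matters.  Ties are
    broken by gene ID lexicographic order for determinism.
    """
    if k > em.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {em.shape[0]}")
    values = em.to_numpy()
    mad = np.median(np.abs(values - np.median(values, axis=1, keepdims=True)), axis=1)
    order = sorted(zip(-mad, em.index))
    return [g for _, g in order[:k]]


def pca_embed(em: pd.DataFrame, genes: list[str] | None = None, n_components: int = 2):
    """Centred PCA of samples on the (optionally gene-restricted) expression
    matrix; returns (sample x component coordinates, explained variance ratio).
    Coordinates are reproducible up to sign."""
    if genes is not None:
        missing = set(genes) - set(em.index)
        if missing:
            raise ValueError(f"genes not in expression matrix: {sorted(missing)[:10]}")
        em = em.loc[genes]
    X = em.to_numpy().T  # samples x genes
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(dims)={min(X.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    coords = pd.DataFrame(
        coords, index=em.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return coords, pca.explained_variance_ratio_
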