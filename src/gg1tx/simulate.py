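"""Synthetic GG1 prostate cohort generator with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage (QC, differential expression, enrichment,
cell-type scoring, tumour-content estimation, clustering, concordance) can be
exercised offline with a known answer:

* counts are negative-binomial (variance ``mu + alpha * mu**2``, gene-wise
  ``alpha`` drawn log-normal) around expected values
  ``libsize_s * sum_c pi_{s,c} * mu_{g,c} * 2**(effects applied to s)``;
* each sample's expression is a convex (Dirichlet) mixture over five prostate
  cell types — basal, luminal, stromal, immune, endothelial — with a
  luminal-heavy "tumour" regime for cancer samples and a stromal-leaning
  "benign" regime for the rest;
* designated marker genes are elevated (default 8x) in their own cell type
  so that mean-of-markers signature scores track the true mixtures;
* a configurable fraction of genes carries ancestry-, cancer-status- and
  PSA-group-associated log2 shifts with recorded true effect sizes;
* an "occult disease" fraction of non-PCa samples is drawn from the tumour
  mixture regime (and the cancer effects) while keeping the non-PCa label in
  the metadata — the construct the occult-fraction clustering analysis probes;
* PSA values are log-normal with configurable per-group medians; occult
  non-PCa samples draw from their ancestry's PCa PSA distribution.

All randomness derives from ``config.seed`` through two child generator
streams with a documented draw order — a gene-level stream (baseline means,
cell-type profiles, dispersions, effect-gene assignment) and a sample-level
stream (occult flags, mixtures, pathology flags, library sizes, PSA,
counts) — so identical configs give bit-identical output.  Setting
``noise_seed`` re-seeds only the sample-level stream: two cohorts with the
same ``seed``/``n_genes`` but different ``noise_seed`` share their gene-level
ground truth (the same spiked genes and effect sizes) while drawing fully
independent samples, which is how discovery/validation cohort pairs for
concordance experiments are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("basal", "luminal", "stromal", "immune", "endothelial")

# Marker panels mirrored from gg1tx.celltype (kept literal here so the
# generator is self-contained about which gene names it reserves).
_PANEL_MARKERS = {
    "basal": ("KRT5", "KRT14", "TP63"),
    "luminal": ("KLK3", "AR", "NKX3-1", "FOLH1"),
    "stromal": ("ACTA2", "COL1A1", "VIM", "TAGLN"),
    "immune": ("CD68", "CD3E", "TNF", "CXCL8", "IL6", "CCL2"),
    "endothelial": ("PECAM1", "VEGFA", "FLT1"),
}
# Tumour-score markers that are not cell-type markers; always spiked as
# cancer-upregulated so the tumour-content score has signal to find.
_TUMOUR_ONLY_MARKERS = ("AMACR", "PCA3", "HOXC4", "HOXC6")


def _parse_group(label: str) -> tuple[str, str]:
    """``"African_PCa" -> ("African", "PCa")``; ``nonPCa`` maps to ``non-PCa``."""
    try:
        ancestry, status = label.rsplit("_", 1)
    except ValueError as exc:
        raise ValueError(f"group label {label!r} is not '<ancestry>_<status>'") from exc
    status = {"PCa": "PCa", "nonPCa": "non-PCa", "non-PCa": "non-PCa"}.get(status)
    if status is None:
        raise ValueError(f"group label {label!r} has unknown status suffix")
    return ancestry, status


@dataclass
class SimulationConfig:
    """Cohort-level parameters; defaults mirror the post-QC study cohort
    (34 African GG1-PCa, 26 African non-PCa, 47 European GG1-PCa).

    Effect sizes are log2 units.  ``mixture_concentration`` gives Dirichlet
    parameters over (basal, luminal, stromal, immune, endothelial) for the
    tumour and benign regimes.  ``dispersion_shape = (log_mean, log_sd)`` of
    the gene-wise NB dispersion's log-normal.  ``psa_medians`` are the target
    log-normal medians (ng/mL) per ``"<ancestry>:<status>"``.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"African_PCa": 34, "African_nonPCa": 26, "European_PCa": 47}
    )
    n_genes: int = 2000
    mixture_concentration: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "tumour": (1.5, 10.0, 2.5, 2.0, 1.0),
            "benign": (3.0, 4.0, 6.0, 4.0, 2.0),
        }
    )
    ancestry_de_fraction: float = 0.10
    ancestry_effect_size: float = 1.0
    cancer_de_fraction: float = 0.05
    cancer_effect_size: float = 1.5
    psa_effect_fraction: float = 0.05
    psa_effect_size: float = 1.0
    occult_fraction: float = 0.0
    dispersion_shape: tuple[float, float] = (float(np.log(0.05)), 0.5)
    libsize_log_mean: float = float(np.log(3.0e7))
    libsize_log_sd: float = 0.25
    marker_elevation: float = 8.0
    psa_medians: dict[str, float] = field(
        default_factory=lambda: {
            "African:PCa": 11.8,
            "African:non-PCa": 14.4,
            "European:PCa": 4.4,
        }
    )
    psa_log_sd: float = 0.6
    seed: int = 0
    noise_seed: int | None = None  # re-seeds sample-level draws only

    def validate(self) -> None:
        for name in ("ancestry_de_fraction", "cancer_de_fraction", "psa_effect_fraction", "occult_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("ancestry_effect_size", "cancer_effect_size", "psa_effect_size"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.n_per_group:
            raise ValueError("n_per_group must not be empty")
        for label, n in self.n_per_group.items():
            _parse_group(label)
            if not float(n).is_integer():
                raise ValueError(f"non-integer sample count {n!r} for group {label!r}")
            if int(n) < 2:
                raise ValueError(f"group {label!r} needs >= 2 samples, got {n}")
        for regime, conc in self.mixture_concentration.items():
            if len(conc) != len(CELL_TYPES):
                raise ValueError(f"mixture_concentration[{regime!r}] needs {len(CELL_TYPES)} entries")
            if any(c <= 0 for c in conc):
                raise ValueError(f"mixture_concentration[{regime!r}] must be strictly positive")
        n_markers = sum(len(v) for v in _PANEL_MARKERS.values()) + len(_TUMOUR_ONLY_MARKERS)
        if self.n_genes < 2 * n_markers:
            raise ValueError(f"n_genes must be >= {2 * n_markers} (2x total marker count)")
        has_nonpca = any(_parse_group(g)[1] == "non-PCa" for g in self.n_per_group)
        if self.occult_fraction > 0 and not has_nonpca:
            raise ValueError("occult_fraction > 0 requires a non-PCa group")


@dataclass
class GroundTruth:
    """Per-gene effect flags/sizes, per-sample true mixtures and occult flags.

    ``gene_truth`` columns: ``ancestry_de``/``cancer_de``/``psa_de`` (bool)
    with signed true log2 shifts ``ancestry_lfc``/``cancer_lfc``/``psa_lfc``
    (ancestry shifts are applied to African samples, cancer shifts to
    tumour-regime samples, PSA shifts to PSA-high samples), plus
    ``marker_cell_type``.  ``mixtures`` is sample x cell-type (rows sum to 1).
    ``sample_truth`` columns: ``group``, ``regime``, ``occult``.
    """

    gene_truth: pd.DataFrame
    mixtures: pd.DataFrame
    sample_truth: pd.DataFrame

    @property
    def marker_genes(self) -> dict[str, list[str]]:
        m = self.gene_truth["marker_cell_type"]
        return {c: list(m.index[m == c]) for c in CELL_TYPES}


def _gene_ids(n_genes: int) -> tuple[list[str], dict[str, str]]:
    """Gene IDs: marker symbols first (fixed order), then G####; returns
    (ids, marker -> cell type)."""
    marker_map: dict[str, str] = {}
    ids: list[str] = []
    for ct in CELL_TYPES:
        for g in _PANEL_MARKERS[ct]:
            ids.append(g)
            marker_map[g] = ct
    ids.extend(_TUMOUR_ONLY_MARKERS)
    ids.extend(f"G{i:04d}" for i in range(n_genes - len(ids)))
    return ids, marker_map


def spike_psa(
    md: pd.DataFrame,
    config: SimulationConfig,
    occult: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign log-normal PSA (ng/mL) per sample with configurable group medians.

    A sample's PSA is ``exp(Normal(log(median), psa_log_sd))`` for its
    ``"<ancestry>:<status>"`` group, so the distribution's median equals the
    configured parameter.  Occult non-PCa samples (``occult`` boolean Series)
    draw from their ancestry's **PCa** distribution instead.  Groups missing
    from ``psa_medians`` get missing PSA.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 7])
    md = md.copy()
    psa = np.full(len(md), np.nan)
    for i, (sid, row) in enumerate(md.iterrows()):
        status = row["cancer_status"]
        if occult is not None and bool(occult.get(sid, False)):
            status = "PCa"
        med = config.psa_medians.get(f"{row['ancestry']}:{status}")
        if med is None:
            med = config.psa_medians.get(f"{row['ancestry']}:{row['cancer_status']}")
        if med is not None:
            psa[i] = float(np.exp(rng.normal(np.log(med), config.psa_log_sd)))
    md["psa_ng_ml"] = psa
    return md


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate (counts, metadata, ground truth) for one cohort.

    Counts are a gene x sample integer DataFrame; metadata follows the
    package's sample-metadata convention (ancestry, cancer_status, psa_ng_ml,
    bph/prostatitis/asap flags).  Same config and seed give bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])  # gene-level stream
    n_genes = config.n_genes
    gene_ids, marker_map = _gene_ids(n_genes)

    # 1. baseline relative means, log-normal across genes
    base = rng.lognormal(mean=np.log(50.0), sigma=1.5, size=n_genes)

    # 2. cell-type profile factors; markers elevated in their own type
    factors = np.exp(rng.normal(0.0, 0.35, size=(n_genes, len(CELL_TYPES))))
    for gi, g in enumerate(gene_ids):
        ct = marker_map.get(g)
        if ct is not None:
            factors[gi, :] = 1.0
            factors[gi, CELL_TYPES.index(ct)] = config.marker_elevation
    mu_gc = base[:, None] * factors  # genes x cell types

    # 3. gene-wise NB dispersion
    log_mean, log_sd = config.dispersion_shape
    alpha = rng.lognormal(mean=log_mean, sigma=log_sd, size=n_genes)

    # 4. effect-gene assignment (unnamed genes only, so marker panels stay clean);
    #    tumour-score markers are always cancer-upregulated
    n_named = len(marker_map) + len(_TUMOUR_ONLY_MARKERS)
    pool = np.arange(n_named, n_genes)
    gene_truth = pd.DataFrame(
        {
            "ancestry_de": False,
            "ancestry_lfc": 0.0,
            "cancer_de": False,
            "cancer_lfc": 0.0,
            "psa_de": False,
            "psa_lfc": 0.0,
            "marker_cell_type": [marker_map.get(g, "") for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for prefix, frac, size in (
        ("ancestry", config.ancestry_de_fraction, config.ancestry_effect_size),
        ("cancer", config.cancer_de_fraction, config.cancer_effect_size),
        ("psa", config.psa_effect_fraction, config.psa_effect_size),
    ):
        n_de = int(round(frac * len(pool)))
        chosen = rng.choice(pool, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        gene_truth.iloc[chosen, gene_truth.columns.get_loc(f"{prefix}_de")] = True
        gene_truth.iloc[chosen, gene_truth.columns.get_loc(f"{prefix}_lfc")] = signs * size
    if config.cancer_de_fraction > 0 or config.occult_fraction > 0:
        for g in _TUMOUR_ONLY_MARKERS:
            gene_truth.loc[g, ["cancer_de", "cancer_lfc"]] = True, config.cancer_effect_size

    # 5. samples: ids, groups, occult flags (exact count per non-PCa group);
    #    sample-level draws switch to their own stream
    noise = config.seed if config.noise_seed is None else config.noise_seed
    rng = np.random.default_rng([int(noise), 1])
    rows = []
    for label, n in config.n_per_group.items():
        ancestry, status = _parse_group(label)
        rows.extend({"group": label, "ancestry": ancestry, "cancer_status": status} for _ in range(int(n)))
    md = pd.DataFrame(rows, index=pd.Index([f"S{i + 1:03d}" for i in range(len(rows))], name="sample_id"))
    occult = pd.Series(False, index=md.index)
    for label in config.n_per_group:
        if _parse_group(label)[1] != "non-PCa":
            continue
        members = md.index[md["group"] == label]
        n_occ = int(round(config.occult_fraction * len(members)))
        if n_occ:
            occult[rng.choice(members, size=n_occ, replace=False)] = True

    # 6. true mixtures: tumour regime for PCa and occult samples
    tumour_regime = (md["cancer_status"] == "PCa") | occult
    conc_t = np.asarray(config.mixture_concentration["tumour"], dtype=float)
    conc_b = np.asarray(config.mixture_concentration["benign"], dtype=float)
    mixtures = np.empty((len(md), len(CELL_TYPES)))
    for i, tum in enumerate(tumour_regime.to_numpy()):
        mixtures[i] = rng.dirichlet(conc_t if tum else conc_b)
    mixtures = pd.DataFrame(mixtures, index=md.index, columns=list(CELL_TYPES))

    # 7. pathology flags (rates emulate the cohort's clinical table)
    u = rng.random((len(md), 3))
    nonpca = (md["cancer_status"] == "non-PCa").to_numpy()
    md["bph"] = np.where(nonpca, u[:, 0] < 0.714, False)
    md["prostatitis"] = np.where(nonpca, u[:, 1] < 0.50, u[:, 1] < 0.225)
    md["asap"] = np.where(nonpca, False, u[:, 2] < 0.15)

    # 8. library sizes
    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=len(md))

    # 9. PSA (occult samples draw from the PCa distribution)
    md = spike_psa(md, config, occult=occult, rng=rng)

    # PSA-high by the same ancestry-median rule the pipeline applies downstream
    psa_high = pd.Series(False, index=md.index)
    for anc, sub in md.groupby("ancestry"):
        vals = sub["psa_ng_ml"].dropna()
        if len(vals):
            psa_high[vals.index[vals > vals.median()]] = True

    # 10. counts: expected value then gamma-Poisson (NB) draw
    rel = mu_gc @ mixtures.to_numpy().T  # genes x samples
    shift = (
        np.outer(gene_truth["ancestry_lfc"], (md["ancestry"] == "African").to_numpy())
        + np.outer(gene_truth["cancer_lfc"], tumour_regime.to_numpy())
        + np.outer(gene_truth["psa_lfc"], psa_high.to_numpy())
    )
    rel = rel * np.exp2(shift)
    mu = rel / rel.sum(axis=0, keepdims=True) * libsize[None, :]
    lam = rng.gamma(shape=1.0 / alpha[:, None], scale=alpha[:, None] * mu)
    counts = rng.poisson(lam).astype(np.int64)
    cm = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=md.index)

    sample_truth = pd.DataFrame(
        {
            "group": md["group"],
            "regime": np.where(tumour_regime, "tumour", "benign"),
            "occult": occult,
        },
        index=md.index,
    )
    md = md.drop(columns="group")
    truth = GroundTruth(gene_truth=gene_truth, mixtures=mixtures, sample_truth=sample_truth)
    assert np.allclose(truth.mixtures.sum(axis=1), 1.0, atol=1e-9)
    return cm, md, truth
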