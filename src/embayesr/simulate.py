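"""Synthetic quantitative-trait datasets for benchmarking genomic prediction.

Each replicate mimics a dense-marker panel in which a small number of the
genotyped markers are causal (QTL).  Genotypes are built from two haplotypes
per individual: allele frequencies are drawn from a neutral-like site
frequency spectrum (density proportional to ``1/p``, truncated at a minor
allele frequency floor), and linkage disequilibrium between adjacent markers
is induced by a first-order Markov chain along the marker axis with a
configurable adjacent-marker correlation.  This is a deliberately simple
surrogate for a coalescent/forward simulation: prediction accuracy at this
scale is driven by sample size, heritability, the number of QTL and the fact
that QTL are themselves genotyped, not by fine-scale LD structure.

Two genetic architectures are supported:

``mixture``
    QTL allele substitution effects drawn from three normal distributions
    with variances ``0.0006``, ``0.006`` and ``0.06`` times the genetic
    variance (17/16/17 QTL by default) — a sparse architecture with a few
    large QTL.
``single_normal``
    All QTL effects from one normal distribution with variance
    ``sigma_g2 / n_qtl`` — an architecture favourable to BLUP methods.

Effects are defined on the standardized-genotype scale, so the component
variances add directly to the variance of true breeding values (TBV).
Phenotypes are TBV plus i.i.d. normal residuals whose variance is set from
the realized TBV variance: ``sigma_e2 = var(TBV) * (1 - h2) / h2``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .genotypes import (
    GenotypeMatrix,
    PhenotypeVector,
    standardize,
    write_dosage_tsv,
    write_phenotype_tsv,
)

__all__ = [
    "SimConfig",
    "SimReplicate",
    "simulate_genotypes",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "split_reference_validation",
    "simulate_replicate",
    "write_replicate",
]

#: component variances as multiples of sigma_g2 for the mixture architecture
MIXTURE_VARIANCE_COEFFS = (0.0006, 0.006, 0.06)


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults reproduce the dense-panel study conditions: 5000 individuals,
    10 050 markers of which 50 are QTL split 17/16/17 over the mixture
    components, unit genetic variance.
    """

    n_individuals: int = 5000
    n_markers: int = 10050
    n_qtl: int = 50
    qtl_counts_per_component: tuple = (17, 16, 17)
    architecture: str = "mixture"
    h2: float = 0.45
    sigma_g2: float = 1.0
    ld_decay: float = 0.5
    maf_floor: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("mixture", "single_normal"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl exceeds n_markers")
        if self.architecture == "mixture":
            if sum(self.qtl_counts_per_component) != self.n_qtl:
                raise ValueError(
                    "qtl_counts_per_component must sum to n_qtl for the "
                    "mixture architecture"
                )


@dataclass
class SimReplicate:
    """One simulated dataset with its ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray
    phenotypes: np.ndarray
    sigma_e2_used: float
    reference_idx: np.ndarray
    validation_idx: np.ndarray


def simulate_genotypes(cfg: SimConfig, rng=None) -> GenotypeMatrix:
    """Draw dosages as the sum of two Markov-correlated haplotypes."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, m, f0, rho = cfg.n_individuals, cfg.n_markers, cfg.maf_floor, cfg.ld_decay

    # SFS density ~ 1/p on [f0, 1-f0]: inverse-CDF sampling, then a random
    # 50% allele flip so the spectrum is symmetric in the counted allele.
    u = rng.random(m)
    p = f0 * ((1.0 - f0) / f0) ** u
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - p, p)

    n_hap = 2 * n
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < p[0]
    for j in range(1, m):
        p_prev, p_cur = p[j - 1], p[j]
        # conditional Bernoulli giving adjacent-marker correlation ~ rho
        slope = rho * np.sqrt(p_cur * (1 - p_cur) / (p_prev * (1 - p_prev)))
        prev = hap[:, j - 1]
        cond = np.clip(p_cur + slope * (prev - p_prev), 0.0, 1.0)
        hap[:, j] = rng.random(n_hap) < cond

    dosages = hap[:n_hap:2] + hap[1:n_hap:2]
    sample_ids = [f"ind{i:05d}" for i in range(n)]
    marker_ids = [f"snp{j:05d}" for j in range(m)]
    return GenotypeMatrix(sample_ids, marker_ids, dosages)


def assign_qtl_effects(cfg: SimConfig, g: GenotypeMatrix, rng=None):
    """Pick QTL markers and draw their effects on the standardized scale."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.n_qtl > g.m:
        raise ValueError("n_qtl exceeds the number of markers")
    qtl_indices = np.sort(rng.choice(g.m, size=cfg.n_qtl, replace=False))
    if cfg.n_qtl == 0:
        return qtl_indices, np.empty(0)
    if cfg.architecture == "mixture":
        sds = []
        for count, coeff in zip(
            cfg.qtl_counts_per_component, MIXTURE_VARIANCE_COEFFS
        ):
            sds += [np.sqrt(coeff * cfg.sigma_g2)] * count
        sds = np.array(sds)
        rng.shuffle(sds)
        effects = rng.normal(0.0, 1.0, size=cfg.n_qtl) * sds
    else:
        effects = rng.normal(
            0.0, np.sqrt(cfg.sigma_g2 / cfg.n_qtl), size=cfg.n_qtl
        )
    return qtl_indices, effects


def simulate_phenotypes(cfg: SimConfig, tbv: np.ndarray, rng=None):
    """Add residuals with variance set from the realized TBV variance."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tbv = np.asarray(tbv, dtype=float)
    var_tbv = float(np.var(tbv, ddof=1)) if tbv.size > 1 else 0.0
    sigma_e2 = var_tbv * (1.0 - cfg.h2) / cfg.h2
    phen = tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=tbv.size)
    return phen, sigma_e2


def split_reference_validation(cfg: SimConfig, n: int, rng=None):
    """Random disjoint reference/validation split.

    Sizes follow the heritability-specific convention: half/half at
    ``h2 = 0.45`` and 3/4 vs 1/4 at ``h2 = 0.10``; any other heritability
    uses the half/half default.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if n < 2:
        raise ValueError("need at least 2 individuals to split")
    if abs(cfg.h2 - 0.10) < 1e-12:
        n_ref = int(round(n * 0.75))
    else:
        n_ref = n // 2
    perm = rng.permutation(n)
    return np.sort(perm[:n_ref]), np.sort(perm[n_ref:])


def simulate_replicate(cfg: SimConfig) -> SimReplicate:
    """Full pipeline: genotypes, QTL, TBV, phenotypes and the data split.

    A single generator seeded with ``cfg.seed`` drives every step, so a
    replicate is a deterministic function of its configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    g = simulate_genotypes(cfg, rng)
    qtl_idx, effects = assign_qtl_effects(cfg, g, rng)
    sg = standardize(g)
    # map QTL indices into the retained-marker columns (none are expected to
    # be monomorphic at these sample sizes, but stay correct if one is)
    col_of = {orig: k for k, orig in enumerate(sg.kept_markers)}
    cols = np.array([col_of[j] for j in qtl_idx if j in col_of], dtype=int)
    kept_mask = np.array([j in col_of for j in qtl_idx])
    tbv = sg.Z[:, cols] @ effects[kept_mask] if cols.size else np.zeros(g.n)
    phen, sigma_e2 = simulate_phenotypes(cfg, tbv, rng)
    ref_idx, val_idx = split_reference_validation(cfg, g.n, rng)
    return SimReplicate(
        config=cfg,
        genotypes=g,
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        tbv=tbv,
        phenotypes=phen,
        sigma_e2_used=sigma_e2,
        reference_idx=ref_idx,
        validation_idx=val_idx,
    )


def write_replicate(rep: SimReplicate, prefix: str):
    """Write a replicate as TSV dosage/phenotype/truth files + JSON sidecar."""
    write_dosage_tsv(f"{prefix}.dosages.tsv", rep.genotypes)
    write_phenotype_tsv(
        f"{prefix}.phenotypes.tsv",
        PhenotypeVector(list(rep.genotypes.sample_ids), rep.phenotypes),
    )
    truth = np.zeros(rep.genotypes.m)
    truth[rep.qtl_indices] = rep.qtl_effects
    with open(f"{prefix}.truth.tsv", "w") as fh:
        fh.write("marker_id\ttrue_effect\n")
        for mid, eff in zip(rep.genotypes.marker_ids, truth):
            fh.write(f"{mid}\t{float(eff)!r}\n")
    with open(f"{prefix}.tbv.tsv", "w") as fh:
        fh.write("sample_id\ttbv\treference\n")
        ref = np.zeros(rep.genotypes.n, dtype=int)
        ref[rep.reference_idx] = 1
        for sid, t, r in zip(rep.genotypes.sample_ids, rep.tbv, ref):
            fh.write(f"{sid}\t{float(t)!r}\t{r}\n")
    sidecar = dataclasses.asdict(rep.config)
    sidecar["sigma_e2_used"] = rep.sigma_e2_used
    with open(f"{prefix}.config.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
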