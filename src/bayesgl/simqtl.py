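"""Synthetic pedigree / genotype / phenotype generator.

Emulates a QTL-MAS-workshop-style design: founder sires and dams, each
sire mated to a fixed number of dams, full-sib families of constant
size; biallelic SNPs on a few chromosomes with linkage disequilibrium
among founders; a handful of additive QTL; residual noise scaled post
hoc so the *realized* (sample) heritability hits its target exactly; and
optional DRP-like records with assigned reliabilities.

Defaults mirror that design: 20 sires x 10 dams each x 15 offspring
(3,000 offspring), 5 chromosomes, ~7,000 SNPs, 8 QTL, h^2 = 0.3, and one
third of each family carrying genotypes but no phenotype.  The
workshop's exotic QTL types (quadri-allelic, imprinted, ...) are
simplified to additive biallelic loci with optional pairwise epistasis.

Founder linkage disequilibrium comes from a latent Gaussian AR(1)
process per haplotype (lag-one correlation ``ld_decay``) thresholded at
the per-marker allele frequency; offspring are produced by
recombination-aware gene dropping with Poisson(1) crossovers per
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .genio import GenotypeMatrix, PhenotypeTable, drp_weights


@dataclass
class SimConfig:
    """Knobs of the synthetic design (defaults = the emulated workshop)."""

    n_sires: int = 20
    dams_per_sire: int = 10
    offspring_per_dam: int = 15
    n_chrom: int = 5
    snps_per_chrom: int = 1400
    n_qtl: int = 8
    h2: float = 0.3
    ld_decay: float = 0.9          # founder latent AR(1) lag-one correlation
    qtl_effect_dist: str = "gaussian"
    qtl_epistasis: bool = False
    prop_genotyped_only: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sires", "dams_per_sire", "offspring_per_dam",
                     "n_chrom", "snps_per_chrom", "n_qtl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        if not 0.0 <= self.prop_genotyped_only < 1.0:
            raise ValueError("prop_genotyped_only must lie in [0, 1)")
        if self.qtl_effect_dist not in ("gaussian", "gamma"):
            raise ValueError("qtl_effect_dist must be 'gaussian' or 'gamma'")


@dataclass
class Pedigree:
    """Founders plus full-sib families; parents refer to founder ids."""

    sire_ids: list
    dam_ids: list
    offspring_ids: list
    offspring_sire: list
    offspring_dam: list

    @property
    def founder_ids(self) -> list:
        return self.sire_ids + self.dam_ids

    @property
    def all_ids(self) -> list:
        return self.founder_ids + self.offspring_ids


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    individual_ids: list
    true_beta: np.ndarray       # zero off-QTL
    true_gv: np.ndarray
    realized_h2: float
    qtl_indices: np.ndarray
    target_h2: float = None

    def __post_init__(self):
        if self.target_h2 is not None and abs(self.realized_h2 - self.target_h2) > 0.02:
            raise ValueError("realized heritability missed its target by > 0.02")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"id": self.individual_ids, "gv": self.true_gv})


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Founder sires/dams and their full-sib families."""
    sires = [f"S{i+1}" for i in range(cfg.n_sires)]
    dams = [f"D{i+1}" for i in range(cfg.n_sires * cfg.dams_per_sire)]
    off, osire, odam = [], [], []
    for si, sire in enumerate(sires):
        for dj in range(cfg.dams_per_sire):
            dam = dams[si * cfg.dams_per_sire + dj]
            for c in range(cfg.offspring_per_dam):
                off.append(f"O{len(off)+1}")
                osire.append(sire)
                odam.append(dam)
    return Pedigree(sires, dams, off, osire, odam)


def _founder_haplotypes(n_hap: int, p: np.ndarray, rho: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Threshold a latent AR(1) Gaussian at Phi^-1(p) per marker."""
    m = p.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    innov = rng.standard_normal((n_hap, m))
    s = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + s * innov[:, j]
    return (z < stats.norm.ppf(p)).astype(np.int8)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, chrom_slices,
            rng: np.random.Generator) -> np.ndarray:
    """Recombine two parental haplotypes: Poisson(1) crossovers per chromosome."""
    out = np.empty_like(hap_a)
    for sl in chrom_slices:
        mlen = sl.stop - sl.start
        phase = rng.integers(2)
        n_x = rng.poisson(1.0)
        cuts = np.sort(rng.uniform(size=n_x)) if n_x else np.empty(0)
        bounds = np.concatenate([[0], np.ceil(cuts * mlen).astype(int), [mlen]])
        seg = np.empty(mlen, dtype=hap_a.dtype)
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            src = hap_a if phase == 0 else hap_b
            seg[b0:b1] = src[sl][b0:b1]
            phase ^= 1
        out[sl] = seg
    return out


def simulate_genotypes(pedigree: Pedigree, cfg: SimConfig,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Gene-drop founder haplotypes through the pedigree; 0/1/2 codes."""
    m = cfg.n_chrom * cfg.snps_per_chrom
    chrom_slices = [slice(c * cfg.snps_per_chrom, (c + 1) * cfg.snps_per_chrom)
                    for c in range(cfg.n_chrom)]
    p = rng.uniform(0.1, 0.9, size=m)
    founders = pedigree.founder_ids
    haps = {}
    fh = _founder_haplotypes(2 * len(founders), p, cfg.ld_decay, rng)
    for i, ind in enumerate(founders):
        haps[ind] = (fh[2 * i], fh[2 * i + 1])
    for child, sire, dam in zip(pedigree.offspring_ids,
                                pedigree.offspring_sire, pedigree.offspring_dam):
        haps[child] = (_gamete(*haps[sire], chrom_slices, rng),
                       _gamete(*haps[dam], chrom_slices, rng))
    ids = pedigree.all_ids
    codes = np.array([haps[i][0] + haps[i][1] for i in ids], dtype=float)
    marker_ids = [f"chr{c+1}_snp{j+1}" for c in range(cfg.n_chrom)
                  for j in range(cfg.snps_per_chrom)]
    return GenotypeMatrix(ids, marker_ids, codes)


def drop_monomorphic(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci without polymorphism (frequency 0 or 1)."""
    keep = (g.freqs > 0.0) & (g.freqs < 1.0)
    if not keep.any():
        raise ValueError("no polymorphic markers")
    return GenotypeMatrix(list(g.individual_ids),
                          [mid for mid, k in zip(g.marker_ids, keep) if k],
                          g.codes[:, keep])


def _draw_effects(n_qtl: int, dist: str, rng: np.random.Generator) -> np.ndarray:
    if dist == "gaussian":
        return rng.standard_normal(n_qtl)
    # gamma effect sizes (many small, few large) with random sign
    mag = rng.gamma(0.4, 1.66, size=n_qtl)
    return mag * rng.choice((-1.0, 1.0), size=n_qtl)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig,
                        rng: np.random.Generator
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Additive QTL effects plus residuals scaled to the target realized h^2.

    The residual vector is decorrelated from the genetic values and
    rescaled so the sample ratio var(gv)/var(y) equals ``cfg.h2`` exactly
    ("realized" rather than expected heritability).
    """
    m = g.n_markers
    if cfg.n_qtl > m:
        raise ValueError("more QTL requested than markers available")
    for attempt in range(100):
        qtl = rng.choice(m, size=cfg.n_qtl, replace=False)
        effects = _draw_effects(cfg.n_qtl, cfg.qtl_effect_dist, rng)
        gv = g.codes[:, qtl] @ effects
        if cfg.qtl_epistasis and cfg.n_qtl >= 2:
            pairs = [(qtl[i], qtl[i + 1]) for i in range(0, cfg.n_qtl - 1, 2)]
            epi = _draw_effects(len(pairs), cfg.qtl_effect_dist, rng)
            for (ka, kb), ee in zip(pairs, epi):
                gv = gv + ee * g.codes[:, ka] * g.codes[:, kb]
        if np.var(gv) > 0:
            break
    else:
        raise ValueError("could not place polymorphic QTL in 100 attempts")
    eps = rng.standard_normal(g.n_individuals)
    gv_c = gv - gv.mean()
    eps = eps - eps.mean()
    eps -= gv_c * float(eps @ gv_c) / float(gv_c @ gv_c)  # decorrelate
    var_g = float(np.var(gv, ddof=1))
    eps *= np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2 / np.var(eps, ddof=1))
    y = gv + eps
    true_beta = np.zeros(m)
    true_beta[qtl] = effects
    realized = var_g / float(np.var(y, ddof=1))
    truth = SimTruth(list(g.individual_ids), true_beta, gv, realized,
                     np.sort(qtl), target_h2=cfg.h2)
    return PhenotypeTable(list(g.individual_ids), y), truth


def simulate_drp(truth: SimTruth, reliability_range: tuple, h2: float,
                 rng: np.random.Generator) -> PhenotypeTable:
    """DRP-like records: gv plus noise with variance var(gv)(1-r^2)/r^2.

    Each record gets a reliability drawn uniformly in
    ``reliability_range`` (a subset of (0,1)) and the matching residual
    weight (1-r^2)/r^2, so the expected squared correlation of DRP with
    gv is r^2.
    """
    lo, hi = reliability_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("reliability_range must lie strictly inside (0, 1)")
    gv = np.asarray(truth.true_gv, dtype=float)
    var_g = float(np.var(gv, ddof=1))
    r2 = rng.uniform(lo, hi, size=gv.size)
    noise = rng.standard_normal(gv.size) * np.sqrt(var_g * (1.0 - r2) / r2)
    return PhenotypeTable(list(truth.individual_ids), gv + noise, reliability=r2)


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Full pipeline: pedigree -> genotypes -> polymorphic loci ->
    offspring phenotypes, with a ``prop_genotyped_only`` fraction of each
    family left without a phenotype record.

    Returns the offspring genotype matrix, the phenotype table of the
    phenotyped subset, and the truth table for all offspring.
    """
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg)
    g_all = simulate_genotypes(ped, cfg, rng)
    keep = [g_all.individual_ids.index(i) for i in ped.offspring_ids]
    g_off = GenotypeMatrix(ped.offspring_ids, list(g_all.marker_ids),
                           g_all.codes[keep])
    g_off = drop_monomorphic(g_off)
    ph_all, truth = simulate_phenotypes(g_off, cfg, rng)
    n = len(ped.offspring_ids)
    n_drop = int(round(cfg.prop_genotyped_only * n))
    drop = set(rng.choice(n, size=n_drop, replace=False)) if n_drop else set()
    keep_idx = np.array([i for i in range(n) if i not in drop], dtype=int)
    return g_off, ph_all.subset(keep_idx), truth
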