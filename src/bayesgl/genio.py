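"""Genotype/phenotype I/O and marker quality control.

Genotypes are held as additive allele counts (dosage of the counted
allele): 0, 1 or 2, with ``nan`` marking a missing call.  The counted
allele is the ALT allele for VCF input and the A1 allele for PLINK
``.raw`` input; CSV input is taken at face value.  After mean imputation
entries may be fractional dosages in [0, 2].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("bayesgl")

MISSING = np.nan

#: QC defaults: markers with MAF below 1% or a Hardy-Weinberg equilibrium
#: chi-square p-value below 1e-6 are dropped, as are individuals with a
#: genotype call rate below 90%.
DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_ALPHA = 1e-6
DEFAULT_CALL_RATE_MIN = 0.90


class GenioError(ValueError):
    """Raised for malformed input files or degenerate data."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive genotype codes.

    Attributes
    ----------
    individual_ids : list of str
    marker_ids : list of str
    codes : ndarray, shape (n, m)
        Float matrix of allele counts in {0, 1, 2}; ``nan`` = missing.
    freqs : ndarray, shape (m,)
        Counted-allele frequency per marker, computed from non-missing
        entries only.
    """

    individual_ids: list
    marker_ids: list
    codes: np.ndarray
    freqs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(i) for i in self.marker_ids]
        n, m = self.codes.shape
        if n < 2 or m < 1:
            raise GenioError(f"need n >= 2 individuals and m >= 1 markers, got {n} x {m}")
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise GenioError("id lists do not match codes shape")
        if len(set(self.individual_ids)) != n or len(set(self.marker_ids)) != m:
            raise GenioError("duplicate ids")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            # fractional dosages are legal only after imputation; raw input
            # must be hard 0/1/2 calls
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            if not np.all((bad >= 0) & (bad <= 2)):
                raise GenioError(f"genotype codes outside [0, 2]: {bad[:5]}")
        if self.freqs is None:
            self.freqs = allele_frequencies(self.codes)
        else:
            self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def write_csv(self, path):
        df = pd.DataFrame(self.codes, index=self.individual_ids, columns=self.marker_ids)
        df.index.name = "id"
        df.to_csv(path)


@dataclass
class PhenotypeTable:
    """Per-individual response with optional DRP reliabilities.

    ``weight`` holds the residual-variance multiplier d_ii: 1 for plain
    (pre-corrected) phenotypes, (1 - r^2) / r^2 for de-regressed proofs
    with reliability r^2.
    """

    individual_ids: list
    y: np.ndarray
    reliability: np.ndarray = None  # r^2 in (0, 1], or None
    weight: np.ndarray = None

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.y = np.asarray(self.y, dtype=float)
        if self.reliability is not None:
            self.reliability = np.asarray(self.reliability, dtype=float)
            if np.any((self.reliability <= 0) | (self.reliability > 1)):
                raise GenioError("reliabilities must lie in (0, 1]")
            expected = drp_weights(self.reliability)
            if self.weight is None:
                self.weight = expected
            elif not np.allclose(self.weight, expected, atol=1e-12, rtol=0):
                raise GenioError("weight inconsistent with (1 - r^2)/r^2")
        if self.weight is None:
            self.weight = np.ones_like(self.y)
        self.weight = np.asarray(self.weight, dtype=float)
        if np.any(self.weight <= 0):
            raise GenioError("weights must be strictly positive")
        if len(self.individual_ids) != self.y.size or self.weight.size != self.y.size:
            raise GenioError("phenotype table fields have inconsistent lengths")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, idx) -> "PhenotypeTable":
        idx = np.asarray(idx)
        rel = None if self.reliability is None else self.reliability[idx]
        return PhenotypeTable(
            [self.individual_ids[i] for i in idx], self.y[idx], rel, self.weight[idx]
        )


@dataclass
class QCReport:
    """Bookkeeping of what quality control removed."""

    n_markers_in: int
    n_markers_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_maf: int
    removed_hwe: int
    removed_monomorphic: int
    removed_call_rate: int
    maf_min: float
    hwe_alpha: float
    call_rate_min: float

    def __post_init__(self):
        for name in ("removed_maf", "removed_hwe", "removed_monomorphic", "removed_call_rate"):
            if getattr(self, name) < 0:
                raise GenioError(f"{name} negative")
        if self.n_individuals_in - self.removed_call_rate != self.n_individuals_out:
            raise GenioError("individual counts inconsistent")
        removed_m = self.removed_maf + self.removed_hwe + self.removed_monomorphic
        if self.n_markers_in - removed_m != self.n_markers_out:
            raise GenioError("marker counts inconsistent")

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def drp_weights(reliability) -> np.ndarray:
    """Residual weights d_ii = (1 - r^2) / r^2 for DRP reliabilities r^2."""
    r2 = np.asarray(reliability, dtype=float)
    return (1.0 - r2) / r2


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per column from non-missing entries."""
    codes = np.asarray(codes, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(codes, axis=0) / 2.0


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``csv``, ``plink_raw`` or ``vcf``."""
    path = Path(path)
    if not path.exists():
        raise GenioError(f"no such file: {path}")
    if format == "csv":
        return _read_csv(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise GenioError(f"unknown genotype format {format!r}")


def _check_codes(values: np.ndarray, path, what: str) -> np.ndarray:
    finite = values[np.isfinite(values)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise GenioError(f"{path}: non-{{0,1,2}} genotype code(s) {bad[:3]} in {what}")
    return values


def _read_csv(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenioError(f"{path}: failed to parse CSV: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    for j, col in enumerate(df.columns):
        raw_na = df.iloc[:, j].isna()
        coerced = ~np.isfinite(values[:, j]) & ~raw_na.to_numpy()
        if coerced.any():
            line = int(np.argmax(coerced)) + 2  # +1 header, +1 one-based
            raise GenioError(f"{path}: unparseable genotype at line {line}, column {col!r}")
    _check_codes(values, path, "CSV body")
    return GenotypeMatrix(list(df.index), list(df.columns), values)


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    missing_meta = [c for c in _PLINK_META if c not in df.columns]
    if missing_meta:
        raise GenioError(f"{path}: not a PLINK .raw file (missing {missing_meta} at line 1)")
    marker_cols = [c for c in df.columns if c not in _PLINK_META]
    if not marker_cols:
        raise GenioError(f"{path}: no marker columns")
    values = df[marker_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    _check_codes(values, path, "PLINK .raw body")
    # marker ids in .raw carry the counted allele as SNP_A suffix; keep as-is
    return GenotypeMatrix(df["IID"].tolist(), marker_cols, values)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise GenioError(f"{path}: failed to open VCF: {exc}") from exc
    ids = list(vcf.samples)
    cols, names, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        col = np.empty(len(ids))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            col[i] = float(sum(alleles)) if len(alleles) == 2 else MISSING
        cols.append(col)
        names.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if skipped:
        logger.warning("%s: skipped %d non-biallelic record(s)", path, skipped)
    if not cols:
        raise GenioError(f"{path}: no biallelic records")
    g = GenotypeMatrix(ids, names, np.column_stack(cols))
    g.n_skipped_records = skipped
    return g


def read_phenotypes(path, h2: float | None = None) -> PhenotypeTable:
    """Read an ``id,y[,reliability]`` table (CSV or TSV by extension).

    Records with a reliability outside (0, 1] are rejected with a logged
    message.  ``h2`` is accepted for symmetry with ERC-based pipelines but
    only recorded on the returned table.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"id", "y"}
    if not required.issubset(df.columns):
        raise GenioError(f"{path}: phenotype table needs columns {sorted(required)}")
    rel = None
    if "reliability" in df.columns:
        r2 = pd.to_numeric(df["reliability"], errors="coerce")
        bad = (r2 <= 0) | (r2 > 1) | r2.isna()
        if bad.any():
            for i in df.index[bad]:
                logger.warning("%s: record id=%s rejected, reliability=%r outside (0,1]",
                               path, df.loc[i, "id"], df.loc[i, "reliability"])
            df = df[~bad]
            r2 = r2[~bad]
        rel = r2.to_numpy(dtype=float)
    tab = PhenotypeTable(df["id"].tolist(), df["y"].to_numpy(dtype=float), rel)
    tab.h2 = h2
    return tab


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def hwe_chi2_pvalue(codes_col: np.ndarray) -> float:
    """One-df chi-square Hardy-Weinberg test p-value for one marker column.

    No continuity correction; monomorphic columns return p = 1.
    """
    col = codes_col[np.isfinite(codes_col)]
    n = col.size
    if n == 0:
        return 1.0
    obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()], dtype=float)
    p = (2 * obs[2] + obs[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-call-rate individuals, then low-MAF / HWE-deviant markers.

    Individuals are filtered first and marker statistics recomputed on the
    survivors; monomorphic markers are always removed.
    """
    for name, v in (("maf_min", maf_min), ("hwe_alpha", hwe_alpha),
                    ("call_rate_min", call_rate_min)):
        if not 0.0 <= v <= 1.0:
            raise GenioError(f"{name}={v} outside [0, 1]")
    codes = g.codes
    n_in, m_in = codes.shape
    call_rate = np.isfinite(codes).mean(axis=1)
    keep_ind = call_rate >= call_rate_min
    removed_cr = int((~keep_ind).sum())
    codes = codes[keep_ind]
    if codes.shape[0] < 2:
        raise GenioError("fewer than 2 individuals remain after call-rate filter")

    freqs = allele_frequencies(codes)
    maf = np.minimum(freqs, 1.0 - freqs)
    mono = np.nan_to_num(maf, nan=0.0) <= 0.0
    low_maf = ~mono & (maf < maf_min)
    hwe_p = np.array([hwe_chi2_pvalue(codes[:, k]) for k in range(codes.shape[1])])
    bad_hwe = ~mono & ~low_maf & (hwe_p < hwe_alpha)
    keep_mark = ~(mono | low_maf | bad_hwe)
    if not keep_mark.any():
        raise GenioError("quality control removed every marker")

    out = GenotypeMatrix(
        [i for i, k in zip(g.individual_ids, keep_ind) if k],
        [mid for mid, k in zip(g.marker_ids, keep_mark) if k],
        codes[:, keep_mark],
    )
    report = QCReport(
        n_markers_in=m_in,
        n_markers_out=out.n_markers,
        n_individuals_in=n_in,
        n_individuals_out=out.n_individuals,
        removed_maf=int(low_maf.sum()),
        removed_hwe=int(bad_hwe.sum()),
        removed_monomorphic=int(mono.sum()),
        removed_call_rate=removed_cr,
        maf_min=maf_min,
        hwe_alpha=hwe_alpha,
        call_rate_min=call_rate_min,
    )
    return out, report


def impute_missing_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with its marker mean dosage 2 p_k."""
    codes = g.codes.copy()
    missing = ~np.isfinite(codes)
    if not missing.any():
        return GenotypeMatrix(list(g.individual_ids), list(g.marker_ids), codes, g.freqs.copy())
    all_missing = missing.all(axis=0)
    if all_missing.any():
        raise GenioError(
            f"cannot impute marker(s) with no observed calls: "
            f"{[g.marker_ids[k] for k in np.flatnonzero(all_missing)[:5]]}"
        )
    fill = np.broadcast_to(2.0 * g.freqs, codes.shape)
    codes[missing] = fill[missing]
    return GenotypeMatrix(list(g.individual_ids), list(g.marker_ids), codes, g.freqs.copy())


def align(g: GenotypeMatrix, ph: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both tables to shared individuals, in genotype order."""
    common = [i for i in g.individual_ids if i in set(ph.individual_ids)]
    if not common:
        raise GenioError("genotype and phenotype tables share no individuals")
    pos = {ind: j for j, ind in enumerate(ph.individual_ids)}
    gi = [g.individual_ids.index(i) for i in common]
    g2 = GenotypeMatrix(common, list(g.marker_ids), g.codes[gi])
    ph2 = ph.subset([pos[i] for i in common])
    return g2, ph2
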