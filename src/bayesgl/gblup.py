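"""GBLUP: genomic relationship matrix, mixed-model equations, EM-REML.

The model is ``y = 1 mu + g + e`` with ``g ~ N(0, G sigma_g^2)`` and
``e ~ N(0, D sigma_e^2)``; G is VanRaden's marker-based relationship
matrix ``(M - P)(M - P)' / (2 sum p_k (1 - p_k))`` with P's columns equal
to twice the allele frequency.  Before any solve, G is stabilized as
``blend*G + (1-blend)*I`` (default blend 0.99) because G is singular
whenever m < n or genotypes are duplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .genio import GenotypeMatrix, PhenotypeTable

DEFAULT_BLEND = 0.99


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling constant."""

    matrix: np.ndarray
    scale: float            # 2 sum p_k (1 - p_k)
    ids: list

    def __post_init__(self):
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def stabilized(self, blend: float = DEFAULT_BLEND) -> np.ndarray:
        return blend * self.matrix + (1.0 - blend) * np.eye(self.n)

    def to_triplets(self, path=None) -> pd.DataFrame:
        iu = np.triu_indices(self.n)
        df = pd.DataFrame({
            "id1": [self.ids[i] for i in iu[0]],
            "id2": [self.ids[j] for j in iu[1]],
            "value": self.matrix[iu],
        })
        if path is not None:
            df.to_csv(path, index=False)
        return df


def build_grm(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """G = (M - P)(M - P)' / (2 sum p_k (1 - p_k)).

    ``freqs`` overrides the matrix's own allele frequencies (used to
    center validation animals with training-set frequencies).
    """
    codes = g.codes
    if not np.isfinite(codes).all():
        raise ValueError("GRM needs complete genotypes; impute first")
    p = np.asarray(g.freqs if freqs is None else freqs, dtype=float)
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    if scale <= 0.0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Z = codes - 2.0 * p
    return GRM((Z @ Z.T) / scale, scale, list(g.individual_ids))


def solve_mme(grm: GRM, ph: PhenotypeTable, sigma2_g: float, sigma2_e: float,
              blend: float = DEFAULT_BLEND) -> tuple[float, np.ndarray]:
    """Solve the single-trait weighted mixed-model equations.

    The second MME block is premultiplied by sigma_g^2 G so that no
    inverse of G is needed (G from data-frequency-centered codes always
    has 1 in its null space):

    ``[1'R1        1'R      ] [mu]   [1'Ry      ]``
    ``[s_g^2 G R 1  I + s_g^2 G R] [g ] = [s_g^2 G R y]``  with R = D^-1/sigma_e^2.

    Returns the BLUE of mu and the BLUP of g.
    """
    if sigma2_g <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    n = grm.n
    if ph.n != n:
        raise ValueError("phenotype table does not match GRM dimension")
    r = (1.0 / ph.weight) / sigma2_e  # R diagonal
    Gs = grm.stabilized(blend)
    GR = sigma2_g * (Gs * r)  # sigma_g^2 G R for diagonal R
    C = np.empty((n + 1, n + 1))
    C[0, 0] = r.sum()
    C[0, 1:] = r
    C[1:, 0] = GR @ np.ones(n)
    C[1:, 1:] = np.eye(n) + GR
    rhs = np.concatenate([[float(r @ ph.y)], GR @ ph.y])
    try:
        sol = linalg.solve(C, rhs)
    except linalg.LinAlgError as exc:
        raise ValueError("mixed-model equations singular after stabilization") from exc
    return float(sol[0]), sol[1:]


def gblup_predict(grm_full: GRM, train_idx, test_idx, ph_train: PhenotypeTable,
                  sigma2_g: float, sigma2_e: float,
                  blend: float = DEFAULT_BLEND) -> np.ndarray:
    """DGV of validation animals: g_test = sigma_g^2 G_ts V_tt^-1 (y - mu 1)."""
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    Gs = blend * grm_full.matrix + (1.0 - blend) * np.eye(grm_full.n)
    G_tt = Gs[np.ix_(train_idx, train_idx)]
    G_st = Gs[np.ix_(test_idx, train_idx)]
    V = sigma2_g * G_tt + sigma2_e * np.diag(ph_train.weight)
    alpha = linalg.solve(V, ph_train.y - _blue_mu(V, ph_train.y), assume_a="pos")
    return sigma2_g * (G_st @ alpha)


def _blue_mu(V: np.ndarray, y: np.ndarray) -> float:
    Vinv_1 = linalg.solve(V, np.ones_like(y), assume_a="pos")
    return float(Vinv_1 @ y) / float(Vinv_1.sum())


def reml_loglik(grm: GRM, ph: PhenotypeTable, sigma2_g: float, sigma2_e: float,
                blend: float = DEFAULT_BLEND) -> float:
    """Restricted log-likelihood of (sigma_g^2, sigma_e^2), up to a constant."""
    V = sigma2_g * grm.stabilized(blend) + sigma2_e * np.diag(ph.weight)
    L = linalg.cholesky(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(grm.n)
    Vinv_1 = linalg.cho_solve((L, True), ones)
    Vinv_y = linalg.cho_solve((L, True), ph.y)
    xvx = float(ones @ Vinv_1)
    mu = float(Vinv_1 @ ph.y) / xvx
    yPy = float(ph.y @ Vinv_y) - xvx * mu * mu
    return -0.5 * (logdetV + np.log(xvx) + yPy)


def estimate_vc_em(grm: GRM, ph: PhenotypeTable, max_iter: int = 5_000,
                   tol: float = 1e-8, blend: float = DEFAULT_BLEND,
                   ) -> tuple[float, float, bool]:
    """EM-REML estimates of (sigma_g^2, sigma_e^2).

    The model is first whitened by D^(-1/2) (so the residual covariance
    is sigma_e^2 I) and the whitened, stabilized GRM eigendecomposed
    once; every EM iteration is then O(n).  Iterates until the relative
    parameter change drops below ``tol``; the restricted log-likelihood
    is checked to be non-decreasing at every step.  Returns
    ``(sigma2_g, sigma2_e, converged)``; on non-convergence the last
    iterate is returned with a warning.
    """
    n = grm.n
    if n < 10:
        raise ValueError("EM-REML needs n >= 10")
    vy = float(np.var(ph.y, ddof=1))
    if vy <= 0:
        raise ValueError("response has zero variance")
    d_isqrt = 1.0 / np.sqrt(ph.weight)
    Gw = d_isqrt[:, None] * grm.stabilized(blend) * d_isqrt
    lam, Q = linalg.eigh(Gw)
    lam = np.maximum(lam, 0.0)
    yt = Q.T @ (d_isqrt * ph.y)
    ot = Q.T @ d_isqrt  # rotated intercept column

    def _step_stats(sg, se):
        dv = sg * lam + se
        xvx = float(np.sum(ot * ot / dv))
        mu = float(np.sum(ot * yt / dv)) / xvx
        pt = (yt - mu * ot) / dv          # rotated P y
        # tr(P A) = tr(V^-1 A) - (1'V^-1 A V^-1 1)/xvx for A in {G, I}
        tr_pg = float(np.sum(lam / dv)) - float(np.sum(ot * ot * lam / dv**2)) / xvx
        tr_pd = float(np.sum(1.0 / dv)) - float(np.sum(ot * ot / dv**2)) / xvx
        ypgpy = float(np.sum(lam * pt * pt))
        ypdpy = float(np.sum(pt * pt))
        ll = -0.5 * (float(np.sum(np.log(dv))) + np.log(xvx)
                     + float(np.sum((yt - mu * ot) ** 2 / dv)))
        return tr_pg, tr_pd, ypgpy, ypdpy, ll

    sg, se = 0.5 * vy, 0.5 * vy
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        tr_pg, tr_pd, ypgpy, ypdpy, ll = _step_stats(sg, se)
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):  # EM guarantees ascent
            raise RuntimeError("EM-REML log-likelihood decreased")
        ll_prev = ll
        # EM update: sigma_i^2 <- [sigma_i^4 y'P Vi P y + sigma_i^2 (n - sigma_i^2 tr(P Vi))]/n
        sg_new = (sg**2 * ypgpy + sg * (n - sg * tr_pg)) / n
        se_new = (se**2 * ypdpy + se * (n - se * tr_pd)) / n
        sg_new = max(sg_new, 1e-10 * vy)
        se_new = max(se_new, 1e-10 * vy)
        # components pinned near the zero boundary count as converged
        rel = max(abs(sg_new - sg) / max(sg, 1e-4 * vy),
                  abs(se_new - se) / max(se, 1e-4 * vy))
        sg, se = sg_new, se_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM-REML did not converge; returning last iterate",
                      RuntimeWarning)
    return sg, se, converged


def snp_blup_ridge(g: GenotypeMatrix, ph: PhenotypeTable, sigma2_beta: float,
                   sigma2_e: float) -> tuple[float, np.ndarray]:
    """Ridge (SNP-BLUP) solution on centered genotypes with a joint intercept.

    With ``sigma2_beta = sigma2_g / (2 sum p_k (1-p_k))`` and an
    unstabilized GRM from the same centered codes, ``X beta_ridge``
    equals the GBLUP ``g_hat`` -- the standard cross-model equivalence.
    """
    X = g.codes - 2.0 * g.freqs
    n, m = X.shape
    w = 1.0 / ph.weight
    lam = sigma2_e / sigma2_beta
    C = np.empty((m + 1, m + 1))
    C[0, 0] = w.sum()
    C[0, 1:] = w @ X
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = X.T @ (w[:, None] * X) + lam * np.eye(m)
    rhs = np.concatenate([[float(w @ ph.y)], X.T @ (w * ph.y)])
    sol = linalg.solve(C, rhs, assume_a="sym")
    return float(sol[0]), sol[1:]
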