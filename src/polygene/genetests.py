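"""Gene-based association statistics from GWAS summary statistics plus LD.

Three gene-level tests are computed from the vector of single-SNP z-scores
``z_j = beta_j / se_j`` of the SNPs in a gene region, whose null distribution
is N(0, R) with R the LD (genotype correlation) matrix:

* **SKAT-O** — the optimal unified kernel test.  For each value of a mixing
  parameter rho the statistic ``Q_rho = z' W^(1/2) [(1-rho) I + rho 11']
  W^(1/2) z`` interpolates between a variance-component (SKAT, rho=0) and a
  burden (rho=1) statistic; the reported p-value is the null probability that
  the *minimum* per-rho p-value falls below the observed minimum.  Here that
  omnibus probability is computed essentially exactly: conditional on the
  burden component, every Q_rho is a monotone function of one noncentral
  quadratic form, so the omnibus p-value is a one-dimensional integral of
  noncentral quadratic-form tail probabilities.
* **PCA** — project z onto the leading principal components of R (enough to
  explain ``var_fraction`` of the variance) and refer the sum of squared
  standardized projections to a chi-square distribution.
* **ACAT-V** — the Cauchy combination of the per-SNP p-values with
  MAF-based weights.

The three are combined into a single gene/scenario p-value with an
equal-weight Cauchy combination (ACAT-O).

SNP weights default to the rare-variant-upweighting Beta(MAF; 1, 25) density
used throughout the summary-statistic gene-test literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .quadform import P_FLOOR, quadform_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "ZVector",
    "WeightScheme",
    "GeneTestResult",
    "DEFAULT_RHO_GRID",
    "zscores",
    "regularize_ld",
    "cauchy_combine",
    "acat_v",
    "pca_test",
    "skat_o",
    "run_gene",
]

# rho in {0, 0.1^2, ..., 0.9^2, 1}: the standard SKAT-O grid
DEFAULT_RHO_GRID = np.concatenate([(np.arange(10) / 10.0) ** 2, [1.0]])

_TINY_P = 1e-15  # switch point of the Cauchy tangent asymptote


@dataclass
class ZVector:
    """Per-SNP z-scores (beta/se) and MAFs for one gene/scenario SNP set."""

    snp_ids: list[str]
    z: np.ndarray
    maf: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if len(self.snp_ids) != self.z.size or self.z.size != self.maf.size:
            raise ValueError("snp_ids, z and maf must have matching lengths")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-scores must be finite")


@dataclass
class WeightScheme:
    """Per-SNP weights w_j for the kernel tests.

    ``beta_maf`` mode uses the Beta(maf; a, b) density, strongly upweighting
    rare variants for the default (1, 25); ``equal`` weights every SNP 1.
    """

    a: float = 1.0
    b: float = 25.0
    mode: str = "beta_maf"

    def weights(self, maf: np.ndarray) -> np.ndarray:
        maf = np.asarray(maf, dtype=float)
        if self.mode == "equal":
            return np.ones_like(maf)
        if self.mode != "beta_maf":
            raise ValueError(f"unknown weight mode {self.mode!r}")
        w = stats.beta.pdf(maf, self.a, self.b)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("Beta-density weights must be strictly positive")
        return w


@dataclass
class GeneTestResult:
    gene_id: str
    scenario: str
    n_snps: int
    p_skato: float
    p_pca: float
    p_acatv: float
    p_acato: float
    rho_opt: float
    k_pcs: int
    tested: bool = True

    @classmethod
    def untested(cls, gene_id: str, scenario: str) -> "GeneTestResult":
        return cls(gene_id, scenario, 0, np.nan, np.nan, np.nan, np.nan,
                   np.nan, 0, tested=False)


def zscores(records) -> ZVector:
    """Build a ZVector from canonical summary-statistic records.

    ``records`` is a DataFrame with columns snp_id, beta, se, maf; order is
    preserved.
    """
    se = records["se"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return ZVector(
        snp_ids=list(records["snp_id"]),
        z=records["beta"].to_numpy(dtype=float) / se,
        maf=records["maf"].to_numpy(dtype=float),
    )


def regularize_ld(r: np.ndarray) -> np.ndarray:
    """Project an estimated correlation matrix to positive semidefinite.

    Negative eigenvalues (reference-panel sampling noise) are clipped to zero
    and the diagonal is renormalized to one.
    """
    r = np.asarray(r, dtype=float)
    r = 0.5 * (r + r.T)
    ev, vec = np.linalg.eigh(r)
    if ev[0] >= 0:
        return r
    ev = np.clip(ev, 0.0, None)
    out = (vec * ev) @ vec.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def cauchy_combine(pvalues, weights=None) -> float:
    """ACAT: combine p-values via the weighted Cauchy transformation.

    T = sum_j w_j tan((0.5 - p_j) pi) / sum_j w_j;  p = 0.5 - arctan(T)/pi.
    For p_j below 1e-15 the tangent is replaced by its asymptote
    1/(p_j pi); p_j at or above 1 - 1e-15 are truncated.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("cauchy_combine requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative, not all zero")
    p = np.minimum(p, 1.0 - _TINY_P)
    small = p < _TINY_P
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    terms[small] = 1.0 / (p[small] * np.pi)
    t = float(np.dot(w, terms) / w.sum())
    # arctan loses the tail for huge T; use the Cauchy tail asymptote instead
    if t > 1e15:
        return float(max(1.0 / (t * np.pi), P_FLOOR))
    return float(np.clip(0.5 - np.arctan(t) / np.pi, P_FLOOR, 1.0))


def per_snp_pvalues(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values of single-SNP z-scores."""
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)


def acat_v(zv: ZVector, w: WeightScheme | None = None) -> float:
    """ACAT-V: Cauchy combination of per-SNP p-values.

    Weights are w_j^2 * maf_j (1 - maf_j) with w_j the Beta-density weight
    (all equal under the equal scheme).
    """
    w = w or WeightScheme()
    p = per_snp_pvalues(zv.z)
    if w.mode == "equal":
        wts = np.ones_like(p)
    else:
        wj = w.weights(zv.maf)
        wts = wj ** 2 * zv.maf * (1.0 - zv.maf)
    return cauchy_combine(p, wts)


def pca_test(zv: ZVector, ld, var_fraction: float = 0.85) -> tuple[float, int]:
    """Principal-component gene test.

    Eigendecompose R; keep the smallest k components explaining at least
    ``var_fraction`` of total variance; T = sum_i (q_i'z)^2 / lambda_i is
    chi-square with k degrees of freedom under the null.
    """
    r = _ld_matrix(ld, zv.snp_ids)
    z = zv.z
    if z.size == 1:
        return float(stats.chi2.sf(z[0] ** 2, 1)), 1
    ev, vec = np.linalg.eigh(r)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise ValueError("degenerate LD matrix: no positive eigenvalues")
    k = int(np.searchsorted(np.cumsum(ev) / total, var_fraction - 1e-12) + 1)
    if ev[k - 1] <= 1e-10 * ev[0]:
        raise ValueError("degenerate LD: a retained eigenvalue is zero")
    proj = vec[:, :k].T @ z
    t = float(np.sum(proj ** 2 / ev[:k]))
    return float(np.clip(stats.chi2.sf(t, k), P_FLOOR, 1.0)), k


def _ld_matrix(ld, snp_ids) -> np.ndarray:
    """Accept either a raw matrix or an io.LDMatrix and align to snp_ids."""
    if hasattr(ld, "submatrix"):
        return ld.submatrix(snp_ids)
    r = np.asarray(ld, dtype=float)
    if r.shape != (len(snp_ids), len(snp_ids)):
        raise ValueError("LD matrix does not match the SNP set")
    return r


def _quantile(lam, prob_upper, tol=1e-4):
    """Upper quantile of sum lam_i chi2_1: solve sf(c) = prob_upper."""
    lam = np.asarray(lam, dtype=float)
    mean = lam.sum()
    lo, hi = 0.0, max(mean, 1.0)
    while quadform_pvalue(lam, hi, tol=1e-7) > prob_upper:
        lo = hi
        hi *= 2.0
        if hi > 1e12:
            break

    def f(c):
        return np.log(quadform_pvalue(lam, c, tol=1e-7)) - np.log(prob_upper)

    return optimize.brentq(f, lo, hi, rtol=tol)


def skat_o(
    zv: ZVector,
    ld,
    w: WeightScheme | None = None,
    rho_grid=None,
) -> tuple[float, float]:
    """SKAT-O p-value and the optimal mixing parameter rho.

    Returns ``(p, rho_opt)`` where ``rho_opt`` attains the per-rho minimum
    p-value.  The omnibus p-value P(min_rho p_rho < T_obs) is computed by
    conditioning on the burden component (see module docstring); if that
    integration fails, a Bonferroni bound min-p * grid-size is reported.
    """
    w = w or WeightScheme()
    grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("rho grid must lie in [0, 1]")
    z = zv.z
    m = z.size
    if m == 1:
        return float(np.clip(stats.chi2.sf(z[0] ** 2, 1), P_FLOOR, 1.0)), float(grid[0])

    r = regularize_ld(_ld_matrix(ld, zv.snp_ids))
    sw = np.sqrt(w.weights(zv.maf))
    phi = sw[:, None] * r * sw[None, :]
    y = sw * z
    q0 = float(y @ y)
    qb = float(y.sum() ** 2)

    ev, vec = np.linalg.eigh(phi)
    ev = np.clip(ev, 0.0, None)
    sqrt_phi = (vec * np.sqrt(ev)) @ vec.T

    ones = np.ones(m)
    s = float(ones @ phi @ ones)

    p_rho = np.empty(grid.size)
    lam_rho = []
    for i, rho in enumerate(grid):
        q_obs = (1.0 - rho) * q0 + rho * qb
        if rho == 1.0:
            lam = np.array([s]) if s > 0 else np.array([])
            p_rho[i] = (
                float(np.clip(stats.chi2.sf(q_obs / s, 1), P_FLOOR, 1.0))
                if s > 0 else 1.0
            )
        else:
            m_rho = (1.0 - rho) * np.eye(m) + rho
            a = sqrt_phi @ m_rho @ sqrt_phi
            lam = np.clip(np.linalg.eigvalsh(a), 0.0, None)
            p_rho[i] = quadform_pvalue(lam, q_obs, tol=1e-8)
        lam_rho.append(lam)

    i_opt = int(np.argmin(p_rho))
    t_min = float(p_rho[i_opt])
    rho_opt = float(grid[i_opt])
    if grid.size == 1:
        return t_min, rho_opt
    bonferroni = min(1.0, t_min * grid.size)

    try:
        p = _skato_omnibus(grid, lam_rho, p_rho, t_min, phi, s, q0, qb)
    except Exception:  # pragma: no cover - numerical fallback
        logger.warning("SKAT-O omnibus integration failed; Bonferroni bound used")
        p = bonferroni
    # the exact omnibus probability is bracketed by min-p and its Bonferroni bound
    p = float(np.clip(p, t_min, bonferroni))
    return max(p, P_FLOOR), rho_opt


def _skato_omnibus(grid, lam_rho, p_rho, t_min, phi, s, q0, qb):
    """Exact P(min_rho p_rho < t_min) via conditioning on the burden axis.

    Writing y = W^(1/2) z ~ N(0, Phi), u = 1'y with var s, and
    x = u^2/s ~ chi2_1:  Q_rho = (1-rho) (D + x c'c/s) + rho s x  where
    D | x is the noncentral quadratic form with weights eig(Phi - cc'/s),
    c = Phi 1.  Hence

      P(any Q_rho > c_rho) = E_x[ sf_D( min_rho d_rho(x) | x ) ] + P(x > xmax)

    with per-rho thresholds c_rho at the observed minimum p-value.
    """
    m = phi.shape[0]
    ones = np.ones(m)
    cvec = phi @ ones

    # per-rho thresholds at level t_min (the argmin needs no inversion:
    # its threshold is the observed statistic itself)
    c_thr = np.empty(grid.size)
    for i, rho in enumerate(grid):
        if p_rho[i] <= t_min * (1.0 + 1e-12):
            c_thr[i] = (1.0 - rho) * q0 + rho * qb
        elif rho == 1.0:
            c_thr[i] = s * stats.chi2.isf(t_min, 1)
        else:
            c_thr[i] = _quantile(lam_rho[i], t_min)

    if s <= 1e-12 * np.trace(phi):
        # burden direction degenerate; min-p Bonferroni is all we can do
        return min(1.0, t_min * grid.size)

    phi_t = phi - np.outer(cvec, cvec) / s
    evt, vect = np.linalg.eigh(phi_t)
    evt = np.clip(evt, 0.0, None)
    pos = evt > 1e-12 * max(evt.max(), 1.0)
    lam_t = evt[pos]
    e = (vect.T @ cvec)[pos]
    kap_e = float(np.sum(e ** 2) / s) if lam_t.size else 0.0
    cc = float(cvec @ cvec)

    sub1 = grid < 1.0
    rho_s = grid[sub1]
    thr_s = c_thr[sub1]

    if 1.0 in grid:
        xmax = c_thr[np.where(grid == 1.0)[0][0]] / s
    else:
        xmax = stats.chi2.isf(1e-16, 1)

    def d_of_x(x):
        return np.min((thr_s - rho_s * s * x) / (1.0 - rho_s)) - x * cc / s

    def sf_inner(x):
        dd = d_of_x(x) + x * kap_e
        if lam_t.size == 0:
            return 1.0 if dd < 0 else 0.0
        if dd <= 0:
            return 1.0
        d2 = e ** 2 * x / (s * lam_t)
        return quadform_pvalue(lam_t, dd, d2, tol=1e-6)

    # integrate over t = sqrt(x): chi2_1 density becomes 2 phi(t)
    tmax = np.sqrt(xmax)
    hi = min(tmax, 8.5)
    nodes_panels = 4
    gl_x, gl_w = np.polynomial.legendre.leggauss(12)
    edges = np.linspace(0.0, hi, nodes_panels + 1)
    acc = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        tt = 0.5 * (b - a) * (gl_x + 1.0) + a
        vals = np.array([sf_inner(t * t) for t in tt])
        dens = 2.0 * stats.norm.pdf(tt)
        acc += 0.5 * (b - a) * float(np.dot(gl_w, vals * dens))
    return acc + float(stats.chi2.sf(xmax, 1))


def run_gene(
    gene_id: str,
    scenario: str,
    zv: ZVector | None,
    ld,
    weights: WeightScheme | None = None,
    rho_grid=None,
    var_fraction: float = 0.85,
) -> GeneTestResult:
    """All three gene tests plus their equal-weight ACAT-O combination."""
    if zv is None or zv.z.size == 0:
        return GeneTestResult.untested(gene_id, scenario)
    weights = weights or WeightScheme()
    p_sk, rho_opt = skat_o(zv, ld, weights, rho_grid)
    p_pc, k = pca_test(zv, ld, var_fraction)
    p_av = acat_v(zv, weights)
    p_ao = cauchy_combine([p_sk, p_pc, p_av])
    return GeneTestResult(
        gene_id=gene_id,
        scenario=scenario,
        n_snps=zv.z.size,
        p_skato=p_sk,
        p_pca=p_pc,
        p_acatv=p_av,
        p_acato=p_ao,
        rho_opt=rho_opt,
        k_pcs=k,
    )
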