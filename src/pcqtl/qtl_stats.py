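"""Nominal association scans, permutation-based phenotype-level FDR, and
allelic fold-change estimation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

AFC_CAP = np.log2(100.0)
DEFAULT_PERMUTATIONS = 1000


@dataclass
class NominalScan:
    """Per-variant simple linear regression of one phenotype on dosage."""

    phenotype_id: str
    variant_ids: list[str]
    slope: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pval: np.ndarray


def nominal_scan(y: np.ndarray, X: np.ndarray, variant_ids: list[str] | None = None,
                 phenotype_id: str = "") -> NominalScan:
    """Regress ``y`` on each dosage column of ``X`` (two-sided t p-values)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= 2:
        raise ValueError("need more than 2 samples for a nominal scan")
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(p)]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    ok = sxx > 0
    sxy = Xc.T @ yc
    slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    dof = n - 2
    rss = (yc @ yc) - slope * sxy
    rss = np.clip(rss, 0.0, None)
    se = np.sqrt(np.where(ok, rss / dof / np.where(ok, sxx, 1.0), np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    t = np.where(ok, t, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return NominalScan(phenotype_id, list(variant_ids), slope, se, t, pval)


@dataclass
class PermutationResult:
    phenotype_id: str
    lead_variant: str
    p_nominal_best: float
    empirical_p_direct: float
    beta_shape1: float
    beta_shape2: float
    empirical_p_beta: float
    beta_ok: bool
    q_value: float = np.nan


def _max_abs_r2(yc: np.ndarray, Xc: np.ndarray, sxx: np.ndarray, syy: float) -> np.ndarray:
    """Max squared correlation across variants for each row of ``yc``.

    ``yc`` may be a matrix (permutations x samples); r^2 is monotone in the
    nominal t statistic, so max r^2 corresponds to the min nominal p.
    """
    sxy = yc @ Xc  # rows x variants
    ok = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ok, sxy**2 / (sxx * syy), 0.0)
    return r2.max(axis=-1)


def _r2_to_pval(r2: np.ndarray, dof: int) -> np.ndarray:
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    t2 = dof * r2 / (1.0 - r2)
    return 2.0 * stats.t.sf(np.sqrt(t2), dof)


def permutation_pass(
    y: np.ndarray,
    X: np.ndarray,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    variant_ids: list[str] | None = None,
    phenotype_id: str = "",
) -> PermutationResult:
    """Phenotype-level empirical p-value by permuting ``y`` across samples.

    ``empirical_p_direct = (1 + #{perm best-p <= observed best-p}) / (B + 1)``.
    A Beta distribution is fit by maximum likelihood to the permutation
    best-p distribution and used for the Beta-tail empirical p (FastQTL
    scheme); if the fit fails the direct p is reported with ``beta_ok=False``.
    """
    if B < 100:
        log.warning("B=%d permutations is low; empirical p resolution is poor", B)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(p)]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = float(yc @ yc)
    dof = n - 2

    obs_sxy = yc @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_r2 = np.where(sxx > 0, obs_sxy**2 / (sxx * syy), 0.0)
    best_idx = int(np.argmax(obs_r2))
    obs_best_r2 = float(obs_r2[best_idx])
    p_obs = float(_r2_to_pval(np.array([obs_best_r2]), dof)[0])

    perms = np.empty((B, n))
    for b in range(B):
        perms[b] = yc[rng.permutation(n)]
    perm_r2 = _max_abs_r2(perms, Xc, sxx, syy)
    perm_p = _r2_to_pval(perm_r2, dof)

    emp_direct = (1.0 + np.sum(perm_p <= p_obs)) / (B + 1.0)

    beta_ok = True
    try:
        eps = 1e-12
        clipped = np.clip(perm_p, eps, 1 - eps)
        shape1, shape2, _, _ = stats.beta.fit(clipped, floc=0.0, fscale=1.0)
        emp_beta = float(stats.beta.cdf(p_obs, shape1, shape2))
        if not np.isfinite(emp_beta):
            raise ValueError("non-finite beta p")
    except Exception:  # fit failure → fall back to direct p
        beta_ok = False
        shape1 = shape2 = np.nan
        emp_beta = emp_direct
        log.warning("Beta fit failed for %s; using direct empirical p", phenotype_id)

    return PermutationResult(
        phenotype_id=phenotype_id,
        lead_variant=variant_ids[best_idx],
        p_nominal_best=p_obs,
        empirical_p_direct=float(emp_direct),
        beta_shape1=float(shape1),
        beta_shape2=float(shape2),
        empirical_p_beta=emp_beta,
        beta_ok=beta_ok,
    )


def qvalues(pvals: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-estimated pi0 (BH when pi0 = 1).

    Fewer than 10 p-values forces pi0 = 1 (plain Benjamini-Hochberg).
    """
    p = np.asarray(pvals, float)
    m = len(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if m < 10:
            log.warning("fewer than 10 phenotypes; fixing pi0 = 1 (BH)")
            pi0 = 1.0
        else:
            pi0 = _pi0_smoother(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _pi0_smoother(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey-Tibshirani smoother: cubic fit of pi0(lambda), evaluated at max."""
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    m = len(p)
    pi0s = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if np.all(pi0s == 0):
        return 1.0 / m
    coeffs = np.polyfit(lambdas, pi0s, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    if pi0 <= 0:
        pi0 = 1.0 / m
    return min(pi0, 1.0)


def estimate_log2_afc(y_linear: np.ndarray, dosage: np.ndarray, cap: float = AFC_CAP) -> float:
    """Allelic fold change from linear-scale expression and dosage.

    Fits the allelic model e = c * (2 - g + g*k) / 2 by least squares on the
    log scale (profiling out c as the intercept) and returns log2(k) clipped
    to +/- log2(100).
    """
    e = np.asarray(y_linear, float)
    g = np.asarray(dosage, float)
    if np.any(e <= 0):
        raise ValueError(
            "aFC estimation needs strictly positive linear-scale expression; "
            "use the simulator's linear channel or supply untransformed data"
        )
    loge = np.log2(e)

    def sse(log2k: float) -> float:
        k = 2.0**log2k
        pred = np.log2((2.0 - g + g * k) / 2.0)
        resid = loge - pred
        resid = resid - resid.mean()  # intercept (log2 c) profiled out
        return float(resid @ resid)

    res = minimize_scalar(sse, bounds=(-cap, cap), method="bounded", options={"xatol": 1e-10})
    best = float(res.x)
    if sse(0.0) <= res.fun:  # flat fit at least as good
        best = 0.0
    return float(np.clip(best, -cap, cap))


def nominal_afc_scan(y_linear: np.ndarray, X: np.ndarray, cap: float = AFC_CAP) -> np.ndarray:
    """log2 aFC per variant column (loop over :func:`estimate_log2_afc`)."""
    return np.array([estimate_log2_afc(y_linear, X[:, j], cap) for j in range(X.shape[1])])
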