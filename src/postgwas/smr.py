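"""Summary-data-based Mendelian randomisation (SMR) with the HEIDI filter.

SMR tests whether gene expression mediates a GWAS signal using the ratio
b_xy = b_GWAS / b_eQTL at the top cis-eQTL variant. The test statistic is

    T_SMR = z_G² · z_E² / (z_G² + z_E²)

referred to a 1-df chi-square. HEIDI (heterogeneity in dependent
instruments) distinguishes a single shared causal variant from linkage of
distinct variants: under a shared variant, b_xy estimated at any cis
variant is the same, so the deviations d_i = b_xy(i) − b_xy(top) should be
jointly null. Their covariance follows from first-order (delta-method)
propagation of the GWAS and eQTL sampling errors through the ratio, with
LD correlations from a reference panel; the sum of squared standardised
deviations is referred to a seeded Monte-Carlo sample of its null
multivariate-normal distribution.

Retention rule: results within 100 kb of a risk variant with
P_SMR < 0.05 and P_HEIDI ≥ 0.05 (an untestable HEIDI passes with a flag).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import LDPanel

HEIDI_P_EQTL = 1.6e-3
HEIDI_MAX_SNPS = 20
HEIDI_R2_HI = 0.9
HEIDI_R2_LO = 0.05


@dataclasses.dataclass
class SmrResult:
    gene: str
    top_snp: str
    b_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float = float("nan")
    n_heidi_snps: int = 0
    heidi_testable: bool = False


def smr_test(b_gwas: float, se_gwas: float, b_eqtl: float, se_eqtl: float):
    """Core SMR statistic at one variant.

    Returns ``(b_xy, t_smr, p_smr)``. Raises on a zero eQTL effect, for
    which the ratio is undefined.
    """
    if se_gwas <= 0 or se_eqtl <= 0:
        raise ValueError("standard errors must be positive")
    if b_eqtl == 0:
        raise ZeroDivisionError("eQTL effect is zero; b_xy undefined")
    z_g = b_gwas / se_gwas
    z_e = b_eqtl / se_eqtl
    zg2, ze2 = z_g * z_g, z_e * z_e
    t = zg2 * ze2 / (zg2 + ze2) if (zg2 + ze2) > 0 else 0.0
    p = float(sps.chi2.sf(t, df=1))
    return b_gwas / b_eqtl, float(t), p


def _aligned(gwas: pd.DataFrame, eqtl: pd.DataFrame, panel: LDPanel):
    merged = gwas.merge(eqtl, on="SNP", suffixes=("_g", "_e"))
    merged = merged[merged["SNP"].isin(panel.variants["SNP"])]
    idx = np.array([panel.index_of(s) for s in merged["SNP"]])
    return merged.reset_index(drop=True), idx


def heidi_test(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    panel: LDPanel,
    seed=0,
    p_eqtl_max: float = HEIDI_P_EQTL,
    max_snps: int = HEIDI_MAX_SNPS,
    r2_hi: float = HEIDI_R2_HI,
    r2_lo: float = HEIDI_R2_LO,
    n_draws: int = 10_000,
):
    """HEIDI heterogeneity test over a cis window.

    Eligible variants besides the top eQTL variant must have eQTL
    P < ``p_eqtl_max`` and r² to the top variant within
    [``r2_lo``, ``r2_hi``]; the ``max_snps`` strongest are kept. With fewer
    than three eligible variants the test is not performed and
    ``(nan, n, False)`` is returned.

    Returns ``(p_heidi, n_snps_used, testable)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    merged, idx = _aligned(gwas, eqtl, panel)
    if merged.empty:
        return float("nan"), 0, False
    z_e = (merged["BETA_e"] / merged["SE_e"]).to_numpy()
    top_pos = int(np.argmax(np.abs(z_e)))
    C = panel.corr()
    r_to_top = C[idx, idx[top_pos]]
    eligible = (
        (merged["P_e"].to_numpy() < p_eqtl_max)
        & (r_to_top**2 <= r2_hi)
        & (r_to_top**2 >= r2_lo)
    )
    eligible[top_pos] = False
    cand = np.flatnonzero(eligible)
    if cand.size > max_snps:
        cand = cand[np.argsort(-np.abs(z_e[cand]))[:max_snps]]
    if cand.size < 3:
        return float("nan"), int(cand.size), False
    sel = np.concatenate([[top_pos], cand])
    bg = merged["BETA_g"].to_numpy()[sel]
    sg = merged["SE_g"].to_numpy()[sel]
    be = merged["BETA_e"].to_numpy()[sel]
    se = merged["SE_e"].to_numpy()[sel]
    if np.any(be == 0):
        keep = be != 0
        keep[0] = True
        sel, bg, sg, be, se = sel[keep], bg[keep], sg[keep], be[keep], se[keep]
        if len(sel) < 4:
            return float("nan"), len(sel) - 1, False
    R = C[np.ix_(idx[sel], idx[sel])]
    bxy = bg / be
    # delta-method covariance of the b_xy vector (GWAS and eQTL independent)
    cov_bxy = (
        R * np.outer(sg, sg) / np.outer(be, be)
        + np.outer(bxy, bxy) * R * np.outer(se, se) / np.outer(be, be)
    )
    k = len(sel) - 1
    # d_i = b_xy(i) - b_xy(top); linear map L over the b_xy vector
    L = np.hstack([-np.ones((k, 1)), np.eye(k)])
    cov_d = L @ cov_bxy @ L.T
    d = bxy[1:] - bxy[0]
    sd = np.sqrt(np.diag(cov_d))
    stat = float(np.sum((d / sd) ** 2))
    jitter = 1e-10 * np.eye(k)
    try:
        chol = np.linalg.cholesky(cov_d + jitter)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov_d)
        chol = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    sims = rng.standard_normal((n_draws, k)) @ chol.T
    null_stats = np.sum((sims / sd) ** 2, axis=1)
    p = float((null_stats >= stat).sum() + 1) / (n_draws + 1)
    return p, k, True


def smr_with_heidi(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    panel: LDPanel,
    gene: str,
    seed=0,
    heidi_draws: int = 10_000,
) -> SmrResult:
    """SMR at the top eQTL variant plus the HEIDI filter over the window."""
    merged, _ = _aligned(gwas, eqtl, panel)
    if merged.empty:
        raise ValueError("no overlapping variants between GWAS and eQTL tables")
    z_e = (merged["BETA_e"] / merged["SE_e"]).to_numpy()
    top = merged.iloc[int(np.argmax(np.abs(z_e)))]
    b_xy, t, p = smr_test(top["BETA_g"], top["SE_g"], top["BETA_e"], top["SE_e"])
    p_h, n_h, testable = heidi_test(gwas, eqtl, panel, seed=seed, n_draws=heidi_draws)
    return SmrResult(
        gene=gene, top_snp=top["SNP"], b_xy=b_xy, t_smr=t, p_smr=p,
        p_heidi=p_h, n_heidi_snps=n_h, heidi_testable=testable,
    )


def filter_smr(
    results: pd.DataFrame,
    risk_positions,
    window: int = 100_000,
    p_smr_max: float = 0.05,
    p_heidi_min: float = 0.05,
    keep_untestable: bool = True,
) -> pd.DataFrame:
    """Retention rule for SMR results.

    ``results`` needs columns ``top_bp p_smr p_heidi heidi_testable``;
    ``risk_positions`` is an iterable of risk-variant bp positions (same
    chromosome context as ``top_bp``). Retains rows whose top eQTL variant
    is within ``window`` of a risk variant, with P_SMR below ``p_smr_max``
    and P_HEIDI at or above ``p_heidi_min`` (untestable HEIDI passes with
    the flag unless ``keep_untestable`` is off).
    """
    risk = np.asarray(list(risk_positions), dtype=np.int64)
    if risk.size == 0:
        return results.iloc[0:0].copy()
    dist = np.array([np.abs(risk - int(bp)).min() for bp in results["top_bp"]])
    heidi_ok = np.where(
        results["heidi_testable"].to_numpy(),
        results["p_heidi"].to_numpy() >= p_heidi_min,
        keep_untestable,
    )
    keep = (dist <= window) & (results["p_smr"].to_numpy() < p_smr_max) & heidi_ok
    return results[keep].reset_index(drop=True)
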