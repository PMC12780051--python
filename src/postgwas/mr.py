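"""Two-sample Mendelian randomisation estimators.

Instruments are variants robustly associated with the exposure
(P < 5 × 10⁻⁸, MAF > 0.01, mutually independent at r² < 0.01), harmonised
so exposure and outcome effects refer to the same allele, with palindromic
variants of ambiguous frequency (0.4–0.6) removed. Estimators:

* Wald ratio per variant: β_out/β_exp with first-order SE.
* IVW-RE: inverse-variance-weighted mean of the ratios under a
  multiplicative random-effects model, the residual scale floored at 1.
* MR-Egger: weighted regression of outcome on exposure effects with an
  intercept; a non-zero intercept estimates directional pleiotropy.
  Instruments are oriented so exposure effects are positive.
* Weighted median / weighted mode: order- and cluster-robust estimators
  with seeded parametric-bootstrap standard errors.
* Steiger directionality test, leave-one-out IVW, variance explained (PVE)
  and analytic power for a binary outcome.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import LDPanel

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclasses.dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    extras: dict = dataclasses.field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def select_instruments(
    exposure: pd.DataFrame,
    panel: LDPanel,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    r2_max: float = 0.01,
) -> list[str]:
    """Threshold filtering followed by greedy LD pruning by ascending P."""
    maf = np.minimum(exposure["FREQ"], 1 - exposure["FREQ"])
    cand = exposure[(exposure["P"] < p_max) & (maf > maf_min)]
    cand = cand[cand["SNP"].isin(set(panel.variants["SNP"]))]
    cand = cand.sort_values(["P", "SNP"], kind="mergesort")
    C = panel.corr()
    kept: list[str] = []
    kept_idx: list[int] = []
    for _, row in cand.iterrows():
        j = panel.index_of(row["SNP"])
        if all(C[j, k] ** 2 < r2_max for k in kept_idx):
            kept.append(row["SNP"])
            kept_idx.append(j)
    return kept


def harmonise(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Outcome rows with swapped alleles have their effect sign flipped and
    frequency complemented; palindromic variants with effect-allele
    frequency in [0.4, 0.6] are dropped, as are variants whose allele pair
    cannot be reconciled.
    """
    merged = exposure.merge(outcome, on="SNP", suffixes=("_exp", "_out"))
    rows = []
    for _, r in merged.iterrows():
        a1e, a2e = r["A1_exp"], r["A2_exp"]
        a1o, a2o = r["A1_out"], r["A2_out"]
        if (a1o, a2o) == (a1e, a2e):
            beta_out, eaf_out = r["BETA_out"], r["FREQ_out"]
        elif (a1o, a2o) == (a2e, a1e):
            beta_out, eaf_out = -r["BETA_out"], 1 - r["FREQ_out"]
        else:
            continue
        if frozenset((a1e, a2e)) in PALINDROMIC and 0.4 <= r["FREQ_exp"] <= 0.6:
            continue
        rows.append(
            {
                "SNP": r["SNP"],
                "beta_exp": r["BETA_exp"],
                "se_exp": r["SE_exp"],
                "beta_out": beta_out,
                "se_out": r["SE_out"],
                "eaf": r["FREQ_exp"],
                "A1": a1e,
                "A2": a2e,
            }
        )
    return pd.DataFrame(rows, columns=["SNP", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "A1", "A2"])


def _arrays(instruments: pd.DataFrame):
    be = instruments["beta_exp"].to_numpy(dtype=float)
    se_e = instruments["se_exp"].to_numpy(dtype=float)
    bo = instruments["beta_out"].to_numpy(dtype=float)
    se_o = instruments["se_out"].to_numpy(dtype=float)
    if np.any(se_e <= 0) or np.any(se_o <= 0):
        raise ValueError("standard errors must be positive")
    if np.any(be == 0):
        raise ZeroDivisionError("zero exposure effect; Wald ratio undefined")
    return be, se_e, bo, se_o


def wald_ratios(instruments: pd.DataFrame) -> pd.DataFrame:
    """Per-variant ratio estimates with first-order standard errors."""
    be, _, bo, se_o = _arrays(instruments)
    return pd.DataFrame(
        {
            "SNP": instruments["SNP"].to_numpy(),
            "beta": bo / be,
            "se": se_o / np.abs(be),
        }
    )


def ivw_re(instruments: pd.DataFrame) -> MrEstimate:
    """Multiplicative random-effects IVW estimate.

    The weighted mean of the Wald ratios with weights 1/se²; the SE is
    inflated by sqrt(max(1, Q/(k−1))) where Q is Cochran's heterogeneity
    statistic. With one instrument this reduces to the Wald ratio.
    """
    ratios = wald_ratios(instruments)
    b, s = ratios["beta"].to_numpy(), ratios["se"].to_numpy()
    w = s**-2
    beta = float(np.sum(w * b) / np.sum(w))
    k = len(b)
    if k == 1:
        se = float(s[0])
        q = float("nan")
        scale = 1.0
    else:
        q = float(np.sum(w * (b - beta) ** 2))
        scale = max(1.0, q / (k - 1))
        se = float(np.sqrt(1.0 / np.sum(w)) * np.sqrt(scale))
    p = 2.0 * float(sps.norm.sf(abs(beta) / se))
    return MrEstimate("IVW-RE", beta, se, p, k, {"Q": q, "scale": scale})


def mr_egger(instruments: pd.DataFrame) -> MrEstimate:
    """MR-Egger weighted regression with an intercept.

    Instruments are oriented so exposure effects are positive (required
    for the intercept to estimate directional pleiotropy); weights are the
    inverse outcome-effect variances, the residual scale is floored at 1,
    and P values use the t distribution with k−2 df. Two instruments give
    an exact fit with zero residual df, flagged in the extras.
    """
    be, _, bo, se_o = _arrays(instruments)
    flip = np.sign(be)
    be, bo = be * flip, bo * flip
    k = len(be)
    if k < 2:
        raise ValueError("MR-Egger requires at least two instruments")
    w = se_o**-2
    X = np.column_stack([np.ones(k), be])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ bo)
    resid = bo - X @ coef
    df = k - 2
    if df > 0:
        scale = float(np.sum(w * resid**2) / df)
        scale = max(1.0, scale)
    else:
        scale = 1.0
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))
    tdist_df = max(df, 1)
    p_slope = 2.0 * float(sps.t.sf(abs(coef[1]) / se[1], df=tdist_df)) if df > 0 else float("nan")
    p_int = 2.0 * float(sps.t.sf(abs(coef[0]) / se[0], df=tdist_df)) if df > 0 else float("nan")
    return MrEstimate(
        "MR-Egger",
        float(coef[1]),
        float(se[1]),
        p_slope,
        k,
        {
            "intercept": float(coef[0]),
            "intercept_se": float(se[0]),
            "intercept_p": p_int,
            "exact_fit": df == 0,
        },
    )


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b, w = b[order], w[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cdf, b))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 5000, seed=0) -> MrEstimate:
    """Weighted median of the Wald ratios with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the weight are
    valid. With equal weights and odd k it is the ordinary median.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    be, se_e, bo, se_o = _arrays(instruments)
    ratios = bo / be
    w = (se_o / np.abs(be)) ** -2
    beta = _weighted_median(ratios, w)
    k = len(ratios)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        be_b = be + rng.standard_normal(k) * se_e
        bo_b = bo + rng.standard_normal(k) * se_o
        rb = bo_b / be_b
        wb = (se_o / np.abs(be_b)) ** -2
        boot[i] = _weighted_median(rb, wb)
    se = float(boot.std(ddof=1))
    p = 2.0 * float(sps.norm.sf(abs(beta) / se))
    return MrEstimate("weighted median", beta, se, p, k)


def _mode_of(b: np.ndarray, w: np.ndarray, bandwidth: float) -> float:
    s = 1.4826 * np.median(np.abs(b - np.median(b)))
    if s == 0:
        s = b.std() or 1e-8
    h = max(bandwidth * 0.9 * s * len(b) ** (-0.2), 1e-8)
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 512)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - b[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    instruments: pd.DataFrame,
    bandwidth: float = 1.0,
    n_boot: int = 5000,
    seed=0,
) -> MrEstimate:
    """Mode of the weighted kernel-smoothed ratio density (ZEMPA-style).

    Consistent when the largest cluster of instruments is valid even if
    they carry under half the weight. The kernel bandwidth scales a
    MAD-based rule of thumb.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    be, se_e, bo, se_o = _arrays(instruments)
    ratios = bo / be
    w = (se_o / np.abs(be)) ** -2
    beta = _mode_of(ratios, w, bandwidth)
    k = len(ratios)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        be_b = be + rng.standard_normal(k) * se_e
        bo_b = bo + rng.standard_normal(k) * se_o
        rb = bo_b / be_b
        wb = (se_o / np.abs(be_b)) ** -2
        boot[i] = _mode_of(rb, wb, bandwidth)
    se = float(boot.std(ddof=1))
    p = 2.0 * float(sps.norm.sf(abs(beta) / se))
    return MrEstimate("weighted mode", beta, se, p, k)


def steiger(
    instruments: pd.DataFrame,
    n_exposure: int,
    n_outcome: int,
    prevalence: float = 0.02,
) -> dict:
    """Steiger test of causal direction.

    Per-variant variance explained is approximated from the association
    z-statistics (r² ≈ z²/(z² + n − 2)); for the binary outcome this is the
    observed-scale approximation (``prevalence`` is recorded for
    interpretation, not used in the approximation). The direction is
    exposure→outcome when the summed exposure r² exceeds the outcome r²;
    the P value compares the Fisher-transformed correlations.
    """
    be, se_e, bo, se_o = _arrays(instruments)
    z_e = be / se_e
    z_o = bo / se_o
    r2_exp = z_e**2 / (z_e**2 + n_exposure - 2)
    r2_out = z_o**2 / (z_o**2 + n_outcome - 2)
    r_exp = float(np.sqrt(min(r2_exp.sum(), 1.0 - 1e-12)))
    r_out = float(np.sqrt(min(r2_out.sum(), 1.0 - 1e-12)))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return {
        "direction": "exposure->outcome" if r_exp >= r_out else "outcome->exposure",
        "correct_direction": r_exp >= r_out,
        "r2_exposure": float(r2_exp.sum()),
        "r2_outcome": float(r2_out.sum()),
        "p": p,
        "prevalence": prevalence,
    }


def leave_one_out(instruments: pd.DataFrame) -> pd.DataFrame:
    """IVW-RE re-estimates, each omitting one instrument."""
    rows = []
    for i in range(len(instruments)):
        rest = instruments.drop(instruments.index[i])
        est = ivw_re(rest) if len(rest) >= 1 else None
        rows.append(
            {
                "omitted": instruments["SNP"].iloc[i],
                "beta": est.beta if est else float("nan"),
                "se": est.se if est else float("nan"),
                "p": est.p if est else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def pve(instruments: pd.DataFrame) -> float:
    """Proportion of exposure variance explained: Σ 2·f(1−f)·β² on the
    standardized exposure."""
    be = instruments["beta_exp"].to_numpy(dtype=float)
    f = instruments["eaf"].to_numpy(dtype=float)
    return float(np.sum(2.0 * f * (1 - f) * be**2))


def mr_power(
    pve_exposure: float,
    n_outcome: int,
    case_fraction: float,
    odds_ratios,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Analytic power for binary-outcome two-sample MR.

    Uses the standard non-centrality approximation: the IVW standard error
    is ≈ 1/sqrt(N·v·(1−v)·R²) with v the case fraction and R² the variance
    in the exposure explained by the instruments, so
    power = Φ(|log OR|·sqrt(N·v·(1−v)·R²) − z_{1−α/2}).
    """
    ors = np.atleast_1d(np.asarray(odds_ratios, dtype=float))
    z_crit = sps.norm.isf(alpha / 2)
    ncp = np.abs(np.log(ors)) * np.sqrt(n_outcome * case_fraction * (1 - case_fraction) * pve_exposure)
    power = sps.norm.cdf(ncp - z_crit)
    return pd.DataFrame({"odds_ratio": ors, "power": power})


def pve_power(
    instruments: pd.DataFrame,
    n_outcome: int,
    prevalence: float = 0.02,
    ratio_cases: float = 0.01,
    or_grid=(1.05, 1.1, 1.15, 1.2, 1.25, 1.5, 2.0),
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """PVE plus a power curve at the study's outcome sample structure.

    ``ratio_cases`` is the case:control ratio of the outcome sample; the
    case fraction used in the non-centrality term is
    ratio/(1 + ratio). ``prevalence`` (lifetime risk) is carried for
    reporting alongside the PVE.
    """
    v = ratio_cases / (1.0 + ratio_cases)
    r2 = pve(instruments)
    curve = mr_power(r2, n_outcome, v, or_grid, alpha)
    curve.attrs["prevalence"] = prevalence
    return r2, curve


def run_all_estimators(instruments: pd.DataFrame, n_boot: int = 5000, seed=0) -> pd.DataFrame:
    """Convenience table of IVW-RE, Egger, weighted median and mode."""
    rng = np.random.default_rng(seed)
    ests = [
        ivw_re(instruments),
        mr_egger(instruments),
        weighted_median(instruments, n_boot=n_boot, seed=rng),
        weighted_mode(instruments, n_boot=n_boot, seed=rng),
    ]
    return pd.DataFrame(
        [
            {
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "p": e.p,
                "odds_ratio": e.odds_ratio,
                "n_snps": e.n_snps,
                **{k: v for k, v in e.extras.items() if np.isscalar(v)},
            }
            for e in ests
        ]
    )
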