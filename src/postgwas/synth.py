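"""Synthetic data with planted truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs:
block-diagonal LD from a latent multivariate normal thresholded to
dosages; case-control GWAS summary statistics under a liability-threshold
model (or a quantitative trait); cis-eQTLs with a shared or distinct
causal variant; peak sets with controllable enrichment over designated
intervals; distance-decaying contact maps with planted loops; and MR
instrument sets with a planted causal effect and optional directional
pleiotropy.

Every generator is a pure function of its configuration and the global
seed; per-stage child seeds are derived by fixed offsets so stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .abc_model import ContactMap
from .sumstats import ConfigurationError, LDPanel

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {"panel": 1, "gwas": 2, "eqtl": 3, "peaks": 4, "contacts": 5, "mr": 6}

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A"),
                 ("G", "A"), ("C", "T"), ("G", "T")]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a pipeline stage, derived from the global seed."""
    offset = _STAGE_OFFSETS[stage]
    logger.debug("stage %s uses child seed sequence [%d, %d]", stage, seed, offset)
    return np.random.default_rng([seed, offset])


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    ``block_sizes`` must sum to ``n_variants``; by default the variants are
    split into equal blocks of 20. Variants are laid out on one chromosome
    with ``variant_spacing`` bp between neighbours and an extra
    ``block_gap`` bp between blocks, so distinct blocks form distinct risk
    loci under the >500 kb rule.
    """

    seed: int = 0
    n_individuals: int = 1000
    n_variants: int = 200
    block_sizes: list[int] | None = None
    within_block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_spec: tuple[tuple[int, float], ...] = ()
    trait_type: str = "quantitative"
    case_fraction: float = 0.1
    peak_enrichment: float = 1.0
    contact_decay_gamma: float = 1.0
    loop_spec: tuple[tuple[int, int, float], ...] = ()
    variant_spacing: int = 5_000
    block_gap: int = 600_000
    peak_width: int = 1_000
    n_background_peaks: int = 200
    contact_scale: float = 100.0
    eqtl_effect: float = 0.5

    def validate(self) -> None:
        if not 0 <= self.within_block_rho < 1:
            raise ConfigurationError("within_block_rho must be in [0, 1)")
        blocks = self.resolved_block_sizes()
        if any(b <= 0 for b in blocks):
            raise ConfigurationError("block sizes must be positive")
        if sum(blocks) != self.n_variants:
            raise ConfigurationError("block sizes must sum to n_variants")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError("trait_type must be 'quantitative' or 'binary'")
        if self.trait_type == "binary" and not 0 < self.case_fraction < 1:
            raise ConfigurationError("case_fraction must be in (0, 1)")
        if self.peak_enrichment < 1:
            raise ConfigurationError("peak_enrichment must be >= 1")
        if self.contact_decay_gamma <= 0:
            raise ConfigurationError("contact_decay_gamma must be positive")
        for i, _ in self.causal_spec:
            if not 0 <= i < self.n_variants:
                raise ConfigurationError(f"causal index {i} out of range")

    def resolved_block_sizes(self) -> list[int]:
        if self.block_sizes is not None:
            return list(self.block_sizes)
        size = min(20, self.n_variants)
        n_full, rem = divmod(self.n_variants, size)
        return [size] * n_full + ([rem] if rem else [])

    def block_ranges(self) -> list[tuple[int, int]]:
        out, start = [], 0
        for b in self.resolved_block_sizes():
            out.append((start, start + b))
            start += b
        return out

    def positions(self) -> np.ndarray:
        pos = np.empty(self.n_variants, dtype=np.int64)
        cur = 1
        for b0, b1 in self.block_ranges():
            for j in range(b0, b1):
                pos[j] = cur
                cur += self.variant_spacing
            cur += self.block_gap
        return pos


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth recorded alongside the generated data."""

    causal_variants: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    shared_eqtl_causal: dict = dataclasses.field(default_factory=dict)
    mr_true_effect: float = 0.0
    pleiotropy_intercept: float = 0.0


def make_truth(config: SimConfig) -> SimTruth:
    idx = tuple(i for i, _ in config.causal_spec)
    eff = tuple(e for _, e in config.causal_spec)
    return SimTruth(causal_variants=idx, causal_effects=eff)


def simulate_ld_panel(config: SimConfig) -> LDPanel:
    """Genotype dosages with block-compound-symmetric latent LD.

    Two latent haplotypes per individual are drawn from a per-block
    equicorrelated normal (correlation ``within_block_rho``) and thresholded
    at the normal quantile of each variant's MAF, so the latent haplotype
    correlation is exactly rho within blocks and zero across blocks.
    """
    config.validate()
    rng = stage_rng(config.seed, "panel")
    n, m = config.n_individuals, config.n_variants
    rho = config.within_block_rho
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = sps.norm.ppf(mafs)
    dosages = np.empty((n, m), dtype=float)
    for b0, b1 in config.block_ranges():
        mb = b1 - b0
        total = np.zeros((n, mb), dtype=np.int8)
        for _ in range(2):  # two haplotypes
            shared = rng.standard_normal((n, 1))
            indep = rng.standard_normal((n, mb))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
            total += (latent < thresholds[b0:b1]).astype(np.int8)
        dosages[:, b0:b1] = total
    variants = pd.DataFrame(
        {
            "SNP": [f"v{i:05d}" for i in range(m)],
            "CHR": "1",
            "BP": config.positions(),
            "A1": [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(m)],
            "A2": [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(m)],
        }
    )
    return LDPanel(dosages=dosages, variants=variants, blocks=config.block_ranges())


def _marginal_ols(y: np.ndarray, G: np.ndarray):
    """Per-column simple linear regression of y on each dosage column."""
    n = len(y)
    gbar = G.mean(axis=0)
    Gc = G - gbar
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return beta, se, p


def _marginal_logistic(y: np.ndarray, G: np.ndarray, max_iter: int = 40, tol: float = 1e-10):
    """Vectorised per-column logistic regression (intercept + dosage slope)."""
    n, m = G.shape
    ybar = y.mean()
    b0 = np.full(m, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(m)
    yv = y[:, None]
    for _ in range(max_iter):
        eta = b0 + G * b1
        p = expit(eta)
        W = p * (1 - p)
        r = yv - p
        g0 = r.sum(axis=0)
        g1 = (r * G).sum(axis=0)
        s00 = W.sum(axis=0)
        s01 = (W * G).sum(axis=0)
        s11 = (W * G * G).sum(axis=0)
        det = s00 * s11 - s01**2
        db0 = (s11 * g0 - s01 * g1) / det
        db1 = (-s01 * g0 + s00 * g1) / det
        b0 += db0
        b1 += db1
        if max(np.max(np.abs(db0)), np.max(np.abs(db1))) < tol:
            break
    eta = b0 + G * b1
    p = expit(eta)
    W = p * (1 - p)
    s00 = W.sum(axis=0)
    s01 = (W * G).sum(axis=0)
    s11 = (W * G * G).sum(axis=0)
    det = s00 * s11 - s01**2
    se1 = np.sqrt(s00 / det)
    z = b1 / se1
    pval = 2.0 * sps.norm.sf(np.abs(z))
    return b1, se1, pval


def _standardize(G: np.ndarray) -> np.ndarray:
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    return (G - G.mean(axis=0)) / sd


def _genetic_liability(panel: LDPanel, truth: SimTruth) -> np.ndarray:
    g = np.zeros(panel.n_individuals)
    Gs = _standardize(panel.dosages)
    for i, e in zip(truth.causal_variants, truth.causal_effects):
        g += e * Gs[:, i]
    return g


def _sumstats_frame(panel: LDPanel, keep, beta, se, p) -> pd.DataFrame:
    df = panel.variants.loc[keep, ["SNP", "CHR", "BP", "A1", "A2"]].copy()
    df["FREQ"] = panel.dosages[:, keep].mean(axis=0) / 2.0
    df["BETA"] = beta
    df["SE"] = se
    df["P"] = p
    return df.reset_index(drop=True)


def simulate_gwas_sumstats(panel: LDPanel, truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Marginal single-variant association statistics for the planted trait.

    Quantitative traits use per-variant OLS; binary traits use a
    liability-threshold model (cases are individuals above the
    ``1 − case_fraction`` liability quantile) with per-variant logistic
    fits. Monomorphic variants are excluded with a warning.
    """
    config.validate()
    rng = stage_rng(config.seed, "gwas")
    G = panel.dosages
    keep = np.flatnonzero(G.std(axis=0) > 0)
    if keep.size < panel.n_variants:
        warnings.warn(
            f"excluded {panel.n_variants - keep.size} monomorphic variants", stacklevel=2
        )
    liab = _genetic_liability(panel, truth) + rng.standard_normal(panel.n_individuals)
    if config.trait_type == "quantitative":
        beta, se, p = _marginal_ols(liab, G[:, keep])
    else:
        y = (liab > sps.norm.ppf(1 - config.case_fraction)).astype(float)
        beta, se, p = _marginal_logistic(y, G[:, keep])
    return _sumstats_frame(panel, keep, beta, se, p)


def simulate_eqtl_sumstats(
    panel: LDPanel,
    gene_tss: int,
    shared: bool,
    config: SimConfig,
    truth: SimTruth,
    effect: float | None = None,
):
    """cis-eQTL summary statistics for one gene.

    If ``shared``, the expression causal variant is the GWAS causal variant
    nearest ``gene_tss``; otherwise a distinct variant is drawn from the
    same LD block. Returns ``(stats, causal_index)``.
    """
    config.validate()
    rng = stage_rng(config.seed, "eqtl")
    effect = config.eqtl_effect if effect is None else effect
    pos = panel.variants["BP"].to_numpy()
    if not truth.causal_variants:
        raise ConfigurationError("eQTL simulation requires a planted GWAS causal variant")
    gwas_causal = min(truth.causal_variants, key=lambda i: abs(int(pos[i]) - gene_tss))
    if shared:
        causal = int(gwas_causal)
    else:
        block = next(b for b in (panel.blocks or [(0, panel.n_variants)]) if b[0] <= gwas_causal < b[1])
        choices = [j for j in range(block[0], block[1]) if j != gwas_causal]
        if not choices:
            raise ConfigurationError("no distinct variant available in the causal block")
        causal = int(rng.choice(choices))
    G = panel.dosages
    keep = np.flatnonzero(G.std(axis=0) > 0)
    if keep.size < panel.n_variants:
        warnings.warn(
            f"excluded {panel.n_variants - keep.size} monomorphic variants", stacklevel=2
        )
    expr = effect * _standardize(G)[:, causal] + rng.standard_normal(panel.n_individuals)
    beta, se, p = _marginal_ols(expr, G[:, keep])
    return _sumstats_frame(panel, keep, beta, se, p), causal


def simulate_peaks(config: SimConfig, target_intervals, genome_size: int | None = None) -> pd.DataFrame:
    """Non-overlapping peak intervals with controllable target enrichment.

    Background peaks are placed uniformly; each target interval additionally
    receives a covering peak with probability ``1 − 1/peak_enrichment``, so
    enrichment 1 leaves target coverage at the genome-wide background rate
    and enrichment ≫ 1 covers essentially all targets.
    """
    config.validate()
    rng = stage_rng(config.seed, "peaks")
    if genome_size is None:
        genome_size = int(config.positions()[-1]) + config.block_gap
    w = config.peak_width
    starts = rng.integers(0, max(1, genome_size - w), size=config.n_background_peaks)
    intervals = [(int(s), int(s) + w) for s in starts]
    p_extra = 1.0 - 1.0 / config.peak_enrichment
    for ts, te in target_intervals:
        if rng.random() < p_extra:
            mid = (int(ts) + int(te)) // 2
            start = max(0, mid - w // 2)
            intervals.append((start, start + w))
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return pd.DataFrame(
        {"chrom": "1", "start": [s for s, _ in merged], "end": [e for _, e in merged]}
    )


def simulate_contact_map(config: SimConfig, n_bins: int, resolution: int) -> ContactMap:
    """Symmetric Poisson contact counts with power-law distance decay.

    Expected count at bin distance d is ``contact_scale × (d+1)^(−gamma)``;
    ``loop_spec`` entries are added on top of the sampled counts.
    """
    config.validate()
    if resolution <= 0:
        raise ConfigurationError("resolution must be positive")
    rng = stage_rng(config.seed, "contacts")
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    expected = config.contact_scale * (d + 1.0) ** (-config.contact_decay_gamma)
    upper = np.triu(rng.poisson(expected).astype(float))
    mat = upper + np.triu(upper, 1).T
    for i, j, extra in config.loop_spec:
        mat[i, j] += extra
        if i != j:
            mat[j, i] += extra
    return ContactMap(matrix=mat, resolution=resolution, gamma=config.contact_decay_gamma)


def simulate_mr_dataset(
    k_instruments: int,
    true_effect: float,
    pleiotropy: float = 0.0,
    seed: int = 0,
    exposure_beta_range: tuple[float, float] = (0.03, 0.10),
    se_exp: float = 0.003,
    se_out: float = 0.03,
) -> pd.DataFrame:
    """Harmonised instrument table with a planted exposure→outcome effect.

    Per instrument, the observed outcome effect is
    ``true_effect × beta_exp + pleiotropy + noise`` with noise SD equal to
    the reported outcome SE, emulating a two-sample design where exposure
    and outcome estimates come from independent studies. Effects are
    oriented to the exposure-increasing allele, as harmonised instrument
    tables conventionally are, so constant pleiotropy is directional.
    """
    rng = stage_rng(seed, "mr")
    b_exp_true = rng.uniform(*exposure_beta_range, size=k_instruments)
    beta_exp = b_exp_true + rng.normal(0.0, se_exp, size=k_instruments)
    beta_out = true_effect * b_exp_true + pleiotropy + rng.normal(0.0, se_out, size=k_instruments)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k_instruments)]
    return pd.DataFrame(
        {
            "SNP": [f"iv{i:04d}" for i in range(k_instruments)],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf": rng.uniform(0.05, 0.95, size=k_instruments),
            "A1": [a for a, _ in pairs],
            "A2": [b for _, b in pairs],
        }
    )
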