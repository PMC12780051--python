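"""Fine-mapping: approximate-Bayes-factor PIPs and 95% credible sets.

Per-variant evidence is the Wakefield approximate Bayes factor

    log ABF = ½·log(se²/(se² + W²)) + ½·z²·W²/(se² + W²)

with a N(0, W²) effect-size prior. Within a signal, posterior inclusion
probabilities are the prior-weighted ABFs normalised over the window
(computed in log space), under the single-causal-variant assumption. For
loci with several conditionally independent signals, each signal's PIPs
are computed on z-scores conditioned on the other signals, which is a
desk-scale stand-in for a sum-of-single-effects model: it preserves the
credible-set semantics (rank PIPs, accumulate to 95%, floor at 0.001)
without re-implementing SuSiE.

Default prior SDs follow the coloc convention: 0.2 for binary-trait
log-odds effects, 0.15 for quantitative traits.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import LDPanel, RiskLocus, attach_z, conditional_z

PRIOR_SD_BINARY = 0.2
PRIOR_SD_QUANTITATIVE = 0.15


@dataclasses.dataclass
class FineMapConfig:
    window: int = 500_000
    prior_sd: float = PRIOR_SD_BINARY
    pip_floor: float = 0.001
    coverage: float = 0.95

    def validate(self) -> None:
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclasses.dataclass
class CredibleSet:
    signal: str
    members: pd.DataFrame  # SNP, PIP rows in descending PIP order
    cumulative: float
    resolved: bool = True


def wakefield_log_abf(beta, se, prior_sd: float):
    """Natural-log Wakefield ABF of association against the null."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    v = se**2
    w2 = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w2)) + 0.5 * z2 * w2 / (v + w2)


def single_signal_pips(
    stats: pd.DataFrame,
    priors=None,
    config: FineMapConfig | None = None,
    signal: str = "s1",
) -> pd.DataFrame:
    """PIPs for one signal: prior-weighted normalised ABFs.

    ``priors`` are optional per-variant multiplicative weights (for
    example externally estimated functional priors); they need not be
    normalised.
    """
    config = config or FineMapConfig()
    config.validate()
    labf = wakefield_log_abf(stats["BETA"].to_numpy(), stats["SE"].to_numpy(), config.prior_sd)
    if priors is not None:
        priors = np.asarray(priors, dtype=float)
        if np.any(priors <= 0):
            raise ValueError("priors must be positive")
        labf = labf + np.log(priors)
    pip = np.exp(labf - logsumexp(labf))
    return pd.DataFrame({"SNP": stats["SNP"].to_numpy(), "signal": signal, "PIP": pip})


def multi_signal_pips(
    stats: pd.DataFrame,
    panel: LDPanel,
    signals,
    config: FineMapConfig | None = None,
) -> pd.DataFrame:
    """Per-signal PIPs for a locus with several independent signals.

    For each signal, every variant's z-score is conditioned on the *other*
    signals before the ABF computation, so each signal's PIPs describe the
    residual association attributable to that signal alone. Variants
    collinear with the conditioning set contribute a null z. With a single
    signal this reduces exactly to :func:`single_signal_pips`.
    """
    config = config or FineMapConfig()
    config.validate()
    signals = list(signals)
    if len(signals) <= 1:
        return single_signal_pips(stats, None, config, signal=signals[0] if signals else "s1")
    stats = attach_z(stats)
    snp_to_idx = {s: i for i, s in enumerate(panel.variants["SNP"])}
    z_full = np.zeros(panel.n_variants)
    for _, row in stats.iterrows():
        if row["SNP"] in snp_to_idx:
            z_full[snp_to_idx[row["SNP"]]] = row["Z"]
    frames = []
    for sig in signals:
        others = [snp_to_idx[s] for s in signals if s != sig]
        z_cond = np.empty(len(stats))
        for k, (_, row) in enumerate(stats.iterrows()):
            j = snp_to_idx.get(row["SNP"])
            if j is None:
                z_cond[k] = 0.0
                continue
            res = conditional_z(z_full, panel, j, others)
            z_cond[k] = 0.0 if res.skipped or not np.isfinite(res.z) else res.z
        cond = stats.copy()
        cond["BETA"] = z_cond * cond["SE"]
        frames.append(single_signal_pips(cond, None, config, signal=sig))
    return pd.concat(frames, ignore_index=True)


def assemble_credible_sets(pips: pd.DataFrame, config: FineMapConfig | None = None) -> list[CredibleSet]:
    """Assemble one credible set per signal from a PIP table.

    Variants with PIP ≤ ``pip_floor`` are ineligible. Eligible variants are
    sorted by descending PIP and added while the cumulative PIP is below
    the coverage level (the variant whose addition reaches the level
    terminates the set). If the eligible variants cannot reach the level,
    the set is returned flagged unresolved.
    """
    config = config or FineMapConfig()
    config.validate()
    out = []
    for sig, grp in pips.groupby("signal", sort=True):
        eligible = grp[grp["PIP"] > config.pip_floor].sort_values(
            ["PIP", "SNP"], ascending=[False, True], kind="mergesort"
        )
        members, cum = [], 0.0
        for _, row in eligible.iterrows():
            if cum >= config.coverage:
                break
            members.append(row)
            cum += float(row["PIP"])
        resolved = cum >= config.coverage
        member_df = pd.DataFrame(members, columns=grp.columns).reset_index(drop=True)
        out.append(CredibleSet(signal=str(sig), members=member_df, cumulative=cum, resolved=resolved))
    return out


def finemap_locus(
    stats: pd.DataFrame,
    panel: LDPanel,
    locus: RiskLocus,
    config: FineMapConfig | None = None,
    priors=None,
) -> tuple[pd.DataFrame, list[CredibleSet]]:
    """Convenience wrapper: PIPs and credible sets for one risk locus."""
    config = config or FineMapConfig()
    half = config.window // 2
    in_window = stats[
        (stats["CHR"].astype(str) == locus.chrom)
        & (stats["BP"] >= locus.position - half)
        & (stats["BP"] <= locus.position + half)
    ].reset_index(drop=True)
    signals = locus.signals or [locus.lead["SNP"]]
    if len(signals) > 1:
        pips = multi_signal_pips(in_window, panel, signals, config)
    else:
        pips = single_signal_pips(in_window, priors, config)
    return pips, assemble_credible_sets(pips, config)
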