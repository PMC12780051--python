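"""Summary-statistics core: LD, risk-locus definition and conditional signals.

A *risk locus* is anchored by a lead variant with association
P < 5 × 10⁻⁸, with leads of distinct loci more than 500 kb apart. Within a
locus, secondary signals are discovered by forward stepwise conditional
analysis on summary statistics and an LD reference panel (the
summary-data analogue of joint multiple regression), and retained signals
are required to be mutually independent at r² ≤ 0.01.

The conditional z-score of candidate ``c`` given selected set ``S`` is

    z_c|S = (z_c − r_cSᵀ R_SS⁻¹ z_S) / sqrt(1 − r_cSᵀ R_SS⁻¹ r_cS)

with ``r`` the genotype correlations from the reference panel. Effects are
treated on the standardized-genotype scale; allele-frequency scaling of
joint effects (as in full COJO) is intentionally not modelled.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
MIN_LOCUS_SEPARATION = 500_000


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class UndefinedLDError(ValueError):
    """LD requested for a monomorphic (zero-variance) variant."""


@dataclasses.dataclass
class LDPanel:
    """Genotype dosages with a variant index aligned to summary statistics.

    Parameters
    ----------
    dosages
        (n_individuals, n_variants) matrix with values in {0, 1, 2}.
    variants
        Table with at least ``SNP CHR BP A1 A2`` rows aligned to the
        dosage columns.
    blocks
        Optional list of ``(start, stop)`` column ranges delimiting LD
        blocks (informational; correlations are always computed from the
        dosages themselves).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    blocks: list[tuple[int, int]] | None = None
    _corr: np.ndarray | None = dataclasses.field(default=None, repr=False, compare=False)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def corr(self) -> np.ndarray:
        """Pairwise dosage correlation matrix (cached).

        Monomorphic columns yield NaN rows/columns.
        """
        if self._corr is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    C = np.corrcoef(self.dosages, rowvar=False)
            self._corr = np.atleast_2d(C)
        return self._corr

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.variants["SNP"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"variant {snp_id!r} not in panel")
        return int(hits[0])

    def avs_sizes(self, r2_min: float = 0.8) -> np.ndarray:
        """Per-variant count of LD partners at r² ≥ ``r2_min`` (self included)."""
        r2 = self.corr() ** 2
        return np.nansum(r2 >= r2_min, axis=1).astype(int)


@dataclasses.dataclass
class RiskLocus:
    locus_id: str
    lead: pd.Series
    window: tuple[int, int]
    signals: list[str] = dataclasses.field(default_factory=list)

    @property
    def chrom(self) -> str:
        return str(self.lead["CHR"])

    @property
    def position(self) -> int:
        return int(self.lead["BP"])


@dataclasses.dataclass
class ConditionalResult:
    z: float
    p: float
    skipped: bool = False


def attach_z(stats: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``stats`` with a ``Z`` column (BETA/SE)."""
    out = stats.copy()
    out["Z"] = out["BETA"] / out["SE"]
    return out


def validate_stats(stats: pd.DataFrame, rtol: float = 1e-3) -> None:
    """Check internal consistency of a summary-statistics table.

    Raises if any SE is non-positive or any P value disagrees with the
    two-sided normal tail of |BETA/SE| beyond relative tolerance ``rtol``
    (for P large enough for the comparison to be meaningful in floats).
    """
    if (stats["SE"] <= 0).any():
        raise ValueError("summary statistics contain non-positive SE")
    z = np.abs(stats["BETA"] / stats["SE"])
    expected = 2.0 * sps.norm.sf(z)
    mask = expected > 1e-300
    p = stats["P"].to_numpy()[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
    e = expected[mask]
    bad = np.abs(p - e) > rtol * np.maximum(e, 1e-300)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} P values inconsistent with |z| normal tail")


def compute_ld(panel: LDPanel, i: int, j: int) -> tuple[float, float]:
    """Pearson correlation ``r`` and ``r²`` between two panel variants."""
    gi = panel.dosages[:, i].astype(float)
    gj = panel.dosages[:, j].astype(float)
    if gi.std() == 0 or gj.std() == 0:
        raise UndefinedLDError(f"variant {i if gi.std() == 0 else j} is monomorphic")
    r = float(np.corrcoef(gi, gj)[0, 1])
    return r, r * r


def define_risk_loci(
    stats: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    min_sep: int = MIN_LOCUS_SEPARATION,
) -> list[RiskLocus]:
    """Greedy risk-locus definition.

    Repeatedly take the smallest-P remaining variant below ``p_threshold``,
    seed a locus with it, and remove all threshold-passing variants within
    ``min_sep`` bp on the same chromosome. Loci on different chromosomes
    are never merged. Returns loci sorted by (chromosome, position); the
    result is invariant to input row order (ties broken on position then id).
    """
    hits = stats.loc[stats["P"] < p_threshold].copy()
    if hits.empty:
        return []
    hits = hits.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
    active = np.ones(len(hits), dtype=bool)
    chrom = hits["CHR"].astype(str).to_numpy()
    pos = hits["BP"].to_numpy()
    loci: list[RiskLocus] = []
    half = min_sep // 2
    for k in range(len(hits)):
        if not active[k]:
            continue
        lead = hits.iloc[k]
        active &= ~((chrom == str(lead["CHR"])) & (np.abs(pos - int(lead["BP"])) <= min_sep))
        loci.append(
            RiskLocus(
                locus_id=f"{lead['CHR']}:{lead['BP']}",
                lead=lead,
                window=(max(0, int(lead["BP"]) - half), int(lead["BP"]) + half),
            )
        )
    loci.sort(key=lambda L: (L.chrom, L.position))
    return loci


def conditional_z(
    z: np.ndarray,
    panel: LDPanel,
    candidate: int,
    selected,
    collinearity_r2: float = 0.9,
    ridge: float = 1e-8,
) -> ConditionalResult:
    """Conditional z-score of ``candidate`` given the ``selected`` variants.

    Parameters
    ----------
    z
        Marginal z-scores aligned to the panel's variant columns.
    candidate, selected
        Column indices into the panel.
    collinearity_r2
        Candidates with max r² to the selected set above this guard are
        skipped (flagged, not an error), mirroring the guard used by
        summary-data conditional analysis tools.
    ridge
        Added to the diagonal if the selected-set correlation matrix is
        numerically singular; the event is logged.
    """
    selected = list(selected)
    zc = float(z[candidate])
    if candidate in selected:
        return ConditionalResult(np.nan, np.nan, skipped=True)
    if not selected:
        return ConditionalResult(zc, 2.0 * sps.norm.sf(abs(zc)))
    C = panel.corr()
    r_cs = C[candidate, selected]
    if np.nanmax(r_cs**2) > collinearity_r2:
        return ConditionalResult(np.nan, np.nan, skipped=True)
    R = C[np.ix_(selected, selected)]
    try:
        sol = np.linalg.solve(R, np.column_stack([z[selected], r_cs]))
    except np.linalg.LinAlgError:
        logger.warning("singular selected-set LD matrix; ridge epsilon %.1e applied", ridge)
        sol = np.linalg.solve(R + ridge * np.eye(len(selected)), np.column_stack([z[selected], r_cs]))
    num = zc - float(r_cs @ sol[:, 0])
    denom2 = 1.0 - float(r_cs @ sol[:, 1])
    if denom2 <= 0:
        return ConditionalResult(np.nan, np.nan, skipped=True)
    z_cond = num / np.sqrt(denom2)
    return ConditionalResult(z_cond, 2.0 * sps.norm.sf(abs(z_cond)))


def stepwise_conditional(
    stats: pd.DataFrame,
    panel: LDPanel,
    locus: RiskLocus,
    p_threshold: float = GENOME_WIDE_P,
    collinearity_r2: float = 0.9,
) -> RiskLocus:
    """Forward stepwise signal selection within a locus window.

    Starts from the lead; while any in-window variant's conditional P
    (given the already-selected signals) is below ``p_threshold``, the
    best such variant is added. Signals are recorded in selection order
    on the returned locus.
    """
    stats = attach_z(stats)
    snp_to_idx = {s: i for i, s in enumerate(panel.variants["SNP"])}
    in_window = stats[
        (stats["CHR"].astype(str) == locus.chrom)
        & (stats["BP"] >= locus.window[0])
        & (stats["BP"] <= locus.window[1])
        & stats["SNP"].isin(snp_to_idx)
    ]
    z = np.zeros(panel.n_variants)
    p_marg = np.ones(panel.n_variants)
    idx_window = []
    for _, row in in_window.iterrows():
        j = snp_to_idx[row["SNP"]]
        z[j] = row["Z"]
        p_marg[j] = row["P"]
        idx_window.append(j)
    lead_idx = snp_to_idx[locus.lead["SNP"]]
    selected = [lead_idx]
    while True:
        best_j, best_p, best_z = None, np.inf, np.nan
        for j in idx_window:
            if j in selected:
                continue
            res = conditional_z(z, panel, j, selected, collinearity_r2=collinearity_r2)
            if res.skipped or not np.isfinite(res.p):
                continue
            if res.p < best_p or (res.p == best_p and best_j is not None and j < best_j):
                best_j, best_p, best_z = j, res.p, res.z
        if best_j is None or best_p >= p_threshold:
            break
        selected.append(best_j)
    out = RiskLocus(locus.locus_id, locus.lead, locus.window)
    out.signals = [panel.variants["SNP"].iloc[j] for j in selected]
    return out


def independence_filter(
    signals,
    stats: pd.DataFrame,
    panel: LDPanel,
    r2_max: float = 0.01,
) -> list[str]:
    """Greedy LD pruning of signals by ascending P.

    A signal is dropped if its r² to any already-retained signal exceeds
    ``r2_max``. Every retained pair therefore has r² ≤ ``r2_max``.
    """
    p_of = dict(zip(stats["SNP"], stats["P"]))
    order = sorted(set(signals), key=lambda s: (p_of.get(s, 1.0), s))
    C = panel.corr()
    retained: list[str] = []
    retained_idx: list[int] = []
    for s in order:
        j = panel.index_of(s)
        if all(C[j, k] ** 2 <= r2_max for k in retained_idx):
            retained.append(s)
            retained_idx.append(j)
    return retained
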