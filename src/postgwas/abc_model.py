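"""Activity-by-Contact (ABC) enhancer–gene scoring and variant linking.

The ABC score of candidate element e for gene g is

    score(e, g) = A_e · C_eg / Σ_{e' within the window of g} A_e' · C_e'g

where activity A is the geometric mean of reads-per-million-normalised
chromatin accessibility (ATAC) and H3K27ac counts, and contact C is the
(pseudocount-augmented) contact-map entry between the element midpoint bin
and the TSS bin. Scores for a gene over its in-window elements sum to one
by construction; a genome-wide ranking then retains the top-scoring
interactions. Promoter-proximal elements take part in the normalising sum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .sumstats import ConfigurationError

ABC_WINDOW = 2_000_000
ABC_TOP_K = 150_000


@dataclasses.dataclass
class ContactMap:
    """Binned symmetric contact counts.

    ``gamma`` is the fallback power-law exponent used when an entry is
    missing (outside the matrix); the pseudocount is the fitted expected
    count at ``ref_distance`` (default 1 Mb).
    """

    matrix: np.ndarray
    resolution: int
    gamma: float = 1.0
    ref_distance: int = 1_000_000
    _fit: tuple[float, float] | None = dataclasses.field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.resolution <= 0:
            raise ConfigurationError("contact-map resolution must be positive")
        if (self.matrix < 0).any():
            raise ValueError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int) -> int:
        return int(pos) // self.resolution

    def fit_decay(self) -> tuple[float, float]:
        """Log-log fit of mean count against bin distance.

        Returns ``(scale_at_one_bin, fitted_gamma)`` so that the expected
        count at bin distance d is ``scale · d^(−fitted_gamma)``.
        """
        if self._fit is None:
            n = self.n_bins
            dists, means = [], []
            for d in range(1, n):
                diag = np.diagonal(self.matrix, offset=d)
                mu = diag.mean()
                if mu > 0:
                    dists.append(d)
                    means.append(mu)
            if len(dists) < 2:
                self._fit = (max(float(self.matrix.mean()), 1e-12), self.gamma)
            else:
                slope, intercept = np.polyfit(np.log(dists), np.log(means), 1)
                self._fit = (float(np.exp(intercept)), float(-slope))
        return self._fit

    def expected_at(self, distance_bp: float) -> float:
        """Power-law expected count at a genomic distance (bp)."""
        scale, gamma = self.fit_decay()
        d_bins = max(distance_bp / self.resolution, 0.5)
        return scale * d_bins ** (-gamma)

    def pseudocount(self) -> float:
        return self.expected_at(self.ref_distance)


def element_activity(atac_rpm: float, h3k27ac_rpm: float) -> float:
    """Geometric mean of the two normalised activity signals."""
    if atac_rpm < 0 or h3k27ac_rpm < 0:
        raise ValueError("activity counts must be non-negative")
    return float(np.sqrt(atac_rpm * h3k27ac_rpm))


def element_activities(
    elements: pd.DataFrame,
    atac_col: str = "atac",
    h3k27ac_col: str = "h3k27ac",
) -> np.ndarray:
    """Per-element activity from raw counts.

    Each track is scaled to reads per million within itself before the
    geometric mean, so uniformly rescaling either track leaves every ABC
    score unchanged.
    """
    atac = elements[atac_col].to_numpy(dtype=float)
    k27 = elements[h3k27ac_col].to_numpy(dtype=float)
    if (atac < 0).any() or (k27 < 0).any():
        raise ValueError("activity counts must be non-negative")
    atac_rpm = atac / max(atac.sum(), 1e-300) * 1e6
    k27_rpm = k27 / max(k27.sum(), 1e-300) * 1e6
    return np.sqrt(atac_rpm * k27_rpm)


def contact_at(cmap: ContactMap, element_mid: int, tss: int) -> float:
    """Contact term between an element midpoint and a TSS.

    The observed count at the two bins plus the pseudocount; if either bin
    lies outside the map, the power-law expectation at that distance is
    used instead of the observed count.
    """
    bi, bj = cmap.bin_of(element_mid), cmap.bin_of(tss)
    pseudo = cmap.pseudocount()
    if 0 <= bi < cmap.n_bins and 0 <= bj < cmap.n_bins:
        return float(cmap.matrix[bi, bj]) + pseudo
    return cmap.expected_at(abs(element_mid - tss)) + pseudo


def abc_scores(
    elements: pd.DataFrame,
    genes: pd.DataFrame,
    cmap: ContactMap,
    window: int = ABC_WINDOW,
) -> pd.DataFrame:
    """Score all element–gene pairs with the element within ``window`` of the TSS.

    ``elements`` needs ``chrom start end atac h3k27ac`` columns, ``genes``
    needs ``gene chrom tss``. Returns one row per in-window pair with the
    activity, contact and normalised ABC score; per-gene scores sum to one.
    """
    act = element_activities(elements)
    mids = ((elements["start"].to_numpy() + elements["end"].to_numpy()) // 2).astype(np.int64)
    echrom = elements["chrom"].astype(str).to_numpy()
    rows = []
    for _, g in genes.iterrows():
        tss = int(g["tss"])
        sel = np.flatnonzero((echrom == str(g["chrom"])) & (np.abs(mids - tss) <= window))
        if sel.size == 0:
            continue
        contacts = np.array([contact_at(cmap, int(mids[j]), tss) for j in sel])
        weight = act[sel] * contacts
        total = weight.sum()
        score = weight / total if total > 0 else np.zeros_like(weight)
        for j, c, w, s in zip(sel, contacts, weight, score):
            rows.append(
                {
                    "element": int(j),
                    "chrom": echrom[j],
                    "start": int(elements["start"].iloc[j]),
                    "end": int(elements["end"].iloc[j]),
                    "gene": g["gene"],
                    "activity": act[j],
                    "contact": c,
                    "score": s,
                }
            )
    return pd.DataFrame(rows)


def select_interactions(
    interactions: pd.DataFrame,
    top_k: int = ABC_TOP_K,
    min_score: float | None = None,
) -> pd.DataFrame:
    """Keep the ``top_k`` highest-scoring interactions (boundary ties all kept),
    then optionally apply a minimum-score filter."""
    if interactions.empty or top_k >= len(interactions):
        out = interactions.copy()
    else:
        scores = np.sort(interactions["score"].to_numpy())[::-1]
        cutoff = scores[top_k - 1]
        out = interactions[interactions["score"] >= cutoff].copy()
    if min_score is not None:
        out = out[out["score"] >= min_score].copy()
    return out.reset_index(drop=True)


def link_variants(credible_positions: dict, selected: pd.DataFrame) -> dict:
    """Link loci to genes through credible-set variants inside selected elements.

    Parameters
    ----------
    credible_positions
        Mapping locus id → iterable of (chrom, 1-based position) of
        credible-set variants.
    selected
        Output of :func:`select_interactions` (element intervals retained).

    Returns
    -------
    dict
        locus id → {gene: best score among supporting interactions}.
    """
    links: dict = {}
    if selected.empty:
        return {locus: {} for locus in credible_positions}
    chroms = selected["chrom"].astype(str).to_numpy()
    starts = selected["start"].to_numpy()
    ends = selected["end"].to_numpy()
    for locus, variants in credible_positions.items():
        genes: dict = {}
        for chrom, pos in variants:
            pos0 = int(pos) - 1  # 1-based variant → 0-based half-open interval
            inside = (chroms == str(chrom)) & (starts <= pos0) & (pos0 < ends)
            for _, row in selected[inside].iterrows():
                g = row["gene"]
                genes[g] = max(genes.get(g, 0.0), float(row["score"]))
        links[locus] = genes
    return links


def cross_cell_consistency(links_a: dict, links_b: dict) -> tuple[pd.DataFrame, float]:
    """Per-locus agreement of linked gene sets between two cell contexts.

    A locus is consistent iff its gene sets are identical in both inputs.
    Returns the per-locus table and the consistent fraction over loci
    present in either input.
    """
    loci = sorted(set(links_a) | set(links_b))
    rows = []
    for locus in loci:
        ga = set(links_a.get(locus, {}))
        gb = set(links_b.get(locus, {}))
        rows.append({"locus": locus, "genes_a": sorted(ga), "genes_b": sorted(gb),
                     "consistent": ga == gb})
    df = pd.DataFrame(rows)
    frac = float(df["consistent"].mean()) if len(df) else float("nan")
    return df, frac
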