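"""Colocalisation of two traits by approximate Bayes factors.

Five configurations of causal variants in a region are weighed: H0 (no
association), H1/H2 (one trait associated), H3 (both, distinct causal
variants) and H4 (both, one shared causal variant). Per-variant Wakefield
log-ABFs for each trait are combined with the prior probabilities that a
variant is causal for trait 1 (p1), trait 2 (p2) or both (p12); the
default priors are the field's conventional 1e-4/1e-4/1e-5. All sums are
carried in log space; a posterior probability ≥ 0.8 is conventionally read
as support for the corresponding configuration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import PRIOR_SD_BINARY, PRIOR_SD_QUANTITATIVE, wakefield_log_abf

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


class AlignmentError(ValueError):
    """The two traits do not cover the same variant list."""


@dataclasses.dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    priors: tuple[float, float, float]
    n_variants: int

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    def best(self) -> int:
        return int(np.argmax(self.pp))


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd1: float = PRIOR_SD_BINARY,
    prior_sd2: float = PRIOR_SD_QUANTITATIVE,
) -> ColocResult:
    """Enumerate H0–H4 posterior probabilities for a shared region.

    Both tables need ``SNP BETA SE`` and must cover the same variant list
    (order-insensitively). ``prior_sd1``/``prior_sd2`` are the Wakefield
    effect-prior SDs of the two traits (binary-trait and quantitative
    defaults respectively).
    """
    if min(p1, p2, p12) <= 0:
        raise ValueError("priors must be positive")
    t1 = trait1.sort_values("SNP").reset_index(drop=True)
    t2 = trait2.sort_values("SNP").reset_index(drop=True)
    if len(t1) != len(t2) or not (t1["SNP"].to_numpy() == t2["SNP"].to_numpy()).all():
        raise AlignmentError("trait variant lists are misaligned")
    la = wakefield_log_abf(t1["BETA"].to_numpy(), t1["SE"].to_numpy(), prior_sd1)
    lb = wakefield_log_abf(t2["BETA"].to_numpy(), t2["SE"].to_numpy(), prior_sd2)
    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    # H3: sum over ordered distinct pairs = ΣA·ΣB − Σ(A_i·B_i). The subtraction
    # cancels catastrophically when one variant dominates both traits, so for
    # desk-scale windows the off-diagonal pair sum is taken exactly.
    n = len(la)
    if n == 1:
        l_h3_sum = -np.inf
    elif n <= 2000:
        pair = la[:, None] + lb[None, :]
        np.fill_diagonal(pair, -np.inf)
        l_h3_sum = logsumexp(pair)
    else:
        inner = lsum_ab - (lsum_a + lsum_b)
        if inner >= 0:
            warnings.warn("H3 inner term non-positive after rounding; clamped", stacklevel=2)
            l_h3_sum = -np.inf
        else:
            l_h3_sum = lsum_a + lsum_b + np.log1p(-np.exp(inner))
    lh = np.array(
        [
            0.0,
            np.log(p1) + lsum_a,
            np.log(p2) + lsum_b,
            np.log(p1) + np.log(p2) + l_h3_sum,
            np.log(p12) + lsum_ab,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(pp=pp, priors=(p1, p2, p12), n_variants=len(t1))
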