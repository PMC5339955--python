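"""Beta diversity: pairwise presence/absence similarity and the
multi-sample turnover suite.

Pairwise similarity uses Sorensen QS = 2a/(2a + b + c) and Jaccard
JS = a/(a + b + c), where a is the shared-species count and b, c the
counts unique to each assemblage.  The multi-sample suite follows the
definitions collated in the Koleff/Wilson-Shmida lineage (as used by
PAST): with pooled richness S, mean per-sample richness alpha_bar, the
maximum per-sample richness alpha_max, n samples, and cumulative gains
g(H) and losses l(H) along a declared gradient order,

    Whittaker      beta_w = S / alpha_bar - 1
    Cody           beta_c = (g + l) / 2
    Wilson-Shmida  beta_t = (g + l) / (2 alpha_bar)
    Mourelle       beta_M = beta_t / (n - 1)
    Harrison 1     beta_1 = (S / alpha_bar - 1) / (n - 1)
    Harrison 2     beta_2 = (S / alpha_max - 1) / (n - 1)
    Williams       beta_W = 1 - alpha_max / S
    Routledge      beta_R = S^2 / (2 r + S) - 1

with r the number of unordered species pairs that co-occur in at least
one sample.  Only Whittaker is order-free among the gradient-dependent
ones; Cody/Wilson-Shmida/Mourelle depend on the declared sample order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AbundanceMatrix

__all__ = [
    "PairDecomposition",
    "BetaSummary",
    "pair_decomposition",
    "similarity_indices",
    "similarity_matrix",
    "whittaker_beta",
    "gradient_beta_suite",
]


@dataclass(frozen=True)
class PairDecomposition:
    """Presence overlap between two assemblages: shared a, unique b and c."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("a, b, c must be non-negative")


def pair_decomposition(set_a: set, set_b: set) -> PairDecomposition:
    """Count shared and tissue-specific taxa for two presence sets."""
    return PairDecomposition(
        a=len(set_a & set_b), b=len(set_a - set_b), c=len(set_b - set_a)
    )


def similarity_indices(d: PairDecomposition) -> tuple[float, float]:
    """(Sorensen QS, Jaccard JS) from an a/b/c decomposition.

    The two are linked by JS = QS / (2 - QS); both are 1 for identical
    sets and 0 for disjoint ones.
    """
    denom = d.a + d.b + d.c
    if denom == 0:
        raise ValueError("both assemblages are empty")
    qs = 2.0 * d.a / (2.0 * d.a + d.b + d.c)
    js = d.a / denom
    return qs, js


def similarity_matrix(matrix: AbundanceMatrix) -> dict[str, pd.DataFrame]:
    """Square Sorensen and Jaccard similarity tables over all tissues.

    Returns ``{"sorensen": ..., "jaccard": ...}``; each table is
    symmetric with unit diagonal.
    """
    from .community import presence_set

    if len(matrix.tissues) < 2:
        raise ValueError("need at least 2 assemblages")
    sets = {t: presence_set(matrix, t) for t in matrix.tissues}
    k = len(matrix.tissues)
    qs = np.eye(k)
    js = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            q, jc = similarity_indices(
                pair_decomposition(sets[matrix.tissues[i]], sets[matrix.tissues[j]])
            )
            qs[i, j] = qs[j, i] = q
            js[i, j] = js[j, i] = jc
    idx = list(matrix.tissues)
    return {
        "sorensen": pd.DataFrame(qs, index=idx, columns=idx),
        "jaccard": pd.DataFrame(js, index=idx, columns=idx),
    }


def _presence(matrix: AbundanceMatrix) -> np.ndarray:
    p = matrix.counts > 0
    if (~p.any(axis=0)).any():
        raise ValueError("empty sample column")
    return p


def whittaker_beta(matrix: AbundanceMatrix) -> float:
    """Whittaker's beta_w = S_total / alpha_bar - 1.

    S_total is the pooled species count under the matrix's taxon
    resolution mode, so the same isolate table yields different values
    in ``label`` vs ``label_per_tissue`` mode whenever labels are
    shared across tissues.
    """
    p = _presence(matrix)
    s_total = int(p.any(axis=1).sum())
    alpha_bar = p.sum(axis=0).mean()
    return float(s_total / alpha_bar - 1.0)


@dataclass(frozen=True)
class BetaSummary:
    """Multi-sample beta diversity suite along a declared gradient."""

    S_total: int
    alpha_bar: float
    alpha_max: int
    n_samples: int
    gains_losses: int
    r_overlap: int
    whittaker_bw: float
    cody_bc: float
    wilson_shmida_bt: float
    routledge_bR: float
    mourelle_bM: float
    harrison_b1: float
    harrison_b2: float
    williams_bW: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Whittaker": self.whittaker_bw,
                "Harrison": self.harrison_b1,
                "Cody": self.cody_bc,
                "Routledge": self.routledge_bR,
                "Wilson-Shmida": self.wilson_shmida_bt,
                "Mourelle": self.mourelle_bM,
                "Harrison 2": self.harrison_b2,
                "Williams": self.williams_bW,
            }
        )


def gradient_beta_suite(matrix: AbundanceMatrix, order: list[str] | None = None) -> BetaSummary:
    """Compute the full turnover suite along a gradient of samples.

    ``order`` must be a permutation of the matrix's tissues; it
    defaults to the matrix column order.  Gains g(H) and losses l(H)
    are accumulated between consecutive samples along that order.
    """
    if order is None:
        order = list(matrix.tissues)
    if sorted(order) != sorted(matrix.tissues):
        raise ValueError(f"order {order!r} is not a permutation of {matrix.tissues}")
    if len(order) < 2:
        raise ValueError("need at least 2 samples")

    p = _presence(matrix)
    cols = [matrix.tissue_index(t) for t in order]
    pres = p[:, cols]  # taxa x ordered samples

    n = len(order)
    richness = pres.sum(axis=0)
    s_total = int(pres.any(axis=1).sum())
    alpha_bar = float(richness.mean())
    alpha_max = int(richness.max())

    gains = losses = 0
    for k in range(n - 1):
        prev, nxt = pres[:, k], pres[:, k + 1]
        gains += int((nxt & ~prev).sum())
        losses += int((prev & ~nxt).sum())
    gl = gains + losses

    # r: unordered taxon pairs sharing at least one sample
    co = pres.astype(int) @ pres.astype(int).T > 0
    r = int((co.sum() - co.trace()) // 2)

    bw = s_total / alpha_bar - 1.0
    bt = gl / (2.0 * alpha_bar)
    return BetaSummary(
        S_total=s_total,
        alpha_bar=alpha_bar,
        alpha_max=alpha_max,
        n_samples=n,
        gains_losses=gl,
        r_overlap=r,
        whittaker_bw=bw,
        cody_bc=gl / 2.0,
        wilson_shmida_bt=bt,
        routledge_bR=s_total**2 / (2.0 * r + s_total) - 1.0,
        mourelle_bM=bt / (n - 1),
        harrison_b1=bw / (n - 1),
        harrison_b2=(s_total / alpha_max - 1.0) / (n - 1),
        williams_bW=1.0 - alpha_max / s_total,
    )
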