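"""Alpha (within-assemblage) diversity indices for count vectors.

All entropies use natural logarithms.  Simpson's dominance is the plain
plug-in form D = sum p_i^2 rather than the small-sample-unbiased
estimator, and Chao-1 is the bias-corrected form with the F2 + 1
denominator — the combination used by the PAST desktop package, so that
profiles computed here can be compared against PAST output cell for
cell.

Fisher's log-series alpha solves S = alpha * ln(1 + N / alpha).  The
left side increases monotonically in alpha with supremum N, so a unique
positive root exists iff S < N; when every individual is its own
species (S = N) the index diverges and is reported as ``None``
(PAST prints 0 in that case; see :func:`AlphaProfile.to_series`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "shannon_entropy",
    "simpson_dominance",
    "richness_indices",
    "brillouin_index",
    "evenness_measures",
    "berger_parker",
    "chao1_estimate",
    "fisher_alpha",
    "alpha_profile",
    "AlphaProfile",
    "round_half_up",
]


def _clean(counts) -> np.ndarray:
    """Validate a count vector; return the positive entries."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("counts must be integers")
    arr = arr[arr > 0].astype(np.int64)
    if arr.size == 0:
        raise ValueError("all-zero count vector")
    return arr


def shannon_entropy(counts) -> float:
    """Shannon index H' = -sum p_i ln p_i (nats)."""
    n = _clean(counts)
    p = n / n.sum()
    return float(-(p * np.log(p)).sum())


def simpson_dominance(counts) -> tuple[float, float]:
    """Simpson's dominance D = sum p_i^2 and diversity 1 - D."""
    n = _clean(counts)
    p = n / n.sum()
    d = float((p * p).sum())
    return d, 1.0 - d


def richness_indices(counts) -> tuple[float, float, float]:
    """Menhinick D_mn = S/sqrt(N), Camargo 1/D_mn, Margalef D_mg = (S-1)/ln N.

    Margalef is 0 for a single individual (N = 1) by convention.
    """
    n = _clean(counts)
    s, total = n.size, int(n.sum())
    d_mn = s / math.sqrt(total)
    d_mg = 0.0 if total == 1 else (s - 1) / math.log(total)
    return d_mn, 1.0 / d_mn, d_mg


def brillouin_index(counts) -> float:
    """Brillouin HB = (ln N! - sum ln n_i!)/N, via log-gamma."""
    n = _clean(counts)
    total = int(n.sum())
    return float((gammaln(total + 1) - gammaln(n + 1).sum()) / total)


def evenness_measures(counts) -> tuple[float, float]:
    """Heip-style evenness e^H'/S and Pielou's equitability J = H'/ln S.

    J is defined as 1 for a single-species assemblage (no possible
    unevenness).
    """
    n = _clean(counts)
    s = n.size
    h = shannon_entropy(n)
    evenness = math.exp(h) / s
    j = 1.0 if s == 1 else h / math.log(s)
    return evenness, j


def berger_parker(counts) -> float:
    """Berger-Parker dominance d = max(n_i)/N."""
    n = _clean(counts)
    return float(n.max() / n.sum())


def chao1_estimate(counts) -> float:
    """Bias-corrected Chao-1: S + F1(F1 - 1) / (2 (F2 + 1))."""
    n = _clean(counts)
    f1 = int((n == 1).sum())
    f2 = int((n == 2).sum())
    return float(n.size + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def fisher_alpha(s: int, n: int, *, tol: float = 1e-12) -> float | None:
    """Fisher's log-series alpha: the root of S = a ln(1 + N/a).

    Returns ``None`` when S = N (the root diverges).  Bracketed root
    finding; the residual of the returned value is below 1e-9.
    """
    if s < 1:
        raise ValueError("S must be >= 1")
    if s > n:
        raise ValueError("S cannot exceed N")
    if s == n:
        return None

    def f(a: float) -> float:
        return a * math.log1p(n / a) - s

    lo, hi = 1e-10, 1.0
    while f(hi) < 0:  # expand until bracketed; f(hi) -> N - S > 0
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid S < N
            raise RuntimeError("failed to bracket Fisher alpha")
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


@dataclass(frozen=True)
class AlphaProfile:
    """All per-assemblage diversity statistics for one count vector."""

    S: int
    N: int
    p_i: np.ndarray
    simpson_D: float
    simpson_1mD: float
    shannon_H: float
    brillouin_HB: float
    menhinick_Dmn: float
    camargo_inv_Dmn: float
    margalef_Dmg: float
    evenness_eHS: float
    equitability_J: float
    fisher_alpha: float | None
    berger_parker_d: float
    chao1: float
    F1: int
    F2: int

    #: Row order and labels used when rendering a per-tissue table.
    FIELD_LABELS = (
        ("S", "Taxa_S"),
        ("N", "Individuals"),
        ("simpson_D", "Simpson's Dominance_D"),
        ("simpson_1mD", "Simpson_1-D"),
        ("shannon_H", "Shannon_H"),
        ("evenness_eHS", "Evenness_e^H/S"),
        ("brillouin_HB", "Brillouin"),
        ("menhinick_Dmn", "Menhinick richness index"),
        ("margalef_Dmg", "Margalef richness index"),
        ("equitability_J", "Equitability_J"),
        ("fisher_alpha", "Fisher_alpha diversity index"),
        ("berger_parker_d", "Berger-Parker dominance"),
        ("chao1", "Chao-1"),
    )

    def to_series(self, compat: bool = False) -> pd.Series:
        """Render as a labelled series.

        With ``compat=True`` values are rendered the way transcribed
        PAST tables print them (see :func:`round_table_compat`) and an
        undefined Fisher alpha prints as 0; otherwise full precision is
        kept and the undefined alpha is NaN.
        """
        out = {}
        for attr, label in self.FIELD_LABELS:
            v = getattr(self, attr)
            if v is None:
                v = 0.0 if compat else math.nan
            out[label] = round_table_compat(float(v)) if compat else float(v)
        return pd.Series(out)


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (spreadsheet convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_table_compat(x: float) -> float:
    """Render a value the way transcribed PAST diversity tables do.

    The desktop display shows 4 significant digits; transcription into
    a 3-decimal table then drops (truncates, does not round) anything
    beyond the third decimal.  This two-step convention reproduces
    published tables exactly (0.21875 -> 0.2188 -> 0.218;
    1.4427 -> 1.443; 10.905 -> 10.91) where a single half-up rounding
    to 3 decimals does not.
    """
    if x == 0 or not math.isfinite(x):
        return x
    # round to 4 significant digits, half away from zero
    exp = math.floor(math.log10(abs(x)))
    r4 = round_half_up(x, 3 - exp)
    # truncate toward zero at the third decimal
    d = Decimal(repr(r4)).quantize(Decimal("0.001"), rounding="ROUND_DOWN")
    return float(d)


def alpha_profile(counts) -> AlphaProfile:
    """Compute every alpha statistic for one assemblage's count vector."""
    n = _clean(counts)
    s, total = int(n.size), int(n.sum())
    d, one_m_d = simpson_dominance(n)
    d_mn, inv_d_mn, d_mg = richness_indices(n)
    ev, j = evenness_measures(n)
    return AlphaProfile(
        S=s,
        N=total,
        p_i=n / total,
        simpson_D=d,
        simpson_1mD=one_m_d,
        shannon_H=shannon_entropy(n),
        brillouin_HB=brillouin_index(n),
        menhinick_Dmn=d_mn,
        camargo_inv_Dmn=inv_d_mn,
        margalef_Dmg=d_mg,
        evenness_eHS=ev,
        equitability_J=j,
        fisher_alpha=fisher_alpha(s, total),
        berger_parker_d=berger_parker(n),
        chao1=chao1_estimate(n),
        F1=int((n == 1).sum()),
        F2=int((n == 2).sum()),
    )
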