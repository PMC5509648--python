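"""Closed-form significance bound for discovered disease-only motifs.

A motif that matches ``a`` of |A| disease subjects and zero of |B| control
subjects could still be *homogeneous* — equally likely to match any
subject regardless of category — in which case its discovery is a chance
artifact of the traversal.  For a homogeneous per-subject match
probability ``p``, the probability of exactly ``a`` category-A matches and
zero category-B matches is

    P(p) = C(|A|, a) * p**a * (1 - p)**(|A| - a) * (1 - p)**|B|

which is maximized at p = w = a / (|A| + |B|).  Substituting gives the
closed-form ceiling

    ML(a, |A|, |B|) = C(|A|, a) * w**a * (1 - w)**(|A| + |B| - a)

(the exponent a*(1/w - 1) equals the integer |A| + |B| - a, computed
exactly as such).  Over a traversal that scored C motifs, the expected
number of spurious homogeneous disease-only motifs with >= a matches is
bounded by the Maximum Expected Value

    Mev = C * sum_{i=a}^{|A|} ML(i, |A|, |B|)

A Mev well below one means the discovery is unlikely to be a traversal
artifact.  Magnitudes reach 1e-15 and binomials 1e14, so the fast path
works in log space (log-gamma + logsumexp) and an exact rational path via
``fractions.Fraction`` serves as the verification route — the closed form
is rational in w, so no precision is lost there at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, exp, inf, lgamma, log

import pandas as pd
from scipy.special import logsumexp


def _check_domain(a: int, size_a: int, size_b: int) -> None:
    if a < 1:
        raise ValueError("a must be >= 1 (w = 0 is outside the formula's domain)")
    if a > size_a:
        raise ValueError(f"a={a} exceeds |A|={size_a}")
    if size_b < 0:
        raise ValueError("|B| must be >= 0")


def ml_log(a: int, size_a: int, size_b: int) -> float:
    """Natural log of ML(a, |A|, |B|) via log-gamma (fast path)."""
    _check_domain(a, size_a, size_b)
    n = size_a + size_b
    if a == n:  # w = 1: both power terms degenerate to 1 and C(|A|,|A|) = 1
        return 0.0
    w = a / n
    log_binom = lgamma(size_a + 1) - lgamma(a + 1) - lgamma(size_a - a + 1)
    return log_binom + a * log(w) + (n - a) * log(1.0 - w)


def ml_exact(a: int, size_a: int, size_b: int) -> Fraction:
    """ML as an exact rational (verification path)."""
    _check_domain(a, size_a, size_b)
    w = Fraction(a, size_a + size_b)
    return Fraction(comb(size_a, a)) * w**a * (1 - w) ** (size_a + size_b - a)


def ml(a: int, size_a: int, size_b: int, *, method: str = "log") -> float:
    """ML(a, |A|, |B|): ceiling on the probability that a homogeneous motif
    matches exactly ``a`` category-A subjects and zero category-B subjects.

    ``method`` selects the log-space fast path (default) or the exact
    rational path ("exact"); the two agree to >= 10 significant digits.
    """
    if method == "exact":
        return float(ml_exact(a, size_a, size_b))
    if method == "log":
        return exp(ml_log(a, size_a, size_b))
    raise ValueError(f"unknown method {method!r}")


def log_mev(c: int, a: int, size_a: int, size_b: int) -> float:
    """Natural log of Mev(C, a, |A|, |B|); -inf when C = 0."""
    _check_domain(a, size_a, size_b)
    if c < 0:
        raise ValueError("C must be >= 0")
    if c == 0:
        return -inf
    tail = logsumexp([ml_log(i, size_a, size_b) for i in range(a, size_a + 1)])
    return log(c) + float(tail)


def mev(c: int, a: int, size_a: int, size_b: int, *, method: str = "log") -> float:
    """Maximum Expected Value: C times the ML tail sum over i = a..|A|.

    Exactly linear in C and monotone non-increasing in ``a``.
    """
    if method == "exact":
        _check_domain(a, size_a, size_b)
        if c < 0:
            raise ValueError("C must be >= 0")
        return float(
            c * sum(ml_exact(i, size_a, size_b) for i in range(a, size_a + 1))
        )
    return exp(log_mev(c, a, size_a, size_b))


def mev_curve(c: int, size_a: int, size_b: int) -> pd.DataFrame:
    """The significance curve: (a, Mev, -ln Mev) for a = 1..|A|.

    -ln(Mev) is negative where Mev > 1 (a count reachable by chance) and
    positive where Mev < 1; the sign change locates the significance
    cutoff for a traversal of C motifs.
    """
    rows = []
    for a in range(1, size_a + 1):
        lm = log_mev(c, a, size_a, size_b)
        rows.append({"a": a, "mev": exp(lm), "neg_ln_mev": -lm})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SignificanceReport:
    """ML/Mev assessment of one discovered disease-only motif."""

    a: int
    size_a: int
    size_b: int
    c: int
    w: float
    ml_value: float
    mev: float
    neg_ln_mev: float

    @classmethod
    def compute(cls, a: int, size_a: int, size_b: int, c: int) -> "SignificanceReport":
        lm = log_mev(c, a, size_a, size_b)
        return cls(
            a=a,
            size_a=size_a,
            size_b=size_b,
            c=c,
            w=a / (size_a + size_b),
            ml_value=ml(a, size_a, size_b),
            mev=exp(lm),
            neg_ln_mev=-lm,
        )

    def is_significant(self, alpha: float = 1.0) -> bool:
        """Whether the expected spurious-DOM count falls below ``alpha``
        (default 1.0: "expected count significantly less than one")."""
        return self.mev < alpha
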