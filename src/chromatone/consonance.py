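"""Interval consonance quantification for just intonation and 12-TET.

The consonance of a two-tone interval is scored from the harmonic series:
two tones whose fundamentals stand in a small-integer frequency ratio p:q
share a partial early in their overtone columns, and the product of the
ordinal numbers of that first shared partial measures how "simple" — hence
how consonant — the interval is.  The score is expressed on a decibel scale
and, for equal-tempered intervals, reduced by a resonance-style penalty for
the cents deviation from the nearest just interval.

Quantities computed per interval:

* ``K = 1/(m·n)`` — consonance coefficient from the first-shared-partial
  ordinals ``m`` (root column) and ``n`` (crown column);
* ``Ip = 20·log10(1000·K)`` dB — just-intonation consonance index;
* ``δ`` — absolute cents deviation of the 12-TET interval from the similar
  just interval;
* ``η = 2**(δ/1200)`` — frequency ratio corresponding to ``δ``;
* ``A = (1 + Q²(η − 1/η)²)^(−1/2)`` — relative amplitude of a resonant
  circuit of quality factor ``Q`` detuned by ``δ`` cents;
* ``−ΔI = 20·log10(A)`` dB — correction, and ``I = Ip − ΔI`` the final
  12-TET consonance index.

Categories A–E ("very complete consonance" … "very incomplete consonance")
are a fixed lookup by interval name, not a numeric threshold on ``I``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import pandas as pd

__all__ = [
    "DEFAULT_Q",
    "IntervalSpec",
    "ConsonanceResult",
    "first_consonant_partial_ordinals",
    "pure_interval_index",
    "cents_of_ratio",
    "cents_deviation",
    "amplitude_correction",
    "tet_interval_index",
    "classify_consonance",
    "default_interval_table",
    "consonance_table",
]

#: Quality factor of the resonant circuit used for the detuning penalty.
DEFAULT_Q = 100.0

#: Category letters by interval abbreviation (A = very complete consonance,
#: B = complete, C/D = incomplete, E = very incomplete).
_CATEGORY: dict[str, str] = {
    "P1": "A", "P8": "A",
    "P4": "B", "P5": "B",
    "m3": "C", "M3": "C", "A4": "C", "m6": "C", "M6": "C",
    "M2": "D", "m7": "D",
    "m2": "E", "M7": "E",
}

# (abbreviation, 12-TET semitones, just ratio crown:root)
_DEFAULT_INTERVALS: list[tuple[str, int, tuple[int, int]]] = [
    ("P1", 0, (1, 1)),
    ("m2", 1, (16, 15)),
    ("M2", 2, (9, 8)),
    ("m3", 3, (6, 5)),
    ("M3", 4, (5, 4)),
    ("P4", 5, (4, 3)),
    ("A4", 6, (64, 45)),
    ("P5", 7, (3, 2)),
    ("m6", 8, (8, 5)),
    ("M6", 9, (5, 3)),
    ("m7", 10, (16, 9)),
    ("M7", 11, (15, 8)),
    ("P8", 12, (2, 1)),
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Presentation rounding: half-up at `ndigits` decimals.

    Internal math is kept in full precision; this is applied only when
    rendering table-style output.
    """
    scale = 10.0 ** ndigits
    if x >= 0:
        return math.floor(x * scale + 0.5) / scale
    return -math.floor(-x * scale + 0.5) / scale


@dataclass(frozen=True)
class IntervalSpec:
    """One of the 13 common two-tone relations.

    Parameters
    ----------
    abbreviation : str
        Conventional interval name, e.g. ``"P5"``.
    tet_semitones : int
        Width in 12-TET semitones (0–12).
    just_ratio : tuple[int, int]
        Crown-to-root frequency ratio ``(p, q)`` of the similar just
        interval, coprime with ``1 ≤ p/q ≤ 2``.
    """

    abbreviation: str
    tet_semitones: int
    just_ratio: tuple[int, int]

    def __post_init__(self) -> None:
        p, q = self.just_ratio
        if p < 1 or q < 1:
            raise ValueError(f"just ratio must be positive, got {p}/{q}")
        if math.gcd(p, q) != 1:
            raise ValueError(f"just ratio {p}/{q} is not in lowest terms")
        if not (1 <= Fraction(p, q) <= 2):
            raise ValueError(f"just ratio {p}/{q} outside [1, 2]")
        if not 0 <= self.tet_semitones <= 12:
            raise ValueError(f"tet_semitones must be 0–12, got {self.tet_semitones}")

    @property
    def tet_cents(self) -> int:
        return 100 * self.tet_semitones

    @property
    def just_cents_exact(self) -> float:
        p, q = self.just_ratio
        return cents_of_ratio(p, q)

    @property
    def just_cents_rounded(self) -> int:
        return _round_half_away(self.just_cents_exact)


@dataclass(frozen=True)
class ConsonanceResult:
    """All intermediate and final consonance quantities for one interval."""

    abbreviation: str
    m: int
    n: int
    K: float
    Ip: float
    delta: int
    eta: float
    A: float
    neg_delta_I: float
    I: float
    category: str


def cents_of_ratio(p: int, q: int) -> float:
    """Cents (1/1200 octave) spanned by frequency ratio ``p/q``."""
    return 1200.0 * math.log2(p / q)


def first_consonant_partial_ordinals(just_ratio: tuple[int, int]) -> tuple[int, int]:
    """Ordinals (m, n) of the first partial shared by the two tones.

    For a crown:root ratio p:q in lowest terms the lowest common overtone is
    at frequency p·q·f_root/q = p·f_root, i.e. the p-th partial of the root
    and the q-th partial of the crown, so ``(m, n) = (p, q)``.

    Raises
    ------
    ValueError
        If the ratio is not a coprime pair of positive integers with
        ``1 ≤ p/q ≤ 2``.
    """
    p, q = just_ratio
    if p < 1 or q < 1 or p < q:
        raise ValueError(f"need p ≥ q ≥ 1, got {p}/{q}")
    if math.gcd(p, q) != 1:
        raise ValueError(f"ratio {p}/{q} is not coprime")
    if Fraction(p, q) > 2:
        raise ValueError(f"ratio {p}/{q} wider than an octave")
    return p, q


def pure_interval_index(m: int, n: int) -> float:
    """Just-intonation consonance index Ip = 20·log10(1000/(m·n)) dB."""
    if m < 1 or n < 1:
        raise ValueError("partial ordinals must be ≥ 1")
    return 20.0 * math.log10(1000.0 / (m * n))


def cents_deviation(tet_cents: int, just_cents_rounded: int) -> int:
    """Absolute deviation δ = |tet − just| in (integer) cents."""
    for c in (tet_cents, just_cents_rounded):
        if not 0 <= c <= 1200:
            raise ValueError(f"cents value {c} outside [0, 1200]")
    return abs(tet_cents - just_cents_rounded)


def amplitude_correction(
    delta: float, Q: float = DEFAULT_Q, literal_amplitude: bool = False
) -> tuple[float, float, float]:
    """Detuning penalty (η, A, −ΔI) for a cents deviation δ.

    A resonant circuit of quality factor Q driven off-resonance by the
    frequency ratio η = 2**(δ/1200) responds with relative amplitude
    ``A = (1 + Q²(η − 1/η)²)^(−1/2)``; the dB penalty is 20·log10(A) ≤ 0.

    ``literal_amplitude=True`` drops the square root (amplitude = squared form),
    roughly doubling the dB penalty; kept for comparison only.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if Q <= 0:
        raise ValueError("Q must be positive")
    eta = 2.0 ** (delta / 1200.0)
    denom = 1.0 + Q * Q * (eta - 1.0 / eta) ** 2
    A = 1.0 / denom if literal_amplitude else denom ** -0.5
    neg_delta_I = 20.0 * math.log10(A)
    return eta, A, neg_delta_I


def classify_consonance(abbreviation: str) -> str:
    """Consonance category letter A–E for one of the 13 interval names."""
    try:
        return _CATEGORY[abbreviation]
    except KeyError:
        raise ValueError(f"unknown interval abbreviation {abbreviation!r}") from None


def tet_interval_index(
    spec: IntervalSpec, Q: float = DEFAULT_Q, literal_amplitude: bool = False
) -> ConsonanceResult:
    """Full 12-TET consonance computation for one interval spec."""
    m, n = first_consonant_partial_ordinals(spec.just_ratio)
    K = 1.0 / (m * n)
    Ip = pure_interval_index(m, n)
    delta = cents_deviation(spec.tet_cents, spec.just_cents_rounded)
    eta, A, neg_delta_I = amplitude_correction(delta, Q, literal_amplitude)
    return ConsonanceResult(
        abbreviation=spec.abbreviation,
        m=m,
        n=n,
        K=K,
        Ip=Ip,
        delta=delta,
        eta=eta,
        A=A,
        neg_delta_I=neg_delta_I,
        I=Ip + neg_delta_I,
        category=classify_consonance(spec.abbreviation),
    )


def default_interval_table() -> list[IntervalSpec]:
    """The 13 common intervals with their conventional just ratios."""
    return [IntervalSpec(a, s, r) for a, s, r in _DEFAULT_INTERVALS]


def consonance_table(
    specs: Iterable[IntervalSpec] | None = None,
    Q: float = DEFAULT_Q,
    literal_amplitude: bool = False,
    rounded: bool = False,
) -> pd.DataFrame:
    """Consonance results for all intervals as a DataFrame.

    Columns follow the conventional tabulation: abbreviation, 12-TET cents,
    just cents, Ip, δ, −ΔI, I, category.  ``rounded=True`` applies half-up
    presentation rounding (2 decimals) to the dB columns.
    """
    specs = default_interval_table() if specs is None else list(specs)
    rows = []
    for spec in specs:
        res = tet_interval_index(spec, Q=Q, literal_amplitude=literal_amplitude)
        rows.append(
            {
                "abbreviation": spec.abbreviation,
                "tet_cents": spec.tet_cents,
                "just_cents": spec.just_cents_rounded,
                "Ip": res.Ip,
                "delta": res.delta,
                "neg_delta_I": res.neg_delta_I,
                "I": res.I,
                "category": res.category,
            }
        )
    df = pd.DataFrame(rows)
    if rounded:
        for col in ("Ip", "neg_delta_I", "I"):
            df[col] = df[col].map(lambda v: round_half_up(v, 2))
    return df
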