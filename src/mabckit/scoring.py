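"""Background-recovery scoring, foreground segregation test, selection
rules, and relative-expression (2^-ddCt) calculation.

Genotype codes follow the co-dominant band-scoring convention:

``RR``
    homozygous for the recurrent-parent allele,
``RD``
    heterozygous,
``DD``
    homozygous for the donor allele,
``NA`` (or ``None`` / empty string)
    missing call.

The background recovery rate for an individual scored at ``I`` markers of
which ``S`` are recurrent-homozygous and ``het`` heterozygous is computed
by allele counting::

    Rg = (2*S + het) / (2*I) * 100

which reduces exactly to the band-count form ``(I + S) / (2*I) * 100``
whenever no donor homozygotes occur (the clean backcross case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RR",
    "RD",
    "DD",
    "MISSING",
    "GenotypeMatrix",
    "RecoveryReport",
    "SegregationTest",
    "ExpressionAssay",
    "HomozygosityVerdict",
    "recovery_rate",
    "score_matrix",
    "chi_square_1to1",
    "select_individuals",
    "homozygosity_by_progeny",
    "ddct",
    "infer_scored_marker_count",
    "invert_recovery_rate",
]

RR = "RR"
RD = "RD"
DD = "DD"
MISSING = "NA"

_VALID_CALLS = {RR, RD, DD, MISSING}

#: chi-square critical value for df=1, alpha=0.05
CHI2_CRITICAL_1DF_05 = 3.84


def _normalise_call(call: object) -> str:
    if call is None:
        return MISSING
    s = str(call).strip().upper()
    if s in ("", "-", "NAN", "NA", "N/A", "."):
        return MISSING
    if s == "DR":
        s = RD
    if s not in _VALID_CALLS:
        raise ValueError(f"unrecognised genotype call {call!r}")
    return s


@dataclass(frozen=True)
class RecoveryReport:
    """Per-individual marker counts and background recovery rate.

    ``I = S + het + dd`` counts only scored (non-missing) markers.
    """

    individual: str
    I: int
    S: int
    het: int
    dd: int = 0

    def __post_init__(self) -> None:
        if self.I != self.S + self.het + self.dd:
            raise ValueError(
                f"{self.individual}: I={self.I} != "
                f"S+het+dd={self.S + self.het + self.dd}"
            )
        if min(self.I, self.S, self.het, self.dd) < 0:
            raise ValueError(f"{self.individual}: negative marker count")

    @property
    def rg(self) -> float:
        """Recovery rate in percent (allele counting)."""
        return (2 * self.S + self.het) / (2 * self.I) * 100.0

    @property
    def rg_band_form(self) -> float:
        """The band-count form (I+S)/(2I)*100; equals ``rg`` when dd=0."""
        return (self.I + self.S) / (2 * self.I) * 100.0


class GenotypeMatrix:
    """Individuals x markers matrix of genotype calls.

    Parameters
    ----------
    individuals, markers
        Row and column identifiers.
    calls
        Nested sequence (rows = individuals) of genotype codes; entries
        are normalised to ``RR``/``RD``/``DD``/``NA``.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        markers: Sequence[str],
        calls: Sequence[Sequence[object]],
    ) -> None:
        individuals = [str(i) for i in individuals]
        markers = [str(m) for m in markers]
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual ids")
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate marker ids")
        if len(calls) != len(individuals):
            raise ValueError(
                f"{len(calls)} call rows for {len(individuals)} individuals"
            )
        norm: list[list[str]] = []
        for ind, row in zip(individuals, calls):
            row = [_normalise_call(c) for c in row]
            if len(row) != len(markers):
                raise ValueError(
                    f"individual {ind!r}: {len(row)} calls for "
                    f"{len(markers)} markers"
                )
            norm.append(row)
        self.individuals = individuals
        self.markers = markers
        self.calls = norm

    def row(self, individual: str) -> list[str]:
        return self.calls[self.individuals.index(individual)]

    @classmethod
    def from_dataframe(cls, df) -> "GenotypeMatrix":
        """Build from a pandas DataFrame (index = individuals)."""
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy().tolist(),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.calls, index=self.individuals, columns=self.markers
        )


def recovery_rate(
    calls: Iterable[object], individual: str = "individual"
) -> RecoveryReport:
    """Score one individual's genotype calls into a :class:`RecoveryReport`.

    Missing calls shrink the denominator ``I``; an all-missing individual
    is an error (there is nothing to score).
    """
    s = het = dd = 0
    for call in calls:
        c = _normalise_call(call)
        if c == RR:
            s += 1
        elif c == RD:
            het += 1
        elif c == DD:
            dd += 1
    total = s + het + dd
    if total == 0:
        raise ValueError(
            f"individual {individual!r} has no scored markers "
            "(all calls missing)"
        )
    return RecoveryReport(individual=individual, I=total, S=s, het=het, dd=dd)


def score_matrix(matrix: GenotypeMatrix) -> list[RecoveryReport]:
    """Score every individual of a genotype matrix."""
    return [
        recovery_rate(row, individual=ind)
        for ind, row in zip(matrix.individuals, matrix.calls)
    ]


@dataclass(frozen=True)
class SegregationTest:
    n_positive: int
    n_negative: int
    chi2: float
    critical_value: float = CHI2_CRITICAL_1DF_05
    yates: bool = False

    @property
    def passed(self) -> bool:
        """True when the observed split is consistent with 1:1."""
        return self.chi2 <= self.critical_value


def chi_square_1to1(
    n1: int,
    n2: int,
    yates: bool = False,
    critical_value: float = CHI2_CRITICAL_1DF_05,
) -> SegregationTest:
    """Chi-square goodness-of-fit of an observed split against 1:1.

    With ``yates`` the continuity-corrected numerators
    ``(|O-E| - 0.5)^2`` are used (clamped at zero for |O-E| < 0.5).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    total = n1 + n2
    if total == 0:
        raise ValueError("cannot test an empty sample against 1:1")
    expected = total / 2.0
    chi2 = 0.0
    for obs in (n1, n2):
        dev = abs(obs - expected)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / expected
    return SegregationTest(
        n_positive=n1,
        n_negative=n2,
        chi2=chi2,
        critical_value=critical_value,
        yates=yates,
    )


def select_individuals(
    reports: Sequence[RecoveryReport],
    min_rg: float,
    phenotype_ok: Mapping[str, bool] | None = None,
) -> list[str]:
    """Ids of individuals with ``Rg > min_rg`` (strict) and an acceptable
    phenotype flag, ordered by descending Rg then id.

    Phenotype similarity is an external boolean; individuals absent from
    ``phenotype_ok`` are treated as acceptable.
    """
    chosen = []
    for r in reports:
        if r.rg <= min_rg:
            continue
        if phenotype_ok is not None and not phenotype_ok.get(r.individual, True):
            continue
        chosen.append(r)
    chosen.sort(key=lambda r: (-r.rg, r.individual))
    return [r.individual for r in chosen]


@dataclass(frozen=True)
class HomozygosityVerdict:
    verdict: str  # "homozygous" | "segregating" | "inconclusive"
    n_progeny: int
    n_carriers: int
    #: probability of the observation under a hemizygous (segregating)
    #: parent with lethal screening of nulls applied in the next round
    p_null: float


def homozygosity_by_progeny(
    progeny_carrier_flags: Sequence[bool],
    alpha: float = 0.05,
) -> HomozygosityVerdict:
    """Classify a selfed parent from its progeny's carrier states.

    Any non-carrier progeny proves the parent segregating. When all
    progeny carry, the false-positive probability under a hemizygous
    parent is ``0.75**n`` (selfing a hemizygote yields carriers with
    probability 3/4); the homozygous verdict is withheld while that
    probability exceeds ``alpha``.
    """
    flags = list(progeny_carrier_flags)
    if not flags:
        raise ValueError("progeny test needs at least one progeny")
    n = len(flags)
    n_carriers = sum(bool(f) for f in flags)
    p_null = 0.75 ** n
    if n_carriers < n:
        verdict = "segregating"
    elif p_null <= alpha:
        verdict = "homozygous"
    else:
        verdict = "inconclusive"
    return HomozygosityVerdict(
        verdict=verdict, n_progeny=n, n_carriers=n_carriers, p_null=p_null
    )


@dataclass(frozen=True)
class ExpressionAssay:
    sample: str
    ct_target: float
    ct_reference: float
    calibrator_dct: float

    @property
    def relative_expression(self) -> float:
        return ddct(self.ct_target, self.ct_reference, self.calibrator_dct)


def ddct(
    ct_target: float, ct_reference: float, calibrator_dct: float
) -> float:
    """Relative expression 2^-ddCt.

    ``ddCt = (ct_target - ct_reference) - calibrator_dct``; the
    calibrator delta-Ct is an explicit input (choose the sample the fold
    changes are expressed against).
    """
    for v in (ct_target, ct_reference, calibrator_dct):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    return 2.0 ** -((ct_target - ct_reference) - calibrator_dct)


# -- marker-count inversion -------------------------------------------------


def invert_recovery_rate(
    rate_pct: float,
    i_range: tuple[int, int],
    tol_pct: float = 0.01,
) -> list[tuple[int, int]]:
    """All integer ``(I, S)`` pairs with ``(I+S)/(2I)*100`` printing as
    ``rate_pct`` at two decimals (rounded or truncated) within ``tol_pct``.
    """
    lo, hi = i_range
    out = []
    for i in range(lo, hi + 1):
        s = round((2 * rate_pct / 100.0 - 1.0) * i)
        if not 0 <= s <= i:
            continue
        v = (i + s) / (2 * i) * 100.0
        rounded = round(v, 2)
        truncated = math.floor(v * 100) / 100.0
        if min(abs(rounded - rate_pct), abs(truncated - rate_pct)) <= tol_pct + 1e-9:
            out.append((i, s))
    return out


def infer_scored_marker_count(
    rates_pct: Sequence[float],
    i_range: tuple[int, int] = (90, 130),
    tol_pct: float = 0.01,
) -> list[int]:
    """Candidate scored-marker counts ``I`` consistent with *every* printed
    percentage in ``rates_pct`` for some integer ``S`` (two-decimal
    printing, rounding or truncation allowed).

    Brute-force search over ``i_range``; returns all fitting ``I``.
    """
    lo, hi = i_range
    out = []
    for i in range(lo, hi + 1):
        if all(
            any(pair[0] == i for pair in invert_recovery_rate(p, (i, i), tol_pct))
            for p in rates_pct
        ):
            out.append(i)
    return out
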