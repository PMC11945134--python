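"""Genetic-map coordinate system (centiMorgans) shared by all modules."""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: a name, a genetic length, and optionally the
    physical length used for linear bp<->cM interpolation."""

    name: str
    length_cM: float
    length_bp: int | None = None
    marker_positions_cM: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.length_cM <= 0:
            raise ValueError(
                f"chromosome {self.name!r}: length_cM must be positive, "
                f"got {self.length_cM}"
            )
        if self.length_bp is not None and self.length_bp <= 0:
            raise ValueError(
                f"chromosome {self.name!r}: length_bp must be positive"
            )
        pos = self.marker_positions_cM
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"chromosome {self.name!r}: marker positions must be "
                "strictly increasing"
            )
        if pos and (pos[0] < 0 or pos[-1] > self.length_cM):
            raise ValueError(
                f"chromosome {self.name!r}: marker positions outside "
                f"[0, {self.length_cM}]"
            )


class GeneticMap:
    """Ordered collection of chromosomes with lengths in centiMorgans.

    Houses the cM coordinate system used for recombination simulation and
    for marker-panel spacing.

    Parameters
    ----------
    chromosomes
        Iterable of :class:`Chromosome`, or of ``(name, length_cM)`` pairs.
    """

    def __init__(self, chromosomes: Iterable[Chromosome | tuple]) -> None:
        chroms: list[Chromosome] = []
        for entry in chromosomes:
            if isinstance(entry, Chromosome):
                chroms.append(entry)
            else:
                name, length = entry[0], entry[1]
                chroms.append(Chromosome(str(name), float(length)))
        if not chroms:
            raise ValueError("a genetic map needs at least one chromosome")
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in map")
        self._chroms = chroms
        self._by_name = {c.name: c for c in chroms}

    @property
    def chromosomes(self) -> list[Chromosome]:
        return list(self._chroms)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self._chroms]

    @property
    def total_length_cM(self) -> float:
        return sum(c.length_cM for c in self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not on map") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self._chroms == other._chroms

    def __repr__(self) -> str:
        return (
            f"GeneticMap({len(self._chroms)} chromosomes, "
            f"{self.total_length_cM:.1f} cM)"
        )

    # -- coordinate conversion ------------------------------------------

    def cm_from_bp(self, chrom: str, pos_bp: int) -> float:
        """Linear interpolation of a 1-based physical position onto cM.

        Requires the chromosome to carry a physical length. A uniform
        recombination-rate profile is assumed.
        """
        c = self[chrom]
        if c.length_bp is None:
            raise ValueError(
                f"chromosome {chrom!r} has no physical length; cannot "
                "interpolate bp -> cM"
            )
        if not 1 <= pos_bp <= c.length_bp:
            raise ValueError(
                f"position {pos_bp} outside chromosome {chrom!r} "
                f"(1..{c.length_bp})"
            )
        return (pos_bp - 0.5) / c.length_bp * c.length_cM

    def bp_from_cm(self, chrom: str, pos_cM: float) -> int:
        """Inverse of :meth:`cm_from_bp` (rounded to the nearest base)."""
        c = self[chrom]
        if c.length_bp is None:
            raise ValueError(
                f"chromosome {chrom!r} has no physical length; cannot "
                "interpolate cM -> bp"
            )
        if not 0 <= pos_cM <= c.length_cM:
            raise ValueError(
                f"position {pos_cM} cM outside chromosome {chrom!r}"
            )
        pos = int(round(pos_cM / c.length_cM * c.length_bp + 0.5))
        return min(max(pos, 1), c.length_bp)

    # -- panel geometry helpers -----------------------------------------

    def evenly_spaced_positions(self, n_markers: int) -> list[tuple[str, float]]:
        """Place ``n_markers`` loci evenly across the map.

        Markers are apportioned to chromosomes proportionally to genetic
        length (largest-remainder rounding, at least one per chromosome)
        and spread uniformly over each chromosome's interior.

        Returns a list of ``(chromosome name, position cM)`` sorted in map
        order.
        """
        if n_markers < len(self._chroms):
            raise ValueError(
                f"need at least one marker per chromosome "
                f"({len(self._chroms)}), got {n_markers}"
            )
        total = self.total_length_cM
        quotas = [n_markers * c.length_cM / total for c in self._chroms]
        counts = [max(1, int(q)) for q in quotas]
        remainders = sorted(
            range(len(quotas)),
            key=lambda i: quotas[i] - int(quotas[i]),
            reverse=True,
        )
        i = 0
        while sum(counts) < n_markers:
            counts[remainders[i % len(remainders)]] += 1
            i += 1
        while sum(counts) > n_markers:
            j = max(range(len(counts)), key=lambda k: counts[k])
            counts[j] -= 1
        out: list[tuple[str, float]] = []
        for c, k in zip(self._chroms, counts):
            # interior placement: midpoints of k equal bins
            step = c.length_cM / k
            out.extend((c.name, step * (j + 0.5)) for j in range(k))
        return out


def interval_index(positions: Sequence[float], x: float) -> int:
    """Index of the interval of sorted breakpoints containing ``x``."""
    return bisect.bisect_right(positions, x)
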