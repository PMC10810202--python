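"""Parental centromere pairs and recombination-breakpoint mapping.

Budding-yeast point centromeres (~117 bp, elements CDEI/CDEII/CDEIII) from two
diverged strain backgrounds differ at a handful of single-nucleotide
polymorphisms.  Those heterozygous positions ("informative sites") let a
sequenced recombinant centromere be decomposed into a parent-of-origin vector,
from which the recombination breakpoint is localised to the interval between
the last site of one parent and the first site of the other.

Coordinates are 1-based inclusive alignment columns throughout, matching the
convention used to number centromere SNPs (e.g. positions 11..101 on a 117-bp
alignment).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

__all__ = [
    "AlignmentError",
    "ParentalCentromerePair",
    "InformativeSiteSet",
    "IdentityTract",
    "Orientation",
    "Category",
    "RecombinantCentromereCall",
    "ConstructMap",
    "CentromereBreakpointMapper",
    "find_informative_sites",
    "longest_identity_tract",
    "genotype_recombinant",
    "map_breakpoint",
    "bin_breakpoints",
    "detect_acentric_ru",
]

_ALPHABET = set("ACGT-")
_GAP = "-"


class AlignmentError(ValueError):
    """Raised when sequences are not congruent with the alignment frame."""


class Orientation(str, Enum):
    W_LEFT_Y_RIGHT = "W_left_Y_right"
    Y_LEFT_W_RIGHT = "Y_left_W_right"


class Category(str, Enum):
    PARENTAL_W = "parental_W"
    PARENTAL_Y = "parental_Y"
    SIMPLE_RECOMBINANT = "simple_recombinant"
    PATCHY = "patchy"
    ACENTRIC_RU = "acentric_RU"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ParentalCentromerePair:
    """Two aligned parental centromere sequences.

    ``functional_state_*`` is False for centromeres inactivated by a CDEIII
    point mutation (the C106T class of alleles).  ``cde_regions`` optionally
    annotates (label, start, end) spans for CDEI/CDEII/CDEIII in 1-based
    inclusive alignment coordinates.
    """

    name_w: str
    name_y: str
    seq_w: str
    seq_y: str
    functional_state_w: bool = True
    functional_state_y: bool = True
    cde_regions: tuple[tuple[str, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.seq_w) != len(self.seq_y):
            raise AlignmentError(
                f"aligned sequences differ in length: "
                f"{len(self.seq_w)} vs {len(self.seq_y)}"
            )
        for name, seq in ((self.name_w, self.seq_w), (self.name_y, self.seq_y)):
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"{name}: illegal characters {sorted(bad)}")
        if self.cde_regions is not None:
            spans = sorted((s, e, lab) for lab, s, e in self.cde_regions)
            for (s, e, lab) in spans:
                if lab not in {"CDEI", "CDEII", "CDEIII"}:
                    raise ValueError(f"unknown CDE label {lab!r}")
                if not (1 <= s <= e <= len(self.seq_w)):
                    raise ValueError(f"{lab} span ({s},{e}) out of bounds")
            for (s1, e1, _), (s2, _, _) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError("CDE regions overlap")

    @property
    def length(self) -> int:
        return len(self.seq_w)


@dataclass(frozen=True)
class InformativeSiteSet:
    """Alignment columns where the two parents carry different non-gap bases."""

    positions: tuple[int, ...]
    allele_w: tuple[str, ...]
    allele_y: tuple[str, ...]
    seq_length: int
    indel_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly ascending")
        if not all(1 <= p <= self.seq_length for p in self.positions):
            raise ValueError("positions out of range")
        for w, y in zip(self.allele_w, self.allele_y):
            if w == y or _GAP in (w, y):
                raise ValueError("informative site must have differing non-gap alleles")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class IdentityTract:
    """A run of alignment columns containing no informative site."""

    start: int
    end: int
    bounded_by: tuple[int | None, int | None]

    @property
    def length(self) -> int:
        return self.end - self.start + 1 if self.end >= self.start else 0


@dataclass(frozen=True)
class RecombinantCentromereCall:
    """Genotype vector and breakpoint interpretation for one recombinant."""

    genotype: tuple[str, ...]
    category: Category
    breakpoint: tuple[int, int] | None
    n_switches: int
    isolate_id: str | None = None

    def __post_init__(self) -> None:
        if (self.breakpoint is not None) != (
            self.category is Category.SIMPLE_RECOMBINANT
        ):
            raise ValueError("breakpoint present iff simple_recombinant")


@dataclass(frozen=True)
class ConstructMap:
    """Feature map of the split-marker construct around the centromere.

    The recombination reporter places the centromere inside an artificial
    intron interrupting a selectable gene: the 5' intron half sits on one
    homolog, the 3' half on the other.  ``five_prime_half`` and
    ``three_prime_half`` are the intron-half sequences flanking the centromere
    feature; an acentric recombinant gene (RU) is their perfect fusion.
    """

    five_prime_half: str
    three_prime_half: str
    cen_interval: tuple[int, int]

    def ru_fusion(self) -> str:
        return self.five_prime_half + self.three_prime_half


def find_informative_sites(pair: ParentalCentromerePair) -> InformativeSiteSet:
    """Scan an aligned parental pair for informative (substitution) sites.

    Columns where the parents differ and neither has a gap are informative;
    columns with a gap in either parent are recorded separately as indel
    columns and excluded from breakpoint logic.
    """
    positions, aw, ay, indels = [], [], [], []
    sw, sy = pair.seq_w.upper(), pair.seq_y.upper()
    for i, (w, y) in enumerate(zip(sw, sy), start=1):
        if w == y:
            continue
        if w == _GAP or y == _GAP:
            indels.append(i)
        else:
            positions.append(i)
            aw.append(w)
            ay.append(y)
    return InformativeSiteSet(
        positions=tuple(positions),
        allele_w=tuple(aw),
        allele_y=tuple(ay),
        seq_length=pair.length,
        indel_columns=tuple(indels),
    )


def _all_runs(sites: InformativeSiteSet) -> list[IdentityTract]:
    """Every maximal site-free run: terminal runs plus inter-site runs."""
    runs: list[IdentityTract] = []
    pos = sites.positions
    n = sites.seq_length
    if not pos:
        return [IdentityTract(1, n, (None, None))]
    if pos[0] > 1:
        runs.append(IdentityTract(1, pos[0] - 1, (None, pos[0])))
    for p, q in zip(pos, pos[1:]):
        if q - p > 1:
            runs.append(IdentityTract(p + 1, q - 1, (p, q)))
    if pos[-1] < n:
        runs.append(IdentityTract(pos[-1] + 1, n, (pos[-1], None)))
    return runs


def longest_identity_tract(sites: InformativeSiteSet) -> IdentityTract:
    """Longest run of columns free of informative sites; ties to smallest start."""
    runs = _all_runs(sites)
    if not runs:
        # every column is a site: degenerate zero-length tract at the start
        return IdentityTract(1, 0, (None, None))
    return max(runs, key=lambda t: (t.length, -t.start))


def genotype_recombinant(
    recomb_seq: str, pair: ParentalCentromerePair,
    sites: InformativeSiteSet | None = None,
) -> tuple[str, ...]:
    """Per informative site: W / Y by parental-allele match, N otherwise."""
    if len(recomb_seq) != pair.length:
        raise AlignmentError(
            f"recombinant length {len(recomb_seq)} != alignment length {pair.length}"
        )
    if sites is None:
        sites = find_informative_sites(pair)
    seq = recomb_seq.upper()
    out = []
    for p, w, y in zip(sites.positions, sites.allele_w, sites.allele_y):
        base = seq[p - 1]
        out.append("W" if base == w else "Y" if base == y else "N")
    return tuple(out)


def map_breakpoint(
    genotype: Sequence[str],
    sites: InformativeSiteSet,
    orientation: Orientation | str = Orientation.W_LEFT_Y_RIGHT,
    isolate_id: str | None = None,
) -> RecombinantCentromereCall:
    """Interpret a genotype vector as parental / simple recombinant / patchy.

    Ambiguous (N) sites are skipped when counting W<->Y switches but widen the
    reported breakpoint interval to the nearest flanking non-N sites.  A single
    switch running against the declared construct orientation cannot arise from
    the expected simple recombinant and is reported as ambiguous.
    """
    orientation = Orientation(orientation)
    if len(genotype) != len(sites):
        raise AlignmentError("genotype vector and site set are not congruent")
    geno = tuple(genotype)
    if any(g not in {"W", "Y", "N"} for g in geno):
        raise ValueError("genotype symbols must be W, Y or N")

    known = [(p, g) for p, g in zip(sites.positions, geno) if g != "N"]
    if not known:
        return RecombinantCentromereCall(geno, Category.AMBIGUOUS, None, 0, isolate_id)

    n_switches = sum(1 for (_, a), (_, b) in zip(known, known[1:]) if a != b)
    alleles = {g for _, g in known}
    if alleles == {"W"}:
        return RecombinantCentromereCall(geno, Category.PARENTAL_W, None, 0, isolate_id)
    if alleles == {"Y"}:
        return RecombinantCentromereCall(geno, Category.PARENTAL_Y, None, 0, isolate_id)
    if n_switches > 1:
        return RecombinantCentromereCall(
            geno, Category.PATCHY, None, n_switches, isolate_id
        )
    # exactly one switch
    left_parent = "W" if orientation is Orientation.W_LEFT_Y_RIGHT else "Y"
    if known[0][1] != left_parent:
        return RecombinantCentromereCall(
            geno, Category.AMBIGUOUS, None, n_switches, isolate_id
        )
    switch_at = next(
        i for i, ((_, a), (_, b)) in enumerate(zip(known, known[1:])) if a != b
    )
    bp = (known[switch_at][0], known[switch_at + 1][0])
    return RecombinantCentromereCall(
        geno, Category.SIMPLE_RECOMBINANT, bp, 1, isolate_id
    )


def bin_breakpoints(
    calls: Iterable[RecombinantCentromereCall], sites: InformativeSiteSet
) -> dict[str, int]:
    """Histogram of simple-recombinant breakpoints over inter-site bins.

    Bins are labelled by flanking site pairs ("24-68").  Non-simple calls are
    rejected with their index reported; counts always sum to the input size.
    """
    bins = {
        f"{p}-{q}": 0 for p, q in zip(sites.positions, sites.positions[1:])
    }
    for i, call in enumerate(calls):
        if call.category is not Category.SIMPLE_RECOMBINANT:
            raise ValueError(
                f"call at index {i} is {call.category.value}, not simple_recombinant"
            )
        left, right = call.breakpoint  # type: ignore[misc]
        label = f"{left}-{right}"
        if label not in bins:
            # N-widened interval spanning several bins: count it once under
            # its own composite label so totals stay conserved.
            bins[label] = 0
        bins[label] += 1
    return bins


def detect_acentric_ru(
    recomb_seq: str, pair: ParentalCentromerePair, construct: ConstructMap
) -> bool:
    """True iff the sequence is the perfect intron-half fusion lacking the centromere."""
    return recomb_seq.upper().replace(_GAP, "") == construct.ru_fusion().upper()


class CentromereBreakpointMapper(BaseEstimator):
    """Map recombinant centromere sequences onto a fitted parental pair.

    Parameters
    ----------
    orientation : which parent contributes the left side of a simple
        recombinant, fixed by the reporter construct (default W-left/Y-right).

    Attributes (after :meth:`fit`)
    ------------------------------
    pair_ : the parental pair.
    sites_ : InformativeSiteSet scanned from the pair.
    longest_tract_ : the maximal identity tract between informative sites.
    """

    def __init__(self, orientation: Orientation | str = Orientation.W_LEFT_Y_RIGHT):
        self.orientation = orientation

    def fit(self, pair: ParentalCentromerePair, y=None) -> "CentromereBreakpointMapper":
        self.pair_ = pair
        self.sites_ = find_informative_sites(pair)
        self.longest_tract_ = longest_identity_tract(self.sites_)
        return self

    def predict(
        self,
        sequences: Iterable[str] | dict[str, str],
    ) -> list[RecombinantCentromereCall]:
        """Genotype each aligned recombinant sequence and call its breakpoint."""
        if not hasattr(self, "sites_"):
            raise RuntimeError("mapper is not fitted; call fit(pair) first")
        items = (
            sequences.items()
            if isinstance(sequences, dict)
            else ((None, s) for s in sequences)
        )
        return [
            map_breakpoint(
                genotype_recombinant(seq, self.pair_, self.sites_),
                self.sites_,
                self.orientation,
                isolate_id=name,
            )
            for name, seq in items
        ]

    def bin_counts(
        self, calls: Sequence[RecombinantCentromereCall]
    ) -> dict[str, int]:
        simple = [c for c in calls if c.category is Category.SIMPLE_RECOMBINANT]
        return bin_breakpoints(simple, self.sites_)


def category_tally(calls: Iterable[RecombinantCentromereCall]) -> Counter:
    return Counter(c.category.value for c in calls)
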