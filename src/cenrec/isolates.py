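"""Classification of Ura+ intercentromere-recombinant isolates.

Each isolate carries one to three copies of chromosome III, and each copy is
summarised by three markers: the distal left-arm allele (LEU2/leu2), the
centromere state read out by diagnostic PCR (parental WP or YP, recombinant
RCU or RC, acentric RU), and the distal right-arm mating-type allele
(MATa/MATalpha).  In the starting hybrid diploid, leu2 is coupled to MATalpha
on the W303-derived homolog and LEU2 to MATa on the YJM789-derived homolog,
so any chromosome with a "crossed" coupling records a crossover between the
flanking markers.

Isolates fall into five classes: disomes retaining the W303 parental
centromere plus a recombinant (class 1), disomes retaining the YJM789
parental centromere plus a recombinant (class 2), disomes with an acentric
recombinant URA3 (class 3), monosomes (class 4), and trisomes (class 5, for
which crossover status is not determined).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator

__all__ = [
    "PCR_PRODUCT_SIZES",
    "CANONICAL_HAPLOTYPES",
    "SUBCLASS_TABLE",
    "HaplotypeIII",
    "IsolateGenotype",
    "Coupling",
    "CoStatus",
    "Ploidy",
    "ClassificationResult",
    "IsolateClassifier",
    "predict_pcr_products",
    "coupling_type",
    "classify",
    "tabulate",
    "fisher_exact_2x2",
    "mechanism_labels",
]

# Diagnostic PCR product sizes in bp, fixed by the reporter construct.
PCR_PRODUCT_SIZES: dict[str, int] = {
    "WP": 274, "YP": 462, "RCU": 489, "RC": 270, "RU": 372,
}

_CEN_STATES = set(PCR_PRODUCT_SIZES)
_LEFT = {"LEU2", "leu2"}
_RIGHT = {"MATa", "MATalpha"}


class Coupling(str, Enum):
    PARENTAL_W = "parental_W"
    PARENTAL_Y = "parental_Y"
    CROSSED = "crossed"


class CoStatus(str, Enum):
    CO = "CO"
    NCO = "NCO"
    ND = "ND"


class Ploidy(str, Enum):
    MONOSOMIC = "monosomic"
    DISOMIC = "disomic"
    TRISOMIC = "trisomic"


@dataclass(frozen=True)
class HaplotypeIII:
    """One chromosome III copy: left distal allele, centromere state, right distal."""

    left_distal: str
    cen_state: str
    right_distal: str
    proximal_tag: str = ""

    def __post_init__(self) -> None:
        if self.left_distal not in _LEFT:
            raise ValueError(f"left_distal must be LEU2/leu2, got {self.left_distal!r}")
        if self.cen_state not in _CEN_STATES:
            raise ValueError(f"cen_state must be one of {sorted(_CEN_STATES)}")
        if self.right_distal not in _RIGHT:
            raise ValueError(
                f"right_distal must be MATa/MATalpha, got {self.right_distal!r}"
            )

    @property
    def marker_tuple(self) -> tuple[str, str, str]:
        return (self.left_distal, self.cen_state, self.right_distal)


@dataclass(frozen=True)
class IsolateGenotype:
    isolate_id: str
    haplotypes: tuple[HaplotypeIII, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.haplotypes) <= 3:
            raise ValueError("isolates carry 1-3 chromosome III copies")


@dataclass(frozen=True)
class ClassificationResult:
    isolate_id: str
    pcr_products: frozenset[str]
    cls: int | str  # 1..5 or "unclassifiable"
    subclass: str | None
    co_status: CoStatus
    ploidy: Ploidy
    reciprocal_pair: bool | None  # None encodes not-determined
    simple_nco: bool

    def __post_init__(self) -> None:
        if self.cls == 4 and self.ploidy is not Ploidy.MONOSOMIC:
            raise ValueError("class 4 must be monosomic")
        if self.cls == 5 and self.ploidy is not Ploidy.TRISOMIC:
            raise ValueError("class 5 must be trisomic")
        if (self.co_status is CoStatus.ND) != (self.cls in (5, "unclassifiable")):
            raise ValueError("CO/NCO is not determined exactly for trisomes")


# Canonical single-chromosome configurations (letters A-E, K-P).  Centromere
# states and ploidies are as tabulated in the source roster; the distal
# couplings are the unique assignment under which the coupling rule
# reproduces every tabulated CO/NCO call (verified by the test suite).
CANONICAL_HAPLOTYPES: dict[str, HaplotypeIII] = {
    "A": HaplotypeIII("leu2", "WP", "MATalpha"),
    "B": HaplotypeIII("LEU2", "YP", "MATa"),
    "C": HaplotypeIII("LEU2", "WP", "MATalpha"),
    "D": HaplotypeIII("LEU2", "YP", "MATalpha"),
    "E": HaplotypeIII("leu2", "WP", "MATa"),
    "K": HaplotypeIII("leu2", "RCU", "MATalpha"),
    "L": HaplotypeIII("LEU2", "RCU", "MATa"),
    "M": HaplotypeIII("leu2", "RCU", "MATa"),
    "N": HaplotypeIII("LEU2", "RCU", "MATalpha"),
    "O": HaplotypeIII("leu2", "RU", "MATa"),
    "P": HaplotypeIII("LEU2", "RU", "MATa"),
}

# subclass -> letters of its chromosome configuration(s)
SUBCLASS_TABLE: dict[str, tuple[str, ...]] = {
    "1A": ("A", "L"), "1B": ("A", "M"), "1C": ("A", "K"), "1D": ("C", "L"),
    "1E": ("E", "M"), "1F": ("C", "M"), "1G": ("E", "N"),
    "2A": ("B", "K"), "2B": ("B", "M"), "2C": ("D", "M"), "2D": ("B", "L"),
    "2E": ("B", "N"), "2F": ("D", "K"), "2G": ("D", "L"), "2H": ("D", "N"),
    "3A": ("A", "O"), "3B": ("D", "O"), "3C": ("B", "P"),
    "4A": ("L",), "4B": ("M",), "4C": ("K",),
    "5": ("A", "B", "L"),
}

RECIPROCAL_SUBCLASSES = frozenset({"1F", "2C", "3B"})

_MARKERS_TO_LETTER = {
    h.marker_tuple: letter for letter, h in CANONICAL_HAPLOTYPES.items()
}
_LETTERS_TO_SUBCLASS = {
    frozenset(Counter(letters).items()): sub
    for sub, letters in SUBCLASS_TABLE.items()
    if sub != "5"
}


def predict_pcr_products(isolate: IsolateGenotype) -> dict[str, int]:
    """Union of diagnostic PCR products over haplotypes, with sizes in bp."""
    return {
        h.cen_state: PCR_PRODUCT_SIZES[h.cen_state] for h in isolate.haplotypes
    }


def coupling_type(hap: HaplotypeIII) -> Coupling:
    """Coupling of the flanking markers relative to the parental phases."""
    pair = (hap.left_distal, hap.right_distal)
    if pair == ("leu2", "MATalpha"):
        return Coupling.PARENTAL_W
    if pair == ("LEU2", "MATa"):
        return Coupling.PARENTAL_Y
    return Coupling.CROSSED


def _is_unrearranged_parental(hap: HaplotypeIII) -> bool:
    """Parental centromere with its own parental flanking phase."""
    c = coupling_type(hap)
    return (hap.cen_state == "WP" and c is Coupling.PARENTAL_W) or (
        hap.cen_state == "YP" and c is Coupling.PARENTAL_Y
    )


def _simple_nco(haps: Sequence[HaplotypeIII]) -> bool:
    """Disome = one unrearranged parental + RCU carrying the *other* parent's phase.

    This is the signature of a plain non-crossover gene conversion (the SDSA
    expectation): the homolog that acquired the recombinant centromere keeps
    its own parental flanking phase, opposite to that of the intact homolog.
    """
    if len(haps) != 2:
        return False
    for parental, recomb in (haps, haps[::-1]):
        if not _is_unrearranged_parental(parental) or recomb.cen_state != "RCU":
            continue
        want = (
            Coupling.PARENTAL_Y if parental.cen_state == "WP" else Coupling.PARENTAL_W
        )
        if coupling_type(recomb) is want:
            return True
    return False


def _lookup_subclass(haps: Sequence[HaplotypeIII], cls: int | str) -> str | None:
    if cls == 5:
        return "5"
    letters = [_MARKERS_TO_LETTER.get(h.marker_tuple) for h in haps]
    if any(let is None for let in letters):
        return None
    return _LETTERS_TO_SUBCLASS.get(frozenset(Counter(letters).items()))


def classify(isolate: IsolateGenotype) -> ClassificationResult:
    """Assign class, subclass, crossover status, and ploidy to one isolate.

    Class rules: disome {WP, RCU} -> 1; disome {YP, RCU} -> 2; disome with RU
    plus one parental centromere -> 3; monosome with a recombinant product
    (RCU or RU) -> 4; trisome with both parentals plus a recombinant -> 5.
    Anything else (e.g. a disome with no recombinant product, which could not
    have been selected) is unclassifiable.
    """
    haps = isolate.haplotypes
    states = Counter(h.cen_state for h in haps)
    n = len(haps)
    ploidy = {1: Ploidy.MONOSOMIC, 2: Ploidy.DISOMIC, 3: Ploidy.TRISOMIC}[n]

    cls: int | str = "unclassifiable"
    if n == 2:
        if states == Counter({"WP": 1, "RCU": 1}):
            cls = 1
        elif states == Counter({"YP": 1, "RCU": 1}):
            cls = 2
        elif states.get("RU", 0) == 1 and (
            states.get("WP", 0) == 1 or states.get("YP", 0) == 1
        ):
            cls = 3
    elif n == 1:
        if states.get("RCU", 0) == 1 or states.get("RU", 0) == 1:
            cls = 4
    elif n == 3:
        if (
            states.get("WP", 0) >= 1
            and states.get("YP", 0) >= 1
            and (states.get("RCU", 0) >= 1 or states.get("RU", 0) >= 1)
        ):
            cls = 5

    if cls in (5, "unclassifiable"):
        co = CoStatus.ND
    else:
        crossed = any(coupling_type(h) is Coupling.CROSSED for h in haps)
        co = CoStatus.CO if crossed else CoStatus.NCO

    subclass = None if cls == "unclassifiable" else _lookup_subclass(haps, cls)
    reciprocal = None if cls in (5, "unclassifiable") else (
        subclass in RECIPROCAL_SUBCLASSES
    )
    return ClassificationResult(
        isolate_id=isolate.isolate_id,
        pcr_products=frozenset(states),
        cls=cls,
        subclass=subclass,
        co_status=co,
        ploidy=ploidy,
        reciprocal_pair=reciprocal,
        simple_nco=(cls in (1, 2) and _simple_nco(haps)),
    )


def tabulate(results: Iterable[ClassificationResult]) -> dict:
    """Summary counts over a classified roster.

    Returns class and subclass totals, CO/NCO/ND counts, the number of
    crossover-associated disomes, simple non-crossover conversions,
    reciprocal pairs, and the aneuploidy frequency
    (monosomic + trisomic) / total.
    """
    results = list(results)
    if not results:
        raise ValueError("empty roster")
    class_counts: Counter = Counter(r.cls for r in results)
    subclass_counts: Counter = Counter(
        r.subclass for r in results if r.subclass is not None
    )
    co_counts = Counter(r.co_status.value for r in results)
    n = len(results)
    n_mono = sum(r.ploidy is Ploidy.MONOSOMIC for r in results)
    n_tri = sum(r.ploidy is Ploidy.TRISOMIC for r in results)
    return {
        "n_isolates": n,
        "class_counts": dict(class_counts),
        "subclass_counts": dict(subclass_counts),
        "co_counts": dict(co_counts),
        "disome_co": sum(
            r.ploidy is Ploidy.DISOMIC and r.co_status is CoStatus.CO
            for r in results
        ),
        "simple_nco": sum(r.simple_nco for r in results),
        "reciprocal_pairs": sum(bool(r.reciprocal_pair) for r in results),
        "n_monosomic": n_mono,
        "n_trisomic": n_tri,
        "aneuploidy_frequency": (n_mono + n_tri) / n,
    }


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    t = [[int(v) for v in row] for row in table]
    if len(t) != 2 or any(len(r) != 2 for r in t):
        raise ValueError("table must be 2x2")
    if any(v < 0 for row in t for v in row):
        raise ValueError("counts must be non-negative")
    rows = [sum(r) for r in t]
    cols = [t[0][0] + t[1][0], t[0][1] + t[1][1]]
    if 0 in rows or 0 in cols:
        raise ValueError("degenerate table: a margin is zero")
    return float(fisher_exact(t, alternative="two-sided")[1])


def mechanism_labels(result: ClassificationResult) -> frozenset[str]:
    """Mechanisms compatible with the classified pattern (annotation only).

    Reciprocal pairs require double-Holliday-junction resolution (DSBR);
    other crossover-associated patterns can arise by DSBR or BIR; plain
    non-crossover conversions are the SDSA expectation.  Trisomes, for which
    crossover status is not determined, get no label.
    """
    if result.co_status is CoStatus.ND:
        return frozenset()
    if result.reciprocal_pair:
        return frozenset({"DSBR"})
    if result.co_status is CoStatus.CO:
        return frozenset({"DSBR", "BIR"})
    return frozenset({"SDSA"})


class IsolateClassifier(BaseEstimator):
    """Rule-based classifier over isolate genotypes (stateless; fit is a no-op)."""

    def fit(self, X=None, y=None) -> "IsolateClassifier":
        self.is_fitted_ = True
        return self

    def predict(
        self, X: Iterable[IsolateGenotype]
    ) -> list[ClassificationResult]:
        return [classify(iso) for iso in X]

    def summarize(self, X: Iterable[IsolateGenotype]) -> dict:
        return tabulate(self.predict(X))
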