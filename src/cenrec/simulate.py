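"""Synthetic-data generators with ground truth for every pipeline stage.

All generators take an integer seed and are byte-reproducible.  Latent values
(true breakpoint column, true rate, true class labels, true copy-number
segments) are returned as :class:`GroundTruth` sidecars sufficient to score
every downstream call without re-deriving them.

The fluctuation simulator uses the classic deterministic-growth descendant
construction (a mutation arising when the culture has N cells leaves a clone
of ~N_t/N cells, i.e. clone size floor(1/u) for u ~ Uniform(0,1]); it shares
no code with the Ma-Sandri-Sarkar pmf, so their distributional agreement is
a genuine cross-validation of both.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .centromere import (
    ConstructMap,
    ParentalCentromerePair,
    find_informative_sites,
)
from .coverage import GenomeMetadata
from .fluctuation import FluctuationExperiment
from .isolates import (
    CANONICAL_HAPLOTYPES,
    SUBCLASS_TABLE,
    HaplotypeIII,
    IsolateGenotype,
)

__all__ = [
    "GroundTruth",
    "CEN3_SNP_POSITIONS",
    "CEN3_ALIGNMENT_LENGTH",
    "CANONICAL_ROSTER_COMPOSITION",
    "PlantedEvent",
    "GenomeModel",
    "DEFAULT_GENOME_MODEL",
    "cen3_fixture_pair",
    "cen3_construct",
    "gen_centromere_pair",
    "gen_recombinant",
    "gen_fluctuation_counts",
    "gen_roster",
    "gen_coverage",
    "gen_colonies",
]


@dataclass(frozen=True)
class GroundTruth:
    """Latent values of a generated dataset, JSON-serializable."""

    kind: str
    seed: int
    data: dict

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not serializable: {type(o)}")

        s = json.dumps(dataclasses.asdict(self), default=default, indent=1,
                       sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


# ---------------------------------------------------------------------------
# centromere sequences
# ---------------------------------------------------------------------------

CEN3_SNP_POSITIONS = (11, 13, 24, 68, 70, 81, 101)
CEN3_ALIGNMENT_LENGTH = 117
_CEN3_CDE = (("CDEI", 1, 9), ("CDEII", 10, 93), ("CDEIII", 94, 117))
_FUNCTIONAL_SITE = 106  # CDEIII C whose mutation to T inactivates the centromere

_TRANSVERSION = {"A": "C", "T": "G", "C": "A", "G": "T"}


def _random_backbone(length: int, rng: np.random.Generator,
                     at_rich: tuple[int, int] | None = None) -> np.ndarray:
    bases = np.array(list("ACGT"))
    probs = np.full((length, 4), 0.25)
    if at_rich is not None:
        s, e = at_rich
        probs[s - 1 : e] = [0.44, 0.06, 0.06, 0.44]  # ~88% AT inside CDEII
    u = rng.random(length)
    cum = probs.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return bases[idx]


def gen_centromere_pair(
    length: int,
    n_snps: int | None = None,
    seed: int = 0,
    positions: Sequence[int] | None = None,
    at_rich: tuple[int, int] | None = None,
    names: tuple[str, str] = ("W", "Y"),
) -> ParentalCentromerePair:
    """Two aligned sequences differing exactly at the chosen columns."""
    rng = np.random.default_rng(seed)
    if positions is None:
        if n_snps is None:
            raise ValueError("give positions or n_snps")
        if n_snps >= length:
            raise ValueError("cannot place n_snps >= length informative sites")
        positions = np.sort(rng.choice(length, size=n_snps, replace=False) + 1)
    else:
        positions = np.asarray(sorted(positions))
        if len(positions) and (positions[0] < 1 or positions[-1] > length):
            raise ValueError("site positions outside sequence")
    w = _random_backbone(length, rng, at_rich)
    y = w.copy()
    for p in positions:
        y[p - 1] = _TRANSVERSION[str(w[p - 1])]
    return ParentalCentromerePair(
        name_w=names[0], name_y=names[1],
        seq_w="".join(w), seq_y="".join(y),
    )


def cen3_fixture_pair(functional: bool = True) -> ParentalCentromerePair:
    """Canonical 117-bp CEN3-like parental alignment.

    Honors the published geometry — informative sites at columns 11, 13, 24,
    68, 70, 81 and 101 (so the longest identity tract is the 43 bp between
    24 and 68), CDEI/CDEII/CDEIII spans with an AT-rich CDEII, and the
    functionally critical C at column 106 — while the remaining bases are
    synthetic (the true sequences appear only as a figure).
    """
    pair = gen_centromere_pair(
        CEN3_ALIGNMENT_LENGTH,
        positions=CEN3_SNP_POSITIONS,
        seed=20231106,
        at_rich=(10, 93),
        names=("CEN3_W303", "CEN3_YJM789"),
    )
    w = list(pair.seq_w)
    y = list(pair.seq_y)
    site = "C" if functional else "T"  # cen3-C106T inactivating allele
    w[_FUNCTIONAL_SITE - 1] = site
    y[_FUNCTIONAL_SITE - 1] = site
    return ParentalCentromerePair(
        name_w=pair.name_w, name_y=pair.name_y,
        seq_w="".join(w), seq_y="".join(y),
        functional_state_w=functional, functional_state_y=functional,
        cde_regions=_CEN3_CDE,
    )


def cen3_construct(pair: ParentalCentromerePair | None = None,
                   flank: int = 30, seed: int = 7) -> ConstructMap:
    """Reporter-construct map: intron halves flanking the centromere feature."""
    rng = np.random.default_rng(seed)
    five = "".join(_random_backbone(flank, rng))
    three = "".join(_random_backbone(flank, rng))
    n = (pair or cen3_fixture_pair()).length
    return ConstructMap(five_prime_half=five, three_prime_half=three,
                        cen_interval=(flank + 1, flank + n))


def gen_recombinant(
    pair: ParentalCentromerePair,
    category: str,
    breakpoint_column: int | None = None,
    switch_positions: Sequence[int] | None = None,
    seed: int = 0,
    construct: ConstructMap | None = None,
) -> tuple[str, GroundTruth]:
    """A recombinant sequence realizing the requested category.

    For ``simple``, columns strictly left of ``breakpoint_column`` come from
    the W parent and the rest from Y (chosen uniformly inside the longest
    identity tract if no column is given).  ``patchy`` switches parent at
    each listed column.  ``acentric_RU`` returns the perfect intron-half
    fusion lacking the centromere.
    """
    rng = np.random.default_rng(seed)
    sites = find_informative_sites(pair)
    if category == "parental_W":
        return pair.seq_w, GroundTruth("recombinant", seed,
                                       {"category": category})
    if category == "parental_Y":
        return pair.seq_y, GroundTruth("recombinant", seed,
                                       {"category": category})
    if category == "acentric_RU":
        cm = construct or cen3_construct(pair)
        return cm.ru_fusion(), GroundTruth("recombinant", seed,
                                           {"category": category})
    if category == "simple":
        if breakpoint_column is None:
            # uniform within the inter-site interval of the longest tract
            from .centromere import longest_identity_tract

            tract = longest_identity_tract(sites)
            breakpoint_column = int(rng.integers(tract.start, tract.end + 1))
        if not 1 <= breakpoint_column <= pair.length:
            raise ValueError("breakpoint column outside sequence")
        seq = pair.seq_w[: breakpoint_column - 1] + pair.seq_y[breakpoint_column - 1 :]
        return seq, GroundTruth(
            "recombinant", seed,
            {"category": category, "breakpoint_column": breakpoint_column},
        )
    if category == "patchy":
        if not switch_positions:
            raise ValueError("patchy requires switch_positions")
        sw = sorted(switch_positions)
        if sw[0] < 1 or sw[-1] > pair.length:
            raise ValueError("switch position outside sequence")
        seq_chars = []
        parent = 0  # 0 = W, 1 = Y
        seqs = (pair.seq_w, pair.seq_y)
        j = 0
        for col in range(1, pair.length + 1):
            while j < len(sw) and col == sw[j]:
                parent = 1 - parent
                j += 1
            seq_chars.append(seqs[parent][col - 1])
        return "".join(seq_chars), GroundTruth(
            "recombinant", seed,
            {"category": category, "switch_positions": list(sw)},
        )
    raise ValueError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# fluctuation assays
# ---------------------------------------------------------------------------

def gen_fluctuation_counts(
    rate: float,
    n_final: float,
    n_initial: float = 1.0,
    n_cultures: int = 20,
    seed: int = 0,
    plating_fraction: float = 1.0,
    screen_fraction: float = 1.0,
    experiment_id: str | None = None,
) -> tuple[FluctuationExperiment, GroundTruth]:
    """Simulate Luria-Delbrueck mutant counts for parallel cultures.

    Events per culture ~ Poisson(rate * (n_final - n_initial)); each event
    founds a clone of min(n_final, floor(1/u)) descendants, u ~ Uniform(0,1]
    (deterministic exponential growth); the culture count is the clone-size
    sum, binomially thinned if only a fraction of the culture is plated.
    """
    m = rate * n_final
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate > 0 and not 1e-4 <= m <= 1e4:
        raise ValueError(
            f"rate*n_final = {m:g} outside the supported [1e-4, 1e4] range"
        )
    rng = np.random.default_rng(seed)
    m_true = rate * (n_final - n_initial)
    events = rng.poisson(m_true, size=n_cultures)
    total = int(events.sum())
    if total:
        u = 1.0 - rng.random(total)  # Uniform(0, 1]
        sizes = np.minimum(np.floor(1.0 / u), n_final).astype(np.int64)
        owner = np.repeat(np.arange(n_cultures), events)
        counts = np.bincount(owner, weights=sizes, minlength=n_cultures)
        counts = counts.astype(np.int64)
    else:
        counts = np.zeros(n_cultures, dtype=np.int64)
    if plating_fraction < 1.0:
        counts = rng.binomial(counts, plating_fraction)
    exp = FluctuationExperiment(
        counts=tuple(int(c) for c in counts),
        n_final=n_final,
        n_initial=n_initial,
        plating_fraction=plating_fraction,
        screen_fraction=screen_fraction,
        experiment_id=experiment_id,
    )
    truth = GroundTruth(
        "fluctuation", seed,
        {"rate": rate, "m": m_true, "n_final": n_final, "n_initial": n_initial,
         "events_per_culture": events.tolist()},
    )
    return exp, truth


def gen_colonies(
    loss_rate: float, n_colonies: int, seed: int = 0
) -> tuple[int, int]:
    """Sectored-colony counts: n_sectored ~ Binomial(n_colonies, loss_rate)."""
    if not 0 <= loss_rate <= 1:
        raise ValueError("loss_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_colonies, loss_rate)), int(n_colonies)


# ---------------------------------------------------------------------------
# isolate rosters
# ---------------------------------------------------------------------------

# Subclass composition of the 100-isolate reference roster.
CANONICAL_ROSTER_COMPOSITION: dict[str, int] = {
    "1A": 23, "1B": 2, "1C": 1, "1D": 2, "1E": 1, "1F": 1, "1G": 1,
    "2A": 14, "2B": 5, "2C": 3, "2D": 8, "2E": 5, "2F": 1, "2G": 2, "2H": 1,
    "3A": 1, "3B": 1, "3C": 1,
    "4A": 3, "4B": 5, "4C": 1,
    "5": 18,
}


def gen_roster(
    composition: Mapping[str, int] | None = None, seed: int = 0
) -> tuple[list[IsolateGenotype], GroundTruth]:
    """Instantiate isolates from subclass counts, shuffled by seed."""
    comp = dict(composition or CANONICAL_ROSTER_COMPOSITION)
    for sub, n in comp.items():
        if sub not in SUBCLASS_TABLE:
            raise ValueError(f"unknown subclass label {sub!r}")
        if n < 0:
            raise ValueError("composition counts must be >= 0")
    labels = [sub for sub, n in comp.items() for _ in range(n)]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    isolates = []
    for i, sub in enumerate(labels, start=1):
        haps = tuple(CANONICAL_HAPLOTYPES[let] for let in SUBCLASS_TABLE[sub])
        isolates.append(IsolateGenotype(isolate_id=f"iso{i:03d}", haplotypes=haps))
    truth = GroundTruth(
        "roster", seed,
        {"labels": {iso.isolate_id: sub for iso, sub in zip(isolates, labels)}},
    )
    return isolates, truth


# ---------------------------------------------------------------------------
# SNP coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """A copy-number event: whole chromosome if start/end are None."""

    chrom: str
    copies_w: int
    copies_y: int
    start: int | None = None
    end: int | None = None

    @property
    def whole_chromosome(self) -> bool:
        return self.start is None


@dataclass(frozen=True)
class GenomeModel:
    metadata: GenomeMetadata
    snp_spacing: int = 400

    def snp_positions(self, chrom: str) -> np.ndarray:
        length = self.metadata.chrom_lengths[chrom]
        return np.arange(self.snp_spacing, length + 1, self.snp_spacing)


# Three-chromosome hybrid genome: a 315-kb chromosome-III analog with the
# centromere at 114 kb, plus two size-realistic companions.
DEFAULT_GENOME_MODEL = GenomeModel(
    metadata=GenomeMetadata(
        chrom_lengths={"chrI": 230_000, "chrIII": 315_000, "chrV": 577_000},
        centromeres={"chrI": 151_000, "chrIII": 114_000, "chrV": 152_000},
    ),
    snp_spacing=400,
)


def gen_coverage(
    genome_model: GenomeModel | None = None,
    planted_events: Sequence[PlantedEvent] = (),
    depth: float = 50.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-SNP parent-resolved read depths with planted copy-number events.

    Expected coverage of parent p at a SNP is depth/2 * copies_p; counts are
    negative-binomial with variance = dispersion * mean (dispersion 1 is
    Poisson, 0 is the noiseless infinite-depth limit).  The baseline state is
    one copy per parent.
    """
    gm = genome_model or DEFAULT_GENOME_MODEL
    rng = np.random.default_rng(seed)
    frames = []
    truth_segments: dict[str, list] = {}
    for chrom in gm.metadata.chrom_lengths:
        pos = gm.snp_positions(chrom)
        cw = np.ones(len(pos), dtype=np.int64)
        cy = np.ones(len(pos), dtype=np.int64)
        touched = np.zeros(len(pos), dtype=bool)
        for ev in planted_events:
            if ev.chrom != chrom:
                continue
            if ev.whole_chromosome:
                mask = np.ones(len(pos), dtype=bool)
            else:
                if not (1 <= ev.start <= ev.end <= gm.metadata.chrom_lengths[chrom]):
                    raise ValueError(f"event outside {chrom} bounds: {ev}")
                mask = (pos >= ev.start) & (pos <= ev.end)
            if not ev.whole_chromosome:
                if (mask & touched).any():
                    raise ValueError(f"contradictory overlapping events on {chrom}")
                touched |= mask
            cw[mask] = ev.copies_w
            cy[mask] = ev.copies_y
        mean_w = depth / 2.0 * cw
        mean_y = depth / 2.0 * cy
        cov_w = _nb_draw(mean_w, dispersion, rng)
        cov_y = _nb_draw(mean_y, dispersion, rng)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "cov_w": cov_w, "cov_y": cov_y,
        }))
        truth_segments[chrom] = _truth_runs(pos, cw, cy)
    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        "coverage", seed,
        {"depth": depth, "dispersion": dispersion,
         "segments": truth_segments,
         "events": [dataclasses.asdict(e) for e in planted_events]},
    )
    return table, truth


def _nb_draw(mean: np.ndarray, dispersion: float,
             rng: np.random.Generator) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0.0:
        out[pos] = np.round(mean[pos]).astype(np.int64)
        return out
    if dispersion <= 1.0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = mean[pos] / (dispersion - 1.0)
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _truth_runs(pos: np.ndarray, cw: np.ndarray, cy: np.ndarray) -> list[dict]:
    runs = []
    j = 0
    n = len(pos)
    while j < n:
        k = j
        while k + 1 < n and cw[k + 1] == cw[j] and cy[k + 1] == cy[j]:
            k += 1
        runs.append({
            "start": int(pos[j]), "end": int(pos[k]),
            "start_idx": int(j), "end_idx": int(k),
            "copies_w": int(cw[j]), "copies_y": int(cy[j]),
        })
        j = k + 1
    return runs
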