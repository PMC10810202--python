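"""Normalized sequence coverage (NSC), copy-number calling, LOH segmentation.

In a hybrid diploid, every heterozygous SNP splits its read depth between the
two parental alleles.  The NSC of an allele at a SNP is its read count
divided by the genome-wide mean of summed (both-parent) per-SNP coverage, so
one chromosome copy has expected NSC 0.5 and a balanced disomic site shows
0.5/0.5.  Deviations reveal copy-number structure: gene-conversion tracts and
LOH show one parent at 0 and the other at 1.0 (two copies), monosomy halves
the chromosome-wide total, trisomy raises it to ~1.5.

Copy states are called per SNP by a sliding-median filter on the NSC of each
parent (robust to isolated miscalled sites), rounded to the nearest multiple
of 0.5; maximal runs of non-(1,1) states become tracts, terminal if they
reach a chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GenomeMetadata",
    "LohTract",
    "TractSegment",
    "ConversionTractSummary",
    "CopyNumberCaller",
    "compute_nsc",
    "call_copy_states",
    "segment_tracts",
    "call_aneuploidy",
    "conversion_tract_stats",
]

COVERAGE_COLUMNS = ["chrom", "pos", "cov_w", "cov_y"]


@dataclass(frozen=True)
class GenomeMetadata:
    """Chromosome lengths and centromere midpoints, both in bp."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int]


@dataclass(frozen=True)
class TractSegment:
    start: int
    end: int
    copies_w: int
    copies_y: int


@dataclass(frozen=True)
class LohTract:
    """A maximal run of SNPs whose copy state deviates from balanced (1,1).

    ``start``/``end`` are 1-based inclusive bp snapped to the outermost SNPs
    of the run.  ``segments`` subdivides the run into constant-copy-state
    pieces (a donor switch inside a tract makes it patchy).
    """

    chrom: str
    start: int
    end: int
    kind: str  # "terminal" | "interstitial"
    segments: tuple[TractSegment, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start must be <= end")
        if self.kind not in {"terminal", "interstitial"}:
            raise ValueError(f"unknown tract kind {self.kind!r}")

    @property
    def retained_parent(self) -> str | None:
        """W/Y if the other parent is absent throughout the tract, else None."""
        if all(s.copies_y == 0 and s.copies_w > 0 for s in self.segments):
            return "W"
        if all(s.copies_w == 0 and s.copies_y > 0 for s in self.segments):
            return "Y"
        return None

    @property
    def donors(self) -> tuple[str, ...]:
        out = []
        for s in self.segments:
            if s.copies_y == 0 and s.copies_w > 0:
                out.append("W")
            elif s.copies_w == 0 and s.copies_y > 0:
                out.append("Y")
            else:
                out.append("?")
        return tuple(out)

    @property
    def patchy(self) -> bool:
        return len(set(self.donors)) > 1

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConversionTractSummary:
    lengths_kb: tuple[float, ...]
    median_kb: float | None
    mean_kb: float | None
    min_kb: float | None
    max_kb: float | None
    n_unidirectional: int
    n_patchy: int
    n_total: int


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVERAGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"coverage table missing columns {missing}")
    if len(table) == 0:
        raise ValueError("coverage table is empty")
    if (table["cov_w"] < 0).any() or (table["cov_y"] < 0).any():
        raise ValueError("coverages must be non-negative")
    for chrom, grp in table.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return table


def compute_nsc(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``nsc_w``/``nsc_y`` columns: per-allele coverage over the genome mean.

    The normalizer is the mean over all SNP records of (cov_w + cov_y), so a
    site present in one copy per parent has expected NSC 0.5 for each allele
    and the genome-wide mean of (nsc_w + nsc_y) is exactly 1.
    """
    table = _validate_table(table)
    denom = float((table["cov_w"] + table["cov_y"]).mean())
    if denom == 0:
        raise ValueError("zero total coverage: NSC undefined")
    out = table.copy()
    out["nsc_w"] = table["cov_w"] / denom
    out["nsc_y"] = table["cov_y"] / denom
    out.attrs["genome_mean_total"] = denom
    return out


def _rolling_median(x: np.ndarray, k: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window=k, center=True, min_periods=1).median().to_numpy()


def call_copy_states(nsc: pd.DataFrame, window_k: int = 11,
                     refine: bool = True) -> pd.DataFrame:
    """Per-SNP integer copy numbers from sliding-median-smoothed NSC.

    The median over ``window_k`` SNPs (shrunk at chromosome edges) is divided
    by the 0.5-per-copy expectation and rounded, placing decision boundaries
    at NSC 0.25, 0.75, 1.25, ...; calls are clipped to 0-4 copies.

    Because the two parental medians cross their thresholds independently,
    a real copy-number step can leave a 1-2 SNP transitional run in a
    half-switched state at its edges.  With ``refine`` (default), interior
    runs shorter than 3 SNPs are re-assigned by a local least-squares
    changepoint fit of the raw NSC against the flanking states, which pins
    the step to the SNP where the raw signal actually changes.
    """
    if window_k < 1 or window_k % 2 == 0:
        raise ValueError("window_k must be a positive odd integer")
    if "nsc_w" not in nsc.columns:
        raise ValueError("run compute_nsc first (missing nsc_w/nsc_y)")
    out = nsc.copy()
    cw = np.empty(len(nsc), dtype=np.int64)
    cy = np.empty(len(nsc), dtype=np.int64)
    for _, idx in nsc.groupby("chrom", sort=False).indices.items():
        for col, dest in (("nsc_w", cw), ("nsc_y", cy)):
            med = _rolling_median(nsc[col].to_numpy()[idx], window_k)
            dest[idx] = np.clip(np.round(med / 0.5), 0, 4).astype(np.int64)
        if refine:
            _resolve_transitional_runs(
                cw, cy,
                nsc["nsc_w"].to_numpy(), nsc["nsc_y"].to_numpy(), idx,
                max_len=window_k // 2,
            )
    out["copies_w"] = cw
    out["copies_y"] = cy
    return out


def _joint_runs(cw: np.ndarray, cy: np.ndarray) -> list[tuple[int, int]]:
    change = np.flatnonzero((np.diff(cw) != 0) | (np.diff(cy) != 0))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(cw) - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _is_transitional(state, left, right) -> bool:
    """True if every parent's copy number lies between the flanking values
    and the flanks actually differ (a step-edge artifact, not an event)."""
    if left == right:
        return False
    return all(
        min(l, r) <= s <= max(l, r) for s, l, r in zip(state, left, right)
    )


def _resolve_transitional_runs(cw, cy, nw, ny, idx, max_len: int) -> None:
    """Re-assign interior transitional runs of <= ``max_len`` SNPs.

    A run whose state interpolates between two differing flanks is a
    smoothing artifact of the independent per-parent medians at a copy-number
    step; runs at or below half the median window cannot be resolved by the
    filter itself.  Each such run is split at the changepoint minimizing the
    squared error of the raw per-parent NSC against the flanking copy
    expectations (0.5 per copy).  Mutates the state arrays in place;
    terminates because every pass strictly reduces the number of runs.
    Genuine short events between identical flanks are never touched.
    """
    lw, ly = cw[idx], cy[idx]
    rw, ry = nw[idx], ny[idx]
    for _ in range(len(lw)):
        runs = _joint_runs(lw, ly)
        short = next(
            (k for k in range(1, len(runs) - 1)
             if runs[k][1] - runs[k][0] + 1 <= max_len
             and _is_transitional(
                 (lw[runs[k][0]], ly[runs[k][0]]),
                 (lw[runs[k - 1][0]], ly[runs[k - 1][0]]),
                 (lw[runs[k + 1][0]], ly[runs[k + 1][0]]),
             )),
            None,
        )
        if short is None:
            break
        i0, i1 = runs[short]
        la, lb = runs[short - 1][0], runs[short + 1][1]
        lvl_l = (0.5 * lw[la], 0.5 * ly[la])
        lvl_r = (0.5 * lw[lb], 0.5 * ly[lb])
        # cost of putting the changepoint before position c within the run
        best_c, best_cost = i0, np.inf
        for c in range(i0, i1 + 2):
            cost = float(
                ((rw[i0:c] - lvl_l[0]) ** 2).sum()
                + ((ry[i0:c] - lvl_l[1]) ** 2).sum()
                + ((rw[c : i1 + 1] - lvl_r[0]) ** 2).sum()
                + ((ry[c : i1 + 1] - lvl_r[1]) ** 2).sum()
            )
            if cost < best_cost:
                best_c, best_cost = c, cost
        lw[i0:best_c], ly[i0:best_c] = lw[la], ly[la]
        lw[best_c : i1 + 1], ly[best_c : i1 + 1] = lw[lb], ly[lb]
    cw[idx], cy[idx] = lw, ly


def segment_tracts(
    states: pd.DataFrame, metadata: GenomeMetadata | None = None,
    min_snps: int = 2,
) -> list[LohTract]:
    """Maximal runs of non-(1,1) copy states, split into constant segments.

    A run is terminal if it includes the first or last SNP of its chromosome;
    boundaries are reported at the outermost SNPs of the run.  Runs shorter
    than ``min_snps`` SNPs (default 2) are discarded: a single deviant
    smoothed SNP is below the resolution of the windowed-median caller and is
    overwhelmingly read noise.
    """
    if "copies_w" not in states.columns:
        raise ValueError("run call_copy_states first")
    tracts: list[LohTract] = []
    for chrom, grp in states.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        cw = grp["copies_w"].to_numpy()
        cy = grp["copies_y"].to_numpy()
        deviant = (cw != 1) | (cy != 1)
        if not deviant.any():
            continue
        # run starts/ends over the deviant mask
        d = np.diff(deviant.astype(np.int8))
        starts = list(np.where(d == 1)[0] + 1)
        ends = list(np.where(d == -1)[0])
        if deviant[0]:
            starts.insert(0, 0)
        if deviant[-1]:
            ends.append(len(deviant) - 1)
        for i0, i1 in zip(starts, ends):
            if i1 - i0 + 1 < min_snps:
                continue
            kind = "terminal" if (i0 == 0 or i1 == len(deviant) - 1) else "interstitial"
            segs: list[TractSegment] = []
            j = i0
            while j <= i1:
                k = j
                while k + 1 <= i1 and cw[k + 1] == cw[j] and cy[k + 1] == cy[j]:
                    k += 1
                segs.append(
                    TractSegment(int(pos[j]), int(pos[k]), int(cw[j]), int(cy[j]))
                )
                j = k + 1
            tracts.append(
                LohTract(
                    chrom=str(chrom),
                    start=int(pos[i0]),
                    end=int(pos[i1]),
                    kind=kind,
                    segments=tuple(segs),
                )
            )
    return tracts


def call_aneuploidy(nsc: pd.DataFrame) -> dict[str, str]:
    """Whole-chromosome ploidy from the mean total NSC per chromosome.

    Mean (nsc_w + nsc_y) < 0.75 -> monosomic; 0.75-1.25 -> disomic;
    1.25-1.75 -> trisomic; anything higher -> other.
    """
    if "nsc_w" not in nsc.columns:
        raise ValueError("run compute_nsc first")
    calls: dict[str, str] = {}
    total = nsc["nsc_w"] + nsc["nsc_y"]
    for chrom, grp in total.groupby(nsc["chrom"], sort=False):
        mu = float(grp.mean())
        if mu < 0.75:
            calls[str(chrom)] = "monosomic"
        elif mu <= 1.25:
            calls[str(chrom)] = "disomic"
        elif mu <= 1.75:
            calls[str(chrom)] = "trisomic"
        else:
            calls[str(chrom)] = "other"
    return calls


def conversion_tract_stats(
    tracts: Sequence[LohTract],
    centromere_pos: int,
    chrom: str | None = None,
) -> ConversionTractSummary:
    """Order statistics and orientation flags for conversion tracts at a centromere.

    Lengths are the bp span between the outermost converted SNPs, in kb.  A
    tract is unidirectional if it lies entirely on one side of the centromere
    midpoint, and patchy if the donor parent switches within it.
    """
    if chrom is not None:
        tracts = [t for t in tracts if t.chrom == chrom]
    if not tracts:
        return ConversionTractSummary((), None, None, None, None, 0, 0, 0)
    lengths = tuple(t.span_bp / 1000.0 for t in tracts)
    uni = sum(t.end < centromere_pos or t.start > centromere_pos for t in tracts)
    patchy = sum(t.patchy for t in tracts)
    arr = np.asarray(lengths)
    return ConversionTractSummary(
        lengths_kb=lengths,
        median_kb=float(np.median(arr)),
        mean_kb=float(arr.mean()),
        min_kb=float(arr.min()),
        max_kb=float(arr.max()),
        n_unidirectional=int(uni),
        n_patchy=int(patchy),
        n_total=len(tracts),
    )


class CopyNumberCaller(BaseEstimator, TransformerMixin):
    """NSC normalization plus windowed-median copy-state calling.

    Parameters
    ----------
    window_k : odd sliding-median window in SNPs (default 11).

    ``fit`` learns the genome-wide normalizer from a coverage table
    (chrom, pos, cov_w, cov_y); ``transform`` returns the table augmented
    with nsc and integer copy-state columns.  Convenience methods expose
    tract segmentation and aneuploidy calls on the transformed frame.
    """

    def __init__(self, window_k: int = 11):
        self.window_k = window_k

    def fit(self, X: pd.DataFrame, y=None) -> "CopyNumberCaller":
        _validate_table(X)
        self.genome_mean_total_ = float((X["cov_w"] + X["cov_y"]).mean())
        if self.genome_mean_total_ == 0:
            raise ValueError("zero total coverage: NSC undefined")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "genome_mean_total_"):
            raise RuntimeError("caller is not fitted")
        out = _validate_table(X).copy()
        out["nsc_w"] = out["cov_w"] / self.genome_mean_total_
        out["nsc_y"] = out["cov_y"] / self.genome_mean_total_
        out.attrs["genome_mean_total"] = self.genome_mean_total_
        return call_copy_states(out, self.window_k)

    def tracts(self, X: pd.DataFrame, metadata: GenomeMetadata | None = None
               ) -> list[LohTract]:
        return segment_tracts(self.transform(X), metadata)

    def aneuploidy(self, X: pd.DataFrame) -> dict[str, str]:
        return call_aneuploidy(self.transform(X))
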