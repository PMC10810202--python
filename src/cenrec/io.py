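"""Format round-tripping: FASTA, TSV, BED, JSON manifests.

All tabular interchange is TSV with a header row; tracts can additionally be
exported as BED, which is the only place the package converts from 1-based
inclusive to 0-based half-open coordinates.  Output ordering is deterministic
(sorted by isolate_id / chrom+pos) so diffs are meaningful.  Invalid rows are
rejected with their line number, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .centromere import RecombinantCentromereCall
from .coverage import COVERAGE_COLUMNS, LohTract
from .fluctuation import FluctuationExperiment, RateEstimate
from .isolates import ClassificationResult, HaplotypeIII, IsolateGenotype

__all__ = [
    "SchemaError",
    "read_fasta",
    "write_fasta",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_rates_tsv",
    "read_roster_tsv",
    "write_roster_tsv",
    "write_classification_tsv",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "write_breakpoint_calls_tsv",
    "write_tracts_bed",
    "write_tracts_tsv",
    "write_aneuploidy_tsv",
    "RunManifest",
]


class SchemaError(ValueError):
    """A file violated its declared schema; message carries the location."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Ordered name -> sequence mapping (aligned sequences keep their gaps)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SchemaError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise SchemaError(f"{path}: no FASTA records found")
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # malformed file
        raise SchemaError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _to_int(df: pd.DataFrame, col: str, path, minimum: int | None = None) -> pd.Series:
    try:
        vals = df[col].astype(float)
        ints = vals.astype(int)
        if (vals != ints).any():
            bad = int((vals != ints).idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path}:{bad}: column {col} must be integer")
    except SchemaError:
        raise
    except Exception:
        bad = df[col].map(lambda v: not str(v).lstrip("-").replace(".", "", 1).isdigit())
        line = int(bad.idxmax()) + 2 if bad.any() else "?"
        raise SchemaError(f"{path}:{line}: column {col} is not numeric")
    if minimum is not None and (ints < minimum).any():
        line = int((ints < minimum).idxmax()) + 2
        raise SchemaError(f"{path}:{line}: column {col} must be >= {minimum}")
    return ints


# ---------------------------------------------------------------------------
# fluctuation counts and rates
# ---------------------------------------------------------------------------

_COUNTS_COLS = ["experiment_id", "culture_id", "mutant_count", "n_final", "n_initial"]


def read_counts_tsv(path) -> list[FluctuationExperiment]:
    df = _read_tsv(path, _COUNTS_COLS)
    df["mutant_count"] = _to_int(df, "mutant_count", path, minimum=0)
    df["n_final"] = df["n_final"].astype(float)
    df["n_initial"] = df["n_initial"].astype(float)
    pf = df["plating_fraction"].astype(float) if "plating_fraction" in df else None
    sf = df["screen_fraction"].astype(float) if "screen_fraction" in df else None
    exps = []
    for eid, grp in df.groupby("experiment_id", sort=True):
        nf = grp["n_final"].unique()
        n0 = grp["n_initial"].unique()
        if len(nf) > 1 or len(n0) > 1:
            raise SchemaError(
                f"{path}: experiment {eid!r} mixes culture sizes"
            )
        exps.append(FluctuationExperiment(
            counts=tuple(int(c) for c in grp["mutant_count"]),
            n_final=float(nf[0]),
            n_initial=float(n0[0]),
            plating_fraction=float(pf[grp.index[0]]) if pf is not None else 1.0,
            screen_fraction=float(sf[grp.index[0]]) if sf is not None else 1.0,
            experiment_id=str(eid),
        ))
    return exps


def write_counts_tsv(path, experiments: Iterable[FluctuationExperiment]) -> None:
    rows = []
    for exp in experiments:
        eid = exp.experiment_id or "exp1"
        for i, c in enumerate(exp.counts, start=1):
            rows.append({
                "experiment_id": eid, "culture_id": f"c{i:03d}",
                "mutant_count": c, "n_final": exp.n_final,
                "n_initial": exp.n_initial,
                "plating_fraction": exp.plating_fraction,
                "screen_fraction": exp.screen_fraction,
            })
    pd.DataFrame(rows).sort_values(["experiment_id", "culture_id"]).to_csv(
        path, sep="\t", index=False)


def write_rates_tsv(path, estimates: dict[str, RateEstimate]) -> None:
    rows = [
        {"experiment_id": eid, "rate": est.rate, "ci_low": est.ci_low,
         "ci_high": est.ci_high, "m_hat": est.m_hat,
         "n_cultures": est.n_cultures}
        for eid, est in sorted(estimates.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rosters and classifications
# ---------------------------------------------------------------------------

_ROSTER_COLS = ["isolate_id", "hap_index", "left_distal", "cen_state",
                "right_distal", "proximal_tag"]


def read_roster_tsv(path) -> list[IsolateGenotype]:
    df = _read_tsv(path, _ROSTER_COLS)
    df["hap_index"] = _to_int(df, "hap_index", path, minimum=1)
    df["proximal_tag"] = df["proximal_tag"].fillna("")
    isolates = []
    for iid, grp in df.groupby("isolate_id", sort=True):
        grp = grp.sort_values("hap_index")
        try:
            haps = tuple(
                HaplotypeIII(r.left_distal, r.cen_state, r.right_distal,
                             r.proximal_tag)
                for r in grp.itertuples()
            )
            isolates.append(IsolateGenotype(str(iid), haps))
        except ValueError as exc:
            line = int(grp.index[0]) + 2
            raise SchemaError(f"{path}:{line}: isolate {iid!r}: {exc}") from exc
    return isolates


def write_roster_tsv(path, isolates: Iterable[IsolateGenotype]) -> None:
    rows = []
    for iso in isolates:
        for i, h in enumerate(iso.haplotypes, start=1):
            rows.append({
                "isolate_id": iso.isolate_id, "hap_index": i,
                "left_distal": h.left_distal, "cen_state": h.cen_state,
                "right_distal": h.right_distal, "proximal_tag": h.proximal_tag,
            })
    pd.DataFrame(rows).sort_values(["isolate_id", "hap_index"]).to_csv(
        path, sep="\t", index=False)


def write_classification_tsv(
    path, results: Iterable[ClassificationResult],
    mechanisms: dict[str, frozenset[str]] | None = None,
) -> None:
    rows = []
    for r in results:
        rows.append({
            "isolate_id": r.isolate_id,
            "class": r.cls,
            "subclass": r.subclass or "",
            "co_status": r.co_status.value,
            "ploidy": r.ploidy.value,
            "pcr_products": ",".join(sorted(r.pcr_products)),
            "mechanisms": ",".join(sorted(mechanisms.get(r.isolate_id, ())))
            if mechanisms else "",
        })
    pd.DataFrame(rows).sort_values("isolate_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage, tracts, aneuploidy
# ---------------------------------------------------------------------------

def read_coverage_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, COVERAGE_COLUMNS)
    df["pos"] = _to_int(df, "pos", path, minimum=1)
    df["cov_w"] = _to_int(df, "cov_w", path, minimum=0)
    df["cov_y"] = _to_int(df, "cov_y", path, minimum=0)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        dup = grp["pos"].duplicated()
        if dup.any():
            line = int(grp.index[dup.idxmax()]) + 2
            raise SchemaError(f"{path}:{line}: duplicate position on {chrom}")
    return df[COVERAGE_COLUMNS]


def write_coverage_tsv(path, table: pd.DataFrame) -> None:
    table.sort_values(["chrom", "pos"]).to_csv(path, sep="\t", index=False)


def write_breakpoint_calls_tsv(
    path, calls: Iterable[RecombinantCentromereCall]
) -> None:
    rows = []
    for i, c in enumerate(calls):
        left, right = c.breakpoint if c.breakpoint else ("", "")
        rows.append({
            "isolate_id": c.isolate_id or f"seq{i + 1:03d}",
            "category": c.category.value,
            "left_snp": left, "right_snp": right,
            "n_switches": c.n_switches,
            "bin": f"{left}-{right}" if c.breakpoint else "",
        })
    pd.DataFrame(rows).sort_values("isolate_id").to_csv(path, sep="\t", index=False)


def write_tracts_bed(path, tracts: Iterable[LohTract]) -> None:
    """BED export (0-based half-open, the package's only coordinate shift)."""
    lines = []
    for t in sorted(tracts, key=lambda t: (t.chrom, t.start)):
        name = f"{t.kind};donor={'/'.join(t.donors)}"
        lines.append(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tracts_tsv(path, tracts: Iterable[LohTract]) -> None:
    rows = [
        {"chrom": t.chrom, "start": t.start, "end": t.end, "kind": t.kind,
         "span_bp": t.span_bp, "retained_parent": t.retained_parent or "",
         "patchy": t.patchy, "n_segments": len(t.segments)}
        for t in sorted(tracts, key=lambda t: (t.chrom, t.start))
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "span_bp",
                                "retained_parent", "patchy", "n_segments"]
                 ).to_csv(path, sep="\t", index=False)


def write_aneuploidy_tsv(path, calls: dict[str, str]) -> None:
    pd.DataFrame(
        [{"chrom": c, "call": v} for c, v in sorted(calls.items())]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to regenerate its outputs."""

    subcommand: str
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    config: dict
    tool_version: str = __version__
    timestamp: str = ""
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        blob = json.dumps(self.config, sort_keys=True, default=str)
        self.config_hash = hashlib.sha256(blob.encode()).hexdigest()[:16]
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
        return self

    def write(self, path) -> None:
        self.finalize()
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"
        )
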