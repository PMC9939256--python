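"""Amplicon read processing: demultiplex, trim, assign, count.

Turns (simulated or real) amplicon FASTQ into construct x sample count
tables.  Reads are routed to samples by their dual (i5, i7) index pair,
adapter-trimmed by bounded-Hamming prefix match, and assigned to the unique
reference amplicon with minimal Hamming distance within a mismatch budget.
Ties and over-budget reads fall into an explicit ``unassigned`` row so read
conservation is auditable.

Quality scores are ignored for assignment: bounded Hamming matching on short,
highly distinct amplicons is robust and keeps the behavior exactly checkable
against an exhaustive-distance oracle.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .util import hamming

DEFAULT_MAX_MISMATCH = 2  # reference assignment budget
DEFAULT_MAX_BC_MISMATCH = 1  # per-index barcode budget

UNASSIGNED = "unassigned"
UNDETERMINED = "undetermined"

SAMPLESHEET_COLUMNS = [
    "sample_id", "i5", "i7", "donor", "replicate", "subset",
    "assay", "timepoint", "bin_id", "cells_sorted",
]


class ConfigurationError(ValueError):
    """Raised for invalid reference sets or colliding sample sheets."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """Construct name -> distinguishing amplicon (all the same length)."""

    sequences: dict
    adapter: str = ""
    max_mismatch: int = DEFAULT_MAX_MISMATCH

    def __post_init__(self):
        if not self.sequences:
            raise ConfigurationError("ReferenceSet requires at least one sequence")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ConfigurationError(f"reference sequences have mixed lengths {sorted(lengths)}")
        (self.length,) = lengths
        names = list(self.sequences)
        if len(set(names)) != len(names):
            raise ConfigurationError("reference names must be unique")
        min_required = 2 * self.max_mismatch + 1
        pairs_too_close = [
            (a, b)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if hamming(self.sequences[a], self.sequences[b]) < min_required
        ]
        if pairs_too_close:
            warnings.warn(
                f"{len(pairs_too_close)} reference pair(s) closer than "
                f"{min_required} mismatches; assignment may be ambiguous "
                f"(first: {pairs_too_close[0]})",
                stacklevel=2,
            )
        self.names = names
        self._matrix = np.frombuffer(
            "".join(self.sequences[n] for n in names).encode(), dtype=np.uint8
        ).reshape(len(names), self.length)

    @classmethod
    def from_fasta(cls, path, adapter: str = "", **kw) -> "ReferenceSet":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=seqs, adapter=adapter, **kw)

    def to_fasta(self, handle) -> None:
        for name, seq in self.sequences.items():
            handle.write(f">{name}\n{seq}\n")


@dataclass
class SampleSheet:
    """Sample metadata table with dual-index barcodes.

    Columns: sample_id, i5, i7, donor, replicate, subset, assay, timepoint,
    bin_id, cells_sorted.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SAMPLESHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"sample sheet missing columns {missing}")
        pairs = list(zip(self.table["i5"], self.table["i7"]))
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("barcode (i5, i7) pairs must be unique")
        ids = list(self.table["sample_id"])
        if len(set(ids)) != len(ids):
            raise ConfigurationError("sample ids must be unique")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def barcodes(self) -> dict:
        return {
            r.sample_id: (r.i5, r.i7) for r in self.table.itertuples(index=False)
        }

    def validate_barcode_separation(self, max_bc_mismatch: int) -> None:
        """Two samples within the mismatch radius of each other is a setup bug."""
        rows = list(self.table.itertuples(index=False))
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                if (
                    hamming(a.i5, b.i5) <= 2 * max_bc_mismatch
                    and hamming(a.i7, b.i7) <= 2 * max_bc_mismatch
                ):
                    raise ConfigurationError(
                        f"samples {a.sample_id} and {b.sample_id} are within "
                        f"barcode mismatch radius {max_bc_mismatch}"
                    )

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"i5": str, "i7": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CountTable:
    """Construct x sample nonnegative integer read counts + unassigned row."""

    counts: pd.DataFrame
    samplesheet: SampleSheet | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    def column(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]

    def assigned(self) -> pd.DataFrame:
        return self.counts.drop(index=UNASSIGNED, errors="ignore")

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "construct", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("construct")
        return cls(counts=df)


# --------------------------------------------------------------------------
# Read-level operations
# --------------------------------------------------------------------------


def parse_fastq(path):
    """Yield (read_id, index_field, sequence) from a FASTQ(.gz) file.

    The (i5, i7) pair is taken from the standard Illumina header index field
    ``... 1:N:0:I5+I7``; reads without one get ``None``.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            head = header[1:].strip()
            index = None
            if " " in head:
                read_id, desc = head.split(" ", 1)
                fields = desc.split(":")
                if len(fields) == 4 and "+" in fields[3]:
                    index = tuple(fields[3].split("+", 1))
            else:
                read_id = head
            yield read_id, index, seq


def demultiplex(reads, samplesheet: SampleSheet, max_bc_mismatch: int = DEFAULT_MAX_BC_MISMATCH):
    """Route reads to samples by dual-index barcode within a mismatch budget.

    ``reads`` yields (read_id, (i5, i7) | None, sequence).  A read goes to the
    unique sample with both indices within ``max_bc_mismatch``; unmatched or
    ambiguous (equidistant-eligible) reads go to the ``undetermined`` stream.
    """
    samplesheet.validate_barcode_separation(max_bc_mismatch)
    bc = samplesheet.barcodes()
    streams = {sid: [] for sid in samplesheet.sample_ids}
    streams[UNDETERMINED] = []
    for read_id, index, seq in reads:
        target = UNDETERMINED
        if index is not None:
            i5, i7 = index
            matches = [
                sid
                for sid, (b5, b7) in bc.items()
                if len(b5) == len(i5)
                and len(b7) == len(i7)
                and hamming(i5, b5) <= max_bc_mismatch
                and hamming(i7, b7) <= max_bc_mismatch
            ]
            if len(matches) == 1:
                target = matches[0]
        streams[target].append((read_id, seq))
    return streams


def trim_adapter(read: str, adapter: str, max_mismatch: int = DEFAULT_MAX_MISMATCH):
    """Strip a bounded-Hamming adapter prefix; (payload, None) or (None, reason)."""
    if len(adapter) > len(read):
        return None, "read shorter than adapter"
    mismatches = hamming(read[: len(adapter)], adapter)
    if mismatches > max_mismatch:
        return None, f"adapter prefix has {mismatches} mismatches (> {max_mismatch})"
    return read[len(adapter) :], None


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def assign_read(read: str, refs: ReferenceSet, max_mismatch: int = DEFAULT_MAX_MISMATCH,
                both_strands: bool = False):
    """Assign a read to the unique minimal-Hamming reference within budget.

    Reads shorter than the reference length are unassigned; longer reads are
    compared on their first L bases.  Distance ties and over-budget minima
    return None.
    """
    candidates = [read]
    if both_strands:
        candidates.append(_revcomp(read))
    best_name, best_d = None, None
    for cand in candidates:
        if len(cand) < refs.length:
            continue
        arr = np.frombuffer(cand[: refs.length].encode(), dtype=np.uint8)
        dists = (refs._matrix != arr).sum(axis=1)
        order = np.argsort(dists, kind="stable")
        d0 = int(dists[order[0]])
        tie = len(dists) > 1 and int(dists[order[1]]) == d0
        if d0 <= max_mismatch and not tie:
            if best_d is None or d0 < best_d:
                best_name, best_d = refs.names[order[0]], d0
            elif d0 == best_d and refs.names[order[0]] != best_name:
                return None  # strand-ambiguous
    return best_name if best_d is not None else None


def build_count_table(
    assignments: dict,
    samplesheet: SampleSheet,
    dedup: bool = False,
) -> CountTable:
    """Aggregate per-sample assignments into a CountTable.

    ``assignments`` maps sample id -> iterable of (construct | None, read
    sequence).  With ``dedup`` set, identical full-length read sequences
    within a sample count once (no UMIs are modeled; this is exact-sequence
    deduplication and is off by default).
    """
    known = set(samplesheet.sample_ids)
    for sid in assignments:
        if sid not in known and sid != UNDETERMINED:
            raise KeyError(f"sample {sid!r} absent from sample sheet")
    constructs: list = []
    seen = set()
    for recs in assignments.values():
        for name, _ in recs:
            if name is not None and name not in seen:
                seen.add(name)
                constructs.append(name)
    constructs = sorted(constructs)
    index = constructs + [UNASSIGNED]
    table = pd.DataFrame(0, index=index, columns=samplesheet.sample_ids, dtype=np.int64)
    for sid in samplesheet.sample_ids:
        recs = list(assignments.get(sid, []))
        if dedup:
            uniq = {}
            for name, seq in recs:
                uniq.setdefault(seq, name)
            recs = [(name, seq) for seq, name in uniq.items()]
        for name, _ in recs:
            table.loc[name if name is not None else UNASSIGNED, sid] += 1
    table.index.name = "construct"
    return CountTable(counts=table, samplesheet=samplesheet)


def count_fastq(
    fastq_paths,
    refs: ReferenceSet,
    samplesheet: SampleSheet,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_bc_mismatch: int = DEFAULT_MAX_BC_MISMATCH,
    dedup: bool = False,
    both_strands: bool = False,
) -> CountTable:
    """FASTQ -> CountTable: demultiplex, trim, assign, count, with a run report."""
    if isinstance(fastq_paths, (str, bytes)) or hasattr(fastq_paths, "__fspath__"):
        fastq_paths = [fastq_paths]

    def _reads():
        for p in fastq_paths:
            yield from parse_fastq(p)

    streams = demultiplex(_reads(), samplesheet, max_bc_mismatch)
    assignments: dict = {}
    report = {"samples": {}, "undetermined": len(streams[UNDETERMINED])}
    total_in = len(streams[UNDETERMINED])
    for sid in samplesheet.sample_ids:
        recs = []
        n_trim_rejected = 0
        for _, seq in streams[sid]:
            payload = seq
            if refs.adapter:
                payload, reason = trim_adapter(seq, refs.adapter, max_mismatch)
                if payload is None:
                    n_trim_rejected += 1
                    recs.append((None, seq))
                    continue
            recs.append((assign_read(payload, refs, max_mismatch, both_strands), seq))
        assignments[sid] = recs
        n_assigned = sum(1 for name, _ in recs if name is not None)
        report["samples"][sid] = {
            "reads_in": len(streams[sid]),
            "assigned": n_assigned,
            "unassigned": len(recs) - n_assigned,
            "adapter_rejected": n_trim_rejected,
        }
        total_in += len(streams[sid])
    report["reads_in_total"] = total_in
    ct = build_count_table(assignments, samplesheet, dedup=dedup)
    ct.report = report
    return ct


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1)
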