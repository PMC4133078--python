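"""Assignment of reads to samples and barcode trimming.

Each read is scored at both ends: the minimal SL distance of the
reference set to the read start (5') and to the start of its reverse
complement (3').  The global minimum over both ends decides the call:

* ASSIGNED — a unique sample attains the minimum and it is within the
  threshold; the matched end(s) are recorded and can be trimmed;
* AMBIGUOUS — two or more different samples tie at the minimum (e.g.
  different barcodes at the 5' and 3' ends);
* UNASSIGNED — the minimum exceeds the threshold.

Trimming removes the read prefix (or suffix, for a 3' match) whose
removal corresponds to the endpoint of the minimal SL alignment, so a
corrupted barcode of unequal length is removed cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqlev
from .barcode_design import BarcodeSet
from .fdr import sample_keys
from .read_sim import ReadSet

ASSIGNED = "ASSIGNED"
AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

FIVE_PRIME = "5prime"
THREE_PRIME = "3prime"
BOTH = "both"


def trim_extent(ref: str, window: str) -> int:
    """Length of the window prefix matched by the minimal SL alignment.

    Among all alignment endpoints achieving the SL minimum, the longest
    consumed window prefix is returned (trimming greedily removes the
    whole corrupted barcode region).
    """
    a = seqlev.encode(seqlev.normalize(window))
    b = seqlev.encode(seqlev.normalize(ref))
    la, lb = len(a), len(b)
    dp = np.zeros((la + 1, lb + 1), dtype=np.int32)
    dp[:, 0] = np.arange(la + 1)
    dp[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            dp[i, j] = min(dp[i - 1, j - 1] + cost, dp[i - 1, j] + 1,
                           dp[i, j - 1] + 1)
    best = min(int(dp[:, lb].min()), int(dp[la, :].min()))
    col = dp[:, lb]
    if int(col.min()) == best:
        return int(np.flatnonzero(col == best).max())
    return la  # read shorter than reference: whole window consumed


@dataclass
class Assignment:
    read_id: str
    status: str
    sample: str | None
    end: str | None
    delta: int


@dataclass
class DemuxResult:
    assignments: pd.DataFrame
    summary: dict

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)

    def summary_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2)


def _per_sample_min(dmat: np.ndarray, key_idx: np.ndarray,
                    n_samples: int) -> np.ndarray:
    out = np.full((dmat.shape[0], n_samples), np.iinfo(np.int32).max,
                  dtype=np.int32)
    for j, k in enumerate(key_idx):
        np.minimum(out[:, k], dmat[:, j], out=out[:, k])
    return out


def assign_reads(reads: ReadSet | list[str], ref: BarcodeSet,
                 threshold: int) -> list[Assignment]:
    """Vectorized per-read assignment over both ends."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    ids = (reads.ids if isinstance(reads, ReadSet)
           else [f"read{i:06d}" for i in range(len(seqs))])
    if any(len(s) < 1 for s in seqs):
        raise ValueError("reads must be at least 1 nt long")
    keys = sample_keys(ref)
    uniq = sorted(set(keys))
    key_idx = np.array([uniq.index(k) for k in keys])
    rc = [seqlev.reverse_complement(s) for s in seqs]
    d5 = _per_sample_min(seqlev.distance_matrix(seqs, ref.barcodes),
                         key_idx, len(uniq))
    d3 = _per_sample_min(seqlev.distance_matrix(rc, ref.barcodes),
                         key_idx, len(uniq))
    out = []
    for i, rid in enumerate(ids):
        m5, m3 = int(d5[i].min()), int(d3[i].min())
        delta = min(m5, m3)
        samples = set()
        if m5 == delta:
            samples.update(np.flatnonzero(d5[i] == delta).tolist())
        if m3 == delta:
            samples.update(np.flatnonzero(d3[i] == delta).tolist())
        if delta > threshold:
            out.append(Assignment(rid, UNASSIGNED, None, None, delta))
        elif len(samples) > 1:
            out.append(Assignment(rid, AMBIGUOUS, None, None, delta))
        else:
            end = BOTH if (m5 == delta and m3 == delta) else (
                FIVE_PRIME if m5 == delta else THREE_PRIME)
            out.append(Assignment(rid, ASSIGNED, uniq[samples.pop()], end,
                                  delta))
    return out


def assign_read(seq: str, ref: BarcodeSet, threshold: int,
                read_id: str = "read") -> Assignment:
    """Assign a single read (see :func:`assign_reads`)."""
    return assign_reads(ReadSet([seq], ids=[read_id]), ref, threshold)[0]


def _trim(seq: str, assignment: Assignment, ref: BarcodeSet) -> str:
    """Strip the matched barcode region from the assigned end(s)."""
    keys = sample_keys(ref)
    member_refs = [b for b, k in zip(ref.barcodes, keys)
                   if k == assignment.sample]
    window = 2 * ref.length

    def best_extent(s: str) -> int:
        w = s[:window]
        extents = []
        for r in member_refs:
            d = seqlev.sl_distance(r, w)
            extents.append((d, trim_extent(r, w)))
        dmin = min(e[0] for e in extents)
        return max(e[1] for e in extents if e[0] == dmin)

    if assignment.end in (FIVE_PRIME, BOTH):
        seq = seq[best_extent(seq):]
    if assignment.end in (THREE_PRIME, BOTH):
        rc = seqlev.reverse_complement(seq)
        rc = rc[best_extent(rc):]
        seq = seqlev.reverse_complement(rc)
    return seq


def demultiplex(reads: ReadSet, ref: BarcodeSet, threshold: int,
                out_dir=None, trim: bool = True) -> DemuxResult:
    """Assign every read, optionally writing trimmed per-sample FASTQ.

    Returns the per-read assignment table and a summary with status
    counts and fractions, per-sample tallies, and per-status read
    length medians.
    """
    keys = sample_keys(ref)
    if len(set(ref.names)) != len(ref.names):
        raise ValueError("duplicate reference names in barcode set")
    assignments = assign_reads(reads, ref, threshold)
    rows = [
        {"read_id": a.read_id, "status": a.status,
         "sample": a.sample or "", "end": a.end or "", "delta": a.delta}
        for a in assignments
    ]
    df = pd.DataFrame(rows, columns=["read_id", "status", "sample", "end",
                                     "delta"])
    lengths = np.array([len(s) for s in reads.sequences])
    status_arr = df["status"].to_numpy()
    summary = {
        "total_reads": len(reads),
        "threshold": threshold,
        "status_counts": {
            s: int((status_arr == s).sum())
            for s in (ASSIGNED, AMBIGUOUS, UNASSIGNED)
        },
        "status_fractions": {
            s: float((status_arr == s).mean()) if len(reads) else 0.0
            for s in (ASSIGNED, AMBIGUOUS, UNASSIGNED)
        },
        "per_sample_counts": {
            k: int(((df["sample"] == k) & (status_arr == ASSIGNED)).sum())
            for k in sorted(set(keys))
        },
        "median_length_by_status": {
            s: (float(np.median(lengths[status_arr == s]))
                if (status_arr == s).any() else None)
            for s in (ASSIGNED, AMBIGUOUS, UNASSIGNED)
        },
    }
    result = DemuxResult(df, summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handles = {}
        try:
            for a, seq in zip(assignments, reads.sequences):
                if a.status != ASSIGNED:
                    continue
                if a.sample not in handles:
                    handles[a.sample] = open(out_dir / f"{a.sample}.fastq",
                                             "w")
                s = _trim(seq, a, ref) if trim else seq
                handles[a.sample].write(f"@{a.read_id}\n{s}\n+\n"
                                        f"{'I' * len(s)}\n")
        finally:
            for fh in handles.values():
                fh.close()
        result.to_tsv(out_dir / "assignments.tsv")
        result.summary_to_json(out_dir / "summary.json")
    return result
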