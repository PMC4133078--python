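"""Frequency profiles of minimal SL distances (the test statistic).

For a read set S and reference set BC, f(delta) counts the reads whose
minimal SL distance to BC equals delta; F(delta) is its cumulative
distribution.  On truth-labeled (simulated) reads the profile splits
into f0 (orphaned, the null component) and f1 (barcoded, the
alternative component), the two ingredients of the tail-area Fdr.

The histogram support is fixed to [0, reference length]: a minimal SL
distance can never exceed the reference length, and keeping empty bins
explicit stabilizes RMS comparisons between profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqlev
from .barcode_design import BarcodeSet
from .read_sim import ORPHANED, ReadSet


@dataclass
class DistanceProfile:
    """Histogram of minimal SL distances with optional labeled split."""

    counts: np.ndarray                  # shape (max_delta + 1,)
    f0: np.ndarray | None = None        # orphaned component
    f1: np.ndarray | None = None        # barcoded component

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        for name in ("f0", "f1"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=np.int64))
        if self.f0 is not None and self.f1 is not None:
            if not np.array_equal(self.f0 + self.f1, self.counts):
                raise ValueError("labeled split does not sum to counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def max_delta(self) -> int:
        return len(self.counts) - 1

    @property
    def labeled(self) -> bool:
        return self.f0 is not None and self.f1 is not None

    def cdf_array(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty profile has no CDF")
        return np.cumsum(self.counts) / self.total

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            header = "delta\tcount"
            if self.labeled:
                header += "\tf0\tf1"
            fh.write(header + "\n")
            for d in range(len(self.counts)):
                row = f"{d}\t{self.counts[d]}"
                if self.labeled:
                    row += f"\t{self.f0[d]}\t{self.f1[d]}"
                fh.write(row + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceProfile":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        n = int(df["delta"].max()) + 1
        counts = np.zeros(n, dtype=np.int64)
        counts[df["delta"].to_numpy()] = df["count"].to_numpy()
        f0 = f1 = None
        if "f0" in df.columns and "f1" in df.columns:
            f0 = np.zeros(n, dtype=np.int64)
            f1 = np.zeros(n, dtype=np.int64)
            f0[df["delta"].to_numpy()] = df["f0"].to_numpy()
            f1[df["delta"].to_numpy()] = df["f1"].to_numpy()
        return cls(counts, f0, f1)


def min_distances(reads: ReadSet | list[str], refset: BarcodeSet) -> np.ndarray:
    """Minimal SL distance of every read to the reference set."""
    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    if len(seqs) == 0:
        return np.empty(0, dtype=np.int32)
    return seqlev.distance_matrix(seqs, refset.barcodes).min(axis=1)


def distance_profile(reads: ReadSet | list[str],
                     refset: BarcodeSet) -> DistanceProfile:
    """Histogram of minimal SL distances of reads against a reference set.

    When the reads carry truth labels the orphaned/barcoded split
    (f0, f1) is populated bin-wise.
    """
    if len(refset) == 0:
        raise ValueError("empty reference set")
    support = refset.length + 1
    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    if len(seqs) == 0:
        return DistanceProfile(np.zeros(support, dtype=np.int64))
    d = min_distances(reads, refset)
    counts = np.bincount(d, minlength=support).astype(np.int64)
    f0 = f1 = None
    if isinstance(reads, ReadSet) and reads.labeled:
        orphan = reads.labels == ORPHANED
        f0 = np.bincount(d[orphan], minlength=support).astype(np.int64)
        f1 = np.bincount(d[~orphan], minlength=support).astype(np.int64)
    return DistanceProfile(counts, f0, f1)


def profile_encoded(mat: np.ndarray, lengths: np.ndarray,
                    labels: np.ndarray | None,
                    refset: BarcodeSet) -> DistanceProfile:
    """Profile an encoded read matrix directly (fitness fast path).

    Equivalent to :func:`distance_profile` on the decoded reads; skips
    the string round-trip.
    """
    from ._kernels import batch_distance_kernel

    support = refset.length + 1
    if mat.shape[0] == 0:
        return DistanceProfile(np.zeros(support, dtype=np.int64))
    ref_mat, ref_lens = seqlev.pack_sequences(refset.barcodes)
    win = 2 * int(ref_lens.max())
    d = batch_distance_kernel(mat[:, :win],
                              np.minimum(lengths, win), ref_mat,
                              ref_lens).min(axis=1)
    counts = np.bincount(d, minlength=support).astype(np.int64)
    f0 = f1 = None
    if labels is not None:
        orphan = labels == ORPHANED
        f0 = np.bincount(d[orphan], minlength=support).astype(np.int64)
        f1 = np.bincount(d[~orphan], minlength=support).astype(np.int64)
    return DistanceProfile(counts, f0, f1)


def read_universe(reads: ReadSet) -> ReadSet:
    """Union of the reads and their reverse complements.

    Every input read contributes two orientation records ("+" and "-"),
    both keeping the originating read id, so that a barcode attached at
    the 3' end is seen at the start of the "-" record.
    """
    seqs, ids, orients = [], [], []
    labels = [] if reads.labeled else None
    rates = [] if reads.error_rates is not None else None
    for i, (rid, seq) in enumerate(zip(reads.ids, reads.sequences)):
        for orient, s in (("+", seq), ("-", seqlev.reverse_complement(seq))):
            seqs.append(s)
            ids.append(rid)
            orients.append(orient)
            if labels is not None:
                labels.append(reads.labels[i])
            if rates is not None:
                rates.append(reads.error_rates[i])
    return ReadSet(
        seqs,
        None if labels is None else np.array(labels, dtype=np.int64),
        None if rates is None else np.array(rates),
        ids=ids,
        orientations=orients,
    )


def sample_subsequences(background: list[str] | str, n: int, length: int,
                        rng: np.random.Generator) -> ReadSet:
    """Uniform random fixed-length windows from background sequence(s).

    Sampling is uniform over all eligible (sequence, offset) pairs;
    windows containing non-ACGT symbols are excluded up front by
    splitting each background sequence at invalid symbols.
    """
    if isinstance(background, str):
        background = [background]
    pool: list[str] = []
    for seq in background:
        s = seq.upper().replace("U", "T")
        # split at invalid symbols; each clean run is sampled separately
        run = []
        for ch in s + "$":
            if ch in "ACGT":
                run.append(ch)
            else:
                if len(run) >= length:
                    pool.append("".join(run))
                run = []
    n_offsets = np.array([len(s) - length + 1 for s in pool], dtype=np.int64)
    total = int(n_offsets.sum())
    if total == 0:
        raise ValueError(f"no background sequence admits a {length}-nt window")
    cum = np.cumsum(n_offsets)
    flat = rng.integers(0, total, size=n)
    seq_idx = np.searchsorted(cum, flat, side="right")
    offset = flat - (cum[seq_idx] - n_offsets[seq_idx])
    return ReadSet([pool[s][o: o + length] for s, o in zip(seq_idx, offset)])


def cdf(profile: DistanceProfile) -> dict[int, float]:
    """Cumulative fraction of reads at minimal distance <= delta."""
    arr = profile.cdf_array()
    return {d: float(arr[d]) for d in range(len(arr))}
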