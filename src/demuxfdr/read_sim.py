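"""Simulation of barcoded and orphaned long reads (PacBio-CLR-like).

The simulator produces the two read populations whose mixture the
detection statistic sees in real data:

* *barcoded* reads: a reference barcode (or barcoded primer) chosen at
  random, followed by insert sequence, corrupted base-by-base at a
  per-read error rate drawn from a normal distribution truncated to
  [0, 1], with insertion/deletion/substitution ratios R;
* *orphaned* reads: fixed-length subsequences that start inside the
  insert and carry no recoverable barcode — sampled from empirical
  reads after position 40, from a background sequence, or i.i.d.
  uniform over ACGT.

Error model assumptions: read accuracies are normally distributed;
error probability is uniform over positions within a read; the three
operation types occur in fixed (possibly unequal) ratios with no
positional structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from . import seqlev
from ._kernels import PAD
from .barcode_design import BarcodeSet

#: Truth label for reads that do not start with a barcode.
ORPHANED = -1

#: Error-model operating point fitted to the validation data set:
#: mean per-base error rate 12.2%, between-read SD 4.8%, and
#: insertion/deletion/substitution ratios 55% / 36.2% / 8.8%.
DEFAULT_MU_ERROR = 0.122
DEFAULT_SIGMA_ERROR = 0.048
DEFAULT_RATIOS = (0.55, 0.362, 0.088)
#: Fitted fraction of reads that still start with a barcode.
DEFAULT_PI1 = 0.34

#: Length of simulated orphan reads and of the insert window appended
#: to simulated barcoded reads.
ORPHAN_LENGTH = 50
#: 1-based position after which orphan windows are sampled from
#: empirical reads (so that no window overlaps a 5' barcode/primer).
ORPHAN_MIN_START = 40


class SimulationError(RuntimeError):
    pass


@dataclass
class ErrorModel:
    """Per-read error rate distribution and operation-type ratios."""

    mu_error: float = DEFAULT_MU_ERROR
    sigma_error: float = DEFAULT_SIGMA_ERROR
    ratios: tuple[float, float, float] = DEFAULT_RATIOS  # (INS, DEL, SUB)

    def __post_init__(self):
        if not 0.0 <= self.mu_error <= 1.0:
            raise ValueError("mu_error must be in [0, 1]")
        if self.sigma_error < 0:
            raise ValueError("sigma_error must be >= 0")
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 3 or any(x < 0 for x in r):
            raise ValueError("ratios must be three non-negative numbers")
        if abs(sum(r) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(r)}")
        self.ratios = r


@dataclass
class MixtureParams:
    """Composition of a simulated read set."""

    m: int
    pi1: float
    error_model: ErrorModel
    insert: str
    barcode_set: BarcodeSet

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must be in [0, 1]")

    @property
    def n_barcoded(self) -> int:
        # nearest integer, round-half-to-even
        return round(self.pi1 * self.m)

    @property
    def n_orphaned(self) -> int:
        return self.m - self.n_barcoded


@dataclass
class ReadSet:
    """Reads with optional truth labels and per-read error rates.

    ``labels[i]`` is the generating barcode index, or ORPHANED (-1);
    ``error_rates[i]`` is NaN for orphans.  ``orientations`` (optional)
    tracks forward/reverse-complement provenance ("+" / "-").
    """

    sequences: list[str]
    labels: np.ndarray | None = None
    error_rates: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)
    orientations: list[str] | None = None

    def __post_init__(self):
        n = len(self.sequences)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != n:
                raise ValueError("labels length mismatch")
        if self.error_rates is not None:
            self.error_rates = np.asarray(self.error_rates, dtype=float)
        if not self.ids:
            self.ids = [f"read{i:06d}" for i in range(n)]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def labeled(self) -> bool:
        return self.labels is not None

    def subset(self, idx) -> "ReadSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ReadSet(
            [self.sequences[i] for i in idx],
            None if self.labels is None else self.labels[idx],
            None if self.error_rates is None else self.error_rates[idx],
            [self.ids[i] for i in idx],
            None if self.orientations is None
            else [self.orientations[i] for i in idx],
        )

    # ---- I/O ----------------------------------------------------------
    def to_fastq(self, path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    def to_truth_tsv(self, path, barcode_set: BarcodeSet | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tlabel\tbarcode_id\terror_rate\n")
            for i, rid in enumerate(self.ids):
                lab = int(self.labels[i]) if self.labels is not None else ORPHANED
                if lab == ORPHANED:
                    name, kind = "", "orphaned"
                else:
                    name = barcode_set.names[lab] if barcode_set else str(lab)
                    kind = "barcoded"
                er = ("" if self.error_rates is None
                      or np.isnan(self.error_rates[i])
                      else f"{self.error_rates[i]:.6f}")
                fh.write(f"{rid}\t{kind}\t{name}\t{er}\n")

    @classmethod
    def from_fastx(cls, path) -> "ReadSet":
        from Bio import SeqIO

        path = str(path)
        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
        ids, seqs = [], []
        for rec in SeqIO.parse(path, fmt):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(seqs, ids=ids)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT sequence (synthetic insert / background)."""
    return seqlev.decode_bases(rng.integers(0, 4, size=length, dtype=np.uint8))


def draw_error_rate(model: ErrorModel, rng: np.random.Generator) -> float:
    """One per-read error rate ~ Normal(mu, sigma) truncated to [0, 1]."""
    return float(draw_error_rates(model, 1, rng)[0])


def draw_error_rates(model: ErrorModel, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Vector of per-read error rates; out-of-range draws are resampled."""
    if model.sigma_error == 0:
        return np.full(n, model.mu_error)
    out = rng.normal(model.mu_error, model.sigma_error, size=n)
    bad = (out < 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(model.mu_error, model.sigma_error,
                              size=int(bad.sum()))
        bad = (out < 0) | (out > 1)
    return out


def corrupt(seq: str, p: float, ratios, rng: np.random.Generator,
            return_ops: bool = False):
    """Corrupt one sequence in a single left-to-right pass.

    At each template base, with probability ``p`` an operation is drawn
    with relative probabilities (R_INS, R_DEL, R_SUB): an insertion
    emits one uniform random base before the template base (which is
    retained), a deletion drops the base, and a substitution replaces
    it with one of the three other bases uniformly.
    """
    r_ins, r_del, r_sub = ratios
    enc = seqlev.encode(seqlev.normalize(seq))
    out = []
    ops = {"ins": 0, "del": 0, "sub": 0}
    for base in enc:
        if rng.random() < p:
            u = rng.random()
            if u < r_ins:
                out.append(int(rng.integers(0, 4)))
                out.append(int(base))
                ops["ins"] += 1
            elif u < r_ins + r_del:
                ops["del"] += 1
            else:
                out.append((int(base) + 1 + int(rng.integers(0, 3))) % 4)
                ops["sub"] += 1
        else:
            out.append(int(base))
    s = seqlev.decode_bases(np.array(out, dtype=np.uint8))
    return (s, ops) if return_ops else s


def corrupt_matrix(templates: np.ndarray, p: np.ndarray, ratios,
                   rng: np.random.Generator):
    """Vectorized corruption of an (n, L) encoded template matrix.

    Same per-base semantics as :func:`corrupt` (the random streams
    differ).  Returns (padded uint8 matrix (n, 2L), lengths (n,)).
    """
    n, L = templates.shape
    r_ins, r_del, _ = ratios
    err = rng.random((n, L)) < p[:, None]
    opu = rng.random((n, L))
    ins_mask = err & (opu < r_ins)
    del_mask = err & (opu >= r_ins) & (opu < r_ins + r_del)
    sub_mask = err & ~ins_mask & ~del_mask
    final = np.where(
        sub_mask,
        (templates + 1 + rng.integers(0, 3, size=(n, L), dtype=np.uint8)) % 4,
        templates,
    ).astype(np.uint8)
    ins_bases = rng.integers(0, 4, size=(n, L), dtype=np.uint8)

    staged = np.empty((n, 2 * L), dtype=np.uint8)
    staged[:, 0::2] = ins_bases
    staged[:, 1::2] = final
    valid = np.empty((n, 2 * L), dtype=bool)
    valid[:, 0::2] = ins_mask
    valid[:, 1::2] = ~del_mask
    # stable sort moves valid cells to the front, preserving order
    order = np.argsort(~valid, axis=1, kind="stable")
    out = np.take_along_axis(staged, order, axis=1)
    lengths = valid.sum(axis=1).astype(np.int64)
    out[np.arange(2 * L)[None, :] >= lengths[:, None]] = PAD
    return out, lengths


def _simulate_barcoded_arrays(n: int, bc: BarcodeSet, insert: str,
                              model: ErrorModel, rng: np.random.Generator,
                              insert_window: int | None = ORPHAN_LENGTH):
    """Array fast path for barcoded reads: (mat, lengths, labels, rates)."""
    insert = seqlev.normalize(insert)
    if not insert:
        raise SimulationError("empty insert sequence")
    if n == 0:
        return (np.empty((0, 0), dtype=np.uint8),
                np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0))
    win = len(insert) if insert_window is None else min(insert_window,
                                                        len(insert))
    bc_mat, _ = seqlev.pack_sequences(bc.barcodes)
    ins_enc = seqlev.encode(insert)[:win]
    idx = rng.integers(0, len(bc), size=n)
    templates = np.concatenate(
        [bc_mat[idx], np.broadcast_to(ins_enc, (n, win))], axis=1
    )
    rates = draw_error_rates(model, n, rng)
    out, lengths = corrupt_matrix(templates, rates, model.ratios, rng)
    return out, lengths, idx.astype(np.int64), rates


def simulate_barcoded(n: int, bc: BarcodeSet, insert: str, model: ErrorModel,
                      rng: np.random.Generator,
                      insert_window: int = ORPHAN_LENGTH) -> ReadSet:
    """Simulate n barcoded reads: random reference + insert, corrupted.

    Only the first ``insert_window`` insert bases are carried (minimal
    SL distances to the reference set never look further than twice the
    reference length, which is below barcode + 50 nt for all shipped
    designs); pass ``insert_window=None`` for full-length reads.
    """
    out, lengths, idx, rates = _simulate_barcoded_arrays(
        n, bc, insert, model, rng, insert_window)
    seqs = [seqlev.decode_bases(out[i, : lengths[i]]) for i in range(n)]
    return ReadSet(seqs, idx, rates)


def simulate_orphaned(n: int, rng: np.random.Generator,
                      source: ReadSet | None = None,
                      background: list[str] | str | None = None,
                      length: int = ORPHAN_LENGTH,
                      min_start: int = ORPHAN_MIN_START) -> ReadSet:
    """Simulate n orphan reads of fixed length.

    Empirical mode (``source``): uniform windows of the source reads
    starting after 1-based position ``min_start`` (never overlapping the
    5' barcode region).  Background mode (``background``): uniform
    windows anywhere in the given sequence(s).  Default: i.i.d. uniform
    ACGT.
    """
    if n == 0:
        return ReadSet([], np.empty(0, dtype=np.int64), np.empty(0))
    if source is not None:
        pool = [seqlev.normalize(s) for s in source.sequences]
        start0 = min_start  # 1-based "after position 40" -> 0-based index 40
    elif background is not None:
        if isinstance(background, str):
            background = [background]
        pool = [seqlev.normalize(s) for s in background]
        start0 = 0
    else:
        mat = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
        seqs = [seqlev.decode_bases(row) for row in mat]
        return ReadSet(seqs, np.full(n, ORPHANED, dtype=np.int64),
                       np.full(n, np.nan))

    # uniform over eligible (sequence, offset) pairs
    n_offsets = np.array([max(0, len(s) - start0 - length + 1) for s in pool])
    total = int(n_offsets.sum())
    if total == 0:
        raise SimulationError(
            f"no source sequence admits a {length}-nt window after "
            f"position {start0}"
        )
    cum = np.cumsum(n_offsets)
    flat = rng.integers(0, total, size=n)
    seq_idx = np.searchsorted(cum, flat, side="right")
    offset = flat - (cum[seq_idx] - n_offsets[seq_idx]) + start0
    seqs = [pool[s][o: o + length] for s, o in zip(seq_idx, offset)]
    return ReadSet(seqs, np.full(n, ORPHANED, dtype=np.int64),
                   np.full(n, np.nan))


def simulate_mixture_arrays(params: MixtureParams, rng: np.random.Generator,
                            insert_window: int = ORPHAN_LENGTH):
    """Encoded fast path for the mixture (uniform-ACGT orphans only).

    Returns (mat (m, W) uint8 padded, lengths, labels, rates) with rows
    shuffled; used by the fitness loop to avoid string round-trips.
    The random stream matches :func:`simulate_mixture` called without an
    orphan source, so both produce the same reads for the same rng state.
    """
    n1, n0 = params.n_barcoded, params.n_orphaned
    b_mat, b_len, b_lab, b_rate = _simulate_barcoded_arrays(
        n1, params.barcode_set, params.insert, params.error_model, rng,
        insert_window)
    o_mat = rng.integers(0, 4, size=(n0, ORPHAN_LENGTH), dtype=np.uint8)
    width = max(b_mat.shape[1], ORPHAN_LENGTH)
    mat = np.full((params.m, width), PAD, dtype=np.uint8)
    mat[:n1, : b_mat.shape[1]] = b_mat
    mat[n1:, :ORPHAN_LENGTH] = o_mat
    lengths = np.concatenate(
        [b_len, np.full(n0, ORPHAN_LENGTH, dtype=np.int64)])
    labels = np.concatenate([b_lab, np.full(n0, ORPHANED, dtype=np.int64)])
    rates = np.concatenate([b_rate, np.full(n0, np.nan)])
    perm = rng.permutation(params.m)
    return mat[perm], lengths[perm], labels[perm], rates[perm]


def simulate_mixture(params: MixtureParams, rng: np.random.Generator,
                     orphan_source: ReadSet | None = None,
                     orphan_background: list[str] | str | None = None,
                     insert_window: int = ORPHAN_LENGTH) -> ReadSet:
    """Simulate the labeled barcoded/orphaned mixture and shuffle it."""
    if orphan_source is None and orphan_background is None:
        mat, lengths, labels, rates = simulate_mixture_arrays(
            params, rng, insert_window)
        seqs = [seqlev.decode_bases(mat[i, : lengths[i]])
                for i in range(params.m)]
        return ReadSet(seqs, labels, rates)
    n1, n0 = params.n_barcoded, params.n_orphaned
    barcoded = simulate_barcoded(n1, params.barcode_set, params.insert,
                                 params.error_model, rng,
                                 insert_window=insert_window)
    orphans = simulate_orphaned(n0, rng, source=orphan_source,
                                background=orphan_background)
    seqs = barcoded.sequences + orphans.sequences
    labels = np.concatenate([barcoded.labels, orphans.labels])
    rates = np.concatenate([barcoded.error_rates, orphans.error_rates])
    perm = rng.permutation(params.m)
    return ReadSet([seqs[i] for i in perm], labels[perm], rates[perm])
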