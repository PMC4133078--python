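"""Sequence-Levenshtein (SL) distance and nearest-barcode decoding.

The SL distance between two sequences is the minimal number of
insertions, deletions and substitutions needed to transform one
sequence into *any prefix* of the other, or vice versa.  It is the
natural metric for barcodes embedded in longer DNA context: trailing
insert sequence after the barcode is free, so a barcode can be scored
against the start of a read without knowing where the barcode ends.

Operationally it is the minimum over the last row and the last column
of the standard Levenshtein dynamic-programming matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import PAD, batch_distance_kernel, sl_distance_kernel

#: Alphabet in encoding order; code 4 is padding.
ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("U")] = 3
_ENCODE[ord("u")] = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Sentinel decode statuses (barcode indices are non-negative ints).
AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"


class SequenceError(ValueError):
    """A sequence contains a symbol outside {A, C, G, T, U}."""


def normalize(seq: str) -> str:
    """Uppercase a sequence and map U to T; reject anything else.

    N and other IUPAC ambiguity codes are rejected rather than treated
    as wildcards, since no wildcard semantics is defined for the SL
    distance.
    """
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in "ACGT":
            raise SequenceError(
                f"invalid symbol {ch!r} at position {pos} (only A/C/G/T/U allowed)"
            )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        pos = int(np.argmax(arr == 255))
        raise SequenceError(
            f"invalid symbol {seq[pos]!r} at position {pos} (only A/C/G/T/U allowed)"
        )
    return arr


def decode_bases(arr: np.ndarray) -> str:
    """Inverse of :func:`encode` (padding is dropped)."""
    return "".join(ALPHABET[b] for b in arr if b < 4)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement."""
    return normalize(seq).translate(_COMPLEMENT)[::-1]


def sl_distance(a: str, b: str) -> int:
    """SL distance between two sequences (either may be empty).

    Symmetric; 0 iff one sequence is a prefix of the other; bounded
    above by both the ordinary Levenshtein distance and min(|a|, |b|).
    """
    ea = encode(normalize(a))
    eb = encode(normalize(b))
    return int(sl_distance_kernel(ea, eb))


def pack_sequences(seqs, window: int | None = None):
    """Pack variable-length sequences into a padded uint8 matrix.

    Returns (matrix (n, W), lengths (n,)).  If ``window`` is given,
    sequences are truncated to their first ``window`` bases.
    """
    enc = [encode(normalize(s)) for s in seqs]
    if window is not None:
        enc = [e[:window] for e in enc]
    lengths = np.array([len(e) for e in enc], dtype=np.int64)
    w = int(lengths.max()) if len(enc) else 0
    mat = np.full((len(enc), w), PAD, dtype=np.uint8)
    for i, e in enumerate(enc):
        mat[i, : len(e)] = e
    return mat, lengths


def distance_matrix(seqs, barcodes, window: bool | int = True) -> np.ndarray:
    """SL distances of every sequence to every barcode, (n, k) int32.

    ``barcodes`` is a sequence of reference strings.  By default each
    query is truncated to a window of twice the longest barcode length
    before the DP; this cannot change any distance because
    d_SL(b, s) <= |b| and a prefix of length 2|b| already contains every
    alignment of cost <= |b|.  Pass ``window=False`` to disable, or an
    int to set the window explicitly.
    """
    bcs = list(barcodes)
    if not bcs:
        raise ValueError("empty barcode set")
    ref_mat, ref_lens = pack_sequences(bcs)
    if window is True:
        win = 2 * int(ref_lens.max())
    elif window is False:
        win = None
    else:
        win = int(window)
    q_mat, q_lens = pack_sequences(seqs, window=win)
    if q_mat.shape[0] == 0:
        return np.empty((0, len(bcs)), dtype=np.int32)
    return batch_distance_kernel(q_mat, q_lens, ref_mat, ref_lens)


@dataclass
class DistanceResult:
    """Minimal SL distance of a sequence to a barcode set."""

    delta: int
    argmin_indices: list[int] = field(default_factory=list)


def min_distance_to_set(seq: str, barcodes) -> DistanceResult:
    """Minimal SL distance of ``seq`` to a barcode set, with all argmins.

    ``barcodes`` may be a BarcodeSet or any iterable of sequences.
    """
    bcs = list(getattr(barcodes, "barcodes", barcodes))
    if not bcs:
        raise ValueError("empty barcode set")
    d = distance_matrix([seq], bcs)[0]
    delta = int(d.min())
    return DistanceResult(delta, [int(i) for i in np.flatnonzero(d == delta)])


def decode(seq: str, barcodes, threshold: int):
    """Decode a read start against a barcode set at a distance threshold.

    Returns the unique argmin barcode index when its distance is within
    the threshold, AMBIGUOUS when several barcodes tie at the minimum,
    and UNASSIGNED when the minimum exceeds the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    res = min_distance_to_set(seq, barcodes)
    if res.delta > threshold:
        return UNASSIGNED
    if len(res.argmin_indices) > 1:
        return AMBIGUOUS
    return res.argmin_indices[0]
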