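"""Design and audit of [l,d] Sequence-Levenshtein barcode sets.

An [l,d] set contains l-nt barcodes whose pairwise SL distance is at
least d; d >= 3 corrects any single insertion, deletion or substitution
even when the barcode is followed by arbitrary insert sequence.

Construction follows a greedy heuristic with random restarts: candidate
l-mers are screened by simple physico-chemical eligibility filters
(GC content 40-60%, no perfect self-complementarity, no homopolymer run
of three or more), a random 3-member seed at pairwise distance >= d is
drawn, and the eligible candidates are scanned in lexicographic order,
adding every candidate compatible with the growing set.  The largest
set over all restarts wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqlev
from ._kernels import filter_compatible_kernel, sl_distance_kernel

#: PCR primers flanking the amplicon in the validation experiment;
#: barcoded primers are barcode + primer concatenations.
FORWARD_PRIMER = "GGGAGCTGCTCTCTTCTCTT"
REVERSE_PRIMER = "TATAAACCTTGCCCGCTGTC"


class DesignError(RuntimeError):
    """Barcode set construction failed (e.g. no eligible seed)."""


@dataclass
class BarcodeSet:
    """Ordered set of equal-length reference barcodes.

    ``names`` carry sample identifiers; ``declared_min_distance`` is the
    design guarantee d, re-checkable with :func:`verify_set`.
    """

    barcodes: list[str]
    names: list[str] = field(default_factory=list)
    declared_min_distance: int = 0

    def __post_init__(self):
        self.barcodes = [seqlev.normalize(b) for b in self.barcodes]
        if not self.names:
            self.names = [f"bc{i:02d}" for i in range(len(self.barcodes))]
        if len(self.names) != len(self.barcodes):
            raise ValueError("names and barcodes differ in length")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(f"barcodes of unequal length: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def length(self) -> int:
        return len(self.barcodes[0]) if self.barcodes else 0

    @property
    def d_mean(self) -> float:
        """Mean pairwise SL distance over unordered pairs."""
        return verify_set(self, self.declared_min_distance).d_mean

    # ---- I/O ----------------------------------------------------------
    @classmethod
    def from_fasta(cls, path, declared_min_distance: int = 0) -> "BarcodeSet":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(seqs, names, declared_min_distance)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, bc in zip(self.names, self.barcodes):
                fh.write(f">{name}\n{bc}\n")

    @classmethod
    def from_tsv(cls, path, declared_min_distance: int = 0) -> "BarcodeSet":
        names, seqs = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, seq = line.split("\t")[:2]
            names.append(name)
            seqs.append(seq)
        return cls(seqs, names, declared_min_distance)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, bc in zip(self.names, self.barcodes):
                fh.write(f"{name}\t{bc}\n")


def gc_fraction(seq: str) -> float:
    s = seqlev.normalize(seq)
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def has_homopolymer_run(seq: str, run: int = 3) -> bool:
    """True if any base repeats ``run`` or more times consecutively."""
    count = 1
    for prev, cur in zip(seq, seq[1:]):
        count = count + 1 if cur == prev else 1
        if count >= run:
            return True
    return False


def is_eligible(seq: str) -> bool:
    """Eligibility filter for barcode candidates.

    GC fraction within [0.40, 0.60], not equal to its own reverse
    complement, and no run of three or more identical bases.
    """
    s = seqlev.normalize(seq)
    if not 0.40 <= gc_fraction(s) <= 0.60:
        return False
    if s == seqlev.reverse_complement(s):
        return False
    if has_homopolymer_run(s):
        return False
    return True


def enumerate_eligible(length: int, max_candidates: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Eligible l-mers in lexicographic order as an (n, l) uint8 matrix.

    Full enumeration for l <= 10; for longer barcodes a random sample of
    ``max_candidates`` distinct l-mers is screened instead (then sorted
    lexicographically), since 4**l grows out of reach.
    """
    if length <= 10:
        cands = np.array(
            list(itertools.product(range(4), repeat=length)), dtype=np.uint8
        )
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        budget = max_candidates or 200_000
        cands = rng.integers(0, 4, size=(budget, length), dtype=np.uint8)
        cands = np.unique(cands, axis=0)  # unique also sorts lexicographically
    keep = [i for i, row in enumerate(cands)
            if is_eligible(seqlev.decode_bases(row))]
    return cands[keep]


def _pairwise_ok(members: list[np.ndarray], cand: np.ndarray, dmin: int) -> bool:
    return all(int(sl_distance_kernel(m, cand)) >= dmin for m in members)


def _draw_seed(eligible: np.ndarray, dmin: int, rng: np.random.Generator,
               seed_size: int = 3, attempts: int = 200) -> list[int] | None:
    """Random seed of ``seed_size`` mutually distant eligible candidates."""
    n = eligible.shape[0]
    for _ in range(attempts):
        idx = [int(rng.integers(n))]
        ok = True
        for _ in range(seed_size - 1):
            found = False
            for _ in range(attempts):
                j = int(rng.integers(n))
                if j in idx:
                    continue
                if _pairwise_ok([eligible[i] for i in idx], eligible[j], dmin):
                    idx.append(j)
                    found = True
                    break
            if not found:
                ok = False
                break
        if ok:
            return idx
    return None


def _greedy_extend(eligible: np.ndarray, seed_idx: list[int], dmin: int) -> list[int]:
    """Lexicographic greedy completion of a seed into a maximal set."""
    members = list(seed_idx)
    compatible = np.ones(eligible.shape[0], dtype=bool)
    for i in members:
        compatible &= filter_compatible_kernel(eligible, eligible[i], dmin)
    while True:
        remaining = np.flatnonzero(compatible)
        if remaining.size == 0:
            break
        nxt = int(remaining[0])  # eligible rows are in lexicographic order
        members.append(nxt)
        compatible &= filter_compatible_kernel(eligible, eligible[nxt], dmin)
    return members


def generate_set(length: int, dmin: int, rng_seed: int = 0,
                 iterations: int = 100,
                 max_candidates: int | None = None) -> BarcodeSet:
    """Generate an [l,d] barcode set via greedy search with restarts.

    Each restart draws a fresh random 3-member seed or randomly modifies
    the best seed found so far (one member swapped for a fresh eligible
    candidate), then completes it greedily over the lexicographically
    ordered eligible candidates.  The largest set across ``iterations``
    restarts is returned.  Deterministic given ``rng_seed``.
    """
    if not length >= dmin >= 1:
        raise ValueError("require length >= dmin >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    eligible = enumerate_eligible(length, max_candidates=max_candidates, rng=rng)
    if eligible.shape[0] == 0:
        raise DesignError(f"no eligible {length}-mers exist")

    best: list[int] = []
    best_seed: list[int] | None = None
    for it in range(iterations):
        seed_idx = None
        if best_seed is not None and it % 2 == 1:
            # randomly modified seed: swap one member for a fresh candidate
            seed_idx = list(best_seed)
            drop = int(rng.integers(len(seed_idx)))
            rest = [eligible[i] for k, i in enumerate(seed_idx) if k != drop]
            for _ in range(200):
                j = int(rng.integers(eligible.shape[0]))
                if j not in seed_idx and _pairwise_ok(rest, eligible[j], dmin):
                    seed_idx[drop] = j
                    break
            else:
                seed_idx = None
        if seed_idx is None:
            seed_idx = _draw_seed(eligible, dmin, rng)
        if seed_idx is None:
            continue
        members = _greedy_extend(eligible, seed_idx, dmin)
        if len(members) > len(best):
            best = members
            best_seed = seed_idx
    if not best:
        raise DesignError(
            f"no seed of 3 mutually distant (>= {dmin}) eligible "
            f"{length}-mers found; the length is likely too small"
        )
    seqs = [seqlev.decode_bases(eligible[i]) for i in best]
    return BarcodeSet(seqs, declared_min_distance=dmin)


@dataclass
class VerifyReport:
    min_distance: int
    d_mean: float
    offending_pairs: list[tuple[int, int, int]]  # (i, j, distance)

    @property
    def ok(self) -> bool:
        return not self.offending_pairs


def verify_set(bc: BarcodeSet, dmin: int) -> VerifyReport:
    """Exact pairwise audit of a barcode set against a distance floor."""
    if len(bc) == 0:
        raise ValueError("empty barcode set")
    enc = [seqlev.encode(b) for b in bc.barcodes]
    dists = []
    offenders = []
    for i in range(len(enc)):
        for j in range(i + 1, len(enc)):
            d = int(sl_distance_kernel(enc[i], enc[j]))
            dists.append(d)
            if d < dmin:
                offenders.append((i, j, d))
    if not dists:  # single-member set
        return VerifyReport(min_distance=len(bc.barcodes[0]), d_mean=float("nan"),
                            offending_pairs=[])
    return VerifyReport(min_distance=min(dists), d_mean=float(np.mean(dists)),
                        offending_pairs=offenders)


def extend_with_primer(bc: BarcodeSet, primer: str,
                       prefix_length: int | None = None) -> BarcodeSet:
    """Append a primer (or a prefix of it) to every barcode.

    A 7-nt barcode extended with a 20-nt primer yields the 27-nt
    barcoded PCR primer used as the detection reference; shorter
    prefixes support studying detection quality versus reference
    length.  ``prefix_length=0`` is the identity.
    """
    p = seqlev.normalize(primer)
    if prefix_length is not None:
        p = p[:prefix_length]
    return BarcodeSet(
        [b + p for b in bc.barcodes],
        names=list(bc.names),
        declared_min_distance=bc.declared_min_distance,
    )


def barcoded_primer_set(bc: BarcodeSet, forward: str = FORWARD_PRIMER,
                        reverse: str = REVERSE_PRIMER,
                        prefix_length: int | None = None) -> BarcodeSet:
    """Materialize the 2n-member forward+reverse barcoded primer set.

    Each sample contributes two references: barcode + forward primer and
    barcode + reverse primer (e.g. 40 references of 27 nt for 20
    samples).  Names carry a ``/fwd`` or ``/rev`` suffix so that both
    decode back to the same sample.
    """
    fwd = extend_with_primer(bc, forward, prefix_length)
    rev = extend_with_primer(bc, reverse, prefix_length)
    return BarcodeSet(
        fwd.barcodes + rev.barcodes,
        names=[f"{n}/fwd" for n in bc.names] + [f"{n}/rev" for n in bc.names],
        declared_min_distance=bc.declared_min_distance,
    )
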