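"""Tail-area false discovery rate over distance thresholds.

A read is *called barcoded* when its minimal SL distance delta to the
reference set is at or below a threshold delta_t.  On a truth-labeled
simulated mixture the tail-area Fdr of that call is the fraction of
calls that are actually orphaned:

    Fdr(delta_t) = F0(delta_t) / (F0(delta_t) + F1(delta_t))

with F0, F1 the cumulative counts of the orphaned and barcoded
components.  Precision is 1 - Fdr; detection sensitivity is the
fraction of truly barcoded reads called.  Assignment metrics
additionally require the called read to decode to its true sample
(unique nearest reference, no tie across samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqlev
from .barcode_design import BarcodeSet, barcoded_primer_set
from .read_sim import (ORPHANED, ErrorModel, MixtureParams, ReadSet,
                       simulate_mixture)


def sample_keys(bc: BarcodeSet) -> list[str]:
    """Collapse forward/reverse reference names onto sample identities."""
    out = []
    for name in bc.names:
        for suffix in ("/fwd", "/rev"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
        out.append(name)
    return out


@dataclass
class FdrTable:
    """Per-threshold detection and assignment quality metrics."""

    table: pd.DataFrame  # indexed by threshold

    def row(self, threshold: int) -> pd.Series:
        return self.table.loc[threshold]

    @property
    def thresholds(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="threshold",
                          float_format="%.6f")

    def to_json(self, path) -> None:
        self.table.reset_index(names="threshold").to_json(
            path, orient="records", indent=2)


def assignment_correct(sim: ReadSet, ref: BarcodeSet,
                       label_keys: list[str] | None = None):
    """Per-read (delta, correctly-decodable) vectors for a labeled set.

    A read is correctly decodable when a unique *sample* attains its
    minimal distance (forward and reverse references of one sample do
    not make a tie) and that sample is the read's true origin.
    ``label_keys`` maps truth-label indices to sample names; it
    defaults to the scoring set's own sample keys and must be supplied
    when the reads were generated from a different reference set (e.g.
    primer-extended templates scored against plain barcodes).
    Returns (deltas (n,), correct (n,) bool).
    """
    if not sim.labeled:
        raise ValueError("truth labels required")
    dmat = seqlev.distance_matrix(sim.sequences, ref.barcodes)
    deltas = dmat.min(axis=1)
    keys = sample_keys(ref)
    uniq = sorted(set(keys))
    key_idx = np.array([uniq.index(k) for k in keys])
    if label_keys is None:
        label_keys = keys
    label_idx = np.array([uniq.index(k) if k in uniq else -2
                          for k in label_keys])
    # per-sample minimal distance: (n, n_samples)
    n_samples = len(uniq)
    per_sample = np.full((dmat.shape[0], n_samples), np.iinfo(np.int32).max,
                         dtype=np.int32)
    for j, k in enumerate(key_idx):
        np.minimum(per_sample[:, k], dmat[:, j], out=per_sample[:, k])
    is_min = per_sample == deltas[:, None]
    unique_sample = is_min.sum(axis=1) == 1
    decoded = per_sample.argmin(axis=1)
    true_sample = np.full(len(sim), -1, dtype=np.int64)
    barcoded = sim.labels != ORPHANED
    true_sample[barcoded] = label_idx[sim.labels[barcoded]]
    correct = unique_sample & barcoded & (decoded == true_sample)
    return deltas, correct


def fdr_table(sim: ReadSet, ref: BarcodeSet,
              assignment_denominator: str = "all",
              label_keys: list[str] | None = None) -> FdrTable:
    """Detection and assignment metrics for every threshold in [0, L].

    ``assignment_denominator`` selects the sensitivity denominator:
    "all" divides by all simulated reads, "barcoded" by the truly
    barcoded reads only.  ``label_keys`` is forwarded to
    :func:`assignment_correct` when the generating and scoring
    reference sets differ.
    """
    if not sim.labeled:
        raise ValueError("fdr_table requires a truth-labeled read set")
    if assignment_denominator not in ("all", "barcoded"):
        raise ValueError("assignment_denominator must be 'all' or 'barcoded'")
    deltas, correct = assignment_correct(sim, ref, label_keys=label_keys)
    support = ref.length + 1
    orphan = sim.labels == ORPHANED
    f0 = np.bincount(deltas[orphan], minlength=support)[:support]
    f1 = np.bincount(deltas[~orphan], minlength=support)[:support]
    fc = np.bincount(deltas[correct], minlength=support)[:support]
    c0, c1, cc = np.cumsum(f0), np.cumsum(f1), np.cumsum(fc)
    called = (c0 + c1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        det_fdr = np.where(called > 0, c0 / called, np.nan)
        asg_prec = np.where(called > 0, cc / called, np.nan)
    total1 = c1[-1] if c1[-1] > 0 else np.nan
    denom = len(sim) if assignment_denominator == "all" else total1
    df = pd.DataFrame(
        {
            "detection_fdr": det_fdr,
            "detection_precision": 1.0 - det_fdr,
            "detection_sensitivity": c1 / total1,
            "assignment_precision": asg_prec,
            "assignment_sensitivity": cc / denom,
        },
        index=pd.RangeIndex(support, name="threshold"),
    )
    return FdrTable(df)


def choose_threshold(table: FdrTable, min_precision: float) -> int | None:
    """Largest threshold with detection precision above ``min_precision``.

    Thresholds with undefined precision (no read called) are skipped;
    returns None when no threshold qualifies.
    """
    prec = table.table["detection_precision"]
    ok = prec[prec > min_precision]
    if ok.empty:
        return None
    return int(ok.index.max())


def sensitivity_vs_primer_length(
    bc: BarcodeSet,
    forward_primer: str,
    reverse_primer: str,
    precision_levels,
    insert: str,
    error_model: ErrorModel,
    pi1: float,
    m: int,
    rng: np.random.Generator,
    prefix_lengths=None,
) -> pd.DataFrame:
    """Detection sensitivity vs barcoded-primer reference length.

    For each primer prefix length k the reference set is rebuilt
    (barcode + k primer bases, forward and reverse), a fresh mixture is
    simulated against it, and for each requested precision level the
    threshold chosen at that precision is applied.  Output is a long
    DataFrame (ref_length, precision_level, threshold, sensitivity);
    sensitivity is 0 when no threshold attains the precision.  The
    curve is piecewise constant in k because thresholds are discrete.
    """
    if prefix_lengths is None:
        prefix_lengths = range(0, len(forward_primer) + 1)
    rows = []
    for k in prefix_lengths:
        ref = (barcoded_primer_set(bc, forward_primer, reverse_primer,
                                   prefix_length=k)
               if k > 0 else barcoded_primer_set(bc, "", ""))
        params = MixtureParams(m=m, pi1=pi1, error_model=error_model,
                               insert=insert, barcode_set=ref)
        sim = simulate_mixture(params, rng)
        tab = fdr_table(sim, ref)
        for level in precision_levels:
            dt = choose_threshold(tab, level)
            sens = (0.0 if dt is None
                    else float(tab.row(dt)["detection_sensitivity"]))
            rows.append({"ref_length": bc.length + k,
                         "precision_level": level,
                         "threshold": dt, "sensitivity": sens})
    return pd.DataFrame(rows)


def plot_precision_sensitivity(table: FdrTable, path) -> None:
    """Precision and sensitivity against threshold, plus the PR curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    t = table.thresholds
    axes[0].plot(t, table.table["detection_precision"], "o-")
    axes[0].set_xlabel("threshold $\\delta_t$")
    axes[0].set_ylabel("precision (1 - Fdr)")
    axes[1].plot(t, table.table["detection_sensitivity"], "o-")
    axes[1].set_xlabel("threshold $\\delta_t$")
    axes[1].set_ylabel("sensitivity")
    axes[2].plot(table.table["detection_sensitivity"],
                 table.table["detection_precision"], "o-")
    axes[2].set_xlabel("sensitivity")
    axes[2].set_ylabel("precision")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
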