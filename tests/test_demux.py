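"""Read-to-sample assignment, both ends, trimming, conservation."""

import numpy as np
import pytest

import demuxfdr as dx
from demuxfdr.demux import trim_extent
from demuxfdr.fdr import sample_keys
from demuxfdr.read_sim import ErrorModel


def test_assign_read_five_prime(primed, insert):
    read = primed.barcodes[0] + insert[:80]
    a = dx.assign_read(read, primed, threshold=2)
    assert a.status == dx.ASSIGNED
    assert a.sample == sample_keys(primed)[0]
    assert a.end == "5prime" and a.delta == 0


def test_assign_read_three_prime(primed, insert):
    read = dx.reverse_complement(primed.barcodes[3] + insert[:80])
    a = dx.assign_read(read, primed, threshold=2)
    assert a.status == dx.ASSIGNED and a.end == "3prime"
    assert a.sample == sample_keys(primed)[3]


def test_assign_read_both_ends_same_sample(primed, insert):
    fwd = primed.barcodes[0]          # sample 0, forward primer
    rev = primed.barcodes[20]         # sample 0, reverse primer
    read = fwd + insert[:120] + dx.reverse_complement(rev)
    a = dx.assign_read(read, primed, threshold=2)
    assert a.status == dx.ASSIGNED and a.end == "both"
    assert a.sample == sample_keys(primed)[0]


def test_assign_read_conflicting_ends_is_ambiguous(primed, insert):
    read = (primed.barcodes[1] + insert[:120]
            + dx.reverse_complement(primed.barcodes[22]))  # samples 1 vs 2
    a = dx.assign_read(read, primed, threshold=2)
    assert a.status == dx.AMBIGUOUS
    assert a.sample is None


def test_assign_read_unassigned(primed, rng):
    read = dx.random_sequence(100, rng)
    a = dx.assign_read(read, primed, threshold=1)
    assert a.status == dx.UNASSIGNED
    with pytest.raises(ValueError):
        dx.assign_read("", primed, threshold=1)


def test_trim_extent_tracks_indels():
    ref = "ACGTACG"
    assert trim_extent(ref, "ACGTACGTTTT") == 7
    assert trim_extent(ref, "ACGTACTTTT") >= 6      # deletion in read
    assert trim_extent(ref, "AACGTACGTTTT") == 8    # insertion in read
    assert trim_extent(ref, "ACGT") == 4            # read shorter than ref


def test_demultiplex_truth_labeled(primed, insert, rng, tmp_path):
    """Error-free barcoded reads all route to their true samples;
    orphans stay unassigned."""
    barcoded = dx.simulate_barcoded(60, primed, insert, ErrorModel(0, 0),
                                    rng)
    orphans = dx.simulate_orphaned(40, rng)
    reads = dx.ReadSet(barcoded.sequences + orphans.sequences,
                       np.concatenate([barcoded.labels, orphans.labels]))
    out = tmp_path / "samples"
    result = dx.demultiplex(reads, primed, threshold=2, out_dir=out)
    counts = result.summary["status_counts"]
    assert counts["ASSIGNED"] == 60 and counts["UNASSIGNED"] == 40
    assert sum(counts.values()) == 100
    keys = sample_keys(primed)
    df = result.assignments
    for i, lab in enumerate(barcoded.labels):
        assert df.iloc[i]["sample"] == keys[lab]
    # per-sample FASTQ written for every sample that received reads
    assigned_samples = set(df[df["status"] == "ASSIGNED"]["sample"])
    for s in assigned_samples:
        assert (out / f"{s}.fastq").exists()
    assert (out / "assignments.tsv").exists()
    assert (out / "summary.json").exists()


def test_trimmed_reads_no_longer_start_with_barcode(primed, insert, rng,
                                                    tmp_path):
    barcoded = dx.simulate_barcoded(40, primed, insert,
                                    ErrorModel(0.05, 0.0), rng)
    out = tmp_path / "samples"
    dx.demultiplex(barcoded, primed, threshold=3, out_dir=out, trim=True)
    trimmed = []
    for fq in out.glob("*.fastq"):
        trimmed += dx.ReadSet.from_fastx(fq).sequences
    assert trimmed
    for seq in trimmed:
        res = dx.min_distance_to_set(seq, primed)
        assert res.delta > 0  # no exact barcode left at the read start


def test_demultiplex_conservation_and_orientation_symmetry(primed, insert):
    params = dx.MixtureParams(m=300, pi1=0.4, error_model=ErrorModel(),
                              insert=insert, barcode_set=primed)
    reads = dx.simulate_mixture(params, np.random.default_rng(31))
    fwd = dx.demultiplex(reads, primed, threshold=6)
    assert len(fwd.assignments) == len(reads)
    flipped = dx.ReadSet([dx.reverse_complement(s) for s in reads.sequences],
                         reads.labels)
    rev = dx.demultiplex(flipped, primed, threshold=6)
    assert fwd.summary["per_sample_counts"] == rev.summary["per_sample_counts"]
    assert fwd.summary["status_counts"] == rev.summary["status_counts"]


def test_demux_agrees_with_fdr_assignment_metrics(primed, insert):
    """On labeled simulated input the demultiplexer's realized accuracy
    matches the Fdr table's assignment metrics at the same threshold."""
    params = dx.MixtureParams(m=2000, pi1=0.34, error_model=ErrorModel(),
                              insert=insert, barcode_set=primed)
    reads = dx.simulate_mixture(params, np.random.default_rng(41))
    threshold = 9
    table = dx.fdr_table(reads, primed)
    result = dx.demultiplex(reads, primed, threshold=threshold)
    keys = sample_keys(primed)
    df = result.assignments
    assigned = df["status"] == "ASSIGNED"
    detected = (df["status"] != "UNASSIGNED").to_numpy()  # incl. ambiguous
    true_keys = np.array([keys[lab] if lab != dx.ORPHANED else ""
                          for lab in reads.labels])
    correct = (df["sample"].to_numpy() == true_keys) & assigned.to_numpy()
    # the table's precision denominator is "reads with detected barcodes",
    # which includes reads later dropped as ambiguous
    demux_precision = correct.sum() / detected.sum()
    demux_sensitivity = correct.sum() / len(reads)
    row = table.row(threshold)
    assert demux_precision == pytest.approx(row["assignment_precision"],
                                            abs=0.03)
    assert demux_sensitivity == pytest.approx(row["assignment_sensitivity"],
                                              abs=0.03)
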