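"""Read-error model: rate draws, corruption semantics, mixtures."""

import numpy as np
import pytest
from scipy import stats

import demuxfdr as dx
from demuxfdr.read_sim import (ErrorModel, SimulationError, corrupt_matrix,
                               draw_error_rates, _simulate_barcoded_arrays)
from demuxfdr import seqlev


def test_error_model_validation():
    with pytest.raises(ValueError):
        ErrorModel(mu_error=1.5)
    with pytest.raises(ValueError):
        ErrorModel(sigma_error=-0.1)
    with pytest.raises(ValueError):
        ErrorModel(ratios=(0.5, 0.5, 0.5))


def test_draw_error_rate_degenerate(rng):
    assert dx.draw_error_rate(ErrorModel(0.1, 0.0), rng) == 0.1
    assert dx.draw_error_rate(ErrorModel(0.0, 0.0), rng) == 0.0


def test_error_rates_match_truncated_normal(rng):
    """KS test of 10,000 draws against the truncated normal."""
    mu, sigma = 0.122, 0.048
    draws = draw_error_rates(ErrorModel(mu, sigma), 10_000, rng)
    assert ((draws >= 0) & (draws <= 1)).all()
    tn = stats.truncnorm((0 - mu) / sigma, (1 - mu) / sigma, loc=mu,
                         scale=sigma)
    assert stats.kstest(draws, tn.cdf).pvalue > 0.01
    se = sigma / np.sqrt(10_000)
    assert abs(draws.mean() - mu) < 3 * se


def test_corrupt_identity_and_forced_substitution(rng):
    s = dx.random_sequence(60, rng)
    assert dx.corrupt(s, 0.0, (0.55, 0.362, 0.088), rng) == s
    out = dx.corrupt(s, 1.0, (0.0, 0.0, 1.0), rng)
    assert len(out) == len(s)
    assert all(a != b for a, b in zip(s, out))


def test_corrupt_mean_op_count(rng):
    """Mean number of introduced edits is length * p."""
    s = dx.random_sequence(50, rng)
    p, n = 0.1, 10_000
    totals = np.empty(n)
    kinds = {"ins": 0, "del": 0, "sub": 0}
    for i in range(n):
        _, ops = dx.corrupt(s, p, (0.5, 0.3, 0.2), rng, return_ops=True)
        totals[i] = sum(ops.values())
        for k in kinds:
            kinds[k] += ops[k]
    se = np.sqrt(50 * p * (1 - p) / n)
    assert abs(totals.mean() - 50 * p) < 3 * se
    # op-type frequencies match the requested ratios
    grand = sum(kinds.values())
    for k, r in zip(("ins", "del", "sub"), (0.5, 0.3, 0.2)):
        se_k = np.sqrt(r * (1 - r) / grand)
        assert abs(kinds[k] / grand - r) < 3 * se_k


def test_corrupt_matrix_semantics(rng):
    templates = rng.integers(0, 4, size=(200, 40), dtype=np.uint8)
    out, lengths = corrupt_matrix(templates, np.zeros(200),
                                  (0.55, 0.362, 0.088), rng)
    assert (lengths == 40).all()
    assert np.array_equal(out[:, :40], templates)
    # forced substitutions: same length, every base changed
    out2, lengths2 = corrupt_matrix(templates, np.ones(200), (0, 0, 1), rng)
    assert (lengths2 == 40).all()
    assert (out2[:, :40] != templates).all()
    # expected length change: L * (1 + p*(R_ins - R_del))
    p = 0.2
    out3, lengths3 = corrupt_matrix(templates, np.full(200, p),
                                    (0.6, 0.4, 0.0), rng)
    expect = 40 * (1 + p * (0.6 - 0.4))
    assert abs(lengths3.mean() - expect) < 1.0


def test_simulate_barcoded_exact_when_error_free(bc20, insert, rng):
    reads = dx.simulate_barcoded(200, bc20, insert, ErrorModel(0, 0), rng)
    for seq, lab in zip(reads.sequences, reads.labels):
        assert seq.startswith(bc20.barcodes[lab])
    assert dx.simulate_barcoded(0, bc20, insert, ErrorModel(), rng).labels.size == 0
    with pytest.raises(SimulationError):
        dx.simulate_barcoded(5, bc20, "", ErrorModel(), rng)


def test_simulate_barcoded_uniform_draws(bc20, insert, rng):
    reads = dx.simulate_barcoded(20_000, bc20, insert, ErrorModel(), rng)
    counts = np.bincount(reads.labels, minlength=20)
    assert stats.chisquare(counts).pvalue > 0.001


def test_orphans_from_empirical_reads_avoid_barcode_region(rng):
    # marker construction: positions 1-40 are G, the rest A
    src = dx.ReadSet(["G" * 40 + "A" * 200 for _ in range(5)])
    orphans = dx.simulate_orphaned(300, rng, source=src)
    assert all(s == "A" * 50 for s in orphans.sequences)
    assert all(len(s) == 50 for s in orphans.sequences)


def test_orphans_error_when_source_too_short(rng):
    src = dx.ReadSet(["ACGT" * 10])  # 40 nt: no window after position 40
    with pytest.raises(SimulationError):
        dx.simulate_orphaned(10, rng, source=src)


def test_uniform_orphans_near_miss_rate(bc20, rng):
    """~6% of random 50-mers fall within distance 1 of a 20x[7,3] set."""
    orphans = dx.simulate_orphaned(5000, rng)
    d = dx.min_distances(orphans, bc20)
    assert (d <= 1).mean() == pytest.approx(0.06, abs=0.02)


def test_mixture_counts_and_labels(bc20, insert, rng):
    params = dx.MixtureParams(m=1000, pi1=0.34, error_model=ErrorModel(),
                              insert=insert, barcode_set=bc20)
    assert params.n_barcoded == 340 and params.n_orphaned == 660
    reads = dx.simulate_mixture(params, rng)
    assert len(reads) == 1000
    assert (reads.labels != dx.ORPHANED).sum() == 340
    all_bar = dx.MixtureParams(m=50, pi1=1.0, error_model=ErrorModel(),
                               insert=insert, barcode_set=bc20)
    reads2 = dx.simulate_mixture(all_bar, rng)
    assert (reads2.labels != dx.ORPHANED).all()


def test_mixture_reproducible_and_arrays_path_consistent(bc20, insert):
    params = dx.MixtureParams(m=300, pi1=0.4, error_model=ErrorModel(),
                              insert=insert, barcode_set=bc20)
    a = dx.simulate_mixture(params, np.random.default_rng(7))
    b = dx.simulate_mixture(params, np.random.default_rng(7))
    assert a.sequences == b.sequences
    assert np.array_equal(a.labels, b.labels)
    mat, lengths, labels, _ = dx.read_sim.simulate_mixture_arrays(
        params, np.random.default_rng(7))
    decoded = [seqlev.decode_bases(mat[i, : lengths[i]])
               for i in range(300)]
    assert decoded == a.sequences
    assert np.array_equal(labels, a.labels)


def test_fastq_truth_roundtrip(bc20, insert, rng, tmp_path):
    params = dx.MixtureParams(m=40, pi1=0.5, error_model=ErrorModel(),
                              insert=insert, barcode_set=bc20)
    reads = dx.simulate_mixture(params, rng)
    fq = tmp_path / "reads.fastq"
    reads.to_fastq(fq)
    reads.to_truth_tsv(tmp_path / "truth.tsv", barcode_set=bc20)
    back = dx.ReadSet.from_fastx(fq)
    assert back.sequences == reads.sequences
    assert back.ids == reads.ids
    lines = (tmp_path / "truth.tsv").read_text().splitlines()
    assert lines[0] == "read_id\tlabel\tbarcode_id\terror_rate"
    assert len(lines) == 41
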