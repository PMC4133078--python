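"""Fitting the simulated mixture to an empirical distance profile.

Two estimation stages:

1. The operation-type ratios R = (R_INS, R_DEL, R_SUB) are read off
   reads at minimal distance exactly 1 to the reference set — such
   reads are near-certainly barcoded, and the single edit separating
   them from their nearest reference can be classified directly.
2. The remaining parameters (pi1, mu_error, sigma_error) are found by
   a (mu + lambda) evolution strategy minimizing the RMS Euclidean
   distance between the simulated and empirical distance histograms.

Fitness is stochastic (every evaluation re-simulates a read set), so
common random numbers are used: one simulation seed is fixed for the
whole run and shared by every candidate, making fitness differences
reflect parameters rather than Monte-Carlo noise and making the search
surface deterministic, so the convergence criterion on the best
parameter vector is meaningful.  The residual bias from optimizing one
noise realization is on the order of the sampling error of a single
simulated set, well inside the reported parameter uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seqlev
from .barcode_design import BarcodeSet
from .profile import DistanceProfile, profile_encoded
from .read_sim import (ErrorModel, MixtureParams, ReadSet,
                       simulate_mixture_arrays)

#: Fallback when no distance-1 reads are available.
DEFAULT_RATIOS_UNIFORM = (1 / 3, 1 / 3, 1 / 3)


class EstimationError(RuntimeError):
    pass


def _single_edit_types(ref: str, window: str) -> set[str]:
    """All single-edit explanations of SL distance 1 from ref to window.

    The read window is longer than the reference, so distance 0 means
    "ref is a prefix of window" and distance 1 means the window starts
    with ref altered by exactly one edit:

    * sub: the first |ref| window bases mismatch ref at exactly one
      position;
    * del: ref minus one base is a prefix of the window (a read base
      was dropped);
    * ins: the window minus one of its first |ref|+1 bases starts with
      ref (an extra base was read).
    """
    out: set[str] = set()
    lr = len(ref)
    if len(window) >= lr:
        if sum(a != b for a, b in zip(ref, window[:lr])) == 1:
            out.add("sub")
    for i in range(lr):
        if window.startswith(ref[:i] + ref[i + 1:]):
            out.add("del")
            break
    for i in range(min(lr + 1, len(window))):
        if (window[:i] + window[i + 1:]).startswith(ref):
            out.add("ins")
            break
    return out


def estimate_error_ratios(reads: ReadSet | list[str],
                          ref: BarcodeSet) -> tuple[float, float, float]:
    """Estimate (R_INS, R_DEL, R_SUB) from minimal-distance-1 reads.

    Reads at distance exactly 1 to the (typically primer-extended)
    reference set are selected; for each, the single corrupting edit is
    classified against its nearest reference.  When one edit admits
    several explanations the fixed precedence substitution > deletion >
    insertion applies, so each read is counted once.
    """
    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    if len(seqs) == 0:
        raise EstimationError(
            "no reads given; supply ratios explicitly or use the uniform "
            f"default {DEFAULT_RATIOS_UNIFORM}"
        )
    dmat = seqlev.distance_matrix(seqs, ref.barcodes)
    dmin = dmat.min(axis=1)
    idx = np.flatnonzero(dmin == 1)
    if idx.size == 0:
        raise EstimationError(
            "no reads at minimal distance exactly 1 to the reference set; "
            f"supply ratios explicitly or use the uniform default "
            f"{DEFAULT_RATIOS_UNIFORM}"
        )
    window = 2 * ref.length
    counts = {"ins": 0, "del": 0, "sub": 0}
    for i in idx:
        ref_i = ref.barcodes[int(dmat[i].argmin())]
        w = seqlev.normalize(seqs[int(i)])[:window]
        kinds = _single_edit_types(ref_i, w)
        if "sub" in kinds:
            counts["sub"] += 1
        elif "del" in kinds:
            counts["del"] += 1
        elif "ins" in kinds:
            counts["ins"] += 1
    total = sum(counts.values())
    if total == 0:
        raise EstimationError("edit classification failed for all "
                              "distance-1 reads")
    return (counts["ins"] / total, counts["del"] / total,
            counts["sub"] / total)


def fitness(params: MixtureParams, empirical: DistanceProfile,
            ref: BarcodeSet, rng: np.random.Generator) -> float:
    """RMS distance between a fresh simulated profile and the empirical one.

    The simulated set has the same size m as the empirical profile and
    the RMS is taken over raw bin counts on the full fixed support
    [0, reference length].
    """
    if empirical.total != params.m:
        raise ValueError(
            f"empirical profile total {empirical.total} != params.m {params.m}"
        )
    mat, lengths, labels, _ = simulate_mixture_arrays(params, rng)
    prof = profile_encoded(mat, lengths, labels, ref)
    diff = prof.counts.astype(float) - empirical.counts.astype(float)
    return float(np.sqrt(np.mean(diff ** 2)))


@dataclass
class EvolveOptions:
    """Hyperparameters of the (mu + lambda) evolution strategy."""

    population: int = 20
    offspring: int = 40
    max_generations: int = 60
    # initial Gaussian mutation step per parameter (pi1, mu, sigma)
    steps: tuple[float, float, float] = (0.10, 0.03, 0.015)
    step_decay: float = 0.95
    bounds: tuple = ((0.0, 1.0), (0.0, 0.5), (0.0, 0.2))
    convergence_tol: float = 0.005
    convergence_window: int = 5


@dataclass
class FitResult:
    pi1: float
    mu_error: float
    sigma_error: float
    ratios: tuple[float, float, float]
    fitness: float
    generations_run: int
    converged: bool
    trace: list[dict] = field(default_factory=list)

    def error_model(self) -> ErrorModel:
        return ErrorModel(self.mu_error, self.sigma_error, self.ratios)

    def to_json(self, path) -> None:
        import json

        payload = {
            "pi1": self.pi1,
            "mu_error": self.mu_error,
            "sigma_error": self.sigma_error,
            "ratios": list(self.ratios),
            "fitness": self.fitness,
            "generations_run": self.generations_run,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def trace_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\tbest_fitness\tpi1\tmu_error\tsigma_error\n")
            for row in self.trace:
                fh.write(
                    f"{row['generation']}\t{row['fitness']:.4f}\t"
                    f"{row['pi1']:.4f}\t{row['mu']:.4f}\t{row['sigma']:.4f}\n"
                )


def evolve(empirical: DistanceProfile, ref: BarcodeSet, ratios,
           insert: str, rng: np.random.Generator,
           opts: EvolveOptions | None = None) -> FitResult:
    """Fit (pi1, mu_error, sigma_error) to an empirical profile.

    (mu + lambda) evolution strategy with elitist selection, Gaussian
    mutation with per-generation step decay, and box constraints.  All
    candidates share one simulation seed drawn at the start of the run
    (common random numbers), so parent fitness is cached and the best
    fitness is non-increasing.  Convergence is declared when the best
    parameter vector moves less than ``convergence_tol`` (max absolute
    change) over ``convergence_window`` consecutive generations.
    """
    opts = opts or EvolveOptions()
    ratios = tuple(float(x) for x in ratios)
    m = empirical.total
    lo = np.array([b[0] for b in opts.bounds])
    hi = np.array([b[1] for b in opts.bounds])
    sim_seed = int(rng.integers(0, 2 ** 31))  # common random numbers

    def score(vec: np.ndarray) -> float:
        params = MixtureParams(
            m=m, pi1=float(vec[0]),
            error_model=ErrorModel(float(vec[1]), float(vec[2]), ratios),
            insert=insert, barcode_set=ref,
        )
        return fitness(params, empirical, ref,
                       np.random.default_rng(sim_seed))

    pop = rng.uniform(lo, hi, size=(opts.population, 3))
    pop_fits = np.array([score(v) for v in pop])
    steps = np.array(opts.steps, dtype=float)
    trace: list[dict] = []
    best_prev: np.ndarray | None = None
    stable = 0
    converged = False
    gen = 0
    best_vec = pop[0]
    best_fit = float(pop_fits.min())
    for gen in range(1, opts.max_generations + 1):
        parents_idx = rng.integers(0, len(pop), size=opts.offspring)
        children = pop[parents_idx] + rng.normal(
            0.0, steps, size=(opts.offspring, 3))
        children = np.clip(children, lo, hi)
        cohort = np.vstack([pop, children])
        fits = np.concatenate(
            [pop_fits, [score(v) for v in children]])
        order = np.argsort(fits, kind="stable")
        pop = cohort[order[: opts.population]]
        pop_fits = fits[order[: opts.population]]
        best_vec = pop[0]
        best_fit = float(pop_fits[0])
        trace.append({"generation": gen, "fitness": best_fit,
                      "pi1": float(best_vec[0]), "mu": float(best_vec[1]),
                      "sigma": float(best_vec[2])})
        if best_prev is not None and np.max(np.abs(best_vec - best_prev)) \
                < opts.convergence_tol:
            stable += 1
            if stable >= opts.convergence_window:
                converged = True
                break
        else:
            stable = 0
        best_prev = best_vec.copy()
        steps *= opts.step_decay
    if not converged:
        import warnings

        warnings.warn(
            f"evolution budget of {opts.max_generations} generations "
            "exhausted without convergence", stacklevel=2)
    return FitResult(
        pi1=float(best_vec[0]), mu_error=float(best_vec[1]),
        sigma_error=float(best_vec[2]), ratios=ratios, fitness=best_fit,
        generations_run=gen, converged=converged, trace=trace,
    )
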