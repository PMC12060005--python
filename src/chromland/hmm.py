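"""Chromatin-state inference: Poisson binarization, Bernoulli-emission HMM,
state-number selection by emission-correlation plateau, and decoding.

The model is the ChromHMM-family one: each 200-bp genome bin carries a 0/1
call per histone mark; hidden states emit the marks as independent
Bernoulli draws; the state sequence is a first-order Markov chain per
chromosome.  Learning is Baum-Welch EM with restarts; decoding is
max-posterior by default (Viterbi behind a flag).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import poisson

from ._hmmcore import forward_backward, viterbi
from .core import BinnedTrack, GenomeModel, Interval

log = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class BinarizationConfig:
    """Poisson upper-tail binarization at significance ``alpha``.

    ``strict`` keeps the exact tail criterion with no fold-change
    fallback (the only mode implemented).
    """

    bin_size: int = 200
    alpha: float = 1e-4
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def poisson_threshold(lam: float, alpha: float) -> int:
    """Smallest integer c with P(X >= c | lam) < alpha for X ~ Poisson(lam).

    A bin is called present when its count reaches this threshold.
    """
    if lam <= 0:
        return 1  # degenerate: any positive count would be called, none occur
    # sf(c - 1) = P(X >= c); search upward from the mean
    c = max(1, int(lam))
    while poisson.sf(c - 1, lam) >= alpha:
        c += 1
    while c > 1 and poisson.sf(c - 2, lam) < alpha:
        c -= 1
    return c


def binarize(
    track: BinnedTrack, config: BinarizationConfig | None = None
) -> dict[str, np.ndarray]:
    """Binary present/absent call per bin for one mark/sample.

    The rate is the genome-wide mean count per bin for this track; a bin is
    1 iff its count meets the exact Poisson upper-tail threshold at alpha.
    """
    config = config or BinarizationConfig()
    lam = track.total() / track.n_bins() if track.n_bins() else 0.0
    if lam == 0:
        warnings.warn(f"all-zero track {track.mark}: binarized to all zeros")
        return {c: np.zeros(len(v), dtype=np.uint8) for c, v in track.values.items()}
    thr = poisson_threshold(lam, config.alpha)
    return {c: (v >= thr).astype(np.uint8) for c, v in track.values.items()}


@dataclass
class BinaryMatrix:
    """Bins x marks 0/1 observations with a (chrom, start) bin index."""

    mark_names: list[str]
    bin_size: int
    chrom_arrays: dict[str, np.ndarray]  # each (n_bins, n_marks) uint8

    def __post_init__(self) -> None:
        for chrom, arr in self.chrom_arrays.items():
            arr = np.asarray(arr, dtype=np.uint8)
            if arr.ndim != 2 or arr.shape[1] != len(self.mark_names):
                raise ValueError(f"{chrom}: expected (bins, {len(self.mark_names)})")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{chrom}: entries must be 0/1")
            self.chrom_arrays[chrom] = arr

    @property
    def n_bins(self) -> int:
        return sum(a.shape[0] for a in self.chrom_arrays.values())

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)


def binarize_tracks(
    tracks: dict[str, BinnedTrack], config: BinarizationConfig | None = None
) -> BinaryMatrix:
    """Stack per-mark binarizations into one matrix (marks in dict order)."""
    config = config or BinarizationConfig()
    marks = list(tracks)
    columns = {m: binarize(tracks[m], config) for m in marks}
    chroms = list(next(iter(columns.values())))
    chrom_arrays = {
        c: np.stack([columns[m][c] for m in marks], axis=1) for c in chroms
    }
    first = tracks[marks[0]]
    return BinaryMatrix(
        mark_names=marks, bin_size=first.bin_size, chrom_arrays=chrom_arrays
    )


@dataclass
class HMMModel:
    """K-state hidden Markov model with independent Bernoulli emissions."""

    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K)
    emissionprob: np.ndarray  # (K, M)
    mark_names: list[str] = field(default_factory=list)
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.emissionprob = np.asarray(self.emissionprob, dtype=float)
        K = self.n_states
        if self.transmat.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if abs(self.startprob.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any((self.emissionprob < 0) | (self.emissionprob > 1)):
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def state_labels(self) -> list[str]:
        return [f"E{k + 1}" for k in range(self.n_states)]


def _framelik(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """(T, K) Bernoulli product likelihoods for binary rows X."""
    Ec = np.clip(E, _EPS, 1 - _EPS)
    logodds = np.log(Ec / (1 - Ec))  # (K, M)
    base = np.log(1 - Ec).sum(axis=1)  # (K,)
    return np.exp(X.astype(float) @ logodds.T + base)


def _init_params(
    X_all: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed emissions from random observed bin patterns, softened; this
    spreads initial states over the patterns actually present."""
    M = X_all.shape[1]
    rows = X_all[rng.integers(0, len(X_all), size=K)].astype(float)
    E = rows * 0.6 + 0.2 + rng.uniform(-0.05, 0.05, size=(K, M))
    E = np.clip(E, 0.05, 0.95)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    return pi, A, E


def fit_hmm(
    binmat: BinaryMatrix,
    n_states: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> HMMModel:
    """Baum-Welch EM fit, best of ``n_restarts`` random initialisations.

    The per-iteration log-likelihood is non-decreasing (EM guarantee);
    convergence is declared when the relative improvement drops below
    ``tol``.  When ``init`` (pi, A, E) is given it replaces the random
    restarts and a single EM run refines it.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states > binmat.n_bins:
        raise ValueError("more states than bins")
    sequences = [a for a in binmat.chrom_arrays.values() if a.shape[0] > 0]
    X_all = np.concatenate(sequences, axis=0)
    rng = np.random.default_rng(seed)
    best: HMMModel | None = None
    for _restart in range(1 if init is not None else max(1, n_restarts)):
        if init is not None:
            pi, A, E = (np.array(x, dtype=float) for x in init)
        else:
            pi, A, E = _init_params(X_all, n_states, rng)
        prev_ll = -np.inf
        for _it in range(max_iter):
            ll = 0.0
            pi_acc = np.zeros(n_states)
            xi_acc = np.zeros((n_states, n_states))
            e_num = np.zeros_like(E)
            e_den = np.zeros(n_states)
            for X in sequences:
                fl = _framelik(X, E)
                seq_ll, gamma, xi = forward_backward(fl, pi, A)
                ll += seq_ll
                pi_acc += gamma[0]
                xi_acc += xi
                e_num += gamma.T @ X
                e_den += gamma.sum(axis=0)
            pi = pi_acc / pi_acc.sum()
            if n_states == 1:
                A = np.ones((1, 1))
            else:
                rows = xi_acc.sum(axis=1, keepdims=True)
                A = np.where(rows > 0, xi_acc / np.maximum(rows, 1e-300), A)
                A = np.clip(A, 1e-10, None)
                A /= A.sum(axis=1, keepdims=True)
            E = e_num / np.maximum(e_den[:, None], 1e-300)
            E = np.clip(E, _EPS, 1 - _EPS)
            if ll - prev_ll < tol * abs(ll) and _it > 0:
                prev_ll = ll
                break
            prev_ll = ll
        model = HMMModel(
            startprob=pi,
            transmat=A,
            emissionprob=E,
            mark_names=binmat.mark_names,
            log_likelihood=prev_ll,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def log_likelihood(model: HMMModel, binmat: BinaryMatrix) -> float:
    """Total scaled-forward log-likelihood of the data under the model."""
    total = 0.0
    for X in binmat.chrom_arrays.values():
        if X.shape[0] == 0:
            continue
        fl = _framelik(X, model.emissionprob)
        ll, _, _ = forward_backward(fl, model.startprob, model.transmat)
        total += ll
    return total


def emission_correlation(e1: np.ndarray, e2: np.ndarray) -> float:
    """Pearson correlation of two emission vectors.

    Below a small variance floor Pearson only reflects fitting noise, so
    near-flat vectors are matched by absolute closeness instead: two flat
    profiles are redundant (1.0), a flat and a structured one are not
    (0.0).
    """
    s1, s2 = np.std(e1), np.std(e2)
    if s1 < 0.02 or s2 < 0.02:
        return 1.0 if np.max(np.abs(e1 - e2)) < 0.05 else 0.0
    return float(np.corrcoef(e1, e2)[0, 1])


def match_states(
    emissions_a: np.ndarray, emissions_b: np.ndarray
) -> np.ndarray:
    """Optimal one-to-one state matching (a -> b) maximising total emission
    correlation; used to undo label switching before scoring recovery."""
    Ka, Kb = len(emissions_a), len(emissions_b)
    corr = np.array(
        [
            [emission_correlation(emissions_a[i], emissions_b[j]) for j in range(Kb)]
            for i in range(Ka)
        ]
    )
    _, cols = linear_sum_assignment(-corr)
    return cols


@dataclass
class SelectionResult:
    chosen_k: int
    curve: dict[int, float]
    models: dict[int, HMMModel]
    plateau: float


def stationary_distribution(transmat: np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(transmat.T)
    i = int(np.argmin(np.abs(vals - 1)))
    w = np.abs(np.real(vecs[:, i]))
    return w / w.sum()


def _merge_closest_states(model: HMMModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pi, A, E) for a (K-1)-state model obtained by merging the two
    states with the most correlated emission vectors, occupancy-weighted."""
    K = model.n_states
    E = model.emissionprob
    best, pair = -np.inf, (0, 1)
    for i in range(K):
        for j in range(i + 1, K):
            c = emission_correlation(E[i], E[j])
            if c > best:
                best, pair = c, (i, j)
    i, j = pair
    w = stationary_distribution(model.transmat)
    keep = [k for k in range(K) if k != j]
    wi, wj = w[i], w[j]
    E_new = E[keep].copy()
    E_new[keep.index(i)] = (wi * E[i] + wj * E[j]) / (wi + wj)
    A = model.transmat
    A_new = A[np.ix_(keep, keep)].copy()
    A_new[:, keep.index(i)] += A[keep, j]
    A_new[keep.index(i)] = (wi * A[i, keep] + wj * A[j, keep]) / (wi + wj)
    A_new[keep.index(i), keep.index(i)] += (wi * A[i, j] + wj * A[j, j]) / (wi + wj)
    A_new = np.clip(A_new, 1e-10, None)
    A_new /= A_new.sum(axis=1, keepdims=True)
    pi_new = model.startprob[keep].copy()
    pi_new[keep.index(i)] += model.startprob[j]
    return pi_new, A_new, E_new


def select_state_number(
    binmat: BinaryMatrix,
    k_min: int = 2,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 5,
    plateau: float = 0.99,
    max_iter: int = 200,
) -> SelectionResult:
    """Choose the state number by the median emission-correlation curve.

    The richest model (K = k_max) is fitted with random restarts; each
    simpler model is then fitted by agglomerative initialisation - the
    (K+1)-state model with its two most-correlated states merged, refined
    by EM - so the nested family degrades gracefully as states are
    removed.  For each simpler K, every state of the richest model is
    matched to the simpler model's maximum-Pearson-correlation state
    (correlating emission vectors); the median of those maxima forms the
    curve.  The chosen K is the smallest whose median reaches ``plateau``
    - beyond it, extra states only duplicate existing emission profiles.
    """
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    models: dict[int, HMMModel] = {}
    models[k_max] = fit_hmm(
        binmat, k_max, seed=seed + 1000 * k_max, n_restarts=n_restarts,
        max_iter=max_iter,
    )
    for k in range(k_max - 1, k_min - 1, -1):
        init = _merge_closest_states(models[k + 1])
        models[k] = fit_hmm(binmat, k, init=init, max_iter=max_iter)
    rich = models[k_max].emissionprob
    curve: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        E = models[k].emissionprob
        maxima = [
            max(emission_correlation(rich[i], E[j]) for j in range(k))
            for i in range(len(rich))
        ]
        curve[k] = float(np.median(maxima))
    chosen = next((k for k in sorted(curve) if curve[k] >= plateau), k_max)
    return SelectionResult(chosen_k=chosen, curve=curve, models=models, plateau=plateau)


@dataclass
class Segmentation:
    """State-labelled intervals tiling each chromosome (merged runs)."""

    intervals: list[tuple[Interval, int]]  # (interval, 1-based state id)
    n_states: int
    bin_size: int
    bin_states: dict[str, np.ndarray] = field(default_factory=dict)

    def state_label(self, state: int) -> str:
        return f"E{state}"


def posterior_states(model: HMMModel, X: np.ndarray) -> np.ndarray:
    """Per-bin argmax-posterior states (ties break to the lower index)."""
    fl = _framelik(X, model.emissionprob)
    _, gamma, _ = forward_backward(fl, model.startprob, model.transmat)
    return gamma.argmax(axis=1)


def segment(
    model: HMMModel,
    binmat: BinaryMatrix,
    genome: GenomeModel | None = None,
    algorithm: str = "posterior",
) -> Segmentation:
    """Decode a genome segmentation from a fitted model.

    ``posterior`` (default) assigns each bin its max-marginal state from
    forward-backward; ``viterbi`` uses the single best path.  Adjacent
    same-state bins merge into one interval; intervals are clipped to the
    chromosome end when the genome is known.
    """
    if model.emissionprob.shape[1] != binmat.n_marks:
        raise ValueError("model/mark dimension mismatch")
    intervals: list[tuple[Interval, int]] = []
    bin_states: dict[str, np.ndarray] = {}
    for chrom, X in binmat.chrom_arrays.items():
        if X.shape[0] == 0:
            warnings.warn(f"chromosome {chrom} has no bins; skipped")
            continue
        if algorithm == "viterbi":
            Ec = np.clip(model.emissionprob, _EPS, 1 - _EPS)
            lfl = X.astype(float) @ np.log(Ec / (1 - Ec)).T + np.log(1 - Ec).sum(1)
            path = viterbi(
                lfl,
                np.log(np.clip(model.startprob, 1e-300, None)),
                np.log(np.clip(model.transmat, 1e-300, None)),
            )
        else:
            path = posterior_states(model, X)
        bin_states[chrom] = path
        length = genome.chrom_length(chrom) if genome else len(path) * binmat.bin_size
        i = 0
        while i < len(path):
            j = i
            while j + 1 < len(path) and path[j + 1] == path[i]:
                j += 1
            start = i * binmat.bin_size
            end = min((j + 1) * binmat.bin_size, length)
            intervals.append((Interval(chrom, start, end), int(path[i]) + 1))
            i = j + 1
    return Segmentation(
        intervals=intervals,
        n_states=model.n_states,
        bin_size=binmat.bin_size,
        bin_states=bin_states,
    )


def write_model(model: HMMModel, path) -> None:
    """Plain-text, diff-friendly model serialization."""
    with open(path, "w") as fh:
        fh.write(f"n_states\t{model.n_states}\n")
        fh.write("marks\t" + "\t".join(model.mark_names) + "\n")
        fh.write("startprob\t" + "\t".join(f"{v:.10g}" for v in model.startprob) + "\n")
        for row in model.transmat:
            fh.write("trans\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        for row in model.emissionprob:
            fh.write("emit\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_model(path) -> HMMModel:
    trans, emit, pi, marks = [], [], None, []
    with open(path) as fh:
        for line in fh:
            key, *vals = line.rstrip("\n").split("\t")
            if key == "marks":
                marks = vals
            elif key == "startprob":
                pi = np.array(vals, dtype=float)
            elif key == "trans":
                trans.append(np.array(vals, dtype=float))
            elif key == "emit":
                emit.append(np.array(vals, dtype=float))
    return HMMModel(
        startprob=pi,
        transmat=np.array(trans),
        emissionprob=np.array(emit),
        mark_names=marks,
    )
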