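"""Poisson-emission hidden Markov model for homozygosity-block calling.

The panel's residual heterozygosity is strongly bimodal at the 10-kb window
scale: windows inside autozygous runs carry essentially zero heterozygous
SNPs (genotyping error only), while windows in not-yet-fixed regions carry
counts proportional to the founder population's diversity.  A K-state HMM
with Poisson emissions, trained jointly on the windowed heterozygous-SNP
counts of every line (shared parameters, one hidden chain per line per
chromosome), separates these regimes; the Viterbi path of each line then
yields its homozygous/heterozygous block structure.  K=2 is used genome-wide;
K=4 gives the finer-grained view used to refine the obligate-heterozygous
sex-determining region.

All recursions run in log space.  States are always relabelled by ascending
emission rate, so state 0 is the most homozygous regardless of
initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_variants import WindowCounts, WindowGrid

LAMBDA_FLOOR = 1e-3


@dataclass
class PoissonHMMParams:
    """HMM parameters: initial distribution, transitions, Poisson rates.

    ``lam`` is sorted ascending so state 0 is the most homozygous state
    (lowest expected heterozygous-SNP count per window).
    """

    pi0: np.ndarray
    A: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        K = self.K
        if self.A.shape != (K, K) or self.lam.shape != (K,):
            raise ValueError("inconsistent parameter shapes")
        if abs(self.pi0.sum() - 1) > 1e-9 or np.abs(self.A.sum(1) - 1).max() > 1e-9:
            raise ValueError("pi0 and each row of A must sum to 1")
        if (self.lam <= 0).any():
            raise ValueError("emission rates must be strictly positive")
        if (np.diff(self.lam) < 0).any():
            raise ValueError("emission rates must be sorted ascending")

    @property
    def K(self) -> int:
        return len(self.pi0)

    def relabelled(self) -> "PoissonHMMParams":
        """Return a copy with states sorted by ascending emission rate."""
        order = np.argsort(self.lam, kind="stable")
        return PoissonHMMParams(self.pi0[order], self.A[np.ix_(order, order)],
                                self.lam[order])

    def to_report(self) -> str:
        lines = [f"K = {self.K}",
                 "lam = " + " ".join(f"{x:.6g}" for x in self.lam),
                 "pi0 = " + " ".join(f"{x:.6g}" for x in self.pi0)]
        for k in range(self.K):
            lines.append(f"A[{k}] = " + " ".join(f"{x:.6g}" for x in self.A[k]))
        return "\n".join(lines) + "\n"


@dataclass
class StatePath:
    """Decoded per-window states for one line on a window grid."""

    line_id: str
    grid: WindowGrid
    states: np.ndarray  # flat window axis, aligned with grid

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (self.grid.total_windows,):
            raise ValueError("state path length does not match grid")

    def per_chromosome(self) -> dict[str, np.ndarray]:
        off = self.grid.window_offsets()
        return {c: self.states[off[c]:off[c] + self.grid.n_windows(c)]
                for c in self.grid.chroms}


@dataclass
class BlockSet:
    """Run-length-encoded state blocks per line.

    ``blocks`` has columns line, chrom, start, end, state, n_windows with
    0-based half-open coordinates; adjacent blocks of a line on a chromosome
    always differ in state, and the blocks tile the grid span exactly.
    """

    blocks: pd.DataFrame = field(default_factory=pd.DataFrame)

    def for_line(self, line_id: str) -> pd.DataFrame:
        return self.blocks[self.blocks["line"] == line_id].reset_index(drop=True)

    def to_bed(self, path, line_id: str | None = None) -> None:
        df = self.blocks if line_id is None else self.for_line(line_id)
        out = df[["chrom", "start", "end"]].copy()
        out["name"] = np.where(df["state"] == 0, "hom", "het_state" + df["state"].astype(str))
        if line_id is None:
            out["line"] = df["line"].to_numpy()
        out.to_csv(path, sep="\t", header=False, index=False)


def _poisson_logpmf(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log P(c | lam_k) for counts (...,) against each state: shape (..., K)."""
    c = np.asarray(counts, dtype=float)[..., None]
    lam = np.asarray(lam, dtype=float)
    return c * np.log(lam) - lam - gammaln(c + 1.0)


def _stack_sequences(wc: WindowCounts) -> list[np.ndarray]:
    """All per-line per-chromosome count sequences, grouped by length.

    Returns a list of (n_seq, T) arrays; every line x chromosome combination
    contributes one row somewhere.
    """
    groups: dict[int, list[np.ndarray]] = {}
    for arr in wc.per_chromosome().values():
        groups.setdefault(arr.shape[1], []).append(arr)
    return [np.concatenate(v, axis=0) for _, v in sorted(groups.items())]


def _forward_backward_batch(seqs: np.ndarray, params: PoissonHMMParams):
    """Log-space forward-backward for a batch of equal-length sequences.

    Returns (loglik per sequence, gamma (N,T,K), xi_sum (N,K,K)).
    """
    N, T = seqs.shape
    K = params.K
    with np.errstate(divide="ignore"):  # structural zeros in A are legal
        log_pi = np.log(params.pi0)
        log_A = np.log(params.A)
    log_b = _poisson_logpmf(seqs, params.lam)  # (N, T, K)

    log_alpha = np.empty((N, T, K))
    log_alpha[:, 0] = log_pi + log_b[:, 0]
    for t in range(1, T):
        # (N, K_prev, 1) + (K_prev, K) -> logsumexp over prev
        log_alpha[:, t] = logsumexp(log_alpha[:, t - 1, :, None] + log_A, axis=1) + log_b[:, t]
    loglik = logsumexp(log_alpha[:, -1], axis=1)

    log_beta = np.zeros((N, T, K))
    for t in range(T - 2, -1, -1):
        log_beta[:, t] = logsumexp(log_A[None] + (log_b[:, t + 1] + log_beta[:, t + 1])[:, None, :],
                                   axis=2)

    log_gamma = log_alpha + log_beta - loglik[:, None, None]
    gamma = np.exp(log_gamma)

    xi_sum = np.zeros((N, K, K))
    if T > 1:
        log_xi = (log_alpha[:, :-1, :, None] + log_A[None, None]
                  + (log_b[:, 1:] + log_beta[:, 1:])[:, :, None, :]
                  - loglik[:, None, None, None])
        xi_sum = np.exp(log_xi).sum(axis=1)
    if not np.isfinite(loglik).all():
        raise FloatingPointError("HMM forward pass underflowed despite log-space recursion")
    return loglik, gamma, xi_sum


def _init_params(counts_pool: np.ndarray, K: int, seed: int | None) -> PoissonHMMParams:
    """Quantile-based initialization of the emission rates.

    K=2 starts from the 25th / 97.5th percentiles of the pooled counts
    (separating the homozygous mass from the residual-heterozygosity tail);
    larger K uses evenly spaced quantiles.  Transitions start sticky
    (stay probability 0.99), the initial distribution uniform.
    """
    rng = np.random.default_rng(seed)
    if K == 2:
        qs = np.array([25.0, 97.5])
    else:
        qs = np.linspace(10.0, 97.5, K)
    lam = np.percentile(counts_pool, qs).astype(float)
    lam = np.maximum(lam, LAMBDA_FLOOR)
    # break exact ties between initial rates so states can differentiate
    for k in range(1, K):
        if lam[k] <= lam[k - 1]:
            lam[k] = lam[k - 1] * (1.5 + 0.1 * rng.random()) + 0.5
    A = np.full((K, K), 0.01 / max(K - 1, 1))
    np.fill_diagonal(A, 0.99)
    A /= A.sum(1, keepdims=True)
    pi0 = np.full(K, 1.0 / K)
    return PoissonHMMParams(pi0, A, lam)


def fit_poisson_hmm(wc: WindowCounts, K: int = 2, init: PoissonHMMParams | None = None,
                    max_iter: int = 500, tol: float = 1e-6, seed: int | None = 0,
                    ) -> tuple[PoissonHMMParams, np.ndarray]:
    """Fit the K-state Poisson HMM jointly over all lines by Baum-Welch EM.

    Every line x chromosome count sequence is an independent realization of
    one shared hidden chain (parameters are pooled across the panel;
    chromosomes restart from the initial distribution).  Returns the fitted
    parameters (states sorted by ascending rate) and the log-likelihood
    trace, which is non-decreasing by the EM guarantee.
    """
    if K < 2:
        raise ValueError("need at least 2 states")
    pool = wc.counts.ravel()
    if (pool < 0).any():
        raise ValueError("counts must be non-negative")
    if len(np.unique(pool)) < K and not (pool == 0).all():
        warnings.warn(f"fewer than K={K} distinct count values; fit may be degenerate",
                      stacklevel=2)
    if (pool == 0).all():
        warnings.warn("all counts are zero; returning floor emission rates", stacklevel=2)
        params = _init_params(pool, K, seed)
        lam = LAMBDA_FLOOR * (1.0 + np.arange(K))
        params = PoissonHMMParams(params.pi0, params.A, lam)
        return params, np.array([])

    params = init if init is not None else _init_params(pool, K, seed)
    batches = _stack_sequences(wc)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        total_ll = 0.0
        g_sum = np.zeros(K)            # sum of gamma over all windows
        gc_sum = np.zeros(K)           # sum of gamma * count
        xi_tot = np.zeros((K, K))
        pi_tot = np.zeros(K)
        n_seq = 0
        for seqs in batches:
            ll, gamma, xi = _forward_backward_batch(seqs, params)
            total_ll += ll.sum()
            g_sum += gamma.sum(axis=(0, 1))
            gc_sum += (gamma * seqs[..., None]).sum(axis=(0, 1))
            xi_tot += xi.sum(axis=0)
            pi_tot += gamma[:, 0].sum(axis=0)
            n_seq += seqs.shape[0]
        trace.append(total_ll)

        lam = np.maximum(gc_sum / np.maximum(g_sum, 1e-300), LAMBDA_FLOOR)
        A = xi_tot / np.maximum(xi_tot.sum(1, keepdims=True), 1e-300)
        # guard rows never visited
        empty = xi_tot.sum(1) <= 0
        A[empty] = 1.0 / K
        pi0 = pi_tot / n_seq
        pi0 = np.maximum(pi0, 1e-300)
        pi0 /= pi0.sum()
        order = np.argsort(lam, kind="stable")
        params = PoissonHMMParams(pi0[order], A[np.ix_(order, order)], lam[order])

        if np.isfinite(prev) and abs(trace[-1] - prev) < tol:
            break
        prev = trace[-1]
    return params, np.asarray(trace)


def _viterbi_single(counts: np.ndarray, params: PoissonHMMParams) -> np.ndarray:
    """Max-probability path for one sequence; ties go to the lower state."""
    T = len(counts)
    K = params.K
    log_b = _poisson_logpmf(counts, params.lam)
    with np.errstate(divide="ignore"):
        log_A = np.log(params.A)
        delta = np.log(params.pi0) + log_b[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + log_A          # (from, to)
        # argmax with ties toward the lower 'from' index
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(K)] + log_b[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def viterbi_decode(params: PoissonHMMParams, wc: WindowCounts, line_id: str) -> StatePath:
    """Viterbi path for one line, each chromosome decoded independently."""
    i = wc.sample_ids.index(line_id)
    pieces = []
    for c in wc.grid.chroms:
        counts = wc.per_chromosome()[c][i]
        pieces.append(_viterbi_single(counts, params))
    return StatePath(line_id, wc.grid, np.concatenate(pieces))


def viterbi_decode_all(params: PoissonHMMParams, wc: WindowCounts) -> list[StatePath]:
    per_chrom = wc.per_chromosome()
    out = []
    for i, line in enumerate(wc.sample_ids):
        states = np.concatenate([_viterbi_single(per_chrom[c][i], params)
                                 for c in wc.grid.chroms])
        out.append(StatePath(line, wc.grid, states))
    return out


def posterior_decode(params: PoissonHMMParams, wc: WindowCounts, line_id: str) -> np.ndarray:
    """Forward-backward state posteriors for one line: (n_windows, K).

    Each window's posteriors sum to 1; chromosomes are independent chains.
    """
    i = wc.sample_ids.index(line_id)
    pieces = []
    for c in wc.grid.chroms:
        counts = wc.per_chromosome()[c][i]
        _, gamma, _ = _forward_backward_batch(counts[None, :], params)
        pieces.append(gamma[0])
    return np.concatenate(pieces, axis=0)


def states_to_blocks(path: StatePath) -> BlockSet:
    """Run-length encode a state path into genomic blocks (BED-exportable)."""
    rows = []
    win = path.grid
    for c, states in path.per_chromosome().items():
        if len(states) == 0:
            continue
        change = np.flatnonzero(np.diff(states)) + 1
        starts_w = np.concatenate([[0], change])
        ends_w = np.concatenate([change, [len(states)]])
        L = win.chrom_lengths[c]
        for s, e in zip(starts_w, ends_w):
            rows.append((path.line_id, c, int(s * win.window_size),
                         int(min(e * win.window_size, L)), int(states[s]), int(e - s)))
    return BlockSet(pd.DataFrame(rows, columns=["line", "chrom", "start", "end",
                                                "state", "n_windows"]))


def blocks_to_states(blocks: BlockSet, grid: WindowGrid, line_id: str) -> StatePath:
    """Inverse of :func:`states_to_blocks` (exact round-trip)."""
    states = np.empty(grid.total_windows, dtype=np.int64)
    off = grid.window_offsets()
    for _, row in blocks.for_line(line_id).iterrows():
        w0 = off[row["chrom"]] + row["start"] // grid.window_size
        states[w0:w0 + row["n_windows"]] = row["state"]
    return StatePath(line_id, grid, states)


def homozygous_fraction(blocks: BlockSet, line_id: str,
                        exclude_chroms: set[str] | None = None,
                        grid: WindowGrid | None = None) -> float:
    """Fraction of the (non-excluded) genome span called state 0 (homozygous)."""
    df = blocks.for_line(line_id)
    if exclude_chroms:
        df = df[~df["chrom"].isin(exclude_chroms)]
    if df.empty:
        raise ValueError("all chromosomes excluded (or line has no blocks)")
    span = (df["end"] - df["start"]).sum()
    hom = (df.loc[df["state"] == 0, "end"] - df.loc[df["state"] == 0, "start"]).sum()
    return float(hom / span)


@dataclass
class HetProportionTrack:
    """Per-window heterozygosity-proportion tracks on one chromosome.

    ``count_based`` is the fraction of lines whose heterozygous-SNP count
    exceeds a threshold; ``weighted`` is the HMM-state-weighted estimate.
    """

    grid: WindowGrid
    chrom: str
    count_based: np.ndarray
    weighted: np.ndarray

    def __post_init__(self) -> None:
        nw = self.grid.n_windows(self.chrom)
        for arr in (self.count_based, self.weighted):
            if arr.shape != (nw,):
                raise ValueError("track length does not match chromosome windows")
            if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
                raise ValueError("track values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        win = self.grid.windows()
        win = win[win["chrom"] == self.chrom].reset_index(drop=True)
        win["prop_count_based"] = self.count_based
        win["prop_weighted"] = self.weighted
        return win


def het_proportion_by_count(wc: WindowCounts, threshold: int = 5) -> np.ndarray:
    """Per-window fraction of lines with count strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (wc.counts > threshold).mean(axis=0)


def state_weights(params: PoissonHMMParams) -> np.ndarray:
    """Min-max-normalized emission rates: weight 0 for the most homozygous
    state, 1 for the most heterozygous."""
    span = params.lam[-1] - params.lam[0]
    if span <= 0:
        raise ValueError("degenerate model: all emission rates equal")
    return (params.lam - params.lam[0]) / span


def het_proportion_weighted(paths: list[StatePath], params: PoissonHMMParams) -> np.ndarray:
    """Per-window mean state weight across lines (states weighted by how
    heterozygous their emission rate is)."""
    w = state_weights(params)
    mat = np.stack([w[p.states] for p in paths])
    return mat.mean(axis=0)


def refine_obligate_het_region(track: HetProportionTrack, min_level: float = 0.8,
                               min_span: int = 200_000,
                               which: str = "weighted") -> tuple[str, int, int] | None:
    """Longest contiguous run of windows with track value >= ``min_level``.

    Returns the run as a 1-based inclusive interval ``(chrom, start, end)``
    provided its span is at least ``min_span`` bp, else None.  Among
    equal-length runs the leftmost is returned.
    """
    values = track.weighted if which == "weighted" else track.count_based
    above = values >= min_level
    best = None  # (length_windows, start_w, end_w)
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if best is None or (j - i) > best[0]:
                best = (j - i, i, j)
            i = j
        else:
            i += 1
    if best is None:
        return None
    ws = track.grid.window_size
    L = track.grid.chrom_lengths[track.chrom]
    start0 = best[1] * ws
    end0 = min(best[2] * ws, L)
    if end0 - start0 < min_span:
        return None
    return (track.chrom, start0 + 1, end0)
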