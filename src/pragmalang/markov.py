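"""Group-level Markov chains over speech acts and their Kullback-Leibler
divergence rate, with a transcript-label permutation test.

Each group's transcripts are pooled into one first-order chain: every
transcript contributes a START -> first-tag transition and its within-
transcript bigrams; transitions never cross transcript boundaries and there
is no END state. Rows are smoothed with a pseudo-count ``alpha`` (default
0.5, a Jeffreys-style prior), which keeps every transition probability
positive so divergences are finite.

The distance between two chains P and Q is the divergence *rate*

    D(P || Q) = sum_i pi_P(i) sum_j P(i,j) ln [ P(i,j) / Q(i,j) ]

— the expected per-step log-likelihood ratio under P, weighted by P's
stationary distribution pi_P. Group order is arbitrary, so the symmetric
mean (D(P||Q) + D(Q||P)) / 2 is used as the test statistic. Significance is
assessed by randomly reassigning transcript-level group labels (group sizes
preserved), which respects within-transcript dependence, with the add-one
permutation p-value (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .transcripts import Speaker, Task, Transcript, participant_tags, EXAMINER_TAGS

__all__ = [
    "START",
    "MarkovChain",
    "KLResult",
    "chain_states",
    "transition_counts",
    "estimate_chain",
    "stationary_distribution",
    "kl_rate",
    "symmetric_kl_rate",
    "permutation_test",
]

START = "START"


def chain_states(task: Task, include_examiner: bool | None = None) -> list[str]:
    """State space for a task: START plus the participant tags, plus the
    examiner tags when speaker-aware (default for conversation)."""
    task = Task(task)
    if include_examiner is None:
        include_examiner = task is Task.CONVERSATION
    states = [START, *participant_tags(task)]
    if include_examiner:
        states += list(EXAMINER_TAGS)
    return states


@dataclass
class MarkovChain:
    states: list[str]
    counts: np.ndarray  # |S| x |S| observed transitions
    P: np.ndarray  # row-stochastic after smoothing
    alpha: float

    def index(self, state: str) -> int:
        return self.states.index(state)


@dataclass
class KLResult:
    forward: float
    reverse: float
    symmetric: float
    p_value: float
    n_permutations: int
    seed: int
    null_distribution: np.ndarray | None = None


def _tag_sequence(t: Transcript, include_examiner: bool) -> list[str]:
    if include_examiner:
        return [u.act for u in t.utterances]
    return [u.act for u in t.participant_utterances()]


def transition_counts(
    t: Transcript,
    states: Sequence[str],
    include_examiner: bool,
) -> np.ndarray:
    """One transcript's transition-count matrix (START -> first tag included)."""
    idx = {s: i for i, s in enumerate(states)}
    seq = _tag_sequence(t, include_examiner)
    C = np.zeros((len(states), len(states)), dtype=np.int64)
    prev = idx[START]
    for tag in seq:
        j = idx[tag]
        C[prev, j] += 1
        prev = j
    return C


def _smooth(counts: np.ndarray, alpha: float) -> np.ndarray:
    k = counts.shape[0]
    if alpha > 0:
        return (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * k)
    row_sums = counts.sum(axis=1, keepdims=True)
    P = np.zeros_like(counts, dtype=float)
    visited = row_sums[:, 0] > 0
    if not visited.all():
        warnings.warn(
            "alpha=0 with unvisited states; rows normalized over visited support",
            stacklevel=3,
        )
    P[visited] = counts[visited] / row_sums[visited]
    P[~visited] = 1.0 / counts.shape[1]
    return P


def estimate_chain(
    transcripts: Sequence[Transcript],
    alpha: float = 0.5,
    include_examiner: bool | None = None,
    pool: Literal["sum", "mean"] = "sum",
) -> MarkovChain:
    """Pooled group chain from a set of same-task transcripts.

    ``pool="sum"`` pools raw transition counts across transcripts (default);
    ``pool="mean"`` averages per-transcript smoothed transition matrices.
    """
    if not transcripts:
        raise ValueError("cannot estimate a chain from an empty group")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    task = Task(transcripts[0].task)
    if any(Task(t.task) is not task for t in transcripts):
        raise ValueError("all transcripts in a group must share a task")
    states = chain_states(task, include_examiner)
    incl = EXAMINER_TAGS[0] in states
    counts = sum(transition_counts(t, states, incl) for t in transcripts)
    if pool == "sum":
        P = _smooth(counts, alpha)
    elif pool == "mean":
        P = np.mean(
            [_smooth(transition_counts(t, states, incl), alpha) for t in transcripts],
            axis=0,
        )
    else:
        raise ValueError(f"unknown pooling mode {pool!r}")
    return MarkovChain(states=states, counts=np.asarray(counts), P=P, alpha=alpha)


def stationary_distribution(
    chain: MarkovChain | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Stationary vector pi (pi P = pi) by power iteration from uniform."""
    P = chain.P if isinstance(chain, MarkovChain) else np.asarray(chain, dtype=float)
    k = P.shape[0]
    pi = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        nxt = pi @ P
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - pi)) < tol:
            return nxt
        pi = nxt
    residual = float(np.max(np.abs(pi @ P - pi)))
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} steps "
        f"(residual {residual:.3e})"
    )


def kl_rate(P: MarkovChain, Q: MarkovChain) -> float:
    """Stationary-weighted per-step divergence D(P || Q), in nats."""
    if P.states != Q.states:
        raise ValueError("state sets differ between chains")
    pi = stationary_distribution(P)
    p, q = P.P, Q.P
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, np.log(np.where(p > 0, p, 1.0) / q), 0.0)
    if np.isinf(ratio).any():
        warnings.warn("Q has zero mass on P's support; divergence is infinite")
        return float("inf")
    return float(pi @ np.sum(p * ratio, axis=1))


def symmetric_kl_rate(P: MarkovChain, Q: MarkovChain) -> float:
    return 0.5 * (kl_rate(P, Q) + kl_rate(Q, P))


def _chain_from_counts(counts: np.ndarray, states: list[str], alpha: float) -> MarkovChain:
    return MarkovChain(states=states, counts=counts, P=_smooth(counts, alpha), alpha=alpha)


def permutation_test(
    group_a: Sequence[Transcript],
    group_b: Sequence[Transcript],
    n_perm: int = 999,
    alpha: float = 0.5,
    seed: int = 0,
    include_examiner: bool | None = None,
    keep_null: bool = False,
) -> KLResult:
    """Transcript-label permutation test on the symmetric divergence rate.

    Group labels are reshuffled across the pooled transcripts with group
    sizes preserved; both chains are re-estimated per permutation.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    task = Task(group_a[0].task)
    states = chain_states(task, include_examiner)
    incl = EXAMINER_TAGS[0] in states
    pooled = list(group_a) + list(group_b)
    if any(Task(t.task) is not task for t in pooled):
        raise ValueError("groups must share a task")
    per_t = np.stack([transition_counts(t, states, incl) for t in pooled])
    n_a = len(group_a)

    def stat(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[float, float]:
        ca = _chain_from_counts(counts_a, states, alpha)
        cb = _chain_from_counts(counts_b, states, alpha)
        return kl_rate(ca, cb), kl_rate(cb, ca)

    fwd, rev = stat(per_t[:n_a].sum(axis=0), per_t[n_a:].sum(axis=0))
    observed = 0.5 * (fwd + rev)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(len(pooled))
    for b in range(n_perm):
        rng.shuffle(idx)
        f, r = stat(per_t[idx[:n_a]].sum(axis=0), per_t[idx[n_a:]].sum(axis=0))
        null[b] = 0.5 * (f + r)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return KLResult(
        forward=fwd,
        reverse=rev,
        symmetric=observed,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        null_distribution=null if keep_null else None,
    )
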