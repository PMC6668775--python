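"""Rescorla-Wagner learning: the iterative rule and its equilibrium solution.

Learning events pair a set of cues with a set of outcomes, weighted by
token frequency.  The iterative delta rule updates cue-outcome association
strengths trial by trial; the equilibrium (Danks) equations give the
asymptotic weights directly as the solution of a linear system driven only
by the conditional probabilities of the event distribution:

    Pr(O_k | C_i) - sum_j Pr(C_j | C_i) V_jk = 0

Outcomes are learned independently of one another (the "naive"
independence assumption), so the system is solved column by column — in
practice as one least-squares solve with a shared coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg


@dataclass(frozen=True)
class RWParams:
    """Learning-rule parameters: asymptote lambda, salience alpha, rates beta."""

    lam: float = 1.0
    alpha: float = 0.1
    beta1: float = 0.1
    beta2: float = 0.1

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        for name in ("beta1", "beta2"):
            b = getattr(self, name)
            if not 0 < b <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {b}")


@dataclass
class EventTable:
    """Frequency-weighted learning events (cue set -> outcome set).

    One event per word type with the token frequency as event weight is
    the canonical construction for lexical training data.
    """

    events: list[tuple[frozenset[str], frozenset[str], int]]
    cues: list[str] = field(init=False)
    outcomes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("EventTable requires at least one event")
        cue_set: set[str] = set()
        out_set: set[str] = set()
        for cues, outs, w in self.events:
            if w < 1:
                raise ValueError(f"event weight must be >= 1, got {w}")
            cue_set.update(cues)
            out_set.update(outs)
        self.cues = sorted(cue_set)
        self.outcomes = sorted(out_set)

    def design_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(events x cues, events x outcomes) indicator matrices and weights."""
        cue_idx = {c: i for i, c in enumerate(self.cues)}
        out_idx = {o: i for i, o in enumerate(self.outcomes)}
        C = np.zeros((len(self.events), len(self.cues)))
        O = np.zeros((len(self.events), len(self.outcomes)))
        w = np.zeros(len(self.events))
        for t, (cues, outs, weight) in enumerate(self.events):
            for c in cues:
                C[t, cue_idx[c]] = 1.0
            for o in outs:
                O[t, out_idx[o]] = 1.0
            w[t] = weight
        return C, O, w


def zero_weights(cues: list[str], outcomes: list[str]) -> pd.DataFrame:
    """All-zero weight matrix with cue rows and outcome columns."""
    return pd.DataFrame(
        np.zeros((len(cues), len(outcomes))), index=list(cues), columns=list(outcomes)
    )


def rw_update(
    weights: pd.DataFrame,
    event: tuple[frozenset[str], frozenset[str]],
    params: RWParams = RWParams(),
) -> pd.DataFrame:
    """One delta-rule update; returns a new weight matrix.

    For every present cue and every outcome, the change is
    alpha*beta1*(lambda - sum V) when the outcome is present and
    alpha*beta2*(0 - sum V) when it is absent, where the sum runs over
    the present cues.  Absent cues are left untouched.
    """
    cues, outs = event
    missing = set(cues) - set(weights.index)
    if missing:
        raise KeyError(f"cues not indexed in weight matrix: {sorted(missing)}")
    missing_o = set(outs) - set(weights.columns)
    if missing_o:
        raise KeyError(f"outcomes not indexed in weight matrix: {sorted(missing_o)}")
    V = weights.to_numpy(copy=True)
    rows = weights.index.get_indexer(sorted(cues))
    present = weights.columns.isin(outs)
    total = V[rows].sum(axis=0)
    rate = np.where(present, params.alpha * params.beta1, params.alpha * params.beta2)
    target = np.where(present, params.lam, 0.0)
    V[rows] += rate * (target - total)
    return pd.DataFrame(V, index=weights.index, columns=weights.columns)


def conditional_probs(events: EventTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conditional probabilities Pr(C_j | C_i) and Pr(O_k | C_i).

    Probabilities are frequency-weighted co-occurrence proportions:
    the total weight of events containing both units divided by the total
    weight of events containing the conditioning cue.
    """
    C, O, w = events.design_matrices()
    Cw = C * w[:, None]
    cue_cooc = Cw.T @ C            # cues x cues, joint weights
    cue_out = Cw.T @ O             # cues x outcomes
    totals = np.diag(cue_cooc).copy()
    if np.any(totals <= 0):
        bad = [events.cues[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"cues with zero total weight: {bad}")
    P_cc = cue_cooc / totals[:, None]
    P_co = cue_out / totals[:, None]
    return (
        pd.DataFrame(P_cc, index=events.cues, columns=events.cues),
        pd.DataFrame(P_co, index=events.cues, columns=events.outcomes),
    )


def equilibrium_residual(events: EventTable, weights: pd.DataFrame) -> float:
    """Max absolute residual of the equilibrium equations under ``weights``."""
    P_cc, P_co = conditional_probs(events)
    V = weights.loc[events.cues, events.outcomes].to_numpy()
    res = P_co.to_numpy() - P_cc.to_numpy() @ V
    return float(np.abs(res).max())


def solve_equilibrium(events: EventTable, tol: float = 1e-8) -> pd.DataFrame:
    """Asymptotic Rescorla-Wagner weights from the equilibrium equations.

    The equilibrium conditions Pr(O_k|C_i) = sum_j Pr(C_j|C_i) V_jk are
    the normal equations of the frequency-weighted event-level
    least-squares problem, G V = T with G = X'WX / sum(W) and
    T = X'WY / sum(W) (X, Y the event-by-cue and event-by-outcome
    indicators, W the event weights).  G is inverted through its
    symmetric eigendecomposition with small eigenvalues (relative
    threshold 1e-9) truncated: on rank-deficient systems (perfectly
    correlated cues) this yields the minimum-norm solution — the fixed
    point the iterative delta rule reaches from zero initial weights.
    Because eigenspace projectors of the block-diagonal co-occurrence
    structure are themselves block-diagonal, cues disconnected from an
    outcome carry (numerically) zero weight.  On full-rank systems a
    residual above ``tol`` raises.
    """
    C, O, w = events.design_matrices()
    total = w.sum()
    Cw = C * w[:, None]
    G = (Cw.T @ C) / total
    T = (Cw.T @ O) / total
    lam, U = scipy.linalg.eigh(G)
    keep = lam > 1e-9 * lam[-1]
    inv = np.where(keep, 1.0 / np.where(keep, lam, 1.0), 0.0)
    V = (U * inv) @ (U.T @ T)
    if bool(keep.all()):
        residual = float(np.abs(T - G @ V).max())
        if residual > tol:
            raise RuntimeError(
                f"equilibrium solve failed on full-rank system: "
                f"residual {residual:.3e} > tol {tol:.0e}"
            )
    return pd.DataFrame(V, index=events.cues, columns=events.outcomes)


def simulate_learning(
    events: EventTable,
    params: RWParams = RWParams(),
    n_trials: int = 10_000,
    seed: int = 0,
    tail_average: int = 0,
) -> pd.DataFrame:
    """Iterative Rescorla-Wagner learning over sampled trials.

    Events are sampled with probability proportional to their weight from
    a seeded generator; the delta rule is applied once per trial.  Serves
    as the independent slow-route check of the equilibrium solution.

    With a constant learning rate the trajectory fluctuates around the
    fixed point; ``tail_average > 0`` returns the mean of the last that
    many per-trial weight states (Polyak averaging), which estimates the
    same fixed point with much lower variance than the final snapshot.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if tail_average > n_trials:
        raise ValueError("tail_average cannot exceed n_trials")
    C, O, w = events.design_matrices()
    rng = np.random.default_rng(seed)
    V = np.zeros((len(events.cues), len(events.outcomes)))
    if n_trials == 0:
        return pd.DataFrame(V, index=events.cues, columns=events.outcomes)
    probs = w / w.sum()
    order = rng.choice(len(events.events), size=n_trials, p=probs)
    cue_rows = [np.flatnonzero(C[t]) for t in range(len(events.events))]
    out_vecs = [O[t] for t in range(len(events.events))]
    ab1 = params.alpha * params.beta1
    ab2 = params.alpha * params.beta2
    lam = params.lam
    acc = np.zeros_like(V)
    tail_start = n_trials - tail_average
    for k, t in enumerate(order):
        rows = cue_rows[t]
        o = out_vecs[t]
        total = V[rows].sum(axis=0)
        V[rows] += np.where(o > 0, ab1 * (lam - total), ab2 * (0.0 - total))
        if tail_average and k >= tail_start:
            acc += V
    out = acc / tail_average if tail_average else V
    return pd.DataFrame(out, index=events.cues, columns=events.outcomes)


def activation(
    weights: pd.DataFrame, active_cues, backoff: float = 0.01
) -> pd.Series:
    """Summed association strength of every outcome given the active cues.

    Cues absent from the weight matrix contribute nothing; a small
    back-off constant is added to every activation, which keeps later
    multiplicative latency formulas away from division by zero.
    """
    if backoff < 0:
        raise ValueError("backoff must be >= 0")
    known = [c for c in active_cues if c in weights.index]
    if not known:
        acts = np.full(weights.shape[1], backoff)
    else:
        rows = weights.index.get_indexer(sorted(known))
        acts = weights.to_numpy()[rows].sum(axis=0) + backoff
    return pd.Series(acts, index=weights.columns)
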