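"""Stochastic character mapping (SIMMAP-style).

Full character histories are drawn conditional on the tip data and a fixed
generator Q: node states are sampled from their joint conditional
distribution (root first, then each child given its parent against the
downward partial likelihoods), and each branch path is drawn from the CTMC
conditioned on its endpoints by uniformization - the dominated-Poisson
construction, which is exact for any Q and branch length.  Transition
counts across a set of maps give the mapped number of origins and losses
with a 2.5-97.5% quantile interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np

from .mk import _down_pass, _root_weights, _tip_partials, transition_matrices
from .tree import Phylogeny

__all__ = [
    "BranchHistory",
    "StochasticMap",
    "StochasticMapSet",
    "TransitionCountSummary",
    "sample_maps",
    "count_transitions",
    "origins_and_losses",
    "node_state_frequencies",
]

MAX_RETRIES = 10_000


@dataclass
class BranchHistory:
    """Piecewise-constant state path along one branch.

    ``segments`` is an ordered list of (state index, dwell duration); dwell
    durations sum to the branch length, consecutive states differ, the first
    state is the parent-node state and the last the child-node state.
    """

    segments: list

    @property
    def n_changes(self) -> int:
        return len(self.segments) - 1

    def duration(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass
class StochasticMap:
    node_states: np.ndarray  # state index per node
    branch_histories: dict   # child node -> BranchHistory
    counts: np.ndarray       # (k, k) transitions tallied over the whole tree

    def dwell_times(self, k: int) -> np.ndarray:
        out = np.zeros(k)
        for h in self.branch_histories.values():
            for s, d in h.segments:
                out[s] += d
        return out


@dataclass
class StochasticMapSet:
    maps: list
    states: tuple
    Q: np.ndarray
    seed: int

    def __len__(self):
        return len(self.maps)

    def count_array(self) -> np.ndarray:
        """(n_maps, k, k) stacked transition-count matrices."""
        return np.stack([m.counts for m in self.maps])


# -- endpoint-conditioned path sampling ------------------------------------

class _Uniformizer:
    """Caches R = I + Q/Omega and its powers for repeated path draws."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.k = Q.shape[0]
        self.omega = float(max(-np.diag(Q).min(), 0.0)) * 1.0000001
        if self.omega > 0:
            self.R = np.eye(self.k) + Q / self.omega
        else:
            self.R = np.eye(self.k)
        self._powers = [np.eye(self.k), self.R.copy()]

    def power(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def sample_n_jumps(self, a: int, b: int, t: float, p_ab: float,
                       rng) -> int:
        """Number of uniformized jumps given endpoints a -> b over t."""
        mu = self.omega * t
        if mu == 0:
            if a != b:
                raise RuntimeError("zero-rate branch with differing endpoints")
            return 0
        n_max = int(mu + 12.0 * np.sqrt(mu) + 60)
        logpois = np.array([-mu + n * log(mu) - lgamma(n + 1)
                            for n in range(n_max + 1)])
        rab = np.array([self.power(n)[a, b] for n in range(n_max + 1)])
        w = np.exp(logpois) * np.clip(rab, 0.0, None)
        tot = w.sum()
        if tot <= 0:
            raise RuntimeError(f"endpoint-conditioned sampling failed ({a}->{b}, t={t})")
        return int(rng.choice(n_max + 1, p=w / tot))

    def sample_path(self, a: int, b: int, t: float, p_ab: float, rng) -> BranchHistory:
        n = self.sample_n_jumps(a, b, t, p_ab, rng)
        states = [a]
        for j in range(1, n + 1):
            prev = states[-1]
            w = self.R[prev] * self.power(n - j)[:, b]
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError("jump-chain sampling failed")
            states.append(int(rng.choice(self.k, p=w / tot)))
        if n > 0 and states[-1] != b:
            raise RuntimeError("jump chain did not reach required endpoint")
        times = np.sort(rng.uniform(0.0, t, size=n))
        # collapse virtual (self) jumps into dwell segments
        segments = []
        cur, t0 = a, 0.0
        for s, tj in zip(states[1:], times):
            if s != cur:
                segments.append((cur, tj - t0))
                cur, t0 = s, tj
        segments.append((cur, t - t0))
        return BranchHistory(segments)


def sample_maps(tree: Phylogeny, tips: dict, Q: np.ndarray, n_maps: int,
                seed: int, root="equal", states=None) -> StochasticMapSet:
    """Draw ``n_maps`` full character histories conditional on tip data.

    Polymorphic or missing tips get a state drawn per map from their
    conditional distribution restricted to the allowed set.  Deterministic
    given ``seed``.
    """
    if n_maps < 1:
        raise ValueError("n_maps >= 1 required")
    if states is None:
        states = tuple(range(Q.shape[0]))
    k = len(states)
    rng = np.random.default_rng(seed)

    P = transition_matrices(Q, tree.blen)
    L = _tip_partials(tree, tips, states)
    partial, logscale, _ = _down_pass(tree, L, P)
    if partial is None:
        raise ValueError("tip data impossible under this Q")
    r = tree.root
    uni = _Uniformizer(Q)
    pre = tree.preorder()

    maps = []
    for _ in range(n_maps):
        node_states = np.empty(tree.n_nodes, dtype=np.int64)
        w = _root_weights(root, partial[r], Q, states) * partial[r]
        w = w / w.sum()
        node_states[r] = rng.choice(k, p=w)
        histories = {}
        counts = np.zeros((k, k), dtype=np.int64)
        for v in pre:
            if v == r:
                continue
            a = node_states[tree.parent[v]]
            pw = P[v][a] * partial[v]
            pw_tot = pw.sum()
            if pw_tot <= 0:
                raise RuntimeError(f"no consistent state for node {v}")
            b = int(rng.choice(k, p=pw / pw_tot))
            node_states[v] = b
            hist = uni.sample_path(int(a), b, float(tree.blen[v]),
                                   float(P[v][a, b]), rng)
            histories[int(v)] = hist
            for (s1, _), (s2, _) in zip(hist.segments, hist.segments[1:]):
                counts[s1, s2] += 1
        maps.append(StochasticMap(node_states, histories, counts))
    return StochasticMapSet(maps, tuple(states), Q, seed)


# -- summaries -------------------------------------------------------------

@dataclass
class TransitionCountSummary:
    """Per-pair and total transition counts across a map set."""

    states: tuple
    per_pair: dict      # (i_label, j_label) -> stats dict
    totals: dict        # stats dict for the per-map total count
    totals_per_map: np.ndarray = field(repr=False, default=None)


def _stats(x: np.ndarray) -> dict:
    lo, hi = np.quantile(x, [0.025, 0.975])
    return {
        "mean": float(x.mean()),
        "min": float(x.min()),
        "max": float(x.max()),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
    }


def count_transitions(mapset: StochasticMapSet) -> TransitionCountSummary:
    """Tally per-ordered-pair transition counts and their quantile interval."""
    if len(mapset) < 2:
        raise ValueError("need >= 2 maps for quantile summaries")
    arr = mapset.count_array().astype(float)  # (n_maps, k, k)
    states = mapset.states
    per_pair = {}
    k = len(states)
    for i in range(k):
        for j in range(k):
            if i != j:
                per_pair[(states[i], states[j])] = _stats(arr[:, i, j])
    totals = arr.sum(axis=(1, 2))
    return TransitionCountSummary(states, per_pair, _stats(totals), totals)


def origins_and_losses(mapset: StochasticMapSet, gain_pairs, loss_pairs) -> dict:
    """Histograms and 95% intervals for per-map gain and loss counts.

    ``gain_pairs`` and ``loss_pairs`` are iterables of ordered state-label
    pairs, e.g. gains [(absent, floral), (absent, hyperfloral)] and losses
    the reverse.  Both the quantile interval (primary) and mean +/- 1.96 sd
    are reported.
    """
    sidx = {s: i for i, s in enumerate(mapset.states)}
    arr = mapset.count_array().astype(float)

    def category(pairs):
        pairs = [(sidx[a], sidx[b]) for a, b in pairs]
        for a, b in pairs:
            if a == b:
                raise ValueError("state pairs must be ordered distinct pairs")
        per_map = sum(arr[:, a, b] for a, b in pairs)
        vals, cnts = np.unique(per_map.astype(int), return_counts=True)
        st = _stats(per_map)
        st["histogram"] = dict(zip(vals.tolist(), cnts.tolist()))
        st["normal_ci"] = (st["mean"] - 1.96 * st["sd"], st["mean"] + 1.96 * st["sd"])
        st["per_map"] = per_map
        return st

    return {"gains": category(gain_pairs), "losses": category(loss_pairs)}


def node_state_frequencies(mapset: StochasticMapSet, n_nodes: int) -> np.ndarray:
    """(n_nodes, k) frequency of each state at each node across maps."""
    k = len(mapset.states)
    freq = np.zeros((n_nodes, k))
    for m in mapset.maps:
        freq[np.arange(n_nodes), m.node_states] += 1
    return freq / len(mapset)
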