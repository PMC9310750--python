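"""Mk models of discrete character evolution on a time-calibrated tree.

Constrained generator matrices (equal-rates ER, symmetric SYM,
all-rates-different ARD, with optional ordering constraints and Pagel-style
two-character combined matrices), Felsenstein-pruning likelihoods with
ambiguity coding, maximum-likelihood fitting with multi-start box-constrained
optimization, AICc model selection, and marginal ancestral state
reconstruction.

An *ordered* character restricts transitions to adjacent states of a chain
(e.g. floral <-> absent <-> hyperfloral, or small <-> medium <-> large), so
a 3-state ordered ARD model has 4 free rates instead of 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import Phylogeny

log = logging.getLogger(__name__)

__all__ = [
    "RateMatrixSpec",
    "MkFit",
    "build_rate_spec",
    "build_combined_spec",
    "assemble_Q",
    "mk_loglik",
    "fit_mk",
    "aicc",
    "model_table",
    "marginal_ancestral",
    "ROOT_POLICIES",
]

ROOT_POLICIES = ("equal", "stationary", "fitzjohn")

RATE_LO, RATE_HI = 1e-9, 100.0  # events/Myr box for optimization


@dataclass(frozen=True)
class RateMatrixSpec:
    """Parameter-sharing structure of a constrained rate matrix.

    ``param_index`` maps each allowed directed edge (i, j) between state
    indices to a free-parameter id; edges absent from the map carry rate 0.
    """

    states: tuple
    param_index: dict
    name: str = ""

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return len(set(self.param_index.values())) if self.param_index else 0

    def state_index(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}


def _chain_edges(k: int, ordered: bool):
    if ordered:
        return [(i, j) for i in range(k) for j in (i - 1, i + 1) if 0 <= j < k]
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def build_rate_spec(structure: str, ordered: bool, states) -> RateMatrixSpec:
    """ER/SYM/ARD spec over one character, optionally ordered along ``states``.

    For a 3-state ordered chain: ER 1 parameter, SYM 2, ARD 4; unordered:
    ER 1, SYM 3, ARD 6.
    """
    structure = structure.upper()
    if structure not in ("ER", "SYM", "ARD"):
        raise ValueError(f"unknown structure {structure!r}")
    states = tuple(states)
    k = len(states)
    if not 2 <= k <= 10:
        raise ValueError("2 <= number of states <= 10 required")
    edges = _chain_edges(k, ordered)
    param_index = {}
    next_id = 0
    for (i, j) in edges:
        if structure == "ER":
            param_index[(i, j)] = 0
        elif structure == "SYM":
            if (j, i) in param_index:
                param_index[(i, j)] = param_index[(j, i)]
            else:
                param_index[(i, j)] = next_id
                next_id += 1
        else:
            param_index[(i, j)] = next_id
            next_id += 1
    label = f"{'Ordered ' if ordered else ''}{structure}"
    return RateMatrixSpec(states, param_index, name=label)


def build_combined_spec(structure: str, correlated: bool,
                        states_a=("floral", "absent", "hyperfloral"),
                        states_b=("small", "medium", "large")) -> RateMatrixSpec:
    """Pagel-style combined spec over the 9 paired states of two ordered chains.

    Allowed moves change exactly one character by one ordering step (24
    directed edges).  Uncorrelated: a move in one character shares its rate
    across the resting states of the other (ARD 8 ids, SYM 4).  Correlated:
    the rate depends on the resting state of the other character (ARD 24,
    SYM 12).
    """
    structure = structure.upper()
    if structure not in ("SYM", "ARD"):
        raise ValueError("combined models are SYM or ARD")
    ka, kb = len(states_a), len(states_b)
    pairs = [(a, b) for a in range(ka) for b in range(kb)]
    pidx = {p: i for i, p in enumerate(pairs)}
    states = tuple(f"{states_a[a]}|{states_b[b]}" for a, b in pairs)

    param_index = {}
    key_ids = {}

    def key_for(move_char, i, j, rest):
        # symmetric structures share (i, j) with (j, i)
        if structure == "SYM":
            i, j = min(i, j), max(i, j)
        return (move_char, i, j, rest if correlated else None)

    for (a, b) in pairs:
        for a2 in (a - 1, a + 1):
            if 0 <= a2 < ka:
                key = key_for("A", a, a2, b)
                key_ids.setdefault(key, len(key_ids))
                param_index[(pidx[(a, b)], pidx[(a2, b)])] = key_ids[key]
        for b2 in (b - 1, b + 1):
            if 0 <= b2 < kb:
                key = key_for("B", b, b2, a)
                key_ids.setdefault(key, len(key_ids))
                param_index[(pidx[(a, b)], pidx[(a, b2)])] = key_ids[key]
    label = f"Ordered {structure}, {'correlated' if correlated else 'uncorrelated'}"
    return RateMatrixSpec(states, param_index, name=label)


def assemble_Q(spec: RateMatrixSpec, params) -> np.ndarray:
    """Instantiate the generator: Q[i, j] = params[id] on allowed edges."""
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} rates, got {params.shape}")
    if np.any(params < 0):
        raise ValueError("rates must be non-negative")
    k = spec.n_states
    Q = np.zeros((k, k))
    for (i, j), pid in spec.param_index.items():
        Q[i, j] = params[pid]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrices(Q: np.ndarray, ts) -> np.ndarray:
    """exp(Q t) for a vector of durations, via eigendecomposition.

    Falls back to scaling-and-squaring per branch when Q is numerically
    defective.
    """
    ts = np.asarray(ts, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        E = np.exp(np.multiply.outer(ts, w))  # (B, k)
        P = np.einsum("ij,bj,jk->bik", V, E, Vinv).real
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * t) for t in ts])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


# -- likelihood ------------------------------------------------------------

def _tip_partials(tree: Phylogeny, tips: dict, states) -> np.ndarray:
    """(n_nodes, k) partials with 1 for each allowed state at each tip."""
    sidx = {s: i for i, s in enumerate(states)}
    k = len(states)
    L = np.ones((tree.n_nodes, k))
    seen = set()
    for t in tree.tips:
        lab = tree.labels[t]
        if lab not in tips:
            raise ValueError(f"tip {lab!r} missing from trait data")
        allowed = tips[lab]
        row = np.zeros(k)
        for s in allowed:
            if s not in sidx:
                raise ValueError(f"state {s!r} not in model states")
            row[sidx[s]] = 1.0
        if row.sum() == 0:
            raise ValueError(f"tip {lab!r} has empty state set")
        L[t] = row
        seen.add(lab)
    return L


def _down_pass(tree: Phylogeny, L: np.ndarray, P: np.ndarray):
    """Felsenstein pruning: returns (partials, per-node log scalers, PL cache).

    ``PL[v] = P_v @ partial_v`` for every non-root node v (the child-side
    message sent up the branch above v).
    """
    n, k = L.shape
    partial = L.copy()
    logscale = np.zeros(n)
    PL = np.empty((n, k))
    for v in tree.postorder():
        kids = tree.children[v]
        if kids:
            acc = np.ones(k)
            sc = 0.0
            for c in kids:
                acc = acc * PL[c]
                sc += logscale[c]
            m = acc.max()
            if m <= 0 or not np.isfinite(m):
                return None, None, None  # impossible data under this Q
            partial[v] = acc / m
            logscale[v] = sc + np.log(m)
        if tree.parent[v] >= 0:
            PL[v] = P[v] @ partial[v]
    return partial, logscale, PL


def _root_weights(policy, partial_root, Q, states):
    k = len(states)
    if isinstance(policy, (list, tuple, np.ndarray)):
        w = np.asarray(policy, dtype=float)
        return w / w.sum()
    if policy == "equal":
        return np.full(k, 1.0 / k)
    if policy == "stationary":
        A = np.vstack([Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        w, *_ = np.linalg.lstsq(A, b, rcond=None)
        w = np.clip(w, 0, None)
        return w / w.sum() if w.sum() > 0 else np.full(k, 1.0 / k)
    if policy == "fitzjohn":
        tot = partial_root.sum()
        if tot == 0:
            return np.full(k, 1.0 / k)
        return partial_root / tot
    raise ValueError(f"unknown root policy {policy!r}")


def mk_loglik(tree: Phylogeny, tips: dict, Q: np.ndarray, root="equal",
              states=None) -> float:
    """Log-likelihood of tip state sets under generator Q by pruning.

    ``tips`` maps tip label -> iterable of allowed state labels (singleton =
    observed, multiple = polymorphic, all = missing).  ``root`` is one of
    ``"equal"``, ``"stationary"``, ``"fitzjohn"`` or an explicit weight
    vector.
    """
    if states is None:
        states = tuple(range(Q.shape[0]))
    P = transition_matrices(Q, tree.blen)
    L = _tip_partials(tree, tips, states)
    partial, logscale, _ = _down_pass(tree, L, P)
    if partial is None:
        return -np.inf
    r = tree.root
    w = _root_weights(root, partial[r], Q, states)
    lik = float(w @ partial[r])
    if lik <= 0:
        return -np.inf
    lnL = np.log(lik) + logscale[r]
    if not np.isfinite(lnL):
        raise FloatingPointError("non-finite likelihood")
    return float(lnL)


def marginal_ancestral(tree: Phylogeny, tips: dict, Q: np.ndarray,
                       root="equal", states=None) -> dict:
    """Marginal state probabilities for every internal node.

    Each row is proportional to the likelihood of the data with the node
    clamped to each state (clamp-and-renormalize), computed in one
    down-pass/up-pass sweep.
    """
    if states is None:
        states = tuple(range(Q.shape[0]))
    k = len(states)
    P = transition_matrices(Q, tree.blen)
    L = _tip_partials(tree, tips, states)
    partial, logscale, PL = _down_pass(tree, L, P)
    if partial is None:
        raise ValueError("data impossible under this Q")
    r = tree.root
    w = _root_weights(root, partial[r], Q, states)

    above = np.zeros((tree.n_nodes, k))
    above[r] = w
    out = {}
    for v in tree.preorder():
        kids = tree.children[v]
        if kids:
            prob = above[v] * partial[v]
            tot = prob.sum()
            out[int(v)] = prob / tot
            for c in kids:
                sib = above[v].copy()
                for c2 in kids:
                    if c2 != c:
                        sib = sib * PL[c2]
                above[c] = sib @ P[c]
    return out


# -- fitting ---------------------------------------------------------------

@dataclass
class MkFit:
    """Maximum-likelihood fit of one Mk model."""

    spec: RateMatrixSpec
    rates: np.ndarray
    lnL: float
    n: int  # tips used for AICc
    root: object = "equal"
    name: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.spec.n_params

    @property
    def AICc(self) -> float:
        return aicc(self.lnL, self.k, self.n)

    @property
    def Q(self) -> np.ndarray:
        return assemble_Q(self.spec, self.rates)


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); n is the number of tips.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mk(tree: Phylogeny, tips: dict, spec: RateMatrixSpec, root="equal",
           n_starts: int = 10, seed: int = 0, tol: float = 1e-8) -> MkFit:
    """Fit rates by ML with multi-start L-BFGS-B on log-transformed rates."""
    rng = np.random.default_rng(seed)
    npar = spec.n_params
    states = spec.states

    def negloglik(logx):
        Q = assemble_Q(spec, np.exp(logx))
        ll = mk_loglik(tree, tips, Q, root=root, states=states)
        return 1e10 if not np.isfinite(ll) else -ll

    # moment-style initial scale: observed changes ~ rate * total length
    scale = max(len(set().union(*(frozenset(v) for v in tips.values()))) /
                max(tree.total_length(), 1e-9), 1e-4)
    starts = [np.full(npar, np.log(scale))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.log(scale) + rng.uniform(-3, 3, size=npar))

    bounds = [(np.log(RATE_LO), np.log(RATE_HI))] * npar
    best = None
    for x0 in starts:
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Mk optimization failed from all starts")
    rates = np.exp(best.x)
    return MkFit(spec=spec, rates=rates, lnL=-float(best.fun), n=tree.n_tips,
                 root=root, name=spec.name)


def profile_interval(tree, tips, spec, fit: MkFit, param: int, root="equal",
                     delta: float = 1.92, factor: float = 50.0):
    """Profile-likelihood interval for one rate parameter.

    Scans the parameter on a log grid around the MLE, re-optimizing the
    remaining rates, and returns the widest (lo, hi) with profile lnL within
    ``delta`` of the maximum (delta 1.92 = 95% chi-square cutoff).
    """
    mle = fit.rates[param]
    grid = mle * np.geomspace(1.0 / factor, factor, 25)
    others = [i for i in range(spec.n_params) if i != param]

    def prof(val):
        if not others:
            Q = assemble_Q(spec, np.array([val]))
            return mk_loglik(tree, tips, Q, root=root, states=spec.states)

        def nll(logx):
            full = np.empty(spec.n_params)
            full[param] = val
            full[others] = np.exp(logx)
            ll = mk_loglik(tree, tips, assemble_Q(spec, full), root=root,
                           states=spec.states)
            return 1e10 if not np.isfinite(ll) else -ll

        x0 = np.log(np.maximum(fit.rates[others], RATE_LO))
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(RATE_LO), np.log(RATE_HI))] * len(others),
                       options={"maxiter": 200})
        return -res.fun

    ok = [v for v in grid if prof(v) >= fit.lnL - delta]
    if not ok:
        return (mle, mle)
    return (min(ok), max(ok))


def model_table(fits):
    """Rank fits by AICc; flag every model within 2 units of the best.

    All fits must share the same n (same data); returns a list of dicts
    sorted ascending by AICc with ``dAICc`` and ``best`` fields.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits computed on different data (n = {sorted(ns)})")
    rows = sorted(
        ({"name": f.name or f.spec.name, "lnL": f.lnL, "k": f.k,
          "AICc": f.AICc, "fit": f} for f in fits),
        key=lambda r: r["AICc"],
    )
    amin = rows[0]["AICc"]
    for r in rows:
        r["dAICc"] = r["AICc"] - amin
        r["best"] = r["dAICc"] < 2.0
    return rows
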