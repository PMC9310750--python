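"""Stepwise AICc detection of diversification-rate shifts (MEDUSA-style).

The tree is partitioned into pieces, each evolving under its own pure-birth
(Yule) or birth-death process.  A piece's log-likelihood combines the
phylogenetic likelihood of its resolved branches (flow factors between
branch endpoint heights plus a factor lambda per speciation node) with
unresolved-clade species-richness probabilities at its tips, so
incompletely sampled genera enter through per-tip richness counts.
Starting from a single global piece, the algorithm greedily adds the shift
(stem or crown attachment, at any node) that most improves the summed AICc
and stops when the best improvement falls below a threshold.

The default threshold is scan-corrected: 2 ln(number of candidate shift
points), a Bonferroni-style control for the fact that every sweep examines
hundreds of nested alternatives.  A flat cutoff can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .mk import aicc
from .tree import Phylogeny, is_ultrametric

log = logging.getLogger(__name__)

__all__ = ["ShiftModel", "medusa_stepwise", "tip_richness_from_genera"]

EPS_MAX = 0.999


def tip_richness_from_genera(tip_labels, genus_richness: dict) -> dict:
    """Per-tip richness by evenly distributing missing species within genera.

    Each sampled tip of a genus receives floor(accepted/sampled), with the
    remainder given to the first tips in label order.
    """
    from .traits import genus_of

    by_genus = {}
    for lab in tip_labels:
        by_genus.setdefault(genus_of(lab), []).append(lab)
    out = {}
    for genus, labs in by_genus.items():
        n_acc = max(int(genus_richness.get(genus, len(labs))), len(labs))
        labs = sorted(labs)
        base, rem = divmod(n_acc, len(labs))
        for i, lab in enumerate(labs):
            out[lab] = base + (1 if i < rem else 0)
    return out


# -- piece likelihoods -----------------------------------------------------

class _PieceData:
    """Arrays describing one piece of the partition."""

    __slots__ = ("flow_hu", "flow_hv", "tip_hu", "tip_n", "n_lambda")

    def __init__(self, tree, heights, richness, edges, is_tip):
        flow_hu, flow_hv, tip_hu, tip_n = [], [], [], []
        edge_set = set(edges)
        child_count = {}
        for v in edges:
            u = int(tree.parent[v])
            child_count[u] = child_count.get(u, 0) + 1
            if is_tip[v]:
                tip_hu.append(heights[u])
                tip_n.append(richness[v])
            else:
                flow_hu.append(heights[u])
                flow_hv.append(heights[v])
        self.flow_hu = np.asarray(flow_hu)
        self.flow_hv = np.asarray(flow_hv)
        self.tip_hu = np.asarray(tip_hu)
        self.tip_n = np.asarray(tip_n, dtype=float)
        self.n_lambda = sum(max(c - 1, 0) for c in child_count.values())
        del edge_set

    def loglik(self, lam, mu):
        if lam <= 0 or mu < 0 or mu >= lam:
            return -np.inf
        r = lam - mu
        ll = self.n_lambda * np.log(lam)
        if self.flow_hu.size:
            if mu == 0:
                ll += -lam * (self.flow_hu.sum() - self.flow_hv.sum())
            else:
                xu = np.exp(-r * self.flow_hu)
                xv = np.exp(-r * self.flow_hv)
                ll += (-r * (self.flow_hu - self.flow_hv)
                       - 2.0 * (np.log(lam - mu * xu) - np.log(lam - mu * xv))).sum()
        if self.tip_hu.size:
            x = np.exp(-r * self.tip_hu)
            denom = lam - mu * x
            E = mu * (1.0 - x) / denom
            beta = lam * (1.0 - x) / denom
            with np.errstate(divide="ignore"):
                ll += (np.log1p(-E) + np.log1p(-beta)
                       + (self.tip_n - 1.0) * np.log(beta)).sum()
        return float(ll)

    def fit(self, process: str):
        """ML (lnL, k, lam, mu, process) for this piece under a process."""
        if process == "mixed":
            y = self.fit("yule")
            b = self.fit("bd")
            # per-piece choice by AIC (comparable: same data)
            return y if (-2 * y[0] + 2 * y[1]) <= (-2 * b[0] + 2 * b[1]) else b
        if process == "yule":
            if self.tip_hu.size and np.all(self.tip_n == 1) or not self.tip_hu.size:
                tot = (self.flow_hu.sum() - self.flow_hv.sum()) + self.tip_hu.sum()
                if self.n_lambda > 0 and tot > 0:
                    # closed-form Yule MLE, clamped to the optimization box
                    lam = min(max(self.n_lambda / tot, 1e-8), 1e3)
                else:
                    lam = 1e-8 if tot > 0 else 1.0
                return (self.loglik(lam, 0.0), 1, lam, 0.0, "yule")
            res = minimize_scalar(lambda x: -self.loglik(np.exp(x), 0.0),
                                  bounds=(np.log(1e-8), np.log(1e3)),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            lam = float(np.exp(res.x))
            return (-float(res.fun), 1, lam, 0.0, "yule")
        if process == "bd":
            y = self.fit("yule")
            x0 = np.array([np.log(max(y[2], 1e-8)), np.log(0.2)])

            def nll(x):
                lam = np.exp(x[0])
                eps = np.exp(x[1])
                if eps >= EPS_MAX:
                    return 1e10
                ll = self.loglik(lam, lam * eps)
                return 1e10 if not np.isfinite(ll) else -ll

            res = minimize(nll, x0, method="L-BFGS-B",
                           bounds=[(np.log(1e-8), np.log(1e3)),
                                   (np.log(1e-8), np.log(EPS_MAX))],
                           options={"maxiter": 200})
            lam = float(np.exp(res.x[0]))
            mu = lam * float(np.exp(res.x[1]))
            if -res.fun < y[0]:  # BD must dominate its Yule submodel
                lam, mu = y[2], 0.0
                return (y[0], 2, lam, mu, "bd")
            return (-float(res.fun), 2, lam, mu, "bd")
        raise ValueError(f"unknown process {process!r}")


@dataclass
class ShiftModel:
    """Fitted piecewise birth-death model."""

    pieces: list          # dicts: node, placement, process, lam, mu, lnL, k
    edge_piece: np.ndarray  # piece index per edge (indexed by child node)
    lnL: float
    k: int
    AICc: float
    threshold: float
    history: list = field(default_factory=list)

    @property
    def n_shifts(self) -> int:
        return len(self.pieces) - 1


def _subtree_edges(tree: Phylogeny):
    """edges (child-node ids) in the subtree of each node, including own edge."""
    sub = [None] * tree.n_nodes
    for v in tree.postorder():
        own = [v] if tree.parent[v] >= 0 else []
        acc = list(own)
        for c in tree.children[v]:
            acc.extend(sub[c])
        sub[v] = acc
    return sub


def medusa_stepwise(tree: Phylogeny, richness: dict, process: str = "mixed",
                    threshold: float = None, max_shifts: int = 30,
                    min_clade_size: int = 5) -> ShiftModel:
    """Greedy stepwise shift detection with clade-richness correction.

    ``richness`` maps tip label -> number of extant species represented by
    that tip (>= 1).  ``process`` is "yule", "bd" or "mixed" (each piece
    picks the better of the two).  ``threshold`` is the minimum AICc
    improvement to accept a shift; default 2 ln(candidate count).
    ``min_clade_size`` restricts candidate shifts to clades with at least
    that many sampled tips: a piece's rates are estimated from its waiting
    times, and a near-zero crown age of a tiny clade would otherwise let
    the piece likelihood grow without bound.
    """
    if not is_ultrametric(tree, 1e-4):
        raise ValueError("rate-shift detection requires an ultrametric tree")
    heights = tree.heights()
    is_tip = tree.is_tip
    rich = np.zeros(tree.n_nodes, dtype=np.int64)
    for t in tree.tips:
        lab = tree.labels[t]
        n = int(richness.get(lab, 1))
        if n < 1:
            raise ValueError(f"richness must be >= 1 (tip {lab!r})")
        rich[t] = n
    sub = _subtree_edges(tree)
    root = tree.root

    subtree_tips = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder():
        subtree_tips[v] = 1 if is_tip[v] else sum(subtree_tips[c]
                                                  for c in tree.children[v])
    candidates = []
    for v in range(tree.n_nodes):
        if v == root or subtree_tips[v] < min_clade_size:
            continue
        candidates.append((v, "stem"))
        if tree.children[v]:
            candidates.append((v, "crown"))
    if threshold is None:
        threshold = 2.0 * np.log(max(len(candidates), 2))

    def fit_edges(edges):
        pd = _PieceData(tree, heights, rich, edges, is_tip)
        return pd.fit(process)

    n_tips = tree.n_tips
    edge_piece = np.full(tree.n_nodes, -1, dtype=np.int64)
    all_edges = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
    edge_piece[all_edges] = 0
    piece_edges = {0: list(all_edges)}
    piece_fits = {0: fit_edges(all_edges)}
    pieces_meta = {0: {"node": int(root), "placement": "root"}}
    history = []

    def total(fits, extra_shifts):
        lnL = sum(f[0] for f in fits.values())
        k = sum(f[1] for f in fits.values()) + extra_shifts
        return lnL, k, aicc(lnL, k, n_tips)

    lnL0, k0, aic0 = total(piece_fits, 0)
    n_shifts = 0
    while n_shifts < max_shifts:
        best = None
        for (v, placement) in candidates:
            owner = int(edge_piece[v])
            take = [e for e in sub[v] if edge_piece[e] == owner]
            if placement == "crown":
                take = [e for e in take if e != v]
            if not take or len(take) == len(piece_edges[owner]):
                continue
            take_set = set(take)
            remain = [e for e in piece_edges[owner] if e not in take_set]
            if not remain:
                continue
            trial = dict(piece_fits)
            trial[owner] = fit_edges(remain)
            new_id = max(piece_fits) + 1
            trial[new_id] = fit_edges(take)
            lnL, k, aic = total(trial, n_shifts + 1)
            if best is None or aic < best["aic"]:
                best = {"aic": aic, "lnL": lnL, "k": k, "node": v,
                        "placement": placement, "owner": owner,
                        "take": take, "remain": remain,
                        "owner_fit": trial[owner], "new_fit": trial[new_id],
                        "new_id": new_id}
        if best is None or aic0 - best["aic"] < threshold:
            break
        # accept
        n_shifts += 1
        edge_piece[best["take"]] = best["new_id"]
        piece_edges[best["owner"]] = best["remain"]
        piece_edges[best["new_id"]] = best["take"]
        piece_fits[best["owner"]] = best["owner_fit"]
        piece_fits[best["new_id"]] = best["new_fit"]
        pieces_meta[best["new_id"]] = {"node": int(best["node"]),
                                       "placement": best["placement"]}
        history.append({"node": int(best["node"]), "placement": best["placement"],
                        "AICc_before": aic0, "AICc_after": best["aic"]})
        log.info("accepted shift at node %d (%s): AICc %.2f -> %.2f",
                 best["node"], best["placement"], aic0, best["aic"])
        lnL0, k0, aic0 = best["lnL"], best["k"], best["aic"]

    pieces = []
    for pid, fit in piece_fits.items():
        lnL, k, lam, mu, proc = fit
        pieces.append({"piece": pid, **pieces_meta[pid], "process": proc,
                       "lambda": lam, "mu": mu, "lnL": lnL, "k": k})
    return ShiftModel(pieces=pieces, edge_piece=edge_piece, lnL=lnL0, k=k0,
                      AICc=aic0, threshold=float(threshold), history=history)
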