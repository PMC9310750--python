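"""Forward simulators with stored ground truth.

Everything the pipeline consumes can be generated here: ultrametric
birth-death trees, discrete-character histories under a known generator Q
(Gillespie along each branch, every event recorded), joint state-dependent
diversification histories, and Table-1-style trait matrices (four primary
count characters plus derived umbel size, six discrete characters) with
configurable missing-data and polymorphism fractions.  All simulators are
reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simmap import BranchHistory
from .traits import Character, TraitMatrix, average_umbel_size
from .tree import Phylogeny

__all__ = [
    "TrueHistory",
    "simulate_bd_tree",
    "simulate_mk_history",
    "simulate_sse",
    "synth_trait_matrix",
    "TABLE1_CHARACTERS",
]

MAX_TREE_RETRIES = 1000


@dataclass
class TrueHistory:
    """Complete simulated character history on the emitted tree."""

    states: tuple                       # state labels
    node_states: np.ndarray             # state index per node
    histories: dict                     # child node -> BranchHistory
    counts: np.ndarray = field(default=None)  # (k, k) true transition counts

    def __post_init__(self):
        if self.counts is None:
            k = len(self.states)
            self.counts = np.zeros((k, k), dtype=np.int64)
            for h in self.histories.values():
                for (a, _), (b, _) in zip(h.segments, h.segments[1:]):
                    self.counts[a, b] += 1

    @property
    def total_changes(self) -> int:
        return int(self.counts.sum())

    def tip_states(self, tree: Phylogeny) -> dict:
        return {tree.labels[t]: frozenset([self.states[self.node_states[t]]])
                for t in tree.tips}

    def dwell_times(self) -> np.ndarray:
        out = np.zeros(len(self.states))
        for h in self.histories.values():
            for s, d in h.segments:
                out[s] += d
        return out


# -- birth-death trees -----------------------------------------------------

class _Lin:
    __slots__ = ("parent", "t0", "t1", "state", "segments", "children", "alive")

    def __init__(self, parent, t0, state=0):
        self.parent = parent
        self.t0 = t0
        self.t1 = None
        self.state = state
        self.segments = []  # (state, duration) along this lineage's edge
        self.children = []
        self.alive = True


def _forward_bd(rng, lam_of, mu_of, q_of, k, root_state, n_tips, max_time):
    """One attempt of joint tree + state simulation; returns lineages or None.

    ``lam_of``/``mu_of`` map a state index to rates; ``q_of`` is a (k, k)
    generator (zeros for state-independent runs).  Stops when the extant
    count first reaches ``n_tips`` (cut uniformly inside that interval) or
    at ``max_time``.
    """
    t = 0.0
    root = _Lin(None, 0.0, root_state)
    c1, c2 = _Lin(root, 0.0, root_state), _Lin(root, 0.0, root_state)
    root.children = [c1, c2]
    root.t1 = 0.0
    root.alive = False
    lineages = [root, c1, c2]
    active = [c1, c2]
    seg_start = {id(c1): 0.0, id(c2): 0.0}

    def close_segment(ln, t_now):
        ln.segments.append((ln.state, t_now - seg_start[id(ln)]))

    while True:
        if n_tips is not None and len(active) >= n_tips:
            rates = np.array([lam_of[l.state] + mu_of[l.state] - q_of[l.state, l.state]
                              for l in active])
            tot = rates.sum()
            dt = rng.exponential(1.0 / tot) if tot > 0 else np.inf
            t_cut = t + rng.uniform(0.0, dt) if np.isfinite(dt) else t + rng.uniform(0, 1)
            for ln in active:
                close_segment(ln, t_cut)
                ln.t1 = t_cut
            return lineages, active, t_cut
        if not active:
            return None
        rates = np.array([lam_of[l.state] + mu_of[l.state] - q_of[l.state, l.state]
                          for l in active])
        tot = rates.sum()
        dt = rng.exponential(1.0 / tot) if tot > 0 else np.inf
        if max_time is not None and t + dt >= max_time:
            for ln in active:
                close_segment(ln, max_time)
                ln.t1 = max_time
            return lineages, active, max_time
        if not np.isfinite(dt):
            return None
        t += dt
        ln = active[int(rng.choice(len(active), p=rates / tot))]
        s = ln.state
        lam, mu = lam_of[s], mu_of[s]
        qrow = q_of[s].copy()
        qrow[s] = 0.0
        u = rng.uniform(0, lam + mu + qrow.sum())
        if u < lam:  # speciation
            close_segment(ln, t)
            ln.t1 = t
            ln.alive = False
            kids = [_Lin(ln, t, s), _Lin(ln, t, s)]
            ln.children = kids
            active.remove(ln)
            for c in kids:
                lineages.append(c)
                active.append(c)
                seg_start[id(c)] = t
        elif u < lam + mu:  # extinction
            close_segment(ln, t)
            ln.t1 = t
            ln.alive = False
            active.remove(ln)
        else:  # state transition
            u -= lam + mu
            new_s = int(np.searchsorted(np.cumsum(qrow), u, side="right"))
            close_segment(ln, t)
            seg_start[id(ln)] = t
            ln.state = new_s


def _assemble(lineages, extant, states, label_prefix="t"):
    """Prune extinct lineages, suppress unifurcations, build arrays."""
    keep = set()
    for ln in extant:
        v = ln
        while v is not None and id(v) not in keep:
            keep.add(id(v))
            v = v.parent

    def surviving_children(ln):
        return [c for c in ln.children if id(c) in keep]

    parent_idx, blen, labels = [], [], []
    node_state, histories = [], {}
    tip_counter = [0]

    def emit(ln, acc_segments, parent_id):
        kids = surviving_children(ln)
        while len(kids) == 1:  # suppress pass-through nodes, concatenating paths
            nxt = kids[0]
            acc_segments = acc_segments + nxt.segments
            ln = nxt
            kids = surviving_children(ln)
        idx = len(parent_idx)
        parent_idx.append(parent_id)
        blen.append(sum(d for _, d in acc_segments) if parent_id is not None else 0.0)
        if kids:
            labels.append(None)
        else:
            tip_counter[0] += 1
            labels.append(f"{label_prefix}{tip_counter[0]}")
        node_state.append(ln.state)
        if parent_id is not None:
            # merge zero-dwell and repeated-state segments
            merged = []
            for s, d in acc_segments:
                if merged and merged[-1][0] == s:
                    merged[-1] = (s, merged[-1][1] + d)
                else:
                    merged.append((s, d))
            histories[idx] = BranchHistory(merged)
        for c in kids:
            emit(c, list(c.segments), idx)

    root = next(ln for ln in lineages if ln.parent is None)
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 20 * len(lineages) + 100))
    try:
        emit(root, [], None)
    finally:
        sys.setrecursionlimit(old)
    parent_arr = np.array([-1 if p is None else p for p in parent_idx],
                          dtype=np.int64)
    tree = Phylogeny(parent_arr, np.array(blen), labels)
    hist = TrueHistory(tuple(states), np.array(node_state, dtype=np.int64),
                       histories)
    return tree, hist


def simulate_bd_tree(lam: float, mu: float = 0.0, n_tips: int = None,
                     max_time: float = None, seed: int = 0) -> Phylogeny:
    """Ultrametric constant-rate birth-death tree of extant species.

    Conditioned either on ``n_tips`` (forward simulation cut uniformly in
    the first interval with n extant lineages - approximate n-conditioning,
    adequate for generating test data) or on ``max_time``.  Extinct
    lineages are pruned.
    """
    if (n_tips is None) == (max_time is None):
        raise ValueError("specify exactly one of n_tips or max_time")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips >= 2 required")
    rng = np.random.default_rng(seed)
    for _ in range(MAX_TREE_RETRIES):
        out = _forward_bd(rng, np.array([lam]), np.array([mu]),
                          np.zeros((1, 1)), 1, 0, n_tips, max_time)
        if out is None:
            continue
        lineages, extant, _ = out
        if len(extant) < 2:
            continue
        tree, _ = _assemble(lineages, extant, ("0",))
        return tree
    raise RuntimeError("all birth-death simulations went extinct; "
                       "increase lambda or lower mu")


def simulate_mk_history(tree: Phylogeny, Q: np.ndarray, root_state,
                        seed: int = 0, states=None):
    """Gillespie simulation of a discrete character along a fixed tree.

    Returns (tip state dict, TrueHistory); every state-change event is
    recorded in the history.
    """
    if states is None:
        states = tuple(str(i) for i in range(Q.shape[0]))
    k = Q.shape[0]
    sidx = {s: i for i, s in enumerate(states)}
    s0 = sidx[root_state] if root_state in sidx else int(root_state)
    rng = np.random.default_rng(seed)
    node_states = np.empty(tree.n_nodes, dtype=np.int64)
    node_states[tree.root] = s0
    histories = {}
    for v in tree.preorder():
        if tree.parent[v] < 0:
            continue
        s = int(node_states[tree.parent[v]])
        t_left = float(tree.blen[v])
        segments = []
        while True:
            rate = -Q[s, s]
            dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if dt >= t_left:
                segments.append((s, t_left))
                break
            segments.append((s, dt))
            t_left -= dt
            qrow = Q[s].copy()
            qrow[s] = 0.0
            s = int(rng.choice(k, p=qrow / qrow.sum()))
        node_states[v] = s
        histories[int(v)] = BranchHistory(segments)
    hist = TrueHistory(tuple(states), node_states, histories)
    return hist.tip_states(tree), hist


def simulate_sse(lam, mu, Q, root_state=0, n_tips: int = None,
                 max_time: float = None, seed: int = 0, states=None,
                 sampling=None):
    """Joint simulation of state-dependent diversification and character change.

    ``lam``/``mu`` are per-state rate vectors and ``Q`` the transition
    generator.  Returns (tree, tip state dict, TrueHistory) for the pruned
    (extant, optionally sampled) tree.  ``sampling`` maps state label ->
    retention probability applied to the extant tips afterwards.
    """
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    Q = np.asarray(Q, dtype=float)
    k = len(lam)
    if states is None:
        states = tuple(str(i) for i in range(k))
    if (n_tips is None) == (max_time is None):
        raise ValueError("specify exactly one of n_tips or max_time")
    rng = np.random.default_rng(seed)
    sidx = {s: i for i, s in enumerate(states)}
    s0 = sidx[root_state] if root_state in sidx else int(root_state)
    for _ in range(MAX_TREE_RETRIES):
        out = _forward_bd(rng, lam, mu, Q, k, s0, n_tips, max_time)
        if out is None:
            continue
        lineages, extant, _ = out
        if sampling is not None:
            fvec = np.array([float(sampling[s]) for s in states])
            extant = [ln for ln in extant if rng.uniform() < fvec[ln.state]]
        if len(extant) < 2:
            continue
        tree, hist = _assemble(lineages, extant, states)
        return tree, hist.tip_states(tree), hist
    raise RuntimeError("state-dependent simulation failed to produce >= 2 "
                       "sampled extant tips")


# -- trait matrices --------------------------------------------------------

TABLE1_CHARACTERS = [
    Character("min_umbellets", "continuous"),
    Character("max_umbellets", "continuous"),
    Character("min_flowers", "continuous"),
    Character("max_flowers", "continuous"),
    Character("avg_umbel_size", "continuous"),
    Character("rays", "discrete", ("unequal", "equal")),
    Character("flower_color", "discrete", ("white", "yellow", "purple")),
    Character("involucral_bracts", "discrete", ("absent", "single", "numerous", "showy")),
    Character("involucellar_bracts", "discrete", ("absent", "single", "numerous", "showy")),
    Character("sepals", "discrete", ("absent", "minute", "conspicuous", "asymmetric")),
    Character("ray_flowers", "discrete", ("absent", "present")),
]


def synth_trait_matrix(n_species: int, missing_fraction: float = 0.05,
                       polymorphic_fraction: float = 0.02, seed: int = 0,
                       syndrome_states=None) -> TraitMatrix:
    """Trait matrix shaped like the study's coding scheme.

    Umbellet and flower counts are log-normal; the six discrete characters
    are tied to a latent pseudanthial syndrome (absent / floral /
    hyperfloral) so the matrix carries genuine correlation structure.
    Missing and polymorphic cells are injected at the requested per-cell
    rates.  Pass ``syndrome_states`` to fix each species' syndrome (e.g.
    from a simulated character history); otherwise syndromes are drawn
    30/35/35%.
    """
    if not (0 <= missing_fraction < 1 and 0 <= polymorphic_fraction < 1):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    species = [f"Genus{chr(65 + i % 20)} species{i + 1}" for i in range(n_species)]
    if syndrome_states is None:
        syndrome = rng.choice(3, size=n_species, p=[0.35, 0.3, 0.35])
    else:
        syndrome = np.asarray(syndrome_states, dtype=np.int64)

    min_u = np.maximum(1, np.round(rng.lognormal(1.8, 0.6, n_species)))
    max_u = np.maximum(min_u, np.round(min_u * rng.lognormal(0.4, 0.3, n_species)))
    min_f = np.maximum(1, np.round(rng.lognormal(2.0, 0.7, n_species)))
    max_f = np.maximum(min_f, np.round(min_f * rng.lognormal(0.5, 0.3, n_species)))
    avg = np.array([average_umbel_size(a, b, c, d)
                    for a, b, c, d in zip(min_u, max_u, min_f, max_f)])

    def pick(probs_by_syndrome, s):
        p = np.asarray(probs_by_syndrome[s], dtype=float)
        return int(rng.choice(len(p), p=p / p.sum()))

    cells = {
        "min_umbellets": list(min_u), "max_umbellets": list(max_u),
        "min_flowers": list(min_f), "max_flowers": list(max_f),
        "avg_umbel_size": list(avg),
    }
    disc_probs = {
        # columns follow each character's state order; rows = syndrome
        "rays": {0: (0.6, 0.4), 1: (0.8, 0.2), 2: (0.2, 0.8)},
        "flower_color": {0: (0.6, 0.25, 0.15), 1: (0.8, 0.1, 0.1), 2: (0.25, 0.6, 0.15)},
        "involucral_bracts": {0: (0.4, 0.2, 0.4, 0.0), 1: (0.35, 0.2, 0.45, 0.0),
                              2: (0.05, 0.05, 0.2, 0.7)},
        "involucellar_bracts": {0: (0.35, 0.15, 0.5, 0.0), 1: (0.3, 0.15, 0.55, 0.0),
                                2: (0.05, 0.05, 0.15, 0.75)},
        "sepals": {0: (0.5, 0.3, 0.2, 0.0), 1: (0.15, 0.2, 0.15, 0.5),
                   2: (0.45, 0.35, 0.2, 0.0)},
        "ray_flowers": {0: (0.97, 0.03), 1: (0.05, 0.95), 2: (0.95, 0.05)},
    }
    for ch in TABLE1_CHARACTERS:
        if ch.kind != "discrete":
            continue
        col = []
        for i in range(n_species):
            s = pick(disc_probs[ch.name], int(syndrome[i]))
            col.append(frozenset([ch.states[s]]))
        cells[ch.name] = col

    # inject missing and polymorphic cells
    for ch in TABLE1_CHARACTERS:
        col = cells[ch.name]
        for i in range(n_species):
            u = rng.uniform()
            if u < missing_fraction:
                col[i] = float("nan") if ch.kind == "continuous" else frozenset(ch.states)
            elif ch.kind == "discrete" and u < missing_fraction + polymorphic_fraction:
                cur = next(iter(col[i]))
                others = [s for s in ch.states if s != cur]
                col[i] = frozenset([cur, others[int(rng.integers(len(others)))]])
    return TraitMatrix(species, list(TABLE1_CHARACTERS), cells)


def graft_clade(background: Phylogeny, tip_label: str, clade: Phylogeny,
                label_prefix: str = "g") -> tuple:
    """Replace a tip of ``background`` by an ultrametric ``clade``.

    The clade's crown is placed at its own height above the present, so the
    replaced tip's branch becomes the clade's stem (the clade must be
    shorter than the tip's stem start).  Clade tips are relabeled with
    ``label_prefix``.  Returns (tree, grafted crown node index) - the truth
    for rate-shift recovery experiments.
    """
    tipmap = background.tip_index()
    if tip_label not in tipmap:
        raise ValueError(f"tip {tip_label!r} not in background tree")
    tip = tipmap[tip_label]
    heights = background.heights()
    h_parent = float(heights[background.parent[tip]])
    h_clade = clade.height
    if h_clade >= h_parent:
        raise ValueError("clade is taller than the stem it must hang from")

    keep = [v for v in range(background.n_nodes) if v != tip]
    remap = {v: i for i, v in enumerate(keep)}
    parent = [(-1 if background.parent[v] < 0 else remap[int(background.parent[v])])
              for v in keep]
    blen = [float(background.blen[v]) for v in keep]
    labels = [background.labels[v] for v in keep]

    offset = len(keep)
    croot = clade.root
    cidx = {}
    order = list(clade.preorder())
    for j, v in enumerate(order):
        cidx[int(v)] = offset + j
    for v in order:
        v = int(v)
        if v == croot:
            parent.append(remap[int(background.parent[tip])])
            blen.append(h_parent - h_clade)
        else:
            parent.append(cidx[int(clade.parent[v])])
            blen.append(float(clade.blen[v]))
        lab = clade.labels[v]
        labels.append(f"{label_prefix}_{lab}" if lab else None)
    tree = Phylogeny(np.array(parent, dtype=np.int64), np.array(blen), labels)
    return tree, cidx[croot]
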