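"""Mixed quantitative-qualitative PCA of inflorescence architecture.

Quantitative columns are centered and scaled to unit (population) variance;
each qualitative character is expanded to its centered indicator matrix
with level columns divided by the square root of the level's relative
frequency.  With uniform row weights 1/n this is the generalized-SVD recipe
for mixed data: the spectrum sums to (number of quantitative variables) +
sum over qualitative variables of (levels - 1), and each eigenvector
corresponds to either a trait (quantitative) or a state (qualitative
level).

Structure detection uses eigenvalue-dispersion statistics on
column-shuffled null matrices: psi is the eigenvalue variance and phi its
normalization to [0, 1]; a data set with correlated characters concentrates
variance in leading components and scores higher than its randomized
counterparts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .traits import TraitMatrix, resolve_polymorphisms

log = logging.getLogger(__name__)

__all__ = [
    "MixedPCAResult",
    "DispersionStats",
    "mixed_pca",
    "eigen_dispersion",
    "randomization_compare",
    "polymorphism_replicates",
]


@dataclass
class MixedPCAResult:
    eigenvalues: np.ndarray      # descending
    scores: np.ndarray           # (n_rows, n_comp), variance per comp = eigenvalue
    sq_loadings: np.ndarray      # (n_cols, n_comp); column sums = eigenvalues
    column_names: list           # trait or trait=level per expanded column
    row_labels: list
    total_inertia: float
    n_dropped_rows: int = 0

    def variance_explained(self, n_comp: int) -> float:
        return float(self.eigenvalues[:n_comp].sum() / self.total_inertia)


@dataclass
class DispersionStats:
    psi: float
    phi: float


def _complete_rows(matrix: TraitMatrix, chars):
    """Row mask without any missing cell among the analyzed characters."""
    keep = np.ones(matrix.n_species, dtype=bool)
    for ch in chars:
        col = matrix.cells[ch.name]
        if ch.kind == "discrete":
            full = frozenset(ch.states)
            for i, cell in enumerate(col):
                if cell == full:
                    keep[i] = False
                elif len(cell) > 1:
                    raise ValueError(
                        f"polymorphic cell for {ch.name!r} at "
                        f"{matrix.species[i]!r}: resolve polymorphisms first"
                    )
        else:
            for i, v in enumerate(col):
                if not np.isfinite(v):
                    keep[i] = False
    return keep


def _build_design(matrix: TraitMatrix, chars, keep):
    """Standardized design matrix Z plus expanded column names and inertia."""
    n = int(keep.sum())
    blocks, names = [], []
    inertia = 0.0
    for ch in chars:
        col = [c for c, k in zip(matrix.cells[ch.name], keep) if k]
        if ch.kind == "continuous":
            x = np.asarray(col, dtype=float)
            sd = x.std()  # population convention
            if sd == 0:
                raise ValueError(f"constant quantitative column {ch.name!r}")
            blocks.append(((x - x.mean()) / sd)[:, None])
            names.append(ch.name)
            inertia += 1.0
        else:
            levels = [s for s in ch.states]
            counts = {s: sum(1 for c in col if s in c) for s in levels}
            used = [s for s in levels if counts[s] > 0]
            dropped = [s for s in levels if counts[s] == 0]
            if dropped:
                log.warning("character %s: dropping unobserved level(s) %s",
                            ch.name, dropped)
            ind = np.zeros((n, len(used)))
            for i, cell in enumerate(col):
                (s,) = cell
                ind[i, used.index(s)] = 1.0
            p = ind.mean(axis=0)
            Zq = (ind - p) / np.sqrt(p)
            blocks.append(Zq)
            names.extend(f"{ch.name}={s}" for s in used)
            inertia += len(used) - 1.0
    return np.hstack(blocks), names, inertia


def mixed_pca(matrix: TraitMatrix, chars=None) -> MixedPCAResult:
    """PCA of mixed data; rows with missing cells are dropped (logged).

    Polymorphic cells must be resolved first (see
    :func:`umbelevo.traits.resolve_polymorphisms`).
    """
    if chars is None:
        chars = matrix.characters
    else:
        chars = [matrix.character(c) if isinstance(c, str) else c for c in chars]
    keep = _complete_rows(matrix, chars)
    n = int(keep.sum())
    if n < 3:
        raise ValueError("fewer than 3 complete rows")
    dropped = matrix.n_species - n
    if dropped:
        log.info("mixed PCA: dropped %d incomplete rows of %d", dropped,
                 matrix.n_species)
    Z, names, inertia = _build_design(matrix, chars, keep)
    S = (Z.T @ Z) / n
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # reproducible orientation: largest-magnitude loading positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = Z @ V
    sq_loadings = (V * np.sqrt(w)[None, :]) ** 2
    rows = [s for s, k in zip(matrix.species, keep) if k]
    return MixedPCAResult(eigenvalues=w, scores=scores, sq_loadings=sq_loadings,
                          column_names=names, row_labels=rows,
                          total_inertia=float(inertia), n_dropped_rows=dropped)


def eigen_dispersion(eigenvalues) -> DispersionStats:
    """Eigenvalue variance psi and its [0, 1] normalization phi.

    psi = sum (l_i - mean)^2 / N; phi = psi / (mean^2 (N - 1)), which is 0
    for a flat spectrum and 1 when all variance sits in one component.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need >= 2 eigenvalues")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    mean = lam.mean()
    psi = float(((lam - mean) ** 2).mean())
    if mean == 0:
        return DispersionStats(0.0, 0.0)
    phi = float(np.clip(psi / (mean ** 2 * (lam.size - 1)), 0.0, 1.0))
    return DispersionStats(psi, phi)


def _shuffle_columns(matrix: TraitMatrix, chars, rng) -> TraitMatrix:
    cells = {}
    for ch in matrix.characters:
        col = list(matrix.cells[ch.name])
        if ch in chars:
            perm = rng.permutation(len(col))
            col = [col[i] for i in perm]
        cells[ch.name] = col
    return TraitMatrix(list(matrix.species), list(matrix.characters), cells)


def randomization_compare(matrix: TraitMatrix, n_reps: int = 100,
                          seed: int = 0, chars=None) -> dict:
    """Observed vs column-shuffled eigenstructure.

    Each replicate permutes every analyzed column independently (preserving
    marginal state counts), recomputes the mixed PCA and the dispersion
    statistics.  Reports the observed psi/phi, the null mean and quantiles,
    and how many leading observed eigenvalues exceed the null 95th
    percentile at the same rank.
    """
    if n_reps < 2:
        raise ValueError("n_reps >= 2 required")
    if chars is None:
        chars = matrix.characters
    else:
        chars = [matrix.character(c) if isinstance(c, str) else c for c in chars]
    rng = np.random.default_rng(seed)
    obs = mixed_pca(matrix, chars)
    obs_disp = eigen_dispersion(obs.eigenvalues)
    null_psi, null_phi, null_eigs = [], [], []
    for _ in range(n_reps):
        shuf = _shuffle_columns(matrix, chars, rng)
        res = mixed_pca(shuf, chars)
        d = eigen_dispersion(res.eigenvalues)
        null_psi.append(d.psi)
        null_phi.append(d.phi)
        null_eigs.append(res.eigenvalues)
    null_psi = np.asarray(null_psi)
    null_phi = np.asarray(null_phi)
    null_eigs = np.vstack([e[:len(obs.eigenvalues)] for e in null_eigs])
    null95 = np.quantile(null_eigs, 0.95, axis=0)
    m = min(len(obs.eigenvalues), null95.size)
    exceed = obs.eigenvalues[:m] > null95[:m]
    n_above = int(np.argmin(exceed)) if not exceed.all() else int(m)
    return {
        "observed": {"psi": obs_disp.psi, "phi": obs_disp.phi,
                     "eigenvalues": obs.eigenvalues},
        "null": {
            "psi_mean": float(null_psi.mean()),
            "psi_q95": float(np.quantile(null_psi, 0.95)),
            "psi_q2.5": float(np.quantile(null_psi, 0.025)),
            "psi_q97.5": float(np.quantile(null_psi, 0.975)),
            "phi_mean": float(null_phi.mean()),
            "phi_q95": float(np.quantile(null_phi, 0.95)),
            "eigenvalues_q95": null95,
        },
        "n_leading_above_null95": n_above,
        "psi_above_null95": bool(obs_disp.psi > np.quantile(null_psi, 0.95)),
    }


def polymorphism_replicates(matrix: TraitMatrix, n_reps: int = 100,
                            seed: int = 0, chars=None, n_comp: int = 5) -> dict:
    """Stability of the ordination under repeated polymorphism resolution.

    Per replicate: resolve polymorphisms with a fresh stream, rerun the
    PCA; report per-component eigenvalue spread and the mean absolute
    between-replicate score correlation after sign alignment.
    """
    if n_reps < 2:
        raise ValueError("n_reps >= 2 required")
    rng = np.random.default_rng(seed)
    eigs, score_list = [], []
    for _ in range(n_reps):
        resolved = resolve_polymorphisms(matrix, int(rng.integers(2 ** 31 - 1)))
        res = mixed_pca(resolved, chars)
        eigs.append(res.eigenvalues)
        score_list.append(res.scores)
    m = min(e.size for e in eigs)
    n_comp = min(n_comp, m)
    eig_arr = np.vstack([e[:m] for e in eigs])
    ref = score_list[0]
    cors = []
    for s in score_list[1:]:
        cc = []
        for j in range(n_comp):
            a, b = ref[:, j], s[:, j]
            if a.std() == 0 or b.std() == 0:
                cc.append(1.0)
                continue
            cc.append(abs(float(np.corrcoef(a, b)[0, 1])))
        cors.append(cc)
    cors = np.asarray(cors) if cors else np.ones((1, n_comp))
    return {
        "eigenvalue_spread": (eig_arr.max(axis=0) - eig_arr.min(axis=0)),
        "eigenvalue_sd": eig_arr.std(axis=0),
        "mean_abs_score_correlation": cors.mean(axis=0),
        "n_reps": n_reps,
    }
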