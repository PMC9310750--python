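"""Species-by-character trait tables for inflorescence architecture.

A :class:`TraitMatrix` holds continuous characters (umbellet and flower
counts, derived umbel size) as floats with NaN for missing values, and
discrete characters as *state sets*: a singleton set is an observed state, a
multi-member set a polymorphism, and the full state set stands for missing
data ("?").  The module also carries the derived umbel-size character, its
tertile discretization into small/medium/large, polymorphism resolution for
ordination, and the genus-level procedure that turns sampled state
proportions plus accepted species richness into per-state sampling
fractions for diversification models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Character",
    "TraitMatrix",
    "TraitError",
    "read_trait_table",
    "infer_characters",
    "average_umbel_size",
    "discretize_tertiles",
    "resolve_polymorphisms",
    "sampling_fractions",
    "read_richness_table",
]

MISSING_TOKEN = "?"
POLY_SEP = "/"


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class Character:
    """Definition of one scored character."""

    name: str
    kind: str  # "continuous" | "discrete"
    states: tuple = ()  # state labels, ordered, for discrete characters

    def __post_init__(self):
        if self.kind not in ("continuous", "discrete"):
            raise TraitError(f"unknown character kind {self.kind!r}")
        if self.kind == "discrete" and len(self.states) < 2:
            raise TraitError(f"discrete character {self.name!r} needs >= 2 states")


@dataclass
class TraitMatrix:
    """Species x character table with missing data and polymorphisms."""

    species: list
    characters: list
    cells: dict = field(default_factory=dict)  # name -> list of cell values

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise TraitError("species labels must be unique")
        for ch in self.characters:
            col = self.cells[ch.name]
            if len(col) != len(self.species):
                raise TraitError(f"column {ch.name!r} has wrong length")
            if ch.kind == "discrete":
                full = frozenset(ch.states)
                for sp, cell in zip(self.species, col):
                    if not isinstance(cell, frozenset) or not cell or not cell <= full:
                        raise TraitError(
                            f"invalid state set {cell!r} for {ch.name!r} at {sp!r}"
                        )
            else:
                for sp, cell in zip(self.species, col):
                    v = float(cell)
                    if np.isfinite(v) and v < 0:
                        raise TraitError(
                            f"negative value {v} for {ch.name!r} at {sp!r}"
                        )

    # -- access ------------------------------------------------------------
    def character(self, name: str) -> Character:
        for ch in self.characters:
            if ch.name == name:
                return ch
        raise KeyError(name)

    def column(self, name: str) -> list:
        return self.cells[name]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def tip_state_sets(self, char: str) -> dict:
        """Species -> state set for a discrete character (likelihood input)."""
        self.character(char)
        return dict(zip(self.species, self.cells[char]))

    def counts(self) -> dict:
        """Numbers of missing and polymorphic cells (for logging)."""
        missing = poly = 0
        for ch in self.characters:
            col = self.cells[ch.name]
            if ch.kind == "discrete":
                full = frozenset(ch.states)
                missing += sum(1 for c in col if c == full)
                poly += sum(1 for c in col if 1 < len(c) < len(full))
            else:
                missing += sum(1 for c in col if not np.isfinite(c))
        return {"missing": missing, "polymorphic": poly}

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {}
        for ch in self.characters:
            col = self.cells[ch.name]
            if ch.kind == "discrete":
                full = frozenset(ch.states)
                order = {s: i for i, s in enumerate(ch.states)}
                data[ch.name] = [
                    MISSING_TOKEN
                    if c == full
                    else POLY_SEP.join(sorted(c, key=order.get))
                    for c in col
                ]
            else:
                data[ch.name] = [
                    MISSING_TOKEN if not np.isfinite(v) else _fmt_num(v) for v in col
                ]
        return pd.DataFrame(data, index=pd.Index(self.species, name="species"))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _fmt_num(v: float) -> str:
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def read_trait_table(path, characters) -> TraitMatrix:
    """Read a trait CSV ("?" = missing, "a/b" = polymorphic).

    ``characters`` is the list of :class:`Character` definitions giving each
    column's kind and, for discrete columns, the allowed state labels.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    species = [str(s) for s in df.index]
    cells = {}
    for ch in characters:
        if ch.name not in df.columns:
            raise TraitError(f"column {ch.name!r} not in table")
        raw = df[ch.name].tolist()
        if ch.kind == "discrete":
            full = frozenset(ch.states)
            col = []
            for sp, tok in zip(species, raw):
                tok = tok.strip()
                if tok in (MISSING_TOKEN, ""):
                    col.append(full)
                    continue
                states = frozenset(t.strip() for t in tok.split(POLY_SEP))
                if not states <= full:
                    bad = sorted(states - full)
                    raise TraitError(
                        f"unknown state token(s) {bad} for character "
                        f"{ch.name!r} at species {sp!r}"
                    )
                col.append(states)
        else:
            col = []
            for sp, tok in zip(species, raw):
                tok = tok.strip()
                if tok in (MISSING_TOKEN, ""):
                    col.append(float("nan"))
                else:
                    try:
                        col.append(float(tok))
                    except ValueError as exc:
                        raise TraitError(
                            f"bad numeric cell {tok!r} for {ch.name!r} at {sp!r}"
                        ) from exc
        cells[ch.name] = col
    m = TraitMatrix(species, list(characters), cells)
    log.info("read %d species; %s", m.n_species, m.counts())
    return m


def infer_characters(path) -> list:
    """Guess character definitions from a CSV (for CLI convenience).

    A column whose every determinate token parses as a number is
    continuous; otherwise it is discrete with the observed tokens (split at
    "/") as states, in first-appearance order.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    chars = []
    for name in df.columns:
        tokens = []
        for cell in df[name]:
            cell = cell.strip()
            if cell in (MISSING_TOKEN, ""):
                continue
            tokens.extend(t.strip() for t in cell.split(POLY_SEP))
        if not tokens:
            raise TraitError(f"column {name!r} has no determinate cells")
        try:
            [float(t) for t in tokens]
            chars.append(Character(name, "continuous"))
        except ValueError:
            states = tuple(dict.fromkeys(tokens))
            chars.append(Character(name, "discrete", states))
    return chars


# -- derived umbel size ----------------------------------------------------

def average_umbel_size(min_umbellets, max_umbellets, min_flowers, max_flowers):
    """Average number of flowers per compound umbel.

    [(min umbellets x min flowers) + (max umbellets x max flowers)] / 2.
    Any missing input makes the result missing (NaN).
    """
    vals = [min_umbellets, max_umbellets, min_flowers, max_flowers]
    arr = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(arr)):
        return float("nan")
    if np.any(arr < 1):
        raise TraitError("umbellet and flower counts must be >= 1")
    return float((arr[0] * arr[2] + arr[1] * arr[3]) / 2.0)


def discretize_tertiles(values, labels=("small", "medium", "large")):
    """Cut a continuous character at its tertiles into three states.

    Thresholds are the 1/3 and 2/3 empirical quantiles (linear-interpolation
    convention) of the non-missing values; a value equal to a threshold goes
    to the lower class.  Returns ``(states, (lower, upper))`` where missing
    inputs map to ``None``.
    """
    arr = np.asarray(values, dtype=float)
    obs = arr[np.isfinite(arr)]
    if obs.size == 0:
        raise TraitError("all values missing")
    if obs.size < 3:
        raise TraitError("need >= 3 non-missing values for tertiles")
    lower, upper = np.quantile(obs, [1.0 / 3.0, 2.0 / 3.0])
    if lower == upper:
        raise TraitError("degenerate distribution: tertile thresholds coincide")
    states = []
    for v in arr:
        if not np.isfinite(v):
            states.append(None)
        elif v <= lower:
            states.append(labels[0])
        elif v <= upper:
            states.append(labels[1])
        else:
            states.append(labels[2])
    log.info("tertile thresholds: <=%g -> %s, <=%g -> %s", lower, labels[0], upper, labels[1])
    return states, (float(lower), float(upper))


def resolve_polymorphisms(matrix: TraitMatrix, seed: int) -> TraitMatrix:
    """Replace every polymorphic cell by one uniformly drawn member state.

    Missing cells (full state set) and singletons are untouched; the result
    is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cells = {}
    for ch in matrix.characters:
        col = matrix.cells[ch.name]
        if ch.kind != "discrete":
            cells[ch.name] = list(col)
            continue
        full = frozenset(ch.states)
        order = {s: i for i, s in enumerate(ch.states)}
        out = []
        for cell in col:
            if 1 < len(cell) < len(full):
                opts = sorted(cell, key=order.get)
                out.append(frozenset([opts[rng.integers(len(opts))]]))
            else:
                out.append(cell)
        cells[ch.name] = out
    return TraitMatrix(list(matrix.species), list(matrix.characters), cells)


# -- sampling fractions ----------------------------------------------------

def read_richness_table(path) -> dict:
    """Genus -> accepted species count, from a CSV with columns genus, accepted_species."""
    df = pd.read_csv(path)
    if not {"genus", "accepted_species"} <= set(df.columns):
        raise TraitError("richness CSV needs columns: genus, accepted_species")
    table = {}
    for _, row in df.iterrows():
        n = int(row["accepted_species"])
        if n <= 0:
            raise TraitError(f"accepted_species must be positive for {row['genus']!r}")
        table[str(row["genus"])] = n
    return table


def genus_of(species_label: str) -> str:
    """First whitespace- or underscore-separated token of a binomial."""
    return species_label.replace("_", " ").split()[0]


def state_proportions(matrix: TraitMatrix, focal_char: str) -> pd.DataFrame:
    """Per-genus state proportions among sampled, determinately scored species."""
    ch = matrix.character(focal_char)
    if ch.kind != "discrete":
        raise TraitError("sampling fractions require a discrete focal character")
    col = matrix.cells[focal_char]
    rows = {}
    for sp, cell in zip(matrix.species, col):
        g = genus_of(sp)
        rec = rows.setdefault(g, {"sampled": 0, **{s: 0 for s in ch.states}})
        rec["sampled"] += 1
        if len(cell) == 1:  # polymorphic or missing species excluded from proportions
            (s,) = cell
            rec[s] += 1
    return pd.DataFrame.from_dict(rows, orient="index")


def sampling_fractions(matrix: TraitMatrix, focal_char: str, richness: dict) -> dict:
    """Per-state fraction of extant species present in the tree.

    For each genus, the state proportions among its sampled, determinately
    scored species are extrapolated to the genus's accepted species count;
    the fraction for state ``s`` is (sampled species in ``s``) / (sum of
    extrapolated extant species in ``s``).  Monomorphic sampled genera are
    treated as monomorphic overall.
    """
    ch = matrix.character(focal_char)
    props = state_proportions(matrix, focal_char)
    missing = sorted(set(props.index) - set(richness))
    if missing:
        raise TraitError(f"genera missing from richness table: {missing}")
    sampled_by_state = {s: 0.0 for s in ch.states}
    extant_by_state = {s: 0.0 for s in ch.states}
    for genus, rec in props.iterrows():
        scored = float(sum(rec[s] for s in ch.states))
        if scored == 0:
            continue  # no determinate scores: genus uninformative for the focal trait
        n_acc = max(richness[genus], int(rec["sampled"]))
        for s in ch.states:
            p = rec[s] / scored
            sampled_by_state[s] += rec[s]
            extant_by_state[s] += p * n_acc
    out = {}
    for s in ch.states:
        if extant_by_state[s] == 0:
            out[s] = 1.0  # state unobserved: vacuously complete
        else:
            out[s] = min(1.0, sampled_by_state[s] / extant_by_state[s])
    return out
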