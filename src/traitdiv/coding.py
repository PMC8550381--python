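"""Tip-trait tables, gap coding, and the two-binary-character state coding.

Continuous body size is discretised by *gap coding*: with ``k`` classes the
``k-1`` class boundaries are placed in the ``k-1`` widest gaps between
consecutive distinct sorted values, each boundary reported as the midpoint of
its gap.  Ties between equally wide gaps are broken toward the smaller value.

Three-state characters (small/medium/large body size, or
benthic/intermediate/pelagic ecotype) are re-expressed as the presence/absence
of two binary characters for the SSE machinery: the first extreme state is
``01``, the second extreme ``10``, and the intermediate ``11``; the fourth
combination ``00`` is never observed and is excluded from the state space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "GapCoding",
    "CodingError",
    "gap_code",
    "encode_binary_pair",
    "decode_binary_pair",
    "BINARY_PAIR_CODE",
    "OBSERVED_CODES",
]

ECOTYPES = ("benthic", "intermediate", "pelagic")

#: observed two-character codes, in canonical order (first extreme,
#: second extreme, intermediate); ``00`` is reserved-unobserved.
OBSERVED_CODES = ("01", "10", "11")

#: state label -> two-binary-character code
BINARY_PAIR_CODE = {
    "S": "01", "L": "10", "M": "11",
    "small": "01", "large": "10", "medium": "11",
    "B": "01", "P": "10", "I": "11",
    "benthic": "01", "pelagic": "10", "intermediate": "11",
}


class CodingError(ValueError):
    """Raised when a trait cannot be discretised or encoded as requested."""


# ----------------------------------------------------------------------
# trait table
# ----------------------------------------------------------------------
TRAIT_COLUMNS = ["species", "total_length_cm", "body_depth_pct", "ecotype", "farming"]


@dataclass
class TraitTable:
    """Per-species trait matrix (continuous sizes plus discrete ecology)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        if df["species"].duplicated().any():
            dup = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValueError(f"duplicate species: {dup}")
        tl = df["total_length_cm"].dropna()
        if (tl <= 0).any():
            raise ValueError("total_length_cm must be positive")
        bd = df["body_depth_pct"].dropna()
        if ((bd <= 0) | (bd >= 100)).any():
            raise ValueError("body_depth_pct must lie in (0, 100)")
        eco = df["ecotype"].dropna()
        bad = sorted(set(eco) - set(ECOTYPES))
        if bad:
            raise ValueError(f"unknown ecotypes: {bad}")
        farm = df["farming"].dropna()
        if not set(np.unique(farm)).issubset({0, 1}):
            raise ValueError("farming must be 0/1")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def species(self) -> list:
        return self.data["species"].tolist()

    def column(self, name: str, species=None) -> pd.Series:
        s = self.data.set_index("species")[name]
        if species is not None:
            missing = [sp for sp in species if sp not in s.index]
            if missing:
                raise KeyError(f"species absent from trait table: {missing}")
            s = s.loc[list(species)]
        return s

    def join_tree(self, tree) -> "TraitTable":
        """Restrict to the tree's tips, erroring on tips without traits."""
        idx = self.data.set_index("species")
        missing = [sp for sp in tree.tip_labels if sp not in idx.index]
        if missing:
            raise KeyError(f"tree tips absent from trait table: {missing}")
        return TraitTable(idx.loc[tree.tip_labels].reset_index())


# ----------------------------------------------------------------------
# gap coding
# ----------------------------------------------------------------------
@dataclass
class GapCoding:
    k: int
    breakpoints: np.ndarray          # k-1 ordered boundary values
    class_labels: list               # length k, smallest class first
    assignment: dict                 # species (or index) -> class label
    gap_widths: np.ndarray           # widths of the chosen gaps

    def classify(self, value: float) -> str:
        return self.class_labels[int(np.searchsorted(self.breakpoints, value))]


def gap_code(values, k: int, labels=None, class_labels=None) -> GapCoding:
    """Discretise ``values`` into ``k`` classes by largest-gaps coding.

    Parameters
    ----------
    values
        Continuous measurements (NaN treated as missing and left unassigned).
    k
        Number of classes; breakpoints go into the ``k-1`` widest gaps
        between consecutive distinct values, ties broken toward smaller
        values, each breakpoint at its gap midpoint.
    labels
        Optional keys for the assignment map (defaults to positional index).
    class_labels
        Names for the classes from smallest to largest; defaults to
        ``("S", "M", "L")`` for ``k == 3``, else ``C1..Ck``.
    """
    vals = np.asarray(values, dtype=float)
    if labels is None:
        labels = list(range(vals.size))
    obs = ~np.isnan(vals)
    distinct = np.unique(vals[obs])
    if distinct.size < k:
        raise CodingError(
            f"gap coding into {k} classes needs >= {k} distinct values, "
            f"got {distinct.size}"
        )
    if class_labels is None:
        class_labels = ["S", "M", "L"] if k == 3 else [f"C{i+1}" for i in range(k)]
    if len(class_labels) != k:
        raise CodingError("need exactly k class labels")
    if k == 1:
        breaks = np.empty(0)
        widths = np.empty(0)
    else:
        gaps = np.diff(distinct)
        # stable selection: widest gaps first, ties toward the smaller value
        order = np.lexsort((np.arange(gaps.size), -gaps))
        chosen = np.sort(order[: k - 1])
        breaks = (distinct[chosen] + distinct[chosen + 1]) / 2.0
        widths = gaps[chosen]
    coding = GapCoding(
        k=k,
        breakpoints=breaks,
        class_labels=list(class_labels),
        assignment={},
        gap_widths=widths,
    )
    assignment = {}
    for lab, v in zip(labels, vals):
        if not np.isnan(v):
            assignment[lab] = coding.classify(v)
    coding.assignment = assignment
    return coding


# ----------------------------------------------------------------------
# two-binary-character coding
# ----------------------------------------------------------------------
def encode_binary_pair(states: dict) -> dict:
    """Map three-state labels to their two-character codes.

    Small/benthic -> ``01``, large/pelagic -> ``10``,
    medium/intermediate -> ``11``.  Unknown labels raise :class:`CodingError`
    listing the offending tips.
    """
    bad = sorted(t for t, s in states.items() if s not in BINARY_PAIR_CODE)
    if bad:
        raise CodingError(f"states outside the 3-state alphabet for tips: {bad}")
    return {t: BINARY_PAIR_CODE[s] for t, s in states.items()}


def decode_binary_pair(codes: dict, alphabet=("S", "M", "L")) -> dict:
    """Inverse of :func:`encode_binary_pair` for a chosen 3-letter alphabet."""
    inverse = {}
    for s in alphabet:
        inverse[BINARY_PAIR_CODE[s]] = s
    out = {}
    for t, c in codes.items():
        if c not in inverse:
            raise CodingError(f"unobservable code {c!r} at tip {t!r}")
        out[t] = inverse[c]
    return out
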