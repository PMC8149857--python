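"""Input pattern sets for the consortium perceptron.

A pattern is the vector of chemical-inducer states presented to the sender
groups: binary entries (1 = OC6 present, 0 = aTc-suppressed sender) or graded
entries in (0, 1] emulating randomized OC6 doses.  Three letter categories
("z", "v", "n") are used on N x N grids; each category contributes one clean
pattern plus N^2 noisy variants with exactly one bit flipped, so a full
three-category set holds (1 + N^2) * 3 patterns.

Default clean bitmaps are hand-designed letterforms constrained to the
documented zero-bit counts (3/9 at 3x3, 16/25 at 5x5, 36/49 at 7x7, 64/81 at
9x9), with "v" and "n" fixed reflections of "z" so the three categories share
bit counts.  The bitmaps are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pattern",
    "PatternSet",
    "TargetSpec",
    "CATEGORIES",
    "clean_bitmap",
    "make_clean",
    "expand_noisy",
    "make_set",
    "make_nonbinary",
    "enumerate_4bit",
    "select_separable",
    "zero_fraction",
]

CATEGORIES = ("z", "v", "n")

# 3x3 letterform: 6 ones / 3 zeros; top bar plus descending diagonal stroke.
# Chosen among all 6-one bitmaps to minimize the pairwise one-bit overlap with
# its two reflections (4 of 6, the combinatorial floor), keeping the three
# categories as distinguishable as the grid allows.
_Z3 = np.array([[1, 1, 1], [0, 1, 1], [0, 0, 1]], dtype=float)


def _z_bitmap(N: int) -> np.ndarray:
    """Generic "z" letterform on an N x N grid (odd N >= 5).

    Top-left bar of length k = (N+1)/2, a shifted anti-diagonal stroke, and a
    centred bottom bar; exactly 2N - 1 ones, hence (N-1)^2 zeros.  The
    staggered bars and shifted stroke break every reflection symmetry, so
    "z", its left-right reflection "v" and its up-down reflection "n" are
    pairwise distinct with pairwise one-bit overlaps of roughly half the
    strokes -- low enough for the categories to be separable.
    """
    if N < 5 or N % 2 == 0:
        raise ValueError("generic z bitmap requires odd N >= 5")
    k = (N + 1) // 2
    g = np.zeros((N, N))
    g[0, :k] = 1
    for i in range(1, N - 1):
        g[i, N - i] = 1
    ba = (N - k + 1) // 2
    g[N - 1, ba : ba + k] = 1
    return g


def clean_bitmap(category: str, N: int) -> np.ndarray:
    """Default clean bitmap for a category at grid size N (odd, N >= 3).

    "v" is the left-right reflection of "z" and "n" the up-down reflection, so
    the three categories are spatial transforms of one another with identical
    zero-bit counts.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    z = _Z3.copy() if N == 3 else _z_bitmap(N)
    if category == "z":
        return z
    if category == "v":
        return np.fliplr(z)
    return np.flipud(z)


@dataclass(eq=False)
class Pattern:
    """One input pattern: flattened grid values in [0, 1].

    ``noise_index`` is -1 for the clean (ideal) pattern, otherwise the flat
    index of the single flipped bit.  ``grid_size`` is the side length N, or
    None for flat (e.g. 4-bit) patterns.
    """

    category: str
    values: np.ndarray
    grid_size: Optional[int] = None
    noise_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("pattern entries must lie in [0, 1]")
        if self.grid_size is not None and len(self.values) != self.grid_size**2:
            raise ValueError(
                f"expected {self.grid_size**2} entries for grid_size {self.grid_size}, "
                f"got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    @property
    def is_clean(self) -> bool:
        return self.noise_index == -1

    def as_grid(self) -> np.ndarray:
        if self.grid_size is None:
            return self.values[None, :]
        return self.values.reshape(self.grid_size, self.grid_size)

    def __eq__(self, other) -> bool:  # value equality, used in tests
        return (
            isinstance(other, Pattern)
            and self.category == other.category
            and self.grid_size == other.grid_size
            and self.noise_index == other.noise_index
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PatternSet:
    """An ordered collection of patterns with generation provenance.

    Ordering is category-major with the clean pattern first, then the N^2
    single-bit flips in raster order.
    """

    patterns: list[Pattern]
    grid_size: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def __getitem__(self, i) -> Pattern:
        return self.patterns[i]

    @property
    def categories(self) -> list[str]:
        seen: list[str] = []
        for p in self.patterns:
            if p.category not in seen:
                seen.append(p.category)
        return seen

    def by_category(self, category: str) -> list[Pattern]:
        return [p for p in self.patterns if p.category == category]

    def matrix(self) -> np.ndarray:
        """(n_patterns, n_bits) array of pattern values in set order."""
        return np.stack([p.values for p in self.patterns])

    def category_mask(self, category: str) -> np.ndarray:
        return np.array([p.category == category for p in self.patterns])

    # ------------------------------------------------------------------ IO
    def to_frame(self) -> pd.DataFrame:
        n_bits = len(self.patterns[0]) if self.patterns else 0
        rows = []
        for p in self.patterns:
            row = {"category": p.category, "noise_index": p.noise_index}
            row.update({f"bit_{i}": v for i, v in enumerate(p.values)})
            rows.append(row)
        df = pd.DataFrame(rows, columns=["category", "noise_index"] + [f"bit_{i}" for i in range(n_bits)])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid_size: Optional[int] = None) -> "PatternSet":
        df = pd.read_csv(path)
        bit_cols = [c for c in df.columns if c.startswith("bit_")]
        if not bit_cols or "category" not in df.columns or "noise_index" not in df.columns:
            raise ValueError(f"pattern CSV {path} must have category, noise_index, bit_* columns")
        bit_cols = sorted(bit_cols, key=lambda c: int(c.split("_")[1]))
        if grid_size is None:
            side = int(round(len(bit_cols) ** 0.5))
            grid_size = side if side * side == len(bit_cols) else None
        patterns = [
            Pattern(r["category"], r[bit_cols].to_numpy(float), grid_size, int(r["noise_index"]))
            for _, r in df.iterrows()
        ]
        return cls(patterns, grid_size)

    def to_json(self, path) -> None:
        payload = {
            "grid_size": self.grid_size,
            "provenance": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.provenance.items()
            },
            "patterns": [
                {
                    "category": p.category,
                    "noise_index": p.noise_index,
                    "values": p.values.tolist(),
                }
                for p in self.patterns
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PatternSet":
        with open(path) as fh:
            payload = json.load(fh)
        gs = payload["grid_size"]
        patterns = [
            Pattern(r["category"], np.array(r["values"]), gs, r["noise_index"])
            for r in payload["patterns"]
        ]
        return cls(patterns, gs, payload.get("provenance", {}))

    def to_pgm(self, pattern_index: int, path) -> None:
        """ASCII PGM raster of one pattern, for visual inspection."""
        g = (np.round(self.patterns[pattern_index].as_grid() * 255)).astype(int)
        lines = [f"P2", f"{g.shape[1]} {g.shape[0]}", "255"]
        lines += [" ".join(str(v) for v in row) for row in g]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def make_clean(category: str, N: int, bitmap: Optional[np.ndarray] = None) -> Pattern:
    """Clean (ideal) pattern of a category at grid size N.

    A custom ``bitmap`` (N x N binary array) overrides the default letterform.
    """
    if bitmap is not None:
        bitmap = np.asarray(bitmap, dtype=float)
        if bitmap.shape != (N, N):
            raise ValueError(f"bitmap shape {bitmap.shape} does not match N={N}")
    else:
        bitmap = clean_bitmap(category, N)
    return Pattern(category, bitmap.ravel(), N, -1)


def expand_noisy(clean: Pattern) -> list[Pattern]:
    """All single-bit-flip variants of a clean binary pattern, in raster order."""
    if not clean.is_binary:
        raise ValueError("noisy expansion requires a binary clean pattern")
    if not clean.is_clean:
        raise ValueError("expand_noisy expects the clean pattern (noise_index == -1)")
    out = []
    for k in range(len(clean)):
        v = clean.values.copy()
        v[k] = 1.0 - v[k]
        out.append(Pattern(clean.category, v, clean.grid_size, k))
    return out


def make_set(
    N: int,
    categories: Sequence[str] = CATEGORIES,
    bitmaps: Optional[dict[str, np.ndarray]] = None,
) -> PatternSet:
    """Full pattern set at grid size N: per category, 1 clean + N^2 noisy.

    Total size (1 + N^2) * len(categories); ordering is category-major with
    the clean pattern first.
    """
    patterns: list[Pattern] = []
    for c in categories:
        clean = make_clean(c, N, None if bitmaps is None else bitmaps.get(c))
        patterns.append(clean)
        patterns.extend(expand_noisy(clean))
    return PatternSet(patterns, N, {"kind": "binary", "grid_size": N, "categories": list(categories)})


def make_nonbinary(s: PatternSet, low: float = 0.5, high: float = 1.0, seed: int = 0) -> PatternSet:
    """Graded variant of a binary set: one shared random scaling vector.

    Draws a single vector u ~ Uniform(low, high) of the pattern length and
    multiplies every pattern elementwise by it, emulating randomized OC6 doses;
    zero bits stay zero.  The same u is shared by all patterns of the set and
    recorded in provenance.
    """
    if not (0 < low <= high <= 1):
        raise ValueError("require 0 < low <= high <= 1")
    for p in s.patterns:
        if not p.is_binary:
            raise ValueError("make_nonbinary requires a binary pattern set")
    n_bits = len(s.patterns[0])
    rng = np.random.default_rng(seed)
    u = rng.uniform(low, high, size=n_bits)
    patterns = [
        Pattern(p.category, p.values * u, p.grid_size, p.noise_index) for p in s.patterns
    ]
    prov = dict(s.provenance)
    prov.update({"kind": "graded", "seed": seed, "low": low, "high": high, "scaling_vector": u})
    return PatternSet(patterns, s.grid_size, prov)


def enumerate_4bit() -> PatternSet:
    """All sixteen 4-bit binary patterns in lexicographic order."""
    patterns = [
        Pattern("free", [(i >> 3) & 1, (i >> 2) & 1, (i >> 1) & 1, i & 1], None, -1)
        for i in range(16)
    ]
    return PatternSet(patterns, None, {"kind": "4bit-enumeration"})


def select_separable(
    s: PatternSet | Iterable[Pattern],
    w: Sequence[float],
    lower: float,
    upper: float,
) -> tuple[list[Pattern], list[Pattern], list[Pattern]]:
    """Partition patterns by weighted sum against decision thresholds.

    Dot product d = w . x: d < lower -> set0, d > upper -> set1, otherwise
    the boundary group.  The partition is exhaustive and disjoint.
    """
    if lower > upper:
        raise ValueError("require lower <= upper")
    w = np.asarray(w, dtype=float)
    patterns = list(s)
    set0: list[Pattern] = []
    set1: list[Pattern] = []
    boundary: list[Pattern] = []
    for p in patterns:
        if len(p) != len(w):
            raise ValueError(f"weight length {len(w)} != pattern length {len(p)}")
        d = float(w @ p.values)
        if d > upper:
            set1.append(p)
        elif d < lower:
            set0.append(p)
        else:
            boundary.append(p)
    return set0, set1, boundary


def zero_fraction(p: Pattern) -> float:
    """Fraction of zero-valued bits (pattern sparseness)."""
    return float(np.mean(p.values == 0))


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

@dataclass
class TargetSpec:
    """One-vs-rest target vectors over a pattern set.

    For each category, patterns of that category get the High receiver-EYFP
    level and all others the Low level.
    """

    high: float
    low: float
    vectors: dict[str, np.ndarray]

    @classmethod
    def one_vs_rest(cls, s: PatternSet, high: float, low: float) -> "TargetSpec":
        if high <= low:
            raise ValueError("require high > low")
        vectors = {
            c: np.where(s.category_mask(c), float(high), float(low)) for c in s.categories
        }
        return cls(high, low, vectors)

    @property
    def threshold(self) -> float:
        """Midpoint decision threshold between the H and L levels."""
        return 0.5 * (self.high + self.low)
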