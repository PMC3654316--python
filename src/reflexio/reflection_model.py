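"""Core domain types: unit cells, symmetry groups, reflection tables.

Everything downstream (shell statistics, cutoff determination, merging)
consumes these types.  Symmetry support is deliberately minimal: a small
registry of explicit rotation-matrix sets, one group per Laue class of
interest, loaded from a plain-text data file.  Matrices act on (h, k, l)
column vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "InvalidCellError",
    "InvalidReflectionError",
    "UnitCell",
    "SymmetryGroup",
    "ReflectionTable",
    "UniqueIndex",
    "load_registry",
    "get_group",
    "d_spacing",
    "canonicalize",
    "canonicalize_array",
    "enumerate_unique",
]


class InvalidCellError(ValueError):
    """Raised for degenerate or out-of-range unit-cell parameters."""


class InvalidReflectionError(ValueError):
    """Raised for impossible reflection indices such as (0,0,0)."""


@dataclass(frozen=True)
class UnitCell:
    """Unit cell in Å / degrees with derived metric quantities."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise InvalidCellError(f"cell angle {name} must be in (0, 180)")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise InvalidCellError("degenerate cell: non-positive volume")

    @property
    def metric_tensor(self) -> np.ndarray:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * np.cos(ga), a * c * np.cos(be)],
                [a * b * np.cos(ga), b * b, b * c * np.cos(al)],
                [a * c * np.cos(be), b * c * np.cos(al), c * c],
            ]
        )

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor)

    @property
    def volume(self) -> float:
        """Cell volume in Å^3."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos(al), np.cos(be), np.cos(ga)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise InvalidCellError("degenerate cell: non-positive volume")
        return self.a * self.b * self.c * math.sqrt(arg)

    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class SymmetryGroup:
    """Point-group rotations plus indexing-ambiguity operators.

    ``rotations`` are proper rotations acting on (h,k,l); ``laue_ops`` is
    their closure under inversion.  ``ambiguity_ops`` are lattice-symmetry
    operators outside the Laue group (one representative per coset), i.e.
    the alternative-indexing choices that merging must resolve.
    """

    symbol: str
    bravais_lattice: str
    rotations: tuple[tuple[int, ...], ...]
    ambiguity_ops: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        mats = self.rotation_matrices
        keys = {m.tobytes() for m in mats}
        if np.eye(3, dtype=int).tobytes() not in keys:
            raise ValueError(f"{self.symbol}: identity missing from rotations")
        for m in mats:
            if round(float(np.linalg.det(m))) not in (-1, 1):
                raise ValueError(f"{self.symbol}: operator determinant not ±1")
            for n in mats:
                if (m @ n).tobytes() not in keys:
                    raise ValueError(f"{self.symbol}: rotations not closed")

    @property
    def rotation_matrices(self) -> list[np.ndarray]:
        return [np.array(m, dtype=int).reshape(3, 3) for m in self.rotations]

    @property
    def laue_matrices(self) -> list[np.ndarray]:
        """Rotations plus their inversion-composed mates, deduplicated."""
        seen: dict[bytes, np.ndarray] = {}
        for m in self.rotation_matrices:
            for s in (m, -m):
                seen.setdefault(s.tobytes(), s)
        return list(seen.values())

    @property
    def ambiguity_matrices(self) -> list[np.ndarray]:
        return [np.array(m, dtype=int).reshape(3, 3) for m in self.ambiguity_ops]

    @property
    def n_rotations(self) -> int:
        return len(self.rotations)


@dataclass(frozen=True)
class UniqueIndex:
    """Canonical symmetry-reduced index, optionally carrying a Friedel sign."""

    h: int
    k: int
    l: int
    friedel_sign: int | None = None

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


REFLECTION_COLUMNS = ("h", "k", "l", "intensity", "sigma", "image", "dataset_id")


class ReflectionTable:
    """Unmerged observations: (h, k, l, intensity, sigma, image, dataset_id).

    Thin wrapper around a pandas DataFrame that enforces the row invariants
    once at construction.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in REFLECTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing reflection columns: {missing}")
        df = df.loc[:, list(REFLECTION_COLUMNS)].reset_index(drop=True)
        for c in ("h", "k", "l", "image"):
            df[c] = df[c].astype(np.int64)
        for c in ("intensity", "sigma"):
            df[c] = df[c].astype(np.float64)
        if validate and len(df):
            if (df["sigma"] <= 0).any():
                raise InvalidReflectionError("sigma must be > 0 for every row")
            zero = (df[["h", "k", "l"]] == 0).all(axis=1)
            if zero.any():
                raise InvalidReflectionError("reflection (0,0,0) is not allowed")
            if (df["image"] < 1).any():
                raise InvalidReflectionError("image indices must be >= 1")
        self.df = df

    @classmethod
    def from_arrays(
        cls,
        h: Iterable[int],
        k: Iterable[int],
        l: Iterable[int],
        intensity: Iterable[float],
        sigma: Iterable[float],
        image: Iterable[int] | int = 1,
        dataset_id: Iterable[str] | str = "ds0",
    ) -> "ReflectionTable":
        h = np.asarray(list(h))
        n = len(h)
        if np.isscalar(image):
            image = np.full(n, image)
        if isinstance(dataset_id, str):
            dataset_id = np.full(n, dataset_id, dtype=object)
        return cls(
            pd.DataFrame(
                {
                    "h": h,
                    "k": np.asarray(list(k)),
                    "l": np.asarray(list(l)),
                    "intensity": np.asarray(list(intensity), dtype=float),
                    "sigma": np.asarray(list(sigma), dtype=float),
                    "image": np.asarray(image),
                    "dataset_id": np.asarray(dataset_id, dtype=object),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def hkl(self) -> np.ndarray:
        """(n, 3) integer index array."""
        return self.df[["h", "k", "l"]].to_numpy()

    def d_spacings(self, cell: UnitCell) -> np.ndarray:
        return d_spacing_array(self.hkl, cell)

    def copy(self) -> "ReflectionTable":
        return ReflectionTable(self.df.copy(), validate=False)

    def concat(self, other: "ReflectionTable") -> "ReflectionTable":
        return ReflectionTable(
            pd.concat([self.df, other.df], ignore_index=True), validate=False
        )


# ---------------------------------------------------------------------------
# registry


def _parse_registry(text: str) -> dict[str, SymmetryGroup]:
    groups: dict[str, SymmetryGroup] = {}
    symbol = bravais = None
    rots: list[tuple[int, ...]] = []
    ambs: list[tuple[int, ...]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tag, _, rest = line.partition(" ")
        if tag == "group":
            symbol, bravais, rots, ambs = rest.strip(), None, [], []
        elif tag == "bravais":
            bravais = rest.strip()
        elif tag in ("rot", "amb"):
            nums = tuple(int(x) for x in rest.split())
            if len(nums) != 9:
                raise ValueError(f"registry: expected 9 integers, got {line!r}")
            (rots if tag == "rot" else ambs).append(nums)
        elif tag == "end":
            if symbol is None or bravais is None or not rots:
                raise ValueError("registry: incomplete group block")
            groups[symbol] = SymmetryGroup(symbol, bravais, tuple(rots), tuple(ambs))
            symbol = None
        else:
            raise ValueError(f"registry: unknown line {line!r}")
    return groups


_REGISTRY: dict[str, SymmetryGroup] | None = None


def load_registry() -> dict[str, SymmetryGroup]:
    """Load (and cache) the bundled symmetry-group registry."""
    global _REGISTRY
    if _REGISTRY is None:
        text = (
            resources.files("reflexio.data")
            .joinpath("symmetry_groups.txt")
            .read_text()
        )
        _REGISTRY = _parse_registry(text)
    return _REGISTRY


def get_group(symbol: str) -> SymmetryGroup:
    reg = load_registry()
    try:
        return reg[symbol]
    except KeyError:
        raise KeyError(
            f"unknown group {symbol!r}; registry has {sorted(reg)}"
        ) from None


# ---------------------------------------------------------------------------
# d-spacing


def d_spacing_array(hkl: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Resolutions (Å) for an (n, 3) index array via the reciprocal metric."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    if ((hkl == 0).all(axis=1)).any():
        raise InvalidReflectionError("reflection (0,0,0) has no d-spacing")
    g = cell.reciprocal_metric_tensor
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, g, hkl)
    return 1.0 / np.sqrt(inv_d2)


def d_spacing(hkl: tuple[int, int, int], cell: UnitCell) -> float:
    """Resolution in Å of one reflection."""
    return float(d_spacing_array(np.asarray(hkl)[None, :], cell)[0])


# ---------------------------------------------------------------------------
# canonicalization

_ENC = 1 << 21  # per-component encoding base; safe for |index| < 2^20


def _lex_keys(hkl: np.ndarray) -> np.ndarray:
    h = hkl[:, 0].astype(np.int64)
    k = hkl[:, 1].astype(np.int64)
    l = hkl[:, 2].astype(np.int64)
    return (h * _ENC + k) * _ENC + l


def canonicalize_array(
    hkl: np.ndarray, group: SymmetryGroup, friedel_merged: bool = True
) -> tuple[np.ndarray, np.ndarray | None]:
    """Map each row of an (n, 3) index array to its canonical representative.

    The representative is the lexicographically greatest index over the orbit
    (under the Laue group when Friedel mates are merged, otherwise over the
    rotation orbit of +hkl and −hkl tracked separately).  Returns the
    canonical (n, 3) array and, when ``friedel_merged`` is false, a ±1 sign
    array (ties on centric reflections resolve to +1).
    """
    hkl = np.asarray(hkl, dtype=np.int64)
    single = hkl.ndim == 1
    hkl = np.atleast_2d(hkl)
    rots = group.rotation_matrices
    # candidates: every rotation applied to +hkl and to -hkl
    plus = np.stack([hkl @ r.T for r in rots])          # (m, n, 3)
    minus = -plus
    cand = np.concatenate([plus, minus])                # (2m, n, 3)
    keys = (cand[:, :, 0] * _ENC + cand[:, :, 1]) * _ENC + cand[:, :, 2]
    m = len(rots)
    if friedel_merged:
        best = np.argmax(keys, axis=0)
        signs = None
    else:
        # prefer the +hkl family on exact key ties (centric reflections)
        best_plus = np.argmax(keys[:m], axis=0)
        best_minus = np.argmax(keys[m:], axis=0)
        kp = keys[:m][best_plus, np.arange(keys.shape[1])]
        km = keys[m:][best_minus, np.arange(keys.shape[1])]
        use_minus = km > kp
        best = np.where(use_minus, best_minus + m, best_plus)
        signs = np.where(use_minus, -1, 1).astype(np.int8)
    canon = cand[best, np.arange(cand.shape[1])]
    if single:
        canon = canon[0]
        signs = None if signs is None else signs[0]
    return canon, signs


def canonicalize(
    hkl: tuple[int, int, int], group: SymmetryGroup, friedel_merged: bool = True
) -> UniqueIndex:
    """Canonical :class:`UniqueIndex` of a single reflection."""
    if tuple(hkl) == (0, 0, 0):
        raise InvalidReflectionError("cannot canonicalize (0,0,0)")
    canon, sign = canonicalize_array(
        np.asarray(hkl, dtype=np.int64)[None, :], group, friedel_merged
    )
    s = None if sign is None else int(sign[0])
    return UniqueIndex(int(canon[0, 0]), int(canon[0, 1]), int(canon[0, 2]), s)


def unique_keys(
    hkl: np.ndarray, group: SymmetryGroup, friedel_merged: bool = True
) -> np.ndarray:
    """Scalar int64 key per reflection: equal keys = symmetry-equivalent.

    When Friedel mates are kept separate the sign is folded into the key so
    (+) and (−) mates of one index get distinct keys.
    """
    canon, signs = canonicalize_array(hkl, group, friedel_merged)
    keys = _lex_keys(np.atleast_2d(canon))
    if signs is not None:
        keys = keys * 2 + (np.atleast_1d(signs) < 0)
    return keys


def enumerate_unique(
    cell: UnitCell,
    group: SymmetryGroup,
    d_min: float,
    d_max: float,
    friedel_merged: bool = True,
) -> np.ndarray:
    """All canonical unique indices with d in [d_min, d_max], as (n, 3) array.

    Systematic absences are not removed; completeness denominators therefore
    carry a small known bias for screw-axis / centred groups.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    if not d_min < d_max:
        raise ValueError("require d_min < d_max")
    # |h| <= |a|/d_min since h = s . a and |s| <= 1/d_min
    hmax = int(math.floor(cell.a / d_min)) + 1
    kmax = int(math.floor(cell.b / d_min)) + 1
    lmax = int(math.floor(cell.c / d_min)) + 1
    hs = np.arange(-hmax, hmax + 1)
    ks = np.arange(-kmax, kmax + 1)
    ls = np.arange(-lmax, lmax + 1)
    grid = np.stack(np.meshgrid(hs, ks, ls, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[~(grid == 0).all(axis=1)]
    g = cell.reciprocal_metric_tensor
    inv_d2 = np.einsum("ni,ij,nj->n", grid.astype(float), g, grid.astype(float))
    d = 1.0 / np.sqrt(inv_d2)
    grid = grid[(d >= d_min) & (d <= d_max)]
    if not len(grid):
        return np.empty((0, 3), dtype=np.int64)
    canon, _ = canonicalize_array(grid, group, friedel_merged)
    keys = _lex_keys(canon)
    _, idx = np.unique(keys, return_index=True)
    return canon[np.sort(idx)]
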