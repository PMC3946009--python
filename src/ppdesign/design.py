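"""Ranking candidate experiments by predictive divergence.

The design matrix tabulates, for one model pair, the kNN-JSD between the
models' joint predictive samples for every combination of two single
measurements from a shared grid (symmetric by construction; the diagonal
holds replicate measurements of the same point).  Rankings across several
model pairs aggregate conservatively by the minimum divergence over pairs
by default: an experiment is only as good as the model pair it fails to
separate.  Greedy augmentation extends a chosen candidate one design point
at a time, which is the practical route when the full combinatorial grid
is too large.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import knn_jsd
from .models import DesignPoint
from .ppd import CandidateColumnSource, CandidateExperiment

__all__ = [
    "DesignMatrix",
    "RankedDesign",
    "compute_design_matrix",
    "rank_candidates",
    "augment_design",
]


@dataclass
class DesignMatrix:
    """JSD values over a candidate grid for one model pair.

    For ``d=2`` ``values`` is the symmetric m x m matrix indexed by
    single-measurement grid points; for ``d=1`` it is a length-m vector.
    """

    pair: tuple[str, str]
    grid: list[DesignPoint]
    values: np.ndarray
    d: int
    k: int
    degeneracies: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.grid)
        if self.d == 2 and self.values.shape != (m, m):
            raise ValueError("d=2 design matrix must be m x m")
        if self.d == 1 and self.values.shape != (m,):
            raise ValueError("d=1 design matrix must be a length-m vector")

    def cell(self, i: int, j: int | None = None) -> float:
        return float(self.values[i] if j is None else self.values[i, j])

    def candidate_label(self, i: int, j: int | None = None) -> str:
        if j is None:
            return self.grid[i].label
        return f"{self.grid[i].label} + {self.grid[j].label}"

    def iter_cells(self):
        if self.d == 1:
            for i in range(len(self.grid)):
                yield (i,), float(self.values[i])
        else:
            for i in range(len(self.grid)):
                for j in range(i, len(self.grid)):
                    yield (i, j), float(self.values[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for idx, v in self.iter_cells():
            rows.append(
                {
                    "candidate_i": self.grid[idx[0]].label,
                    "candidate_j": self.grid[idx[-1]].label if self.d == 2 else "",
                    "pair": f"{self.pair[0]} vs {self.pair[1]}",
                    "jsd": v,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def compute_design_matrix(
    sources: Mapping[str, CandidateColumnSource],
    pair: tuple[str, str],
    k: int = 10,
    d: int = 2,
    seed: int = 0,
) -> DesignMatrix:
    """Fill the candidate grid with kNN-JSD values for one model pair.

    Both models must expose column sources over the same grid.  Symmetric
    cells are computed once; noise realizations are drawn from
    per-cell generators spawned deterministically from ``seed``, so the
    matrix is reproducible bit-for-bit.
    """
    a, b = sources[pair[0]], sources[pair[1]]
    if len(a.grid) != len(b.grid):
        raise ValueError("column sources must share the candidate grid")
    for pa, pb in zip(a.grid, b.grid):
        if pa != pb:
            raise ValueError(f"grid mismatch between models at {pa.label} vs {pb.label}")
    m = len(a.grid)
    degen = 0
    if d == 1:
        vals = np.empty(m)
        for i in range(m):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
            rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(2)]
            est = knn_jsd(
                a.columns([i], rng_a), b.columns([i], rng_b), k=k, labels=pair
            )
            vals[i] = est.jsd_bits
            degen += est.degeneracies
        return DesignMatrix(pair, list(a.grid), vals, d=1, k=k, degeneracies=degen)
    if d != 2:
        raise ValueError("design matrices support d in {1, 2}")
    vals = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(i, j))
            rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(2)]
            est = knn_jsd(
                a.columns([i, j], rng_a), b.columns([i, j], rng_b), k=k, labels=pair
            )
            vals[i, j] = vals[j, i] = est.jsd_bits
            degen += est.degeneracies
    return DesignMatrix(pair, list(a.grid), vals, d=2, k=k, degeneracies=degen)


@dataclass
class RankedDesign:
    """Candidates ordered by aggregate discriminability (descending); ties
    broken by candidate label."""

    entries: list[dict] = field(default_factory=list)

    def top(self, n: int = 10) -> list[dict]:
        return self.entries[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


_AGGREGATES = {
    "min": np.min,
    "mean": np.mean,
    "max": np.max,
}


def rank_candidates(
    matrices: Sequence[DesignMatrix],
    aggregate: str = "min",
) -> RankedDesign:
    """Rank the shared candidate grid across model pairs.

    The default worst-case (minimum over pairs) aggregation is the
    conservative choice: a candidate only scores well if it separates
    every pair.
    """
    if not matrices:
        raise ValueError("need at least one design matrix")
    if aggregate not in _AGGREGATES:
        raise ValueError(f"aggregate must be one of {sorted(_AGGREGATES)}")
    agg = _AGGREGATES[aggregate]
    ref = matrices[0]
    cells = [idx for idx, _ in ref.iter_cells()]
    entries = []
    for idx in cells:
        per_pair = {}
        for mat in matrices:
            v = mat.cell(*idx) if mat.d == 2 else mat.cell(idx[0])
            per_pair[f"{mat.pair[0]} vs {mat.pair[1]}"] = v
        label = ref.candidate_label(*idx) if ref.d == 2 else ref.candidate_label(idx[0])
        entries.append(
            {
                "candidate": label,
                "indices": idx,
                **per_pair,
                "score": float(agg(list(per_pair.values()))),
            }
        )
    entries.sort(key=lambda e: (-e["score"], e["candidate"]))
    return RankedDesign(entries=entries)


def augment_design(
    current: Sequence[int] | CandidateExperiment,
    pool: Sequence[int] | Sequence[DesignPoint],
    source_a: CandidateColumnSource,
    source_b: CandidateColumnSource,
    k: int = 10,
    seed: int = 0,
    max_d: int = 3,
    pair: tuple[str, str] = ("M1", "M2"),
) -> list[tuple[int, float]]:
    """Rank one-point extensions of a candidate by the JSD of the extended
    design.

    Adding a coordinate can never decrease the true JSD, so extensions are
    judged on their absolute divergence; the dimension cap reflects the
    declining accuracy of neighbor-distance density estimates in higher
    dimension.  Returns (pool index into the grid, jsd) sorted descending.
    """
    cur_idx = _to_indices(current, source_a)
    pool_idx = _to_indices(pool, source_a)
    if len(cur_idx) + 1 > max_d:
        raise ValueError(
            f"extension would exceed the design-dimension cap of {max_d}; "
            "density estimation accuracy degrades with added experiments"
        )
    results = []
    for pi in pool_idx:
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(pi,))
        rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(2)]
        idx = list(cur_idx) + [pi]
        est = knn_jsd(
            source_a.columns(idx, rng_a), source_b.columns(idx, rng_b), k=k, labels=pair
        )
        results.append((pi, est.jsd_bits))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results


def _to_indices(spec, source: CandidateColumnSource) -> list[int]:
    if isinstance(spec, CandidateExperiment):
        items: Sequence = spec.points
    else:
        items = list(spec)
    out = []
    for it in items:
        if isinstance(it, DesignPoint):
            out.append(source.grid.index(it))
        else:
            out.append(int(it))
    return out
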