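"""Nested random downsampling of cell sets.

Subsets are drawn uniformly without replacement, each level from the
previous one, either by repeated halving (floor division on odd sizes) or
by an explicit descending fraction series. Uniform sampling keeps library
proportions in expectation; :func:`library_representation` verifies that
post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SatkitError
from .io import CountMatrix

__all__ = [
    "DownsampleSeries",
    "nested_halving",
    "fraction_series",
    "library_representation",
]


@dataclass
class DownsampleSeries:
    """An ordered chain of nested barcode subsets."""

    subsets: list[list[str]]
    seed: int
    scheme: str
    parent_id: str = "full"

    def __post_init__(self) -> None:
        sizes = self.sizes
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise SatkitError("subset sizes must be strictly decreasing")
        for larger, smaller in zip(self.subsets, self.subsets[1:]):
            if not set(smaller) <= set(larger):
                raise SatkitError("each subset must be nested in its predecessor")

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.subsets]

    def __iter__(self):
        return iter(self.subsets)

    def __len__(self) -> int:
        return len(self.subsets)


def _draw(rng: np.random.Generator, cells: list[str], size: int) -> list[str]:
    idx = rng.choice(len(cells), size=size, replace=False)
    idx.sort()
    return [cells[i] for i in idx]


def nested_halving(
    cells: list[str], n_levels: int, seed: int, parent_id: str = "full"
) -> DownsampleSeries:
    """Halve the cell set ``n_levels`` times, each level sampled from the last.

    Level i holds floor(n / 2^i) cells; e.g. 101,592 cells halve to 50,796
    then 25,398, 12,699, 6,349.
    """
    cells = list(cells)
    n = len(cells)
    if n_levels < 1:
        raise SatkitError("n_levels must be >= 1")
    if 2**n_levels > n:
        raise SatkitError(f"cannot halve {n} cells {n_levels} times")
    rng = np.random.default_rng(seed)
    subsets = []
    current = cells
    for level in range(1, n_levels + 1):
        current = _draw(rng, current, n // 2**level)
        subsets.append(current)
    return DownsampleSeries(subsets=subsets, seed=seed, scheme="halving", parent_id=parent_id)


def fraction_series(
    cells: list[str],
    fractions: list[float],
    seed: int,
    parent_id: str = "full",
) -> DownsampleSeries:
    """Nested subsets of size round(f * n) for a descending fraction list."""
    cells = list(cells)
    if any(not 0 < f <= 1 for f in fractions):
        raise SatkitError("fractions must lie in (0, 1]")
    if any(b >= a for a, b in zip(fractions, fractions[1:])):
        raise SatkitError("fractions must be strictly descending")
    rng = np.random.default_rng(seed)
    subsets = []
    current = cells
    n = len(cells)
    for f in fractions:
        size = int(round(f * n))
        if size >= len(current):
            current = list(current)
        else:
            current = _draw(rng, current, size)
        subsets.append(current)
    return DownsampleSeries(subsets=subsets, seed=seed, scheme="fractions", parent_id=parent_id)


def library_representation(subset: list[str], matrix: CountMatrix) -> pd.DataFrame:
    """Per-library counts in ``subset`` and the subset/source proportion ratio.

    A ratio near 1 for every library confirms that uniform sampling kept
    library composition intact.
    """
    libs = pd.Series(matrix.library_labels, index=matrix.barcodes, name="library")
    source_counts = libs.value_counts()
    in_subset = libs.loc[[b for b in subset if b in libs.index]]
    subset_counts = in_subset.value_counts().reindex(source_counts.index, fill_value=0)
    source_frac = source_counts / source_counts.sum()
    subset_frac = subset_counts / max(len(subset), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = subset_frac / source_frac
    return pd.DataFrame(
        {
            "source_count": source_counts,
            "subset_count": subset_counts,
            "source_frac": source_frac,
            "subset_frac": subset_frac,
            "ratio": ratio,
        }
    )
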