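"""Candidate cis-regulatory module (CRM) enumeration.

A candidate CRM is a unique combination of TFs observed binding together at
the regulatory regions of at least one gene. Candidates are collected into a
K×T binary matrix B whose first row is the all-zero *background* module —
the explicit model for genes regulated by none of the candidates. For each
gene we also precompute which modules are *compatible* with its observed
bindings: module k is compatible with gene n when every TF of module k binds
gene n (row k is entrywise ≤ the gene's binding row). Module assignments are
sampled only over a gene's compatible set, which keeps the inferred network
consistent with the binding prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import BindingTable

__all__ = [
    "CandidateCRMSet",
    "CompatibilityMap",
    "enumerate_candidates",
    "build_compatibility",
]


class CompatibilityMap(list):
    """Per-gene arrays of compatible module indices.

    Behaves as a plain list of index arrays; the Gibbs engine additionally
    caches flattened (gene, module) pair arrays on it so the assignment
    step can score all compatible pairs with batched array operations.
    """

    _pair_cache: tuple | None = None


@dataclass
class CandidateCRMSet:
    """Matrix B of candidate modules plus the background row."""

    tf_ids: list[str]
    B: np.ndarray  # K×T binary
    background_index: int
    support: np.ndarray  # per-row count of genes whose pattern contains the row

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.int8)
        self.support = np.asarray(self.support, dtype=int)
        if len({tuple(row) for row in self.B}) != self.B.shape[0]:
            raise ValueError("candidate rows must be distinct")
        zero_rows = np.flatnonzero(~self.B.any(axis=1))
        if zero_rows.size != 1 or zero_rows[0] != self.background_index:
            raise ValueError("exactly one all-zero background row required")

    @property
    def n_modules(self) -> int:
        return self.B.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.B.shape[1]

    def module_tfs(self, k: int) -> np.ndarray:
        """Indices of the TFs that are members of module k."""
        return np.flatnonzero(self.B[k])

    def module_size(self, k: int) -> int:
        return int(self.B[k].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: module_id, size, member TFs, gene support."""
        tfs = np.asarray(self.tf_ids, dtype=object)
        rows = [
            {
                "module_id": k,
                "size": self.module_size(k),
                "tfs": ",".join(tfs[self.module_tfs(k)]),
                "gene_support": int(self.support[k]),
            }
            for k in range(self.n_modules)
        ]
        return pd.DataFrame(rows)


def _pattern_key(pattern: np.ndarray) -> tuple[int, ...]:
    # sort key: module size first, then member TF indices lexicographically
    members = tuple(int(i) for i in np.flatnonzero(pattern))
    return members


def enumerate_candidates(
    binding: BindingTable,
    min_tfs: int = 1,
    min_gene_support: int = 1,
    max_subset_size: int | None = None,
) -> CandidateCRMSet:
    """Collect candidate modules from the observed binding patterns.

    The candidate list is the set of distinct non-zero gene binding rows with
    at least ``min_tfs`` member TFs, observed in at least ``min_gene_support``
    genes, plus the background row. Rows are ordered background first, then
    lexicographically by member TF indices.

    When ``max_subset_size`` is given, all non-empty TF subsets of each
    observed pattern up to that size are additionally enumerated (sensitivity
    analysis mode; combinatorially expensive and off by default). Subsets
    inherit support counts from every gene whose pattern contains them.
    """
    if min_tfs < 1 or min_gene_support < 1:
        raise ValueError("min_tfs and min_gene_support must be >= 1")
    patterns: dict[tuple[int, ...], int] = {}
    for row in binding.values:
        key = _pattern_key(row)
        if key:
            patterns[key] = patterns.get(key, 0) + 1

    candidates: set[tuple[int, ...]] = set()
    if max_subset_size is None:
        candidates.update(patterns)
    else:
        for key in patterns:
            for size in range(1, min(len(key), max_subset_size) + 1):
                candidates.update(combinations(key, size))
            candidates.add(key)

    def _mask(key: tuple[int, ...]) -> int:
        m = 0
        for i in key:
            m |= 1 << i
        return m

    pattern_masks = [(_mask(pat), count) for pat, count in patterns.items()]

    def support_of(key: tuple[int, ...]) -> int:
        m = _mask(key)
        return sum(count for pm, count in pattern_masks if m & pm == m)

    kept = sorted(
        key
        for key in candidates
        if len(key) >= min_tfs and support_of(key) >= min_gene_support
    )
    if not patterns:
        warnings.warn(
            "binding matrix is all-zero; only the background module exists "
            "and inference degenerates to noise fitting",
            stacklevel=2,
        )

    T = binding.n_tfs
    B = np.zeros((1 + len(kept), T), dtype=np.int8)
    support = np.zeros(1 + len(kept), dtype=int)
    support[0] = binding.n_genes  # every gene is compatible with background
    for i, key in enumerate(kept, start=1):
        B[i, list(key)] = 1
        support[i] = support_of(key)
    return CandidateCRMSet(list(binding.tf_ids), B, 0, support)


def build_compatibility(
    binding: BindingTable, crms: CandidateCRMSet
) -> CompatibilityMap:
    """Per-gene arrays of module indices compatible with the gene's bindings.

    Module k is compatible with gene n iff ``B[k, t] <= binding[n, t]`` for
    every TF t; the background module is compatible with every gene.
    """
    if list(binding.tf_ids) != list(crms.tf_ids):
        raise ValueError("TF ordering differs between binding table and CRM set")
    # subset test via missing-TF counts: module k is compatible with gene n
    # iff none of its TFs is unbound at the gene
    missing = crms.B.astype(np.int32) @ (1 - binding.values.astype(np.int32)).T
    ok = missing == 0  # K×N
    return CompatibilityMap(
        np.flatnonzero(ok[:, n]) for n in range(binding.n_genes)
    )
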