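"""Posterior summaries: CRM target calls, CRM ranking, TF–gene network.

A gene's sampling frequency for a module — the fraction of collected Gibbs
sweeps in which the gene was assigned that module — is its posterior
probability of regulation by that module. Calls threshold these
frequencies; the TF–gene regulation probability sums frequencies over all
modules containing the TF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import CandidateCRMSet

__all__ = [
    "PosteriorSummary",
    "CRMReport",
    "TFGeneNetwork",
    "call_targets",
    "tf_gene_probabilities",
]


@dataclass
class PosteriorSummary:
    """Accumulated posterior quantities from the Gibbs sampler."""

    gene_ids: list[str]
    freq: np.ndarray  # N×K per-gene module sampling frequencies
    mean_X: np.ndarray  # T×M
    mean_A: np.ndarray  # N×T
    mean_R: np.ndarray  # length N
    mean_sigma2_e: float

    def __post_init__(self) -> None:
        rows = self.freq.sum(axis=1)
        if np.abs(rows - 1.0).max(initial=0.0) > 1e-9:
            raise ValueError("per-gene module frequencies must sum to 1")
        if (self.freq < 0).any() or (self.freq > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")

    def freq_frame(self, crms: CandidateCRMSet) -> pd.DataFrame:
        cols = [f"module_{k}" for k in range(crms.n_modules)]
        return pd.DataFrame(self.freq, index=self.gene_ids, columns=cols)


@dataclass
class CRMModuleCall:
    """One ranked module with its called target genes."""

    rank: int
    module_id: int
    tf_ids: list[str]
    target_gene_ids: list[str]

    @property
    def n_targets(self) -> int:
        return len(self.target_gene_ids)


@dataclass
class CRMReport:
    """Ranked list of modules with at least one called target gene."""

    cutoff: float
    modules: list[CRMModuleCall]

    def called_pairs(self) -> list[tuple[str, int]]:
        """All (gene id, module id) calls across the report."""
        return [
            (g, m.module_id) for m in self.modules for g in m.target_gene_ids
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": m.rank,
                "module_id": m.module_id,
                "tfs": ",".join(m.tf_ids),
                "n_targets": m.n_targets,
                "target_genes": ",".join(m.target_gene_ids),
            }
            for m in self.modules
        ]
        return pd.DataFrame(
            rows, columns=["rank", "module_id", "tfs", "n_targets", "target_genes"]
        )


@dataclass
class TFGeneNetwork:
    """TF–gene regulation probabilities (genes × TFs)."""

    gene_ids: list[str]
    tf_ids: list[str]
    prob: np.ndarray  # N×T in [0, 1]

    def edges(self, cutoff: float) -> set[tuple[str, str]]:
        """(gene, TF) pairs whose regulation probability reaches the cutoff."""
        idx = np.argwhere(self.prob >= cutoff)
        return {(self.gene_ids[n], self.tf_ids[t]) for n, t in idx}

    def to_frame(self, edge_cutoff: float = 0.85) -> pd.DataFrame:
        rows = []
        for n, g in enumerate(self.gene_ids):
            for t, tf in enumerate(self.tf_ids):
                p = float(self.prob[n, t])
                rows.append(
                    {
                        "gene": g,
                        "tf": tf,
                        "probability": p,
                        "called": int(p >= edge_cutoff),
                    }
                )
        return pd.DataFrame(rows)


def call_targets(
    summary: PosteriorSummary, crms: CandidateCRMSet, cutoff: float = 0.85
) -> CRMReport:
    """Call gene–module regulation at a posterior-frequency cutoff and rank.

    Gene n is a target of module k iff ``freq[n, k] >= cutoff``. The
    background module is never reported. Modules are ranked by descending
    target count; ties break toward the smaller module, then by
    lexicographic member TF ids.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    tfs = np.asarray(crms.tf_ids, dtype=object)
    entries = []
    for k in range(crms.n_modules):
        if k == crms.background_index:
            continue
        genes = [
            summary.gene_ids[n]
            for n in np.flatnonzero(summary.freq[:, k] >= cutoff)
        ]
        if genes:
            member_ids = sorted(tfs[crms.module_tfs(k)])
            entries.append((len(genes), crms.module_size(k), member_ids, k, genes))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    modules = [
        CRMModuleCall(rank, k, member_ids, genes)
        for rank, (_, _, member_ids, k, genes) in enumerate(entries, start=1)
    ]
    return CRMReport(cutoff, modules)


def tf_gene_probabilities(
    summary: PosteriorSummary, crms: CandidateCRMSet
) -> TFGeneNetwork:
    """P(TF t regulates gene n) = sum of freq over modules containing t.

    The background module contains no TF and so contributes to no edge;
    every probability is bounded by 1 - freq[n, background].
    """
    prob = summary.freq @ crms.B.astype(float)
    return TFGeneNetwork(list(summary.gene_ids), list(crms.tf_ids), prob)
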