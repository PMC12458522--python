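"""Network anatomy of a predictive edge set.

Edges are attributed to atlas *blocks*: unordered pairs of functional
networks (within-network when the two networks coincide). For a 10-network
atlas there are 55 blocks (10 within + 45 between). Enrichment of a mask's
m edges in a block holding K of the N possible edges is assessed with the
hypergeometric tail p = P[X >= k] (over-representation only; depletion is
not flagged) and reported as a likelihood 1 - p, with blocks whose
likelihood exceeds 0.95 flagged as greater than chance. No multiple-testing
correction is applied across blocks; flags are at raw p < .05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EdgeMask
from .datamodel import NetworkAtlas, edge_count, edge_pairs
from .transfer import consensus_mask

__all__ = [
    "BlockCounts",
    "NetworkAttribution",
    "block_edge_counts",
    "hypergeometric_likelihood",
    "attribute_network",
    "shared_edges",
]

FLAG_LIKELIHOOD = 0.95


@dataclass(frozen=True)
class BlockCounts:
    """One network block: how many node pairs it spans, how many the mask hit."""

    block: tuple[str, str]
    possible_edges: int
    observed_edges: int

    def __post_init__(self) -> None:
        if not (0 <= self.observed_edges <= self.possible_edges):
            raise ValueError("observed_edges must lie in [0, possible_edges]")


@dataclass(frozen=True)
class NetworkAttribution:
    """Per-block counts and enrichment likelihoods, sorted by likelihood."""

    blocks: tuple[BlockCounts, ...]
    p_enrich: np.ndarray
    likelihoods: np.ndarray
    mask_size: int
    total_edges: int

    def flagged(self) -> np.ndarray:
        return self.likelihoods > FLAG_LIKELIHOOD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": ["-".join(b.block) for b in self.blocks],
                "possible_edges": [b.possible_edges for b in self.blocks],
                "observed_edges": [b.observed_edges for b in self.blocks],
                "p_enrich": self.p_enrich,
                "likelihood": self.likelihoods,
                "flagged": self.flagged(),
            }
        )


def block_edge_counts(mask: EdgeMask, atlas: NetworkAtlas) -> list[BlockCounts]:
    """Assign every node pair to its unordered network block and count.

    Returns one entry per block (within-network blocks first, then
    between-network pairs, in atlas network order); the possible-edge
    counts sum to E and the observed counts to the mask size.
    """
    n = atlas.node_count
    if edge_count(n) != mask.n_edges:
        raise ValueError(
            f"atlas implies E = {edge_count(n)} but mask has n_edges = {mask.n_edges}"
        )
    codes = atlas.label_codes()
    iu, ju = edge_pairs(n)
    ci, cj = codes[iu], codes[ju]
    lo = np.minimum(ci, cj)
    hi = np.maximum(ci, cj)
    G = len(atlas.network_names)
    block_of_edge = lo * G + hi
    K = np.bincount(block_of_edge, minlength=G * G)
    k = np.bincount(block_of_edge[mask.indices], minlength=G * G)
    out: list[BlockCounts] = []
    for a in range(G):
        for b in range(a, G):
            out.append(
                BlockCounts(
                    block=(atlas.network_names[a], atlas.network_names[b]),
                    possible_edges=int(K[a * G + b]),
                    observed_edges=int(k[a * G + b]),
                )
            )
    return out


def hypergeometric_likelihood(k, K, m, N) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Hypergeometric over-representation tail and its complement.

    For X ~ Hypergeometric(population N, successes K, draws m):
    ``p_enrich = P[X >= k]`` and ``likelihood = 1 - p_enrich = CDF(k - 1)``.
    Evaluated in log space by scipy, stable at N in the tens of thousands.
    Scalar or array arguments are accepted elementwise.
    """
    k = np.asarray(k)
    K = np.asarray(K)
    m = np.asarray(m)
    N = np.asarray(N)
    if np.any(k < 0) or np.any(k > np.minimum(K, m)):
        raise ValueError("require 0 <= k <= min(K, m)")
    if np.any(K > N) or np.any(m > N) or np.any(K < 0) or np.any(m < 0):
        raise ValueError("require 0 <= K <= N and 0 <= m <= N")
    p_enrich = stats.hypergeom.sf(k - 1, N, K, m)
    likelihood = stats.hypergeom.cdf(k - 1, N, K, m)
    if p_enrich.ndim == 0:
        return float(p_enrich), float(likelihood)
    return p_enrich, likelihood


def attribute_network(mask: EdgeMask, atlas: NetworkAtlas) -> NetworkAttribution:
    """Per-block hypergeometric enrichment of a mask against the atlas.

    Blocks are ordered from greatest to least likelihood (ties broken
    alphabetically by block name for deterministic output).
    """
    counts = block_edge_counts(mask, atlas)
    N = mask.n_edges
    m = len(mask)
    k = np.array([c.observed_edges for c in counts])
    K = np.array([c.possible_edges for c in counts])
    p_enrich, likelihood = hypergeometric_likelihood(k, K, m, N)
    order = sorted(
        range(len(counts)), key=lambda i: (-likelihood[i], counts[i].block)
    )
    return NetworkAttribution(
        blocks=tuple(counts[i] for i in order),
        p_enrich=np.asarray(p_enrich)[order],
        likelihoods=np.asarray(likelihood)[order],
        mask_size=m,
        total_edges=N,
    )


def shared_edges(
    masks_a: list[EdgeMask],
    masks_b: list[EdgeMask],
    mode: str = "low",
    high_fraction: float = 0.9,
) -> EdgeMask:
    """Edges common to two cohorts' fold masks at a consistency threshold.

    ``mode="low"``: union of fold masks per cohort (any edge identified in
    any fold); ``mode="high"``: per-cohort consensus at ``high_fraction``.
    The intersection of the two cohorts' resulting masks is returned.
    """
    if mode not in ("low", "high"):
        raise ValueError("mode must be 'low' or 'high'")
    # a vanishing fraction makes the consensus requirement 1 fold, i.e. union
    fraction = high_fraction if mode == "high" else 1e-9
    combined_a = consensus_mask(masks_a, fraction)
    combined_b = consensus_mask(masks_b, fraction)
    if combined_a.sign != combined_b.sign or combined_a.n_edges != combined_b.n_edges:
        raise ValueError("cohort masks differ in sign or edge count")
    shared = np.intersect1d(combined_a.indices, combined_b.indices)
    return EdgeMask(indices=shared, sign=combined_a.sign, n_edges=combined_a.n_edges)
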