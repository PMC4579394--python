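"""Reference-haplotype selection for the copying HMM.

With very large panels, conditioning every study haplotype on every
reference haplotype is wasteful; most references contribute nothing to a
given mosaic.  Three strategies are provided:

* ``all`` — no approximation; every reference haplotype conditions the HMM.
* ``hamming`` — the classic k_hap heuristic: keep the k references with the
  smallest region-wide Hamming distance to the study haplotype over the
  typed sites of the (buffered) chunk.
* ``tracts`` — a local-sharing heuristic: at a set of evenly spaced anchor
  sites, rank references by the length of the contiguous exact-match tract
  (in typed sites) around the anchor and keep the best few per anchor.
  Long local tracts flag references that share a recent haplotype segment
  with the study individual even when their region-wide distance is poor,
  which is what matters for imputing rare alleles carried on such segments.

Selection is deterministic: ties always break toward the lower reference
index, and chosen indices are returned in ascending order so that a
saturated selection (k >= panel size) is bit-identical to ``all``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionSpec",
    "SelectionResult",
    "select_all",
    "select_hamming",
    "select_tracts",
    "select_references",
    "shared_tract_length",
]

STRATEGIES = ("all", "hamming", "tracts")


@dataclass(frozen=True)
class SelectionSpec:
    """How to choose conditioning references.

    ``k`` is the target number of reference haplotypes (the k_hap analog,
    clipped to the panel size); ``anchors`` is the number of evenly spaced
    anchor sites used by the ``tracts`` strategy.
    """

    strategy: str = "hamming"
    k: int = 10_000
    anchors: int = 16

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; use one of {STRATEGIES}")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.anchors < 1:
            raise ValueError("anchors must be at least 1")


@dataclass
class SelectionResult:
    """Chosen reference indices (ascending) and the scores that chose them."""

    indices: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("selected indices must be unique")

    @property
    def k(self) -> int:
        return self.indices.size


def select_all(panel_size: int) -> SelectionResult:
    """Use every reference haplotype (no approximation)."""
    if panel_size < 2:
        raise ValueError("panel must contain at least two haplotypes")
    idx = np.arange(panel_size)
    return SelectionResult(indices=idx, scores=np.zeros(panel_size))


def select_hamming(
    study_typed: np.ndarray, panel_typed: np.ndarray, k: int
) -> SelectionResult:
    """k references with smallest region-wide Hamming distance to the study.

    Distances are counted over all typed sites supplied (i.e. the buffered
    chunk); ties break toward the lower reference index.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    panel_typed = np.asarray(panel_typed)
    study_typed = np.asarray(study_typed)
    if panel_typed.ndim != 2 or panel_typed.shape[1] != study_typed.shape[0]:
        raise ValueError("panel and study typed matrices are misaligned")
    dist = (panel_typed != study_typed[np.newaxis, :]).sum(axis=1)
    order = np.argsort(dist, kind="stable")  # stable => lower index wins ties
    chosen = np.sort(order[: min(k, panel_typed.shape[0])])
    return SelectionResult(indices=chosen, scores=dist[chosen].astype(float))


def shared_tract_length(
    study_typed: np.ndarray, ref_typed: np.ndarray, site_idx: int
) -> int:
    """Length (in typed sites) of the maximal exact-match run covering site_idx.

    Zero if study and reference disagree at ``site_idx`` itself.
    """
    study_typed = np.asarray(study_typed)
    ref_typed = np.asarray(ref_typed)
    t = study_typed.shape[0]
    if ref_typed.shape != (t,):
        raise ValueError("study and reference vectors must have equal length")
    if not (0 <= site_idx < t):
        raise IndexError(f"site index {site_idx} out of range [0, {t})")
    if study_typed[site_idx] != ref_typed[site_idx]:
        return 0
    left = site_idx
    while left > 0 and study_typed[left - 1] == ref_typed[left - 1]:
        left -= 1
    right = site_idx
    while right < t - 1 and study_typed[right + 1] == ref_typed[right + 1]:
        right += 1
    return right - left + 1


def _tract_lengths_at_anchors(
    study_typed: np.ndarray, panel_typed: np.ndarray, anchors: np.ndarray
) -> np.ndarray:
    """Matrix (n_refs x n_anchors) of shared-tract lengths, vectorized.

    Uses run-length recurrences over the match matrix: L[.,t] = length of
    the match run ending at t, R[.,t] = run starting at t; the tract
    covering an anchor a has length L + R - 1 when the anchor matches.
    """
    match = panel_typed == study_typed[np.newaxis, :]
    n_refs, t = match.shape
    left = np.zeros((n_refs, t), dtype=np.int32)
    left[:, 0] = match[:, 0]
    for j in range(1, t):
        left[:, j] = (left[:, j - 1] + 1) * match[:, j]
    right = np.zeros((n_refs, t), dtype=np.int32)
    right[:, t - 1] = match[:, t - 1]
    for j in range(t - 2, -1, -1):
        right[:, j] = (right[:, j + 1] + 1) * match[:, j]
    tracts = left[:, anchors] + right[:, anchors] - 1
    tracts[~match[:, anchors]] = 0
    return tracts


def _anchor_positions(n_typed: int, anchors: int) -> np.ndarray:
    pos = np.unique(np.round(np.linspace(0, n_typed - 1, anchors)).astype(np.int64))
    return pos


def select_tracts(
    study_typed: np.ndarray, panel_typed: np.ndarray, spec: SelectionSpec
) -> SelectionResult:
    """Local tract-sharing selection.

    At each of ``spec.anchors`` evenly spaced anchor sites the references
    are ranked by the shared-tract length around that anchor and the top
    ``ceil(k / anchors)`` are kept; the union of the per-anchor sets is the
    candidate pool.  A pool larger than k is trimmed by the maximum tract
    length over anchors (ties toward the lower index); a smaller pool is
    topped up with the best remaining region-wide Hamming candidates.
    """
    panel_typed = np.asarray(panel_typed)
    study_typed = np.asarray(study_typed)
    n_refs, t = panel_typed.shape
    if spec.anchors > t:
        raise ValueError("more anchors than typed sites")
    k = min(spec.k, n_refs)
    if k >= n_refs:
        return SelectionResult(
            indices=np.arange(n_refs), scores=np.zeros(n_refs)
        )
    anchors = _anchor_positions(t, spec.anchors)
    tracts = _tract_lengths_at_anchors(study_typed, panel_typed, anchors)
    quota = math.ceil(k / anchors.size)

    chosen: set[int] = set()
    for a in range(anchors.size):
        # stable sort on negated tract length => ties favour lower index
        order = np.argsort(-tracts[:, a], kind="stable")
        chosen.update(int(i) for i in order[:quota])

    max_tract = tracts.max(axis=1)
    if len(chosen) > k:
        pool = np.fromiter(chosen, dtype=np.int64)
        pool = pool[np.argsort(pool)]  # ascending index for stable tie-break
        order = np.argsort(-max_tract[pool], kind="stable")
        chosen = set(int(i) for i in pool[order[:k]])
    elif len(chosen) < k:
        dist = (panel_typed != study_typed[np.newaxis, :]).sum(axis=1)
        order = np.argsort(dist, kind="stable")
        for i in order:
            if len(chosen) >= k:
                break
            chosen.add(int(i))

    idx = np.sort(np.fromiter(chosen, dtype=np.int64))
    return SelectionResult(indices=idx, scores=max_tract[idx].astype(float))


def select_references(
    study_typed: np.ndarray, panel_typed: np.ndarray, spec: SelectionSpec
) -> SelectionResult:
    """Dispatch to the strategy named in ``spec``."""
    n_refs = np.asarray(panel_typed).shape[0]
    if spec.strategy == "all":
        return select_all(n_refs)
    if spec.strategy == "hamming":
        return select_hamming(study_typed, panel_typed, spec.k)
    return select_tracts(study_typed, panel_typed, spec)
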