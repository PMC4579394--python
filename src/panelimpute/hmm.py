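"""Li-Stephens haplotype-copying HMM for pre-phased imputation.

Each study haplotype is modelled as an imperfect mosaic of K reference
haplotypes.  The hidden state at a typed site is the reference haplotype
being copied; between adjacent typed sites separated by genetic distance
d (cM) the chain stays on the same template with probability
``exp(-rho/K)`` where ``rho = 4 * Ne * d/100`` (Morgans), and otherwise
switches to a uniformly chosen template (including the current one).  The
emitted study allele equals the copied reference allele with probability
``1 - epsilon``, where epsilon derives from the Watterson mutation
parameter ``theta = 1 / sum_{i<K} 1/i`` as
``epsilon = theta / (2 * (theta + K))``.

Posterior copying probabilities at typed sites come from a scaled
forward-backward pass; at untyped sites the state posterior is
interpolated linearly in cM between the flanking typed sites before the
allele-emission mixture is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .panels import GeneticMap, HaplotypePanel

__all__ = [
    "HMMParams",
    "DiploidCalls",
    "theta_watterson",
    "emission_epsilon",
    "transition",
    "forward_backward",
    "impute_haploid",
    "impute_diploid",
    "best_guess",
]


@dataclass(frozen=True)
class HMMParams:
    """Tunable HMM parameters.

    ``epsilon`` defaults to the Watterson-derived value for the number of
    conditioning haplotypes K actually in use (after selection); set it
    explicitly to override.
    """

    ne: float = 20_000.0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if self.epsilon is not None and not (0.0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must lie in [0, 0.5)")

    def epsilon_for(self, k: int) -> float:
        return self.epsilon if self.epsilon is not None else emission_epsilon(k)


@dataclass
class DiploidCalls:
    """Per-site genotype probability triples and dosages for one sample."""

    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    @property
    def dosage(self) -> np.ndarray:
        return self.p1 + 2.0 * self.p2

    def probs(self) -> np.ndarray:
        """Stacked (n_sites, 3) probability matrix."""
        return np.stack([self.p0, self.p1, self.p2], axis=1)


def theta_watterson(k: int) -> float:
    """Watterson mutation parameter for K reference haplotypes."""
    if k < 2:
        raise ValueError("need at least two reference haplotypes")
    return 1.0 / np.sum(1.0 / np.arange(1, k))


def emission_epsilon(k: int) -> float:
    """Copying-error probability derived from the Watterson theta."""
    theta = theta_watterson(k)
    return theta / (2.0 * (theta + k))


def transition(d_cm: float, ne: float, k: int) -> tuple[float, float]:
    """No-recombination and per-state switch probabilities for one gap.

    Returns ``(p_norecomb, p_switch_each)``: the probability of moving to a
    specific state j is ``p_switch_each``, plus ``p_norecomb`` when j is the
    current state.
    """
    if d_cm < 0:
        raise ValueError("genetic distance must be non-negative")
    rho = 4.0 * ne * (d_cm / 100.0)
    p_norecomb = float(np.exp(-rho / k))
    return p_norecomb, (1.0 - p_norecomb) / k


def forward_backward(
    obs: np.ndarray,
    refs: np.ndarray,
    dists_cm: np.ndarray,
    params: HMMParams | None = None,
) -> np.ndarray:
    """Posterior copying probabilities ``gamma`` (T x K) at typed sites.

    ``obs`` holds the study alleles at T typed sites, ``refs`` is the K x T
    reference allele matrix, and ``dists_cm`` the T-1 genetic gaps.  Both
    messages are normalized per site, so the result is invariant to the
    scaling strategy.
    """
    params = params or HMMParams()
    refs = np.asarray(refs)
    obs = np.asarray(obs)
    if refs.ndim != 2:
        raise ValueError("refs must be a K x T matrix")
    k, t = refs.shape
    if k < 2:
        raise ValueError("need at least two reference haplotypes")
    if obs.shape != (t,):
        raise ValueError(f"obs has length {obs.shape}, expected ({t},)")
    dists_cm = np.asarray(dists_cm, dtype=float)
    if dists_cm.shape != (max(t - 1, 0),):
        raise ValueError("dists_cm must have length T-1")
    if np.any(dists_cm < 0):
        raise ValueError("genetic distance must be non-negative")

    eps = params.epsilon_for(k)
    # emission likelihood per site per state, site-major for contiguous rows
    em = np.where(refs.T == obs[:, np.newaxis], 1.0 - eps, eps)

    p_nr = np.exp(-4.0 * params.ne * (dists_cm / 100.0) / k)

    alpha = np.empty((t, k))
    a = em[0] / k
    alpha[0] = a / a.sum()
    for i in range(1, t):
        pnr = p_nr[i - 1]
        # previous alpha row sums to 1 after normalization
        a = em[i] * (pnr * alpha[i - 1] + (1.0 - pnr) / k)
        alpha[i] = a / a.sum()

    beta = np.empty((t, k))
    beta[t - 1] = 1.0 / k
    for i in range(t - 2, -1, -1):
        pnr = p_nr[i]
        nxt = em[i + 1] * beta[i + 1]
        b = pnr * nxt + (1.0 - pnr) / k * nxt.sum()
        beta[i] = b / b.sum()

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def _interpolation_weights(
    cm_all: np.ndarray, cm_typed: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flanking typed-site index and right-weight for every panel site.

    Sites before the first (after the last) typed site get weight 0 (1) on
    the boundary row; zero-cM gaps collapse to the left row.
    """
    left = np.searchsorted(cm_typed, cm_all, side="right") - 1
    left = np.clip(left, 0, len(cm_typed) - 2 if len(cm_typed) > 1 else 0)
    if len(cm_typed) == 1:
        return left, np.zeros(len(cm_all))
    span = cm_typed[left + 1] - cm_typed[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(span > 0, (cm_all - cm_typed[left]) / np.where(span > 0, span, 1.0), 0.0)
    return left, np.clip(w, 0.0, 1.0)


def impute_haploid(
    study_typed: np.ndarray,
    panel: HaplotypePanel,
    typed_mask: np.ndarray,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    selection: "Sequence[int] | np.ndarray | None" = None,
) -> np.ndarray:
    """P(ALT) for one pre-phased study haplotype at every panel site.

    ``study_typed`` holds the study alleles at the typed sites (panel sites
    where ``typed_mask`` is True, in legend order).  ``selection`` limits
    the conditioning reference haplotypes (default: the whole panel).
    """
    params = params or HMMParams()
    typed_mask = np.asarray(typed_mask, dtype=bool)
    if typed_mask.shape != (panel.n_sites,):
        raise ValueError("typed_mask length must equal panel legend length")
    typed_idx = np.flatnonzero(typed_mask)
    if typed_idx.size == 0:
        raise ValueError("no typed sites in the panel")
    study_typed = np.asarray(study_typed)
    if study_typed.shape != (typed_idx.size,):
        raise ValueError("study_typed length must equal the number of typed sites")

    if selection is None:
        sel = np.arange(panel.n_haplotypes)
    else:
        sel = np.asarray(getattr(selection, "indices", selection), dtype=np.int64)
    k = sel.size
    if k < 2:
        raise ValueError("need at least two reference haplotypes")
    eps = params.epsilon_for(k)

    cm_all = np.asarray(gmap.cm_at(panel.positions), dtype=float)
    cm_typed = cm_all[typed_idx]
    dists = np.diff(cm_typed)

    refs_typed = panel.alleles[np.ix_(sel, typed_idx)]
    hmm_params = replace(params, epsilon=eps)
    gamma = forward_backward(study_typed, refs_typed, dists, hmm_params)

    left, w = _interpolation_weights(cm_all, cm_typed)
    gamma_all = gamma[left]
    gamma_all *= (1.0 - w)[:, np.newaxis]
    gamma_all += gamma[np.minimum(left + 1, len(typed_idx) - 1)] * w[:, np.newaxis]
    # typed sites keep their exact posterior row
    gamma_all[typed_idx] = gamma

    # emission mixture (1-eps)*a + eps*(1-a) collapses to eps + (1-2eps)*a
    q = np.einsum("sk,ks->s", gamma_all, panel.alleles[sel])
    p_alt = eps + (1.0 - 2.0 * eps) * q
    return np.clip(p_alt, 0.0, 1.0)


def impute_diploid(hap_a_post: np.ndarray, hap_b_post: np.ndarray) -> DiploidCalls:
    """Combine two independent haploid ALT posteriors into genotype calls."""
    a = np.asarray(hap_a_post, dtype=float)
    b = np.asarray(hap_b_post, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haploid posterior vectors must have equal length")
    for v in (a, b):
        if np.any((v < 0) | (v > 1)):
            raise ValueError("haploid posteriors must lie in [0, 1]")
    p2 = a * b
    p0 = (1.0 - a) * (1.0 - b)
    p1 = 1.0 - p0 - p2
    return DiploidCalls(p0=p0, p1=np.clip(p1, 0.0, None), p2=p2)


def best_guess(posterior: np.ndarray | float) -> np.ndarray | int:
    """Threshold an ALT posterior at 0.5; exact ties resolve to REF (0)."""
    arr = np.asarray(posterior, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("posterior must lie in [0, 1]")
    out = (arr > 0.5).astype(np.uint8)
    if np.isscalar(posterior) or arr.ndim == 0:
        return int(out)
    return out
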