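"""Seeded synthetic haplotype panels for end-to-end evaluation.

Real WGS reference panels are managed-access; every evaluation in this
package therefore runs on synthetic panels with the statistical structure
the method exploits: linkage disequilibrium from shared ancestral
segments, a frequency spectrum skewed toward rare alleles, panel-private
sites, singletons, and an array-like typed-site mask biased toward common
variants.

The generator is a copying-mosaic model rather than a coalescent
simulator: a pool of founder haplotypes is drawn with per-site derived
allele frequencies from a 1/f spectrum, and each panel haplotype is a
recombinant mosaic of founders (template switches between adjacent sites
with probability 1 - exp(-switch_rate * d_cM)) with independent per-site
allele flips at rate ``mut_rate``.  This creates exactly the block-sharing
structure that haplotype-copying HMMs and tract-based selection rely on,
at a tiny fraction of the cost of population-genetic realism.

Everything is a pure function of (config, seed): reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panels import GeneticMap, HaplotypePanel, SiteRecord, uniform_map

__all__ = ["SimConfig", "SimScenario", "simulate_founders", "simulate_mosaic", "make_scenario"]


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters.

    Defaults define the package's standard evaluation scenario: a 5 Mb
    region (uniform 1 cM/Mb) with 5,000 segregating sites, a 400-haplotype
    primary reference panel, a 200-haplotype secondary panel, and 100 study
    haplotypes, with 20% of sites on a pseudo-array biased toward
    MAF >= 5% and 10% of sites private to each reference panel.
    """

    n_founders: int = 60
    n_sites: int = 5_000
    region_bp: int = 5_000_000
    n_ref_a: int = 400
    n_ref_b: int = 200
    n_study: int = 100
    switch_rate: float = 1.0  # expected template switches per cM
    mut_rate: float = 0.001  # per-site per-haplotype allele flip probability
    typed_fraction: float = 0.2
    typed_maf_floor: float = 0.05
    private_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_sites", "region_bp", "n_ref_a", "n_ref_b", "n_study"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.typed_fraction <= 1.0:
            raise ValueError("typed_fraction must lie in (0, 1]")
        for name in ("mut_rate", "typed_maf_floor", "private_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be non-negative")


@dataclass
class SimScenario:
    """One synthetic study condition.

    ``study_truth`` carries the full sequence truth for the pseudo-GWAS
    haplotypes; ``typed_mask`` marks the array-like sites over the study
    legend.  Reference legends are subsets of the full site set (private
    sites removed from the other panel), all sharing coordinates.
    """

    config: SimConfig
    ref_a: HaplotypePanel
    ref_b: HaplotypePanel
    study_truth: HaplotypePanel
    typed_mask: np.ndarray
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if self.typed_mask.shape != (self.study_truth.n_sites,):
            raise ValueError("typed_mask must align with the study legend")


def _spectrum_frequencies(rng: np.random.Generator, n_sites: int, n_founders: int) -> np.ndarray:
    """Derived-allele frequencies with density ∝ 1/f on [1/(2n), 0.5]."""
    fmin = 1.0 / (2.0 * n_founders)
    u = rng.random(n_sites)
    return fmin * (0.5 / fmin) ** u


def simulate_founders(
    n_founders: int, n_sites: int, region_bp: int, seed: int
) -> HaplotypePanel:
    """Founder haplotypes at uniform-random distinct positions.

    Per-site derived allele frequencies follow a neutral-like 1/f spectrum
    truncated to [1/(2*n_founders), 0.5]; founder alleles are independent
    Bernoulli draws at that frequency.
    """
    if n_sites > region_bp:
        raise ValueError("cannot place n_sites distinct positions in region_bp bases")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(region_bp, size=n_sites, replace=False)) + 1
    freqs = _spectrum_frequencies(rng, n_sites, n_founders)
    alleles = (rng.random((n_founders, n_sites)) < freqs[np.newaxis, :]).astype(np.uint8)
    legend = [
        SiteRecord(chrom="1", pos=int(p), id=f"site{i}", ref="A", alt="C")
        for i, p in enumerate(positions)
    ]
    ids = [f"F{i}" for i in range(n_founders)]
    return HaplotypePanel(legend=legend, haplotype_ids=ids, alleles=alleles)


def simulate_mosaic(
    founders: HaplotypePanel,
    n_haps: int,
    switch_rate: float,
    mut_rate: float,
    gmap: GeneticMap,
    seed: int,
    id_prefix: str = "H",
) -> HaplotypePanel:
    """Recombinant mosaics of the founder haplotypes.

    Each output haplotype copies a founder template; between consecutive
    sites at genetic distance d cM the template switches with probability
    ``1 - exp(-switch_rate * d)`` to a uniformly drawn founder (possibly
    the same one).  Each emitted allele is flipped with probability
    ``mut_rate``.
    """
    rng = np.random.default_rng(seed)
    n_f = founders.n_haplotypes
    n_sites = founders.n_sites
    cm = np.asarray(gmap.cm_at(founders.positions), dtype=float)
    p_switch = 1.0 - np.exp(-switch_rate * np.diff(cm))

    out = np.empty((n_haps, n_sites), dtype=np.uint8)
    template = rng.integers(0, n_f, size=n_haps)
    out[:, 0] = founders.alleles[template, 0]
    for j in range(1, n_sites):
        switch = rng.random(n_haps) < p_switch[j - 1]
        if switch.any():
            template = np.where(switch, rng.integers(0, n_f, size=n_haps), template)
        out[:, j] = founders.alleles[template, j]
    if mut_rate > 0:
        flips = rng.random((n_haps, n_sites)) < mut_rate
        out ^= flips.astype(np.uint8)
    ids = [f"{id_prefix}{i}" for i in range(n_haps)]
    return HaplotypePanel(legend=list(founders.legend), haplotype_ids=ids, alleles=out)


def _plant_singletons(
    panel: HaplotypePanel, rng: np.random.Generator, n_target: int
) -> int:
    """Flip one allele at up to ``n_target`` monomorphic sites, in place.

    Creates panel singletons so that downstream cross-panel singleton
    filters have something to act on.  Returns the number planted.
    """
    counts = panel.alleles.sum(axis=0, dtype=np.int64)
    mono = np.flatnonzero((counts == 0) | (counts == panel.n_haplotypes))
    if mono.size == 0 or n_target == 0:
        return 0
    sites = rng.choice(mono, size=min(n_target, mono.size), replace=False)
    rows = rng.integers(0, panel.n_haplotypes, size=sites.size)
    panel.alleles[rows, sites] ^= 1
    return sites.size


def _choose_typed_mask(
    study: HaplotypePanel,
    shared_ok: np.ndarray,
    typed_fraction: float,
    typed_maf_floor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Array-like typed mask: prefer common variants among shared sites."""
    n_typed = max(1, int(round(typed_fraction * study.n_sites)))
    maf = study.mafs()
    eligible = np.flatnonzero(shared_ok & (maf > 0))
    common = eligible[maf[eligible] >= typed_maf_floor]
    rare = eligible[maf[eligible] < typed_maf_floor]
    if common.size >= n_typed:
        typed = rng.choice(common, size=n_typed, replace=False)
    else:
        extra = rng.choice(rare, size=min(n_typed - common.size, rare.size), replace=False)
        typed = np.concatenate([common, extra])
    mask = np.zeros(study.n_sites, dtype=bool)
    mask[typed] = True
    return mask


def make_scenario(config: SimConfig) -> SimScenario:
    """Generate a full study condition from one seed.

    Founders are simulated once, then three independent mosaic sets form
    the two reference panels and the study truth.  A ``private_fraction``
    of segregating sites is removed from each reference legend (disjoint
    sets, so each panel keeps sites the other lacks), singletons are
    planted in each reference panel, and the typed mask picks
    ``typed_fraction`` of the sites shared by both panels, preferring
    MAF >= ``typed_maf_floor``.
    """
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]

    founders = simulate_founders(
        config.n_founders, config.n_sites, config.region_bp, seeds[0]
    )
    gmap = uniform_map((0, config.region_bp))
    ref_a = simulate_mosaic(
        founders, config.n_ref_a, config.switch_rate, config.mut_rate, gmap, seeds[1], "A"
    )
    ref_b = simulate_mosaic(
        founders, config.n_ref_b, config.switch_rate, config.mut_rate, gmap, seeds[2], "B"
    )
    study = simulate_mosaic(
        founders, config.n_study, config.switch_rate, config.mut_rate, gmap, seeds[3], "G"
    )

    rng = np.random.default_rng(seeds[4])
    seg = np.flatnonzero(
        (ref_a.minor_allele_counts() > 0) | (ref_b.minor_allele_counts() > 0)
    )
    n_private = int(round(config.private_fraction * seg.size))
    if 2 * n_private >= seg.size:
        raise ValueError("private_fraction too large: no shared sites would remain")
    priv = rng.choice(seg, size=2 * n_private, replace=False)
    drop_from_b = np.sort(priv[:n_private])  # these become ref_a-private
    drop_from_a = np.sort(priv[n_private:])  # these become ref_b-private

    keep_a = np.ones(config.n_sites, dtype=bool)
    keep_a[drop_from_a] = False
    keep_b = np.ones(config.n_sites, dtype=bool)
    keep_b[drop_from_b] = False
    ref_a = ref_a.subset_sites(keep_a)
    ref_b = ref_b.subset_sites(keep_b)

    sing_rng = np.random.default_rng(seeds[5])
    n_sing = max(1, config.n_sites // 50)
    _plant_singletons(ref_a, sing_rng, n_sing)
    _plant_singletons(ref_b, sing_rng, n_sing)

    shared_ok = keep_a & keep_b
    typed_mask = _choose_typed_mask(
        study, shared_ok, config.typed_fraction, config.typed_maf_floor, rng
    )
    return SimScenario(
        config=config,
        ref_a=ref_a,
        ref_b=ref_b,
        study_truth=study,
        typed_mask=typed_mask,
        gmap=gmap,
    )
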