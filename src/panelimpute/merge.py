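"""Harmonize two phased panels and merge them by reciprocal imputation.

Merging proceeds in three steps: (1) harmonize the two site legends —
drop multi-allelic positions, reconcile or drop allele-coding conflicts,
and drop cross-panel singletons (sites private to one panel whose minor
allele is observed on exactly one haplotype there); (2) reciprocally
impute each panel's private sites into the other panel, treating every
haplotype as a pre-phased haploid study sequence typed at the shared
sites and taking best-guess alleles; (3) stack the haplotypes over the
position-sorted union legend.  Observed alleles are never altered — only
panel-private sites receive imputed alleles.

All site accounting is carried in :class:`FilterReport` and
:class:`MergeReport`, whose inclusion-exclusion identities are verified on
every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import HMMParams, best_guess, impute_haploid
from .panels import Chunk, ChunkPlan, GeneticMap, HaplotypePanel, SiteRecord, plan_chunks
from .select import SelectionSpec, select_references

__all__ = [
    "FilterReport",
    "MergeReport",
    "harmonize",
    "cross_impute",
    "merge",
    "union_count",
]


class MergeError(ValueError):
    pass


@dataclass
class FilterReport:
    """Per-panel site accounting for the harmonization filters."""

    n_input_a: int = 0
    n_input_b: int = 0
    n_multiallelic_a: int = 0
    n_multiallelic_b: int = 0
    n_mismatch: int = 0
    n_allele_swaps: int = 0
    n_private_singletons_a: int = 0
    n_private_singletons_b: int = 0
    n_kept_a: int = 0
    n_kept_b: int = 0

    def expected_kept_a(self) -> int:
        return (
            self.n_input_a
            - self.n_multiallelic_a
            - self.n_mismatch
            - self.n_private_singletons_a
        )

    def expected_kept_b(self) -> int:
        return (
            self.n_input_b
            - self.n_multiallelic_b
            - self.n_mismatch
            - self.n_private_singletons_b
        )

    def validate(self) -> None:
        if self.n_kept_a != self.expected_kept_a():
            raise MergeError(
                f"panel A accounting broken: kept {self.n_kept_a}, "
                f"expected {self.expected_kept_a()}"
            )
        if self.n_kept_b != self.expected_kept_b():
            raise MergeError(
                f"panel B accounting broken: kept {self.n_kept_b}, "
                f"expected {self.expected_kept_b()}"
            )

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MergeReport:
    """Union accounting for a completed merge."""

    n_a_only: int
    n_b_only: int
    n_shared: int
    by_class: dict = field(default_factory=dict)
    filter_report: FilterReport | None = None

    @property
    def n_union(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_shared

    def validate(self) -> None:
        if self.filter_report is not None:
            fr = self.filter_report
            if self.n_union != fr.n_kept_a + fr.n_kept_b - self.n_shared:
                raise MergeError("union inclusion-exclusion identity broken")
        total = sum(
            sum(counts.values()) for counts in self.by_class.values()
        )
        if self.by_class and total != self.n_union:
            raise MergeError("per-class breakdown does not sum to the union")

    def as_dict(self) -> dict:
        return {
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "n_shared": self.n_shared,
            "n_union": self.n_union,
            "by_class": self.by_class,
            "filter": self.filter_report.as_dict() if self.filter_report else None,
        }


def union_count(n_a: int, n_b: int, n_overlap: int) -> int:
    """Union site count by inclusion-exclusion."""
    if n_overlap > min(n_a, n_b) or min(n_a, n_b, n_overlap) < 0:
        raise ValueError(
            f"overlap {n_overlap} exceeds a panel size ({n_a}, {n_b})"
        )
    return n_a + n_b - n_overlap


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _duplicate_positions(panel: HaplotypePanel) -> set[tuple[str, int]]:
    seen: set[tuple[str, int]] = set()
    dups: set[tuple[str, int]] = set()
    for s in panel.legend:
        key = (s.chrom, s.pos)
        if key in seen:
            dups.add(key)
        seen.add(key)
    return dups


def harmonize(
    panel_a: HaplotypePanel, panel_b: HaplotypePanel
) -> tuple[HaplotypePanel, HaplotypePanel, FilterReport]:
    """Reconcile two panels' site sets before merging.

    Removes (per panel): positions with duplicate records (multi-allelic
    encodings); shared positions whose allele pairs still differ after
    allele-swap resolution (REF/ALT exchanged in one panel is fixed by
    flipping that panel's codes, not dropped); and panel-private sites
    whose minor-allele count in their panel is exactly 1 (cross-panel
    singletons).  Returns the filtered panels and the accounting report.
    """
    report = FilterReport(n_input_a=panel_a.n_sites, n_input_b=panel_b.n_sites)

    dups_a = _duplicate_positions(panel_a)
    dups_b = _duplicate_positions(panel_b)
    report.n_multiallelic_a = sum(
        1 for s in panel_a.legend if (s.chrom, s.pos) in dups_a
    )
    report.n_multiallelic_b = sum(
        1 for s in panel_b.legend if (s.chrom, s.pos) in dups_b
    )

    keep_a = np.array([(s.chrom, s.pos) not in dups_a for s in panel_a.legend])
    keep_b = np.array([(s.chrom, s.pos) not in dups_b for s in panel_b.legend])

    index_a = {
        (s.chrom, s.pos): i for i, s in enumerate(panel_a.legend) if keep_a[i]
    }
    flip_b: list[int] = []
    mismatched: set[tuple[str, int]] = set()
    for j, s in enumerate(panel_b.legend):
        if not keep_b[j]:
            continue
        key = (s.chrom, s.pos)
        i = index_a.get(key)
        if i is None:
            continue
        rec_a = panel_a.legend[i]
        if (rec_a.ref, rec_a.alt) == (s.ref, s.alt):
            continue
        if (rec_a.ref, rec_a.alt) == (s.alt, s.ref):
            flip_b.append(j)
        else:
            mismatched.add(key)

    report.n_allele_swaps = len(flip_b)
    report.n_mismatch = len(mismatched)
    for key in mismatched:
        keep_a[index_a[key]] = False
    for j, s in enumerate(panel_b.legend):
        if (s.chrom, s.pos) in mismatched:
            keep_b[j] = False

    # resolve swapped allele coding in panel B
    b_alleles = panel_b.alleles.copy()
    b_legend = list(panel_b.legend)
    for j in flip_b:
        s = b_legend[j]
        b_legend[j] = SiteRecord(chrom=s.chrom, pos=s.pos, id=s.id, ref=s.alt, alt=s.ref)
        b_alleles[:, j] = 1 - b_alleles[:, j]
    panel_b = HaplotypePanel(
        legend=b_legend, haplotype_ids=list(panel_b.haplotype_ids), alleles=b_alleles
    )

    # cross-panel singleton rule on private sites
    pos_a = {
        (s.chrom, s.pos) for i, s in enumerate(panel_a.legend) if keep_a[i]
    }
    pos_b = {
        (s.chrom, s.pos) for j, s in enumerate(panel_b.legend) if keep_b[j]
    }
    mac_a = panel_a.minor_allele_counts()
    mac_b = panel_b.minor_allele_counts()
    for i, s in enumerate(panel_a.legend):
        if keep_a[i] and (s.chrom, s.pos) not in pos_b and mac_a[i] == 1:
            keep_a[i] = False
            report.n_private_singletons_a += 1
    for j, s in enumerate(panel_b.legend):
        if keep_b[j] and (s.chrom, s.pos) not in pos_a and mac_b[j] == 1:
            keep_b[j] = False
            report.n_private_singletons_b += 1

    out_a = panel_a.subset_sites(keep_a)
    out_b = panel_b.subset_sites(keep_b)
    report.n_kept_a = out_a.n_sites
    report.n_kept_b = out_b.n_sites
    report.validate()
    return out_a, out_b, report


# ---------------------------------------------------------------------------
# Reciprocal imputation
# ---------------------------------------------------------------------------

def _chunk_site_mask(positions: np.ndarray, start: int, end: int) -> np.ndarray:
    return (positions >= start) & (positions < end)


def cross_impute(
    target: HaplotypePanel,
    donor: HaplotypePanel,
    sites_to_add: list[SiteRecord],
    gmap: GeneticMap,
    params: HMMParams | None = None,
    spec: SelectionSpec | None = None,
    chunk_plan: ChunkPlan | None = None,
) -> HaplotypePanel:
    """Impute donor-private sites into every target haplotype.

    Each target haplotype is treated as a pre-phased haploid study
    sequence typed at the sites shared with the donor; the donor panel
    drives the copying HMM and the resulting ALT posteriors at
    ``sites_to_add`` are thresholded to best-guess alleles.  With a chunk
    plan, inference runs per buffered chunk and only core-interval results
    are kept.
    """
    params = params or HMMParams()
    spec = spec or SelectionSpec(strategy="all")
    if not sites_to_add:
        return target

    donor_index = donor.site_index()
    target_keys = set(target.site_index())
    add_keys = [(s.chrom, s.pos) for s in sites_to_add]
    for key in add_keys:
        if key not in donor_index:
            raise MergeError(f"site {key[0]}:{key[1]} to add is absent from the donor")
        if key in target_keys:
            raise MergeError(f"site {key[0]}:{key[1]} already present in the target")
    shared = [key for key in target.site_index() if key in donor_index]
    if not shared:
        raise MergeError("panels share no sites after harmonization")

    donor_pos = donor.positions
    typed_mask_full = np.zeros(donor.n_sites, dtype=bool)
    shared_donor_idx = np.array([donor_index[key] for key in shared])
    typed_mask_full[shared_donor_idx] = True
    # target column index for each shared donor site, in donor legend order
    t_index = target.site_index()
    order = np.argsort(shared_donor_idx)
    shared_donor_idx = shared_donor_idx[order]
    shared_target_idx = np.array([t_index[shared[i]] for i in order])

    add_donor_idx = np.array([donor_index[key] for key in add_keys])

    if chunk_plan is None:
        span_start = int(donor_pos.min())
        span_end = int(donor_pos.max()) + 1
        chunk_plan = ChunkPlan(
            chunks=(
                Chunk(
                    core_start=span_start,
                    core_end=span_end,
                    buf_start=span_start,
                    buf_end=span_end,
                ),
            ),
            chunk_size=span_end - span_start,
            buffer=0,
        )

    new_alleles = np.zeros((target.n_haplotypes, len(sites_to_add)), dtype=np.uint8)
    add_pos = donor_pos[add_donor_idx]

    for chunk in chunk_plan.chunks:
        in_buf = _chunk_site_mask(donor_pos, chunk.buf_start, chunk.buf_end)
        donor_cols = np.flatnonzero(in_buf)
        if donor_cols.size == 0:
            continue
        core_add = np.flatnonzero(
            _chunk_site_mask(add_pos, chunk.core_start, chunk.core_end)
        )
        if core_add.size == 0:
            continue
        sub_donor = donor.subset_sites(donor_cols)
        sub_typed = typed_mask_full[donor_cols]
        if not sub_typed.any():
            raise MergeError(
                f"no shared typed sites in chunk [{chunk.buf_start}, {chunk.buf_end})"
            )
        # target alleles at the shared sites inside this chunk
        in_chunk_shared = np.isin(shared_donor_idx, donor_cols)
        tgt_cols = shared_target_idx[in_chunk_shared]
        # donor-local column of each site to add in this chunk's core
        local_of_donor = {int(d): i for i, d in enumerate(donor_cols)}
        add_local = np.array(
            [local_of_donor[int(add_donor_idx[c])] for c in core_add]
        )
        panel_typed = sub_donor.alleles[:, sub_typed]
        for h in range(target.n_haplotypes):
            study_typed = target.alleles[h, tgt_cols]
            sel = select_references(study_typed, panel_typed, spec)
            p_alt = impute_haploid(
                study_typed, sub_donor, sub_typed, gmap, params, sel
            )
            new_alleles[h, core_add] = best_guess(p_alt[add_local])

    # assemble the union panel
    legend = list(target.legend) + [donor.legend[i] for i in add_donor_idx]
    alleles = np.concatenate([target.alleles, new_alleles], axis=1)
    order = sorted(range(len(legend)), key=lambda i: (legend[i].chrom, legend[i].pos))
    return HaplotypePanel(
        legend=[legend[i] for i in order],
        haplotype_ids=list(target.haplotype_ids),
        alleles=alleles[:, order],
    )


def merge(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    spec: SelectionSpec | None = None,
    chunk_size: int = 3_000_000,
    buffer: int = 250_000,
) -> tuple[HaplotypePanel, MergeReport]:
    """Harmonize and merge two phased panels over their union of variants.

    Both panels are first harmonized; B-private sites are then imputed
    into A and A-private sites into B (per buffered chunk), and the
    haplotypes are stacked over the union legend.  Shared-site alleles are
    preserved exactly.
    """
    panel_a, panel_b, filt = harmonize(panel_a, panel_b)
    keys_a = set(panel_a.site_index())
    keys_b = set(panel_b.site_index())
    shared = keys_a & keys_b
    if not shared:
        raise MergeError("panels share no sites after harmonization")
    a_only = [s for s in panel_a.legend if (s.chrom, s.pos) not in keys_b]
    b_only = [s for s in panel_b.legend if (s.chrom, s.pos) not in keys_a]

    all_pos = np.concatenate([panel_a.positions, panel_b.positions])
    span = (int(all_pos.min()), int(all_pos.max()) + 1)
    plan = plan_chunks(span, chunk_size=chunk_size, buffer=buffer)

    merged_a = cross_impute(panel_a, panel_b, b_only, gmap, params, spec, plan)
    merged_b = cross_impute(panel_b, panel_a, a_only, gmap, params, spec, plan)
    if [(s.chrom, s.pos) for s in merged_a.legend] != [
        (s.chrom, s.pos) for s in merged_b.legend
    ]:
        raise MergeError("reciprocal imputation produced inconsistent legends")

    merged = HaplotypePanel(
        legend=list(merged_a.legend),
        haplotype_ids=list(merged_a.haplotype_ids) + list(merged_b.haplotype_ids),
        alleles=np.concatenate([merged_a.alleles, merged_b.alleles], axis=0),
    )

    by_class: dict[str, dict[str, int]] = {}
    groups = {
        "a_only": a_only,
        "b_only": b_only,
        "shared": [s for s in panel_a.legend if (s.chrom, s.pos) in shared],
    }
    for name, sites in groups.items():
        for s in sites:
            by_class.setdefault(s.vclass, {}).setdefault(name, 0)
            by_class[s.vclass][name] += 1
    report = MergeReport(
        n_a_only=len(a_only),
        n_b_only=len(b_only),
        n_shared=len(shared),
        by_class=by_class,
        filter_report=filt,
    )
    report.validate()

    # allele-preservation check: originals must be untouched
    merged_index = merged.site_index()
    cols_a = [merged_index[key] for key in ((s.chrom, s.pos) for s in panel_a.legend)]
    if not np.array_equal(
        merged.alleles[: panel_a.n_haplotypes][:, cols_a], panel_a.alleles
    ):
        raise MergeError("merge altered observed panel A alleles")
    cols_b = [merged_index[key] for key in ((s.chrom, s.pos) for s in panel_b.legend)]
    if not np.array_equal(
        merged.alleles[panel_a.n_haplotypes :][:, cols_b], panel_b.alleles
    ):
        raise MergeError("merge altered observed panel B alleles")
    return merged, report
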