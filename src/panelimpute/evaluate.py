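"""Imputation quality metrics and evaluation harnesses.

Two complementary per-site metrics:

* **true r²** — squared Pearson correlation between imputed dosages (0-2)
  and held-out truth genotypes (0/1/2); requires masked truth data.
* **info (expected r²)** — a panel-free confidence score computed from the
  genotype-probability uncertainty alone: with per-sample
  ``e_i = p1_i + 2 p2_i`` and ``f_i = p1_i + 4 p2_i`` and estimated ALT
  frequency ``theta = sum(e_i) / 2N``,

      info = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta))

  (1.0 when theta is 0 or 1, clamped to [0, 1]).  Info tends to exceed
  true r² at low-frequency variants, so absolute counts of high-info sites
  are upper bounds on well-imputed sites.

The harnesses run pseudo-GWAS (mask a study panel to array-like typed
sites, impute, score against the full truth) and leave-one-out
evaluations (each sample removed from the reference in turn), rolling
per-site metrics into MAF-binned reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import HMMParams, impute_diploid, impute_haploid
from .panels import GeneticMap, HaplotypePanel, plan_chunks
from .select import SelectionSpec, select_references
from .simulate import SimScenario

__all__ = [
    "EvalReport",
    "info_score",
    "true_r2",
    "maf_of",
    "impute_cohort",
    "pseudo_gwas_eval",
    "leave_one_out_eval",
    "compare_configs",
    "DEFAULT_MAF_EDGES",
    "DEFAULT_INFO_EDGES",
]

# MAF bin edges covering the thresholds commonly quoted for rare (<0.5-1%)
# and low-frequency (1-5%) variants; half-open bins (lo, hi].
DEFAULT_MAF_EDGES = (0.0, 0.001, 0.005, 0.01, 0.02, 0.05, 0.5)
# info bin edges supporting both the 0.4 and 0.8 confidence thresholds
DEFAULT_INFO_EDGES = (0.0, 0.4, 0.8, 1.0)


def info_score(probs: np.ndarray) -> float:
    """IMPUTE-style info score from an (N, 3) genotype-probability matrix."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("probs must be an (N, 3) matrix of genotype triples")
    if probs.shape[0] < 1:
        raise ValueError("need at least one sample")
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("malformed genotype probability triples")
    e = probs[:, 1] + 2.0 * probs[:, 2]
    f = probs[:, 1] + 4.0 * probs[:, 2]
    n = probs.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    info = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(np.clip(info, 0.0, 1.0))


def true_r2(dosages: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vs truth; NaN when undefined."""
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if dosages.shape != truth.shape:
        raise ValueError("dosage and truth vectors must have equal length")
    if dosages.size < 2:
        raise ValueError("need at least two samples")
    d = dosages - dosages.mean()
    t = truth - truth.mean()
    vd = (d**2).sum()
    vt = (t**2).sum()
    if vd == 0.0 or vt == 0.0:
        return float("nan")
    r = (d * t).sum() / np.sqrt(vd * vt)
    return float(min(r * r, 1.0))


def maf_of(alleles: np.ndarray) -> float:
    """Minor allele frequency of a haploid 0/1 allele vector."""
    alleles = np.asarray(alleles)
    if alleles.size == 0:
        raise ValueError("empty allele vector")
    f = float(alleles.mean())
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-site metrics plus MAF-binned summaries.

    ``sites`` has one row per evaluated site with columns ``pos``, ``maf``
    (truth-based), ``imputed_maf``, ``info``, ``true_r2`` (NaN when
    undefined or no truth) and ``typed``.
    """

    sites: pd.DataFrame
    maf_edges: tuple = DEFAULT_MAF_EDGES
    info_edges: tuple = DEFAULT_INFO_EDGES

    def _bin(self, maf_source: str = "maf") -> pd.Series:
        return pd.cut(self.sites[maf_source], bins=list(self.maf_edges), right=True)

    def mean_true_r2_by_bin(self, untyped_only: bool = True) -> pd.Series:
        """Mean defined true r² per MAF bin (undefined sites excluded)."""
        df = self.sites
        if untyped_only:
            df = df[~df["typed"]]
        return df.groupby(self._bin()[df.index], observed=False)["true_r2"].mean()

    def mean_true_r2(self, maf_max: float = 0.5, untyped_only: bool = True) -> float:
        df = self.sites
        if untyped_only:
            df = df[~df["typed"]]
        df = df[(df["maf"] > 0) & (df["maf"] < maf_max)]
        return float(df["true_r2"].mean())

    def mean_info(self, maf_max: float = 0.5, untyped_only: bool = True) -> float:
        df = self.sites
        if untyped_only:
            df = df[~df["typed"]]
        df = df[(df["maf"] > 0) & (df["maf"] < maf_max)]
        return float(df["info"].mean())

    def counts_by_maf_info(self, maf_source: str = "imputed_maf") -> pd.DataFrame:
        """Site counts per (MAF bin x info bin)."""
        info_bin = pd.cut(
            self.sites["info"], bins=list(self.info_edges), right=True,
            include_lowest=True,
        )
        return (
            self.sites.groupby([self._bin(maf_source), info_bin], observed=False)
            .size()
            .unstack(fill_value=0)
        )

    def n_high_confidence(self, threshold: float = 0.8) -> pd.Series:
        """Number of sites with info above threshold, per truth-MAF bin."""
        high = self.sites[self.sites["info"] > threshold]
        return high.groupby(self._bin()[high.index], observed=False)["info"].count()

    def n_undefined_r2(self) -> int:
        return int(self.sites["true_r2"].isna().sum())

    def validate(self) -> None:
        counts = self.counts_by_maf_info(maf_source="maf")
        in_range = self.sites[
            (self.sites["maf"] > self.maf_edges[0])
            & (self.sites["maf"] <= self.maf_edges[-1])
        ]
        if counts.to_numpy().sum() != len(in_range):
            raise AssertionError("MAF x info counts do not conserve site totals")


# ---------------------------------------------------------------------------
# Harness internals
# ---------------------------------------------------------------------------

def _check_typed_in_ref(
    study: HaplotypePanel, typed_mask: np.ndarray, ref: HaplotypePanel
) -> tuple[np.ndarray, np.ndarray]:
    """Map study typed sites into the reference legend.

    Returns (study typed column indices, reference typed mask).  A typed
    study site missing from the reference legend is a hard error.
    """
    ref_index = ref.site_index()
    typed_cols = np.flatnonzero(typed_mask)
    ref_mask = np.zeros(ref.n_sites, dtype=bool)
    for c in typed_cols:
        s = study.legend[c]
        i = ref_index.get((s.chrom, s.pos))
        if i is None:
            raise ValueError(
                f"study typed site {s.chrom}:{s.pos} is absent from the reference legend"
            )
        ref_mask[i] = True
    return typed_cols, ref_mask


def _impute_samples(
    study_haps: np.ndarray,
    ref: HaplotypePanel,
    ref_typed_mask: np.ndarray,
    gmap: GeneticMap,
    params: HMMParams,
    spec: SelectionSpec,
) -> np.ndarray:
    """Dosage matrix (n_samples, ref sites) for paired study haplotypes."""
    panel_typed = ref.alleles[:, ref_typed_mask]
    n_haps = study_haps.shape[0]
    post = np.empty((n_haps, ref.n_sites))
    for h in range(n_haps):
        sel = select_references(study_haps[h], panel_typed, spec)
        post[h] = impute_haploid(
            study_haps[h], ref, ref_typed_mask, gmap, params, sel
        )
    return post


def _site_table(
    ref: HaplotypePanel,
    ref_typed_mask: np.ndarray,
    hap_posteriors: np.ndarray,
    truth_genotypes: dict[int, np.ndarray],
    truth_mafs: dict[int, float],
) -> pd.DataFrame:
    """Assemble the per-site metric table from haploid posteriors.

    ``truth_genotypes`` / ``truth_mafs`` map reference site columns to the
    truth vectors (absent keys mean no truth at that site).
    """
    n_haps = hap_posteriors.shape[0]
    a = hap_posteriors[0::2]
    b = hap_posteriors[1::2]
    calls = impute_diploid(a.ravel(), b.ravel())
    n_samples = n_haps // 2
    p1 = calls.p1.reshape(n_samples, -1)
    p2 = calls.p2.reshape(n_samples, -1)
    dosage = p1 + 2.0 * p2

    infos = _info_scores_by_site(p1, p2)
    imputed_f = dosage.mean(axis=0) / 2.0
    rows = []
    for j in range(ref.n_sites):
        truth = truth_genotypes.get(j)
        r2 = true_r2(dosage[:, j], truth) if truth is not None else float("nan")
        rows.append(
            {
                "pos": ref.legend[j].pos,
                "maf": truth_mafs.get(j, float("nan")),
                "imputed_maf": min(float(imputed_f[j]), 1.0 - float(imputed_f[j])),
                "info": float(infos[j]),
                "true_r2": r2,
                "typed": bool(ref_typed_mask[j]),
            }
        )
    return pd.DataFrame(rows)


def _info_scores_by_site(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorized info over site columns of (N x S) probability matrices."""
    n = p1.shape[0]
    e = p1 + 2.0 * p2
    f = p1 + 4.0 * p2
    theta = e.sum(axis=0) / (2.0 * n)
    num = (f - e**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = 1.0 - num / (2.0 * n * theta * (1.0 - theta))
    info = np.where((theta <= 0.0) | (theta >= 1.0), 1.0, np.clip(info, 0.0, 1.0))
    return info


def impute_cohort(
    study_typed: HaplotypePanel,
    ref: HaplotypePanel,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    spec: SelectionSpec | None = None,
    chunk_size: int | None = None,
    buffer: int = 250_000,
) -> np.ndarray:
    """Haploid ALT posteriors (n_study_haps x ref sites) for a typed cohort.

    ``study_typed`` is a pre-phased panel containing only the typed sites
    (every one must exist in the reference legend).  With ``chunk_size``
    set, inference runs per buffered chunk — selection and the HMM see
    the buffered interval; only core-interval posteriors are kept.
    """
    params = params or HMMParams()
    spec = spec or SelectionSpec(strategy="all")
    all_typed = np.ones(study_typed.n_sites, dtype=bool)
    typed_cols, ref_typed_mask = _check_typed_in_ref(study_typed, all_typed, ref)

    if chunk_size is None:
        return _impute_samples(
            study_typed.alleles, ref, ref_typed_mask, gmap, params, spec
        )

    ref_pos = ref.positions
    span = (int(ref_pos.min()), int(ref_pos.max()) + 1)
    plan = plan_chunks(span, chunk_size=chunk_size, buffer=buffer)
    out = np.empty((study_typed.n_haplotypes, ref.n_sites))
    typed_pos = ref_pos[ref_typed_mask]
    for chunk in plan.chunks:
        buf_cols = np.flatnonzero(
            (ref_pos >= chunk.buf_start) & (ref_pos < chunk.buf_end)
        )
        core = (ref_pos[buf_cols] >= chunk.core_start) & (
            ref_pos[buf_cols] < chunk.core_end
        )
        if buf_cols.size == 0 or not core.any():
            continue
        sub_ref = ref.subset_sites(buf_cols)
        sub_mask = ref_typed_mask[buf_cols]
        if not sub_mask.any():
            raise ValueError(
                f"no typed sites in chunk [{chunk.buf_start}, {chunk.buf_end})"
            )
        in_chunk = (typed_pos >= chunk.buf_start) & (typed_pos < chunk.buf_end)
        sub_study = study_typed.alleles[:, in_chunk]
        post = _impute_samples(sub_study, sub_ref, sub_mask, gmap, params, spec)
        out[:, buf_cols[core]] = post[:, core]
    return out


# ---------------------------------------------------------------------------
# Harnesses
# ---------------------------------------------------------------------------

def pseudo_gwas_eval(
    study_truth: HaplotypePanel,
    typed_mask: np.ndarray,
    ref: HaplotypePanel,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    spec: SelectionSpec | None = None,
    maf_edges: tuple = DEFAULT_MAF_EDGES,
) -> EvalReport:
    """Mask a study panel to its typed sites, impute from ``ref``, score.

    All reference sites are imputed and receive an info score; sites with
    truth available (present in the study legend) also receive true r².
    MAF is the truth MAF where truth exists.
    """
    params = params or HMMParams()
    spec = spec or SelectionSpec(strategy="all")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    typed_cols, ref_typed_mask = _check_typed_in_ref(study_truth, typed_mask, ref)

    study_haps = study_truth.alleles[:, typed_cols]
    post = _impute_samples(study_haps, ref, ref_typed_mask, gmap, params, spec)

    study_index = study_truth.site_index()
    truth_geno = study_truth.genotypes()
    truth_g: dict[int, np.ndarray] = {}
    truth_maf: dict[int, float] = {}
    study_mafs = study_truth.mafs()
    for j, s in enumerate(ref.legend):
        c = study_index.get((s.chrom, s.pos))
        if c is not None:
            truth_g[j] = truth_geno[:, c]
            truth_maf[j] = float(study_mafs[c])
    table = _site_table(ref, ref_typed_mask, post, truth_g, truth_maf)
    report = EvalReport(sites=table, maf_edges=maf_edges)
    report.validate()
    return report


def leave_one_out_eval(
    panel: HaplotypePanel,
    typed_mask: np.ndarray,
    gmap: GeneticMap,
    params: HMMParams | None = None,
    spec: SelectionSpec | None = None,
    n_eval_samples: int | None = None,
    seed: int = 0,
    maf_edges: tuple = DEFAULT_MAF_EDGES,
) -> EvalReport:
    """Remove each sample from the panel in turn, impute it back, score.

    ``n_eval_samples`` restricts evaluation to a seeded random subsample
    of the panel's samples (all samples by default).
    """
    params = params or HMMParams()
    spec = spec or SelectionSpec(strategy="all")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    if not typed_mask.any():
        raise ValueError("typed_mask selects no sites")
    if panel.n_samples < 3:
        raise ValueError("leave-one-out needs at least three diploid samples")
    if n_eval_samples is not None and n_eval_samples < 1:
        raise ValueError("must evaluate at least one sample")

    rng = np.random.default_rng(seed)
    samples = np.arange(panel.n_samples)
    if n_eval_samples is not None and n_eval_samples < panel.n_samples:
        samples = np.sort(rng.choice(samples, size=n_eval_samples, replace=False))

    typed_cols = np.flatnonzero(typed_mask)
    dosages = np.empty((samples.size, panel.n_sites))
    probs = np.empty((samples.size, panel.n_sites, 3))
    for si, sample in enumerate(samples):
        ref = panel.drop_sample(sample)
        hap_a = panel.alleles[2 * sample, typed_cols]
        hap_b = panel.alleles[2 * sample + 1, typed_cols]
        post_a = impute_haploid(
            hap_a, ref, typed_mask, gmap, params,
            select_references(hap_a, ref.alleles[:, typed_cols], spec),
        )
        post_b = impute_haploid(
            hap_b, ref, typed_mask, gmap, params,
            select_references(hap_b, ref.alleles[:, typed_cols], spec),
        )
        calls = impute_diploid(post_a, post_b)
        dosages[si] = calls.dosage
        probs[si] = calls.probs()

    truth = panel.genotypes()[samples]
    mafs = panel.mafs()
    rows = []
    for j in range(panel.n_sites):
        info = info_score(probs[:, j, :])
        r2 = true_r2(dosages[:, j], truth[:, j]) if samples.size >= 2 else float("nan")
        rows.append(
            {
                "pos": panel.legend[j].pos,
                "maf": float(mafs[j]),
                "imputed_maf": min(
                    float(dosages[:, j].mean() / 2.0),
                    1.0 - float(dosages[:, j].mean() / 2.0),
                ),
                "info": info,
                "true_r2": r2,
                "typed": bool(typed_mask[j]),
            }
        )
    report = EvalReport(sites=pd.DataFrame(rows), maf_edges=maf_edges)
    report.validate()
    return report


def compare_configs(
    scenario: SimScenario,
    configs: list[tuple[str, HaplotypePanel, SelectionSpec]],
    params: HMMParams | None = None,
    maf_edges: tuple = DEFAULT_MAF_EDGES,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Evaluate several (panel, selection) configurations on one scenario.

    Every configuration sees identical study haplotypes and typed sites.
    Returns the per-config reports and a summary table with mean true r²
    per MAF bin and high-confidence site counts per config.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    params = params or HMMParams()
    reports: dict[str, EvalReport] = {}
    summary_rows = []
    for label, panel, spec in configs:
        rep = pseudo_gwas_eval(
            scenario.study_truth,
            scenario.typed_mask,
            panel,
            scenario.gmap,
            params,
            spec,
            maf_edges,
        )
        reports[label] = rep
        row = {"config": label, "n_sites": len(rep.sites)}
        for interval, value in rep.mean_true_r2_by_bin().items():
            row[f"r2 {interval}"] = value
        for interval, value in rep.n_high_confidence().items():
            row[f"n_info>0.8 {interval}"] = value
        summary_rows.append(row)
    return reports, pd.DataFrame(summary_rows)
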