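"""Phased haplotype panels, genetic maps, and imputation chunk planning.

The central container is :class:`HaplotypePanel`: an ordered legend of
biallelic sites plus a haplotype-major binary allele matrix (one row per
haplotype, one column per site).  Panels are read and written as phased VCF
(via pysam) or as IMPUTE-style ``.hap``/``.legend``/``.sample`` text
triplets; gzip is handled transparently for the text formats.

Coordinate conventions used throughout the package:

* site positions are 1-based (VCF convention);
* genomic intervals (regions, chunks) are half-open ``[start, end)`` in bp.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

__all__ = [
    "SiteRecord",
    "HaplotypePanel",
    "GeneticMap",
    "Chunk",
    "ChunkPlan",
    "read_haplotypes_vcf",
    "write_haplotypes_vcf",
    "read_hap_legend",
    "write_hap_legend",
    "read_genetic_map",
    "uniform_map",
    "plan_chunks",
]


class PanelFormatError(ValueError):
    """Raised for malformed panel, legend, or map inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """One biallelic variant site.

    ``vclass`` is ``"SNP"`` iff both alleles are single bases, otherwise
    ``"INDEL"``.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelFormatError(f"site position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise PanelFormatError(
                f"REF and ALT must differ at {self.chrom}:{self.pos}"
            )

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref, self.alt)


@dataclass
class HaplotypePanel:
    """A set of phased haplotypes over an ordered biallelic site legend.

    ``alleles`` is haplotype-major: shape ``(n_haplotypes, n_sites)``,
    entries in {0, 1} with 0 = REF and 1 = ALT.
    """

    legend: list[SiteRecord]
    haplotype_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise PanelFormatError("allele matrix must be 2-dimensional")
        if self.alleles.shape != (len(self.haplotype_ids), len(self.legend)):
            raise PanelFormatError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.haplotype_ids)} haplotypes x {len(self.legend)} sites"
            )
        if self.alleles.size and self.alleles.max(initial=0) > 1:
            raise PanelFormatError("allele matrix entries must be 0 or 1")
        # non-decreasing so that split multi-allelic records (duplicate
        # positions) survive I/O long enough for harmonization to count them
        pos = self.positions
        chroms = [s.chrom for s in self.legend]
        for i in range(1, len(self.legend)):
            if chroms[i] == chroms[i - 1] and pos[i] < pos[i - 1]:
                raise PanelFormatError(
                    f"legend positions must be sorted within a chromosome "
                    f"(offending position {pos[i]})"
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_samples(self) -> int:
        if self.n_haplotypes % 2:
            raise PanelFormatError("odd haplotype count: panel is not diploid")
        return self.n_haplotypes // 2

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.legend], dtype=np.int64)

    def alt_frequencies(self) -> np.ndarray:
        """ALT allele frequency per site."""
        return self.alleles.mean(axis=0)

    def minor_allele_counts(self) -> np.ndarray:
        alt = self.alleles.sum(axis=0, dtype=np.int64)
        return np.minimum(alt, self.n_haplotypes - alt)

    def mafs(self) -> np.ndarray:
        f = self.alt_frequencies()
        return np.minimum(f, 1.0 - f)

    def genotypes(self) -> np.ndarray:
        """Diploid genotype matrix (n_samples x n_sites), values in {0,1,2}."""
        n = self.n_samples
        return (
            self.alleles[0::2].astype(np.int16) + self.alleles[1::2]
        ).reshape(n, self.n_sites)

    # -- subsetting ---------------------------------------------------------

    def subset_sites(self, idx: np.ndarray | Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            legend=[self.legend[i] for i in idx],
            haplotype_ids=list(self.haplotype_ids),
            alleles=self.alleles[:, idx].copy(),
        )

    def subset_haplotypes(self, idx: np.ndarray | Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            legend=list(self.legend),
            haplotype_ids=[self.haplotype_ids[i] for i in idx],
            alleles=self.alleles[idx].copy(),
        )

    def drop_sample(self, sample_index: int) -> "HaplotypePanel":
        """Remove one diploid sample (two consecutive haplotype rows)."""
        keep = np.ones(self.n_haplotypes, dtype=bool)
        keep[2 * sample_index : 2 * sample_index + 2] = False
        return self.subset_haplotypes(keep)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(s.chrom, s.pos): i for i, s in enumerate(self.legend)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.legend == other.legend
            and self.haplotype_ids == other.haplotype_ids
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass(frozen=True)
class GeneticMap:
    """Monotone bp -> cumulative-cM mapping.

    Between map points, positions are interpolated linearly; outside the
    mapped range the cumulative cM is clamped to the nearest endpoint
    (constant extrapolation, i.e. a local rate of zero).
    """

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, dtype=np.float64)
        cm = np.asarray(self.cm, dtype=np.float64)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise PanelFormatError("genetic map needs >= 2 (bp, cM) points")
        if np.any(np.diff(bp) <= 0):
            raise PanelFormatError("genetic map bp positions must strictly increase")
        if np.any(np.diff(cm) < 0):
            raise PanelFormatError("genetic map cumulative cM must be non-decreasing")

    def cm_at(self, bp: np.ndarray | float) -> np.ndarray | float:
        """Cumulative cM at one or many bp positions."""
        return np.interp(bp, self.bp, self.cm)


@dataclass(frozen=True)
class Chunk:
    """A core interval plus its buffered extension, both half-open in bp."""

    core_start: int
    core_end: int
    buf_start: int
    buf_end: int

    def __post_init__(self) -> None:
        if not (self.buf_start <= self.core_start < self.core_end <= self.buf_end):
            raise PanelFormatError("buffered interval must contain its core")


@dataclass(frozen=True)
class ChunkPlan:
    chunks: tuple[Chunk, ...]
    chunk_size: int
    buffer: int


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_haplotypes_vcf(
    path: str | Path,
    region: tuple[int, int] | None = None,
    skip_multiallelic: bool = False,
) -> HaplotypePanel | tuple[HaplotypePanel, int]:
    """Read a phased, biallelic VCF into a :class:`HaplotypePanel`.

    Parameters
    ----------
    region:
        Optional half-open bp interval ``[start, end)``; records outside it
        are ignored.
    skip_multiallelic:
        If False (default), a multi-allelic record raises; if True such
        records are dropped and the panel is returned together with the
        number of dropped records.
    """
    legend: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if region is not None and not (region[0] <= rec.pos < region[1]):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                if skip_multiallelic:
                    n_multi += 1
                    continue
                raise PanelFormatError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}"
                )
            col = np.empty(2 * len(samples), dtype=np.uint8)
            for i, sample in enumerate(samples):
                call = rec.samples[sample]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    raise PanelFormatError(
                        f"missing allele at {rec.chrom}:{rec.pos} sample {sample}"
                    )
                if not call.phased:
                    raise PanelFormatError(
                        f"unphased genotype at {rec.chrom}:{rec.pos} sample {sample}"
                    )
                col[2 * i] = gt[0]
                col[2 * i + 1] = gt[1]
            legend.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    ref=rec.ref,
                    alt=rec.alts[0],
                )
            )
            columns.append(col)
    hap_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    alleles = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(hap_ids), 0), dtype=np.uint8)
    )
    panel = HaplotypePanel(legend=legend, haplotype_ids=hap_ids, alleles=alleles)
    if skip_multiallelic:
        return panel, n_multi
    return panel


def write_haplotypes_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a diploid panel as a phased VCF (bgzip-compressed if ``.gz``)."""
    if panel.n_haplotypes % 2:
        raise PanelFormatError("VCF output requires an even haplotype count")
    samples = _sample_names(panel)
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Phased genotype")
    for chrom in dict.fromkeys(s.chrom for s in panel.legend):
        max_pos = max(s.pos for s in panel.legend if s.chrom == chrom)
        header.contigs.add(chrom, length=max_pos + 1)
    for s in samples:
        header.add_sample(s)
    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(str(path), mode, header=header) as vf:
        for j, site in enumerate(panel.legend):
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
                id=site.id,
            )
            for i, sample in enumerate(samples):
                rec.samples[sample]["GT"] = (
                    int(panel.alleles[2 * i, j]),
                    int(panel.alleles[2 * i + 1, j]),
                )
                rec.samples[sample].phased = True
            vf.write(rec)


def _sample_names(panel: HaplotypePanel) -> list[str]:
    """Collapse haplotype ids ``X_1``/``X_2`` into sample names."""
    names = []
    ids = panel.haplotype_ids
    for i in range(0, len(ids), 2):
        a, b = ids[i], ids[i + 1]
        if a.endswith("_1") and b.endswith("_2") and a[:-2] == b[:-2]:
            names.append(a[:-2])
        else:
            names.append(f"S{i // 2}")
    return names


# ---------------------------------------------------------------------------
# IMPUTE-style hap/legend/sample I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_hap_legend(
    hap_path: str | Path,
    legend_path: str | Path,
    sample_path: str | Path | None = None,
    chrom: str = "1",
) -> HaplotypePanel:
    """Read an IMPUTE-style hap/legend(/sample) triplet.

    The hap file is site-major (one row per site); the returned panel is
    haplotype-major.  The legend has a one-line header followed by
    ``id position a0 a1`` columns.
    """
    legend: list[SiteRecord] = []
    with _open_text(legend_path) as fh:
        header = fh.readline()
        if not header.strip():
            raise PanelFormatError("empty legend file")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PanelFormatError(f"legend line has <4 columns: {line!r}")
            legend.append(
                SiteRecord(
                    chrom=chrom,
                    pos=int(parts[1]),
                    id=parts[0],
                    ref=parts[2],
                    alt=parts[3],
                )
            )
    rows: list[list[str]] = []
    with _open_text(hap_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                rows.append(parts)
    if len(rows) != len(legend):
        raise PanelFormatError(
            f"hap file has {len(rows)} rows but legend has {len(legend)} sites"
        )
    width = len(rows[0]) if rows else 0
    site_major = np.empty((len(rows), width), dtype=np.uint8)
    for i, parts in enumerate(rows):
        if len(parts) != width:
            raise PanelFormatError(f"ragged hap file at row {i + 1}")
        for j, tok in enumerate(parts):
            if tok == "0":
                site_major[i, j] = 0
            elif tok == "1":
                site_major[i, j] = 1
            else:
                raise PanelFormatError(
                    f"non-binary allele {tok!r} at hap row {i + 1}"
                )
    n_haps = width
    if sample_path is not None:
        with _open_text(sample_path) as fh:
            fh.readline()  # header
            names = [line.split()[0] for line in fh if line.strip()]
        if 2 * len(names) == n_haps:
            hap_ids = [f"{s}_{h}" for s in names for h in (1, 2)]
        elif len(names) == n_haps:
            hap_ids = names
        else:
            raise PanelFormatError(
                f"sample file lists {len(names)} entries for {n_haps} haplotypes"
            )
    else:
        hap_ids = [f"H{i}" for i in range(n_haps)]
    return HaplotypePanel(
        legend=legend, haplotype_ids=hap_ids, alleles=site_major.T.copy()
    )


def write_hap_legend(
    panel: HaplotypePanel,
    hap_path: str | Path,
    legend_path: str | Path,
    sample_path: str | Path | None = None,
) -> None:
    with _open_text(legend_path, "wt") as fh:
        fh.write("id position a0 a1\n")
        for s in panel.legend:
            fh.write(f"{s.id} {s.pos} {s.ref} {s.alt}\n")
    with _open_text(hap_path, "wt") as fh:
        for j in range(panel.n_sites):
            fh.write(" ".join(str(int(a)) for a in panel.alleles[:, j]))
            fh.write("\n")
    if sample_path is not None:
        with _open_text(sample_path, "wt") as fh:
            fh.write("ID\n")
            if panel.n_haplotypes % 2 == 0:
                for name in _sample_names(panel):
                    fh.write(name + "\n")
            else:
                for hid in panel.haplotype_ids:
                    fh.write(hid + "\n")


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a 3-column genetic map: ``position rate(cM/Mb) cumulative_cM``.

    The first line is a header; only columns 1 and 3 are used.
    """
    bps: list[float] = []
    cms: list[float] = []
    with _open_text(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise PanelFormatError(f"genetic map line has <3 columns: {line!r}")
            bps.append(float(parts[0]))
            cms.append(float(parts[2]))
    return GeneticMap(bp=np.array(bps), cm=np.array(cms))


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        rates = np.empty_like(gmap.cm)
        rates[:-1] = np.diff(gmap.cm) / np.diff(gmap.bp) * 1e6
        rates[-1] = 0.0
        for bp, rate, cm in zip(gmap.bp, rates, gmap.cm):
            fh.write(f"{bp:.0f} {rate:.6f} {cm:.8f}\n")


def uniform_map(
    region: tuple[int, int], rate_cm_per_mb: float = 1.0
) -> GeneticMap:
    """Constant-rate map covering a half-open bp region."""
    start, end = region
    return GeneticMap(
        bp=np.array([start, end], dtype=float),
        cm=np.array([0.0, (end - start) / 1e6 * rate_cm_per_mb]),
    )


# ---------------------------------------------------------------------------
# Chunk planning
# ---------------------------------------------------------------------------

def plan_chunks(
    region: tuple[int, int],
    chunk_size: int = 3_000_000,
    buffer: int = 250_000,
) -> ChunkPlan:
    """Tile a half-open region with fixed-size cores plus clipped buffers.

    Cores partition the region left to right (the last core may be short);
    each buffered interval extends the core by ``buffer`` bp on both sides,
    clipped to the region bounds.
    """
    start, end = int(region[0]), int(region[1])
    if end <= start:
        raise ValueError(f"empty region [{start}, {end})")
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    chunks = []
    s = start
    while s < end:
        e = min(s + chunk_size, end)
        chunks.append(
            Chunk(
                core_start=s,
                core_end=e,
                buf_start=max(start, s - buffer),
                buf_end=min(end, e + buffer),
            )
        )
        s = e
    return ChunkPlan(chunks=tuple(chunks), chunk_size=chunk_size, buffer=buffer)
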