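"""Sparse per-cell allele-count container shared by every stage of the pipeline.

The central object is :class:`AlleleCountMatrix`: for a panel of expressed
SNV sites (rows) and a list of droplet barcodes (columns) it holds two
sparse integer matrices, the alternative-allele read count and the total
read count at each (site, cell). Allele fractions, genotype models,
simulations and benchmarks are all derived from this object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["SNVSite", "AlleleCountMatrix"]


class MatrixFormatError(ValueError):
    """Raised when allele-count inputs are internally inconsistent."""


@dataclass(frozen=True)
class SNVSite:
    """A biallelic SNV locus.

    ``pos`` is 1-based (VCF convention); ``id`` is the 0-based row index of
    the site within its panel. Mitochondrial sites use chrom ``"MT"`` and
    receive no special treatment.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_allele}>{self.alt_allele}"


@dataclass
class AlleleCountMatrix:
    """Alt and total read counts per (SNV site, cell barcode).

    Both matrices are stored CSR with shape ``(n_sites, n_cells)``;
    ``0 <= alt <= total`` holds entrywise and all counts are non-negative
    integers. A ``total`` of zero means the cell has no reads at the site
    (the site is *uncovered* in that cell), which is distinct from a covered
    site with zero alt reads.
    """

    sites: list[SNVSite]
    barcodes: list[str]
    alt: sp.csr_matrix
    total: sp.csr_matrix

    def __post_init__(self) -> None:
        self.alt = sp.csr_matrix(self.alt)
        self.total = sp.csr_matrix(self.total)
        self.alt.eliminate_zeros()
        self.total.eliminate_zeros()
        self._validate()

    def _validate(self) -> None:
        shape = (len(self.sites), len(self.barcodes))
        if self.alt.shape != shape or self.total.shape != shape:
            raise MatrixFormatError(
                f"count matrices {self.alt.shape}/{self.total.shape} do not "
                f"match {len(self.sites)} sites x {len(self.barcodes)} barcodes"
            )
        for name, m in (("alt", self.alt), ("total", self.total)):
            if m.nnz and m.data.min() < 0:
                raise MatrixFormatError(f"{name} counts contain negative entries")
            if not np.issubdtype(m.dtype, np.integer):
                if m.nnz and np.any(m.data != np.round(m.data)):
                    raise MatrixFormatError(f"{name} counts are not integers")
                m.data = m.data.astype(np.int64)
        if (self.alt > self.total).nnz:
            raise MatrixFormatError(
                "alt count exceeds total count at one or more (site, cell) entries"
            )
        seen = set()
        for s in self.sites:
            key = (s.chrom, s.pos, s.ref_allele, s.alt_allele)
            if key in seen:
                raise MatrixFormatError(f"duplicate site {s.chrom}:{s.pos}")
            seen.add(key)

    # -- basic geometry -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_sites, self.n_cells)

    # -- derived summaries ----------------------------------------------

    def sites_covered_per_cell(self) -> np.ndarray:
        """Number of sites with at least one read, per cell."""
        return np.asarray((self.total > 0).sum(axis=0)).ravel()

    def cells_covered_per_site(self) -> np.ndarray:
        return np.asarray((self.total > 0).sum(axis=1)).ravel()

    def reads_per_cell(self) -> np.ndarray:
        return np.asarray(self.total.sum(axis=0)).ravel()

    # -- subsetting ------------------------------------------------------

    def subset_sites(self, idx: Sequence[int] | np.ndarray) -> "AlleleCountMatrix":
        idx = np.asarray(idx, dtype=int)
        sites = [
            SNVSite(s.chrom, s.pos, s.ref_allele, s.alt_allele, new_id)
            for new_id, s in enumerate(self.sites[i] for i in idx)
        ]
        return AlleleCountMatrix(
            sites=sites,
            barcodes=list(self.barcodes),
            alt=self.alt[idx, :],
            total=self.total[idx, :],
        )

    def subset_cells(self, idx: Sequence[int] | np.ndarray) -> "AlleleCountMatrix":
        idx = np.asarray(idx, dtype=int)
        return AlleleCountMatrix(
            sites=list(self.sites),
            barcodes=[self.barcodes[i] for i in idx],
            alt=self.alt[:, idx],
            total=self.total[:, idx],
        )

    def equals(self, other: "AlleleCountMatrix") -> bool:
        """Bit-exact equality of sites, barcodes and both count matrices."""
        if self.barcodes != other.barcodes:
            return False
        if [(s.chrom, s.pos, s.ref_allele, s.alt_allele) for s in self.sites] != [
            (s.chrom, s.pos, s.ref_allele, s.alt_allele) for s in other.sites
        ]:
            return False
        return (self.alt != other.alt).nnz == 0 and (self.total != other.total).nnz == 0
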