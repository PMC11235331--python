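"""Read, write, filter and convert per-cell allele-count data.

The on-disk layout mirrors the cellSNP-lite convention: a VCF of SNV sites,
a pair of MatrixMarket sparse matrices (alt-allele depth ``AD`` and total
depth ``DP``, sites as rows, cells as columns, 1-based coordinates) and a
plain-text barcode list. The same layout is what Vireo consumes, so the
"vireo" export dialect is simply a faithful re-serialization; the
"souporcell" dialect writes alt/ref matrices instead (ref = total - alt).

SNV filtering implements the minimal pre-demultiplexing filter set:
drop near-fixed sites (mean minor-allele fraction across covered cells
above 0.999 — homozygous in every cell, hence uninformative), sites
covered in fewer than 10 cells, and sites with alt reads in fewer than
5 cells.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .matrix import AlleleCountMatrix, MatrixFormatError, SNVSite

__all__ = [
    "FilterConfig",
    "read_counts",
    "write_counts",
    "filter_snvs",
    "export_demux_input",
]

log = logging.getLogger(__name__)

_VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


@dataclass
class FilterConfig:
    """Thresholds for the pre-demultiplexing SNV filter.

    max_mean_maf
        Sites whose mean minor-allele fraction over covered cells exceeds
        this are removed as effectively homozygous. Default 0.999.
    min_cells_covered
        Minimum number of cells with >= 1 read at the site. Default 10.
    min_cells_with_alt
        Minimum number of cells with >= 1 alt read. Default 5.
    """

    max_mean_maf: float = 0.999
    min_cells_covered: int = 10
    min_cells_with_alt: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mean_maf <= 1.0:
            raise ValueError("max_mean_maf must be in [0, 1]")


def _open_text(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_sites_vcf(vcf_path: Path) -> list[SNVSite]:
    """Parse SNV sites from a VCF, rejecting multi-allelic records.

    Returns (sites, kept_row_indices, total_record_count); multi-allelic
    records are skipped with a logged count and callers drop the matching
    matrix rows.
    """
    import pysam

    sites: list[SNVSite] = []
    kept_rows: list[int] = []
    n_multi = 0
    n_records = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # header-less site VCFs are fine
        try:
            vf = pysam.VariantFile(str(vcf_path))
        except (OSError, ValueError) as exc:
            raise MatrixFormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc
        with vf:
            for row, rec in enumerate(vf):
                n_records = row + 1
                alts = rec.alts or ()
                if len(alts) != 1:
                    n_multi += 1
                    continue
                try:
                    site = SNVSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alts[0],
                        id=len(sites),
                    )
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"malformed VCF record #{row + 1} in {vcf_path}: {exc}"
                    ) from exc
                sites.append(site)
                kept_rows.append(row)
    if n_multi:
        log.warning("rejected %d multi-allelic record(s) in %s", n_multi, vcf_path)
    return sites, kept_rows, n_records


def _read_barcodes(path: Path) -> list[str]:
    with _open_text(path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if not barcodes:
        raise MatrixFormatError(f"no cells: barcode file {path} is empty")
    return barcodes


def _read_mtx(path: Path, what: str) -> sp.csr_matrix:
    try:
        m = scipy.io.mmread(str(path))
    except Exception as exc:
        raise MatrixFormatError(f"cannot parse {what} matrix {path}: {exc}") from exc
    return sp.csr_matrix(m)


def read_counts(
    vcf_path: str | Path,
    alt_mtx_path: str | Path,
    total_mtx_path: str | Path,
    barcodes_path: str | Path,
) -> AlleleCountMatrix:
    """Load a cellSNP-style directory layout into an AlleleCountMatrix.

    Dimensions of both MTX files must agree with the VCF record count
    (rows) and the barcode count (columns); any entry with alt > total
    raises. Multi-allelic VCF records are rejected (with a logged count)
    and their matrix rows dropped.
    """
    sites, kept_rows, n_records = _read_sites_vcf(Path(vcf_path))
    barcodes = _read_barcodes(Path(barcodes_path))
    alt = _read_mtx(Path(alt_mtx_path), "alt")
    total = _read_mtx(Path(total_mtx_path), "total")

    for name, m, path in (("alt", alt, alt_mtx_path), ("total", total, total_mtx_path)):
        if m.shape != (n_records, len(barcodes)):
            raise MatrixFormatError(
                f"{name} matrix {path} has shape {m.shape}, expected "
                f"({n_records} VCF records, {len(barcodes)} barcodes)"
            )
    if len(kept_rows) != n_records:
        keep = np.asarray(kept_rows, dtype=int)
        alt, total = alt[keep, :], total[keep, :]
    return AlleleCountMatrix(sites=sites, barcodes=barcodes, alt=alt, total=total)


def _write_mtx(path: Path, m: sp.spmatrix) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(m).astype(np.int64))


def _write_sites_vcf(path: Path, sites: list[SNVSite]) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\n")


def write_counts(matrix: AlleleCountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the cellSNP/vireo layout; inverse of :func:`read_counts`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cellSNP.base.vcf",
        "alt": out / "cellSNP.tag.AD.mtx",
        "total": out / "cellSNP.tag.DP.mtx",
        "barcodes": out / "cellSNP.samples.tsv",
    }
    _write_sites_vcf(paths["vcf"], matrix.sites)
    _write_mtx(paths["alt"], matrix.alt)
    _write_mtx(paths["total"], matrix.total)
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")
    return paths


def read_counts_dir(in_dir: str | Path) -> AlleleCountMatrix:
    """Load a directory written by :func:`write_counts`."""
    d = Path(in_dir)
    return read_counts(
        d / "cellSNP.base.vcf",
        d / "cellSNP.tag.AD.mtx",
        d / "cellSNP.tag.DP.mtx",
        d / "cellSNP.samples.tsv",
    )


def mean_minor_allele_fraction(matrix: AlleleCountMatrix) -> np.ndarray:
    """Per-site mean alt-allele fraction over cells with coverage.

    Cells without coverage at a site are excluded from that site's mean
    (they carry no allele information); sites covered in no cell get NaN.
    """
    af = matrix.alt.multiply(matrix.total.power(-1.0))  # pattern of alt
    n_cov = matrix.cells_covered_per_site().astype(float)
    sums = np.asarray(af.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_cov > 0, sums / np.maximum(n_cov, 1), np.nan)


def filter_snvs(
    matrix: AlleleCountMatrix, config: FilterConfig | None = None
) -> AlleleCountMatrix:
    """Apply the minimal SNV filter; returns a new matrix, site order kept.

    Removes sites that are (a) effectively homozygous across cells
    (mean minor-allele fraction over covered cells > ``max_mean_maf``),
    (b) covered in fewer than ``min_cells_covered`` cells, or (c) carry an
    alt read in fewer than ``min_cells_with_alt`` cells. Idempotent.
    """
    config = config or FilterConfig()
    mean_maf = mean_minor_allele_fraction(matrix)
    n_cov = matrix.cells_covered_per_site()
    n_alt = np.asarray((matrix.alt > 0).sum(axis=1)).ravel()

    with np.errstate(invalid="ignore"):
        keep = (
            ~(mean_maf > config.max_mean_maf)
            & (n_cov >= config.min_cells_covered)
            & (n_alt >= config.min_cells_with_alt)
        )
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        log.warning("SNV filter removed all %d sites", matrix.n_sites)
    return matrix.subset_sites(kept)


def export_demux_input(
    matrix: AlleleCountMatrix, dialect: str, out_dir: str | Path
) -> dict[str, Path]:
    """Write demultiplexer input files for Vireo or Souporcell.

    ``vireo``: cellSNP layout (site VCF + AD/DP MTX + barcodes); a
    round-trip through :func:`read_counts` reproduces the matrix exactly.
    ``souporcell``: alt.mtx / ref.mtx (ref = total - alt) + barcodes.tsv.
    """
    if matrix.n_sites == 0 or matrix.n_cells == 0:
        raise MatrixFormatError("refusing to export an empty allele-count matrix")
    out = Path(out_dir)
    if dialect == "vireo":
        return write_counts(matrix, out)
    if dialect == "souporcell":
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "souporcell.base.vcf",
            "alt": out / "alt.mtx",
            "ref": out / "ref.mtx",
            "barcodes": out / "barcodes.tsv",
        }
        _write_sites_vcf(paths["vcf"], matrix.sites)
        _write_mtx(paths["alt"], matrix.alt)
        _write_mtx(paths["ref"], matrix.total - matrix.alt)
        with open(paths["barcodes"], "w") as fh:
            fh.write("\n".join(matrix.barcodes) + "\n")
        return paths
    raise ValueError(f"unknown export dialect {dialect!r}; use 'vireo' or 'souporcell'")
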