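"""Synthetic two-genotype droplet scRNA-seq allele-count simulator.

Emulates a transplant-style mixture of cells from two genetically distinct
individuals, with the droplet artifacts that make demultiplexing hard:

* two diploid genotypes drawn under Hardy-Weinberg equilibrium from
  Beta-distributed population allele frequencies, with a configurable
  fraction of "false positive" SNV sites where the two individuals do not
  differ and the sequencing error rate is inflated (mimicking spurious
  SNV calls from sparse single-cell data);
* sparse, highly skewed per-cell coverage: each site carries a relative
  expression weight drawn from a symmetric Dirichlet (a few hot sites —
  think mitochondrial transcripts — soak up much of the depth, most
  sites are rarely seen, as in real droplet data), each cell receives a
  Poisson number of molecules allocated multinomially over sites, and
  alt reads are Binomial at the genotype's true allele fraction;
* cell-cell doublets formed by summing the counts of one cell of each
  genotype, at a rate expressed as a fraction of the minor population;
* ambient RNA simulated at the collapsed-molecule level: every molecule
  is independently swapped, with a given probability, to a uniformly
  chosen *other* barcode, conserving the total molecule count exactly.

The default mixing grid is 3 replicates x 12 minor-population sizes
(25 .. 2,000 of 4,000 singlets) x 5 ambient rates (0 .. 40%) = 180
samples; every sample carries ground-truth labels per barcode.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator

import numpy as np
import scipy.sparse as sp

from .matrix import AlleleCountMatrix, SNVSite

__all__ = [
    "GenotypePair",
    "SimConfig",
    "SimulatedSample",
    "draw_genotypes",
    "simulate_singlet",
    "make_doublets",
    "add_ambient",
    "simulate_sample",
    "simulate_grid",
    "n_doublets_for",
]

_DEFAULT_MINOR_COUNTS = (25, 50, 75, 100, 150, 200, 300, 400, 500, 750, 1000, 2000)
_DEFAULT_AMBIENT_RATES = (0.0, 0.1, 0.2, 0.3, 0.4)


@dataclass
class GenotypePair:
    """Two diploid genotypes over a shared SNV panel.

    ``gt1``/``gt2`` hold alt-allele copy numbers in {0, 1, 2}; ``true_af``
    per genotype is the expected alt-read fraction: error_rate for 0/0,
    0.5 for 0/1, 1 - error_rate for 1/1 (false positive sites use the
    inflated error rate instead).
    """

    pop_af: np.ndarray
    gt1: np.ndarray
    gt2: np.ndarray
    true_af1: np.ndarray
    true_af2: np.ndarray
    fp_mask: np.ndarray
    site_weights: np.ndarray | None = None  # relative expression per site

    @property
    def n_sites(self) -> int:
        return self.pop_af.size


@dataclass
class SimConfig:
    """Study conditions for the simulation grid.

    The mixing grid defaults reproduce the benchmark design: 4,000
    singlets per sample, minor-population sizes 25..2,000, three
    replicates, ambient rates 0-40%, and doublets at 10% of the minor
    population. The coverage model (mean reads per cell allocated
    multinomially over Dirichlet-skewed site weights) and the genotype
    model (Beta(0.8, 0.8) population allele frequencies truncated to
    [0.05, 0.95], sequencing error 0.005, 5% false-positive sites at
    error 0.05) are stated parametric choices.
    """

    n_total: int = 4000
    minor_counts: tuple[int, ...] = _DEFAULT_MINOR_COUNTS
    n_replicates: int = 3
    ambient_rates: tuple[float, ...] = _DEFAULT_AMBIENT_RATES
    doublet_rate: float = 0.10
    doublet_rate_base: str = "minor"  # or "total"
    n_sites: int = 2000
    mean_reads_per_cell: float = 250.0
    site_concentration: float = 0.3
    error_rate: float = 0.005
    fp_snv_fraction: float = 0.05
    fp_error_rate: float = 0.05
    beta_shape: tuple[float, float] = (0.8, 0.8)
    pop_af_bounds: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m >= self.n_total for m in self.minor_counts):
            raise ValueError("every minor count must be smaller than n_total")
        for r in (*self.ambient_rates, self.doublet_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.doublet_rate_base not in ("minor", "total"):
            raise ValueError("doublet_rate_base must be 'minor' or 'total'")

    def grid_cells(self) -> list[tuple[int, int, float]]:
        """All (replicate, minor_count, ambient_rate) combinations."""
        return [
            (rep, m, a)
            for rep in range(self.n_replicates)
            for m in self.minor_counts
            for a in self.ambient_rates
        ]


@dataclass
class SimulatedSample:
    """An allele-count matrix with per-barcode ground truth."""

    matrix: AlleleCountMatrix
    truth: np.ndarray  # per-barcode label in {GT1, GT2, doublet}
    provenance: dict

    def truth_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.truth, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def n_doublets_for(minor_count: int, rate: float, base_count: int | None = None) -> int:
    """Doublet count for a mixture: round-half-even of rate x population.

    Exact rational arithmetic avoids float artifacts (0.1 x 25 rounds to
    2, not 3).
    """
    base = minor_count if base_count is None else base_count
    return int(round(Fraction(str(rate)) * base))


def _genotype_af(gt: np.ndarray, eps: np.ndarray) -> np.ndarray:
    af = np.empty(gt.shape, dtype=float)
    af[gt == 0] = eps[gt == 0]
    af[gt == 1] = 0.5
    af[gt == 2] = 1.0 - eps[gt == 2]
    return af


def draw_genotypes(n_sites: int, seed: int, config: SimConfig | None = None) -> GenotypePair:
    """Draw two Hardy-Weinberg genotypes over a fresh SNV panel.

    Population allele frequencies come from a truncated Beta; each
    individual's copy number is Binomial(2, pop_af). A configured
    fraction of sites is forced genotype-identical with inflated error
    ("false positive" SNV calls, which carry no demultiplexing signal but
    add noise).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    a, b = cfg.beta_shape
    lo, hi = cfg.pop_af_bounds
    pop_af = lo + (hi - lo) * rng.beta(a, b, size=n_sites)
    gt1 = rng.binomial(2, pop_af)
    gt2 = rng.binomial(2, pop_af)

    fp_mask = rng.random(n_sites) < cfg.fp_snv_fraction
    gt2 = np.where(fp_mask, gt1, gt2)
    eps = np.where(fp_mask, cfg.fp_error_rate, cfg.error_rate)
    site_weights = rng.dirichlet(np.full(n_sites, cfg.site_concentration))
    return GenotypePair(
        pop_af=pop_af,
        gt1=gt1,
        gt2=gt2,
        true_af1=_genotype_af(gt1, eps),
        true_af2=_genotype_af(gt2, eps),
        fp_mask=fp_mask,
        site_weights=site_weights,
    )


def _simulate_singlets(
    true_af: np.ndarray,
    weights: np.ndarray,
    n_cells: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (n_sites, n_cells) alt/total count arrays for one genotype."""
    reads = rng.poisson(cfg.mean_reads_per_cell, size=n_cells)
    tot = rng.multinomial(reads, weights)  # (n_cells, n_sites)
    alt = rng.binomial(tot, true_af[None, :])
    return alt.T.astype(np.int32), tot.T.astype(np.int32)


def simulate_singlet(
    genotype: int, pair: GenotypePair, config: SimConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One cell's (alt, total) count vectors for genotype 1 or 2.

    The cell receives ~Poisson(mean_reads_per_cell) molecules allocated
    multinomially over the panel's expression weights; per covered site
    alt ~ Binomial(total, true_af). A cell may legally cover zero sites.
    """
    if genotype not in (1, 2):
        raise ValueError("genotype must be 1 or 2")
    rng = np.random.default_rng(seed)
    af = pair.true_af1 if genotype == 1 else pair.true_af2
    w = pair.site_weights
    if w is None:
        w = np.full(pair.n_sites, 1.0 / pair.n_sites)
    alt, tot = _simulate_singlets(af, w, 1, config, rng)
    return alt[:, 0], tot[:, 0]


def make_doublets(
    alt1: np.ndarray,
    tot1: np.ndarray,
    alt2: np.ndarray,
    tot2: np.ndarray,
    n_doublets: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum parent pairs drawn without replacement from two singlet pools.

    ``alt1``/``tot1`` are (n_sites, pool1) GT1 parent counts (likewise
    GT2); each doublet is the elementwise count sum of one parent from
    each pool, so a doublet's reads carry both genotypes' alleles.
    """
    if n_doublets > min(alt1.shape[1], alt2.shape[1]):
        raise ValueError(
            f"cannot draw {n_doublets} doublet parents without replacement "
            f"from pools of {alt1.shape[1]} and {alt2.shape[1]}"
        )
    i1 = rng.permutation(alt1.shape[1])[:n_doublets]
    i2 = rng.permutation(alt2.shape[1])[:n_doublets]
    return alt1[:, i1] + alt2[:, i2], tot1[:, i1] + tot2[:, i2]


def add_ambient(
    sample: SimulatedSample, rate: float, seed: int
) -> SimulatedSample:
    """Swap each collapsed molecule to another barcode with probability ``rate``.

    Every read unit of every (site, cell) count is treated as one
    collapsed molecule; swapped molecules move wholesale to a uniformly
    drawn *different* barcode (a molecule's tags never split across
    cells). The total molecule count over the sample is conserved
    exactly and truth labels are unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("ambient rate must be in [0, 1]")
    if rate == 0.0:
        return sample
    rng = np.random.default_rng(seed)
    m = sample.matrix
    n_cells = m.n_cells

    alt = np.asarray(m.alt.todense(), dtype=np.int64)
    tot = np.asarray(m.total.todense(), dtype=np.int64)
    ref = tot - alt

    for is_alt, counts in ((True, alt), (False, ref)):
        coo = sp.coo_matrix(counts)
        n_swap = rng.binomial(coo.data, rate)
        keep = n_swap > 0
        src_site = np.repeat(coo.row[keep], n_swap[keep])
        src_cell = np.repeat(coo.col[keep], n_swap[keep])
        # uniform over the n_cells - 1 *other* barcodes
        dest = rng.integers(0, n_cells - 1, size=src_site.size)
        dest = dest + (dest >= src_cell)
        np.subtract.at(counts, (coo.row[keep], coo.col[keep]), n_swap[keep])
        np.add.at(counts, (src_site, dest), 1)

    new_tot = alt + ref
    matrix = AlleleCountMatrix(
        sites=list(m.sites),
        barcodes=list(m.barcodes),
        alt=sp.csr_matrix(alt),
        total=sp.csr_matrix(new_tot),
    )
    prov = dict(sample.provenance)
    prov["ambient_rate"] = rate
    return SimulatedSample(matrix=matrix, truth=sample.truth.copy(), provenance=prov)


def _panel_sites(pair: GenotypePair) -> list[SNVSite]:
    # synthetic coordinates: sites laid out along chromosomes 1..22 + MT
    chroms = [str(c) for c in range(1, 23)] + ["MT"]
    sites = []
    bases = ("A", "C", "G", "T")
    for i in range(pair.n_sites):
        chrom = chroms[i % len(chroms)]
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        sites.append(SNVSite(chrom=chrom, pos=1000 + i, ref_allele=ref, alt_allele=alt, id=i))
    return sites


def simulate_sample(
    pair: GenotypePair,
    minor_count: int,
    ambient_rate: float,
    config: SimConfig,
    seed: int,
    replicate: int = 0,
) -> SimulatedSample:
    """One mixture: (n_total - minor) GT1 + minor GT2 singlets + doublets.

    Doublet parents come from dedicated extra pools (no barcode is both a
    singlet and a doublet parent); doublet counts are parent sums before
    ambient contamination is applied to the whole sample. Barcode order
    is shuffled so genotype is not encoded in column position.
    """
    rng = np.random.default_rng(seed)
    n_gt1 = config.n_total - minor_count
    n_gt2 = minor_count
    base = minor_count if config.doublet_rate_base == "minor" else config.n_total
    n_dbl = n_doublets_for(minor_count, config.doublet_rate, base)

    weights = pair.site_weights
    if weights is None:
        weights = np.full(pair.n_sites, 1.0 / pair.n_sites)
    alt1, tot1 = _simulate_singlets(pair.true_af1, weights, n_gt1 + n_dbl, config, rng)
    alt2, tot2 = _simulate_singlets(pair.true_af2, weights, n_gt2 + n_dbl, config, rng)

    s_alt = [alt1[:, :n_gt1], alt2[:, :n_gt2]]
    s_tot = [tot1[:, :n_gt1], tot2[:, :n_gt2]]
    truth = ["GT1"] * n_gt1 + ["GT2"] * n_gt2
    if n_dbl > 0:
        d_alt, d_tot = make_doublets(
            alt1[:, n_gt1:], tot1[:, n_gt1:], alt2[:, n_gt2:], tot2[:, n_gt2:], n_dbl, rng
        )
        s_alt.append(d_alt)
        s_tot.append(d_tot)
        truth += ["doublet"] * n_dbl

    alt = np.concatenate(s_alt, axis=1)
    tot = np.concatenate(s_tot, axis=1)
    truth = np.asarray(truth, dtype=object)

    order = rng.permutation(alt.shape[1])
    alt, tot, truth = alt[:, order], tot[:, order], truth[order]
    barcodes = [f"BC{j:06d}" for j in range(alt.shape[1])]

    matrix = AlleleCountMatrix(
        sites=_panel_sites(pair),
        barcodes=barcodes,
        alt=sp.csr_matrix(alt),
        total=sp.csr_matrix(tot),
    )
    sample = SimulatedSample(
        matrix=matrix,
        truth=truth,
        provenance={
            "replicate": replicate,
            "minor_count": minor_count,
            "ambient_rate": 0.0,
            "n_doublets": n_dbl,
            "seed": seed,
        },
    )
    if ambient_rate > 0:
        sample = add_ambient(sample, ambient_rate, seed=seed + 1)
    return sample


def simulate_grid(config: SimConfig | None = None) -> Iterator[SimulatedSample]:
    """Yield one sample per (replicate x minor count x ambient rate).

    With defaults this is 3 x 12 x 5 = 180 samples. One genotype pair
    (the same two individuals) underlies the whole grid; the singlet
    mixture of a (replicate, minor count) cell is shared across its five
    ambient rates, matching a design where contamination is layered onto
    a fixed base mixture. Per-sample seeds derive deterministically from
    ``config.seed``.
    """
    cfg = config or SimConfig()
    ss = np.random.SeedSequence(cfg.seed)
    pair_seed, *rest = ss.generate_state(
        1 + cfg.n_replicates * len(cfg.minor_counts), dtype=np.uint32
    ).tolist()
    pair = draw_genotypes(cfg.n_sites, pair_seed, cfg)

    k = 0
    for rep in range(cfg.n_replicates):
        for minor in cfg.minor_counts:
            base_seed = int(rest[k]) % (2**31 - 1)
            k += 1
            base = simulate_sample(pair, minor, 0.0, cfg, seed=base_seed, replicate=rep)
            for amb in cfg.ambient_rates:
                if amb == 0.0:
                    yield base
                else:
                    contaminated = add_ambient(
                        base, amb, seed=(base_seed + int(round(amb * 1000))) % (2**31 - 1)
                    )
                    yield contaminated
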