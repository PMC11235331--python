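"""Two-stage genotype discovery and iterative refinement for two-genotype
droplet scRNA-seq samples.

The algorithm separates the cells of two genetically distinct individuals
(e.g. transplant donor and recipient) using only expressed SNV allele
fractions, with no external genotypes:

Stage 1 — discovery by clustering. High-quality cells (covering at least
``min_snvs_per_cell`` SNV sites) are embedded by their per-site minor
allele fractions (mAF = alt reads / total reads). A k-nearest-neighbour
graph under the mean-absolute-difference mAF distance (restricted to
sites covered in both cells) is clustered with modularity-based community
detection; communities are agglomerated into at most two candidate
genotype groups.

Stage 2 — rescue of a rare second genotype. When clustering finds a
single group (the minor genotype may be far too small to form its own
community), every eligible cell is scored against the dominant genotype
with a per-read binomial log-likelihood ("genotype score"); cells falling
more than ``mad_k`` scaled median-absolute-deviations below the median
score are candidate minor-genotype cells. If neither stage finds a second
genotype the sample is reported as single-genotype.

Refinement — once two groups exist, genotype allele-fraction profiles are
re-estimated from the current singlet assignments and every cell
(including discovery-ineligible ones) is re-classified under three
binomial profiles: genotype 1, genotype 2, and a derived doublet profile
(coverage-weighted mean of the two). Synthetic doublets built by summing
the counts of random GT1/GT2 cell pairs calibrate the doublet acceptance
region. Estimation and classification alternate until the labels reach a
fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix import AlleleCountMatrix

__all__ = [
    "DemuxConfig",
    "GenotypeModel",
    "AssignmentResult",
    "cell_maf_profiles",
    "select_eligible_cells",
    "af_distance",
    "stage1_discover",
    "genotype_score",
    "stage2_rescue",
    "estimate_genotype",
    "simulate_doublet_profiles",
    "classify_cells",
    "refine",
    "demultiplex",
]

log = logging.getLogger(__name__)

LABELS = ("GT1", "GT2", "doublet", "unassigned")

# Allele fractions are clamped away from {0, 1} before taking logs so a
# single contaminating read cannot contribute an unbounded penalty.
AF_FLOOR = 1e-3


class InsufficientCellsError(RuntimeError):
    pass


@dataclass
class DemuxConfig:
    """Free parameters of the demultiplexer.

    min_snvs_per_cell
        Coverage gate for discovery: only cells covering at least this
        many SNV sites enter clustering and genotype estimation.
    knn_k
        Neighbours per cell in the stage-1 graph.
    min_shared_sites
        Minimum number of co-covered sites for a pairwise mAF distance to
        be defined.
    mad_k
        Stage-2 threshold: cells scoring below median - mad_k * MAD
        (MAD scaled by 1.4826 for normal consistency) are rescue
        candidates.
    separation_floor
        Minimum mean |delta mAF| between two candidate genotype profiles
        for a second genotype to be accepted.
    doublet_sim_multiplier
        Synthetic doublets simulated per observed cell.
    pseudocount
        Beta prior pseudocount for genotype allele-fraction estimates.
    assign_margin
        Minimum log-likelihood gap (nats) between best and runner-up
        profile; cells under the margin are left unassigned.
    """

    min_snvs_per_cell: int = 25
    knn_k: int = 10
    min_shared_sites: int = 5
    mad_k: float = 5.0
    separation_floor: float = 0.1
    doublet_sim_multiplier: float = 1.0
    pseudocount: float = 1.0
    max_iter: int = 50
    assign_margin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_snvs_per_cell", "knn_k", "min_shared_sites", "mad_k",
                     "doublet_sim_multiplier", "pseudocount", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.assign_margin < 0:
            raise ValueError("assign_margin must be non-negative")


@dataclass
class GenotypeModel:
    """Per-site allele-fraction profiles for the two genotypes.

    ``af_gt1``/``af_gt2`` are posterior-mean allele fractions (pseudocount
    prior); ``support_*`` the total reads behind each estimate and
    ``n_cells_*`` the number of cells it was estimated from. The doublet
    profile is the coverage-weighted mean of the two singlet profiles,
    weighted by each genotype's mean per-cell read depth at the site — a
    droplet holds one cell of each genotype, so its reads mix in
    proportion to what a single cell of each contributes, not in
    proportion to the population sizes.
    """

    af_gt1: np.ndarray
    support_gt1: np.ndarray
    af_gt2: np.ndarray | None = None
    support_gt2: np.ndarray | None = None
    n_cells_gt1: int = 1
    n_cells_gt2: int = 1

    @property
    def af_doublet(self) -> np.ndarray:
        if self.af_gt2 is None:
            raise ValueError("doublet profile requires two genotypes")
        w1 = self.support_gt1 / max(self.n_cells_gt1, 1)
        w2 = self.support_gt2 / max(self.n_cells_gt2, 1)
        w = w1 + w2
        with np.errstate(invalid="ignore"):
            mix = (self.af_gt1 * w1 + self.af_gt2 * w2) / np.where(w > 0, w, 1.0)
        return np.where(w > 0, mix, 0.5 * (self.af_gt1 + self.af_gt2))


@dataclass
class AssignmentResult:
    """Per-cell demultiplexing outcome.

    ``labels`` maps every barcode to GT1 | GT2 | doublet | unassigned
    (single-genotype samples use only GT1 | unassigned). Log-likelihood
    columns are natural-log binomial likelihoods summed over covered
    sites; ``genotype_score`` is the stage-2 per-read score against the
    dominant genotype.
    """

    barcodes: list[str]
    labels: np.ndarray
    loglik_gt1: np.ndarray
    loglik_gt2: np.ndarray
    loglik_doublet: np.ndarray
    n_informative_sites: np.ndarray
    genotype_score: np.ndarray
    second_genotype_found: bool
    n_iterations: int
    converged: bool

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "label": self.labels,
                "loglik_gt1": self.loglik_gt1,
                "loglik_gt2": self.loglik_gt2,
                "loglik_doublet": self.loglik_doublet,
                "n_informative_sites": self.n_informative_sites,
                "genotype_score": self.genotype_score,
            }
        )

    def summary(self) -> dict:
        return {
            "second_genotype_found": self.second_genotype_found,
            "counts": self.counts(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# allele-fraction profiles and distances


def cell_maf_profiles(matrix: AlleleCountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-cell allele fractions plus a coverage mask.

    Returns ``(af, covered)`` of shape (n_cells, n_sites): ``af[c, s]`` is
    alt/total where the cell covers the site; uncovered entries are 0 in
    ``af`` and False in ``covered`` (absence, not an observed fraction).
    """
    af_sparse = matrix.alt.multiply(matrix.total.power(-1.0))
    af = np.asarray(af_sparse.todense(), dtype=np.float32).T
    covered = np.asarray((matrix.total > 0).todense()).T
    return af, covered


def select_eligible_cells(matrix: AlleleCountMatrix, config: DemuxConfig) -> np.ndarray:
    """Indices of cells covering at least ``min_snvs_per_cell`` sites."""
    eligible = np.flatnonzero(matrix.sites_covered_per_cell() >= config.min_snvs_per_cell)
    if eligible.size < 2 * config.knn_k:
        raise InsufficientCellsError(
            f"insufficient cells for discovery: {eligible.size} cells cover "
            f">= {config.min_snvs_per_cell} SNVs (need >= {2 * config.knn_k})"
        )
    return eligible


def af_distance(
    af_a: np.ndarray,
    cov_a: np.ndarray,
    af_b: np.ndarray,
    cov_b: np.ndarray,
    min_shared_sites: int = 5,
) -> float:
    """Mean absolute mAF difference over sites covered in both cells.

    Returns NaN (undefined; no graph edge) when fewer than
    ``min_shared_sites`` sites are co-covered. Symmetric, in [0, 1].
    """
    shared = cov_a & cov_b
    n = int(shared.sum())
    if n < min_shared_sites:
        return float("nan")
    return float(np.abs(af_a[shared] - af_b[shared]).mean())


def _pairwise_af_distance(
    af: np.ndarray, covered: np.ndarray, min_shared_sites: int, chunk: int = 24
) -> np.ndarray:
    """All-pairs masked L1 mean distance; NaN where under-shared."""
    n = af.shape[0]
    cov_f = covered.astype(np.float32)
    dist = np.empty((n, n), dtype=np.float32)
    shared = cov_f @ cov_f.T
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        diff = np.abs(af[i0:i1, None, :] - af[None, :, :])
        diff *= covered[i0:i1, None, :]
        diff *= covered[None, :, :]
        dist[i0:i1] = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = dist / shared
    dist[shared < min_shared_sites] = np.nan
    return dist


def _knn_graph(dist: np.ndarray, k: int):
    """Undirected union-of-kNN igraph from a (possibly NaN-holed) matrix."""
    import igraph

    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.nan)
    edges: set[tuple[int, int]] = set()
    order = np.argsort(np.where(np.isnan(d), np.inf, d), axis=1, kind="stable")
    n_valid = (~np.isnan(d)).sum(axis=1)
    for i in range(n):
        kk = min(k, int(n_valid[i]))
        for j in order[i, :kk]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.add((a, b))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def _centroid_distance(cent_a, cent_b, n_a=None, n_b=None) -> float:
    """Mean |delta mAF| between two community centroids.

    When per-site covered-cell counts are given, sites are weighted by
    their co-support min(n_a, n_b): a small community's centroid is
    dominated by noise at sites only one or two of its cells cover, and
    an unweighted mean lets that noise inflate the distance past the
    true genotype separation.
    """
    shared = ~np.isnan(cent_a) & ~np.isnan(cent_b)
    if not shared.any():
        return float("nan")
    diff = np.abs(cent_a[shared] - cent_b[shared])
    if n_a is None or n_b is None:
        return float(diff.mean())
    w = np.minimum(n_a[shared], n_b[shared]).astype(float)
    if w.sum() == 0:
        return float(diff.mean())
    return float((diff * w).sum() / w.sum())


def stage1_discover(
    matrix: AlleleCountMatrix, config: DemuxConfig
) -> tuple[np.ndarray, np.ndarray] | None:
    """Discover two genotype groups by community clustering, or ``None``.

    Clusters eligible cells on a kNN graph of mAF distances with
    modularity-based (Leiden) community detection, then agglomerates the
    communities pairwise by closest centroid mAF distance until two
    super-groups remain; the pair is accepted as two genotypes only if
    its centroid distance exceeds ``separation_floor`` (same-genotype
    community splits sit far below it, opposite genotypes far above).
    Returns (gt1_cell_indices, gt2_cell_indices) into ``matrix`` columns,
    the larger group first, or ``None`` if no convincing second genotype
    emerges (stage 2 then takes over).
    """
    import leidenalg

    eligible = select_eligible_cells(matrix, config)
    sub = matrix.subset_cells(eligible)
    af, covered = cell_maf_profiles(sub)
    dist = _pairwise_af_distance(af, covered, config.min_shared_sites)
    g = _knn_graph(dist, config.knn_k)
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, seed=config.seed, n_iterations=-1
    )
    membership = np.asarray(part.membership)
    n_comm = membership.max() + 1
    if n_comm < 2:
        return None

    groups = [[c] for c in range(n_comm)]
    alt_csc = sp.csc_matrix(sub.alt)
    tot_csc = sp.csc_matrix(sub.total)

    def group_stats(group):
        # read-pooled allele fractions: precise at well-covered sites even
        # for a community of very few cells (where a mean of per-cell mAFs
        # would be dominated by shallow-site noise)
        rows = np.flatnonzero(np.isin(membership, group))
        a = np.asarray(alt_csc[:, rows].sum(axis=1)).ravel()
        n = np.asarray(tot_csc[:, rows].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            cent = np.where(n > 0, a / np.maximum(n, 1), np.nan)
        return cent, n

    def closest_pair(groups):
        stats = [group_stats(g_) for g_ in groups]
        best, best_d = None, np.inf
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = _centroid_distance(
                    stats[i][0], stats[j][0], stats[i][1], stats[j][1]
                )
                if np.isnan(d):
                    d = np.inf
                if d < best_d:
                    best, best_d = (i, j), d
        return best, best_d

    # agglomerate closest community pairs down to two candidate genotype
    # groups; never merge the last two — the separation floor below decides
    # whether they are genuinely distinct genotypes
    while len(groups) > 2:
        (i, j), d = closest_pair(groups)
        groups[i] = groups[i] + groups[j]
        del groups[j]
    ca, na = group_stats(groups[0])
    cb, nb = group_stats(groups[1])
    d_final = _centroid_distance(ca, cb, na, nb)
    if not np.isfinite(d_final) or d_final <= config.separation_floor:
        return None
    idx = [eligible[np.isin(membership, g_)] for g_ in groups]
    idx.sort(key=lambda a: (-a.size, a[0] if a.size else -1))
    return idx[0], idx[1]


# ---------------------------------------------------------------------------
# genotype models and scoring


def estimate_genotype(
    matrix: AlleleCountMatrix, cells: np.ndarray, pseudocount: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean per-site allele fraction over a cell set.

    af = (sum alt + pc) / (sum total + 2 pc); support = sum total.
    """
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise ValueError("cannot estimate a genotype from an empty cell set")
    alt = np.asarray(matrix.alt[:, cells].sum(axis=1)).ravel()
    tot = np.asarray(matrix.total[:, cells].sum(axis=1)).ravel()
    af = (alt + pseudocount) / (tot + 2.0 * pseudocount)
    return af, tot


def _log_profile(af: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.clip(af, AF_FLOOR, 1.0 - AF_FLOOR)
    return np.log(p), np.log1p(-p)


def _loglik_under(matrix: AlleleCountMatrix, af: np.ndarray) -> np.ndarray:
    """Per-cell binomial log-likelihood (combinatorial term omitted)."""
    logp, log1mp = _log_profile(af)
    ref = matrix.total - matrix.alt
    return np.asarray(matrix.alt.T @ logp + ref.T @ log1mp).ravel()


def genotype_score(
    matrix: AlleleCountMatrix, dominant_af: np.ndarray
) -> np.ndarray:
    """Mean per-read binomial log-likelihood under the dominant genotype.

    Depth-normalized: the sum of per-site binomial log-likelihoods is
    divided by the cell's total read count, so deep and shallow cells are
    comparable. Cells with zero reads get NaN (undefined; such cells are
    routed to unassigned downstream). Higher (closer to 0) means more
    consistent with the dominant genotype; the minimum attainable value
    is log(AF_FLOOR) per read.
    """
    ll = _loglik_under(matrix, dominant_af)
    reads = matrix.reads_per_cell().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(reads > 0, ll / np.maximum(reads, 1), np.nan)


def stage2_rescue(
    matrix: AlleleCountMatrix,
    dominant_af: np.ndarray,
    config: DemuxConfig,
    eligible: np.ndarray | None = None,
) -> np.ndarray | None:
    """Find a rare second genotype by genotype-score outlier detection.

    Cells scoring below ``median - mad_k * MAD`` (MAD scaled by 1.4826)
    are flagged; the flagged set is accepted as a second genotype only if
    its pooled allele-fraction profile differs from the dominant one by a
    mean |delta mAF| above ``separation_floor`` over the sites it covers.
    Returns flagged cell indices into ``matrix`` columns, or ``None``.
    """
    if eligible is None:
        eligible = select_eligible_cells(matrix, config)
    sub = matrix.subset_cells(eligible)
    scores = genotype_score(sub, dominant_af)
    ok = np.isfinite(scores)
    med = float(np.median(scores[ok]))
    mad = 1.4826 * float(np.median(np.abs(scores[ok] - med)))
    if mad == 0.0:
        return None
    flagged_local = np.flatnonzero(ok & (scores < med - config.mad_k * mad))
    if flagged_local.size == 0:
        return None

    flagged = eligible[flagged_local]
    f_alt = np.asarray(matrix.alt[:, flagged].sum(axis=1)).ravel()
    f_tot = np.asarray(matrix.total[:, flagged].sum(axis=1)).ravel()
    informative = f_tot > 0
    if not informative.any():
        return None
    delta = np.abs(f_alt[informative] / f_tot[informative] - dominant_af[informative])
    if float(delta.mean()) < config.separation_floor:
        return None
    return flagged


def simulate_doublet_profiles(
    matrix: AlleleCountMatrix,
    gt1_cells: np.ndarray,
    gt2_cells: np.ndarray,
    n: int,
    seed: int,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Synthetic doublets: count sums of random GT1 x GT2 cell pairs.

    Returns (alt, total) sparse matrices of shape (n_sites, n); column j
    is the elementwise sum of one uniformly drawn GT1 cell and one
    uniformly drawn GT2 cell. Used to calibrate the doublet acceptance
    region of :func:`classify_cells`.
    """
    if n <= 0:
        raise ValueError("number of synthetic doublets must be positive")
    if len(gt1_cells) == 0 or len(gt2_cells) == 0:
        raise ValueError("both genotype groups must be non-empty")
    rng = np.random.default_rng(seed)
    i1 = rng.choice(np.asarray(gt1_cells), size=n, replace=True)
    i2 = rng.choice(np.asarray(gt2_cells), size=n, replace=True)
    alt = sp.csr_matrix(matrix.alt[:, i1] + matrix.alt[:, i2])
    tot = sp.csr_matrix(matrix.total[:, i1] + matrix.total[:, i2])
    return alt, tot


def _doublet_calibration_threshold(
    matrix: AlleleCountMatrix,
    model: GenotypeModel,
    gt1_cells: np.ndarray,
    gt2_cells: np.ndarray,
    config: DemuxConfig,
    seed: int,
) -> float:
    """5th percentile of per-read doublet log-likelihood over synthetic doublets."""
    n = max(20, int(round(config.doublet_sim_multiplier * matrix.n_cells)))
    alt, tot = simulate_doublet_profiles(matrix, gt1_cells, gt2_cells, n, seed)
    logp, log1mp = _log_profile(model.af_doublet)
    ll = np.asarray(alt.T @ logp + (tot - alt).T @ log1mp).ravel()
    reads = np.asarray(tot.sum(axis=0)).ravel().astype(float)
    per_read = np.where(reads > 0, ll / np.maximum(reads, 1), np.nan)
    per_read = per_read[np.isfinite(per_read)]
    if per_read.size == 0:
        return -np.inf
    return float(np.percentile(per_read, 5.0))


def classify_cells(
    matrix: AlleleCountMatrix,
    model: GenotypeModel,
    config: DemuxConfig,
    doublet_threshold: float = -np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign every cell to GT1 / GT2 / doublet / unassigned.

    Each cell's alt counts are scored under the three clamped binomial
    profiles; the label is the arg-max, downgraded to unassigned when the
    top-vs-runner-up margin is below ``assign_margin`` nats or the cell
    covers no site. A doublet call additionally requires the cell's
    per-read doublet log-likelihood to clear the synthetic-doublet
    calibration threshold; otherwise the cell falls back to the better
    singlet profile (margin re-checked between the two singlets).

    Returns (labels, loglik matrix of shape (n_cells, 3)).
    """
    ll = np.column_stack(
        [
            _loglik_under(matrix, model.af_gt1),
            _loglik_under(matrix, model.af_gt2),
            _loglik_under(matrix, model.af_doublet),
        ]
    )
    n_cov = matrix.sites_covered_per_cell()
    reads = matrix.reads_per_cell().astype(float)
    labels = np.full(matrix.n_cells, "unassigned", dtype=object)

    order = np.argsort(ll, axis=1)
    best = order[:, -1]
    margin = ll[np.arange(len(best)), best] - ll[np.arange(len(best)), order[:, -2]]

    singlet_best = np.where(ll[:, 0] >= ll[:, 1], 0, 1)
    singlet_margin = np.abs(ll[:, 0] - ll[:, 1])

    with np.errstate(invalid="ignore", divide="ignore"):
        per_read_doublet = np.where(reads > 0, ll[:, 2] / np.maximum(reads, 1), -np.inf)

    for c in range(matrix.n_cells):
        if n_cov[c] == 0:
            continue
        b = best[c]
        if b == 2 and per_read_doublet[c] < doublet_threshold:
            # doublet profile wins but the cell is less doublet-like than
            # 95% of true (synthetic) doublets: fall back to singlets
            b = singlet_best[c]
            if singlet_margin[c] >= config.assign_margin:
                labels[c] = LABELS[b]
            continue
        if margin[c] >= config.assign_margin:
            labels[c] = LABELS[b]
    return labels, ll


def _total_loglik(ll: np.ndarray) -> float:
    """Hard-assignment data log-likelihood: each cell under its best profile."""
    return float(ll.max(axis=1).sum())


def refine(
    matrix: AlleleCountMatrix,
    gt1_cells: np.ndarray,
    gt2_cells: np.ndarray,
    config: DemuxConfig,
    eligible: np.ndarray | None = None,
) -> tuple[AssignmentResult | None, list[float]]:
    """Alternate genotype estimation and cell classification to a fixed point.

    Genotype profiles are estimated from the current GT1/GT2 singlet
    assignments (eligible cells only); all cells are then re-classified,
    with synthetic doublets re-simulated each iteration to calibrate the
    doublet acceptance region. Stops when the label vector is unchanged or
    ``max_iter`` is reached. Returns (result, per-iteration total
    log-likelihood trace); result is ``None`` if a genotype group empties
    (caller falls back to the single-genotype path).
    """
    if eligible is None:
        eligible = select_eligible_cells(matrix, config)
    elig_mask = np.zeros(matrix.n_cells, dtype=bool)
    elig_mask[eligible] = True

    gt1, gt2 = np.asarray(gt1_cells), np.asarray(gt2_cells)
    labels_prev: np.ndarray | None = None
    seen_states: dict[bytes, int] = {}
    history: list[tuple[np.ndarray, np.ndarray, float]] = []
    ll_trace: list[float] = []
    converged = False
    n_iter = 0
    labels = None
    ll = None

    for n_iter in range(1, config.max_iter + 1):
        if gt1.size == 0 or gt2.size == 0:
            log.warning("a genotype group emptied during refinement")
            return None, ll_trace
        af1, sup1 = estimate_genotype(matrix, gt1, config.pseudocount)
        af2, sup2 = estimate_genotype(matrix, gt2, config.pseudocount)
        model = GenotypeModel(af1, sup1, af2, sup2,
                              n_cells_gt1=gt1.size, n_cells_gt2=gt2.size)
        # fixed calibration seed: the synthetic-parent draw must not jitter
        # between iterations or the label fixed point can never be reached
        thr = _doublet_calibration_threshold(
            matrix, model, gt1, gt2, config, seed=config.seed
        )
        labels, ll = classify_cells(matrix, model, config, doublet_threshold=thr)
        ll_trace.append(_total_loglik(ll))
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            converged = True
            break
        state = "|".join(labels).encode()
        if state in seen_states:
            # limit cycle (a few borderline cells flipping between states):
            # keep the cycle state with the best total log-likelihood and
            # stop; not a fixed point, so converged stays False
            first = seen_states[state]
            cycle = history[first - 1 : n_iter]
            labels, ll, _ = max(cycle, key=lambda h: h[2])
            log.info("label cycle of period %d detected at iteration %d",
                     n_iter - first, n_iter)
            break
        seen_states[state] = n_iter
        history.append((labels, ll, ll_trace[-1]))
        labels_prev = labels
        gt1 = np.flatnonzero((labels == "GT1") & elig_mask)
        gt2 = np.flatnonzero((labels == "GT2") & elig_mask)

    gt1 = np.flatnonzero((labels == "GT1") & elig_mask)
    gt2 = np.flatnonzero((labels == "GT2") & elig_mask)
    if gt1.size == 0 or gt2.size == 0:
        log.warning("a genotype group emptied during refinement")
        return None, ll_trace

    dominant = gt1 if gt1.size >= gt2.size else gt2
    dom_af, _ = estimate_genotype(matrix, dominant, config.pseudocount)
    result = AssignmentResult(
        barcodes=list(matrix.barcodes),
        labels=labels,
        loglik_gt1=ll[:, 0],
        loglik_gt2=ll[:, 1],
        loglik_doublet=ll[:, 2],
        n_informative_sites=matrix.sites_covered_per_cell(),
        genotype_score=genotype_score(matrix, dom_af),
        second_genotype_found=True,
        n_iterations=n_iter,
        converged=converged,
    )
    return result, ll_trace


def _single_genotype_result(
    matrix: AlleleCountMatrix, config: DemuxConfig, eligible: np.ndarray
) -> AssignmentResult:
    af, sup = estimate_genotype(matrix, eligible, config.pseudocount)
    ll1 = _loglik_under(matrix, af)
    n_cov = matrix.sites_covered_per_cell()
    labels = np.where(n_cov > 0, "GT1", "unassigned").astype(object)
    nan = np.full(matrix.n_cells, np.nan)
    return AssignmentResult(
        barcodes=list(matrix.barcodes),
        labels=labels,
        loglik_gt1=ll1,
        loglik_gt2=nan,
        loglik_doublet=nan,
        n_informative_sites=n_cov,
        genotype_score=genotype_score(matrix, af),
        second_genotype_found=False,
        n_iterations=0,
        converged=True,
    )


def demultiplex(matrix: AlleleCountMatrix, config: DemuxConfig | None = None) -> AssignmentResult:
    """Run the full two-stage pipeline on a (filtered) allele-count matrix.

    Stage-1 clustering; if it finds a single genotype, stage-2 MAD rescue;
    if both fail, a single-genotype result (all covered cells GT1,
    ``second_genotype_found=False``). Otherwise the two-group seed is
    refined iteratively with doublet simulation. Deterministic given
    ``config.seed``.
    """
    config = config or DemuxConfig()
    if matrix.n_cells < 2 or matrix.n_sites == 0:
        raise ValueError("demultiplexing requires a non-empty filtered matrix")
    eligible = select_eligible_cells(matrix, config)

    groups = stage1_discover(matrix, config)
    if groups is None:
        dom_af, _ = estimate_genotype(matrix, eligible, config.pseudocount)
        minor = stage2_rescue(matrix, dom_af, config, eligible=eligible)
        if minor is None:
            return _single_genotype_result(matrix, config, eligible)
        major = np.setdiff1d(eligible, minor)
        groups = (major, minor)

    result, _ = refine(matrix, groups[0], groups[1], config, eligible=eligible)
    if result is None:
        return _single_genotype_result(matrix, config, eligible)
    return result
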