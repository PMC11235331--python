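"""Select genotype-predictive SNVs and build dot-plot validation tables.

After demultiplexing, a compact panel of SNVs that (a) discriminate the
two genotypes and (b) jointly cover every cell at least N times lets the
assignments be validated visually: plotted per (label group x SNV) with
dot size = fraction of the group's cells covered and dot color = mean
allele fraction, singlet groups show opposite homozygous fractions while
doublets sit in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demux import AssignmentResult
from .matrix import AlleleCountMatrix

__all__ = ["PredictiveSet", "rank_snvs", "greedy_cover", "dotplot_table", "plot_dotplot"]


@dataclass
class PredictiveSet:
    """Greedy cover outcome: selected site ids in selection order."""

    site_ids: list[int]
    coverage_per_cell: np.ndarray
    feasible: bool
    deficit_cells: list[int]


def _group_stats(matrix: AlleleCountMatrix, cells: np.ndarray):
    """Per-site (coverage breadth, mean mAF over covered cells) for a group."""
    sub_alt = matrix.alt[:, cells]
    sub_tot = matrix.total[:, cells]
    n_cov = np.asarray((sub_tot > 0).sum(axis=1)).ravel()
    af = sub_alt.multiply(sub_tot.power(-1.0))
    af_sum = np.asarray(af.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_af = np.where(n_cov > 0, af_sum / np.maximum(n_cov, 1), np.nan)
    breadth = n_cov / max(len(cells), 1)
    return breadth, mean_af


def rank_snvs(matrix: AlleleCountMatrix, assignment: AssignmentResult) -> pd.DataFrame:
    """Score every site's power to discriminate the two genotypes.

    predictiveness = |mean_af(GT1) - mean_af(GT2)| x min(breadth(GT1),
    breadth(GT2)) where breadth is the fraction of the group's cells with
    coverage; sites uncovered in a group score 0. Sorted descending,
    ties broken by (chrom, pos) ascending.
    """
    if not assignment.second_genotype_found:
        raise ValueError("nothing to contrast: only one genotype was assigned")
    labels = np.asarray(assignment.labels)
    gt1 = np.flatnonzero(labels == "GT1")
    gt2 = np.flatnonzero(labels == "GT2")
    if gt1.size == 0 or gt2.size == 0:
        raise ValueError("nothing to contrast: a genotype group is empty")

    b1, m1 = _group_stats(matrix, gt1)
    b2, m2 = _group_stats(matrix, gt2)
    with np.errstate(invalid="ignore"):
        delta = np.abs(m1 - m2)
    score = np.where(np.isnan(delta), 0.0, delta) * np.minimum(b1, b2)

    df = pd.DataFrame(
        {
            "site_id": [s.id for s in matrix.sites],
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "score": score,
            "mean_af_gt1": m1,
            "mean_af_gt2": m2,
            "breadth_gt1": b1,
            "breadth_gt2": b2,
        }
    )
    return df.sort_values(
        ["score", "chrom", "pos"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def greedy_cover(
    ranked: pd.DataFrame, matrix: AlleleCountMatrix, n_cover: int = 5
) -> PredictiveSet:
    """Greedy pick of scored sites until every cell is covered N times.

    At each step the site with the largest score-weighted gain (score x
    number of still-deficient cells it covers) is added; coverage is
    presence-based (a selected site covers a cell once if the cell has
    any read there). Stops when all cells reach ``n_cover`` or no
    remaining site helps; infeasible cells are reported. Deterministic:
    ties fall to the earlier-ranked site.
    """
    if n_cover <= 0:
        raise ValueError("n_cover must be positive")
    covered = (matrix.total > 0).astype(np.int8).toarray()  # sites x cells
    n_cells = matrix.n_cells
    achieved = np.zeros(n_cells, dtype=int)

    order = ranked["site_id"].to_numpy()
    scores = ranked["score"].to_numpy()
    remaining = list(range(len(order)))
    selected: list[int] = []

    while remaining and (achieved < n_cover).any():
        deficient = achieved < n_cover
        best_gain, best_pos = 0.0, None
        for pos in remaining:
            sid = order[pos]
            gain = scores[pos] * int(covered[sid, deficient].sum())
            if gain > best_gain:
                best_gain, best_pos = gain, pos
        if best_pos is None:
            break
        sid = int(order[best_pos])
        selected.append(sid)
        achieved += covered[sid]
        remaining.remove(best_pos)

    feasible = bool((achieved >= n_cover).all())
    deficit = [] if feasible else np.flatnonzero(achieved < n_cover).tolist()
    return PredictiveSet(
        site_ids=selected,
        coverage_per_cell=achieved,
        feasible=feasible,
        deficit_cells=deficit,
    )


def dotplot_table(
    matrix: AlleleCountMatrix,
    assignment: AssignmentResult,
    pset: PredictiveSet,
    cell_types: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (label group [x cell type] x selected SNV) dot-plot statistics.

    ``cell_fraction`` is the proportion of the group's cells with
    coverage at the SNV; ``mean_af`` the mean allele fraction over those
    covered cells (NaN when the group has no coverage there).
    """
    if not pset.site_ids:
        raise ValueError("predictive set is empty")
    labels = np.asarray(assignment.labels)
    if cell_types is not None:
        cell_types = np.asarray(cell_types)
        group_keys = [
            (lab, ct) for lab in np.unique(labels) for ct in np.unique(cell_types)
        ]
    else:
        group_keys = [(lab, None) for lab in np.unique(labels)]

    rows = []
    for lab, ct in group_keys:
        members = labels == lab
        if ct is not None:
            members &= cell_types == ct
        cells = np.flatnonzero(members)
        if cells.size == 0:
            continue
        sub = matrix.subset_cells(cells)
        for sid in pset.site_ids:
            tot = np.asarray(sub.total[sid].todense()).ravel()
            alt = np.asarray(sub.alt[sid].todense()).ravel()
            cov = tot > 0
            frac = float(cov.mean())
            mean_af = float((alt[cov] / tot[cov]).mean()) if cov.any() else np.nan
            site = matrix.sites[sid]
            row = {
                "group": lab,
                "snv": site.name,
                "chrom": site.chrom,
                "pos": site.pos,
                "cell_fraction": frac,
                "mean_af": mean_af,
            }
            if ct is not None:
                row["cell_type"] = ct
            rows.append(row)
    return pd.DataFrame(rows)


def plot_dotplot(table: pd.DataFrame, out_path: str) -> None:
    """Render the dot-plot table: dot size = cell fraction, color = mean mAF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(table["group"]))
    snvs = list(dict.fromkeys(table["snv"]))
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(snvs)), max(2.5, 0.5 * len(groups) + 1.5))
    )
    for _, r in table.iterrows():
        x, y = snvs.index(r["snv"]), groups.index(r["group"])
        if r["cell_fraction"] > 0:
            ax.scatter(
                x, y, s=20 + 380 * r["cell_fraction"], c=[r["mean_af"]],
                cmap="coolwarm", vmin=0, vmax=1, edgecolors="k", linewidths=0.3,
            )
    ax.set_xticks(range(len(snvs)), snvs, rotation=90, fontsize=7)
    ax.set_yticks(range(len(groups)), groups)
    ax.set_xlim(-0.5, len(snvs) - 0.5)
    ax.set_ylim(-0.5, len(groups) - 0.5)
    sm = plt.cm.ScalarMappable(cmap="coolwarm", norm=plt.Normalize(0, 1))
    fig.colorbar(sm, ax=ax, label="mean allele fraction")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
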