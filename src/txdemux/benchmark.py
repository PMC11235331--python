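"""Score demultiplexing output against simulation ground truth.

Genotype labels are arbitrary up to a GT1/GT2 permutation, so predictions
are first matched to truth by the permutation maximizing singlet
agreement. Per-class one-vs-rest TPR (TP / (TP + FN)) and FDR
(FP / (TP + FP)) follow, with unassigned predictions counted as false
negatives for the true class and never as false positives. The adjusted
Rand index compares whole partitions. The grid report aggregates per
(replicate, minor count, ambient rate, class) and stratifies by
minor count > 100 versus <= 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionSummary",
    "match_labels",
    "tpr_fdr",
    "ari",
    "grid_report",
    "run_grid_benchmark",
]

_SINGLET = ("GT1", "GT2")


@dataclass
class ConfusionSummary:
    """One-vs-rest confusion for a single class after label matching."""

    cls: str
    tp: int
    fp: int
    fn: int
    label_mapping: dict[str, str]

    @property
    def tpr(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def fdr(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else float("nan")


def match_labels(predicted: np.ndarray, truth: np.ndarray) -> dict[str, str]:
    """GT1/GT2 permutation of predictions maximizing singlet agreement.

    Doublet and unassigned labels are never permuted; a tie keeps the
    identity mapping.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth label vectors differ in length")
    identity = {"GT1": "GT1", "GT2": "GT2"}
    swapped = {"GT1": "GT2", "GT2": "GT1"}
    agree_id = int(np.sum((predicted == truth) & np.isin(truth, _SINGLET)))
    pred_sw = np.asarray([swapped.get(p, p) for p in predicted], dtype=object)
    agree_sw = int(np.sum((pred_sw == truth) & np.isin(truth, _SINGLET)))
    return swapped if agree_sw > agree_id else identity


def apply_mapping(predicted: np.ndarray, mapping: dict[str, str]) -> np.ndarray:
    return np.asarray([mapping.get(p, p) for p in predicted], dtype=object)


def tpr_fdr(
    predicted: np.ndarray,
    truth: np.ndarray,
    cls: str,
    mapping: dict[str, str] | None = None,
) -> ConfusionSummary:
    """One-vs-rest confusion for ``cls`` in {GT1, GT2, doublet}.

    Unassigned predictions are false negatives for the cell's true class
    and never false positives for any class; if ``cls`` is absent from
    truth, TPR is NaN.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if mapping is None:
        mapping = match_labels(predicted, truth)
    pred = apply_mapping(predicted, mapping)

    is_true = truth == cls
    is_pred = pred == cls
    tp = int(np.sum(is_true & is_pred))
    fp = int(np.sum(~is_true & is_pred))
    fn = int(np.sum(is_true & ~is_pred))  # includes unassigned predictions
    return ConfusionSummary(cls=cls, tp=tp, fp=fp, fn=fn, label_mapping=mapping)


def ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two partitions of the same barcodes."""
    from sklearn.metrics import adjusted_rand_score

    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must cover the same barcode set")
    return float(adjusted_rand_score(labels_a, labels_b))


def sample_metrics(
    predicted: np.ndarray, truth: np.ndarray, provenance: dict
) -> pd.DataFrame:
    """Per-class TPR/FDR rows for one demultiplexed sample."""
    mapping = match_labels(predicted, truth)
    rows = []
    for cls in ("GT1", "GT2", "doublet"):
        c = tpr_fdr(predicted, truth, cls, mapping=mapping)
        rows.append(
            {
                "replicate": provenance.get("replicate"),
                "minor_count": provenance.get("minor_count"),
                "ambient_rate": provenance.get("ambient_rate"),
                "class": cls,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "tpr": c.tpr,
                "fdr": c.fdr,
            }
        )
    return pd.DataFrame(rows)


def grid_report(
    results: list[tuple[np.ndarray, np.ndarray, dict]],
) -> tuple[pd.DataFrame, dict]:
    """Score a whole grid of (predicted, truth, provenance) triples.

    Returns the per-(grid cell x class) metric table plus aggregate
    singlet TPR/FDR means +- sample SD stratified by minor count > 100
    versus <= 100 (doublet rows aggregated separately).
    """
    if not results:
        raise ValueError("no demultiplexed samples to report on")
    table = pd.concat(
        [sample_metrics(p, t, prov) for p, t, prov in results], ignore_index=True
    )
    return table, _aggregate(table)


def _aggregate(table: pd.DataFrame) -> dict:
    def _agg(df: pd.DataFrame, metric: str) -> dict:
        vals = df[metric].dropna()
        return {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
        }

    singlets = table[table["class"].isin(_SINGLET)]
    doublets = table[table["class"] == "doublet"]
    high = singlets[singlets["minor_count"] > 100]
    low = singlets[singlets["minor_count"] <= 100]
    return {
        "singlet_minor_gt_100": {
            "tpr": _agg(high, "tpr"),
            "fdr": _agg(high, "fdr"),
        },
        "singlet_minor_le_100": {
            "tpr": _agg(low, "tpr"),
            "fdr": _agg(low, "fdr"),
        },
        "doublet": {"tpr": _agg(doublets, "tpr"), "fdr": _agg(doublets, "fdr")},
    }


def run_grid_benchmark(sim_config, demux_config=None, progress: bool = False):
    """Simulate a mixing grid, demultiplex every sample, and score it.

    Returns the per-(grid cell x class) metric table and the stratified
    aggregate dict of :func:`grid_report`. The demultiplexer seed defaults
    to the simulation seed.
    """
    from .demux import DemuxConfig, demultiplex
    from .simulate import simulate_grid

    if demux_config is None:
        demux_config = DemuxConfig(seed=sim_config.seed)
    results = []
    for sample in simulate_grid(sim_config):
        res = demultiplex(sample.matrix, demux_config)
        results.append((res.labels, sample.truth, sample.provenance))
        if progress:
            p = sample.provenance
            print(
                f"  rep={p['replicate']} minor={p['minor_count']} "
                f"ambient={p['ambient_rate']:.1f} -> {res.counts()}",
                flush=True,
            )
    return grid_report(results)
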