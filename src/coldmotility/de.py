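"""Differential-expression threshold rules, summaries and display matrices.

Consumes a per-gene statistics table (gene_id, log2fc, pvalue[, padj]) of the
DESeq2 output schema.  Genes are classified against the joint rule
|log2FC| >= 1 (inclusive) and BH-adjusted p < 0.05 (strict); "detected genes"
means the rows of the input table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DESummary",
    "bh_adjust",
    "classify_genes",
    "summarize_de",
    "zscore_rows",
    "volcano_coordinates",
]


@dataclass
class DESummary:
    """Counts and one-decimal percentages of up/down-classified genes."""

    n_detected: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_genes(
    table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Label each gene up / down / ns against the joint DE rule.

    Returns a copy of the table with ``padj`` (computed by BH from ``pvalue``
    if absent) and ``label`` columns.  ``up`` iff log2fc >= +lfc_min and
    padj < fdr_max; ``down`` iff log2fc <= -lfc_min and padj < fdr_max.
    Genes with missing log2fc are labeled ns with a warning.
    """
    out = table.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    lfc = out["log2fc"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lfc)):
        warnings.warn(
            f"{int(np.sum(~np.isfinite(lfc)))} genes have missing log2fc; labeled ns",
            RuntimeWarning,
            stacklevel=2,
        )
    sig = out["padj"].to_numpy() < fdr_max
    with np.errstate(invalid="ignore"):
        up = sig & (lfc >= lfc_min)
        down = sig & (lfc <= -lfc_min)
    out["label"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def summarize_de(table: pd.DataFrame) -> DESummary:
    """Counts and one-decimal percentages over the detected (= listed) genes."""
    if "label" not in table.columns:
        table = classify_genes(table)
    n = len(table)
    if n == 0:
        raise ValueError("cannot summarize an empty DE table")
    n_up = int((table["label"] == "up").sum())
    n_down = int((table["label"] == "down").sum())
    return DESummary(
        n_detected=n,
        n_up=n_up,
        n_down=n_down,
        pct_up=round(100.0 * n_up / n, 1),
        pct_down=round(100.0 * n_down / n, 1),
    )


def zscore_rows(matrix, clamp: float = 2.0, ddof: int = 1):
    """Row-wise Z-scoring with clamping, for heatmap display.

    Each row (gene) is centered by its mean and scaled by its sample SD
    (denominator n - ddof), then clamped to [-clamp, +clamp].  Constant rows
    become all zeros with a warning.  Accepts and returns a DataFrame or
    ndarray (genes x samples).
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples per row")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant rows z-scored to zeros", RuntimeWarning, stacklevel=2
        )
    sd = np.where(sd == 0, 1.0, sd)
    Z = np.clip((X - mu) / sd, -clamp, clamp)
    Z[flat] = 0.0
    if is_df:
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z


def volcano_coordinates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene volcano coordinates (log2fc, -log10 padj, label).

    Zero adjusted p-values are floored at one tenth of the smallest nonzero
    padj so coordinates stay finite; floored genes are flagged.
    """
    classified = table if "label" in table.columns else classify_genes(table)
    padj = classified["padj"].to_numpy(dtype=float)
    floored = padj == 0
    if floored.any():
        nonzero = padj[padj > 0]
        floor = nonzero.min() / 10.0 if nonzero.size else np.finfo(float).tiny
        padj = np.where(floored, floor, padj)
    return pd.DataFrame(
        {
            "gene_id": classified["gene_id"],
            "log2fc": classified["log2fc"],
            "neg_log10_padj": -np.log10(padj),
            "label": classified["label"],
            "padj_floored": floored,
        }
    )
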