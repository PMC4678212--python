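"""Ratio statistics and the fold-change / significance filter cascade.

Per gene the pipeline computes log2 AZ/NAZ ratios at each time point
(tissue specificity), log2 time/0 h ratios per tissue (temporal change),
and a Welch two-sample t p-value on log2 replicate values for every
time-vs-0 contrast.  Genes are then classified with strict inequalities:
changed (>8-fold, |log2| > 3 at any time), AZ-specific (AZ/NAZ log2 > 3 at
any time), and significant_changed (changed up with p < 0.015 on a
contrast that itself exceeds the fold threshold).

Column naming in the flat differential table:

- ``log2_AZspec_t{T}``   — log2(first tissue / second tissue) at time T
- ``log2_{tissue}_t{T}v0`` — log2(time T / time 0) within a tissue
- ``p_{tissue}_t{T}v0``  — Welch-t p-value for the same contrast
- ``log2_{A}v{B}`` / ``p_{A}v{B}`` — the single genotype contrast in
  two-genotype (read-count) mode
- flags: expressed, changed_up, changed_down, az_specific,
  significant_changed
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import condition_means, floor_frame
from .types import (
    AzfluxError,
    ExpressionMatrix,
    SampleDesign,
    ThresholdConfig,
    condition_label,
)

__all__ = [
    "log2_ratio",
    "reverse_contrast",
    "test_contrast",
    "compute_differential",
    "classify_genes",
    "transcriptome_share",
    "FLAG_COLUMNS",
]

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ("expressed", "changed_up", "changed_down", "az_specific", "significant_changed")

_T0_RE = re.compile(r"^log2_(?P<tissue>.+)_t(?P<time>[0-9.]+)v0$")
_AZSPEC_RE = re.compile(r"^log2_AZspec_t(?P<time>[0-9.]+)$")
_GENO_RE = re.compile(r"^log2_(?P<num>[^_]+)v(?P<den>[^_]+)$")

_TINY_P = 1e-300


def log2_ratio(means: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """log2(mean_num / mean_den) per gene; antisymmetric in its conditions."""
    for cond in (numerator, denominator):
        if cond not in means.columns:
            raise AzfluxError(f"unknown condition {cond!r}")
    num = means[numerator].to_numpy(dtype=float)
    den = means[denominator].to_numpy(dtype=float)
    if (num <= 0).any() or (den <= 0).any():
        raise AzfluxError("log2_ratio requires positive (floored) means")
    return pd.Series(np.log2(num / den), index=means.index)


def reverse_contrast(table):
    """Negate log2 fold changes, flipping the contrast orientation.

    Used to re-orient the mutant contrast to WT/mutant.  On a DataFrame
    only ``log2_*`` columns (or, failing that, all numeric columns) are
    negated; a Series or array is negated wholesale.  Involution.
    """
    if isinstance(table, pd.DataFrame):
        out = table.copy()
        log2_cols = [c for c in out.columns if str(c).startswith("log2_")]
        if not log2_cols:
            log2_cols = out.select_dtypes("number").columns.tolist()
        out[log2_cols] = -out[log2_cols]
        return out
    return -table


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t p-values along axis 1; degenerate -> 1."""
    if a.shape[1] < 2 or b.shape[1] < 2:
        logger.warning(
            "fewer than 2 replicates in a condition (%d vs %d): p set to 1",
            a.shape[1],
            b.shape[1],
        )
        return np.ones(a.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    # zero-variance/equal-mean groups yield nan: no evidence of difference
    p[np.isnan(p)] = 1.0
    return np.clip(p, _TINY_P, 1.0)


def test_contrast(a, b) -> float:
    """Welch two-sample t on log2-transformed replicate values.

    Returns a two-sided p in (0, 1]; with fewer than 2 replicates in
    either condition the contrast is untestable and p = 1 is returned
    (with a warning logged).
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise AzfluxError("empty condition in test_contrast")
    if (a <= 0).any() or (b <= 0).any():
        raise AzfluxError("test_contrast requires positive (floored) values")
    return float(_welch_p(np.log2(a)[None, :], np.log2(b)[None, :])[0])


def t0_ratio_columns(diff: pd.DataFrame) -> list[str]:
    """Time-vs-0 log2 ratio columns (plus the genotype contrast if present)."""
    cols = [c for c in diff.columns if _T0_RE.match(str(c))]
    cols += [c for c in diff.columns if _GENO_RE.match(str(c)) and not _AZSPEC_RE.match(str(c))]
    return cols


def azspec_columns(diff: pd.DataFrame) -> list[str]:
    return [c for c in diff.columns if _AZSPEC_RE.match(str(c))]


def _p_column(ratio_col: str) -> str:
    return "p_" + str(ratio_col)[len("log2_"):]


def compute_differential(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    expressed: pd.Index,
    floor: float,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Build and classify the per-gene differential table.

    ``matrix`` holds the analysis-scale values (RPKM, signal, or reads);
    values and condition means are floored at ``floor`` before any ratio
    or log transform.  Only genes in ``expressed`` are analysed.
    """
    thresholds = thresholds if thresholds is not None else ThresholdConfig()
    expressed = pd.Index(expressed)
    sub = matrix.with_values(matrix.values.loc[matrix.genes.intersection(expressed)])
    floored_values = sub.values.clip(lower=floor).astype(float)
    floored = sub.with_values(floored_values)
    means = floor_frame(condition_means(floored, design), floor)

    diff = pd.DataFrame(index=floored.genes)
    genotypes = design.genotypes
    times = design.timepoints
    tissues = design.tissues

    if len(genotypes) == 2 and len(times) == 1:
        g_num, g_den = genotypes
        tissue = tissues[0]
        t0 = times[0]
        diff[f"log2_{g_num}v{g_den}"] = log2_ratio(
            means, condition_label(tissue, t0, g_num), condition_label(tissue, t0, g_den)
        )
        a = np.log2(floored_values[design.samples_for(tissue, t0, g_num)].to_numpy())
        b = np.log2(floored_values[design.samples_for(tissue, t0, g_den)].to_numpy())
        diff[f"p_{g_num}v{g_den}"] = _welch_p(a, b)
    else:
        genotype = genotypes[0]
        if len(tissues) >= 2:
            az, naz = tissues[0], tissues[1]
            for t in times:
                diff[f"log2_AZspec_t{t:g}"] = log2_ratio(
                    means, condition_label(az, t, genotype), condition_label(naz, t, genotype)
                )
        for tissue in tissues:
            base = condition_label(tissue, times[0], genotype)
            base_reps = np.log2(
                floored_values[design.samples_for(tissue, times[0], genotype)].to_numpy()
            )
            for t in times[1:]:
                diff[f"log2_{tissue}_t{t:g}v0"] = log2_ratio(
                    means, condition_label(tissue, t, genotype), base
                )
                reps = np.log2(
                    floored_values[design.samples_for(tissue, t, genotype)].to_numpy()
                )
                diff[f"p_{tissue}_t{t:g}v0"] = _welch_p(reps, base_reps)

    diff["expressed"] = True
    return classify_genes(diff, thresholds)


def classify_genes(diff: pd.DataFrame, thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Apply the strict-inequality filter cascade and set the flag columns.

    changed_up: log2(t/0) > fold_log2 at some contrast; changed_down:
    < -fold_log2 (when a gene qualifies both ways the larger magnitude
    wins; an exact tie sets neither and is logged).  az_specific:
    log2(AZ/NAZ) > az_specific_log2 at some time.  significant_changed:
    changed_up and p < pvalue_max on a contrast whose log2 exceeds
    fold_log2.
    """
    thresholds = thresholds if thresholds is not None else ThresholdConfig()
    out = diff.copy()
    ratio_cols = t0_ratio_columns(out)
    if not ratio_cols:
        raise AzfluxError("differential table has no time/0 or genotype ratio columns")
    ratios = out[ratio_cols].to_numpy(dtype=float)
    mx = ratios.max(axis=1)
    mn = ratios.min(axis=1)

    up = mx > thresholds.fold_log2
    down = mn < -thresholds.fold_log2
    both = up & down
    if both.any():
        tie = both & (np.abs(mx) == np.abs(mn))
        if tie.any():
            logger.info(
                "%d genes with exactly tied up/down magnitudes: neither flag set", int(tie.sum())
            )
        up = up & ~both | (both & (np.abs(mx) > np.abs(mn)))
        down = down & ~both | (both & (np.abs(mn) > np.abs(mx)))
    out["changed_up"] = up
    out["changed_down"] = down

    az_cols = azspec_columns(out)
    if az_cols:
        out["az_specific"] = (
            out[az_cols].to_numpy(dtype=float).max(axis=1) > thresholds.az_specific_log2
        )
    else:
        out["az_specific"] = False

    sig = np.zeros(len(out), dtype=bool)
    for col in ratio_cols:
        p_col = _p_column(col)
        if p_col not in out.columns:
            continue
        sig |= (out[col].to_numpy(dtype=float) > thresholds.fold_log2) & (
            out[p_col].to_numpy(dtype=float) < thresholds.pvalue_max
        )
    out["significant_changed"] = out["changed_up"].to_numpy() & sig
    if "expressed" not in out.columns:
        out["expressed"] = True
    return out


def transcriptome_share(matrix: ExpressionMatrix, gene_set, sample: str) -> float:
    """A gene set's summed signal as percent of the sample's total.

    The denominator is the sum over *all* genes in the matrix (which, in
    the pipeline, is the expressed set); result in [0, 100].
    """
    if sample not in matrix.samples:
        raise AzfluxError(f"unknown sample {sample!r}")
    gene_set = pd.Index(gene_set)
    stray = gene_set.difference(matrix.genes)
    if len(stray):
        raise AzfluxError(f"gene {stray[0]!r} not in matrix")
    total = float(matrix.values[sample].sum())
    if total == 0:
        raise AzfluxError(f"zero total expression in sample {sample!r}")
    part = float(matrix.values.loc[gene_set, sample].sum())
    return 100.0 * part / total
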