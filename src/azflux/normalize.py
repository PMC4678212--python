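"""Scale conversion, expression gating and floor substitution.

The analysis unit throughout is the replicate mean per condition.  A gene
is "expressed" when that mean clears a platform-specific threshold in at
least one condition (tissue x time, or genotype); the gate is evaluated on
the *unfloored* values, and only afterwards are sub-floor values replaced
by the floor so that ratios never see a zero in numerator or denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    AzfluxError,
    ConfigurationError,
    ExpressionMatrix,
    GateProfile,
    SampleDesign,
    condition_label,
)

__all__ = ["compute_rpkm", "condition_means", "apply_gate", "apply_floor"]

logger = logging.getLogger(__name__)


def compute_rpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Reads Per Kilobase of transcript per Million mapped reads.

    RPKM(g, s) = counts(g, s) * 1e9 / (length_bp(g) * library_size(s)),
    where the library size is the column sum of the count matrix.

    Parameters
    ----------
    counts
        Matrix with ``value_kind='counts'``.
    lengths
        Transcript length in bp, indexed by gene id; must cover every gene.
    """
    if counts.value_kind != "counts":
        raise ConfigurationError(
            f"RPKM requires raw counts, got value_kind={counts.value_kind!r}"
        )
    missing = counts.genes.difference(lengths.index)
    if len(missing):
        raise AzfluxError(f"missing transcript length for gene {missing[0]!r}")
    lens = lengths.reindex(counts.genes).astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise AzfluxError(f"non-positive transcript length for gene {bad!r}")
    lib = counts.values.sum(axis=0).astype(float)
    zero = lib.index[lib == 0]
    if len(zero):
        raise AzfluxError(f"zero library size in sample {zero[0]!r}")
    rpkm = counts.values.astype(float).mul(1.0e9).div(lib, axis=1).div(lens, axis=0)
    return ExpressionMatrix(rpkm, "rpkm")


def condition_means(matrix: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Arithmetic mean over replicates for every (tissue, time, genotype).

    Returns a gene-by-condition DataFrame whose columns are canonical
    condition labels in design order.
    """
    not_in_design = matrix.samples.difference(design.sample_ids)
    if len(not_in_design):
        raise AzfluxError(f"sample {not_in_design[0]!r} absent from the design table")
    cols = {}
    for tissue, time_h, genotype in design.conditions():
        samples = design.samples_for(tissue, time_h, genotype)
        samples = [s for s in samples if s in matrix.samples]
        if not samples:
            continue
        cols[condition_label(tissue, time_h, genotype)] = (
            matrix.values[samples].astype(float).mean(axis=1)
        )
    return pd.DataFrame(cols)


def apply_gate(
    matrix: ExpressionMatrix, design: SampleDesign, profile: GateProfile
) -> pd.Index:
    """Expressed-gene set under a platform gate.

    A gene passes iff its replicate-mean value in at least one condition
    satisfies the profile's threshold (strict or non-strict).  Evaluated on
    the values as given — gate before floor.
    """
    if matrix.value_kind != profile.value_kind:
        raise ConfigurationError(
            f"gate profile {profile.name!r} expects value_kind "
            f"{profile.value_kind!r}, matrix has {matrix.value_kind!r}"
        )
    means = condition_means(matrix, design)
    best = means.max(axis=1)
    if profile.threshold_is_strict:
        passed = best > profile.expression_threshold
    else:
        passed = best >= profile.expression_threshold
    expressed = matrix.genes[passed.reindex(matrix.genes).to_numpy()]
    logger.info(
        "gate %s: %d of %d genes expressed", profile.name, len(expressed), len(matrix.genes)
    )
    return expressed


def apply_floor(matrix: ExpressionMatrix, floor: float) -> ExpressionMatrix:
    """Replace every value below ``floor`` with ``floor`` (idempotent, monotone)."""
    if floor <= 0:
        raise ConfigurationError("floor must be positive")
    return matrix.with_values(matrix.values.clip(lower=floor).astype(float))


def floor_frame(frame: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Floor substitution on a bare DataFrame (e.g. condition means)."""
    if floor <= 0:
        raise ConfigurationError("floor must be positive")
    return frame.clip(lower=floor)
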