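"""Shared data containers for the abscission-transcriptome pipeline.

Everything tabular is backed by pandas; the thin wrapper classes exist to
carry the bits of metadata (value kind, platform profile) that a bare
DataFrame cannot, and to validate the invariants every downstream stage
assumes (no missing values, unique ids, non-negative expression).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AzfluxError",
    "ConfigurationError",
    "ExpressionMatrix",
    "SampleDesign",
    "GateProfile",
    "GATE_PROFILES",
    "ThresholdConfig",
    "condition_label",
    "VALUE_KINDS",
]

VALUE_KINDS = ("counts", "rpkm", "signal")


class AzfluxError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AzfluxError):
    """Invalid configuration (bad fractions, unknown profile, bad paths...)."""


def condition_label(tissue: str, time_h: float, genotype: str = "WT") -> str:
    """Canonical string key for a (tissue, time, genotype) condition.

    Time is formatted with %g so 12.0 and 12 produce the same label.
    """
    return f"{tissue}.t{time_h:g}.{genotype}"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values plus a marker for what they are.

    ``values`` has gene ids as the index and sample ids as columns;
    ``value_kind`` is one of 'counts' (raw reads), 'rpkm' or 'signal'
    (microarray intensities).
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ConfigurationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise AzfluxError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise AzfluxError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise AzfluxError("expression values must be numeric")
        if np.isnan(arr).any():
            raise AzfluxError("expression matrix contains missing values")
        if (arr < 0).any():
            raise AzfluxError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, value_kind: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, value_kind or self.value_kind)


@dataclass
class SampleDesign:
    """Per-sample metadata: tissue, time (h), replicate index, genotype.

    The (tissue, time_h, genotype) triple defines a *condition*, the unit
    over which replicate means are taken.
    """

    table: pd.DataFrame  # columns: sample_id, tissue, time_h, replicate, genotype

    REQUIRED = ("sample_id", "tissue", "time_h", "replicate", "genotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise AzfluxError(f"design table missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise AzfluxError("duplicate sample ids in design")
        dup = t.duplicated(subset=["tissue", "time_h", "genotype", "replicate"])
        if dup.any():
            raise AzfluxError("replicate indices not unique within a condition")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def conditions(self) -> list[tuple[str, float, str]]:
        """Distinct (tissue, time_h, genotype) triples in stable design order."""
        seen: dict[tuple[str, float, str], None] = {}
        for _, row in self.table.iterrows():
            seen[(row["tissue"], float(row["time_h"]), row["genotype"])] = None
        return list(seen)

    def samples_for(self, tissue: str, time_h: float, genotype: str) -> list[str]:
        t = self.table
        m = (
            (t["tissue"] == tissue)
            & (t["time_h"].astype(float) == float(time_h))
            & (t["genotype"] == genotype)
        )
        return t.loc[m, "sample_id"].tolist()

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.table["tissue"]))

    @property
    def timepoints(self) -> list[float]:
        return sorted({float(t) for t in self.table["time_h"]})

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))


@dataclass(frozen=True)
class GateProfile:
    """Platform-specific rule deciding which genes count as expressed.

    A gene passes if the replicate-mean value in at least one condition
    satisfies the threshold; ``threshold_is_strict`` selects > versus >=.
    ``floor`` is the substitution value applied afterwards so ratios never
    see a zero.
    """

    name: str
    value_kind: str
    expression_threshold: float
    threshold_is_strict: bool
    floor: float

    def __post_init__(self) -> None:
        if not self.floor < self.expression_threshold:
            raise ConfigurationError(
                f"floor ({self.floor}) must be below the expression threshold "
                f"({self.expression_threshold})"
            )
        if self.floor <= 0:
            raise ConfigurationError("floor must be positive")

    def passes(self, mean_value: float) -> bool:
        if self.threshold_is_strict:
            return mean_value > self.expression_threshold
        return mean_value >= self.expression_threshold


#: Built-in gate profiles. Soybean RNA-seq gates on mean RPKM >= 1.0
#: (non-strict) with a 0.1 floor; the tomato microarray and Arabidopsis
#: read-count profiles gate strictly at >10 with a 1.0 floor.
GATE_PROFILES: dict[str, GateProfile] = {
    "soybean_rnaseq": GateProfile("soybean_rnaseq", "rpkm", 1.0, False, 0.1),
    "tomato_microarray": GateProfile("tomato_microarray", "signal", 10.0, True, 1.0),
    "arabidopsis_readcount": GateProfile("arabidopsis_readcount", "counts", 10.0, True, 1.0),
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs for the fold-change / significance filter cascade.

    Defaults encode the >8-fold (|log2| > 3) change rule, the p < 0.015
    significance filter, and the >8-fold AZ/NAZ specificity rule, all with
    strict inequalities.
    """

    fold_log2: float = 3.0
    pvalue_max: float = 0.015
    az_specific_log2: float = 3.0
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.fold_log2 > 0:
            raise ConfigurationError("fold_log2 must be > 0")
        if not 0 < self.pvalue_max < 1:
            raise ConfigurationError("pvalue_max must be in (0, 1)")
        if not self.az_specific_log2 > 0:
            raise ConfigurationError("az_specific_log2 must be > 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
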