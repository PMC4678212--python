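"""Synthetic two-tissue time-course expression experiments with planted effects.

Emulates the structure of the three abscission datasets the pipeline is
built for: an RNA-seq leaf-abscission time course (two tissues, AZ and
NAZ, sampled over ~72 h with replicates), a microarray flower-abscission
time course, and a two-genotype (WT vs non-abscising mutant) read-count
contrast.  Genes are planted in one of four classes — AZ-specifically
up-regulated, commonly up-regulated, commonly down-regulated, or unchanged
— and the ground truth is returned alongside the data so every downstream
stage (gating, ratios, tests, classification) can be scored for recovery.

Count model: negative binomial around a log-normal baseline abundance,
with per-sample library sizes drawn (not constant) so depth normalization
is genuinely exercised.  Microarray signals use multiplicative log-normal
noise.  Effects multiply the mean as a step beginning at ``onset_time_h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import ConfigurationError, ExpressionMatrix, SampleDesign

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "generate_experiment",
    "write_truth",
    "EFFECT_CLASSES",
    "DESCRIPTION_POOL",
]

EFFECT_CLASSES = ("az_up", "shared_up", "shared_down", "null")

PLATFORMS = ("rnaseq", "microarray", "readcount")

#: Free-text descriptions sampled onto a fraction of genes so the
#: annotation-keyword category engine has realistic input end-to-end.
DESCRIPTION_POOL = (
    "endo-1,4-beta-glucanase (cellulase)",
    "glycoside hydrolase family 9 B2",
    "glycoside hydrolase 9A1 (KORRIGAN)",
    "polygalacturonase precursor",
    "pectin lyase-like superfamily protein",
    "alpha-expansin 1",
    "beta-expansin 3",
    "xyloglucan endotransglucosylase/hydrolase XTH9",
    "thaumatin-like pathogenesis-related protein",
    "basic chitinase class I",
    "beta-1,3-glucanase 2",
    "kunitz trypsin inhibitor 1",
    "photoassimilate-responsive protein PAR1",
    "GDSL esterase/lipase",
    "nonspecific lipid-transfer protein LTP1",
    "fatty acyl-CoA reductase CER4",
    "class III peroxidase",
    "laccase 4",
    "callose synthase 5",
    "extensin-like cell wall protein",
    "arabinogalactan protein AGP9",
    "hydroxyproline-rich glycoprotein family",
    "1-aminocyclopropane-1-carboxylate synthase ACS2",
    "1-aminocyclopropane-1-carboxylate oxidase ACO1",
    "auxin efflux carrier PIN3",
    "indole-3-acetic acid-amido synthetase GH3.6",
    "SAUR-like auxin-responsive protein",
    "AUX/IAA transcriptional regulator",
    "cellulose synthase A4",
    "unknown function DUF642 family",
)


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a synthetic experiment.

    Defaults mirror the soybean leaf time course: AZ vs NAZ tissue,
    sampling at 0/12/24/48/72 h of ethylene exposure, three biological
    replicates.  ``platform='readcount'`` switches to a two-genotype
    (WT vs mutant) contrast with no time axis.
    """

    n_genes: int
    tissues: tuple[str, ...] = ("AZ", "NAZ")
    timepoints_h: tuple[float, ...] | None = None
    n_replicates: int = 3
    platform: str = "rnaseq"
    genotypes: tuple[str, str] = ("WT", "mutant")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ConfigurationError(f"platform must be one of {PLATFORMS}")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.platform == "readcount":
            if self.timepoints_h not in (None, (0.0,), (0,)):
                raise ConfigurationError(
                    "readcount mode is a two-genotype contrast with no time axis"
                )
            if len(self.genotypes) != 2:
                raise ConfigurationError("readcount mode requires exactly two genotypes")
            object.__setattr__(self, "timepoints_h", (0.0,))
        else:
            tp = self.timepoints_h if self.timepoints_h is not None else (0.0, 12.0, 24.0, 48.0, 72.0)
            tp = tuple(float(t) for t in tp)
            if tp[0] != 0.0:
                raise ConfigurationError("first timepoint must be 0 h")
            if any(b <= a for a, b in zip(tp, tp[1:])):
                raise ConfigurationError("timepoints must be strictly increasing")
            if len(self.tissues) < 1:
                raise ConfigurationError("at least one tissue required")
            object.__setattr__(self, "timepoints_h", tp)


@dataclass(frozen=True)
class EffectSpec:
    """Statistical parameters of the planted effects and the noise model.

    ``class_fractions`` are proportions over the four effect classes and
    must sum to 1.  Planted |log2 fold| values are drawn uniformly from
    ``fold_range_log2``, whose lower bound must exceed 3 so non-null genes
    clear the >8-fold selection threshold by construction.  Baselines are
    log-normal on the platform's natural scale (RPKM, signal, or reads);
    ``near_gate_fraction`` of the null genes are drawn with baselines
    straddling the platform's expression-gate threshold.
    """

    class_fractions: dict = field(
        default_factory=lambda: {"az_up": 0.02, "shared_up": 0.03, "shared_down": 0.30, "null": 0.65}
    )
    fold_range_log2: tuple[float, float] = (3.5, 6.0)
    onset_time_h: float | None = None  # default: first non-zero timepoint
    baseline_log_mean: float | None = None  # default per platform, see _baseline_params
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    cv_noise: float = 0.25
    near_gate_fraction: float = 0.1
    library_size_mean: float = 4.0e6
    library_size_sdlog: float = 0.2
    annotated_fraction: float = 0.3

    def __post_init__(self) -> None:
        fr = self.class_fractions
        unknown = set(fr) - set(EFFECT_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown effect classes: {sorted(unknown)}")
        vals = [fr.get(c, 0.0) for c in EFFECT_CLASSES]
        if any(v < 0 for v in vals):
            raise ConfigurationError("class fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(f"class fractions must sum to 1, got {sum(vals)}")
        lo, hi = self.fold_range_log2
        if not lo > 3:
            raise ConfigurationError(
                "fold_range_log2 lower bound must exceed 3 (the selection threshold)"
            )
        if hi < lo:
            raise ConfigurationError("fold_range_log2 must be a non-empty interval")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.cv_noise < 0:
            raise ConfigurationError("cv_noise must be >= 0")
        if not 0 <= self.near_gate_fraction <= 1:
            raise ConfigurationError("near_gate_fraction must be in [0, 1]")


def _class_counts(fractions: dict, n: int) -> dict[str, int]:
    """Exact integer counts per class: floor then largest-remainder."""
    raw = {c: fractions.get(c, 0.0) * n for c in EFFECT_CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(EFFECT_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_frac[:short]:
        counts[c] += 1
    return counts


def _baseline_params(platform: str, effects: EffectSpec) -> tuple[float, float]:
    if effects.baseline_log_mean is not None:
        mu = effects.baseline_log_mean
    elif platform == "rnaseq":
        mu = math.log(5.0)  # median ~5 RPKM against a gate of 1.0
    else:
        mu = math.log(200.0)  # median ~200 signal/reads against a gate of 10
    return mu, effects.baseline_log_sd


def _gate_threshold(platform: str) -> float:
    return 1.0 if platform == "rnaseq" else 10.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion*mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_experiment(
    design: DesignSpec, effects: EffectSpec | None = None
) -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame, pd.DataFrame]:
    """Simulate one experiment.

    Returns ``(matrix, design_table, annotation, truth)`` where annotation
    has columns (gene_id, length_bp, description) and truth has
    (gene_id, class, true_log2_fold, length_bp).  Identical arguments and
    seed reproduce the matrix bit-for-bit.
    """
    effects = effects if effects is not None else EffectSpec()
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    gene_ids = np.array([f"G{str(i + 1).zfill(5)}" for i in range(n)])

    # classes: exact counts, randomly placed
    counts = _class_counts(effects.class_fractions, n)
    labels = np.concatenate([np.repeat(c, k) for c, k in counts.items()])
    labels = labels[rng.permutation(n)]

    # signed planted folds
    lo, hi = effects.fold_range_log2
    mag = rng.uniform(lo, hi, size=n)
    fold = np.zeros(n)
    fold[labels == "az_up"] = mag[labels == "az_up"]
    fold[labels == "shared_up"] = mag[labels == "shared_up"]
    fold[labels == "shared_down"] = -mag[labels == "shared_down"]

    # baselines, with a near-gate subpopulation among the nulls
    mu_log, sd_log = _baseline_params(design.platform, effects)
    baseline = rng.lognormal(mu_log, sd_log, size=n)
    null_idx = np.flatnonzero(labels == "null")
    n_near = int(round(effects.near_gate_fraction * null_idx.size))
    if n_near:
        near = rng.choice(null_idx, size=n_near, replace=False)
        gate = _gate_threshold(design.platform)
        baseline[near] = rng.lognormal(math.log(gate), 0.15, size=n_near)

    lengths = rng.integers(500, 5001, size=n)

    # annotation descriptions for the category engine
    descriptions = np.full(n, "hypothetical protein", dtype=object)
    n_annot = int(round(effects.annotated_fraction * n))
    if n_annot:
        which = rng.choice(n, size=n_annot, replace=False)
        descriptions[which] = rng.choice(DESCRIPTION_POOL, size=n_annot)

    onset = effects.onset_time_h
    if onset is None and design.platform != "readcount":
        onset = design.timepoints_h[1] if len(design.timepoints_h) > 1 else 0.0

    rows = []
    columns: dict[str, np.ndarray] = {}
    if design.platform == "readcount":
        for genotype in design.genotypes:
            for rep in range(1, design.n_replicates + 1):
                sid = f"{genotype}_r{rep}"
                rows.append((sid, "receptacle", 0.0, rep, genotype))
                # up-classes are elevated in WT (the abscising genotype)
                active = np.isin(labels, ("az_up", "shared_up", "shared_down"))
                eff = np.where(active & (genotype == design.genotypes[0]), fold, 0.0)
                depth = rng.lognormal(0.0, effects.library_size_sdlog)
                mean = baseline * np.exp2(eff) * depth
                columns[sid] = _nb_draw(rng, mean, effects.dispersion)
        value_kind = "counts"
    else:
        az_tissue = design.tissues[0]
        for tissue in design.tissues:
            for time_h in design.timepoints_h:
                for rep in range(1, design.n_replicates + 1):
                    sid = f"{tissue}_t{time_h:g}_r{rep}"
                    rows.append((sid, tissue, time_h, rep, "WT"))
                    on = time_h >= onset and time_h > 0
                    in_az = tissue == az_tissue
                    eff = np.where(
                        (labels == "az_up") & on & in_az, fold, 0.0
                    ) + np.where(np.isin(labels, ("shared_up", "shared_down")) & on, fold, 0.0)
                    expected = baseline * np.exp2(eff)
                    if design.platform == "rnaseq":
                        lib = rng.lognormal(
                            math.log(effects.library_size_mean), effects.library_size_sdlog
                        )
                        mean_counts = expected * lengths * lib / 1.0e9
                        columns[sid] = _nb_draw(rng, mean_counts, effects.dispersion)
                    else:  # microarray signal, multiplicative log-normal noise
                        if effects.cv_noise > 0:
                            sd = math.sqrt(math.log1p(effects.cv_noise**2))
                            noise = rng.lognormal(-sd * sd / 2.0, sd, size=n)
                        else:
                            noise = 1.0
                        columns[sid] = expected * noise
        value_kind = "counts" if design.platform == "rnaseq" else "signal"

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    if value_kind == "counts":
        values = values.astype(np.int64)
    matrix = ExpressionMatrix(values, value_kind)
    design_table = SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "tissue", "time_h", "replicate", "genotype"])
    )
    annotation = pd.DataFrame(
        {"gene_id": gene_ids, "length_bp": lengths, "description": descriptions}
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": labels,
            "true_log2_fold": fold,
            "length_bp": lengths,
        }
    )
    return matrix, design_table, annotation, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the planted-truth table as tab-delimited text (lossless round trip)."""
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")
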