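"""Tab-delimited readers/writers and the end-to-end pipeline orchestrator.

All artifacts are UTF-8 tab-delimited text with header rows.  Floats are
written in their shortest round-trip representation, so write-then-read
is lossless and identical runs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .categories import (
    assign_categories,
    category_profile,
    default_rules,
    load_rules,
    members_of,
)
from .differential import compute_differential
from .normalize import apply_floor, apply_gate, compute_rpkm
from .outputs import (
    build_heatmap_panel,
    build_timecourse_profile,
    build_volcano,
    render_heatmap,
    render_timecourse,
    render_volcano,
)
from .types import (
    AzfluxError,
    ConfigurationError,
    ExpressionMatrix,
    GATE_PROFILES,
    SampleDesign,
    ThresholdConfig,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "read_annotation",
    "write_annotation",
    "read_truth",
    "read_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ParseError(AzfluxError):
    """Malformed tabular input; the message names the offending line."""


def read_matrix(path, value_kind: str = "counts") -> ExpressionMatrix:
    """Parse a gene-by-sample matrix (first column gene id, header sample ids).

    Rejects ragged rows, non-numeric cells and duplicate gene/sample ids
    with the line number in the error message.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        samples = cols[1:]
        seen_samples = set()
        for s in samples:
            if s in seen_samples:
                raise ParseError(f"{path}:1: duplicate sample id {s!r}")
            seen_samples.add(s)
        gene_ids: list[str] = []
        seen_genes: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, found {len(parts)}"
                )
            gid = parts[0]
            if gid in seen_genes:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen_genes.add(gid)
            gene_ids.append(gid)
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    values = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    logger.info("read %s: %d genes x %d samples", path, *values.shape)
    return ExpressionMatrix(values, value_kind)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_design(design: SampleDesign, path) -> None:
    write_table(design.table, path)


def read_design(path) -> SampleDesign:
    return SampleDesign(read_table(path))


def write_annotation(annotation: pd.DataFrame, path) -> None:
    write_table(annotation, path)


def read_annotation(path) -> pd.DataFrame:
    # keep_default_na=False: empty descriptions stay "", not NaN
    return read_table(path, dtype={"gene_id": str}, keep_default_na=False)


def read_truth(path) -> pd.DataFrame:
    # the effect class "null" must not be parsed as missing
    df = read_table(path, dtype={"gene_id": str, "class": str}, keep_default_na=False)
    return df.astype({"true_log2_fold": float, "length_bp": int})


def read_diff(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


@dataclass
class PipelineConfig:
    """Everything one `azflux run` needs, loadable from YAML."""

    profile: str
    matrix: str
    design: str
    annotations: str
    out_dir: str
    rules: str | None = None
    matrix_kind: str | None = None  # default: what the profile expects as input
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    log_level: str = "INFO"
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.profile not in GATE_PROFILES:
            raise ConfigurationError(
                f"unknown profile {self.profile!r}; known: {sorted(GATE_PROFILES)}"
            )
        for name in ("matrix", "design", "annotations"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.rules is not None and not Path(self.rules).exists():
            raise ConfigurationError(f"rules path does not exist: {self.rules}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        thr = obj.pop("thresholds", None)
        cfg = cls(**obj)
        if thr:
            cfg.thresholds = ThresholdConfig(**thr)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.as_dict()
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage's name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, AzfluxError):
                raise AzfluxError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, AzfluxError) and not str(exc).startswith("stage"):
                raise AzfluxError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute normalize -> gate -> floor -> ratios/tests -> classify ->
    categories -> report, writing every table plus a run manifest.

    Returns the manifest dict.  Identical config and inputs produce
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = GATE_PROFILES[config.profile]

    with _stage("load"):
        expected_kind = "counts" if profile.value_kind in ("counts", "rpkm") else "signal"
        raw_kind = config.matrix_kind or expected_kind
        if raw_kind != expected_kind:
            raise ConfigurationError(
                f"profile {profile.name!r} expects a {expected_kind!r} matrix, "
                f"config declares {raw_kind!r}"
            )
        matrix = read_matrix(config.matrix, value_kind=raw_kind)
        design = read_design(config.design)
        annotation = read_annotation(config.annotations)
        rules = load_rules(config.rules) if config.rules else default_rules()

    with _stage("normalize"):
        if profile.value_kind == "rpkm":
            lengths = annotation.set_index("gene_id")["length_bp"]
            analysis = compute_rpkm(matrix, lengths)
        else:
            if matrix.value_kind != profile.value_kind:
                raise ConfigurationError(
                    f"profile {profile.name!r} expects {profile.value_kind!r} input"
                )
            analysis = matrix
        write_matrix(analysis, out / "analysis_matrix.tsv")

    with _stage("gate"):
        expressed = apply_gate(analysis, design, profile)
        pd.Series(expressed, name="gene_id").to_csv(out / "expressed_genes.tsv", sep="\t", index=False)

    with _stage("floor"):
        floored = apply_floor(analysis, profile.floor)
        expressed_floored = floored.with_values(floored.values.loc[expressed])
        write_matrix(expressed_floored, out / "floored_matrix.tsv")

    with _stage("differential"):
        diff = compute_differential(
            floored, design, expressed, profile.floor, config.thresholds
        )
        diff.rename_axis("gene_id").to_csv(out / "differential.tsv", sep="\t")

    with _stage("categories"):
        mapping = assign_categories(annotation, rules)
        mapping_rows = [
            (g, c) for g in sorted(mapping) for c in sorted(mapping[g])
        ]
        write_table(
            pd.DataFrame(mapping_rows, columns=["gene_id", "category"]),
            out / "category_mapping.tsv",
        )
        profile_res = category_profile(expressed_floored, mapping, design, rules)
        profile_res.percent.rename_axis("category").to_csv(out / "category_percent.tsv", sep="\t")
        profile_res.member_counts.rename_axis("category").rename("n_genes").to_csv(
            out / "category_counts.tsv", sep="\t"
        )
        write_table(profile_res.dominant, out / "category_dominant.tsv")

    with _stage("report"):
        is_contrast = len(design.genotypes) == 2 and len(design.timepoints) == 1
        panels = []
        categories_in_order = list(profile_res.percent.index)
        for cat in categories_in_order:
            members = [g for g in members_of(mapping, cat) if g in diff.index]
            panel = build_heatmap_panel(diff, members)
            if len(panel.table):
                block = panel.table.copy()
                block.insert(0, "category", cat)
                block = block.join(panel.markers)
                panels.append(block)
        if panels:
            pd.concat(panels).rename_axis("gene_id").to_csv(out / "heatmap_panels.tsv", sep="\t")
        if not is_contrast and len(design.tissues) >= 2:
            tc = build_timecourse_profile(profile_res, design, tuple(design.tissues[:2]))
            write_table(tc, out / "timecourse_profile.tsv")
            if config.make_figures:
                render_timecourse(tc, out / "timecourse_profile.svg")
        if is_contrast:
            volcano = build_volcano(diff, significance_p=config.thresholds.pvalue_max)
            volcano.table.rename_axis("gene_id").to_csv(out / "volcano.tsv", sep="\t")
            if config.make_figures:
                render_volcano(volcano, out / "volcano.svg")
        if config.make_figures and panels:
            first = categories_in_order[0]
            render_heatmap(
                build_heatmap_panel(diff, members_of(mapping, first)),
                out / "heatmap_first_category.svg",
                title=first,
            )

    manifest = {
        "azflux_version": __version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.echo(),
        "counts": {
            "n_genes": int(len(matrix.genes)),
            "n_expressed": int(len(expressed)),
            "n_changed_up": int(diff["changed_up"].sum()),
            "n_changed_down": int(diff["changed_down"].sum()),
            "n_az_specific": int(diff["az_specific"].sum()),
            "n_significant_changed": int(diff["significant_changed"].sum()),
            "n_categorized": int(len(mapping)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
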