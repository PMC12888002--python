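"""End-to-end orchestration of the differential proximitome analysis.

``run_all`` executes, for every configured bait-vs-reference comparison:
flag filtering -> log transform -> replicate-presence filter (restricted to
the two condition groups of that comparison) -> downshifted-Gaussian
imputation -> two-sample t test and significance classification ->
annotation overlay and category/compartment summaries.  Each comparison
uses a sub-seed derived by stable hashing of the comparison name from the
run seed, so adding a comparison never perturbs the others.  Everything is
deterministic given the seed; the manifest records per-stage row counts,
parameters and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_results, category_counts, compartment_distribution
from .diffstats import ThresholdSpec, adjust_p, compare
from .io_model import (
    AnnotationMap,
    Comparison,
    DesignSpec,
    ProteinGroupTable,
    read_annotation_map,
    read_design,
    read_protein_groups,
    write_table,
)
from .preprocess import (
    ImputationSpec,
    ValidityRule,
    filter_flagged,
    filter_min_valid,
    log_transform,
)


@dataclass
class RunConfig:
    """Fully resolved run configuration (see ``RunConfig.from_yaml``)."""

    protein_groups: Path
    design: Path
    out_dir: Path
    comparisons: list[Comparison]
    annotation_maps: list[tuple[Path, str]] = field(default_factory=list)
    dialect: str = "maxquant"
    seed: int = 0
    log_base: int = 10
    impute_width: float = 0.3
    impute_downshift: float = 1.9
    min_valid_mode: str = "any_group"
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    adjust: str = "none"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        thr = ThresholdSpec(**raw.get("thresholds", {}))
        pre = raw.get("preprocess", {})
        return cls(
            protein_groups=base / raw["protein_groups"],
            design=base / raw["design"],
            out_dir=base / raw.get("out_dir", "results"),
            comparisons=[
                Comparison(c["name"], c["a"], c["b"]) for c in raw["comparisons"]
            ],
            annotation_maps=[
                (base / m["path"], m["vocabulary"]) for m in raw.get("annotation_maps", [])
            ],
            dialect=raw.get("dialect", "maxquant"),
            seed=int(raw.get("seed", 0)),
            log_base=int(pre.get("log_base", 10)),
            impute_width=float(pre.get("width", 0.3)),
            impute_downshift=float(pre.get("downshift", 1.9)),
            min_valid_mode=pre.get("min_valid_mode", "any_group"),
            thresholds=thr,
            adjust=raw.get("adjust", "none"),
        )

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for p in [self.protein_groups, self.design, *(p for p, _ in self.annotation_maps)]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def comparison_seed(run_seed: int, comparison_name: str) -> int:
    """Stable per-comparison sub-seed (< 2^31)."""
    return (run_seed ^ zlib.crc32(comparison_name.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_comparison(
    table: ProteinGroupTable,
    design: DesignSpec,
    comparison: Comparison,
    *,
    seed: int,
    log_base: int = 10,
    impute_width: float = 0.3,
    impute_downshift: float = 1.9,
    min_valid_mode: str = "any_group",
    thresholds: ThresholdSpec | None = None,
    adjust: str = "none",
    maps: list[AnnotationMap] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Preprocess + test one comparison on an already flag-filtered table.

    The replicate-presence filter and imputation are restricted to the two
    condition groups of the comparison (pairwise Perseus-style analysis).
    Returns the (optionally annotated) result and a stage-count dict.
    """
    from .preprocess import impute_downshifted_gaussian  # local to keep import cycle-free

    thresholds = thresholds or ThresholdSpec()
    samples = design.samples_of(comparison.condition_a) + design.samples_of(comparison.condition_b)
    sub_design = DesignSpec(samples=design.samples.loc[samples].copy())

    matrix = log_transform(table, base=log_base)
    matrix.values = matrix.values[samples]
    matrix.imputed = matrix.imputed[samples]
    matrix, valid_counts = filter_min_valid(
        matrix, sub_design, ValidityRule(group_mode=min_valid_mode)
    )
    matrix = impute_downshifted_gaussian(
        matrix, ImputationSpec(width=impute_width, downshift=impute_downshift, seed=seed)
    )
    result = compare(matrix, sub_design, (comparison.condition_a, comparison.condition_b), thresholds)
    result = adjust_p(result, method=adjust)
    summary = result.attrs["summary"]
    if maps:
        key = table.meta["gene_names"].copy()
        fallback = table.meta.index.to_series().str.split(";").str[0]
        key = key.where(key.str.len() > 0, fallback).str.split(";").str[0]
        result = result.merge(
            key.rename("annotation_key"), left_on="protein", right_index=True, how="left"
        )
        result = annotate_results(result, maps, key_column="annotation_key")
    stage_counts = {
        "rows_in": len(table),
        "min_valid_kept": valid_counts["kept"],
        "min_valid_dropped": valid_counts["dropped"],
        "n_imputed_cells": int(matrix.imputed.to_numpy().sum()),
        **summary,
    }
    result.attrs["summary"] = summary
    return result, stage_counts


def run_all(config: RunConfig) -> dict:
    """Execute the full comparison battery and write all outputs.

    Writes per-comparison volcano TSVs, category-count and compartment
    summaries, and a ``manifest.json`` with per-stage counts, parameters and
    output checksums.  Returns the manifest dict.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = read_protein_groups(config.protein_groups, dialect=config.dialect)
    design = read_design(config.design)
    for cmp_ in config.comparisons:
        for cond in (cmp_.condition_a, cmp_.condition_b):
            if cond not in set(design.samples["condition"]):
                raise ValueError(f"comparison {cmp_.name!r}: unknown condition {cond!r}")
    maps = [read_annotation_map(p, vocab) for p, vocab in config.annotation_maps]

    filtered, flag_counts = filter_flagged(table)
    manifest: dict = {
        "software": f"proxitome {__version__}",
        "seed": config.seed,
        "started": datetime.now(timezone.utc).isoformat(),
        "parameters": {
            "log_base": config.log_base,
            "impute_width": config.impute_width,
            "impute_downshift": config.impute_downshift,
            "min_valid_mode": config.min_valid_mode,
            "p_max": config.thresholds.p_max,
            "min_log2_diff": config.thresholds.min_log2_diff,
            "s0": config.thresholds.s0,
            "difference_units": config.thresholds.difference_units,
            "adjust": config.adjust,
        },
        "flag_filter": flag_counts,
        "comparisons": {},
        "outputs": {},
    }

    for cmp_ in config.comparisons:
        try:
            result, counts = run_comparison(
                filtered,
                design,
                cmp_,
                seed=comparison_seed(config.seed, cmp_.name),
                log_base=config.log_base,
                impute_width=config.impute_width,
                impute_downshift=config.impute_downshift,
                min_valid_mode=config.min_valid_mode,
                thresholds=config.thresholds,
                adjust=config.adjust,
                maps=maps,
            )
        except Exception as exc:
            raise RuntimeError(f"comparison {cmp_.name!r} failed: {exc}") from exc
        volcano_path = out_dir / f"{cmp_.name}_volcano.tsv"
        write_table(result, volcano_path)
        manifest["comparisons"][cmp_.name] = counts
        manifest["outputs"][volcano_path.name] = _sha256(volcano_path)
        for amap in maps:
            cats = category_counts(result, amap.vocabulary_name)
            dist = compartment_distribution(result, amap.vocabulary_name)
            for suffix, frame in (("categories", cats), ("distribution", dist)):
                p = out_dir / f"{cmp_.name}_{amap.vocabulary_name}_{suffix}.tsv".replace(" ", "_")
                write_table(frame, p)
                manifest["outputs"][p.name] = _sha256(p)

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["parameters"], sort_keys=True).encode()
    ).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
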