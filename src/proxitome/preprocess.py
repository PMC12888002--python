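"""Filtering, log transformation and missing-value imputation.

The preprocessing chain mirrors standard Perseus practice for label-free
proximity-labeling data:

1. drop decoy (reverse), potential-contaminant and only-identified-by-site
   protein groups;
2. log-transform LFQ intensities (base 10 by default), mapping the MaxQuant
   0 = "not quantified" convention to an explicit missing value;
3. keep a protein only if it is quantified in at least two of three
   replicates of some condition group (for groups of n > 3 replicates, in
   at least ceil(0.75 * n));
4. impute the remaining missing values per sample column from a downshifted
   Gaussian: with observed column mean mu and SD sigma, draws come from
   Normal(mu - downshift * sigma, (width * sigma)^2).  Low-abundance
   proteins go missing preferentially (left-censoring), so imputing below
   the observed distribution reflects that the missing value was most
   likely small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import DesignSpec, ProteinGroupTable


@dataclass
class ImputationSpec:
    """Downshifted-Gaussian imputation parameters (Perseus defaults)."""

    width: float = 0.3
    downshift: float = 1.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass
class ValidityRule:
    """Replicate-presence rule: >= 2 of 3, or >= ceil(0.75 n) for n > 3."""

    min_valid_small: int = 2
    fraction_large: float = 0.75
    group_mode: str = "any_group"  # any_group | all_groups | whole_row

    def __post_init__(self) -> None:
        if not 0 < self.fraction_large <= 1:
            raise ValueError("fraction_large must be in (0, 1]")
        if self.group_mode not in ("any_group", "all_groups", "whole_row"):
            raise ValueError(f"unknown group_mode: {self.group_mode!r}")

    def required(self, n_replicates: int) -> int:
        """Minimum number of quantified replicates for a group of size n."""
        if n_replicates <= 3:
            return min(self.min_valid_small, n_replicates)
        return math.ceil(self.fraction_large * n_replicates)


@dataclass
class IntensityMatrix:
    """Log-scale intensity matrix with explicit missingness and provenance.

    ``values`` is proteins x samples with NaN for missing; ``imputed`` marks
    cells filled by imputation (everything else non-missing is observed).
    ``validity_filtered`` records that the replicate-presence filter ran, so
    the imputation step can enforce the pipeline order.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    log_base: int = 10
    validity_filtered: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != self.imputed.shape:
            raise ValueError("values and imputed mask must have the same shape")
        if self.log_base not in (10, 2):
            raise ValueError("log_base must be 10 or 2")
        if bool((self.imputed & self.values.isna()).to_numpy().any()):
            raise ValueError("imputed cells cannot be missing")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.imputed.copy(), self.log_base, self.validity_filtered
        )


def filter_flagged(
    table: ProteinGroupTable, remove_reverse: bool = True
) -> tuple[ProteinGroupTable, dict[str, int]]:
    """Drop contaminant / only-by-site (and by default reverse) groups.

    Returns the filtered table and per-category removal counts (a row
    flagged in several categories is counted in each).
    """
    meta = table.meta
    drop = meta["contaminant"] | meta["only_by_site"]
    if remove_reverse:
        drop = drop | meta["reverse"]
    counts = {
        "contaminant": int(meta["contaminant"].sum()),
        "only_by_site": int(meta["only_by_site"].sum()),
        "reverse": int(meta["reverse"].sum()) if remove_reverse else 0,
        "removed": int(drop.sum()),
        "kept": int((~drop).sum()),
    }
    return table.subset(meta.index[~drop]), counts


def log_transform(table: ProteinGroupTable, base: int = 10) -> IntensityMatrix:
    """Log-transform linear LFQ intensities; 0 becomes missing (NaN)."""
    if base not in (10, 2):
        raise ValueError("base must be 10 or 2")
    vals = table.intensities.to_numpy(dtype=float)
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError("negative intensity encountered")
    with np.errstate(divide="ignore"):
        logged = np.log10(vals) if base == 10 else np.log2(vals)
    logged[~np.isfinite(logged) & (vals == 0)] = np.nan
    values = pd.DataFrame(logged, index=table.intensities.index, columns=table.intensities.columns)
    imputed = pd.DataFrame(False, index=values.index, columns=values.columns)
    return IntensityMatrix(values=values, imputed=imputed, log_base=base)


def filter_min_valid(
    matrix: IntensityMatrix,
    design: DesignSpec,
    rule: ValidityRule | None = None,
) -> tuple[IntensityMatrix, dict[str, int]]:
    """Keep proteins quantified in enough replicates of a condition group.

    With ``group_mode="any_group"`` (default) a protein survives if the rule
    holds in at least one condition; ``all_groups`` requires every condition;
    ``whole_row`` applies the rule to all samples pooled.  ``any_group``
    preserves on/off candidates such as proteins entirely absent from an
    uninduced control.
    """
    rule = rule or ValidityRule()
    observed = matrix.values.notna()
    design_samples = [s for s in matrix.samples if s in design.samples.index]
    if not design_samples:
        raise ValueError("design covers none of the matrix samples")

    if rule.group_mode == "whole_row":
        n = len(design_samples)
        keep = observed[design_samples].sum(axis=1) >= rule.required(n)
    else:
        per_group = []
        for cond in design.conditions:
            samples = [s for s in design.samples_of(cond) if s in matrix.samples]
            if not samples:
                continue
            if len(samples) < 2:
                raise ValueError(f"condition {cond!r} has < 2 replicates in the matrix")
            ok = observed[samples].sum(axis=1) >= rule.required(len(samples))
            per_group.append(ok)
        stacked = pd.concat(per_group, axis=1)
        keep = stacked.any(axis=1) if rule.group_mode == "any_group" else stacked.all(axis=1)

    out = IntensityMatrix(
        values=matrix.values.loc[keep].copy(),
        imputed=matrix.imputed.loc[keep].copy(),
        log_base=matrix.log_base,
        validity_filtered=True,
    )
    counts = {"kept": int(keep.sum()), "dropped": int((~keep).sum())}
    return out, counts


def impute_downshifted_gaussian(
    matrix: IntensityMatrix,
    spec: ImputationSpec | None = None,
    allow_unfiltered: bool = False,
) -> IntensityMatrix:
    """Impute missing cells from a per-sample downshifted Gaussian.

    For each sample column with observed mean mu and sample SD sigma, every
    missing cell is replaced by an independent draw from
    Normal(mu - downshift * sigma, (width * sigma)^2).  Columns are processed
    in sample order and missing cells in protein order from a single seeded
    generator, so identical seeds give bitwise-identical matrices.

    Raises if the replicate-presence filter has not run (the downstream test
    assumes filtering precedes imputation) unless ``allow_unfiltered=True``.
    """
    spec = spec or ImputationSpec()
    if not matrix.validity_filtered and not allow_unfiltered:
        raise ValueError(
            "matrix has not passed filter_min_valid; imputation must follow the "
            "replicate-presence filter (pass allow_unfiltered=True to override)"
        )
    rng = np.random.default_rng(spec.seed)
    values = matrix.values.copy()
    imputed = matrix.imputed.copy()
    for sample in matrix.samples:
        col = values[sample].to_numpy(dtype=float)
        missing = np.isnan(col)
        observed = col[~missing]
        if observed.size < 2:
            raise ValueError(
                f"sample {sample!r} has {observed.size} observed value(s); "
                "cannot estimate an imputation distribution"
            )
        mu = float(observed.mean())
        sigma = float(observed.std(ddof=1))
        if missing.any():
            if sigma == 0:
                warnings.warn(
                    f"sample {sample!r} has zero observed SD; imputing the constant {mu}",
                    stacklevel=2,
                )
            draws = rng.normal(mu - spec.downshift * sigma, spec.width * sigma, missing.sum())
            col[missing] = draws
            values[sample] = col
            imp = imputed[sample].to_numpy().copy()
            imp[missing] = True
            imputed[sample] = imp
    return IntensityMatrix(
        values=values, imputed=imputed, log_base=matrix.log_base,
        validity_filtered=matrix.validity_filtered,
    )
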