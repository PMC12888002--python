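"""Annotation overlays, category counts and multi-set overlaps.

Comparison results are joined to annotation vocabularies (MitoCarta-style
compartments, GO-style function labels) on gene symbols (falling back to
the first accession), then summarised: per-label counts within each
significance class, per-label distributions of the difference column
(plot-ready boxplot tables), and UpSet-style intersection counts across
several protein lists.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from .io_model import AnnotationMap

_LABEL_SEP = ";"


def _round_half_up_percent(fraction: float) -> int:
    return int(math.floor(fraction * 100 + 0.5))


def _vocab_column(vocabulary_name: str) -> str:
    return "labels_" + "".join(c if c.isalnum() else "_" for c in vocabulary_name)


def annotate_results(
    result: pd.DataFrame,
    maps: list[AnnotationMap],
    key_column: str = "protein",
) -> pd.DataFrame:
    """Attach one semicolon-joined label column per vocabulary.

    Unmatched proteins keep an empty label set and are never dropped.  The
    returned frame's ``attrs["annotation_matches"]`` records how many rows
    matched each vocabulary.
    """
    out = result.copy()
    matches: dict[str, int] = {}
    for amap in maps:
        col = _vocab_column(amap.vocabulary_name)
        labels = [
            _LABEL_SEP.join(sorted(amap.labels_for(str(key))))
            for key in out[key_column]
        ]
        out[col] = labels
        matches[amap.vocabulary_name] = int(sum(1 for v in labels if v))
    out.attrs.update(result.attrs)
    out.attrs["annotation_matches"] = matches
    return out


def label_sets(annotated: pd.DataFrame, vocabulary_name: str) -> pd.Series:
    """Per-row label sets for one vocabulary (empty set when unannotated)."""
    col = _vocab_column(vocabulary_name)
    if col not in annotated.columns:
        raise KeyError(f"result has no annotation for vocabulary {vocabulary_name!r}")
    return annotated[col].map(lambda v: set(v.split(_LABEL_SEP)) if v else set())


def category_counts(
    annotated: pd.DataFrame,
    vocabulary_name: str,
    classes: set[str] | None = None,
) -> pd.DataFrame:
    """Count proteins per (label, significance class).

    ``fraction`` is count / class size; ``percent`` is the half-up-rounded
    integer percentage.  A protein with several labels counts once per label
    (multi-membership), so per-class fractions can sum above 1.
    """
    classes = classes or {"up", "down"}
    sets = label_sets(annotated, vocabulary_name)
    rows = []
    for cls in sorted(classes):
        mask = annotated["class"] == cls
        class_total = int(mask.sum())
        counts: dict[str, int] = {}
        for labels in sets[mask]:
            for label in labels:
                counts[label] = counts.get(label, 0) + 1
        for label in sorted(counts):
            frac = counts[label] / class_total if class_total else 0.0
            rows.append(
                {
                    "vocabulary": vocabulary_name,
                    "class": cls,
                    "label": label,
                    "count": counts[label],
                    "class_total": class_total,
                    "fraction": frac,
                    "percent": _round_half_up_percent(frac),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["vocabulary", "class", "label", "count", "class_total", "fraction", "percent"],
    )


def compartment_distribution(
    annotated: pd.DataFrame, vocabulary_name: str
) -> pd.DataFrame:
    """Boxplot-ready summary of the difference column per label.

    One row per label plus an ``all proteins`` row: n, median, quartiles,
    min/max.  Labels with no members are omitted.
    """
    sets = label_sets(annotated, vocabulary_name)
    all_labels = sorted(set().union(*sets) if len(sets) else set())
    groups = [("all proteins", np.ones(len(annotated), dtype=bool))]
    for label in all_labels:
        groups.append((label, sets.map(lambda s: label in s).to_numpy()))
    rows = []
    diffs = annotated["difference"].to_numpy(dtype=float)
    for label, mask in groups:
        vals = diffs[mask]
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "label": label,
                "n": int(vals.size),
                "min": float(vals.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows, columns=["label", "n", "min", "q1", "median", "q3", "max"])


def overlap_sets(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """UpSet-style intersection counts for two or more protein sets.

    Emits exclusive-region counts (each element counted exactly once, in the
    region of the sets it belongs to), plus plain pairwise intersections and
    the full intersection.  Exclusive counts sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = list(named_sets)
    union: set[str] = set().union(*named_sets.values())
    rows = []
    membership: dict[frozenset, int] = {}
    for item in union:
        key = frozenset(n for n in names if item in named_sets[n])
        membership[key] = membership.get(key, 0) + 1
    for key in sorted(membership, key=lambda k: (-len(k), "&".join(sorted(k)))):
        rows.append(
            {
                "region": "&".join(sorted(key)),
                "kind": "exclusive",
                "degree": len(key),
                "count": membership[key],
            }
        )
    for a, b in combinations(names, 2):
        rows.append(
            {
                "region": f"{a}&{b}",
                "kind": "pairwise",
                "degree": 2,
                "count": len(named_sets[a] & named_sets[b]),
            }
        )
    full = set.intersection(*named_sets.values())
    rows.append({"region": "&".join(names), "kind": "full", "degree": len(names), "count": len(full)})
    rows.append({"region": "union", "kind": "union", "degree": len(names), "count": len(union)})
    return pd.DataFrame(rows, columns=["region", "kind", "degree", "count"])
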