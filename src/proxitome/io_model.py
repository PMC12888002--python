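"""Readers, writers and the shared data model.

The pipeline starts from a protein-group quantification table in the
MaxQuant ``proteinGroups.txt`` dialect (tab-separated, one ``LFQ intensity
<sample>`` column per sample, ``+``-flag columns for reverse hits,
potential contaminants and only-identified-by-site groups).  Annotation
vocabularies (MitoCarta-style compartments, GO-style function labels)
arrive as two-column TSV files.  Predicted complexes arrive as PDB/mmCIF
coordinates plus a predicted-aligned-error (PAE) matrix in the AlphaFold
server JSON dialect.

An LFQ intensity of 0 in a MaxQuant table means "not quantified"; readers
store the 0 verbatim and the preprocessing stage converts it to an explicit
missing value, so the raw file stays faithfully representable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

LFQ_PREFIX = "LFQ intensity "

_MAXQUANT_FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}


@dataclass
class ProteinGroupTable:
    """Parsed protein-group quantification table.

    Attributes
    ----------
    meta:
        One row per protein group, indexed by ``group_id`` (semicolon-joined
        accessions allowed), with columns ``gene_names`` (string, may be
        empty), ``reverse``, ``contaminant``, ``only_by_site`` (bool).
    intensities:
        Linear-scale LFQ intensities, same index as ``meta``, one column per
        sample.  0 encodes "not quantified".
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensities must share the same protein index")
        if self.meta.index.has_duplicates:
            dupes = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein group ids: {dupes[:5]}")
        vals = self.intensities.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("LFQ intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def group_ids(self) -> list[str]:
        return list(self.meta.index)

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, keep: pd.Index | list[str]) -> "ProteinGroupTable":
        return ProteinGroupTable(self.meta.loc[keep].copy(), self.intensities.loc[keep].copy())


@dataclass(frozen=True)
class Comparison:
    name: str
    condition_a: str
    condition_b: str


@dataclass
class DesignSpec:
    """Sample -> condition/replicate mapping plus the comparison battery.

    ``samples`` maps each sample id to ``(condition, replicate_index)``;
    each condition needs at least two replicates for a two-sample test.
    """

    samples: pd.DataFrame  # index sample_id; columns condition, replicate
    comparisons: list[Comparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"condition", "replicate"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        pairs = list(zip(self.samples["condition"], self.samples["replicate"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("(condition, replicate) pairs must be unique")
        counts = self.samples["condition"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"conditions with < 2 replicates: {list(small.index)}")
        known = set(self.samples["condition"])
        for cmp_ in self.comparisons:
            for cond in (cmp_.condition_a, cmp_.condition_b):
                if cond not in known:
                    raise ValueError(f"comparison {cmp_.name!r} references unknown condition {cond!r}")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        if len(sel) == 0:
            raise KeyError(f"unknown condition: {condition!r}")
        return list(sel)


def read_design(path: str | Path) -> DesignSpec:
    """Read a design TSV with columns sample, condition, replicate
    and optional comparison rows in a companion sense (comparisons are
    usually supplied in the run config instead)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    df = df.set_index("sample")
    df["replicate"] = df["replicate"].astype(int)
    return DesignSpec(samples=df)


@dataclass
class AnnotationMap:
    """Protein key -> set of labels for one vocabulary (e.g. MitoCarta3.0)."""

    vocabulary_name: str
    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [k for k, v in self.entries.items() if not v]
        if empty:
            raise ValueError(f"empty label sets for keys: {empty[:5]}")

    def labels_for(self, key: str) -> set[str]:
        return set(self.entries.get(key, set()))

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Protein-group tables


def read_protein_groups(path: str | Path, dialect: str = "maxquant") -> ProteinGroupTable:
    """Read a protein-group quantification table.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    dialect:
        ``"maxquant"`` expects ``Protein IDs``, ``Gene names``, the three
        ``+``-flag columns and ``LFQ intensity <sample>`` columns.
        ``"generic"`` expects ``protein_id`` plus optional ``gene_names`` /
        flag columns; every remaining column is a sample intensity.
    """
    if dialect not in ("maxquant", "generic"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if dialect == "maxquant":
        id_col = "Protein IDs" if "Protein IDs" in df.columns else "Majority protein IDs"
        if id_col not in df.columns:
            raise ValueError("no protein id column ('Protein IDs') found")
        gene_col = "Gene names"
        lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
        if not lfq_cols:
            raise ValueError(f"no '{LFQ_PREFIX}<sample>' columns found")
        sample_ids = [c[len(LFQ_PREFIX):] for c in lfq_cols]
        flags = {}
        for name, col in _MAXQUANT_FLAG_COLUMNS.items():
            if col in df.columns:
                flags[name] = df[col].str.strip() == "+"
            else:
                flags[name] = pd.Series(False, index=df.index)
        genes = df[gene_col] if gene_col in df.columns else pd.Series("", index=df.index)
        meta = pd.DataFrame({"gene_names": genes, **flags})
        meta.index = pd.Index(df[id_col], name="group_id")
        inten = df[lfq_cols].copy()
        inten.columns = sample_ids
    else:
        if "protein_id" not in df.columns:
            raise ValueError("generic dialect needs a 'protein_id' column")
        reserved = {"protein_id", "gene_names", "reverse", "contaminant", "only_by_site"}
        sample_ids = [c for c in df.columns if c not in reserved]
        if not sample_ids:
            raise ValueError("no intensity columns found")
        flags = {}
        for name in ("reverse", "contaminant", "only_by_site"):
            if name in df.columns:
                flags[name] = df[name].str.strip().isin(["+", "True", "true", "1"])
            else:
                flags[name] = pd.Series(False, index=df.index)
        genes = df["gene_names"] if "gene_names" in df.columns else pd.Series("", index=df.index)
        meta = pd.DataFrame({"gene_names": genes, **flags})
        meta.index = pd.Index(df["protein_id"], name="group_id")
        inten = df[sample_ids].copy()

    parsed = {}
    for col in inten.columns:
        raw = inten[col].str.strip().replace({"": "0", "NA": "0", "NaN": "0"})
        try:
            parsed[col] = raw.astype(float).to_numpy()
        except ValueError:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna()]
            pos, val = bad.index[0], bad.iloc[0]
            group = meta.index[df.index.get_loc(pos)]
            raise ValueError(
                f"non-numeric intensity {val!r} in column {col!r}, protein group {group!r}"
            ) from None
    inten = pd.DataFrame(parsed, index=meta.index)
    return ProteinGroupTable(meta=meta, intensities=inten)


def write_protein_groups(table: ProteinGroupTable, path: str | Path) -> None:
    """Write a ProteinGroupTable back to the MaxQuant dialect (lossless)."""
    out = pd.DataFrame({"Protein IDs": table.meta.index, "Gene names": table.meta["gene_names"].values})
    for name, col in _MAXQUANT_FLAG_COLUMNS.items():
        out[col] = np.where(table.meta[name].values, "+", "")
    for sample in table.sample_ids:
        out[LFQ_PREFIX + sample] = table.intensities[sample].values
    out.to_csv(path, sep="\t", index=False)


def write_table(result, path: str | Path) -> None:
    """Write any tabular result as TSV with ``NA`` for missing values.

    ProteinGroupTable instances round-trip through :func:`read_protein_groups`;
    plain DataFrames (e.g. comparison results) round-trip through
    ``pd.read_csv(..., sep="\\t")``.
    """
    if isinstance(result, ProteinGroupTable):
        write_protein_groups(result, path)
        return
    if not isinstance(result, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    result.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Annotation maps


def read_annotation_map(path: str | Path, vocabulary_name: str) -> AnnotationMap:
    """Read a two-column (key <tab> label) file; repeated keys aggregate."""
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            key, label = parts[0].strip(), parts[1].strip()
            entries.setdefault(key, set()).add(label)
    if not entries:
        warnings.warn(f"annotation file {path} is empty", stacklevel=2)
    return AnnotationMap(vocabulary_name=vocabulary_name, entries=entries)


# ---------------------------------------------------------------------------
# Structures and PAE matrices


@dataclass(frozen=True)
class Residue:
    author_seq_id: int
    name: str
    # atoms: (atom_name, element, x, y, z); heavy atoms only
    atoms: tuple[tuple[str, str, float, float, float], ...]

    def coords(self) -> np.ndarray:
        return np.array([[a[2], a[3], a[4]] for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Heavy-atom model of a (predicted) complex, author residue numbering."""

    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            seen = set()
            for res in residues:
                if res.author_seq_id in seen:
                    raise ValueError(f"duplicate residue {res.author_seq_id} in chain {cid}")
                seen.add(res.author_seq_id)
                if not res.atoms:
                    raise ValueError(f"residue {cid}/{res.author_seq_id} has no heavy atoms")
                for a in res.atoms:
                    if not all(np.isfinite(a[2:5])):
                        raise ValueError(f"non-finite coordinate in {cid}/{res.author_seq_id}")

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residue_order(self) -> list[tuple[str, int]]:
        """Flattened (chain_id, author_seq_id) order, chain by chain as in file."""
        return [(cid, res.author_seq_id) for cid, residues in self.chains.items() for res in residues]


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a heavy-atom StructureModel.

    Hydrogens and HETATM records (waters, ligands) are excluded; chain ids
    and author residue numbers are preserved from the file.
    """
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.remove_hydrogens()
    if len(st) == 0:
        raise ValueError(f"structure {path} contains no models")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.het_flag == "H":  # heteroatoms excluded from contact analysis
                continue
            atoms = tuple(
                (atom.name, atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z)
                for atom in res
                if not atom.is_hydrogen()
            )
            if atoms:
                residues.append(Residue(res.seqid.num, res.name, atoms))
        if residues:
            chains[chain.name] = residues
    if len(chains) < 2:
        raise ValueError(
            f"structure {path} has {len(chains)} polymer chain(s); interface analysis needs two chains"
        )
    return StructureModel(chains=chains)


@dataclass
class PAEMatrix:
    """Predicted aligned error, Å.  Row i / column j is the error of residue
    j's position when the model is aligned on residue i; the matrix need not
    be symmetric and is never symmetrized."""

    values: np.ndarray
    index_map: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"PAE matrix must be square, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("PAE values must be non-negative")
        if self.index_map is not None and len(self.index_map) != self.values.shape[0]:
            raise ValueError("index_map length must equal matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def paired_with(self, structure: StructureModel) -> "PAEMatrix":
        """Attach the structure's flattened residue order as the index map."""
        order = structure.residue_order()
        if len(order) != self.n:
            raise ValueError(
                f"PAE dimension {self.n} != structure residue count {len(order)}"
            )
        return PAEMatrix(values=self.values, index_map=order)


def read_pae(path: str | Path) -> PAEMatrix:
    """Read a PAE matrix from AlphaFold-server style JSON.

    Accepts a top-level N x N array, an object with a ``pae`` or
    ``predicted_aligned_error`` field, or a one-element list of such objects
    (the server's full-data export).
    """
    with open(path) as fh:
        data = json.load(fh)
    obj = data
    if isinstance(obj, list) and obj and isinstance(obj[0], dict):
        obj = obj[0]
    if isinstance(obj, dict):
        for key in ("pae", "predicted_aligned_error"):
            if key in obj:
                obj = obj[key]
                break
        else:
            raise ValueError(f"{path}: no 'pae' or 'predicted_aligned_error' field")
    lengths = {len(row) for row in obj}
    if len(lengths) != 1 or lengths != {len(obj)}:
        raise ValueError(f"{path}: ragged or non-square PAE array")
    return PAEMatrix(values=np.array(obj, dtype=float))


def annotation_key(group_id: str, gene_names: str) -> str:
    """Protein key used for annotation joins: first gene-name token, falling
    back to the first accession of the group id (MitoCarta and GO tables key
    on gene symbols)."""
    if gene_names:
        return gene_names.split(";")[0].strip()
    return group_id.split(";")[0].strip()
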