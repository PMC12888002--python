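"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without any download:

``simulate_lfq``
    Label-free quantification tables with per-condition replicate groups,
    log-scale baseline abundances, bait-specific enrichment effects,
    intensity-dependent left-censored missingness (low-abundance cells go
    missing preferentially, the regime that motivates downshifted-Gaussian
    imputation), injected decoy/contaminant/only-by-site rows, and
    annotation labels correlated with enrichment status.

``simulate_complex``
    Toy two-chain CA-trace complexes with an exactly known inter-chain
    contact set and a matching PAE matrix, written as valid PDB + JSON.

Every generator is driven by a single ``numpy`` Generator seed and is
bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.special import expit

from .io_model import (
    AnnotationMap,
    Comparison,
    DesignSpec,
    PAEMatrix,
    ProteinGroupTable,
    Residue,
    StructureModel,
)

# default annotation scheme: label -> (P(label | enriched), P(label | background))
DEFAULT_ANNOTATION_SCHEME: dict[str, tuple[float, float]] = {
    "Mitochondria": (0.85, 0.15),
    "MOM": (0.45, 0.03),
    "RNA binding": (0.30, 0.10),
}


@dataclass
class LfqSimConfig:
    """Configuration of the LFQ table simulator.

    Log10-scale abundance of protein i in sample s is
    ``baseline_i + effect_i(s) + Normal(0, residual_sd)`` where
    ``baseline_i ~ Normal(baseline_mean, baseline_sd)`` and the effect is
    ``effect_size_log2 * log10(2)`` in the enriched condition for the
    ``frac_enriched`` fraction of proteins.  Cells are observed with
    probability ``logistic(censor_slope * (x - censor_midpoint))``.
    """

    n_proteins: int = 1000
    conditions: dict[str, int] = field(default_factory=lambda: {"bait": 3, "control": 3})
    enriched_condition: str | None = None  # default: first condition
    baseline_mean: float = 7.5
    baseline_sd: float = 1.0
    frac_enriched: float = 0.05
    effect_size_log2: float = 4.0
    residual_sd: float = 0.15
    frac_contaminant: float = 0.0
    frac_only_by_site: float = 0.0
    frac_reverse: float = 0.0
    censor_midpoint: float = 5.5  # baseline_mean - 2 * baseline_sd
    censor_slope: float = 1.5
    annotation_scheme: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_SCHEME)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("frac_enriched", self.frac_enriched),
            ("frac_contaminant", self.frac_contaminant),
            ("frac_only_by_site", self.frac_only_by_site),
            ("frac_reverse", self.frac_reverse),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(n < 2 for n in self.conditions.values()):
            raise ValueError("every condition needs >= 2 replicates")
        if self.baseline_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("SDs must be > 0")
        if self.censor_slope < 0:
            raise ValueError("censor_slope must be >= 0")

    def design(self) -> DesignSpec:
        rows = []
        for cond, n_rep in self.conditions.items():
            for r in range(1, n_rep + 1):
                rows.append({"sample": f"{cond}_{r}", "condition": cond, "replicate": r})
        df = pd.DataFrame(rows).set_index("sample")
        conds = list(self.conditions)
        comparisons = [Comparison(f"{conds[0]}_vs_{c}", conds[0], c) for c in conds[1:]]
        return DesignSpec(samples=df, comparisons=comparisons)


@dataclass
class SimulatedLfq:
    """Simulator output: the table, the design and the ground truth."""

    table: ProteinGroupTable
    design: DesignSpec
    truth: pd.DataFrame  # per protein: enriched_in, effect_log2, flags, labels
    censored: pd.DataFrame  # per cell: True where censored (set to 0 in table)
    annotations: list[AnnotationMap]


def simulate_missingness(
    log_abundances: np.ndarray,
    censor_midpoint: float,
    censor_slope: float,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply logistic left-censoring to a log-abundance matrix.

    Each cell with value x stays observed with probability
    ``logistic(censor_slope * (x - censor_midpoint))``; censored cells are
    NaN in the returned matrix.  ``censor_slope = 0`` gives uniform 50%
    missingness; a very low midpoint gives none.  Returns
    ``(censored_matrix, missing_mask)``.
    """
    if censor_slope < 0:
        raise ValueError("censor_slope must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    x = np.asarray(log_abundances, dtype=float)
    p_obs = expit(censor_slope * (x - censor_midpoint))
    missing = rng.random(x.shape) >= p_obs
    out = x.copy()
    out[missing] = np.nan
    return out, missing


def simulate_lfq(config: LfqSimConfig | None = None) -> SimulatedLfq:
    """Generate a ProteinGroupTable with known ground truth."""
    cfg = config or LfqSimConfig()
    rng = np.random.default_rng(cfg.seed)
    design = cfg.design()
    samples = list(design.samples.index)
    sample_cond = design.samples["condition"]
    n = cfg.n_proteins
    enriched_cond = cfg.enriched_condition or next(iter(cfg.conditions))

    n_enriched = round(cfg.frac_enriched * n)
    enriched_idx = rng.choice(n, size=n_enriched, replace=False)
    enriched = np.zeros(n, dtype=bool)
    enriched[enriched_idx] = True

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    effect_log10 = cfg.effect_size_log2 * np.log10(2)
    log_ab = np.empty((n, len(samples)))
    for s_i, sample in enumerate(samples):
        shift = np.where(enriched & (sample_cond[sample] == enriched_cond), effect_log10, 0.0)
        log_ab[:, s_i] = baseline + shift + rng.normal(0, cfg.residual_sd, n)

    censored_log, missing = simulate_missingness(
        log_ab, cfg.censor_midpoint, cfg.censor_slope, rng
    )
    linear = np.where(missing, 0.0, 10.0 ** log_ab)

    # flagged rows drawn from non-enriched proteins, non-overlapping categories
    flags = {"contaminant": np.zeros(n, bool), "only_by_site": np.zeros(n, bool), "reverse": np.zeros(n, bool)}
    pool = rng.permutation(np.flatnonzero(~enriched))
    offset = 0
    for name, frac in (
        ("contaminant", cfg.frac_contaminant),
        ("only_by_site", cfg.frac_only_by_site),
        ("reverse", cfg.frac_reverse),
    ):
        k = round(frac * n)
        flags[name][pool[offset : offset + k]] = True
        offset += k

    genes = [f"GENE{i:05d}" for i in range(n)]
    group_ids = [f"P{i:05d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "gene_names": genes,
            "reverse": flags["reverse"],
            "contaminant": flags["contaminant"],
            "only_by_site": flags["only_by_site"],
        },
        index=pd.Index(group_ids, name="group_id"),
    )
    intensities = pd.DataFrame(linear, index=meta.index, columns=samples)
    table = ProteinGroupTable(meta=meta, intensities=intensities)

    annotations = []
    truth_labels: dict[str, list[bool]] = {}
    for label, (p_enr, p_bg) in cfg.annotation_scheme.items():
        has = rng.random(n) < np.where(enriched, p_enr, p_bg)
        truth_labels[label] = list(has)
        entries = {genes[i]: {label} for i in np.flatnonzero(has)}
        if entries:
            annotations.append(AnnotationMap(vocabulary_name=label, entries=entries))

    truth = pd.DataFrame(
        {
            "gene_names": genes,
            "enriched_in": np.where(enriched, enriched_cond, "none"),
            "effect_log2": np.where(enriched, cfg.effect_size_log2, 0.0),
            **{f"flag_{k}": v for k, v in flags.items()},
            **{f"label_{k}": v for k, v in truth_labels.items()},
        },
        index=meta.index,
    )
    censored = pd.DataFrame(missing, index=meta.index, columns=samples)
    return SimulatedLfq(table=table, design=design, truth=truth, censored=censored, annotations=annotations)


# ---------------------------------------------------------------------------
# Toy complexes


@dataclass
class SimulatedComplex:
    """Two-chain CA-trace toy complex with known contacts."""

    structure: StructureModel
    pae: PAEMatrix
    contacts: list[tuple[int, int]]  # designed (resA_num, resB_num), author numbering

    def write(self, out_dir: str | Path, stem: str = "complex") -> tuple[Path, Path]:
        """Write the model as PDB and the PAE as AlphaFold-style JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pdb_path = out_dir / f"{stem}.pdb"
        pae_path = out_dir / f"{stem}_pae.json"
        st = gemmi.Structure()
        st.name = stem
        model = gemmi.Model("1")
        for cid, residues in self.structure.chains.items():
            chain = gemmi.Chain(cid)
            for res in residues:
                r = gemmi.Residue()
                r.name = res.name
                r.seqid = gemmi.SeqId(res.author_seq_id, " ")
                for name, element, x, y, z in res.atoms:
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(element)
                    atom.pos = gemmi.Position(x, y, z)
                    atom.occ = 1.0
                    r.add_atom(atom)
                chain.add_residue(r)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(pdb_path))
        with open(pae_path, "w") as fh:
            json.dump({"pae": self.pae.values.tolist()}, fh)
        return pdb_path, pae_path


_RES_SPACING = 12.0  # Å between consecutive CA positions (toy geometry)
_CHAIN_GAP = 30.0  # Å between non-contacting stretches of the two chains
_CONTACT_DIST = 6.0  # Å designed contact distance (< 8)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR-based) and a translation in [-50, 50]^3."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.uniform(-50, 50, 3)


def simulate_complex(
    n_res_a: int,
    n_res_b: int,
    n_contacts: int,
    pae_inside: float = 3.0,
    pae_outside: float = 12.0,
    seed: int = 0,
    rigid_transform: bool = True,
) -> SimulatedComplex:
    """Build a two-chain CA trace with exactly ``n_contacts`` designed pairs.

    Chains run along parallel lines 12 Å apart per residue; designed pairs
    sit 6 Å apart (< 8) while every other inter-chain residue pair is at
    least 10 Å away.  The PAE matrix is ``pae_outside`` everywhere except
    the designed pairs (both orientations) at ``pae_inside`` and zero on
    the diagonal.  An optional random rigid-body transform of the whole
    complex exercises rotation invariance downstream.
    """
    if n_contacts > min(n_res_a, n_res_b):
        raise ValueError(
            f"cannot place {n_contacts} one-per-residue contacts with chains of "
            f"{n_res_a} and {n_res_b} residues"
        )
    rng = np.random.default_rng(seed)
    contact_slots = sorted(rng.choice(min(n_res_a, n_res_b), size=n_contacts, replace=False))
    slot_set = set(int(s) for s in contact_slots)

    coords_a = np.array([[i * _RES_SPACING, 0.0, 0.0] for i in range(n_res_a)])
    coords_b = np.array(
        [
            [j * _RES_SPACING, _CONTACT_DIST if j in slot_set else _CHAIN_GAP, 0.0]
            for j in range(n_res_b)
        ]
    )
    if rigid_transform:
        rot, trans = _random_rigid(rng)
        coords_a = coords_a @ rot.T + trans
        coords_b = coords_b @ rot.T + trans

    def make_chain(coords: np.ndarray) -> list[Residue]:
        return [
            Residue(i + 1, "ALA", (("CA", "C", float(x), float(y), float(z)),))
            for i, (x, y, z) in enumerate(coords)
        ]

    structure = StructureModel(chains={"A": make_chain(coords_a), "B": make_chain(coords_b)})
    n_total = n_res_a + n_res_b
    pae_vals = np.full((n_total, n_total), float(pae_outside))
    np.fill_diagonal(pae_vals, 0.0)
    for s in slot_set:
        i, j = s, n_res_a + s
        pae_vals[i, j] = pae_inside
        pae_vals[j, i] = pae_inside
    pae = PAEMatrix(values=pae_vals, index_map=structure.residue_order())
    contacts = [(s + 1, s + 1) for s in sorted(slot_set)]
    return SimulatedComplex(structure=structure, pae=pae, contacts=contacts)
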