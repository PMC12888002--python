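"""Interface contacts of a predicted two-chain complex, filtered by PAE.

A residue pair (i in chain A, j in chain B) is an interface contact when
any heavy atom of i lies strictly closer than 8 Å to any heavy atom of j.
Contacts are then annotated with the predicted aligned error in both
orientations, PAE(i, j) and PAE(j, i); a contact is high-confidence when
the maximum of the two is at most 5 Å.  The PAE matrix indexes residues in
file order, chain by chain, matching the AlphaFold server export.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .io_model import PAEMatrix, StructureModel

DISTANCE_CUTOFF = 8.0  # Å, strict (<)
PAE_CUTOFF = 5.0  # Å, inclusive (<=)


@dataclass(frozen=True)
class ContactPair:
    chain_a: str
    res_a_num: int
    res_a_name: str
    chain_b: str
    res_b_num: int
    res_b_name: str
    min_distance: float
    pae_ij: float | None = None
    pae_ji: float | None = None
    max_pae: float | None = None
    high_confidence: bool | None = None

    def swapped(self) -> "ContactPair":
        return ContactPair(
            self.chain_b, self.res_b_num, self.res_b_name,
            self.chain_a, self.res_a_num, self.res_a_name,
            self.min_distance, self.pae_ji, self.pae_ij,
            self.max_pae, self.high_confidence,
        )


def _chain_atoms(structure: StructureModel, chain_id: str):
    """Stacked heavy-atom coordinates of one chain plus per-atom residue index."""
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure (has {sorted(structure.chains)})")
    residues = structure.chains[chain_id]
    coords, res_idx = [], []
    for i, res in enumerate(residues):
        c = res.coords()
        coords.append(c)
        res_idx.append(np.full(len(c), i))
    if not coords:
        raise ValueError(f"chain {chain_id!r} has no heavy atoms")
    return residues, np.vstack(coords), np.concatenate(res_idx)


def interface_residues(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    distance_cutoff: float = DISTANCE_CUTOFF,
) -> list[ContactPair]:
    """All residue pairs whose minimum heavy-atom distance is < cutoff.

    Sorted by (residue_A, residue_B) author numbers; each pair records the
    minimum heavy-atom distance in Å.
    """
    res_a, xyz_a, idx_a = _chain_atoms(structure, chain_a)
    res_b, xyz_b, idx_b = _chain_atoms(structure, chain_b)
    dist = cdist(xyz_a, xyz_b)
    # reduce the atom-atom matrix to per-residue-pair minima
    min_d = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(min_d, (idx_a[:, None], idx_b[None, :]), dist)
    pairs = []
    for i, j in zip(*np.nonzero(min_d < distance_cutoff)):
        pairs.append(
            ContactPair(
                chain_a, res_a[i].author_seq_id, res_a[i].name,
                chain_b, res_b[j].author_seq_id, res_b[j].name,
                float(min_d[i, j]),
            )
        )
    pairs.sort(key=lambda p: (p.res_a_num, p.res_b_num))
    return pairs


def filter_by_pae(
    contacts: list[ContactPair],
    pae: PAEMatrix,
    pae_cutoff: float = PAE_CUTOFF,
) -> tuple[list[ContactPair], list[ContactPair]]:
    """Annotate contacts with PAE and keep those with max PAE <= cutoff.

    The PAE matrix must carry an ``index_map`` (see
    :meth:`PAEMatrix.paired_with`).  Returns ``(kept, dropped)``; both lists
    carry the pae_ij / pae_ji / max_pae annotations.
    """
    if pae.index_map is None:
        raise ValueError("PAE matrix has no index map; pair it with the structure first")
    flat = {key: i for i, key in enumerate(pae.index_map)}
    kept, dropped = [], []
    for pair in contacts:
        key_a = (pair.chain_a, pair.res_a_num)
        key_b = (pair.chain_b, pair.res_b_num)
        for key in (key_a, key_b):
            if key not in flat:
                raise KeyError(f"residue {key} not resolvable in the PAE index map")
        i, j = flat[key_a], flat[key_b]
        pae_ij = float(pae.values[i, j])
        pae_ji = float(pae.values[j, i])
        max_pae = max(pae_ij, pae_ji)
        high = max_pae <= pae_cutoff
        annotated = replace(
            pair, pae_ij=pae_ij, pae_ji=pae_ji, max_pae=max_pae, high_confidence=high
        )
        (kept if high else dropped).append(annotated)
    return kept, dropped


def interface_report(
    structure: StructureModel,
    pae: PAEMatrix,
    chain_a: str,
    chain_b: str,
    distance_cutoff: float = DISTANCE_CUTOFF,
    pae_cutoff: float = PAE_CUTOFF,
) -> dict:
    """Per-residue interface summary for one chain pair.

    Lists every interface residue of each chain (author numbering + name)
    with its number of high-confidence partners, and an overall verdict:
    ``"no interface"`` when no residue pair is within the distance cutoff,
    ``"no high-confidence interface"`` when contacts exist but none passes
    the PAE filter, else ``"high-confidence interface"``.
    """
    contacts = interface_residues(structure, chain_a, chain_b, distance_cutoff)
    if pae.index_map is None:
        pae = pae.paired_with(structure)
    kept, dropped = filter_by_pae(contacts, pae, pae_cutoff)

    def residue_rows(chain_id: str, side: str):
        rows = {}
        for pair in kept + dropped:
            num = pair.res_a_num if side == "a" else pair.res_b_num
            name = pair.res_a_name if side == "a" else pair.res_b_name
            entry = rows.setdefault(num, {"residue": num, "name": name, "n_partners": 0, "n_high_confidence": 0})
            entry["n_partners"] += 1
        for pair in kept:
            num = pair.res_a_num if side == "a" else pair.res_b_num
            rows[num]["n_high_confidence"] += 1
        return [rows[k] for k in sorted(rows)]

    if not contacts:
        verdict = "no interface"
    elif not kept:
        verdict = "no high-confidence interface"
    else:
        verdict = "high-confidence interface"
    return {
        "chain_a": chain_a,
        "chain_b": chain_b,
        "distance_cutoff": distance_cutoff,
        "pae_cutoff": pae_cutoff,
        "n_contacts": len(contacts),
        "n_high_confidence": len(kept),
        "verdict": verdict,
        "residues_a": residue_rows(chain_a, "a"),
        "residues_b": residue_rows(chain_b, "b"),
        "contacts": kept,
        "dropped": dropped,
    }


def contacts_to_frame(contacts: list[ContactPair]):
    """Contacts as a plot/export-ready DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chainA": c.chain_a, "resA_num": c.res_a_num, "resA_name": c.res_a_name,
                "chainB": c.chain_b, "resB_num": c.res_b_num, "resB_name": c.res_b_name,
                "min_dist": c.min_distance, "pae_ij": c.pae_ij, "pae_ji": c.pae_ji,
                "max_pae": c.max_pae, "high_confidence": c.high_confidence,
            }
            for c in contacts
        ],
        columns=[
            "chainA", "resA_num", "resA_name", "chainB", "resB_num", "resB_name",
            "min_dist", "pae_ij", "pae_ji", "max_pae", "high_confidence",
        ],
    )
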