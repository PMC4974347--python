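"""Assess cross-links against crystal structures.

A cross-link between surface residues implies their Cα atoms were within
the theoretical cross-linkable limit (spacer + side chains + displacement
allowance) when the linker reacted. Links whose Cα–Cα distance in a crystal
structure exceeds that limit are incompatible with the crystallized
conformation — the central structural readout of a QCLMS comparison.

Residue numbering: structures are loaded through per-chain offsets mapping
PDB author numbering to 1-based mature-protein numbering (identity by
default). Residues missing from the model can be substituted by the nearest
resolved residue in sequence, with every substitution recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from xlmstruct.core import CrossLink, LinkerSpec, ResidueRef, max_link_distance
from xlmstruct.errors import StructureError, UnresolvedResidueError

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """Cα coordinates of a structure indexed by mature-protein numbering."""

    structure_id: str
    chains: dict[str, dict[int, tuple[np.ndarray, str]]]

    def __post_init__(self) -> None:
        index: dict[int, tuple[np.ndarray, str]] = {}
        for chain in self.chains.values():
            for pos, entry in chain.items():
                if pos in index:
                    raise StructureError(
                        f"residue {pos} resolved in more than one chain after "
                        f"offset mapping"
                    )
                index[pos] = entry
        self._index = index

    @property
    def resolved_positions(self) -> list[int]:
        return sorted(self._index)

    def is_resolved(self, pos: int) -> bool:
        return pos in self._index

    def ca(self, pos: int) -> np.ndarray:
        try:
            return self._index[pos][0]
        except KeyError:
            raise UnresolvedResidueError(
                f"residue {pos} has no Cα in {self.structure_id}"
            ) from None

    def residue_type(self, pos: int) -> str:
        return self._index[pos][1]


def read_structure(
    path,
    offsets: Optional[Mapping[str, int]] = None,
    structure_id: Optional[str] = None,
) -> StructureModel:
    """Extract Cα atoms from a PDB or mmCIF file.

    ``offsets`` maps chain name to the integer added to author residue
    numbers to reach mature-protein numbering (default 0 for every chain).
    Alternate locations keep the highest-occupancy copy (first in file on
    ties); residues with insertion codes have no mature-numbering equivalent
    and are skipped.
    """
    offsets = dict(offsets or {})
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    unknown = set(offsets) - {ch.name for ch in st[0]}
    if unknown:
        raise StructureError(
            f"offset chains {sorted(unknown)} not present in {path}; "
            f"available: {[ch.name for ch in st[0]]}"
        )
    chains: dict[str, dict[int, tuple[np.ndarray, str]]] = {}
    for chain in st[0]:
        offset = offsets.get(chain.name, 0)
        resmap: dict[int, tuple[np.ndarray, str]] = {}
        for res in chain:
            if res.seqid.icode.strip():
                continue  # insertion codes: outside the mature numbering
            best = None
            for atom in res:
                if atom.name != "CA" or atom.element.name == "Ca":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                continue
            pos = res.seqid.num + offset
            if pos in resmap:
                continue  # first occurrence wins
            coord = np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)
            if not np.all(np.isfinite(coord)):
                raise StructureError(f"non-finite Cα coordinate at residue {pos}")
            resmap[pos] = (coord, _THREE_TO_ONE.get(res.name, "X"))
        if resmap:
            chains[chain.name] = resmap
    if not chains:
        raise StructureError(f"no Cα atoms found in {path}")
    return StructureModel(structure_id=structure_id or str(path), chains=chains)


def nearest_resolved(s: StructureModel, pos: int) -> int:
    """The resolved position nearest to ``pos`` in sequence (ties: lower number).

    Returns ``pos`` itself when it is resolved. Idempotent.
    """
    if s.is_resolved(pos):
        return pos
    resolved = s.resolved_positions
    if not resolved:
        raise StructureError("structure has no resolved residues")
    return min(resolved, key=lambda p: (abs(p - pos), p))


def ca_distance(
    s: StructureModel,
    a: ResidueRef | int,
    b: ResidueRef | int,
    substitute: bool = False,
) -> float:
    """Euclidean Cα–Cα distance in Å between two residues.

    With ``substitute=True`` unresolved residues fall back to the nearest
    resolved residue in sequence; otherwise they raise
    :class:`UnresolvedResidueError`.
    """
    pa = a.position if isinstance(a, ResidueRef) else int(a)
    pb = b.position if isinstance(b, ResidueRef) else int(b)
    if substitute:
        pa, pb = nearest_resolved(s, pa), nearest_resolved(s, pb)
    return float(np.linalg.norm(s.ca(pa) - s.ca(pb)))


@dataclass
class LinkAssessment:
    """One cross-link measured against one structure."""

    crosslink: CrossLink
    distance: Optional[float]  # Å; None when a residue could not be placed
    limit: float
    violated: Optional[bool]
    substituted_positions: list[tuple[int, int]] = field(default_factory=list)


def assess_links(
    s: StructureModel,
    links: Sequence[CrossLink],
    linker: LinkerSpec,
    substitute: bool = True,
) -> list[LinkAssessment]:
    """Measure every link's Cα–Cα distance and compare it to its theoretical limit.

    The limit comes from the linker geometry and the residue types of the
    linked residues; residues of unknown type are assumed lysine (the
    dominant reactive site), which gives the widest commonly quoted limit.
    """
    out = []
    for link in links:
        ta = link.a.residue_type if link.a.residue_type in linker.reactive_residues else "K"
        tb = link.b.residue_type if link.b.residue_type in linker.reactive_residues else "K"
        limit = max_link_distance(linker, ta, tb)
        subs: list[tuple[int, int]] = []
        try:
            pa, pb = link.a.position, link.b.position
            if substitute:
                qa, qb = nearest_resolved(s, pa), nearest_resolved(s, pb)
                if qa != pa:
                    subs.append((pa, qa))
                if qb != pb:
                    subs.append((pb, qb))
                pa, pb = qa, qb
            d = float(np.linalg.norm(s.ca(pa) - s.ca(pb)))
            out.append(LinkAssessment(link, d, limit, d > limit, subs))
        except (UnresolvedResidueError, StructureError):
            out.append(LinkAssessment(link, None, limit, None, subs))
    return out


def assessments_to_frame(assessments: Sequence[LinkAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        rows.append(
            {
                "res_a": a.crosslink.a.position,
                "res_b": a.crosslink.b.position,
                "distance": a.distance,
                "limit": a.limit,
                "violated": a.violated,
                "substituted": ";".join(f"{x}->{y}" for x, y in a.substituted_positions),
            }
        )
    return pd.DataFrame(rows)


#: Category colors following the published display convention:
#: state-1-unique blue, state-1-enriched cyan, mutual gray, state-2-enriched
#: dark (forest) green, state-2-unique green.
CATEGORY_COLORS = {
    "unique_1": "blue",
    "enriched_1": "cyan",
    "mutual": "gray50",
    "enriched_2": "forest",
    "unique_2": "green",
}


def export_visualization(
    s: StructureModel,
    assessments: Sequence[LinkAssessment],
    categories: Optional[Mapping[CrossLink, str]] = None,
    object_name: str = "xlinks",
) -> str:
    """Emit a PyMOL command script drawing each link between Cα atoms.

    Each assessed link becomes a ``distance`` object (a solid dash between
    the two Cα atoms) colored by its category; links without a measured
    distance are skipped. Output ordering is deterministic (by residue
    positions).
    """
    categories = categories or {}
    lines = [
        f"# cross-link visualization for {s.structure_id}",
        "# one 'distance' object per cross-link, colored by category",
        "set dash_gap, 0",
        "set dash_radius, 0.4",
    ]
    ordered = sorted(
        (a for a in assessments if a.distance is not None),
        key=lambda a: a.crosslink.positions,
    )
    for i, a in enumerate(ordered, start=1):
        pa, pb = a.crosslink.positions
        for req, used in a.substituted_positions:
            if req == pa:
                pa = used
            if req == pb:
                pb = used
        cat = categories.get(a.crosslink, "mutual")
        color = CATEGORY_COLORS.get(cat, "gray50")
        name = f"{object_name}_{i:03d}"
        lines.append(f"distance {name}, resi {pa} and name CA, resi {pb} and name CA")
        lines.append(f"color {color}, {name}")
    lines.append("hide labels")
    return "\n".join(lines) + "\n"
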