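"""Shared domain types: residue addressing, cross-link identity, linker chemistry.

All residue positions are 1-based mature-protein numbering. For complement
C3 that convention places residues 1–645 in the β-chain and 650–1641 in the
α-chain; the four basic residues excised during maturation (646–649) belong
to no chain. Mapping to PDB author numbering is a concern of
:mod:`xlmstruct.struct` (per-chain offsets), never of these types.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from xlmstruct.errors import AnnotationError, UnknownReactiveResidueError

UNKNOWN = "unknown"

#: Reactive site key for a protein N terminus (not a real residue type).
N_TERMINUS = "NTERM"


@dataclass(frozen=True)
class LinkerSpec:
    """Geometry of a bifunctional cross-linker.

    The theoretical maximum Cα–Cα distance a linker can bridge is the spacer
    length plus both side-chain lengths plus a per-residue displacement
    allowance (to absorb coordinate error / side-chain flexibility in the
    crystal structure).

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"BS3"``.
    spacer_length:
        Length of the spacer arm in Å. Must be positive.
    reactive_residues:
        Map from one-letter residue type (plus the special key ``NTERM``)
        to side-chain length in Å.
    displacement_allowance:
        Extra Å granted per linked residue.
    """

    name: str
    spacer_length: float
    reactive_residues: Mapping[str, float]
    displacement_allowance: float = 2.0

    def __post_init__(self) -> None:
        if self.spacer_length <= 0:
            raise ValueError("spacer_length must be > 0")
        if self.displacement_allowance < 0:
            raise ValueError("displacement_allowance must be >= 0")
        if not self.reactive_residues:
            raise ValueError("reactive_residues must be non-empty")

    def side_chain_length(self, residue_type: str) -> float:
        try:
            return self.reactive_residues[residue_type]
        except KeyError:
            raise UnknownReactiveResidueError(residue_type, self.name) from None


def default_bs3_linker() -> LinkerSpec:
    """BS3 (bis[sulfosuccinimidyl]suberate) with an 11.4 Å spacer.

    Side-chain lengths: 6.0 Å lysine, 2.4 Å serine, 2.4 Å threonine,
    6.5 Å tyrosine. The protein N terminus is a reactive site with no
    side chain and is assigned 0 Å (conservative lower bound). A 2 Å
    displacement allowance is granted per residue, so the lysine–lysine
    limit is 11.4 + 6.0 + 6.0 + 2 + 2 = 27.4 Å.
    """
    return LinkerSpec(
        name="BS3",
        spacer_length=11.4,
        reactive_residues={"K": 6.0, "S": 2.4, "T": 2.4, "Y": 6.5, N_TERMINUS: 0.0},
        displacement_allowance=2.0,
    )


def max_link_distance(linker: LinkerSpec, type_a: str, type_b: str) -> float:
    """Theoretical maximum Cα–Cα distance for a cross-link between two residue types.

    spacer + side_chain(a) + side_chain(b) + 2 × displacement allowance.
    Symmetric in the two residue types.

    Raises
    ------
    UnknownReactiveResidueError
        If either residue type is not a reactive site of the linker.
    """
    # summing in sorted order keeps the result bit-identical under argument swap
    lo, hi = sorted((linker.side_chain_length(type_a), linker.side_chain_length(type_b)))
    return linker.spacer_length + lo + hi + 2.0 * linker.displacement_allowance


@dataclass(frozen=True)
class Domain:
    """A named domain as a list of ascending, non-overlapping segments."""

    name: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = 0
        for start, end in segs:
            if start > end:
                raise AnnotationError(f"domain {self.name}: segment {start}-{end} reversed")
            if start <= prev_end:
                raise AnnotationError(
                    f"domain {self.name}: segments overlap or are not ascending"
                )
            prev_end = end

    def __contains__(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.segments)

    @property
    def residues(self) -> list[int]:
        out: list[int] = []
        for a, b in self.segments:
            out.extend(range(a, b + 1))
        return out


@dataclass(frozen=True)
class DomainAnnotation:
    """Chain ranges and domain boundaries of a protein, in mature numbering."""

    protein_id: str
    chains: tuple[tuple[str, int, int], ...]
    domains: tuple[Domain, ...]

    def __post_init__(self) -> None:
        chains = tuple((str(c), int(a), int(b)) for c, a, b in self.chains)
        object.__setattr__(self, "chains", chains)
        doms = tuple(
            d if isinstance(d, Domain) else Domain(d[0], tuple(d[1])) for d in self.domains
        )
        object.__setattr__(self, "domains", doms)
        spans = sorted((a, b, c) for c, a, b in chains)
        for (a1, b1, _), (a2, _, _) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise AnnotationError("chain ranges overlap")
        seen: dict[int, str] = {}
        for d in doms:
            for pos in d.residues:
                if pos in seen:
                    raise AnnotationError(
                        f"residue {pos} belongs to both {seen[pos]} and {d.name}"
                    )
                seen[pos] = d.name

    def domain_of(self, pos: int) -> str:
        """Domain name covering ``pos``, or ``'unknown'``."""
        for d in self.domains:
            if pos in d:
                return d.name
        return UNKNOWN

    def chain_of(self, pos: int) -> Optional[str]:
        for chain_id, a, b in self.chains:
            if a <= pos <= b:
                return chain_id
        return None

    def domain(self, name: str) -> Domain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)


@dataclass(frozen=True)
class ResidueRef:
    """A residue in mature-protein numbering, optionally labelled."""

    position: int
    domain: str = UNKNOWN
    residue_type: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")

    def __str__(self) -> str:  # e.g. "1049^TED"
        if self.domain != UNKNOWN:
            return f"{self.position}^{self.domain}"
        return str(self.position)


def annotate_residue(
    pos: int, ann: DomainAnnotation, residue_type: str = UNKNOWN
) -> ResidueRef:
    """Build a :class:`ResidueRef` with its domain label filled from ``ann``.

    Positions in a gap between domains get domain ``'unknown'``.
    """
    return ResidueRef(position=pos, domain=ann.domain_of(pos), residue_type=residue_type)


class CrossLink:
    """An unordered pair of cross-linked residues.

    Identity is order-independent: ``CrossLink(a, b)`` equals
    ``CrossLink(b, a)``. The endpoints are stored sorted by position, so
    ``link.a.position <= link.b.position`` always holds.
    """

    __slots__ = ("a", "b", "linker")

    def __init__(self, a: ResidueRef, b: ResidueRef, linker: Optional[LinkerSpec] = None):
        if b.position < a.position:
            a, b = b, a
        self.a = a
        self.b = b
        self.linker = linker

    @property
    def positions(self) -> tuple[int, int]:
        return (self.a.position, self.b.position)

    @property
    def intra_domain(self) -> bool:
        return self.a.domain != UNKNOWN and self.a.domain == self.b.domain

    def _key(self) -> tuple:
        return (self.a.position, self.b.position, self.linker.name if self.linker else None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossLink):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:
        return f"CrossLink({self.a}-{self.b})"


# ---------------------------------------------------------------------------
# Config and table I/O


def load_domain_annotation(source) -> DomainAnnotation:
    """Read a domain annotation from a YAML path, file object or string.

    Expected layout::

        protein_id: C3_human_mature
        chains:
          - [beta, 1, 645]
          - [alpha, 650, 1641]
        domains:
          MG1: [[1, 104]]
          ...
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    domains = tuple(
        Domain(name, tuple(tuple(seg) for seg in segs))
        for name, segs in raw["domains"].items()
    )
    return DomainAnnotation(
        protein_id=raw["protein_id"],
        chains=tuple(tuple(c) for c in raw["chains"]),
        domains=domains,
    )


def c3_annotation() -> DomainAnnotation:
    """The shipped (reconstructed) domain annotation for mature human C3."""
    ref = importlib.resources.files("xlmstruct") / "data" / "c3_domains.yaml"
    return load_domain_annotation(ref.read_text())


def read_crosslinks(
    path,
    linker: Optional[LinkerSpec] = None,
    annotation: Optional[DomainAnnotation] = None,
) -> list[CrossLink]:
    """Read a cross-link list from TSV with columns res_a, res_b[, type_a, type_b]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("res_a", "res_b"):
        if col not in df.columns:
            raise AnnotationError(f"cross-link table missing column {col!r}")
    links = []
    for row in df.itertuples(index=False):
        ta = getattr(row, "type_a", UNKNOWN)
        tb = getattr(row, "type_b", UNKNOWN)
        if annotation is not None:
            a = annotate_residue(int(row.res_a), annotation, ta)
            b = annotate_residue(int(row.res_b), annotation, tb)
        else:
            a = ResidueRef(int(row.res_a), residue_type=ta)
            b = ResidueRef(int(row.res_b), residue_type=tb)
        links.append(CrossLink(a, b, linker))
    return links


def write_crosslinks(links: Iterable[CrossLink], path) -> None:
    """Write a cross-link list as TSV (res_a, res_b, type_a, type_b, domains)."""
    import pandas as pd

    rows = [
        {
            "res_a": ln.a.position,
            "res_b": ln.b.position,
            "type_a": ln.a.residue_type,
            "type_b": ln.b.residue_type,
            "domain_a": ln.a.domain,
            "domain_b": ln.b.domain,
        }
        for ln in links
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
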