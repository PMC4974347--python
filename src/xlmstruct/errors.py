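"""Typed errors shared across the package."""


class XlmsError(Exception):
    """Base class for all package errors."""


class UnknownReactiveResidueError(XlmsError):
    """A residue type has no side-chain length in the linker spec."""

    def __init__(self, residue_type: str, linker_name: str):
        self.residue_type = residue_type
        self.linker_name = linker_name
        super().__init__(
            f"residue type {residue_type!r} is not a reactive site of linker "
            f"{linker_name!r}"
        )


class AnnotationError(XlmsError):
    """A domain annotation violates its invariants."""


class QuantInputError(XlmsError):
    """A quantitation record or table is malformed."""


class SingletRecordError(QuantInputError):
    """A ratio was requested for a singlet record; use singlet handling."""


class DegenerateSampleError(XlmsError):
    """Too few values or zero spread for the robust outlier test."""


class StructureError(XlmsError):
    """A structure file or residue lookup problem."""


class UnresolvedResidueError(StructureError):
    """A residue has no Cα in the structure and substitution is disabled."""


class RepresentationError(XlmsError):
    """A coarse-grained representation config is inconsistent."""
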