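"""Exception hierarchy shared across the package."""


class PhasetagError(Exception):
    """Base class for all package-specific errors."""


class InvalidResidueError(PhasetagError, ValueError):
    """A sequence contains a character outside the canonical amino-acid alphabet."""

    def __init__(self, residue: str, position: int, sequence_id: str = ""):
        self.residue = residue
        self.position = position
        self.sequence_id = sequence_id
        where = f" in sequence {sequence_id!r}" if sequence_id else ""
        super().__init__(
            f"invalid residue {residue!r} at position {position}{where}: "
            "expected one of the 20 canonical amino-acid letters"
        )


class EmptyInputError(PhasetagError, ValueError):
    """An operation received an empty sequence, list, or table."""


class InfeasibleDesignError(PhasetagError, ValueError):
    """No tag design can reach the requested net charge."""


class PlacementError(PhasetagError, RuntimeError):
    """Synthetic cells could not be placed without overlap.

    Usually solved by fewer or smaller cells, or a larger field of view.
    """


class DegenerateImageError(PhasetagError, ValueError):
    """The image has no intensity contrast (constant pixels)."""


class DegenerateCellError(PhasetagError, ValueError):
    """A cell region is too small or malformed for the requested measurement."""


class AlignmentError(PhasetagError, ValueError):
    """Replicates disagree on the set of timepoints."""


class InsufficientDataError(PhasetagError, ValueError):
    """Not enough timepoints (or replicates) for the requested classification."""
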