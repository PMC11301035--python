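"""Exception hierarchy for leaf3d.

All package errors derive from :class:`Leaf3DError` so callers (and the CLI)
can catch one type.  Data problems are split into parse errors (the file is
malformed) and validation errors (the file is readable but the leaf violates
the acquisition-grid contract); geometric degeneracies get their own class
because they name the offending patch.
"""

from __future__ import annotations


class Leaf3DError(Exception):
    """Base class for all leaf3d errors."""


class ParseError(Leaf3DError):
    """A leaf table or config file could not be parsed."""


class ValidationError(Leaf3DError):
    """A leaf grid violates the structured-acquisition invariants."""

    def __init__(self, leaf_id: str, violations: list[str]):
        self.leaf_id = leaf_id
        self.violations = list(violations)
        msg = f"leaf {leaf_id!r}: " + "; ".join(self.violations)
        super().__init__(msg)


class DegenerateGeometryError(Leaf3DError):
    """Collinear, coincident or otherwise degenerate point geometry."""


class InsufficientDataError(Leaf3DError):
    """Too few patches/values to form the requested statistic."""


class TopologyError(Leaf3DError):
    """Mesh is not manifold-with-boundary where the operation requires it."""
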