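"""Exception hierarchy for diagcea."""

from __future__ import annotations


class DiagCeaError(Exception):
    """Base class for all diagcea errors."""


class TreeFormatError(DiagCeaError):
    """A tree file does not conform to the JSON schema.

    The message names the JSON path of the offending field, e.g.
    ``nodes[3].kind: unknown node kind 'triage'``.
    """


class InvalidTreeError(DiagCeaError):
    """A structural invariant of a diagnostic tree is violated.

    Carries the list of :class:`~diagcea.tree.Violation` records that
    ``validate_tree`` produced.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(v.message for v in self.violations)
        super().__init__(f"invalid diagnostic tree: {lines}")


class ModelingError(DiagCeaError):
    """The tree is structurally valid but cannot be analysed as requested.

    Examples: an exit node with no diagnostic result among its ancestors
    and no caller-supplied outcome; a missing entry in the test-performance
    registry.
    """


class HorizonError(DiagCeaError):
    """A pathway's turnaround time exceeds the evaluation horizon."""


class SizeError(DiagCeaError):
    """A brute-force computation would exceed its configured path cap."""


class ConfigError(DiagCeaError):
    """A parameter file or scenario configuration is incomplete or invalid."""
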