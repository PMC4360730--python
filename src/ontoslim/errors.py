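"""Exception hierarchy."""

from __future__ import annotations


class OntoslimError(Exception):
    """Base class for all toolkit errors."""


class OboParseError(OntoslimError):
    """Malformed OBO input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownTermError(OntoslimError, KeyError):
    """A CURIE was looked up that is not a node of the graph."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"unknown term {term_id!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


class CycleError(OntoslimError):
    """The merged graph has a directed cycle over the core relations."""

    def __init__(self, cycles: list[list[str]]):
        self.cycles = cycles
        shown = "; ".join(" -> ".join(c) for c in cycles[:3])
        super().__init__(f"{len(cycles)} cycle(s) in core relations: {shown}")


class ConfigError(OntoslimError):
    """Invalid slim, facet, rule or fixture configuration."""
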