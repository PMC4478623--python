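"""Exception hierarchy shared by all pedstitch modules."""


class PedstitchError(Exception):
    """Base class for all errors raised by this package."""


class NoSuchIndividualError(PedstitchError, KeyError):
    """An identifier does not resolve in the pedigree it was looked up in."""

    def __init__(self, individual_id: str, pedigree_name: str):
        super().__init__(
            f"no such individual {individual_id!r} in pedigree {pedigree_name!r}"
        )
        self.individual_id = individual_id
        self.pedigree_name = pedigree_name


class ConfigError(PedstitchError):
    """Malformed or incomplete configuration file."""


class ParseError(PedstitchError):
    """Malformed pedigree or metadata file content."""


class GeometryError(ParseError):
    """Metadata file dimensions disagree with the companion pedigree file."""


class SessionOverwriteError(PedstitchError):
    """Refusal to overwrite an input file of the current session."""


class ProvenanceError(PedstitchError):
    """Provenance lookup or update outside the table's domain."""


class MergeError(PedstitchError):
    """A merge plan cannot be executed."""


class AmbiguousMatchError(MergeError):
    """One individual matches several candidates under the match key."""

    def __init__(self, source_id: str, candidates):
        cands = ", ".join(sorted(candidates))
        super().__init__(
            f"individual {source_id!r} matches multiple destination "
            f"candidates under the match key: {cands}"
        )
        self.source_id = source_id
        self.candidates = list(candidates)


class IdCollisionError(MergeError):
    """A source id collides with an unmatched destination id."""


class EditError(PedstitchError):
    """An add/remove/edit/reconcile operation violates its preconditions."""
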