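"""Exception hierarchy shared across csense modules."""


class CsenseError(Exception):
    """Base class for all csense errors."""


class FormatError(CsenseError):
    """Malformed serialized input (JSON/TSV schema violation)."""


class InvariantError(CsenseError):
    """A domain-type invariant is violated."""


class InvalidSpecificationError(CsenseError, ValueError):
    """Caller asked for an impossible or inconsistent construction."""


class InvalidDesignError(CsenseError, ValueError):
    """A sensitivity-analysis design is unusable (e.g. too few samples)."""


class ConfigurationError(CsenseError):
    """A design references entities absent from the model/graph."""


class InvalidParameterError(CsenseError, ValueError):
    """A numeric parameter is out of its legal range."""


class InvalidSeedError(CsenseError):
    """Seed set inconsistent with the requested propagation mode."""


class LookupError_(CsenseError, KeyError):
    """A referenced sample/node is absent from a table."""


class MappingError(CsenseError):
    """A feature-to-node mapping matched nothing."""


class AlignmentError(CsenseError):
    """Two rankings do not cover the same item set."""


class UndefinedConcordanceError(CsenseError):
    """Concordance is undefined (e.g. all-zero prediction)."""


class MissingQcError(CsenseError):
    """An operation requiring QC injections found none."""


class DegenerateSampleError(CsenseError):
    """A sample produced a zero/undefined normalization coefficient."""
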