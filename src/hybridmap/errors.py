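"""Exception hierarchy for hybridmap."""


class HybridMapError(Exception):
    """Base class for all hybridmap errors."""


class InvalidAlphabetError(HybridMapError):
    """A sequence contains a symbol outside {A, C, G, T} where none is allowed."""


class EmptyReferenceError(HybridMapError):
    """No usable reference sequence was supplied."""


class SequenceTooShortError(HybridMapError):
    """The reference is shorter than the requested q-gram length."""


class QueryTooShortError(HybridMapError):
    """A lookup query is shorter than the hash-table q-gram length."""


class InvalidQGramError(HybridMapError):
    """An encoded q-gram value falls outside [0, 4^q)."""


class IndexFormatError(HybridMapError):
    """An index file is missing, truncated, or has a bad magic/header."""


class IndexVersionError(IndexFormatError):
    """An index file was written by an incompatible format version."""


class InvalidCarError(HybridMapError):
    """A candidate alignment region violates its ordering contract."""


class CorruptCarError(InvalidCarError):
    """A matching region's claimed bases do not match the reference."""


class ReadTooShortError(HybridMapError):
    """A read is shorter than the hash-table q-gram length."""


class EvaluationError(HybridMapError):
    """A mapped read is missing from the truth table."""
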