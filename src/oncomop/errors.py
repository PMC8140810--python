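"""Exception types shared across the toolkit."""


class OncomopError(Exception):
    """Base class for all toolkit errors."""


class VocabularyError(OncomopError):
    """Invalid vocabulary content: duplicate ids, dangling references,
    malformed rows, cycles in the subsumption hierarchy."""


class IntegrityError(OncomopError):
    """Referential or containment violation in the clinical data store."""


class MappingError(OncomopError):
    """A code could not be parsed or mapped through the vocabulary."""
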