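"""Exception hierarchy.

Errors are split so callers can tell configuration problems (a missing
external tool, an invalid threshold) from data problems (a chain absent
from a file, an alignment that does not reach the acceptance thresholds).
"""


class CathSFError(Exception):
    """Base class for all package errors."""


class StructureParseError(CathSFError):
    """A structure file is missing, unreadable, or lacks usable atoms."""


class ChainNotFoundError(StructureParseError):
    """The requested chain has no Cα atoms in the file."""


class MappingFailureError(CathSFError):
    """Domain-to-chain alignment fell below coverage/identity thresholds.

    Carries the achieved values so the caller can log why a domain became
    structure-unavailable.
    """

    def __init__(self, domain_id: str, coverage: float, identity: float,
                 min_coverage: float, min_identity: float):
        self.domain_id = domain_id
        self.coverage = coverage
        self.identity = identity
        super().__init__(
            f"alignment for domain {domain_id!r} achieved coverage "
            f"{coverage:.3f} (need >= {min_coverage}) and identity "
            f"{identity:.3f} (need >= {min_identity})"
        )


class IntegrityError(CathSFError):
    """Internal consistency violated (index out of range, duplicate ids,
    mismatched domain ids between channels)."""


class EncoderUnavailableError(CathSFError):
    """A structural-alphabet encoder cannot run (configuration problem)."""


class ChannelMismatchError(CathSFError):
    """Sequence alphabet or embedding channel does not match the consumer."""


class ConfigurationError(CathSFError):
    """An invalid parameter value or an operation whose preconditions make
    it meaningless (e.g. pLDDT filtering without structure metadata)."""


class EmptyDatasetError(CathSFError):
    """Filtering left the training set empty."""
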