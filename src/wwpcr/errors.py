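"""Exception hierarchy for wwpcr."""


class WWPCRError(Exception):
    """Base class for all wwpcr errors."""


class DegenerateBaseError(WWPCRError):
    """Sequence contains a non-ACGT (degenerate/IUPAC) character."""


class SequenceTooShortError(WWPCRError):
    """Sequence is below the minimum length for the requested operation."""


class MaskError(WWPCRError):
    """A pairing mask is inconsistent with the primer/site sequences."""


class DesignError(WWPCRError):
    """Primer design could not satisfy the requested constraints."""


class ProfileError(WWPCRError):
    """A cycling profile violates a structural constraint of the method."""


class SimulationError(WWPCRError):
    """Inconsistent inputs to the walking-PCR simulator."""


class FormatError(WWPCRError):
    """Malformed input file (FASTA, primer table, config)."""
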