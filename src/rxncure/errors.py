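"""Exception hierarchy for rxncure."""


class RxncureError(Exception):
    """Base class for all rxncure errors."""


class ReactionParseError(RxncureError):
    """A reaction record could not be parsed.

    Carries the opaque record identifier so the caller can drop and log
    the offending record.
    """

    def __init__(self, record_id, message):
        self.record_id = record_id
        super().__init__(f"record {record_id!r}: {message}")


class EmptyCoreError(RxncureError):
    """Every reactant of a reaction is a spectator; the record is unusable."""


class CgrIntegrityError(RxncureError):
    """Duplicate atom-map numbers on one side of a reaction."""


class NullTransformationError(RxncureError):
    """Reactants and products are identical under the mapping: no reaction
    center exists."""


class GenerationError(RxncureError):
    """A synthetic fixture family produced an invalid molecule."""


class ValenceLookupError(RxncureError, KeyError):
    """No allowed-valence entry for an (element, charge) pair."""
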