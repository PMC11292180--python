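"""Exception hierarchy for the broker.

All domain failures derive from :class:`TolBrokerError` so callers can
catch broker problems without swallowing programming errors.  Role
violations raise the builtin :class:`PermissionError`.
"""


class TolBrokerError(Exception):
    """Base class for all broker-domain errors."""


class VersionNotFound(TolBrokerError):
    """Requested schema version is not in the registry."""


class SchemaDefinitionError(TolBrokerError):
    """A schema document is malformed; the message names the field."""


class ExtensionConflict(TolBrokerError):
    """An extension redefines a core field incompatibly."""


class ManifestFormatError(TolBrokerError):
    """A manifest file cannot be parsed as a single-header table."""


class TaxonomyIntegrityError(TolBrokerError):
    """The taxonomy table violates its invariants (e.g. two MAIN names)."""


class GraphConstraintError(TolBrokerError):
    """A manifest breaks the specimen/sample relationship constraints."""


class ExportError(TolBrokerError):
    """An export cannot be produced (unknown format, missing taxon id)."""


class SubmissionRefused(TolBrokerError):
    """A manifest with a failed validation report was submitted."""


class InvalidTransition(TolBrokerError):
    """A lifecycle operation was applied to a sample in the wrong state."""


class AccessionError(TolBrokerError):
    """An accession minter produced a duplicate or is exhausted."""


class UpdateRejected(TolBrokerError):
    """A metadata update failed re-validation.

    Carries the offending :class:`~tolbroker.validate.ValidationIssue`
    objects on ``.issues``.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "update rejected: " + "; ".join(i.code for i in self.issues)
        )


class NotFound(TolBrokerError):
    """No sample or specimen matches the given key or accession."""


class FixtureConfigError(TolBrokerError):
    """A fixture generator was asked for an impossible configuration."""
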