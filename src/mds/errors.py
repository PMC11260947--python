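"""Exception hierarchy for the MDS toolkit.

Every error raised on purpose by this package derives from :class:`MdsError`,
so callers (and the CLI) can catch one base class. Errors that abort a batch
are distinguished from per-file conditions, which are reported, not raised:
a curation run over thousands of files must complete and say what it skipped.
"""


class MdsError(Exception):
    """Base class for all errors raised by the MDS toolkit."""


class MalformedName(MdsError):
    """A filename does not follow the ``<Pat>_<Acq>_<Phase>_<Tag>.<ext>`` grammar.

    Files with malformed names must be quarantined, never guessed at.
    """


class InvalidKey(MdsError):
    """A file key violates a token invariant and cannot be formatted."""


class InvalidTag(MdsError):
    """A tag token is empty or contains an underscore / path separator."""


class SourceMissing(MdsError):
    """The source directory handed to the structuring step does not exist."""


class CollisionError(MdsError):
    """A destination file already exists and the collision policy is ``error``."""


class MissingIdColumn(MdsError):
    """The clinical CSV lacks the configured patient-ID column."""


class DuplicatePatientRow(MdsError):
    """The clinical CSV contains two rows with the same patient ID."""


class MalformedId(MdsError):
    """A clinical CSV row carries an ID that is not a valid patient token."""


class BadHeader(MdsError):
    """A request or key CSV does not start with the expected header."""


class MalformedToken(MdsError):
    """A request CSV row contains a token that fails the filename grammar."""


class DuplicatePatient(MdsError):
    """The same patient appears twice in a pseudonym-assignment request."""


class OutputNotEmpty(MdsError):
    """The extraction output directory already contains files."""


class KeyPathMissing(MdsError):
    """De-identified extraction was requested without a path for the key log."""


class NotAnMdsTree(MdsError):
    """The given path is not a readable structured-dataset root."""


class AmbiguousExtension(MdsError):
    """More than one file extension matches a requested (patient, acquisition,
    phase, tag) stem, so the extractor cannot pick one."""


class UnknownCase(MdsError):
    """A corrected file carries a Case pseudonym absent from the key table."""


class TagCollision(MdsError):
    """A staged label filename already exists in the staging directory."""


class ShapeMismatch(MdsError):
    """Two volumes that must share a voxel grid have different shapes."""


class UnreadableVolume(MdsError):
    """A path could not be loaded as a 3D label volume."""


class OverlapWithoutPriority(MdsError):
    """Multi-label fusion of overlapping masks was requested without a
    priority order to resolve the overlap."""


class InfeasibleCounts(MdsError):
    """A requested confusion-count triple does not fit in the voxel grid."""
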