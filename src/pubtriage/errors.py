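"""Exception hierarchy for the triage pipeline.

Every error a pipeline stage can raise derives from :class:`PubtriageError`,
so callers (CLI, service layer) can report failures uniformly while still
distinguishing corpus problems from artifact problems.
"""


class PubtriageError(Exception):
    """Base class for all package errors."""


class CorpusError(PubtriageError):
    """Malformed or missing training-corpus input."""


class KeywordError(PubtriageError):
    """Invalid keyword file or keyword set."""


class ConfigError(PubtriageError):
    """Invalid parameter value (fractions, fold counts, thresholds...)."""


class ArtifactError(PubtriageError):
    """Base class for model/vocabulary artifact problems."""


class ArtifactNotFoundError(ArtifactError):
    """Artifact file does not exist."""


class ArtifactVersionError(ArtifactError):
    """Artifact has an unsupported schema version."""


class ArtifactCorruptError(ArtifactError):
    """Artifact content does not match its recorded checksum."""


class PipelineStageError(PubtriageError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
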