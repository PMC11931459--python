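"""Exception hierarchy for afmscreen.

Grouped by the pipeline stage that raises them so callers (and the CLI's
exit-code mapping) can distinguish malformed inputs from degenerate data.
"""


class AfmScreenError(Exception):
    """Base class for all afmscreen errors."""


class InputError(AfmScreenError):
    """Unreadable or malformed input (CLI exit code 2)."""


class StructureShapeError(InputError):
    """Structure does not have exactly two protein chains."""


class FormatError(InputError):
    """File could not be parsed in any supported dialect."""


class ConsistencyError(InputError):
    """Companion files disagree (e.g. PAE dimension vs residue count)."""


class EmptySetError(InputError):
    """No matched structure/score file pairs found."""


class ConfidenceMissingError(InputError):
    """An operation requires PAE or pLDDT data that is absent."""


class LookupError_(AfmScreenError):
    """Residue or key lookup failed."""


class DegenerateDataError(AfmScreenError):
    """Data is structurally valid but unusable (CLI exit code 3)."""


class TrainingError(DegenerateDataError):
    """Classifier training impossible (e.g. single-class labels)."""


class DegenerateModelError(DegenerateDataError):
    """Pruning removed every feature."""


class ScoringError(AfmScreenError):
    """Feature schema mismatch between model and scoring input."""


class ModelLoadError(AfmScreenError):
    """Persisted model artifact unreadable or version-incompatible."""
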