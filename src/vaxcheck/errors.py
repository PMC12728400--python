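"""Typed error hierarchy.

Every user-facing failure mode has its own exception class carrying a stable
``code`` token, so callers (and the CLI) can dispatch on error kind without
string-matching messages.
"""

from __future__ import annotations


class VaxcheckError(Exception):
    """Base class for all package errors."""

    code: str = "error"


# ---------------------------------------------------------------- profiles
class ProfileError(VaxcheckError):
    code = "profile-error"


class MissingRequiredFieldError(ProfileError):
    code = "missing-required-field"


class UnknownFieldError(ProfileError):
    code = "unknown-field"


class UnknownMedicationError(ProfileError):
    code = "unknown-medication"


class UnknownConditionError(ProfileError):
    code = "unknown-condition"


class ConditionalFieldViolationError(ProfileError):
    code = "conditional-field-violation"


class OutOfRangeDoseError(ProfileError):
    code = "out-of-range-dose"


class InvalidFieldValueError(ProfileError):
    code = "invalid-field-value"


# --------------------------------------------------------- knowledge base
class KnowledgeBaseError(VaxcheckError):
    code = "kb-error"


class KBParseError(KnowledgeBaseError):
    code = "parse-error"


class DanglingReferenceError(KnowledgeBaseError):
    code = "dangling-reference"


class DuplicateIdError(KnowledgeBaseError):
    code = "duplicate-id"


class DrugCountMismatchError(KnowledgeBaseError):
    code = "drug-count-mismatch"


class KBInvariantError(KnowledgeBaseError):
    code = "kb-invariant-violation"


# ---------------------------------------------------------- classification
class ClassificationError(VaxcheckError):
    code = "classification-error"


class MissingWeightError(ClassificationError):
    code = "missing-weight"


class UnknownDrugError(ClassificationError):
    code = "unknown-drug"


# ------------------------------------------------------------- rendering
class UnknownFormatError(VaxcheckError):
    code = "unknown-format"


# ------------------------------------------------------------ geospatial
class InvalidCoordinateError(VaxcheckError):
    code = "invalid-coordinate"


class EmptyRegistryError(VaxcheckError):
    code = "empty-registry"


class InvalidRadiusError(VaxcheckError):
    code = "invalid-radius"


# ------------------------------------------------------------ readability
class EmptyTextError(VaxcheckError):
    code = "empty-text"


class EmptyCorpusError(VaxcheckError):
    code = "empty-corpus"


# ------------------------------------------------------------- statistics
class StatsError(VaxcheckError):
    code = "stats-error"


class EmptyInputError(StatsError):
    code = "empty-input"


class MalformedSheetError(StatsError):
    code = "malformed-sheet"


class InsufficientNError(StatsError):
    code = "insufficient-n"


class ZeroVarianceError(StatsError):
    code = "zero-variance"


class InvalidParameterError(StatsError):
    code = "invalid-parameter"


# ---------------------------------------------------------------- cohorts
class InvalidSpecError(VaxcheckError):
    code = "invalid-spec"
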