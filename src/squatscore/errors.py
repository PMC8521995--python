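"""Exception hierarchy; each class carries the CLI exit code it maps to."""


class SquatScoreError(Exception):
    """Base class for all squatscore errors."""

    exit_code = 1


class PoseParseError(SquatScoreError):
    """Input could not be decoded at all (malformed JSON/CSV)."""

    exit_code = 3


class PoseSchemaError(SquatScoreError):
    """Input decoded but violates the pose schema (unknown part, missing column)."""

    exit_code = 3


class PoseValidationError(SquatScoreError):
    """Schema-valid input violating a semantic invariant (timestamps, duplicates)."""

    exit_code = 3


class TooShortError(SquatScoreError):
    """Series does not cover even one repetition round."""

    exit_code = 4


class StartNotFoundError(SquatScoreError):
    """No hip descent found, so the set start cue cannot be placed."""

    exit_code = 4


class UnusableSequenceError(SquatScoreError):
    """Too few confident samples (or too long a gap) to derive kinematics."""

    exit_code = 5


class DegeneratePostureError(SquatScoreError):
    """Baseline posture is impossible (hip at or below knee while standing)."""

    exit_code = 5


class UnknownPresetError(SquatScoreError):
    """Simulator preset name not recognised."""

    exit_code = 3


class SurveySchemaError(SquatScoreError):
    """Survey CSV row violates the closed category sets."""

    exit_code = 3
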