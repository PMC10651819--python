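"""Structured exceptions raised throughout the pipeline.

Every malformed input surfaces as one of these, never as a partially
loaded cohort or a silent NaN.
"""


class FrailtyKitError(Exception):
    """Base class for all frailtykit errors."""


class SchemaError(FrailtyKitError):
    """A table is missing required columns or carries unexpected ones."""


class CohortValidationError(FrailtyKitError):
    """A table parses but violates a cohort invariant.

    The message names the offending ``animal_id`` and field wherever
    one can be identified.
    """
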