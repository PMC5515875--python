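"""Exception hierarchy for the rootplates pipeline.

Every error raised by the package derives from :class:`RootPlatesError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class RootPlatesError(Exception):
    """Base class for all rootplates errors."""


class LabelParseError(RootPlatesError, ValueError):
    """A traced-structure label does not follow the seedNrtK grammar."""


class FilenameParseError(RootPlatesError, ValueError):
    """An export filename does not follow the '<date> <genotype> ... WW1 day0.csv' scheme."""


class ExportError(RootPlatesError, ValueError):
    """A CSV export is malformed (missing columns, bad lengths, duplicate labels)."""


class MergeError(RootPlatesError, ValueError):
    """A set of exports cannot be merged (mixed conditions/days, empty folder)."""


class ConsistencyError(RootPlatesError, ValueError):
    """Time-course records contradict each other (e.g. a root measured, then absent)."""


class ModelFitError(RootPlatesError, RuntimeError):
    """A treatment-contrast model could not be fitted."""


class PlotSpecError(RootPlatesError, ValueError):
    """A plot specification is empty or internally inconsistent."""


class SimParamError(RootPlatesError, ValueError):
    """Invalid simulation parameters; carries the offending field names."""

    def __init__(self, fields_and_messages):
        self.fields = [f for f, _ in fields_and_messages]
        msg = "; ".join(f"{f}: {m}" for f, m in fields_and_messages)
        super().__init__(f"invalid simulation parameters — {msg}")


class DataQualityWarning(UserWarning):
    """Non-fatal data oddity (e.g. a measured length that decreased between days)."""
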