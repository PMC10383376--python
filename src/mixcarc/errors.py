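"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`MixcarcError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class MixcarcError(Exception):
    """Base class for all mixcarc errors."""


class SmilesError(MixcarcError, ValueError):
    """A SMILES string failed to parse or encode."""


class RowValidationError(MixcarcError, ValueError):
    """A CSV row violated a record invariant; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class FormatError(MixcarcError, ValueError):
    """An input table is structurally malformed (e.g. missing a mandatory column)."""


class MappingError(MixcarcError, KeyError):
    """A (source, group) label is not in the documented label set."""


class CapacityError(MixcarcError, ValueError):
    """The synthetic generator cannot produce the requested number of unique structures."""


class CaseMismatchError(MixcarcError, ValueError):
    """Component labels do not match the pattern an assumption case requires."""


class InterclassError(MixcarcError, ValueError):
    """A multiclass mixture was requested across two different classes."""


class InfeasibleSplitError(MixcarcError, ValueError):
    """A compound split would leave a side with fewer than two chemicals."""


class LeakageError(MixcarcError, ValueError):
    """A chemical occurs in both the train and the test side of a disjoint evaluation."""

    def __init__(self, overlap):
        self.overlap = sorted(overlap)
        super().__init__(
            "chemicals present on both sides of a compound-disjoint split: "
            + ", ".join(self.overlap)
        )


class EmptyFeatureError(MixcarcError, ValueError):
    """Completeness filtering removed every descriptor column."""


class EncodingError(MixcarcError, ValueError):
    """A character cannot be tokenized, or a token vector is malformed."""


class DivergenceError(MixcarcError, RuntimeError):
    """Training produced a non-finite loss; carries the epoch index."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class ManifestError(MixcarcError, ValueError):
    """Prediction-time inputs are incompatible with the fitted feature manifest."""
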