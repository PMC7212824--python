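"""Exception types shared across the package."""


class DietOptError(Exception):
    """Base class for all package errors."""


class SchemaError(DietOptError):
    """An input table does not conform to the expected schema."""


class ValidationError(DietOptError):
    """A domain invariant is violated by the data."""


class CoverageError(DietOptError):
    """A required subcategory has no emission coefficient."""


class InfeasibleBoxError(DietOptError):
    """Intersected single-variable bounds are syntactically empty."""

    def __init__(self, subcategory_id: int, lb: float, ub: float):
        self.subcategory_id = subcategory_id
        self.lb = lb
        self.ub = ub
        super().__init__(
            f"empty bound intersection for subcategory {subcategory_id}: "
            f"lb={lb} > ub={ub}"
        )
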