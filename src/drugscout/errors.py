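"""Exception hierarchy shared across the package."""


class DrugscoutError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(DrugscoutError):
    """A SMILES string could not be parsed; carries the offending input id."""

    def __init__(self, input_id: str, smiles: str):
        self.input_id = input_id
        self.smiles = smiles
        super().__init__(f"unparsable SMILES for input {input_id!r}: {smiles!r}")


class RuleApplicationError(DrugscoutError):
    """A metabolic rule produced an unparsable product; carries the rule name."""

    def __init__(self, rule_name: str, detail: str = ""):
        self.rule_name = rule_name
        msg = f"metabolic rule {rule_name!r} produced an unparsable product"
        super().__init__(msg + (f": {detail}" if detail else ""))


class IntegrityError(DrugscoutError):
    """Referential-integrity violation in a loaded knowledge base."""


class FormatError(DrugscoutError):
    """A structured input file does not conform to its declared schema."""


class EnrichmentError(DrugscoutError):
    """Invalid enrichment inputs (bounds, empty query after restriction, ...)."""


class DesignError(DrugscoutError):
    """Invalid expression group design (missing samples, group too small, ...)."""


class FixtureError(DrugscoutError):
    """Synthetic-fixture generation could not satisfy its constraints."""


class PipelineStageError(DrugscoutError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.__cause__ = cause


class ConfigError(DrugscoutError):
    """Run configuration failed schema validation."""
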