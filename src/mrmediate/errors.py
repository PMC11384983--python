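"""Exception hierarchy for the MR pipeline.

Every error a pipeline stage can raise derives from :class:`MRError`, so the
orchestrator can record a per-exposure failure and move on without masking
programming errors (which stay plain Python exceptions).
"""


class MRError(Exception):
    """Base class for all pipeline-domain errors."""


class ConfigurationError(MRError):
    """A config/column-map problem detected before any computation."""


class EmptyInputError(MRError):
    """An input table contained zero valid rows."""


class EmptyInstrumentSetError(MRError):
    """Instrument selection emptied the candidate set.

    Carries ``stage``: the selection stage that removed the last record.
    """

    def __init__(self, trait_id: str, stage: str):
        self.trait_id = trait_id
        self.stage = stage
        super().__init__(
            f"no instruments left for trait {trait_id!r} after stage {stage!r}"
        )


class HarmonizationError(MRError):
    """Zero SNP pairs survived exposure/outcome harmonization."""


class InsufficientInstrumentsError(MRError):
    """An estimator was asked for fewer SNPs than its minimum."""

    def __init__(self, method: str, needed: int, got: int):
        self.method = method
        self.needed = needed
        self.got = got
        super().__init__(f"{method} needs >= {needed} SNPs, got {got}")


class DegenerateInstrumentError(MRError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""


class DegenerateCorrectionError(MRError):
    """Outlier correction would remove every instrument."""
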