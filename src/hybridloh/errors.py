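"""Exception hierarchy for hybridloh."""


class HybridLohError(Exception):
    """Base class for all hybridloh errors."""


class ConfigurationError(HybridLohError):
    """Invalid genome configuration (out-of-bounds intervals, bad fractions)."""


class PlanningError(HybridLohError):
    """An event plan cannot be realized on the given genome/annotation."""


class ParameterError(HybridLohError):
    """Invalid numeric parameter passed to a simulator or estimator."""


class InputError(HybridLohError):
    """Input table malformed or degenerate (e.g. all-zero counts)."""


class QualityError(HybridLohError):
    """Too many sites unclassifiable for reliable genotype calling."""

    def __init__(self, message, offending_sites=None):
        super().__init__(message)
        self.offending_sites = offending_sites


class ConsistencyError(HybridLohError):
    """Internal invariant violated (segments not covering a chromosome...)."""


class CalibrationError(HybridLohError):
    """Ladder calibration failed (peak/size mismatch, non-monotone sizes)."""


class PredictionError(HybridLohError):
    """Translocation prediction refused (no repeat element near breakpoint)."""
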