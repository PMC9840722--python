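"""Exception types raised across the pipeline."""


class PcctError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(PcctError):
    """Phantom/detector geometry violates a physical constraint."""


class DegenerateProfileError(PcctError):
    """A line profile has no (or too few) valid columns left."""


class VarianceUnavailableError(PcctError):
    """Fewer than two usable lines of interest; variance undefined."""


class ExtrapolationError(PcctError):
    """A temperature outside the support of a thermal series was requested."""


class IllConditionedBasisError(PcctError):
    """Basis LAC matrix is (near-)collinear; decomposition unreliable."""

    def __init__(self, condition_number: float):
        self.condition_number = condition_number
        super().__init__(
            f"basis matrix is ill-conditioned (cond = {condition_number:.3g})"
        )


class TrainingFailureError(PcctError):
    """Loss became non-finite during SGD."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
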