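"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A specification object violates one of its invariants."""


class SchemaError(ValueError):
    """A file does not conform to the expected column/field schema."""


class InfeasibleError(ValueError):
    """A design target cannot be met within the physical parameter range."""


class IntegrationBlowupError(RuntimeError):
    """The integrator produced non-finite state.

    Carries diagnostics: the step index at failure plus the largest force
    magnitude and speed observed in the offending block.
    """

    def __init__(self, step: int, max_force: float, max_speed: float):
        self.step = step
        self.max_force = max_force
        self.max_speed = max_speed
        super().__init__(
            f"integration blew up at step {step} "
            f"(max |F| = {max_force:.3g} N, max |v| = {max_speed:.3g} m/s); "
            "reduce the timestep or use the split_damping integrator"
        )


class FitError(RuntimeError):
    """A distribution fit failed (degenerate sample or non-convergence)."""
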