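"""Exception hierarchy for the gait simulator."""


class GaitModelError(Exception):
    """Base class for all model-level failures."""


class SingularMassMatrixError(GaitModelError):
    """The 2x2 acceleration system of the compass pendulum is numerically
    singular (condition number above the configured bound), e.g. at the
    inter-leg degeneracy phi -> 0."""


class IntegrationFailure(GaitModelError):
    """The ODE integrator failed (step-size underflow or solver abort)."""


class GroundPenetrationError(GaitModelError):
    """The centre of gravity reached y <= 0 during double stance."""


class NonWalkingParamsError(GaitModelError):
    """The parameter set does not produce a complete gait cycle.

    Carries the name of the phase that failed to terminate so the user
    can tell which half of the hybrid model is at fault.
    """

    def __init__(self, phase: str, message: str):
        self.phase = phase
        super().__init__(f"{phase}: {message}")


class UnreachableTargetError(GaitModelError):
    """Too many inverse-kinematics targets lie outside the leg's reach."""


class CCDConvergenceError(GaitModelError):
    """Cyclic coordinate descent did not reach the requested tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"CCD did not converge after {max_iter} iterations "
            f"(end-effector error {residual:.3e} m)"
        )


class IllConditionedBasisError(GaitModelError):
    """The Gaussian regression basis is numerically ill conditioned."""
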