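"""Published reference quantities for cross-axis saccade adaptation.

``REFERENCE_MODEL1`` and ``REFERENCE_MODEL2`` are the reported group-level
best-fit parameter sets for the two nine-parameter state-space models,
obtained by jointly fitting the acceleration- and deceleration-period
displacement series of the alternating-clamp and spontaneous-recovery
experiments.  They serve as simulation centers for synthetic cohorts and as
ground truth in round-trip identifiability checks.

``CONTROL_ACCEL_MS`` / ``CONTROL_DECEL_MS`` are the mean durations of the
acceleration and deceleration periods of unadapted control saccades to a
15-degree target (milliseconds); their ratio gives the fraction of movement
duration spent accelerating, the natural comparison point for the fitted
expression fraction p.
"""

from .statespace import Model1Params, Model2Params

REFERENCE_MODEL1 = Model1Params(
    a_slow=0.9963,
    a_fast=0.8071,
    b_slow0=0.002852,
    b_fast0=0.03267,
    d_slow=0.9481,
    d_fast=0.0599,
    p=0.3127,
    beta_slow=7.844e-6,
    beta_fast=9.397e-5,
)

REFERENCE_MODEL2 = Model2Params(
    a_aim=0.9817,
    a_acc=0.8680,
    a_dec=0.8433,
    b_aim0=0.0051,
    b_acc0=0.0063,
    b_dec0=0.0199,
    d_dec=0.1680,
    beta=0.0027,
    p=0.3088,
)

# mean control-saccade phase durations (ms) for 15-degree movements
CONTROL_ACCEL_MS = 20.71
CONTROL_DECEL_MS = 54.00
# same quantities for fully adapted saccades
ADAPTED_ACCEL_MS = 20.04
ADAPTED_DECEL_MS = 49.35


def acceleration_duration_fraction(accel_ms: float = CONTROL_ACCEL_MS,
                                   decel_ms: float = CONTROL_DECEL_MS) -> float:
    """Fraction of saccade duration spent in the acceleration period."""
    return accel_ms / (accel_ms + decel_ms)
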