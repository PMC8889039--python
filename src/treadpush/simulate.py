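"""Condition-level drivers: NO-EXO, NO-POWER and ACTIVE simulations."""

from __future__ import annotations

from .config import ExoGeometry, ExoParams, ModelConfig, default_config
from .planar_walker import Model, SimResult, build_model, integrate
from .reference_gait import GaitReference, KinematicAdjustment, adjust_reference, make_reference

CONDITIONS = ("NO-EXO", "NO-POWER", "ACTIVE")


def run_condition(
    condition: str = "NO-EXO",
    exo_params: ExoParams | None = None,
    exo_geometry: ExoGeometry | None = None,
    config: ModelConfig | None = None,
    reference: GaitReference | None = None,
    adjustment: KinematicAdjustment | None = None,
    n_cycles: int = 4,
    **integrate_kwargs,
) -> SimResult:
    """Simulate one study condition over ``n_cycles`` chained gait cycles.

    NO-EXO: bare model.  NO-POWER: the worn device adds its mass (0.8 kg
    split over shank and foot) but the brake never engages.  ACTIVE: mass
    plus phase-scheduled brake and elastic-tendon assistance.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    config = config or default_config()
    reference = reference or make_reference(n_cycles=n_cycles)
    if adjustment is not None:
        reference = adjust_reference(reference, adjustment)
    with_mass = condition in ("NO-POWER", "ACTIVE")
    model = build_model(config, with_exo_mass=with_mass)
    if condition == "ACTIVE":
        exo_params = exo_params or ExoParams()
    else:
        exo_params = None
    return integrate(
        model, reference, exo_params=exo_params, exo_geometry=exo_geometry,
        n_cycles=n_cycles, condition=condition, **integrate_kwargs,
    )


def build_default_model(with_exo_mass: bool = False) -> Model:
    return build_model(default_config(), with_exo_mass=with_exo_mass)
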