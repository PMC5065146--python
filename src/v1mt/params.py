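"""Model parameter registry.

Every constant of the V1->MT model lives in :class:`ModelParams` — gains of the
excitatory/inhibitory connections, activity thresholds, decay rates, delays and
the two clocks (frame interval vs. Euler time step).  No equation in the package
reads a constant from anywhere else.

Naming follows the conventions of the model: ``cx`` = complex V1 cells,
``es`` = end-stopped V1 cells, ``ig`` = MT integration cells, ``sg`` = MT
segmentation cells.  ``G_a_b`` is the gain of the connection from population
``b`` onto population ``a`` (``G_es_cx1`` is the first of two gains from
complex onto end-stopped cells, and so on).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "load_params", "save_params", "GA_PARAM_NAMES"]

#: Names of the free parameters fitted by the genetic algorithm, in the order
#: they are laid out on a GA chromosome.  ``tau_igsg`` sets both tau_ig and
#: tau_sg (the two decay rates are fitted as a single value).
GA_PARAM_NAMES = (
    "G_ig_cx",
    "G_ig_es",
    "G_sg_es",
    "G_ig_ig2",
    "G_ig_ig1",
    "G_ig_sg",
    "G_sg_sg",
    "G_sg_cx",
    "G_ig_ig3",
    "G_sg_ig",
    "tau_igsg",
)


@dataclass
class ModelParams:
    # --- end-stopped cell gains -------------------------------------------
    G_es_cx1: float = 2.0     # complex drive onto end-stopped cells
    G_es_cx2: float = 3.0     # same-direction surround inhibition (Gamma)
    G_es_es1: float = 1.0     # inter-directional inhibition (Omega)
    G_es_es2: float = 0.5     # long-range inhibition between ES cells (Lambda)
    # --- MT integration gains ---------------------------------------------
    G_ig_cx: float = 0.3      # complex V1 -> integration
    G_ig_es: float = 1.0      # end-stopped V1 -> integration
    G_ig_ig2: float = 0.1     # lateral excitation between integration cells
    G_ig_ig1: float = 0.741   # inter-directional inhibition (gamma)
    G_ig_ig3: float = 0.1     # long-range ring inhibition (zeta)
    G_ig_sg: float = 1.0      # segmentation -> integration inhibition
    # --- MT segmentation gains --------------------------------------------
    G_sg_cx: float = 1.0      # complex V1 -> segmentation
    G_sg_es: float = 1.0      # end-stopped V1 -> segmentation (inhibitory)
    G_sg_ig: float = 0.7      # integration -> segmentation excitation (eta)
    G_sg_sg: float = 1.0      # surround suppression between segmentation cells
    # --- thresholds --------------------------------------------------------
    rho_sg: float = 0.01      # segmentation activity threshold
    rho_ig: float = 0.1       # integration activity threshold
    rho_igig: float = 0.01    # neighbour-minus-self gate of lateral excitation
    rho_es: float = 0.008     # end-stopped activity threshold (Lambda sources)
    rho_cx: float = 0.01      # complex cell "active" threshold (Gamma gate)
    # --- decay rates (per ms) ---------------------------------------------
    tau_ig: float = 0.101
    tau_sg: float = 0.101
    tau_es: float = 0.01
    # --- clocks and delays (ms) -------------------------------------------
    dt: float = 0.1                 # Euler step of the neural dynamics
    T_es: float = 6.0               # delay of inhibition between ES cells
    T_ig: float = 6.0               # delay of inhibition between MT cells
    mt_frame_duration: float = 12.0  # dynamics simulated per stimulus frame
    frame_interval: float = 20.0     # stimulus frame interval
    # --- motion-energy front end ------------------------------------------
    n_directions: int = 8
    f_cyc_per_deg: float = 1.1      # carrier spatial frequency
    sigma_x: float = 0.5            # Gabor envelope deviations (degrees)
    sigma_y: float = 0.5
    pixels_per_degree: float = 4.0  # pixel scale: 4 px/deg -> ~4 px support
    spatial_radius: int = 4         # half-width of spatial kernels (pixels)
    tau_g_frames: float = 0.5       # temporal-filter time constant, in frames
    temporal_len: int = 12          # temporal kernel support (frames)
    energy_epsilon: float = 0.004   # semi-saturation of the opponent normalisation
    # normalisation pool of the complex-cell nonlinearity: "all" divides each
    # channel by the energy pooled over the four orientations at that pixel
    # (divisive normalisation), "pair" only by its own opponent pair
    norm_pool: str = "all"
    # opponent subtraction before normalisation: the directional signal is
    # [r - l]_+ (positive output = preferred direction, negative = opposite),
    # which cancels non-directional flicker energy; False normalises raw r, l
    opponent_subtraction: bool = True
    energy_floor: float = 1e-6      # opponent energy below this -> silent cell
    norm_squared_denominator: bool = False  # use (r^2+l^2) instead of sqrt
    # --- neighbourhood geometry (pixels) ----------------------------------
    gamma_radius: int = 8           # Gamma weight window (+-8)
    gamma_act_radius: int = 3       # Gamma activation-condition window (+-3)
    gamma_condition: str = "any"    # "any" | "mean" neighbour above rho_cx
    mu_sigma: float = 4.0           # Gaussian sigma of the Gamma weights
    mu_normalize: str = "peak"       # "sum": sum(mu)=1; "peak": mu(0,0)=1
    lambda_es_radius: int = 3       # ES long-range window (+-3)
    # source channels of the two inter-directional ES inhibition terms:
    # "other" sums the 7 other direction channels; "own" (Omega) /
    # "same" (Lambda) read the equations as printed, using the cell's own
    # channel (an activity-normalising suppression of strongly driven
    # channels rather than cross-channel competition)
    omega_mode: str = "own"
    lambda_es_mode: str = "other"
    # whether the Gamma / Lambda surround sums include the cell itself
    # ("lateral inhibition between neighbouring neurons" argues for excluding
    # the centre; the printed sums run over the full window)
    gamma_exclude_self: bool = False
    lambda_es_exclude_self: bool = False
    # inner radius of the Gamma weight matrix: weights within this Chebyshev
    # radius are zeroed, making the ES surround a true inhibitory end-zone
    # beyond the excitatory RF core (0 = full Gaussian window)
    mu_inner_radius: int = 2
    # complex activity a neighbour must exceed to count as a Gamma source
    # (the surround inhibition is driven by strongly active neighbours; weak
    # residual activity does not end-stop a cell)
    rho_gamma_source: float = 0.5
    excitation_radius: int = 6      # MT lateral-excitation window (+-6)
    ring_radius: int = 3            # MT long-range ring (Chebyshev distance 3)
    surround_center_radius: int = 3  # segmentation RF centre (7 px diameter)
    surround_outer_radius: int = 10  # surround extent
    surround_sigma: float = 2.0      # Gaussian weighting of the surround
    # --- segmentation cells -------------------------------------------------
    sg_baseline: float = 0.005      # spontaneous steady-state activity
    # activity level above which segmentation cells take part in the
    # centre-surround interaction (the literal model uses rho_sg)
    rho_chi: float = 0.01
    annulus_normalize: bool = True  # normalise surround weights to sum 1
    chi_e_enabled: bool = False     # undefined excitatory surround term; off
    # segmentation cells pool their complex-cell input over the 7-pixel RF
    # centre (Gaussian, radius = surround_center_radius).  The pooled drive
    # extends the high-segmentation "wall" a few pixels beyond the stimulus
    # border, which is what stops lateral excitation (reach +-6) from
    # spreading integration activity into the still background.
    sg_input_pooling: bool = True
    sg_center_sigma: float = 1.75
    # --- integration scheme ------------------------------------------------
    clip_mode: str = "state"        # "state": v<-h(v+dt*rhs); "derivative"
    # how the inhibition delays T_es/T_ig act: "onset" = inhibitory terms are
    # zero until T after stimulus onset and instantaneous afterwards (the
    # competition starts only once activity has developed); "lookup" = the
    # terms are evaluated on the state at t - T via a delay line
    delay_mode: str = "onset"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if f_.name.startswith(("G_", "tau", "rho")) and not isinstance(v, str):
                if v < 0:
                    raise ValueError(f"{f_.name} must be >= 0, got {v}")
        if not (0 < self.dt <= min(self.T_es, self.T_ig)):
            raise ValueError("require 0 < dt <= min(T_es, T_ig)")
        if self.n_directions != 8:
            raise ValueError("the model is defined for 8 direction channels")
        if self.mu_normalize not in ("sum", "peak"):
            raise ValueError("mu_normalize must be 'sum' or 'peak'")
        if self.gamma_condition not in ("any", "mean"):
            raise ValueError("gamma_condition must be 'any' or 'mean'")
        if self.clip_mode not in ("state", "derivative"):
            raise ValueError("clip_mode must be 'state' or 'derivative'")
        if self.delay_mode not in ("onset", "lookup"):
            raise ValueError("delay_mode must be 'onset' or 'lookup'")
        if self.omega_mode not in ("other", "own"):
            raise ValueError("omega_mode must be 'other' or 'own'")
        if self.lambda_es_mode not in ("other", "same"):
            raise ValueError("lambda_es_mode must be 'other' or 'same'")
        if self.surround_center_radius >= self.surround_outer_radius:
            raise ValueError("surround centre must be smaller than its extent")

    # -- GA chromosome <-> params ------------------------------------------
    def ga_vector(self) -> list[float]:
        out = []
        for name in GA_PARAM_NAMES:
            out.append(self.tau_ig if name == "tau_igsg" else getattr(self, name))
        return out

    def with_ga_vector(self, vec) -> "ModelParams":
        if len(vec) != len(GA_PARAM_NAMES):
            raise ValueError(f"expected {len(GA_PARAM_NAMES)} values")
        p = self.copy()
        for name, v in zip(GA_PARAM_NAMES, vec):
            if name == "tau_igsg":
                p.tau_ig = p.tau_sg = float(v)
            else:
                setattr(p, name, float(v))
        p.validate()
        return p

    def copy(self, **overrides: Any) -> "ModelParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    # provenance: which keys were set by the user rather than defaulted
    user_set: frozenset = field(default_factory=frozenset, repr=False, compare=False)


_VALID_KEYS = {f.name for f in dataclasses.fields(ModelParams)} - {"user_set"}


def load_params(path: str | Path | None = None, **overrides: Any) -> ModelParams:
    """Build a :class:`ModelParams` from a flat YAML file plus overrides.

    An empty or missing-key file yields the reference defaults.  Unknown keys
    and invalid values fail loudly.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat mapping")
        data.update(raw)
    data.update(overrides)
    unknown = set(data) - _VALID_KEYS
    if unknown:
        raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
    p = ModelParams(**data)
    p.user_set = frozenset(data)
    return p


def save_params(p: ModelParams, path: str | Path) -> None:
    d = p.to_dict()
    d.pop("user_set", None)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
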