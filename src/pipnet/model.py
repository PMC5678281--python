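"""Reaction network for class I PI3K-driven phosphoinositide turnover.

The network follows the minimal scheme needed to explain EGF-stimulated
PI(3,4,5)P3 and PI(3,4)P2 dynamics in Mcf10a cells: EGF activates EGFR,
active EGFR activates class I PI3K, PI3K phosphorylates PI(4,5)P2 to
PI(3,4,5)P3, and a set of lipid phosphatases (PTEN, SHIP2, a lumped
5-phosphatase pool X, INPP4B and an unknown residual phosphatase Y)
dephosphorylate PI(3,4,5)P3 and PI(3,4)P2. A constitutive PI4P/PI(4,5)P2
futile cycle buffers the PI(4,5)P2 pool and zeroth-order PI4P synthesis
from the (effectively infinite) PI reservoir closes the system.

Concentrations are in arbitrary units normalised so that basal PI(4,5)P2
is 100 a.u.; time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "Species",
    "Enzyme",
    "RateLaw",
    "ReactionSpec",
    "ModelSpec",
    "Genotype",
    "InhibitorEvent",
    "SPECIES_ORDER",
    "CONSTANT_SPECIES",
    "build_reference_network",
    "apply_genotype",
    "reaction_rate",
    "rhs",
    "stoichiometry_matrix",
]


class Species(str, Enum):
    """Identifiers of the model species (state variables plus inputs)."""

    EGF = "EGF"
    EGFR_INACTIVE = "EGFR_inactive"
    EGFR_ACTIVE = "EGFR_active"
    PI3K_INACTIVE = "PI3K_inactive"
    PI3K_ACTIVE = "PI3K_active"
    PI45P2 = "PI45P2"
    PIP3 = "PIP3"
    PI34P2 = "PI34P2"
    PI34P2_BG = "PI34P2_BG"
    PI4P = "PI4P"
    PI3P = "PI3P"


#: Canonical state-vector ordering used by the integrator.
SPECIES_ORDER: tuple[Species, ...] = tuple(Species)

#: Species that never change along a trajectory.  The EGF-insensitive
#: background PI(3,4)P2 pool participates in no reaction; it is added to
#: the PI(3,4)P2 observable only.
CONSTANT_SPECIES: frozenset[Species] = frozenset({Species.PI34P2_BG})


class Enzyme(str, Enum):
    """Catalytic route labels.

    ``RECEPTOR_MACHINERY`` covers ligand clearance and the receptor/PI3K
    (de)activation steps; ``BASAL`` covers constitutive lipid housekeeping
    (synthesis, futile cycling, sinks).
    """

    PI3K = "PI3K"
    PTEN = "PTEN"
    SHIP2 = "SHIP2"
    X = "X"
    INPP4B = "INPP4B"
    Y = "Y"
    RECEPTOR_MACHINERY = "receptor_machinery"
    BASAL = "basal"


#: Enzymes a genotype may modulate (dephosphorylation routes and PI3K).
PERTURBABLE_ENZYMES: frozenset[Enzyme] = frozenset(
    {Enzyme.PI3K, Enzyme.PTEN, Enzyme.SHIP2, Enzyme.X, Enzyme.INPP4B, Enzyme.Y}
)


@dataclass(frozen=True)
class RateLaw:
    """A single-substrate rate law.

    kind
        ``mass_action``: flux = k * [S]  (k in 1/s per unit enzyme activity)
        ``michaelis_menten``: flux = vmax * [S] / (km + [S])
        ``zeroth_order``: flux = v  (constant source, used for PI4P synthesis
        from the PI reservoir, which is treated as infinite)
    """

    kind: str
    k: float = 0.0
    vmax: float = 0.0
    km: float = 1.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action", "michaelis_menten", "zeroth_order"):
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        if self.k < 0 or self.vmax < 0 or self.v < 0:
            raise ValueError("rate constants must be non-negative")
        if self.kind == "michaelis_menten" and self.km <= 0:
            raise ValueError("Km must be positive")

    def evaluate(self, substrate_conc: float) -> float:
        if substrate_conc < 0:
            raise ValueError(f"negative substrate concentration {substrate_conc}")
        if self.kind == "mass_action":
            return self.k * substrate_conc
        if self.kind == "michaelis_menten":
            return self.vmax * substrate_conc / (self.km + substrate_conc)
        return self.v


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: a single-substrate conversion with an optional activator.

    ``substrate is None`` denotes a zeroth-order source and ``product is
    None`` a sink.  ``activator`` multiplies the rate by the activator's
    concentration (receptor/PI3K activation and PI3K catalysis).
    ``pi3k_effective`` marks reactions whose rate is scaled by the
    residual-PI3K factor after an inhibitor event: both the formation of
    active PI3K and its catalytic use, so that inhibition acts on the
    concentration of effective PI3K.
    """

    id: str
    substrate: Optional[Species]
    product: Optional[Species]
    enzyme: Enzyme
    rate_law: RateLaw
    activator: Optional[Species] = None
    pi3k_effective: bool = False


@dataclass(frozen=True)
class Genotype:
    """A genetic perturbation as enzyme-activity multipliers.

    Knockout (KO) is multiplier 0.0 exactly; knockdown (KD) is the residual
    activity fraction (default 0.1 in the panel definitions); wild type
    omits the enzyme (multiplier 1).
    """

    name: str
    activity_overrides: Mapping[Enzyme, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for enzyme, mult in self.activity_overrides.items():
            if not isinstance(enzyme, Enzyme):
                raise KeyError(f"unknown enzyme label {enzyme!r}")
            if not 0.0 <= mult <= 1.0:
                raise ValueError(
                    f"activity multiplier for {enzyme.value} must be in [0, 1], got {mult}"
                )


@dataclass(frozen=True)
class InhibitorEvent:
    """Timed PI3K inhibition (PI-103-style).

    From ``time`` on, the effective active-PI3K concentration is scaled by
    ``residual_pi3k_fraction`` and stays scaled for the rest of the
    simulation.  Complete inhibition at 1 uM is residual 0.
    """

    time: float = 60.0
    residual_pi3k_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if not 0.0 <= self.residual_pi3k_fraction <= 1.0:
            raise ValueError("residual PI3K fraction must be in [0, 1]")


@dataclass(frozen=True)
class ModelSpec:
    """The full model: reactions, initial state, activities and constants."""

    reactions: tuple[ReactionSpec, ...]
    initial_state: Mapping[Species, float]
    enzyme_activities: Mapping[Enzyme, float] = field(default_factory=dict)
    egf_dose: float = 1.0
    pi34p2_background: float = 5.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        declared = set(Species)
        for rx in self.reactions:
            for sp in (rx.substrate, rx.product, rx.activator):
                if sp is not None and sp not in declared:
                    raise ValueError(f"reaction {rx.id} references unknown species {sp}")
            if rx.substrate is Species.PI34P2_BG or rx.product is Species.PI34P2_BG:
                raise ValueError("the background PI(3,4)P2 pool is constant: no reactions")
        for sp, c in self.initial_state.items():
            if c < 0:
                raise ValueError(f"negative initial concentration for {sp}")

    def activity(self, enzyme: Enzyme) -> float:
        return float(self.enzyme_activities.get(enzyme, 1.0))

    def reaction(self, reaction_id: str) -> ReactionSpec:
        for rx in self.reactions:
            if rx.id == reaction_id:
                return rx
        raise KeyError(reaction_id)


def apply_genotype(model: ModelSpec, genotype: Genotype) -> ModelSpec:
    """Return a new model with activities scaled by the genotype multipliers.

    Multipliers compose multiplicatively with whatever the model already
    carries, so applying a KO (multiplier 0) twice is the same as once.
    The input model is not modified.
    """
    activities = {e: model.activity(e) for e in Enzyme}
    for enzyme, mult in genotype.activity_overrides.items():
        if not isinstance(enzyme, Enzyme):
            raise KeyError(f"unknown enzyme label {enzyme!r}")
        activities[enzyme] = activities[enzyme] * float(mult)
    return replace(model, enzyme_activities=activities)


def reaction_rate(
    reaction: ReactionSpec,
    state: Mapping[Species, float],
    activity: float = 1.0,
    inhibitor_factor: float = 1.0,
) -> float:
    """Instantaneous flux of one reaction at one state (a.u./s).

    The base rate law is evaluated on the substrate concentration,
    multiplied by the activator concentration for activation/catalysis
    steps, by the enzyme-activity multiplier, and by the residual-PI3K
    factor for inhibitor-sensitive steps.  Never negative.
    """
    conc = 1.0 if reaction.substrate is None else float(state[reaction.substrate])
    if conc < 0:
        raise ValueError(
            f"negative concentration for {reaction.substrate} in reaction {reaction.id}"
        )
    rate = reaction.rate_law.evaluate(conc)
    if reaction.activator is not None:
        act_conc = float(state[reaction.activator])
        if act_conc < 0:
            raise ValueError(f"negative activator concentration in reaction {reaction.id}")
        rate *= act_conc
    if reaction.pi3k_effective:
        rate *= inhibitor_factor
    return max(rate * activity, 0.0)


def rhs(
    model: ModelSpec,
    state: Mapping[Species, float],
    time: float = 0.0,
    events: Sequence[InhibitorEvent] = (),
) -> dict[Species, float]:
    """Time derivative of every species: signed sum of reaction fluxes.

    The background pool's derivative is identically zero.  After an
    inhibitor event the PI3K-effective reactions are scaled by the event's
    residual fraction.
    """
    phi = 1.0
    for ev in events:
        if time >= ev.time:
            phi *= ev.residual_pi3k_fraction
    deriv = {sp: 0.0 for sp in Species}
    for rx in model.reactions:
        flux = reaction_rate(rx, state, model.activity(rx.enzyme), phi)
        if rx.substrate is not None:
            deriv[rx.substrate] -= flux
        if rx.product is not None:
            deriv[rx.product] += flux
    deriv[Species.PI34P2_BG] = 0.0
    return deriv


def stoichiometry_matrix(model: ModelSpec):
    """(n_species, n_reactions) signed stoichiometry array (numpy)."""
    import numpy as np

    mat = np.zeros((len(SPECIES_ORDER), len(model.reactions)))
    index = {sp: i for i, sp in enumerate(SPECIES_ORDER)}
    for j, rx in enumerate(model.reactions):
        if rx.substrate is not None:
            mat[index[rx.substrate], j] -= 1.0
        if rx.product is not None:
            mat[index[rx.product], j] += 1.0
    return mat


# ---------------------------------------------------------------------------
# Reference network construction
# ---------------------------------------------------------------------------

#: Default rate constants of the reference network.  Units: first-order
#: constants 1/s (per unit activator concentration where an activator is
#: present); zeroth-order source a.u./s; Km and pool sizes a.u.  The
#: phosphatase constants are set so that the PI(3,4,5)P3 routes carry
#: (SHIP2+X):PTEN = 1.4 and SHIP2:X = 2.65, and the PI(3,4)P2 routes split
#: PTEN:INPP4B:Y = 57:37.4:5.6 at the wild-type response peak; the cascade
#: constants place the PI(3,4,5)P3 peak near 60 s with a decline over
#: minutes driven by ligand clearance.
DEFAULT_PARAMS: dict[str, float] = {
    # input / receptor / PI3K cascade
    "k_egf_clearance": 0.0052,
    "k_egfr_activation": 0.10,
    "k_egfr_desensitization": 0.05,
    "k_pi3k_activation": 0.022,
    "k_pi3k_deactivation": 0.030,
    "k_pi3k_basal_activation": 0.0002,
    "k_pi3k_catalysis": 0.0150,
    # PI(3,4,5)P3 dephosphorylation routes
    "k_pten_pip3": 0.145833,
    "k_ship2_pip3": 0.148242,
    "k_x_pip3": 0.055940,
    # PI(3,4)P2 dephosphorylation routes
    "k_inpp4b": 0.1797,
    "k_pten_pi34p2": 0.2736,
    "vmax_y": 0.014990,
    "km_y": 0.05,
    # linear-range equivalent of the Y route (vmax_y at the WT peak substrate
    # level), used when the fully linear variant is requested
    "k_y_linear": 0.028800,
    # housekeeping lipid metabolism
    "v_pi4p_synthesis": 0.0211,
    "k_pip5k": 0.010,
    "k_pip2_5ptase": 0.005,
    "k_pi4p_sink": 0.0004,
    "k_pi3p_sink": 0.010,
    # pools and constants
    "egfr_total": 1.0,
    "pi3k_total": 1.0,
    "pi45p2_basal": 100.0,
    "pi34p2_background": 5.0,
}


def _phosphatase_law(k: float, saturable: bool, km: float) -> RateLaw:
    if saturable:
        return RateLaw("michaelis_menten", vmax=k * km, km=km)
    return RateLaw("mass_action", k=k)


def build_reference_network(
    params: Optional[Mapping[str, float]] = None,
    *,
    phosphatase_rate_law: str = "mass_action",
    saturable_km: float = 1000.0,
    y_saturable: bool = False,
    y_product: Species = Species.PI4P,
    include_direct_pi4p_route: bool = False,
    egf_dose: float = 1.0,
    provenance: str = "reference-network",
) -> ModelSpec:
    """Construct the canonical minimal network.

    By default all named phosphatases use mass-action (linear-range)
    kinetics, the variant selected by fitting the measured panel.  A fully
    saturable variant of the same network is obtained with
    ``phosphatase_rate_law="michaelis_menten"`` (each phosphatase k becomes
    vmax/km with ``saturable_km``, preserving the linear limit when Km is
    far above the substrate excursion).  ``y_saturable`` gives only the
    unknown phosphatase Y a saturable rate law with the calibrated low Km;
    this is the reference configuration (see docs/methods.md).

    ``y_product`` routes Y's output (PI4P by default: a 3-phosphatase-like
    activity, as its candidate identities are PTEN-family enzymes).
    ``include_direct_pi4p_route`` adds the class I PI3K PI4P->PI(3,4)P2
    shunt, off by default because the measured panel does not require it.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        p.update(params)
    if y_product not in (Species.PI4P, Species.PI3P):
        raise ValueError("Y product must be PI4P or PI3P")
    saturable = phosphatase_rate_law == "michaelis_menten"

    def phos(k: float) -> RateLaw:
        return _phosphatase_law(k, saturable, saturable_km)

    reactions = [
        ReactionSpec(
            "egf_clearance", Species.EGF, None, Enzyme.RECEPTOR_MACHINERY,
            RateLaw("mass_action", k=p["k_egf_clearance"]),
        ),
        ReactionSpec(
            "egfr_activation", Species.EGFR_INACTIVE, Species.EGFR_ACTIVE,
            Enzyme.RECEPTOR_MACHINERY,
            RateLaw("mass_action", k=p["k_egfr_activation"]), activator=Species.EGF,
        ),
        ReactionSpec(
            "egfr_desensitization", Species.EGFR_ACTIVE, Species.EGFR_INACTIVE,
            Enzyme.RECEPTOR_MACHINERY,
            RateLaw("mass_action", k=p["k_egfr_desensitization"]),
        ),
        ReactionSpec(
            "pi3k_activation", Species.PI3K_INACTIVE, Species.PI3K_ACTIVE,
            Enzyme.RECEPTOR_MACHINERY,
            RateLaw("mass_action", k=p["k_pi3k_activation"]),
            activator=Species.EGFR_ACTIVE, pi3k_effective=True,
        ),
        ReactionSpec(
            "pi3k_basal_activation", Species.PI3K_INACTIVE, Species.PI3K_ACTIVE,
            Enzyme.RECEPTOR_MACHINERY,
            RateLaw("mass_action", k=p["k_pi3k_basal_activation"]),
            pi3k_effective=True,
        ),
        ReactionSpec(
            "pi3k_deactivation", Species.PI3K_ACTIVE, Species.PI3K_INACTIVE,
            Enzyme.RECEPTOR_MACHINERY,
            RateLaw("mass_action", k=p["k_pi3k_deactivation"]),
        ),
        ReactionSpec(
            "pi3k_pip3_synthesis", Species.PI45P2, Species.PIP3, Enzyme.PI3K,
            RateLaw("mass_action", k=p["k_pi3k_catalysis"]),
            activator=Species.PI3K_ACTIVE, pi3k_effective=True,
        ),
        ReactionSpec(
            "pten_pip3", Species.PIP3, Species.PI45P2, Enzyme.PTEN,
            phos(p["k_pten_pip3"]),
        ),
        ReactionSpec(
            "ship2_pip3", Species.PIP3, Species.PI34P2, Enzyme.SHIP2,
            phos(p["k_ship2_pip3"]),
        ),
        ReactionSpec(
            "x_pip3", Species.PIP3, Species.PI34P2, Enzyme.X,
            phos(p["k_x_pip3"]),
        ),
        ReactionSpec(
            "inpp4b_pi34p2", Species.PI34P2, Species.PI3P, Enzyme.INPP4B,
            phos(p["k_inpp4b"]),
        ),
        ReactionSpec(
            "pten_pi34p2", Species.PI34P2, Species.PI4P, Enzyme.PTEN,
            phos(p["k_pten_pi34p2"]),
        ),
        ReactionSpec(
            "y_pi34p2", Species.PI34P2, y_product, Enzyme.Y,
            RateLaw("michaelis_menten", vmax=p["vmax_y"], km=p["km_y"])
            if y_saturable
            else phos(p["k_y_linear"]),
        ),
        ReactionSpec(
            "pi4p_synthesis", None, Species.PI4P, Enzyme.BASAL,
            RateLaw("zeroth_order", v=p["v_pi4p_synthesis"]),
        ),
        ReactionSpec(
            "pip5k_pi45p2_synthesis", Species.PI4P, Species.PI45P2, Enzyme.BASAL,
            RateLaw("mass_action", k=p["k_pip5k"]),
        ),
        ReactionSpec(
            "pi45p2_5ptase", Species.PI45P2, Species.PI4P, Enzyme.BASAL,
            RateLaw("mass_action", k=p["k_pip2_5ptase"]),
        ),
        ReactionSpec(
            "pi4p_sink", Species.PI4P, None, Enzyme.BASAL,
            RateLaw("mass_action", k=p["k_pi4p_sink"]),
        ),
        ReactionSpec(
            "pi3p_sink", Species.PI3P, None, Enzyme.BASAL,
            RateLaw("mass_action", k=p["k_pi3p_sink"]),
        ),
    ]
    if include_direct_pi4p_route:
        reactions.append(
            ReactionSpec(
                "pi3k_pi4p_direct", Species.PI4P, Species.PI34P2, Enzyme.PI3K,
                RateLaw("mass_action", k=0.0),
                activator=Species.PI3K_ACTIVE, pi3k_effective=True,
            )
        )

    pi4p_basal = (p["v_pi4p_synthesis"] + p["k_pip2_5ptase"] * p["pi45p2_basal"]) / (
        p["k_pip5k"] + p["k_pi4p_sink"]
    )
    initial_state = {
        Species.EGF: 0.0,
        Species.EGFR_INACTIVE: p["egfr_total"],
        Species.EGFR_ACTIVE: 0.0,
        Species.PI3K_INACTIVE: p["pi3k_total"],
        Species.PI3K_ACTIVE: 0.0,
        Species.PI45P2: p["pi45p2_basal"],
        Species.PIP3: 0.0,
        Species.PI34P2: 0.0,
        Species.PI34P2_BG: p["pi34p2_background"],
        Species.PI4P: pi4p_basal,
        Species.PI3P: 0.0,
    }
    return ModelSpec(
        reactions=tuple(reactions),
        initial_state=initial_state,
        enzyme_activities={e: 1.0 for e in Enzyme},
        egf_dose=egf_dose,
        pi34p2_background=p["pi34p2_background"],
        provenance=provenance,
    )
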