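"""Kinetic schemes for origin-licensing experiments.

Each experiment class (ORC alone, ORC + Cdc6, quencher-DNA OCCM assays,
Mcm2-7 FRET assays with DNA dyes at -4/+51/+82, ORC-ACS assays, ATPase and
WHD mutants) is described by a labeled-state continuous-time Markov chain
over one DNA molecule, together with the FRET/quench photophysics of each
state.  Default rate constants are tuned so that the aggregate observables
(apparent dissociation rates, unbent-state occupancy, unbending and
deposition delays, event ordering) match the published single-molecule
measurements they emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["KineticScheme", "default_scheme", "VARIANTS"]

# Aggregate apparent ORC dissociation rates (s^-1): ORC alone and with Cdc6.
K_OFF_APP_ORC = 0.0131
K_OFF_APP_ORC_CDC6 = 0.0073
CDC6_STABILIZATION = K_OFF_APP_ORC_CDC6 / K_OFF_APP_ORC

# Per-state decomposition of the ORC-alone aggregate.  With an unbent:bent
# release ratio of 45 and a true unbent dwell-time fraction f_u = 0.005,
# the renewal identity (events per unit bound time = sum of state time
# fractions times state off-rates) fixes the off-rates:
# 0.995 * 0.01074 + 0.005 * 0.4832 = 0.01310 s^-1.
# The bend-fluctuation rates are then solved so that the *absorbing* chain
# (dissociation included) really spends fraction 0.005 of a bound dwell in
# the unbent state, with a 1-s mean unbent visit (k_rebend + k_off,unbent
# = 1 s^-1): mean bound dwell = 1/0.0131 s exactly.
K_OFF_BENT = 0.01074
K_OFF_UNBENT = 0.4832
K_UNBEND_ORC = 0.0050251
K_REBEND_ORC = 0.5168

# Helicase-loading steps (s^-1).
MEAN_UNBEND_DELAY_S = 3.9   # Mcm2-7 arrival -> DNA unbending
MEAN_DEPOSIT_DELAY_S = 1.0  # unbending -> deposition (arrival->deposition ~4.9 s)
K_UNBEND_OCCM = 1.0 / MEAN_UNBEND_DELAY_S
K_DEPOSIT = 1.0 / MEAN_DEPOSIT_DELAY_S
K_CDC6_RELEASE = 0.05
K_SLIDE_ONSET_WT = 0.05
K_SLIDE_ONSET_RA = 0.005
K_CDT1_RELEASE = 0.02
K_ORC_ARRIVAL = 0.02
K_MCM_ARRIVAL = 0.03

# State E_FRET values for the dye pairs with published fit centers.
E_ORC_C51_BENT = 0.62
E_ORC_C51_UNBENT = 0.05
E_MCM51_PREDEPOSIT = 0.12
E_MCM51_DEPOSITED = 0.55
E_ORCN_ACS = 0.60
E_ORCN_POST_CDT1 = 0.02

QUENCH_BENT = 0.80  # donor quench factor while the BPR quencher is proximal

# Dye-pair geometry defaults.  The Mcm3 N-terminal dye rides on the N-tier
# face of the ~13-nm hexamer, well off the DNA axis: its axial offset is set
# so that the closest sliding approach to a DNA dye gives E ~ 0.6, just
# above the deposited-state value (E = 0.55 at ~4 bp lateral separation).
# A small offset would instead let sliding transients reach E ~ 1, a regime
# the deposited-state dye pair never shows.
FORSTER_RADIUS_NM = 6.0
BP_TO_NM = 0.34
DEPOSIT_POSITION_BP = 46.9   # Mcm2-7 position after deposition (ACS origin)
DIFFUSION_BP2_S = 100.0
SLIDING_BOUNDS_BP = (-300.0, 1100.0)
MCM_AXIAL_OFFSET_NM = 5.63
# ORC^N carries its dye on the large N-face of the complex; the bigger axial
# offset makes the ACS-engaged state E = 0.60 for a dye at -4 bp.
ORCN_AXIAL_OFFSET_NM = 5.639
ORCN_PROTEIN_OFFSET_BP = -35.0


@dataclass(frozen=True)
class KineticScheme:
    """Continuous-time Markov model of one DNA molecule's licensing pathway.

    Parameters
    ----------
    variant_id : str
        Experiment label (see :data:`VARIANTS`).
    states : tuple of str
        All state labels; the first entries fix iteration order.
    rates : dict
        ``(from_state, to_state) -> rate constant`` in 1/s; all >= 0.
    efret_map : dict
        ``state -> true E_FRET`` for states whose dye-pair distance is fixed.
        Sliding-capable states are listed in ``sliding_states`` instead and
        get their E_FRET from the instantaneous sliding position.
    quench_map : dict
        ``state -> donor quench factor`` in [0, 1] (quencher-DNA assays).
    initial_state : str
        State occupied at t = 0.
    sliding_states : frozenset of str
        States in which the complex diffuses on DNA.
    event_states : dict
        ``event name -> state`` whose first entry timestamps the event.
    dye_position_bp : float or None
        DNA-coupled dye position (bp from the first ACS base; -4/+51/+82).
    protein_offset_bp, axial_offset_nm : float
        Protein label position relative to the complex position, and its
        offset from the DNA axis (added in quadrature).
    """

    variant_id: str
    states: tuple[str, ...]
    rates: dict[tuple[str, str], float]
    efret_map: dict[str, float]
    quench_map: dict[str, float] = field(default_factory=dict)
    initial_state: str = "unbound"
    sliding_states: frozenset[str] = frozenset()
    event_states: dict[str, str] = field(default_factory=dict)
    dye_position_bp: float | None = None
    protein_offset_bp: float = 0.0
    axial_offset_nm: float = MCM_AXIAL_OFFSET_NM
    deposit_position_bp: float = DEPOSIT_POSITION_BP
    diffusion_coeff: float = DIFFUSION_BP2_S
    bounds: tuple[float, float] = SLIDING_BOUNDS_BP
    forster_radius_nm: float = FORSTER_RADIUS_NM
    bp_to_nm: float = BP_TO_NM
    unbound_states: frozenset[str] = frozenset({"unbound", "dissociated"})

    def __post_init__(self):
        for (a, b), k in self.rates.items():
            if k < 0:
                raise ValueError(f"negative rate for {a}->{b}: {k}")
            if a not in self.states or b not in self.states:
                raise ValueError(f"rate references unknown state: {a}->{b}")
        for s, e in self.efret_map.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"E_FRET out of [0,1] for state {s}: {e}")

    def out_rates(self, state: str) -> list[tuple[str, float]]:
        return [(b, k) for (a, b), k in self.rates.items() if a == state and k > 0]

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q with Q[i, j] = rate i->j, diagonal = -row sum."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for (a, b), k in self.rates.items():
            q[idx[a], idx[b]] += k
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q

    def stationary_distribution(self) -> dict[str, float]:
        """Stationary distribution of a conservative (recurrent) scheme.

        Solves pi Q = 0 with sum(pi) = 1; raises if the chain has an
        absorbing state (no stationary distribution of interest).
        """
        q = self.rate_matrix()
        diag = -q.diagonal()
        absorbing = [s for s, d in zip(self.states, diag) if d == 0]
        if absorbing:
            raise ValueError(f"absorbing states present: {absorbing}")
        a = np.vstack([q.T, np.ones(len(self.states))])
        b = np.zeros(len(self.states) + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return dict(zip(self.states, pi))

    def is_bound(self, state: str) -> bool:
        return state not in self.unbound_states

    def scale_rates(self, factor: float, transitions) -> "KineticScheme":
        """Return a copy with the listed transitions' rates multiplied."""
        rates = dict(self.rates)
        for tr in transitions:
            rates[tr] = rates[tr] * factor
        return replace(self, rates=rates)


def _orc_only() -> KineticScheme:
    states = ("unbound", "ORC_bent", "ORC_unbent", "dissociated")
    rates = {
        ("unbound", "ORC_bent"): K_ORC_ARRIVAL,
        ("ORC_bent", "ORC_unbent"): K_UNBEND_ORC,
        ("ORC_unbent", "ORC_bent"): K_REBEND_ORC,
        ("ORC_bent", "dissociated"): K_OFF_BENT,
        ("ORC_unbent", "dissociated"): K_OFF_UNBENT,
    }
    return KineticScheme(
        variant_id="ORC_only",
        states=states,
        rates=rates,
        efret_map={"ORC_bent": E_ORC_C51_BENT, "ORC_unbent": E_ORC_C51_UNBENT},
        event_states={"orc_arrival": "ORC_bent", "off": "dissociated"},
        dye_position_bp=51.0,
    )


def _orc_cdc6() -> KineticScheme:
    base = _orc_only()
    scheme = base.scale_rates(
        CDC6_STABILIZATION,
        [("ORC_bent", "dissociated"), ("ORC_unbent", "dissociated")],
    )
    return replace(scheme, variant_id="ORC_Cdc6")


def _occm_quench(k_unbend: float = K_UNBEND_OCCM) -> KineticScheme:
    # Donor on ORC^C, Black-Hole quencher at +51: bent states quench the
    # donor; unbending unquenches it.  Mcm2-7 carries a red-excited label.
    states = (
        "unbound", "ORC_bent", "ORC_unbent_pre", "OCCM_bent",
        "OCCM_unbent", "OCCM_deposited", "dissociated",
    )
    off = CDC6_STABILIZATION
    rates = {
        ("unbound", "ORC_bent"): K_ORC_ARRIVAL,
        ("ORC_bent", "ORC_unbent_pre"): K_UNBEND_ORC,
        ("ORC_unbent_pre", "ORC_bent"): K_REBEND_ORC,
        ("ORC_bent", "dissociated"): K_OFF_BENT * off,
        ("ORC_unbent_pre", "dissociated"): K_OFF_UNBENT * off,
        ("ORC_bent", "OCCM_bent"): K_MCM_ARRIVAL,
        ("OCCM_bent", "OCCM_unbent"): k_unbend,
        ("OCCM_unbent", "OCCM_deposited"): K_DEPOSIT,
    }
    return KineticScheme(
        variant_id="OCCM_quench",
        states=states,
        rates=rates,
        efret_map={},
        quench_map={
            "ORC_bent": QUENCH_BENT,
            "OCCM_bent": QUENCH_BENT,
            "ORC_unbent_pre": 0.0,
            "OCCM_unbent": 0.0,
            "OCCM_deposited": 0.0,
        },
        event_states={
            "orc_arrival": "ORC_bent",
            "mcm_arrival": "OCCM_bent",
            "unbend": "OCCM_unbent",
            "deposit": "OCCM_deposited",
            "off": "dissociated",
        },
        dye_position_bp=51.0,
    )


def _mcm_fret(dye_bp: float, variant_id: str,
              k_slide: float = K_SLIDE_ONSET_WT) -> KineticScheme:
    # Donor on Mcm3 N terminus; acceptor on DNA at -4, +51 or +82.  The
    # molecule is followed from first Mcm2-7 arrival; all events lead to a
    # salt-stable loaded helicase (no dissociation branch).
    states = (
        "unbound", "OCCM_bent", "OCCM_unbent", "OCCM_deposited",
        "OC1M_deposited", "OC1M_sliding", "postCdt1_sliding",
    )
    rates = {
        ("unbound", "OCCM_bent"): K_MCM_ARRIVAL,
        ("OCCM_bent", "OCCM_unbent"): K_UNBEND_OCCM,
        ("OCCM_unbent", "OCCM_deposited"): K_DEPOSIT,
        ("OCCM_deposited", "OC1M_deposited"): K_CDC6_RELEASE,
        ("OC1M_deposited", "OC1M_sliding"): k_slide,
        ("OC1M_sliding", "postCdt1_sliding"): K_CDT1_RELEASE,
    }
    if dye_bp == 51.0:
        e_pre, e_dep = E_MCM51_PREDEPOSIT, E_MCM51_DEPOSITED
    else:
        # distant dye: pre-sliding E set by geometry from the deposit position
        from .simulate import efret_from_distance, dye_pair_distance
        r = dye_pair_distance(DEPOSIT_POSITION_BP, dye_bp,
                              axial_offset_nm=MCM_AXIAL_OFFSET_NM)
        e_pre = e_dep = efret_from_distance(r, FORSTER_RADIUS_NM)
    return KineticScheme(
        variant_id=variant_id,
        states=states,
        rates=rates,
        efret_map={
            "OCCM_bent": e_pre,
            "OCCM_unbent": e_pre,
            "OCCM_deposited": e_dep,
            "OC1M_deposited": e_dep,
        },
        sliding_states=frozenset({"OC1M_sliding", "postCdt1_sliding"}),
        event_states={
            "mcm_arrival": "OCCM_bent",
            "unbend": "OCCM_unbent",
            "deposit": "OCCM_deposited",
            "cdc6_release": "OC1M_deposited",
            "slide_onset": "OC1M_sliding",
            "cdt1_release": "postCdt1_sliding",
        },
        dye_position_bp=dye_bp,
    )


def _orcn_m4() -> KineticScheme:
    # Donor on the ORC N-face, acceptor at -4 (ACS-proximal).  E_FRET is high
    # while ORC engages the ACS, follows the sliding position in the OC1M
    # state, and collapses after Cdt1 release (ORC leaves the ACS for good).
    states = (
        "unbound", "ORC_acs", "OCCM_bent", "OCCM_unbent", "OCCM_deposited",
        "OC1M_deposited", "OC1M_sliding", "postCdt1",
    )
    rates = {
        ("unbound", "ORC_acs"): K_ORC_ARRIVAL,
        ("ORC_acs", "OCCM_bent"): K_MCM_ARRIVAL,
        ("OCCM_bent", "OCCM_unbent"): K_UNBEND_OCCM,
        ("OCCM_unbent", "OCCM_deposited"): K_DEPOSIT,
        ("OCCM_deposited", "OC1M_deposited"): K_CDC6_RELEASE,
        ("OC1M_deposited", "OC1M_sliding"): K_SLIDE_ONSET_WT,
        ("OC1M_sliding", "postCdt1"): K_CDT1_RELEASE,
    }
    high = {s: E_ORCN_ACS for s in
            ("ORC_acs", "OCCM_bent", "OCCM_unbent", "OCCM_deposited",
             "OC1M_deposited")}
    high["postCdt1"] = E_ORCN_POST_CDT1
    return KineticScheme(
        variant_id="ORCN_m4",
        states=states,
        rates=rates,
        efret_map=high,
        sliding_states=frozenset({"OC1M_sliding"}),
        event_states={
            "orc_arrival": "ORC_acs",
            "mcm_arrival": "OCCM_bent",
            "unbend": "OCCM_unbent",
            "deposit": "OCCM_deposited",
            "cdc6_release": "OC1M_deposited",
            "slide_onset": "OC1M_sliding",
            "cdt1_release": "postCdt1",
        },
        dye_position_bp=-4.0,
        protein_offset_bp=ORCN_PROTEIN_OFFSET_BP,
        axial_offset_nm=ORCN_AXIAL_OFFSET_NM,
    )


def _whd_del_quench() -> KineticScheme:
    # Mcm4/6 WHD truncations nearly abolish unbending.
    scheme = _occm_quench(k_unbend=1e-4)
    return replace(scheme, variant_id="WHD_del_quench")


VARIANTS = {
    "ORC_only": _orc_only,
    "ORC_Cdc6": _orc_cdc6,
    "OCCM_quench": _occm_quench,
    "MCM_51": lambda: _mcm_fret(51.0, "MCM_51"),
    "MCM_m4": lambda: _mcm_fret(-4.0, "MCM_m4"),
    "MCM_p82": lambda: _mcm_fret(82.0, "MCM_p82"),
    "ORCN_m4": _orcn_m4,
    "ATPase_RA_51": lambda: _mcm_fret(51.0, "ATPase_RA_51",
                                      k_slide=K_SLIDE_ONSET_RA),
    "WHD_del_quench": _whd_del_quench,
}


def default_scheme(variant_id: str) -> KineticScheme:
    """Return the tuned default kinetic scheme for an experiment class.

    Raises
    ------
    ValueError
        If ``variant_id`` is not a recognized label; the message lists the
        valid labels.
    """
    try:
        factory = VARIANTS[variant_id]
    except KeyError:
        valid = ", ".join(sorted(VARIANTS))
        raise ValueError(
            f"unknown variant {variant_id!r}; valid labels: {valid}"
        ) from None
    return factory()
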