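"""Mass-action TXTL reaction network construction and ODE right-hand side.

The default reaction scheme, per transcription unit *i* (all species in nM):

====  =====================================================  ==================
R1    DNA_i + Pol  <=>  C_tx,i                               kf_tx, kr_tx
R2    C_tx,i  ->  DNA_i + Pol + mRNA_i                       (k_tx_elong / L_nt)
                                                             * [NTP]/(K_NTP+[NTP]),
                                                             consumes L_nt NTP
R3    mRNA_i + Ribo  <=>  C_tl,i          (translatable)     kf_rbs, kr_rbs
R4    C_tl,i  ->  mRNA_i + Ribo + P_i                        (k_tl_elong / L_aa)
                                                             * [AA]/(K_AA+[AA]),
                                                             consumes L_aa AA
R5    mRNA_i + RNase  <=>  C_deg,i                           kf_nuc, kr_nuc
R6    C_deg,i  ->  RNase        (mRNA destroyed)             k_deg
R7    P_i  ->  F_i              (maturation, if k_mat > 0)   k_mat
====  =====================================================  ==================

Only free mRNA binds ribonuclease (ribosome-bound mRNA is protected), and
elongation rates scale inversely with transcript/protein length.  The lumped
toxin obeys  d[toxin]/dt = sum(source rates) - b  where the source is the sum
of translation (R4) or transcription (R2) rates depending on the mechanism
variant, and the targeted free resource pool is degraded at
``k_toxin * (1 + tanh([toxin] - threshold)) * [target]``.  The toxin level is
deliberately not clipped at zero.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .units import PromoterSpec, ResourceSpec, ToxinConfig, TranscriptionUnitSpec

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "NetworkError",
    "build_network",
    "evaluate_rhs",
    "toxin_gate",
    "conservation_totals",
    "GLOBAL_SPECIES",
]

GLOBAL_SPECIES = ("RNAP_native", "RNAP_T7", "Ribo", "RNase", "NTP", "AA", "toxin")


class NetworkError(ValueError):
    """Raised for structurally invalid network declarations or states."""


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: mass-action with optional saturation/gate.

    rate = k * prod(reactant concentrations) * [pool]/(K + [pool]) * gate
    where k resolves from the parameter set entry ``k_name`` (falling back to
    ``k_default``) times ``scale`` (the 1/length factor for elongation steps).
    ``gated`` marks toxin-driven degradation; a reaction with no reactants is
    zeroth-order (the constant toxin drain at rate b).
    """

    name: str
    stoich: Mapping[str, float]
    k_name: str
    k_default: float
    reactants: tuple[str, ...] = ()
    scale: float = 1.0
    sat_pool: str | None = None
    sat_K_name: str | None = None
    gated: bool = False

    def rate_law(self) -> str:
        parts = [self.k_name]
        if self.scale != 1.0:
            parts[0] = f"({self.k_name}*{self.scale:g})"
        parts += [f"[{r}]" for r in self.reactants]
        if self.sat_pool:
            parts.append(f"[{self.sat_pool}]/({self.sat_K_name}+[{self.sat_pool}])")
        if self.gated:
            parts.append("(1+tanh([toxin]-toxin_threshold))")
        return "*".join(parts)


class ReactionNetwork:
    """Compiled species list, stoichiometry and rate laws for one model."""

    def __init__(
        self,
        units: list[TranscriptionUnitSpec],
        resources: ResourceSpec,
        toxin: ToxinConfig,
        species: list[str],
        reactions: list[Reaction],
    ):
        self.units = list(units)
        self.resources = resources
        self.toxin = toxin
        self.species = list(species)
        self.reactions = list(reactions)
        self.species_index = {s: i for i, s in enumerate(species)}
        S = np.zeros((len(species), len(reactions)))
        for j, rxn in enumerate(reactions):
            for sp, coeff in rxn.stoich.items():
                S[self.species_index[sp], j] += coeff
        self.stoichiometry = S
        self._compiled: dict[tuple, "_CompiledRHS"] = {}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def rate_laws(self) -> list[str]:
        return [r.rate_law() for r in self.reactions]

    @property
    def toxin_coupling(self) -> dict:
        """Source flux and degradation targets of the toxin mechanism."""
        return {
            "variant": self.toxin.variant,
            "source": self.toxin.source,
            "targets": _toxin_targets(self.toxin),
        }

    def unit(self, unit_id: str) -> TranscriptionUnitSpec:
        for u in self.units:
            if u.id == unit_id:
                return u
        raise KeyError(f"unknown unit id {unit_id!r}")

    # -- parameter resolution -------------------------------------------------

    def resolved_rate_constants(self, params: Mapping[str, float] | None) -> np.ndarray:
        params = params or {}
        return np.array(
            [r.scale * params.get(r.k_name, r.k_default) for r in self.reactions]
        )

    def compile(self, params: Mapping[str, float] | None = None) -> "_CompiledRHS":
        key = tuple(sorted((params or {}).items()))
        cached = self._compiled.get(key)
        if cached is None:
            cached = _CompiledRHS(self, params or {})
            if len(self._compiled) > 8:
                self._compiled.clear()
            self._compiled[key] = cached
        return cached

    def initial_state(
        self,
        params: Mapping[str, float] | None = None,
        dna_doses: Mapping[str, float] | None = None,
        rna_doses: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """State vector at t=0: resource pools plus DNA/mRNA bolus doses."""
        params = params or {}
        y0 = np.zeros(self.n_species)
        res = self.resources
        for name, attr in (
            ("RNAP_native", "RNAP0_native"),
            ("RNAP_T7", "RNAP0_T7"),
            ("Ribo", "Ribo0"),
            ("RNase", "RNase0"),
            ("NTP", "NTP0"),
            ("AA", "AA0"),
        ):
            y0[self.species_index[name]] = params.get(attr, getattr(res, attr))
        for unit_id, dose in (dna_doses or {}).items():
            if dose < 0:
                raise NetworkError(f"negative DNA dose for {unit_id!r}")
            y0[self.species_index[f"DNA_{self.unit(unit_id).id}"]] = dose
        for unit_id, dose in (rna_doses or {}).items():
            if dose < 0:
                raise NetworkError(f"negative RNA dose for {unit_id!r}")
            y0[self.species_index[f"mRNA_{self.unit(unit_id).id}"]] = dose
        return y0


def _toxin_targets(toxin: ToxinConfig) -> tuple[str, ...]:
    if toxin.target == "TL":
        return ("Ribo",)
    if toxin.target == "TX":
        return ("RNAP_native", "RNAP_T7")
    return ()


def _unit_species(unit: TranscriptionUnitSpec) -> list[str]:
    sp = [f"DNA_{unit.id}", f"C_tx_{unit.id}", f"mRNA_{unit.id}"]
    if unit.translatable:
        sp.append(f"C_tl_{unit.id}")
        sp.append(f"P_{unit.id}")
        if unit.k_mat > 0:
            sp.append(f"F_{unit.id}")
    sp.append(f"C_deg_{unit.id}")
    return sp


def build_network(
    units: list[TranscriptionUnitSpec],
    resources: ResourceSpec | None = None,
    toxin: ToxinConfig | None = None,
) -> ReactionNetwork:
    """Compile transcription units + resource pools into a reaction network.

    Raises :class:`NetworkError` on duplicate unit ids.  The network always
    contains the 7 global species and the constant toxin drain; per-unit
    species and reactions follow the default scheme in the module docstring.
    """
    resources = resources or ResourceSpec()
    toxin = toxin or ToxinConfig()
    ids = [u.id for u in units]
    if len(set(ids)) != len(ids):
        raise NetworkError(f"duplicate unit ids in {ids}")

    species = list(GLOBAL_SPECIES)
    for u in units:
        species.extend(_unit_species(u))

    reactions: list[Reaction] = []
    for u in units:
        pol = "RNAP_T7" if u.promoter.polymerase_class == "T7" else "RNAP_native"
        pname = u.promoter.name
        dna, ctx, mrna = f"DNA_{u.id}", f"C_tx_{u.id}", f"mRNA_{u.id}"
        cdeg = f"C_deg_{u.id}"
        reactions.append(
            Reaction(
                f"bind_tx_{u.id}",
                {dna: -1, pol: -1, ctx: +1},
                f"kf_tx_{pname}",
                u.promoter.kf_tx,
                (dna, pol),
            )
        )
        reactions.append(
            Reaction(
                f"unbind_tx_{u.id}",
                {ctx: -1, dna: +1, pol: +1},
                f"kr_tx_{pname}",
                u.promoter.kr_tx,
                (ctx,),
            )
        )
        tx_stoich = {ctx: -1, dna: +1, pol: +1, mrna: +1, "NTP": -float(u.transcript_length)}
        if toxin.source == "TX":
            tx_stoich["toxin"] = +1
        reactions.append(
            Reaction(
                f"tx_{u.id}",
                tx_stoich,
                "k_tx_elong",
                40.0,
                (ctx,),
                scale=1.0 / u.transcript_length,
                sat_pool="NTP",
                sat_K_name="K_NTP",
            )
        )
        if u.translatable:
            ctl, prot = f"C_tl_{u.id}", f"P_{u.id}"
            reactions.append(
                Reaction(
                    f"bind_rbs_{u.id}",
                    {mrna: -1, "Ribo": -1, ctl: +1},
                    f"kf_rbs_{u.cargo}",
                    u.kf_rbs,
                    (mrna, "Ribo"),
                )
            )
            reactions.append(
                Reaction(
                    f"unbind_rbs_{u.id}",
                    {ctl: -1, mrna: +1, "Ribo": +1},
                    f"kr_rbs_{u.cargo}",
                    u.kr_rbs,
                    (ctl,),
                )
            )
            tl_stoich = {ctl: -1, mrna: +1, "Ribo": +1, prot: +1, "AA": -float(u.protein_length)}
            if toxin.source == "TL":
                tl_stoich["toxin"] = +1
            reactions.append(
                Reaction(
                    f"tl_{u.id}",
                    tl_stoich,
                    "k_tl_elong",
                    4.0,
                    (ctl,),
                    scale=1.0 / u.protein_length,
                    sat_pool="AA",
                    sat_K_name="K_AA",
                )
            )
            if u.k_mat > 0:
                reactions.append(
                    Reaction(
                        f"mat_{u.id}",
                        {prot: -1, f"F_{u.id}": +1},
                        f"k_mat_{u.cargo}",
                        u.k_mat,
                        (prot,),
                    )
                )
        reactions.append(
            Reaction(
                f"bind_nuc_{u.id}",
                {mrna: -1, "RNase": -1, cdeg: +1},
                f"kf_nuc_{u.cargo}",
                u.kf_nuc,
                (mrna, "RNase"),
            )
        )
        reactions.append(
            Reaction(
                f"unbind_nuc_{u.id}",
                {cdeg: -1, mrna: +1, "RNase": +1},
                f"kr_nuc_{u.cargo}",
                u.kr_nuc,
                (cdeg,),
            )
        )
        reactions.append(
            Reaction(
                f"deg_{u.id}",
                {cdeg: -1, "RNase": +1},
                f"k_deg_{u.cargo}",
                u.k_deg,
                (cdeg,),
            )
        )

    # toxin drain: zeroth-order buffering at rate b (always present)
    reactions.append(Reaction("toxin_drain", {"toxin": -1}, "b", toxin.b, ()))
    # gated toxin-driven degradation of the targeted free resource pool(s)
    for target in _toxin_targets(toxin):
        reactions.append(
            Reaction(
                f"toxin_deg_{target}",
                {target: -1},
                "k_toxin",
                toxin.k_toxin,
                (target,),
                gated=True,
            )
        )
    return ReactionNetwork(units, resources, toxin, species, reactions)


class _CompiledRHS:
    """Vectorised rate evaluation:  dy/dt = S @ rates(y)."""

    def __init__(self, network: ReactionNetwork, params: Mapping[str, float]):
        self.network = network
        n_rxn = len(network.reactions)
        self.k = network.resolved_rate_constants(params)
        idx = network.species_index
        # reactant index arrays; -1 indexes the trailing 1.0 of the extended state
        r = np.full((n_rxn, 2), -1, dtype=int)
        for j, rxn in enumerate(network.reactions):
            for m, sp in enumerate(rxn.reactants[:2]):
                r[j, m] = idx[sp]
        self.r1, self.r2 = r[:, 0], r[:, 1]
        sat_rows, sat_idx, sat_K = [], [], []
        for j, rxn in enumerate(network.reactions):
            if rxn.sat_pool is not None:
                sat_rows.append(j)
                sat_idx.append(idx[rxn.sat_pool])
                default_K = getattr(network.resources, rxn.sat_K_name)
                sat_K.append(params.get(rxn.sat_K_name, default_K))
        self.sat_rows = np.array(sat_rows, dtype=int)
        self.sat_idx = np.array(sat_idx, dtype=int)
        self.sat_K = np.array(sat_K)
        self.gate_rows = np.array(
            [j for j, rxn in enumerate(network.reactions) if rxn.gated], dtype=int
        )
        self.toxin_idx = idx["toxin"]
        tox = network.toxin
        self.toxin_threshold = params.get("toxin_threshold", tox.toxin_threshold)
        self.S = network.stoichiometry

    def rates(self, y: np.ndarray) -> np.ndarray:
        ye = np.append(y, 1.0)
        rates = self.k * ye[self.r1] * ye[self.r2]
        if self.sat_rows.size:
            pool = ye[self.sat_idx]
            rates[self.sat_rows] *= pool / (self.sat_K + pool)
        if self.gate_rows.size:
            gate = 1.0 + math.tanh(y[self.toxin_idx] - self.toxin_threshold)
            rates[self.gate_rows] *= gate
        return rates

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(y)


def evaluate_rhs(
    network: ReactionNetwork,
    state: np.ndarray,
    params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Species time-derivatives at ``state`` (stoichiometry x rate vector)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise NetworkError(
            f"state has shape {state.shape}, expected ({network.n_species},)"
        )
    if not np.all(np.isfinite(state)):
        raise NetworkError("state contains non-finite entries")
    return network.compile(params)(0.0, state)


def toxin_gate(toxin_level: float, config: ToxinConfig) -> float:
    """Dimensionless gate 1 + tanh([toxin] - threshold), in (0, 2)."""
    return 1.0 + math.tanh(toxin_level - config.toxin_threshold)


def conservation_totals(network: ReactionNetwork, state: np.ndarray) -> dict[str, float]:
    """Free + bound totals of each conserved machinery pool.

    With the toxin mechanism inactive (k_toxin = 0) these are exact invariants
    of the dynamics; toxin-driven degradation removes the targeted pool.
    """
    state = np.asarray(state, dtype=float)
    idx = network.species_index
    totals = {
        "RNAP_native": state[idx["RNAP_native"]],
        "RNAP_T7": state[idx["RNAP_T7"]],
        "Ribo": state[idx["Ribo"]],
        "RNase": state[idx["RNase"]],
    }
    for u in network.units:
        pol = "RNAP_T7" if u.promoter.polymerase_class == "T7" else "RNAP_native"
        totals[pol] += state[idx[f"C_tx_{u.id}"]]
        if u.translatable:
            totals["Ribo"] += state[idx[f"C_tl_{u.id}"]]
        totals["RNase"] += state[idx[f"C_deg_{u.id}"]]
    return totals
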