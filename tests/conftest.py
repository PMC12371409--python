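import numpy as np
import pytest

from txtlcrosstalk import (
    CrosstalkModel,
    ResourceSpec,
    ToxinConfig,
    TranscriptionUnitSpec,
    build_network,
    default_promoters,
    default_registry,
)
from txtlcrosstalk.parameters import reference_parameters


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_model():
    return CrosstalkModel.default()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def one_unit_translatable():
    """A single sfGFP-like translatable unit on the strong T7 promoter."""
    prom = default_promoters()["T7_strong"]
    return TranscriptionUnitSpec(
        id="rep",
        promoter=prom,
        transcript_length=900,
        translatable=True,
        protein_length=250,
        kf_rbs=1e-3,
        kr_rbs=0.1,
        kf_nuc=1e-2,
        kr_nuc=0.1,
        k_deg=0.05,
        k_mat=1.5e-3,
        readout="mature_protein",
        cargo="sfGFP",
    )


@pytest.fixture
def one_unit_untranslated():
    prom = default_promoters()["sig70_strong"]
    return TranscriptionUnitSpec(
        id="apt",
        promoter=prom,
        transcript_length=200,
        translatable=False,
        kf_nuc=1e-2,
        kr_nuc=0.1,
        k_deg=0.05,
        readout="free_rna",
        cargo="aptamer",
    )


def naive_rhs(network, state, params):
    """Independent brute-force oracle: stoichiometry x rates, recomputed
    reaction-by-reaction from the declared rate laws with plain Python."""
    import math

    params = dict(params or {})
    idx = network.species_index
    deriv = [0.0] * network.n_species
    for rxn in network.reactions:
        k = params.get(rxn.k_name, rxn.k_default) * rxn.scale
        rate = k
        for sp in rxn.reactants:
            rate *= state[idx[sp]]
        if rxn.sat_pool is not None:
            pool = state[idx[rxn.sat_pool]]
            K = params.get(rxn.sat_K_name, getattr(network.resources, rxn.sat_K_name))
            rate *= pool / (K + pool)
        if rxn.gated:
            thr = params.get("toxin_threshold", network.toxin.toxin_threshold)
            rate *= 1.0 + math.tanh(state[idx["toxin"]] - thr)
        for sp, coeff in rxn.stoich.items():
            deriv[idx[sp]] += coeff * rate
    return np.array(deriv)


def rk4_integrate(f, y0, t_grid, h):
    """Fixed-step classic Runge-Kutta reference integrator."""
    y = np.asarray(y0, dtype=float).copy()
    out = [y.copy()]
    t = t_grid[0]
    for t_next in t_grid[1:]:
        while t < t_next - 1e-12:
            step = min(h, t_next - t)
            k1 = f(t, y)
            k2 = f(t + step / 2, y + step / 2 * k1)
            k3 = f(t + step / 2, y + step / 2 * k2)
            k4 = f(t + step, y + step * k3)
            y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
        out.append(y.copy())
    return np.array(out).T
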