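import numpy as np
import pytest
from hypothesis import settings

import glk
from glk.kinetics import (
    KineticAssembly,
    LinlogModel,
    Provenance,
    assign_concentrations,
    assign_elasticities,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def chain3():
    net, known = glk.make_fixture(glk.FixtureSpec("chain", size=3))
    return net, known


@pytest.fixture
def diamond():
    net, known = glk.make_fixture(glk.FixtureSpec("diamond"))
    return net, known


@pytest.fixture
def moiety_cycle():
    net, known = glk.make_fixture(glk.FixtureSpec("moiety-cycle"))
    return net, known


def centred_problem(net, known):
    """FluxProblem for a fixture with its defining constraints applied."""
    p = glk.problem_from_network(net)
    if "targets" in known:
        p.targets = dict(known["targets"])
    if "export_reaction" in known:
        j = p.column(known["export_reaction"])
        p.lower_bounds[j] = 1.0
        p.upper_bounds[j] = 1.0
    return p


def assemble_fixture(net, v_star, known_conc=None, seed=0,
                     known_eps=None):
    """Build a KineticAssembly/LinlogModel around a given reference flux.

    Reference concentrations are drawn reproducibly in (0.1, 2) mM unless
    given; elasticities use the tendency-modelling defaults unless
    overridden.
    """
    N, row, col = glk.build_stoichiometric_matrix(net)
    met_ids = [m for m, _ in sorted(row.items(), key=lambda kv: kv[1])]
    rxn_ids = [r for r, _ in sorted(col.items(), key=lambda kv: kv[1])]
    rng = np.random.default_rng(seed)
    if known_conc is None:
        known_conc = {m: float(rng.uniform(0.1, 2.0)) for m in met_ids}
    x_star, x_prov, _ = assign_concentrations(met_ids, known_conc)
    reversible = [net.reaction(r).reversible for r in rxn_ids]
    eps, eps_prov = assign_elasticities(N, met_ids, rxn_ids, reversible,
                                        known_eps)
    comp = net.compartments_by_id
    sp = net.species_by_id
    volumes = np.array([comp[sp[m].compartment].volume for m in met_ids])
    assembly = KineticAssembly(
        metabolite_ids=met_ids, reaction_ids=rxn_ids,
        x_star=x_star, x_provenance=x_prov,
        v_star=np.asarray(v_star, dtype=float),
        epsilon_scaled=eps, epsilon_provenance=eps_prov,
        volumes=volumes,
    )
    return assembly, LinlogModel(assembly=assembly, N=N)


def random_steady_network(seed, m=10, n=15):
    """Random sparse N (m x n) with a steady-state flux from its null space.

    Independent oracle-side construction: the null space is computed with
    scipy's SVD-based null_space, not with any package machinery.
    """
    from scipy.linalg import null_space

    rng = np.random.default_rng(seed)
    while True:
        N = np.zeros((m, n))
        for j in range(n):
            rows = rng.choice(m, size=rng.integers(2, 4), replace=False)
            N[rows, j] = rng.integers(-2, 3, size=rows.size)
        if np.any(np.all(N == 0, axis=0)) or np.any(np.all(N == 0, axis=1)):
            continue
        ns = null_space(N)
        if ns.shape[1] == 0:
            continue
        v = ns @ rng.normal(size=ns.shape[1])
        if np.max(np.abs(v)) < 1e-6:
            continue
        return N, v


def random_epsilon_prime(seed, N, v_star, x_star=None):
    """eps' = diag(v*) . eps^T . diag(1/x*) with random scaled elasticities."""
    rng = np.random.default_rng(seed + 1)
    m, n = N.shape
    eps = rng.normal(size=(m, n)) * (np.abs(N) > 0)
    if x_star is None:
        x_star = rng.uniform(0.2, 3.0, size=m)
    return v_star[:, None] * eps.T / x_star[None, :]
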