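"""Toy and randomized test networks with independently derived answers.

Every fixture ships a ``known`` dictionary of expected quantities obtained by
hand calculation or closed-form reasoning (recorded in the comments below),
never by running this package — so the fixtures can serve as independent
oracles for the flux-centering and control-analysis machinery.

Kinds:

* ``chain``   — a linear k-step pathway between two boundary species; the
  steady-state polytope is a point once the uptake is fixed, so the unique
  flux is all-ones at uptake 1.
* ``diamond`` — two parallel branches of equal capacity; centering must
  return the symmetric 0.5/0.5 split.
* ``moiety-cycle`` — an ATP/ADP-style conserved pair; the conserved total
  makes the number of independent metabolites m0 = 1 < m = 2.
* ``random``  — a seeded sparse network built on a cycle backbone so a
  nonzero steady-state flux is certified by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .network import Compartment, MetabolicNetwork, Reaction, Species


@dataclass
class FixtureSpec:
    kind: str
    size: int = 3
    seed: int = 0
    extra: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec) -> tuple[MetabolicNetwork, dict]:
    builders = {
        "chain": _chain,
        "diamond": _diamond,
        "moiety-cycle": _moiety_cycle,
        "random": _random_network,
    }
    if spec.kind not in builders:
        raise ValidationError(f"unknown fixture kind {spec.kind!r}")
    return builders[spec.kind](spec)


def _compartments() -> list[Compartment]:
    return [
        Compartment("cell", 1.0, "intracellular"),
        Compartment("ext", 1.0, "extracellular"),
    ]


def _chain(spec: FixtureSpec) -> tuple[MetabolicNetwork, dict]:
    """X_ext -> M1 -> ... -> M_{k-1} -> Y_ext, k irreversible steps."""
    k = spec.size
    if k < 2:
        raise ValidationError("chain needs at least 2 steps")
    species = [Species("X_ext", compartment="ext", is_boundary=True)]
    species += [Species(f"M{i}", compartment="cell") for i in range(1, k)]
    species += [Species("Y_ext", compartment="ext", is_boundary=True)]
    ids = [s.id for s in species]
    reactions = [
        Reaction(f"R{i}", stoichiometry={ids[i]: -1.0, ids[i + 1]: 1.0})
        for i in range(k)
    ]
    net = MetabolicNetwork(species, reactions, _compartments())
    known = {
        # with uptake fixed at 1, mass balance forces every step to 1
        "uptake_reaction": "R0",
        "export_reaction": f"R{k - 1}",
        "v_star": np.ones(k),
        "Z_1": float(k),          # k unit fluxes
        "pointlike": True,        # polytope is a single point
        # supply-controlled two-step variant (supply elasticity 0,
        # consumption rate k_cat * M1): hand algebra in the module tests
        # gives C_S' = (1/k_cat, -1/k_cat), scaled C^J rows = (1, 0).
    }
    return net, known


def _diamond(spec: FixtureSpec) -> tuple[MetabolicNetwork, dict]:
    """ext -> A -> {branch 1, branch 2} -> B -> ext."""
    species = [
        Species("X_ext", compartment="ext", is_boundary=True),
        Species("A", compartment="cell"),
        Species("B", compartment="cell"),
        Species("Y_ext", compartment="ext", is_boundary=True),
    ]
    reactions = [
        Reaction("R_in", stoichiometry={"X_ext": -1.0, "A": 1.0}),
        Reaction("R_b1", stoichiometry={"A": -1.0, "B": 1.0}),
        Reaction("R_b2", stoichiometry={"A": -1.0, "B": 1.0}),
        Reaction("R_out", stoichiometry={"B": -1.0, "Y_ext": 1.0}),
    ]
    net = MetabolicNetwork(species, reactions, _compartments())
    known = {
        "uptake_reaction": "R_in",
        "export_reaction": "R_out",
        "branches": ("R_b1", "R_b2"),
        # uptake cap 1.5, branch caps 1 each: max export = 1.5 (hand LP)
        "fba_max_export": 1.5,
        # export fixed at 1: Z1 = 1 (in) + 1 (branches total) + 1 (out) = 3
        "Z_1_at_export_1": 3.0,
        # symmetry: the centred flux must split the branches equally
        "centred_fluxes": {"R_in": 1.0, "R_b1": 0.5, "R_b2": 0.5,
                           "R_out": 1.0},
    }
    return net, known


def _moiety_cycle(spec: FixtureSpec) -> tuple[MetabolicNetwork, dict]:
    """S_ext + ATP -> P_ext + ADP; ADP -> ATP (regeneration).

    Over the internal pair {ATP, ADP}: N = [[-1, 1], [1, -1]], rank 1;
    the conserved total ATP + ADP makes m0 = 1 < m = 2.
    """
    species = [
        Species("S_ext", compartment="ext", is_boundary=True),
        Species("P_ext", compartment="ext", is_boundary=True),
        Species("ATP", compartment="cell"),
        Species("ADP", compartment="cell"),
    ]
    reactions = [
        Reaction("R_use", stoichiometry={"S_ext": -1.0, "ATP": -1.0,
                                         "P_ext": 1.0, "ADP": 1.0}),
        Reaction("R_regen", stoichiometry={"ADP": -1.0, "ATP": 1.0}),
    ]
    net = MetabolicNetwork(species, reactions, _compartments())
    known = {
        "targets": {"R_use": 1.0},
        "v_star": np.array([1.0, 1.0]),
        "rank_N": 1,
        "m0": 1,
        "m": 2,
        "conserved_pair": ("ATP", "ADP"),
    }
    return net, known


def _random_network(spec: FixtureSpec) -> tuple[MetabolicNetwork, dict]:
    """Seeded sparse network with a certified nonzero steady state.

    A cycle backbone M0 -> M1 -> ... -> M0 guarantees the all-ones backbone
    flux is a steady state; extra random reactions (each balanced against
    the backbone metabolites) receive flux 0 in the certificate.
    """
    m = max(3, spec.size)
    rng = np.random.default_rng(spec.seed)
    species = [Species(f"M{i}", compartment="cell") for i in range(m)]
    reactions = [
        Reaction(f"R{i:02d}",
                 stoichiometry={f"M{i}": -1.0, f"M{(i + 1) % m}": 1.0})
        for i in range(m)
    ]
    n_extra = max(1, m // 2)
    for e in range(n_extra):
        picks = rng.choice(m, size=3, replace=False)
        coeffs = rng.integers(1, 3, size=3).astype(float)
        st = {f"M{picks[0]}": -coeffs[0], f"M{picks[1]}": -coeffs[1],
              f"M{picks[2]}": coeffs[2]}
        reactions.append(
            Reaction(f"X{e:02d}", stoichiometry=st,
                     reversible=bool(rng.integers(0, 2)))
        )
    net = MetabolicNetwork(species, reactions, _compartments())
    v = np.zeros(len(reactions))
    v[:m] = 1.0
    known = {"v_star": v, "backbone_length": m}
    return net, known
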