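"""Stoichiometric network representation and model-reduction steps.

A :class:`MetabolicNetwork` holds species, reactions and compartments and
derives the m x n stoichiometric matrix ``N`` over its internal (non-boundary)
metabolites.  The reduction steps mirror the preprocessing used to bring a
compartmentalized genome-scale reconstruction down to a kinetic-model scale:

* :func:`decompartmentalize` merges every intracellular compartment into one,
  unifies species that represent the same chemical (matched by shared database
  annotations, falling back to case-insensitive names), drops reactions whose
  stoichiometry becomes empty (pure intracellular transport) and lumps
  reactions that become duplicates.
* :func:`lump_isoenzymes` collapses reactions with identical stoichiometry
  (for reversible reactions, also identical up to a global sign flip) into a
  single reaction carrying the union of catalysts.
* :func:`add_biomass_reaction` appends the irreversible growth pseudo-reaction
  used as the flux-balance objective.

Both reductions are idempotent and never increase m, n or rank(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np

from .errors import StructuralError, ValidationError

SPECIES_ROLES = ("metabolite", "enzyme", "enzyme-complex")
COMPARTMENT_SCOPES = ("intracellular", "extracellular")

#: id given to the merged intracellular compartment
MERGED_COMPARTMENT_ID = "intracellular"


@dataclass(frozen=True)
class Species:
    """A chemical species (metabolite, enzyme or enzyme complex).

    ``annotations`` is a tuple of ``(database, accession)`` pairs used as the
    identity key when unifying species across compartments.  Boundary species
    have fixed concentrations and are excluded from the rows of ``N``.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    role: str = "metabolite"
    is_boundary: bool = False
    annotations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise ValidationError(
                f"species {self.id!r}: unknown role {self.role!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed).

    ``catalysts`` lists the ids of enzyme species catalysing the reaction.
    ``is_metabolic`` is False for pseudo-reactions such as biomass production
    and pure enzyme-assembly steps.
    """

    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    reversible: bool = False
    catalysts: tuple[str, ...] = ()
    is_metabolic: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValidationError(
                f"reaction {self.id!r}: zero stoichiometric coefficient"
            )


@dataclass(frozen=True)
class Compartment:
    id: str
    volume: float = 1.0
    scope: str = "intracellular"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValidationError(
                f"compartment {self.id!r}: volume must be positive"
            )
        if self.scope not in COMPARTMENT_SCOPES:
            raise ValidationError(
                f"compartment {self.id!r}: unknown scope {self.scope!r}"
            )


@dataclass
class MetabolicNetwork:
    """Species, reactions and compartments with resolved cross-references."""

    species: list[Species]
    reactions: list[Reaction]
    compartments: list[Compartment]

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    @property
    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    @property
    def compartments_by_id(self) -> dict[str, Compartment]:
        return {c.id: c for c in self.compartments}

    def internal_metabolites(self) -> list[Species]:
        """Species forming the rows of N: non-boundary metabolites."""
        return [
            s for s in self.species
            if s.role == "metabolite" and not s.is_boundary
        ]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        sids = [s.id for s in self.species]
        if len(set(sids)) != len(sids):
            dup = sorted({x for x in sids if sids.count(x) > 1})
            raise StructuralError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise StructuralError(f"duplicate reaction ids: {dup}")
        comp_ids = {c.id for c in self.compartments}
        known = set(sids)
        for s in self.species:
            if s.compartment not in comp_ids:
                raise StructuralError(
                    f"species {s.id!r} references unknown compartment "
                    f"{s.compartment!r}"
                )
        for r in self.reactions:
            for sid in r.stoichiometry:
                if sid not in known:
                    raise StructuralError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
            for sid in r.catalysts:
                if sid not in known:
                    raise StructuralError(
                        f"reaction {r.id!r} lists unknown catalyst {sid!r}"
                    )


def build_stoichiometric_matrix(
    net: MetabolicNetwork,
) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
    """Return (N, row_index, col_index) for the internal metabolites.

    ``N[i, j]`` is the signed coefficient of metabolite ``i`` in reaction
    ``j``; boundary species and enzyme-role species contribute no rows.
    Column order follows reaction order in the network.
    """
    net.validate()
    mets = net.internal_metabolites()
    row_index = {s.id: i for i, s in enumerate(mets)}
    col_index = {r.id: j for j, r in enumerate(net.reactions)}
    N = np.zeros((len(mets), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for sid, coeff in r.stoichiometry.items():
            i = row_index.get(sid)
            if i is not None:
                N[i, j] = coeff
    return N, row_index, col_index


# -- species identity --------------------------------------------------------


def default_identity_keys(s: Species) -> tuple:
    """Keys used to recognise the same chemical across compartments.

    Annotated species match on any shared (database, accession) pair;
    unannotated species fall back to their case-insensitive name (or id
    when the name is empty).
    """
    if s.annotations:
        return tuple(("ann",) + tuple(a) for a in s.annotations)
    return ((("name", (s.name or s.id).strip().lower()),))


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # lexicographically smallest root for determinism
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _merge_duplicate_reactions(reactions: list[Reaction]) -> list[Reaction]:
    """Collapse duplicate reactions.

    Two reactions are duplicates when their stoichiometry maps are identical
    and their reversibility flags agree, or when both are reversible and one
    map is the global sign-flip of the other.  The survivor is the reaction
    with the lexicographically smallest id; catalysts are unioned and the
    merged reaction is metabolic only if all members are.
    """

    def stoich_key(st: Mapping[str, float]) -> tuple:
        return tuple(sorted(st.items()))

    groups: dict[tuple, list[Reaction]] = {}
    for r in reactions:
        key = stoich_key(r.stoichiometry)
        if r.reversible:
            flipped = stoich_key({k: -v for k, v in r.stoichiometry.items()})
            canon = ("rev", min(key, flipped))
        else:
            canon = ("irr", key)
        groups.setdefault(canon, []).append(r)

    merged: list[Reaction] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        survivor = min(members, key=lambda r: r.id)
        catalysts = tuple(sorted({c for r in members for c in r.catalysts}))
        merged.append(
            replace(
                survivor,
                catalysts=catalysts,
                is_metabolic=all(r.is_metabolic for r in members),
            )
        )
    order = {r.id: k for k, r in enumerate(reactions)}
    merged.sort(key=lambda r: order[r.id])
    return merged


def lump_isoenzymes(net: MetabolicNetwork) -> MetabolicNetwork:
    """Collapse isoenzyme-duplicated reactions into single reactions."""
    return MetabolicNetwork(
        species=list(net.species),
        reactions=_merge_duplicate_reactions(net.reactions),
        compartments=list(net.compartments),
    )


def decompartmentalize(
    net: MetabolicNetwork,
    identity_keys: Callable[[Species], Iterable[tuple]] = default_identity_keys,
) -> MetabolicNetwork:
    """Merge all intracellular compartments into one.

    Species representing the same chemical (shared identity key) in merged
    compartments are unified; reactions whose stoichiometry becomes empty
    (pure intracellular transport) are removed and reactions that become
    duplicates are lumped.  Extracellular species and compartments are left
    untouched.
    """
    comp_by_id = net.compartments_by_id
    intra = [c for c in net.compartments if c.scope == "intracellular"]
    intra_ids = {c.id for c in intra}

    if not intra:
        return net

    # group intracellular species by shared identity keys
    uf = _UnionFind()
    key_owner: dict[tuple, str] = {}
    intra_species = [s for s in net.species if s.compartment in intra_ids]
    for s in intra_species:
        uf.find(s.id)
        for key in identity_keys(s):
            if key in key_owner:
                uf.union(key_owner[key], s.id)
            else:
                key_owner[key] = s.id

    groups: dict[str, list[Species]] = {}
    for s in intra_species:
        groups.setdefault(uf.find(s.id), []).append(s)

    rename: dict[str, str] = {}
    merged_species: list[Species] = []
    for members in groups.values():
        roles = {s.role for s in members}
        if len(roles) > 1:
            ids = sorted(s.id for s in members)
            raise ValidationError(
                f"species {ids} share an identity key but have different "
                f"roles {sorted(roles)}"
            )
        survivor = min(members, key=lambda s: s.id)
        annotations = tuple(
            sorted({a for s in members for a in s.annotations})
        )
        unified = replace(
            survivor,
            compartment=MERGED_COMPARTMENT_ID,
            is_boundary=any(s.is_boundary for s in members),
            annotations=annotations,
        )
        merged_species.append(unified)
        for s in members:
            rename[s.id] = survivor.id

    # merged compartment volume conserves the total intracellular volume
    merged_comp = Compartment(
        id=MERGED_COMPARTMENT_ID,
        volume=sum(c.volume for c in intra),
        scope="intracellular",
    )
    compartments = [c for c in net.compartments if c.scope != "intracellular"]
    compartments.append(merged_comp)

    species_order = {s.id: k for k, s in enumerate(net.species)}
    new_species = [s for s in net.species if s.compartment not in intra_ids]
    new_species.extend(merged_species)
    new_species.sort(key=lambda s: species_order[s.id])

    new_reactions: list[Reaction] = []
    for r in net.reactions:
        st: dict[str, float] = {}
        for sid, coeff in r.stoichiometry.items():
            tid = rename.get(sid, sid)
            st[tid] = st.get(tid, 0.0) + coeff
        st = {k: v for k, v in st.items() if v != 0.0}
        if not st:
            continue  # pure intracellular transport
        catalysts = tuple(
            sorted({rename.get(c, c) for c in r.catalysts})
        )
        new_reactions.append(
            replace(r, stoichiometry=st, catalysts=catalysts)
        )

    return MetabolicNetwork(
        species=new_species,
        reactions=_merge_duplicate_reactions(new_reactions),
        compartments=compartments,
    )


def add_biomass_reaction(
    net: MetabolicNetwork,
    composition: Mapping[str, float],
    reaction_id: str = "biomass",
) -> MetabolicNetwork:
    """Append the irreversible growth pseudo-reaction.

    The reaction consumes the listed precursors in the given (positive)
    proportions and produces nothing; it is flagged non-metabolic so it can
    serve as an objective without counting as a metabolic reaction.
    """
    if not composition:
        raise ValidationError("biomass composition must not be empty")
    internal = {s.id for s in net.internal_metabolites()}
    for sid, coeff in composition.items():
        if sid not in internal:
            raise ValidationError(
                f"biomass precursor {sid!r} is not an internal metabolite"
            )
        if coeff <= 0:
            raise ValidationError(
                f"biomass precursor {sid!r}: coefficient must be positive"
            )
    if any(r.id == reaction_id for r in net.reactions):
        raise ValidationError(f"reaction id {reaction_id!r} already exists")
    biomass = Reaction(
        id=reaction_id,
        name="growth",
        stoichiometry={sid: -float(c) for sid, c in composition.items()},
        reversible=False,
        is_metabolic=False,
    )
    return MetabolicNetwork(
        species=list(net.species),
        reactions=list(net.reactions) + [biomass],
        compartments=list(net.compartments),
    )
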