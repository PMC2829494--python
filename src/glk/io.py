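"""Readers and writers: the TSV network dialect, parameter tables and SBML.

The TSV dialect is a directory holding ``species.tsv``, ``reactions.tsv``
and optionally ``compartments.tsv``.  Reaction stoichiometry is written as
an equation string (``2 A + B -> C``); a coefficient defaults to 1, ``->``
marks an irreversible and ``<->`` a reversible reaction.

SBML support covers the Level 2 subset needed here: compartments, species
(with boundary condition, an SBO term for the role and MIRIAM identity
annotations), reactions (reversibility, modifiers as catalysts) and, on
export of an assembled kinetic model, explicit linlog kinetic laws whose
parameters carry provenance annotations.  Events, rules and unit
definitions beyond mM / mM s^-1 are outside the subset and are skipped with
a warning.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import libsbml
import pandas as pd

from . import __version__
from .errors import ValidationError
from .kinetics import LinlogModel, Provenance
from .network import Compartment, MetabolicNetwork, Reaction, Species

logger = logging.getLogger(__name__)

_SBO_ROLE = {"metabolite": 247, "enzyme": 252, "enzyme-complex": 253}
_ROLE_SBO = {v: k for k, v in _SBO_ROLE.items()}
_SBO_NON_METABOLIC = 629  # biomass production / pseudo-reaction

_EXTRACELLULAR_HINTS = {"e", "ext", "extracellular", "external", "medium",
                        "out", "boundary"}


def output_header(config=None, seed: int | None = None) -> str:
    """Standard one-line provenance header written atop every output file."""
    chash = config.config_hash() if config is not None else "default"
    seed = seed if seed is not None else (
        config.seed if config is not None else 0
    )
    return f"# glk {__version__} config={chash} seed={seed}"


# -- equation grammar --------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B -> C`` into (stoichiometry map, reversible flag)."""
    if "<->" in text:
        lhs, rhs = text.split("<->", 1)
        reversible = True
    elif "->" in text:
        lhs, rhs = text.split("->", 1)
        reversible = False
    else:
        raise ValidationError(f"equation {text!r} lacks '->' or '<->'")
    st: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            match = _TERM_RE.match(term)
            if match is None:
                raise ValidationError(
                    f"cannot parse term {term!r} in equation {text!r}"
                )
            coeff = float(match.group(1)) if match.group(1) else 1.0
            sid = match.group(2)
            st[sid] = st.get(sid, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, 1.0)
    return {k: v for k, v in st.items() if v != 0.0}, reversible


def format_equation(stoichiometry: Mapping[str, float],
                    reversible: bool) -> str:
    def fmt(side: Iterable[tuple[str, float]]) -> str:
        parts = []
        for sid, coeff in side:
            parts.append(sid if coeff == 1.0 else f"{coeff:g} {sid}")
        return " + ".join(parts)

    lhs = [(s, -c) for s, c in sorted(stoichiometry.items()) if c < 0]
    rhs = [(s, c) for s, c in sorted(stoichiometry.items()) if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{fmt(lhs)} {arrow} {fmt(rhs)}".strip()


# -- TSV network dialect -----------------------------------------------------


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                           keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def read_network_tsv(directory) -> MetabolicNetwork:
    directory = Path(directory)
    sp_path = directory / "species.tsv"
    rx_path = directory / "reactions.tsv"
    if not sp_path.exists() or not rx_path.exists():
        raise ValidationError(
            f"{directory} must contain species.tsv and reactions.tsv"
        )
    sp = _read_tsv(sp_path)
    rx = _read_tsv(rx_path)

    comp_path = directory / "compartments.tsv"
    if comp_path.exists():
        cdf = _read_tsv(comp_path)
        compartments = [
            Compartment(row["id"], float(row.get("volume", 1.0) or 1.0),
                        row.get("scope", "intracellular") or "intracellular")
            for _, row in cdf.iterrows()
        ]
    else:
        comp_ids = sorted(set(sp["compartment"]))
        compartments = [
            Compartment(cid, 1.0,
                        "extracellular"
                        if cid.lower() in _EXTRACELLULAR_HINTS
                        else "intracellular")
            for cid in comp_ids
        ]

    species = []
    for k, row in sp.iterrows():
        ann = tuple(
            tuple(pair.split(":", 1))
            for pair in str(row.get("annotations", "") or "").split(";")
            if ":" in pair
        )
        try:
            species.append(Species(
                id=row["id"],
                name=row.get("name", "") or "",
                compartment=row["compartment"],
                role=row.get("role", "metabolite") or "metabolite",
                is_boundary=str(row.get("boundary", "false")).lower()
                in ("1", "true", "yes"),
                annotations=ann,
            ))
        except (KeyError, ValidationError) as exc:
            raise ValidationError(f"{sp_path} row {k + 2}: {exc}") from exc

    reactions = []
    for k, row in rx.iterrows():
        try:
            st, rev_eq = parse_equation(row["equation"])
            rev_col = str(row.get("reversible", "")).lower()
            reversible = rev_eq or rev_col in ("1", "true", "yes")
            catalysts = tuple(
                c for c in str(row.get("catalysts", "") or "").split(";") if c
            )
            metabolic = str(row.get("metabolic", "true")).lower() not in (
                "0", "false", "no")
            reactions.append(Reaction(
                id=row["id"],
                name=row.get("name", "") or "",
                stoichiometry=st,
                reversible=reversible,
                catalysts=catalysts,
                is_metabolic=metabolic,
            ))
        except (KeyError, ValidationError) as exc:
            raise ValidationError(f"{rx_path} row {k + 2}: {exc}") from exc

    return MetabolicNetwork(species, reactions, compartments)


def write_network_tsv(net: MetabolicNetwork, directory,
                      config=None, seed: int | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = output_header(config, seed)

    with open(directory / "compartments.tsv", "w") as fh:
        fh.write(header + "\nid\tvolume\tscope\n")
        for c in net.compartments:
            fh.write(f"{c.id}\t{c.volume:g}\t{c.scope}\n")
    with open(directory / "species.tsv", "w") as fh:
        fh.write(header + "\nid\tname\tcompartment\trole\tboundary\t"
                 "annotations\n")
        for s in net.species:
            ann = ";".join(f"{db}:{acc}" for db, acc in s.annotations)
            fh.write(f"{s.id}\t{s.name}\t{s.compartment}\t{s.role}\t"
                     f"{str(s.is_boundary).lower()}\t{ann}\n")
    with open(directory / "reactions.tsv", "w") as fh:
        fh.write(header + "\nid\tname\tequation\treversible\tcatalysts\t"
                 "metabolic\n")
        for r in net.reactions:
            eq = format_equation(r.stoichiometry, r.reversible)
            fh.write(f"{r.id}\t{r.name}\t{eq}\t"
                     f"{str(r.reversible).lower()}\t"
                     f"{';'.join(r.catalysts)}\t"
                     f"{str(r.is_metabolic).lower()}\n")


# -- SBML --------------------------------------------------------------------

_MIRIAM_URN = re.compile(r"^urn:miriam:([^:]+):(.+)$")
_IDENTIFIERS_URL = re.compile(
    r"^https?://identifiers\.org/([^/:]+)[/:](.+)$")


def _parse_resource(uri: str) -> tuple[str, str] | None:
    for pattern in (_MIRIAM_URN, _IDENTIFIERS_URL):
        match = pattern.match(uri)
        if match:
            return match.group(1), match.group(2)
    return None


def _cv_annotations(sbase) -> tuple[tuple[str, str], ...]:
    out = []
    for k in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(k)
        for r in range(term.getNumResources()):
            parsed = _parse_resource(term.getResourceURI(r))
            if parsed:
                out.append(parsed)
    return tuple(out)


def _compartment_scope(comp) -> str:
    notes = comp.getNotesString() if comp.isSetNotes() else ""
    if "scope: extracellular" in notes:
        return "extracellular"
    if "scope: intracellular" in notes:
        return "intracellular"
    for key in (comp.getId(), comp.getName()):
        if key and key.lower() in _EXTRACELLULAR_HINTS:
            return "extracellular"
    return "intracellular"


def read_network_sbml(path) -> MetabolicNetwork:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ValidationError(
            f"SBML parse error in {path}: line {err.getLine()}: "
            f"{err.getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise ValidationError(f"{path} contains no SBML model")
    for construct, count in (("events", model.getNumEvents()),
                             ("rules", model.getNumRules()),
                             ("constraints", model.getNumConstraints())):
        if count:
            logger.warning(
                "%s: %d %s outside the supported SBML subset; ignored",
                path, count, construct,
            )

    compartments = [
        Compartment(
            c.getId(),
            c.getSize() if c.isSetSize() else 1.0,
            _compartment_scope(c),
        )
        for c in model.getListOfCompartments()
    ]
    species = []
    for s in model.getListOfSpecies():
        role = _ROLE_SBO.get(s.getSBOTerm(), "metabolite")
        species.append(Species(
            id=s.getId(),
            name=s.getName() or "",
            compartment=s.getCompartment(),
            role=role,
            is_boundary=bool(s.getBoundaryCondition()),
            annotations=_cv_annotations(s),
        ))
    reactions = []
    for r in model.getListOfReactions():
        st: dict[str, float] = {}
        for ref in r.getListOfReactants():
            st[ref.getSpecies()] = st.get(ref.getSpecies(), 0.0) - \
                ref.getStoichiometry()
        for ref in r.getListOfProducts():
            st[ref.getSpecies()] = st.get(ref.getSpecies(), 0.0) + \
                ref.getStoichiometry()
        st = {k: v for k, v in st.items() if v != 0.0}
        catalysts = tuple(mod.getSpecies()
                          for mod in r.getListOfModifiers())
        reactions.append(Reaction(
            id=r.getId(),
            name=r.getName() or "",
            stoichiometry=st,
            reversible=bool(r.getReversible()),
            catalysts=catalysts,
            is_metabolic=r.getSBOTerm() != _SBO_NON_METABOLIC,
        ))
    return MetabolicNetwork(species, reactions, compartments)


def write_network_sbml(net: MetabolicNetwork, path) -> None:
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId("glk_network")
    for c in net.compartments:
        comp = model.createCompartment()
        comp.setId(c.id)
        comp.setSize(c.volume)
        comp.setNotes(
            f"<body xmlns='http://www.w3.org/1999/xhtml'>"
            f"<p>scope: {c.scope}</p></body>"
        )
    for s in net.species:
        sp = model.createSpecies()
        sp.setId(s.id)
        if s.name:
            sp.setName(s.name)
        sp.setCompartment(s.compartment)
        sp.setBoundaryCondition(s.is_boundary)
        sp.setSBOTerm(_SBO_ROLE[s.role])
        if s.annotations:
            sp.setMetaId(f"meta_{s.id}")
            term = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            term.setBiologicalQualifierType(libsbml.BQB_IS)
            for db, acc in s.annotations:
                term.addResource(f"urn:miriam:{db}:{acc}")
            sp.addCVTerm(term)
    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        if r.name:
            rx.setName(r.name)
        rx.setReversible(r.reversible)
        if not r.is_metabolic:
            rx.setSBOTerm(_SBO_NON_METABOLIC)
        for sid, coeff in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(coeff))
        for cid in r.catalysts:
            mod = rx.createModifier()
            mod.setSpecies(cid)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ValidationError(f"failed to write SBML to {path}")


def write_assembled_sbml(model: LinlogModel, net: MetabolicNetwork,
                         path) -> None:
    """Export the assembled kinetic model with explicit linlog rate laws.

    Every reaction gets a kinetic law ``v_star * (1 + sum eps * ln(x/x_star))``
    over its elastic metabolites; the local parameters carry the per-value
    provenance as MIRIAM-style annotations (the origin as a urn resource,
    the provenance class in the parameter notes).
    """
    write_network_sbml(net, path)
    doc = libsbml.readSBMLFromFile(str(path))
    sbml_model = doc.getModel()
    asm = model.assembly
    met_index = {m: i for i, m in enumerate(asm.metabolite_ids)}

    for i, mid in enumerate(asm.metabolite_ids):
        sp = sbml_model.getSpecies(mid)
        if sp is not None:
            sp.setInitialConcentration(float(asm.x_star[i]))
            _annotate_provenance(sp, f"x_{mid}", asm.x_provenance[i])

    for j, rid in enumerate(asm.reaction_ids):
        rx = sbml_model.getReaction(rid)
        if rx is None:
            continue
        law = rx.createKineticLaw()
        terms = []
        for mid, idx in met_index.items():
            eps = asm.epsilon_scaled[idx, j]
            if eps == 0.0:
                continue
            pname = f"eps_{mid}"
            par = law.createParameter()
            par.setId(pname)
            par.setValue(float(eps))
            _annotate_provenance(
                par, f"{rid}_{pname}",
                asm.epsilon_provenance.get((mid, rid)),
            )
            terms.append(f"{pname} * ln({mid} / xstar_{mid})")
            xs = law.createParameter()
            xs.setId(f"xstar_{mid}")
            xs.setValue(float(asm.x_star[idx]))
        vp = law.createParameter()
        vp.setId("v_star")
        vp.setValue(float(asm.v_star[j]))
        if asm.flux_provenance is not None:
            _annotate_provenance(vp, f"{rid}_v_star",
                                 asm.flux_provenance[j])
        formula = "v_star"
        if terms:
            formula = f"v_star * (1 + {' + '.join(terms)})"
        law.setMath(libsbml.parseL3Formula(formula))
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ValidationError(f"failed to write SBML to {path}")


def _annotate_provenance(sbase, meta_id: str,
                         prov: Provenance | None) -> None:
    if prov is None:
        return
    sbase.setNotes(
        f"<body xmlns='http://www.w3.org/1999/xhtml'>"
        f"<p>provenance: {prov.source}</p></body>"
    )
    if prov.origin and ":" in prov.origin:
        sbase.setMetaId(f"meta_{meta_id}")
        term = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
        term.setBiologicalQualifierType(libsbml.BQB_IS_DESCRIBED_BY)
        for origin in prov.origin.split(";"):
            db, acc = origin.split(":", 1)
            term.addResource(f"urn:miriam:{db}:{acc}")
        sbase.addCVTerm(term)


def read_network(path, fmt: str | None = None) -> MetabolicNetwork:
    """Read a network from SBML (.xml/.sbml) or a TSV directory."""
    path = Path(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if fmt == "sbml":
        return read_network_sbml(path)
    if fmt == "tsv":
        return read_network_tsv(path)
    raise ValidationError(f"unknown network format {fmt!r}")


def write_network(net: MetabolicNetwork, path, fmt: str | None = None,
                  **kwargs) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if fmt == "sbml":
        write_network_sbml(net, path)
    elif fmt == "tsv":
        write_network_tsv(net, path, **kwargs)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


# -- parameter tables --------------------------------------------------------


def _provenance_from_row(row) -> Provenance:
    source = row.get("source", "") or "user"
    origin = row.get("origin", "") or None
    if source in ("default-median", "tendency-estimate"):
        origin = None
    return Provenance(source, origin)


def read_targets_tsv(path) -> tuple[dict[str, float], dict[str, Provenance]]:
    """``reaction_id  flux_mM_s  [source  origin]`` -> targets + provenance."""
    df = _read_tsv(Path(path))
    if "reaction_id" not in df.columns or "flux_mM_s" not in df.columns:
        raise ValidationError(
            f"{path}: expected columns reaction_id, flux_mM_s"
        )
    targets = {}
    prov = {}
    for _, row in df.iterrows():
        targets[row["reaction_id"]] = float(row["flux_mM_s"])
        prov[row["reaction_id"]] = _provenance_from_row(row)
    return targets, prov


def read_concentrations_tsv(path) -> tuple[dict[str, float],
                                           dict[str, Provenance]]:
    """``metabolite_id  mM  [source  origin]``."""
    df = _read_tsv(Path(path))
    if "metabolite_id" not in df.columns or "mM" not in df.columns:
        raise ValidationError(f"{path}: expected columns metabolite_id, mM")
    conc = {}
    prov = {}
    for _, row in df.iterrows():
        conc[row["metabolite_id"]] = float(row["mM"])
        prov[row["metabolite_id"]] = _provenance_from_row(row)
    return conc, prov


def read_elasticities_tsv(path) -> tuple[dict[tuple[str, str], float],
                                         dict[tuple[str, str], Provenance]]:
    """``metabolite_id  reaction_id  value  [source  origin]``."""
    df = _read_tsv(Path(path))
    needed = {"metabolite_id", "reaction_id", "value"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(needed)}")
    values = {}
    prov = {}
    for _, row in df.iterrows():
        key = (row["metabolite_id"], row["reaction_id"])
        values[key] = float(row["value"])
        prov[key] = _provenance_from_row(row)
    return values, prov


def read_biomass_tsv(path) -> dict[str, float]:
    """``metabolite_id  coefficient`` (positive consumption proportions)."""
    df = _read_tsv(Path(path))
    if "metabolite_id" not in df.columns or "coefficient" not in df.columns:
        raise ValidationError(
            f"{path}: expected columns metabolite_id, coefficient"
        )
    return {row["metabolite_id"]: float(row["coefficient"])
            for _, row in df.iterrows()}


def write_fluxes_tsv(result, path, config=None, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(config, seed) + "\n")
        fh.write("reaction_id\tflux_mM_s\n")
        for rid, v in zip(result.reaction_ids, result.v_star):
            fh.write(f"{rid}\t{v:.12g}\n")


def write_trace_tsv(result, path, config=None, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(config, seed) + "\n")
        fh.write("iteration\treaction_id\tlower\tupper\tcentre\n")
        for k, (lo, hi, centre) in enumerate(result.iterations, 1):
            for rid, a, b, c in zip(result.reaction_ids, lo, hi, centre):
                fh.write(f"{k}\t{rid}\t{a:.12g}\t{b:.12g}\t{c:.12g}\n")


def write_control_tsv(ids_rows, ids_cols, matrix, path, config=None,
                      seed=None, scaled=False) -> None:
    """Coefficient table sorted by |coefficient| descending."""
    import numpy as np

    rows = []
    for i, rid in enumerate(ids_rows):
        for j, cid in enumerate(ids_cols):
            val = matrix[i, j]
            if np.isnan(val):
                continue
            rows.append((rid, cid, val))
    rows.sort(key=lambda t: -abs(t[2]))
    kind = "scaled" if scaled else "unscaled"
    with open(path, "w") as fh:
        fh.write(output_header(config, seed) + f"\n# {kind} coefficients\n")
        fh.write("target_id\treaction_id\tcoefficient\n")
        for rid, cid, val in rows:
            fh.write(f"{rid}\t{cid}\t{val:.12g}\n")
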