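"""End-to-end orchestration: reduce -> center -> assemble -> control analysis.

:func:`run_pipeline` composes the package's stages on validated inputs and
(optionally) writes the standard output bundle: reference fluxes, the
assembled SBML model, control-coefficient tables, the theorem residual
report and a provenance summary.  Any stage failure aborts with the stage
name attached to the underlying error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as glkio
from .config import RunConfig
from .errors import GlkError
from .fluxes import CenteredFluxResult, center_fluxes, problem_from_network
from .kinetics import (
    KineticAssembly,
    LinlogModel,
    Provenance,
    assign_concentrations,
    assign_elasticities,
    unscaled_elasticity_matrix,
)
from .mca import ControlCoefficients, LinkDecomposition, \
    control_coefficients, link_decomposition
from .network import (
    MetabolicNetwork,
    build_stoichiometric_matrix,
    decompartmentalize,
    lump_isoenzymes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    network: MetabolicNetwork
    flux_result: CenteredFluxResult
    assembly: KineticAssembly
    model: LinlogModel
    link: LinkDecomposition
    coefficients: ControlCoefficients
    provenance_summary: dict


class StageError(GlkError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def assemble_model(
    net: MetabolicNetwork,
    flux_result: CenteredFluxResult,
    concentrations: Mapping[str, float] | None = None,
    conc_provenance: Mapping[str, Provenance] | None = None,
    elasticities: Mapping[tuple[str, str], float] | None = None,
    elast_provenance: Mapping[tuple[str, str], Provenance] | None = None,
    extracellular: Mapping[str, float] | None = None,
    flux_provenance: Mapping[str, Provenance] | None = None,
) -> tuple[KineticAssembly, LinlogModel]:
    """Combine the reduced network, centred flux and kinetic data."""
    N, row, col = build_stoichiometric_matrix(net)
    met_ids = [m for m, _ in sorted(row.items(), key=lambda kv: kv[1])]
    rxn_ids = [r for r, _ in sorted(col.items(), key=lambda kv: kv[1])]

    known_conc = {k: v for k, v in (concentrations or {}).items()
                  if k in row}
    x_star, x_prov, median = assign_concentrations(
        met_ids, known_conc, conc_provenance
    )
    if median is not None:
        logger.info("default-median concentration used: %.4g mM", median)

    reversible = [net.reaction(r).reversible for r in rxn_ids]
    eps, eps_prov = assign_elasticities(
        N, met_ids, rxn_ids, reversible, elasticities, elast_provenance
    )

    comp_by_id = net.compartments_by_id
    sp_by_id = net.species_by_id
    volumes = np.array([
        comp_by_id[sp_by_id[m].compartment].volume for m in met_ids
    ])

    v_star = np.array([flux_result.flux(r) for r in rxn_ids])
    flux_prov_list = None
    if flux_provenance is not None:
        flux_prov_list = [
            flux_provenance.get(r, Provenance("user")) for r in rxn_ids
        ]

    assembly = KineticAssembly(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        x_star=x_star,
        x_provenance=x_prov,
        v_star=v_star,
        epsilon_scaled=eps,
        epsilon_provenance=eps_prov,
        volumes=volumes,
        extracellular=dict(extracellular or {}),
        flux_provenance=flux_prov_list,
    )
    return assembly, LinlogModel(assembly=assembly, N=N)


def run_pipeline(
    config: RunConfig,
    network: MetabolicNetwork,
    targets: Mapping[str, float] | None = None,
    target_provenance: Mapping[str, Provenance] | None = None,
    concentrations: Mapping[str, float] | None = None,
    conc_provenance: Mapping[str, Provenance] | None = None,
    elasticities: Mapping[tuple[str, str], float] | None = None,
    elast_provenance: Mapping[tuple[str, str], Provenance] | None = None,
    extracellular: Mapping[str, float] | None = None,
    objective_reaction: str | None = None,
    reduce: bool = True,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full construction and analysis pipeline."""
    try:
        net = network
        if reduce:
            net = lump_isoenzymes(decompartmentalize(network))
    except Exception as exc:
        raise StageError("reduce", exc) from exc

    try:
        problem = problem_from_network(
            net,
            objective_reaction=objective_reaction,
            targets={rid: t for rid, t in (targets or {}).items()
                     if any(r.id == rid for r in net.reactions)},
            default_bound=config.default_bound,
        )
        if targets is not None and not problem.targets:
            logger.info("no targets resolve to reactions; skipping the "
                        "target-fitting stage")
        flux_result = center_fluxes(
            problem,
            tolerance=config.convergence_tolerance,
            max_iterations=config.max_iterations,
            objective_ordering=config.objective_ordering,
        )
    except Exception as exc:
        raise StageError("center", exc) from exc

    try:
        flux_prov = None
        if targets:
            flux_prov = {
                rid: (target_provenance or {}).get(
                    rid, Provenance("organism-match", "targets")
                )
                for rid in (targets or {})
            }
        assembly, model = assemble_model(
            net, flux_result,
            concentrations, conc_provenance,
            elasticities, elast_provenance,
            extracellular, flux_prov,
        )
    except Exception as exc:
        raise StageError("assemble", exc) from exc

    try:
        eps_prime = unscaled_elasticity_matrix(assembly)
        link = link_decomposition(
            model.N, eps_prime, assembly.volumes, config.rank_tolerance
        )
        cc = control_coefficients(link, eps_prime, assembly.v_star)
    except Exception as exc:
        raise StageError("mca", exc) from exc

    summary = assembly.provenance_summary()
    result = PipelineResult(
        network=net,
        flux_result=flux_result,
        assembly=assembly,
        model=model,
        link=link,
        coefficients=cc,
        provenance_summary=summary,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir), config)
    return result


def _write_bundle(result: PipelineResult, outdir: Path,
                  config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    glkio.write_fluxes_tsv(result.flux_result, outdir / "fluxes.tsv",
                           config)
    glkio.write_trace_tsv(result.flux_result, outdir / "trace.tsv", config)
    glkio.write_assembled_sbml(result.model, result.network,
                               outdir / "assembled.xml")
    rxns = result.assembly.reaction_ids
    mets = result.assembly.metabolite_ids
    glkio.write_control_tsv(rxns, rxns, result.coefficients.C_J_scaled,
                            outdir / "cc_flux_scaled.tsv", config,
                            scaled=True)
    glkio.write_control_tsv(mets, rxns, result.coefficients.C_S_unscaled,
                            outdir / "cc_conc_unscaled.tsv", config)
    with open(outdir / "theorems.txt", "w") as fh:
        fh.write(glkio.output_header(config) + "\n")
        for name, value in result.coefficients.theorem_residuals.items():
            if name == "passed":
                fh.write(f"passed\t{bool(value)}\n")
            else:
                fh.write(f"{name}\t{value:.3e}\n")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
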