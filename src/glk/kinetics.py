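"""Reference concentrations, scaled elasticities and the linlog rate law.

The kinetic layer around a reduced stoichiometric network needs four inputs:
the matrix N, a reference flux v* (mM/s), reference concentrations x* (mM)
and scaled elasticities eps_ij = d ln v_j / d ln x_i at the reference state.
Known values (from curated kinetic models) override defaults; every
parameter carries a :class:`Provenance` record so the origin of each number
in the assembled model stays auditable.

Defaults follow the tendency-modelling rule: unknown elasticities are the
negatives of the stoichiometric coefficients (so substrates, whose
coefficients are negative, get positive elasticities), except that products
of irreversible reactions get exactly zero.  These defaults coincide with the
scaled elasticities of a mass-action rate law.  Unknown concentrations fall
back to the median of the known pool.

The assembled linlog model evaluates

    v_j(x) = v*_j * (1 + sum_i eps_ij * ln(x_i / x*_i))
    dx/dt  = diag(c)^-1 . N . v(x)

where c holds the compartment volume of each metabolite.  At x = x* every
log term is ln 1 = 0, so v(x*) reproduces v* bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

PROVENANCE_SOURCES = (
    "organism-match",
    "other-organism",
    "default-median",
    "tendency-estimate",
    "user",
)


@dataclass(frozen=True)
class Provenance:
    """Origin of a single kinetic parameter.

    ``origin`` points at the external source (a repository model id, a
    taxonomy id); computed defaults (``default-median``,
    ``tendency-estimate``) carry no origin.
    """

    source: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.source not in PROVENANCE_SOURCES:
            raise ValidationError(f"unknown provenance source {self.source!r}")
        if self.source in ("default-median", "tendency-estimate") and (
            self.origin is not None
        ):
            raise ValidationError(
                f"{self.source} provenance must not carry an origin"
            )


def aggregate_parameter_records(
    records: Sequence[tuple[str, float]],
    source: str = "organism-match",
) -> tuple[float, Provenance]:
    """Median-aggregate multiple (origin, value) records for one parameter."""
    if not records:
        raise ValidationError("no records to aggregate")
    value = float(np.median([v for _, v in records]))
    origins = ";".join(sorted({o for o, _ in records}))
    return value, Provenance(source, origins)


def assign_concentrations(
    metabolite_ids: Sequence[str],
    known: Mapping[str, float],
    provenance: Mapping[str, Provenance] | None = None,
) -> tuple[np.ndarray, list[Provenance], float | None]:
    """Reference concentrations with median fallback.

    Known metabolites take their values (provenance from ``provenance``,
    defaulting to ``user``); the rest take the median of the known pool with
    ``default-median`` provenance.  Returns (x*, provenances, median used);
    the median is None when every metabolite is known.
    """
    provenance = dict(provenance or {})
    for mid, val in known.items():
        if val <= 0:
            raise ValidationError(
                f"concentration of {mid!r} must be positive, got {val}"
            )
    unknown = [m for m in metabolite_ids if m not in known]
    median: float | None = None
    if unknown:
        pool = [known[m] for m in metabolite_ids if m in known]
        if not pool:
            raise ValidationError(
                "no known concentrations to take a median from; provide an "
                "explicit default"
            )
        median = float(np.median(pool))
    x = np.empty(len(metabolite_ids))
    prov: list[Provenance] = []
    for i, mid in enumerate(metabolite_ids):
        if mid in known:
            x[i] = known[mid]
            prov.append(provenance.get(mid, Provenance("user")))
        else:
            x[i] = median
            prov.append(Provenance("default-median"))
    return x, prov, median


def assign_elasticities(
    N: np.ndarray,
    metabolite_ids: Sequence[str],
    reaction_ids: Sequence[str],
    reversible: Sequence[bool],
    known: Mapping[tuple[str, str], float] | None = None,
    known_provenance: Mapping[tuple[str, str], Provenance] | None = None,
) -> tuple[np.ndarray, dict[tuple[str, str], Provenance]]:
    """Scaled elasticity matrix (m x n) with tendency-modelling defaults.

    For every nonzero N_ij without a known value: eps_ij = -N_ij when the
    reaction is reversible; for irreversible reactions substrates (N_ij < 0)
    get -N_ij and products exactly 0.  Known entries override with their own
    provenance; entries where N_ij = 0 (explicit modifiers/effectors) come
    only from ``known``.
    """
    known = dict(known or {})
    known_provenance = dict(known_provenance or {})
    row = {m: i for i, m in enumerate(metabolite_ids)}
    col = {r: j for j, r in enumerate(reaction_ids)}
    for mid, rid in known:
        if mid not in row or rid not in col:
            raise ValidationError(
                f"known elasticity on unknown pair ({mid!r}, {rid!r})"
            )
    m, n = N.shape
    eps = np.zeros((m, n))
    prov: dict[tuple[str, str], Provenance] = {}
    tendency = Provenance("tendency-estimate")
    for j, rid in enumerate(reaction_ids):
        rev = bool(reversible[j])
        for i in np.nonzero(N[:, j])[0]:
            mid = metabolite_ids[i]
            if (mid, rid) in known:
                continue
            if rev or N[i, j] < 0:
                eps[i, j] = -N[i, j]
                prov[(mid, rid)] = tendency
            else:
                eps[i, j] = 0.0
                prov[(mid, rid)] = tendency
    for (mid, rid), val in known.items():
        if not np.isfinite(val):
            raise ValidationError(
                f"elasticity ({mid!r}, {rid!r}) is not finite"
            )
        eps[row[mid], col[rid]] = val
        prov[(mid, rid)] = known_provenance.get((mid, rid), Provenance("user"))
    return eps, prov


@dataclass
class KineticAssembly:
    """Reference state, elasticities and volumes with full provenance."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    x_star: np.ndarray
    x_provenance: list[Provenance]
    v_star: np.ndarray
    epsilon_scaled: np.ndarray  # m x n
    epsilon_provenance: dict[tuple[str, str], Provenance]
    volumes: np.ndarray  # per-metabolite compartment volume, length m
    extracellular: dict[str, float] = field(default_factory=dict)
    flux_provenance: list[Provenance] | None = None

    def __post_init__(self) -> None:
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        self.x_star = np.asarray(self.x_star, dtype=float)
        self.v_star = np.asarray(self.v_star, dtype=float)
        self.epsilon_scaled = np.asarray(self.epsilon_scaled, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.x_star.shape != (m,) or self.v_star.shape != (n,):
            raise ValidationError("assembly dimension mismatch")
        if self.epsilon_scaled.shape != (m, n):
            raise ValidationError("elasticity matrix must be m x n")
        if np.any(self.x_star <= 0):
            bad = [self.metabolite_ids[i]
                   for i in np.nonzero(self.x_star <= 0)[0]]
            raise ValidationError(f"non-positive reference concentration "
                                  f"for {bad}")
        if np.any(self.volumes <= 0):
            raise ValidationError("compartment volumes must be positive")
        if not np.all(np.isfinite(self.epsilon_scaled)):
            raise ValidationError("elasticities must be finite")

    def provenance_summary(self) -> dict[str, dict[str, int]]:
        """Counts per provenance class for concentrations, elasticities
        and (when recorded) fluxes."""
        out: dict[str, dict[str, int]] = {}

        def tally(items) -> dict[str, int]:
            counts: dict[str, int] = {}
            for p in items:
                counts[p.source] = counts.get(p.source, 0) + 1
            return dict(sorted(counts.items()))

        out["concentrations"] = tally(self.x_provenance)
        out["elasticities"] = tally(self.epsilon_provenance.values())
        if self.flux_provenance is not None:
            out["fluxes"] = tally(self.flux_provenance)
        return out


def unscaled_elasticity_matrix(assembly: KineticAssembly) -> np.ndarray:
    """The n x m unscaled elasticity matrix eps'.

    eps'_{ji} = v*_j * eps_ij / x*_i, the partial derivative of rate j with
    respect to concentration i at the reference state.  Rows belonging to
    zero-flux reactions are identically zero; this is what can push
    rank(N . eps') below rank(N) and is deliberately preserved.
    """
    return (assembly.v_star[:, None] * assembly.epsilon_scaled.T
            / assembly.x_star[None, :])


@dataclass
class LinlogModel:
    """An evaluable linlog kinetic model around the reference state."""

    assembly: KineticAssembly
    N: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        m = len(self.assembly.metabolite_ids)
        n = len(self.assembly.reaction_ids)
        if self.N.shape != (m, n):
            raise ValidationError("N must be m x n")

    def _check_positive(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != self.assembly.x_star.shape:
            raise ValidationError("state vector has wrong length")
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            names = [self.assembly.metabolite_ids[i] for i in bad]
            raise ValidationError(
                f"non-positive concentration for {names}; linlog rates are "
                "undefined at zero"
            )
        return x

    def evaluate_rates(self, x: np.ndarray) -> np.ndarray:
        """v_j(x) = v*_j (1 + sum_i eps_ij ln(x_i/x*_i)); may be negative."""
        x = self._check_positive(x)
        logs = np.log(x / self.assembly.x_star)
        return self.assembly.v_star * (
            1.0 + self.assembly.epsilon_scaled.T @ logs
        )

    def time_derivative(self, x: np.ndarray) -> np.ndarray:
        """dx/dt = diag(c)^-1 N v(x) (mM/s); boundary species are not part
        of the state and therefore implicitly constant."""
        v = self.evaluate_rates(x)
        return (self.N @ v) / self.assembly.volumes

    def jacobian(self) -> np.ndarray:
        """Analytic Jacobian of dx/dt at x*: diag(c)^-1 N eps'."""
        eps_prime = unscaled_elasticity_matrix(self.assembly)
        return (self.N @ eps_prime) / self.assembly.volumes[:, None]
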