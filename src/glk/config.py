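"""Run configuration: tolerances, switches, defaults and the config hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

from .errors import ValidationError


@dataclass
class RunConfig:
    """Tunable settings shared across the pipeline stages.

    Tolerances are absolute unless noted.  ``feasibility_tolerance`` bounds
    ||N v||_inf for accepted fluxes (1e-9 suits desk-scale problems; relax
    to ~1e-6 at genome scale).  ``rank_tolerance`` is relative to the
    largest singular value.
    """

    feasibility_tolerance: float = 1e-9
    rank_tolerance: float = 1e-9
    convergence_tolerance: float = 1e-6   # mM/s, centering box width
    max_iterations: int = 50
    objective_ordering: str = "lexicographic"  # or "targets-first"
    distance_norm: str = "l1"                  # or "l2" (target fitting)
    default_bound: float = 1000.0              # mM/s
    default_volume: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("feasibility_tolerance", "rank_tolerance",
                     "convergence_tolerance", "default_bound",
                     "default_volume"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.objective_ordering not in ("lexicographic", "targets-first"):
            raise ValidationError(
                f"unknown objective_ordering {self.objective_ordering!r}"
            )
        if self.distance_norm not in ("l1", "l2"):
            raise ValidationError(
                f"unknown distance_norm {self.distance_norm!r}"
            )

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file."""
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 'key = value'"
                    )
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in types:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown setting {key!r}"
                    )
                if types[key] in ("float", float):
                    kwargs[key] = float(value)
                elif types[key] in ("int", int):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)
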