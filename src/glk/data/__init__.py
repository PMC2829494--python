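"""Packaged parameter tables.

``yeast_targets.tsv``, ``yeast_concentrations.tsv`` and
``yeast_extracellular.tsv`` reproduce the published yeast kinetic inputs
(21 curated reference fluxes, 22 intracellular concentrations, the
metabolic-footprinting extracellular medium).  ``biomass_synthetic.tsv`` is
a synthetic stand-in composition table for demonstrations.
"""

from importlib import resources
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a packaged table."""
    with resources.as_file(
        resources.files("glk.data").joinpath(name)
    ) as p:
        return Path(p)
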