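"""Bundled datasets."""

from __future__ import annotations

from importlib import resources

from .grid import GridDialect, SolubilityGrid, load_grid

__all__ = ["load_sulfamerazine", "sulfamerazine_path"]


def sulfamerazine_path():
    """Path to the bundled sulfamerazine {MeCN (1) + EtOH (2)} table."""
    return resources.files("solutherm.data").joinpath("sulfamerazine_mecn_etoh.csv")


def load_sulfamerazine() -> SolubilityGrid:
    """Mole-fraction solubility of sulfamerazine in acetonitrile (1) +
    ethanol (2) mixtures: 21 compositions (w1 = 0.00-1.00 in steps of 0.05)
    at nine temperatures, 278.15-318.15 K in steps of 5 K; 189 points with
    standard uncertainties, stored as true mole fractions.
    """
    with resources.as_file(sulfamerazine_path()) as p:
        return load_grid(p, GridDialect(), labels=("MeCN", "EtOH"))
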