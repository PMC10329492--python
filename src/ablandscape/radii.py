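"""NACCESS-style van der Waals radii, keyed by (residue, atom name).

The table ships with the package and is versioned bit-exactly; element-level
fallbacks (rows with residue ``*``) cover atoms absent from the per-residue
entries. An atom with neither entry receives a configurable default radius
and triggers a warning.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["RadiiTable", "default_radii"]

DEFAULT_FALLBACK_RADIUS = 1.80


class RadiiTable:
    def __init__(self, table: pd.DataFrame, fallback: float = DEFAULT_FALLBACK_RADIUS):
        self._by_res_atom: dict[tuple[str, str], float] = {}
        self._by_element: dict[str, float] = {}
        for res, atom, r in table.itertuples(index=False):
            if res == "*":
                self._by_element[atom.upper()] = float(r)
            else:
                self._by_res_atom[(res.upper(), atom.upper())] = float(r)
        self.fallback = fallback

    def radius(self, resname3: str, atom_name: str, element: str = "") -> float:
        r = self._by_res_atom.get((resname3.upper(), atom_name.upper()))
        if r is not None:
            return r
        r = self._by_element.get(element.upper() or atom_name[:1].upper())
        if r is not None:
            return r
        warnings.warn(
            f"no radius for {resname3}/{atom_name} (element {element!r}); "
            f"using fallback {self.fallback} A"
        )
        return self.fallback


@lru_cache(maxsize=1)
def default_radii() -> RadiiTable:
    with resources.files("ablandscape.data").joinpath("naccess_radii.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return RadiiTable(table)
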