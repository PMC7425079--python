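"""Bundled worked-example data.

Small literature-reported tables used in docs, examples and validation:
the fragment populations of four triazole-linked Ru tris-bipyridine
complexes (click-chemistry adducts whose N- vs C-connected triazole flips
the direction of the excitation) and the dmb/dcb dye composition for the
additivity predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .fragments import FragmentScheme, merge_fragments, merge_populations
from .predictor import LigandComposition

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class TriazoleComplex:
    """One triazole-linked complex: 5-fragment populations + published SIEL."""

    name: str
    r1: str
    populations: np.ndarray  # percent, ordered as scheme.fragment_names
    reported_siel: float


def load_triazole_complexes() -> tuple[FragmentScheme, dict[str, TriazoleComplex]]:
    """The 5-fragment scheme (bpy1 substituted) and the four complexes."""
    with open(_DATA / "triazole_complexes.yaml") as fh:
        raw = yaml.safe_load(fh)
    scheme = FragmentScheme(raw["fragments"], raw["roles"]).with_substituted("bpy1")
    complexes = {}
    for name, row in raw["complexes"].items():
        pops = np.array([row["populations"][f] for f in scheme.fragment_names], float)
        complexes[name] = TriazoleComplex(
            name=name,
            r1=row["r1"],
            populations=pops,
            reported_siel=float(row["reported_siel"]),
        )
    return scheme, complexes


def triazole_merged_populations(
    scheme: FragmentScheme, complex_: TriazoleComplex
) -> tuple[FragmentScheme, np.ndarray]:
    """Fold the triazole linker into its bpy, giving the 4-fragment view."""
    merged_scheme, assignment = merge_fragments(scheme, "triazole", "bpy1")
    return merged_scheme, merge_populations(complex_.populations, assignment)


def dmb_dcb_composition() -> LigandComposition:
    """[Ru(dmb)2(dcb)]2+: two methyls per dmb, two carboxylic acids on dcb."""
    return LigandComposition(
        {
            "dcb": ("COOH", "COOH"),
            "dmb_a": ("CH3", "CH3"),
            "dmb_b": ("CH3", "CH3"),
        }
    )
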