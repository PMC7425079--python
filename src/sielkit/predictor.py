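"""Additivity-based design rule for directional excitations.

Per-substituent SIEL contributions, tabulated once on a reference scaffold
(one substituent at the 4-position of one bipyridine of a tris-bipyridine
complex), are summed per ligand to predict where a multi-substituted
complex will direct its excited electron.  The classic worked example is
the dye [Ru(dmb)2(dcb)]2+: two carboxylic acids on the dcb ligand give a
net SIEL of 2 × (−0.71) = −1.42 (strong attraction, towards the
semiconductor surface the acid groups anchor to), while two methyls on each
dmb give 2 × (+0.26) = +0.52 (repulsion) — so the excitation goes to dcb.

The rule is plain summation: no saturation, no cross-ligand coupling.  Net
values therefore live on an open scale and may leave the single-state SIEL
range [−1, 1/(m−1)]; they rank ligands, they are not populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats
import yaml

from .descriptors import classify_direction
from .errors import SielkitError, UnknownSubstituentError

SINGLET = "singlet"
TRIPLET = "triplet"

_BUNDLED_TABLE = Path(__file__).parent / "data" / "substituents.yaml"


@dataclass(frozen=True)
class SubstituentEntry:
    """Tabulated contributions of one substituent."""

    siel_singlet: float | None
    siel_triplet: float | None
    sigma_p: float | None = None
    sigma_p_plus: float | None = None

    def siel(self, state: str) -> float:
        value = self.siel_singlet if state == SINGLET else self.siel_triplet
        if value is None:
            raise SielkitError(f"no {state} SIEL tabulated for this substituent")
        return value


@dataclass(frozen=True)
class SubstituentTable:
    """Label → per-substituent SIEL contributions (and optional Hammett σ)."""

    entries: dict[str, SubstituentEntry]

    def __post_init__(self):
        for label, entry in self.entries.items():
            if not isinstance(entry, SubstituentEntry):
                raise TypeError(f"entry {label!r} is not a SubstituentEntry")

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> SubstituentEntry:
        try:
            return self.entries[label]
        except KeyError:
            raise UnknownSubstituentError(
                f"substituent {label!r} not in table "
                f"(known: {sorted(self.entries)})"
            ) from None

    @classmethod
    def from_dict(cls, data: dict) -> "SubstituentTable":
        entries = {}
        for label, row in data.items():
            entries[str(label)] = SubstituentEntry(
                siel_singlet=row.get("siel_singlet"),
                siel_triplet=row.get("siel_triplet"),
                sigma_p=row.get("sigma_p"),
                sigma_p_plus=row.get("sigma_p_plus"),
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubstituentTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data.get("substituents", data))

    @classmethod
    def bundled(cls) -> "SubstituentTable":
        """Literature triplet-state contributions shipped with the package."""
        return cls.from_yaml(_BUNDLED_TABLE)


@dataclass(frozen=True)
class LigandComposition:
    """Ligand label → multiset of substituent labels (empty = unsubstituted)."""

    ligands: dict[str, tuple[str, ...]]

    def __init__(self, ligands: dict):
        object.__setattr__(
            self,
            "ligands",
            {str(k): tuple(v) for k, v in ligands.items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LigandComposition":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data.get("ligands", data))


def predict_net_siel(
    comp: LigandComposition,
    table: SubstituentTable,
    state: str = TRIPLET,
) -> dict[str, float]:
    """Net SIEL per ligand: the sum of its substituents' tabulated values.

    ``state`` picks the singlet or triplet column; triplet is the default
    because the long-lived charge-transfer state that drives the subsequent
    photochemistry is the relaxed triplet.
    """
    if state not in (SINGLET, TRIPLET):
        raise ValueError(f"state must be 'singlet' or 'triplet', got {state!r}")
    return {
        ligand: float(sum(table[label].siel(state) for label in subs))
        for ligand, subs in comp.ligands.items()
    }


def rank_ligands(net_siel: dict[str, float], tol: float | None = None) -> list[tuple[str, float, str]]:
    """Order ligands from most attracting (lowest net SIEL) upward.

    Returns (ligand, net_siel, direction) triples; ties break
    alphabetically so the ranking is deterministic regardless of the input
    dict's ordering.
    """
    if not net_siel:
        raise SielkitError("no ligands to rank")
    kwargs = {} if tol is None else {"tol": tol}
    return [
        (ligand, float(value), classify_direction(value, **kwargs))
        for ligand, value in sorted(net_siel.items(), key=lambda kv: (kv[1], kv[0]))
    ]


def correlate_constants(x, y) -> dict[str, float]:
    """Ordinary least-squares fit of y on x with R².

    Used to compare SIEL against empirical ground-state substituent scales
    such as the Hammett σp constants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SielkitError(f"x and y must be equal-length 1-D vectors, got {x.shape}, {y.shape}")
    if x.size < 3:
        raise SielkitError(f"need at least 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SielkitError("x and y must be finite")
    fit = scipy.stats.linregress(x, y)
    # linregress r is NaN for constant y; zero explained variance is 0
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept), "r_squared": r2}
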