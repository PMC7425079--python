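"""Fragment schemes: how a complex is partitioned for exciton analysis.

A :class:`FragmentScheme` names the fragments of a coordination complex
(typically the metal centre plus its ligands), records which fragments play
the ligand role, and optionally marks the ligand that carries the chemical
substituent of interest.  The scheme fixes the two integers that appear in
the descriptors: ``n`` (all fragments, used by the participation ratio and
the delocalization-length histogram) and ``m`` (ligand fragments only, used
by the substituent-induced localization descriptor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemeError

METAL = "metal"
LIGAND = "ligand"


@dataclass(frozen=True)
class FragmentScheme:
    """Partition of a complex into named fragments.

    Parameters
    ----------
    fragment_names
        One label per fragment, e.g. ``["Ru", "bpy1", "bpy2", "bpy3"]``.
    roles
        Per-fragment role, each ``"metal"`` or ``"ligand"``.  At most one
        fragment may be the metal centre.
    substituted_index
        Index (into ``fragment_names``) of the ligand bearing the
        substituent R.  Required only for SIEL.
    """

    fragment_names: tuple[str, ...]
    roles: tuple[str, ...]
    substituted_index: int | None = None

    def __init__(self, fragment_names, roles, substituted_index=None):
        object.__setattr__(self, "fragment_names", tuple(fragment_names))
        object.__setattr__(self, "roles", tuple(roles))
        object.__setattr__(self, "substituted_index", substituted_index)
        self._validate()

    def _validate(self) -> None:
        if len(self.fragment_names) != len(self.roles):
            raise SchemeError(
                f"{len(self.fragment_names)} names but {len(self.roles)} roles"
            )
        if len(self.fragment_names) == 0:
            raise SchemeError("a scheme needs at least one fragment")
        if len(set(self.fragment_names)) != len(self.fragment_names):
            raise SchemeError("fragment names must be unique")
        bad = [r for r in self.roles if r not in (METAL, LIGAND)]
        if bad:
            raise SchemeError(f"unknown role(s) {bad}; use 'metal' or 'ligand'")
        if self.roles.count(METAL) > 1:
            raise SchemeError("at most one metal fragment is allowed")
        if self.substituted_index is not None:
            i = self.substituted_index
            if not (0 <= i < len(self.roles)):
                raise SchemeError(f"substituted_index {i} out of range")
            if self.roles[i] != LIGAND:
                raise SchemeError(
                    f"substituted fragment {self.fragment_names[i]!r} must be a ligand"
                )

    @property
    def n_fragments(self) -> int:
        """Total number of fragments, n."""
        return len(self.fragment_names)

    @property
    def n_ligands(self) -> int:
        """Number of ligand-role fragments, m."""
        return self.roles.count(LIGAND)

    @property
    def metal_index(self) -> int | None:
        """Index of the metal fragment, or None for ligand-only schemes."""
        try:
            return self.roles.index(METAL)
        except ValueError:
            return None

    @property
    def ligand_indices(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.roles) if r == LIGAND)

    def ligand_position(self, fragment_index: int) -> int:
        """Position of a fragment within the ligand-only ordering."""
        if self.roles[fragment_index] != LIGAND:
            raise SchemeError(
                f"fragment {self.fragment_names[fragment_index]!r} is not a ligand"
            )
        return self.ligand_indices.index(fragment_index)

    def with_substituted(self, name_or_index: str | int) -> "FragmentScheme":
        """Return a copy with the substituted ligand set."""
        if isinstance(name_or_index, str):
            if name_or_index not in self.fragment_names:
                raise SchemeError(f"no fragment named {name_or_index!r}")
            idx = self.fragment_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return FragmentScheme(self.fragment_names, self.roles, idx)


def merge_fragments(
    scheme: FragmentScheme, source: str | int, target: str | int
) -> tuple[FragmentScheme, np.ndarray]:
    """Merge one fragment into another, e.g. a triazole linker into its bpy.

    Returns the reduced scheme and an assignment vector ``a`` of length
    ``scheme.n_fragments`` with ``a[old] = new`` so population vectors and
    charge-transfer matrices can be aggregated consistently: merged
    population ``p'[j] = sum_{a[i]=j} p[i]``.
    """

    def _idx(x):
        return scheme.fragment_names.index(x) if isinstance(x, str) else int(x)

    src, tgt = _idx(source), _idx(target)
    if src == tgt:
        raise SchemeError("cannot merge a fragment into itself")
    keep = [i for i in range(scheme.n_fragments) if i != src]
    assignment = np.empty(scheme.n_fragments, dtype=int)
    for new, old in enumerate(keep):
        assignment[old] = new
    assignment[src] = assignment[tgt]

    names = tuple(scheme.fragment_names[i] for i in keep)
    roles = tuple(scheme.roles[i] for i in keep)
    sub = scheme.substituted_index
    if sub is not None:
        sub = int(assignment[sub])
    return FragmentScheme(names, roles, sub), assignment


def merge_populations(pops: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Aggregate a per-fragment population vector under a merge assignment."""
    pops = np.asarray(pops, dtype=float)
    out = np.zeros(int(assignment.max()) + 1)
    np.add.at(out, assignment, pops)
    return out
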