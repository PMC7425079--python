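"""Excited-state containers: single states and geometry ensembles.

An :class:`ExcitonState` holds the fragment-resolved excited-electron
population of one excited state at one nuclear geometry, together with its
energy, oscillator strength and spin multiplicity.  An
:class:`EnsembleBand` collects many such states (e.g. 25 singlets over each
of 100 geometries) — the unit over which delocalization-length histograms
and ensemble SIEL statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyEnsembleError, InvalidPopulationError, ShapeError
from .fragments import FragmentScheme

logger = logging.getLogger(__name__)

SINGLET = "singlet"
TRIPLET = "triplet"

#: Raw populations whose sum deviates from 1 by more than this are assumed
#: to come from truncated state expansions and trigger a warning (they are
#: still renormalized).
NORMALIZATION_WARN_TOL = 0.05


@dataclass(frozen=True)
class ExcitonState:
    """One excited state at one geometry.

    ``electron_pops`` is the per-fragment excited-electron population vector
    e_i; it is renormalized to unit sum on construction.  ``hole_pops``, if
    given, is treated the same way.
    """

    geometry_id: str
    state_index: int
    multiplicity: str
    energy: float  # eV
    electron_pops: np.ndarray
    oscillator_strength: float | None = None
    hole_pops: np.ndarray | None = None

    def __init__(
        self,
        geometry_id,
        state_index,
        multiplicity,
        energy,
        electron_pops,
        oscillator_strength=None,
        hole_pops=None,
    ):
        e = np.asarray(electron_pops, dtype=float)
        if e.ndim != 1 or e.size == 0:
            raise ShapeError("electron_pops must be a nonempty 1-D vector")
        if np.any(e < 0):
            raise InvalidPopulationError(
                f"negative electron population in state {state_index} "
                f"of geometry {geometry_id}: {e}"
            )
        total = float(e.sum())
        if total <= 0:
            raise InvalidPopulationError(
                f"zero total electron population in state {state_index} "
                f"of geometry {geometry_id}"
            )
        if abs(total - 1.0) > NORMALIZATION_WARN_TOL:
            logger.warning(
                "raw electron populations of geometry %s state %s sum to %.4f; "
                "renormalizing (truncated expansion?)",
                geometry_id,
                state_index,
                total,
            )
        e = e / total
        e.setflags(write=False)

        if multiplicity not in (SINGLET, TRIPLET):
            raise ValueError(f"multiplicity must be 'singlet' or 'triplet', got {multiplicity!r}")
        if oscillator_strength is not None and oscillator_strength < 0:
            raise ValueError("oscillator strength must be >= 0")

        h = None
        if hole_pops is not None:
            h = np.asarray(hole_pops, dtype=float)
            if h.shape != e.shape:
                raise ShapeError("hole_pops must match electron_pops in length")
            if np.any(h < 0) or h.sum() <= 0:
                raise InvalidPopulationError("invalid hole populations")
            h = h / h.sum()
            h.setflags(write=False)

        object.__setattr__(self, "geometry_id", str(geometry_id))
        object.__setattr__(self, "state_index", int(state_index))
        object.__setattr__(self, "multiplicity", multiplicity)
        object.__setattr__(self, "energy", float(energy))
        object.__setattr__(self, "electron_pops", e)
        object.__setattr__(
            self,
            "oscillator_strength",
            None if oscillator_strength is None else float(oscillator_strength),
        )
        object.__setattr__(self, "hole_pops", h)

    @property
    def n_fragments(self) -> int:
        return self.electron_pops.size


@dataclass
class EnsembleBand:
    """A band of excited states over a geometry ensemble."""

    states: list[ExcitonState]
    scheme: FragmentScheme
    label: str = ""

    def __post_init__(self):
        if not self.states:
            raise EmptyEnsembleError(f"band {self.label!r} contains no states")
        n = self.scheme.n_fragments
        for s in self.states:
            if s.n_fragments != n:
                raise ShapeError(
                    f"state {s.state_index} of geometry {s.geometry_id} has "
                    f"{s.n_fragments} fragments, scheme has {n}"
                )

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def electron_pops(self) -> np.ndarray:
        """(n_states, n_fragments) matrix of normalized electron populations."""
        return np.vstack([s.electron_pops for s in self.states])

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states])

    @property
    def oscillator_strengths(self) -> np.ndarray:
        """Oscillator strengths; raises if any state lacks one."""
        fs = [s.oscillator_strength for s in self.states]
        if any(f is None for f in fs):
            raise InvalidPopulationError(
                "band contains states without oscillator strengths"
            )
        return np.array(fs, dtype=float)


@dataclass(frozen=True)
class DescriptorSummary:
    """Ensemble-level descriptor report for one band."""

    eedl: dict[int, float]  # n -> percentage of states
    siel_mean: float | None
    siel_std: float | None
    n_states: int
    weighting: str
    label: str = ""

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n_states": self.n_states,
            "weighting": self.weighting,
            "siel_mean": self.siel_mean,
            "siel_std": self.siel_std,
        }
        for n in sorted(self.eedl):
            d[f"eedl_{n}"] = self.eedl[n]
        return d
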