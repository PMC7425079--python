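"""Seeded synthetic ensembles and toy transition density matrices.

Real inputs to the descriptor pipeline are fragment populations from
TD-DFT calculations over a thermally sampled geometry ensemble (typically
25 states × 100 geometries for an absorption band).  The generators here
emulate that data shape without any electronic-structure calculation:

* :func:`generate_ensemble` draws per-state electron populations from a
  Dirichlet distribution on the fragment simplex — a single concentration
  vector α tunes localization (α spiked on one fragment → localized states,
  large uniform α → evenly delocalized states) — with normal state energies
  and folded-normal oscillator strengths;

* :func:`generate_toy_tdm` builds a small random AO-basis transition
  density matrix with a diagonally dominant SPD overlap, its electron-side
  weight concentrated on a chosen fragment.

Dirichlet sampling is a stand-in, not a physical model of TD-DFT
ensembles: it reproduces the support and normalization of real population
data, not its energy–population correlations.  All randomness flows from
an explicit integer seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError
from .fragments import FragmentScheme
from .states import SINGLET, EnsembleBand, ExcitonState
from .tdm import AOContext


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic band.

    ``concentration`` is the Dirichlet α (one entry per fragment);
    ``energy_center``/``energy_spread`` are the mean and standard deviation
    of the normal law the state energies are drawn from, in eV.
    """

    n_geometries: int
    n_states_per_geometry: int
    n_fragments: int
    concentration: tuple[float, ...]
    seed: int
    energy_center: float = 2.9
    energy_spread: float = 0.15
    multiplicity: str = SINGLET

    def __post_init__(self):
        if self.n_geometries < 1 or self.n_states_per_geometry < 1:
            raise ValueError("geometry and state counts must be >= 1")
        if self.n_fragments < 1:
            raise ValueError("need at least one fragment")
        alpha = tuple(float(a) for a in self.concentration)
        if len(alpha) != self.n_fragments:
            raise ShapeError(
                f"concentration has {len(alpha)} entries for "
                f"{self.n_fragments} fragments"
            )
        if any(a <= 0 for a in alpha):
            raise ValueError("all Dirichlet concentrations must be > 0")
        object.__setattr__(self, "concentration", alpha)


def generate_ensemble(spec: SyntheticSpec, scheme: FragmentScheme, label: str = "synthetic") -> EnsembleBand:
    """Draw a reproducible synthetic band matching ``spec`` on ``scheme``."""
    if scheme.n_fragments != spec.n_fragments:
        raise ShapeError(
            f"scheme has {scheme.n_fragments} fragments, spec {spec.n_fragments}"
        )
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_geometries * spec.n_states_per_geometry
    pops = rng.dirichlet(spec.concentration, size=n_total)
    energies = rng.normal(spec.energy_center, spec.energy_spread, size=n_total)
    osc = np.abs(rng.normal(0.0, 0.05, size=n_total))
    states = []
    k = 0
    for g in range(spec.n_geometries):
        for s in range(spec.n_states_per_geometry):
            states.append(
                ExcitonState(
                    geometry_id=f"g{g:04d}",
                    state_index=s + 1,
                    multiplicity=spec.multiplicity,
                    energy=energies[k],
                    electron_pops=pops[k],
                    oscillator_strength=osc[k],
                )
            )
            k += 1
    return EnsembleBand(states=states, scheme=scheme, label=label)


def localization_concentration(
    n_fragments: int, target_index: int, target_mean: float, strength: float = 20.0
) -> tuple[float, ...]:
    """Dirichlet α whose mean population on one fragment is ``target_mean``.

    With total concentration ``strength``, the Dirichlet mean on fragment i
    is α_i / strength; the remainder is spread evenly over the others.
    """
    if not 0 < target_mean < 1:
        raise ValueError("target_mean must be in (0, 1)")
    alpha = np.full(n_fragments, strength * (1 - target_mean) / (n_fragments - 1))
    alpha[target_index] = strength * target_mean
    return tuple(alpha)


def generate_toy_tdm(
    n_ao: int,
    scheme: FragmentScheme,
    target_electron_fragment: int,
    seed: int,
    identity_overlap: bool = False,
) -> AOContext:
    """Random small AOContext with electron weight piled on one fragment.

    AOs are dealt round-robin to fragments, so every fragment owns at least
    one AO when ``n_ao >= n_fragments``.  The overlap is built diagonally
    dominant (I + small symmetric noise), hence SPD.
    """
    n_frag = scheme.n_fragments
    if n_ao < n_frag:
        raise ShapeError(f"need at least {n_frag} AOs, got {n_ao}")
    if not 0 <= target_electron_fragment < n_frag:
        raise ShapeError(f"target fragment {target_electron_fragment} out of range")
    rng = np.random.default_rng(seed)
    ao_fragments = np.arange(n_ao) % n_frag

    d = rng.normal(0.0, 0.1, size=(n_ao, n_ao))
    target_cols = ao_fragments == target_electron_fragment
    d[:, target_cols] += rng.normal(0.0, 1.0, size=(n_ao, int(target_cols.sum())))

    if identity_overlap:
        s = np.eye(n_ao)
    else:
        noise = rng.normal(0.0, 0.05 / n_ao, size=(n_ao, n_ao))
        s = np.eye(n_ao) + 0.5 * (noise + noise.T)
    return AOContext(tdm=d, overlap=s, ao_fragments=ao_fragments)
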