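"""Orbital-free exciton descriptors.

Three quantities characterize where an electronic excitation puts the
excited electron, using only fragment-resolved populations (no orbitals):

* the final participation ratio ``PR_f = (Σ e_i)² / Σ e_i²``, an
  inverse-participation-style count of how many fragments effectively share
  the excited electron (1 = fully localized, n = evenly spread over all n
  fragments);

* the excited-electron delocalization length ``EEDL_n``, the percentage of
  ensemble states whose PR_f falls in the unit-width bin around the integer
  n — a histogram of delocalization lengths over a geometry ensemble;

* the substituent-induced exciton localization
  ``SIEL = (1/(m−1)) Σ_{i≠R} ê_i − ê_R``, a signed scalar computed over the
  m ligand fragments only (metal dropped, populations renormalized) that
  measures whether the functional group on ligand R attracts (SIEL < 0) or
  repels (SIEL > 0) the excited electron relative to an even spread
  (SIEL = 0).  Its range is [−1, 1/(m−1)]: −1 when the electron sits
  entirely on the substituted ligand, 1/(m−1) when it avoids it completely.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import (
    DegenerateSchemeError,
    EmptyEnsembleError,
    InvalidPopulationError,
    InvalidPRError,
    InvalidTemperatureError,
    SchemeError,
)
from .fragments import FragmentScheme
from .states import DescriptorSummary, EnsembleBand

#: Boltzmann constant in eV/K.
K_B_EV = 8.617333e-5

ATTRACT = "attract"
REPEL = "repel"
NEUTRAL = "neutral"

#: Default dead band for direction classification: ensemble-mean SIEL of an
#: unsubstituted parent complex is ~0 but never exactly 0 over a finite
#: ensemble.
DIRECTION_TOL = 0.02


def _check_pops(pops) -> np.ndarray:
    e = np.asarray(pops, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise InvalidPopulationError("population vector must be nonempty and 1-D")
    if np.any(e < 0):
        raise InvalidPopulationError(f"negative population entries: {e}")
    if e.sum() <= 0:
        raise InvalidPopulationError("all-zero population vector")
    return e


def participation_ratio(electron_pops) -> float:
    """Final participation ratio PR_f of a fragment population vector.

    Scale-invariant: the vector need not be normalized.  Bounded by
    ``1 <= PR_f <= n`` with equality at full localization / uniformity.
    """
    e = _check_pops(electron_pops)
    s = e.sum()
    return float(s * s / np.dot(e, e))


def eedl_bin(pr: float) -> int:
    """Integer delocalization-length bin of a participation ratio.

    Bin n collects ``n − 0.5 < PR_f < n + 0.5``; exact half-integers round
    up (1.5 → 2).
    """
    if pr < 1:
        raise InvalidPRError(f"participation ratio {pr} < 1")
    return int(math.floor(pr + 0.5))


def eedl_spectrum(band: EnsembleBand, max_n: int | None = None) -> dict[int, float]:
    """EEDL_n histogram of a band: percentage of states per bin n = 1..max_n.

    Bins above the number of fragments are structurally empty (PR_f <= n)
    and reported as exact zeros.  The percentages sum to 100.
    """
    if max_n is None:
        max_n = band.scheme.n_fragments
    if max_n < band.scheme.n_fragments:
        raise ValueError(
            f"max_n={max_n} is below the fragment count {band.scheme.n_fragments}"
        )
    counts = dict.fromkeys(range(1, max_n + 1), 0)
    for state in band:
        counts[eedl_bin(participation_ratio(state.electron_pops))] += 1
    total = len(band)
    return {n: 100.0 * c / total for n, c in counts.items()}


def _ligand_pops(electron_pops, scheme: FragmentScheme) -> np.ndarray:
    """Drop the metal fragment and renormalize over the m ligands."""
    e = _check_pops(electron_pops)
    if e.size != scheme.n_fragments:
        raise SchemeError(
            f"population vector has {e.size} entries, scheme {scheme.n_fragments}"
        )
    lig = e[list(scheme.ligand_indices)]
    total = lig.sum()
    if total <= 0:
        raise InvalidPopulationError("zero total ligand population")
    return lig / total


def siel_state(electron_pops, scheme: FragmentScheme) -> float:
    """SIEL of one state: (1/(m−1)) Σ_{i≠R} ê_i − ê_R over ligand fragments.

    ``electron_pops`` spans all fragments of ``scheme``; the metal (if any)
    is dropped and the ligand populations ê renormalized before evaluation.
    The scheme must mark the substituted ligand R.
    """
    if scheme.substituted_index is None:
        raise SchemeError("scheme does not mark a substituted ligand")
    m = scheme.n_ligands
    if m < 2:
        raise DegenerateSchemeError(f"SIEL needs at least 2 ligand fragments, got {m}")
    e_hat = _ligand_pops(electron_pops, scheme)
    r = scheme.ligand_position(scheme.substituted_index)
    return float((e_hat.sum() - e_hat[r]) / (m - 1) - e_hat[r])


def siel_bounds(m: int) -> tuple[float, float]:
    """(min, max) attainable SIEL for m ligand fragments: (−1, 1/(m−1))."""
    if m < 2:
        raise DegenerateSchemeError(f"SIEL needs at least 2 ligand fragments, got {m}")
    return -1.0, 1.0 / (m - 1)


def boltzmann_weights(energies, temperature: float) -> np.ndarray:
    """Normalized Boltzmann weights of a set of state energies (eV) at T (K).

    Shift-invariant: energies are referenced to their minimum before
    exponentiation, so adding a constant changes nothing.
    """
    if temperature <= 0:
        raise InvalidTemperatureError(f"temperature must be > 0 K, got {temperature}")
    e = np.asarray(energies, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    w = np.exp(-(e - e.min()) / (K_B_EV * temperature))
    return w / w.sum()


def _state_weights(band: EnsembleBand, weighting: str, temperature: float | None):
    if weighting == "uniform":
        return np.full(len(band), 1.0 / len(band))
    if weighting == "boltzmann":
        if temperature is None:
            raise InvalidTemperatureError("boltzmann weighting requires a temperature")
        return boltzmann_weights(band.energies, temperature)
    if weighting == "oscillator":
        f = band.oscillator_strengths
        if f.sum() <= 0:
            raise InvalidPopulationError("all oscillator strengths are zero")
        return f / f.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def siel_ensemble(
    band: EnsembleBand,
    weighting: str = "uniform",
    temperature: float | None = None,
) -> tuple[float, float]:
    """Weighted mean and standard deviation of per-state SIEL over a band.

    ``weighting`` is one of ``uniform`` (every state counts equally, the
    default for absorption bands), ``boltzmann`` (thermal weights from state
    energies at ``temperature``; appropriate for a near-degenerate triplet
    manifold) or ``oscillator`` (bright states count more).
    """
    w = _state_weights(band, weighting, temperature)
    vals = np.array([siel_state(s.electron_pops, band.scheme) for s in band])
    mean = float(np.dot(w, vals))
    var = float(np.dot(w, (vals - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


def classify_direction(siel: float, tol: float = DIRECTION_TOL) -> str:
    """Label a SIEL value: 'attract' (< −tol), 'repel' (> +tol) or 'neutral'."""
    if siel < -tol:
        return ATTRACT
    if siel > tol:
        return REPEL
    return NEUTRAL


def summarize(
    band: EnsembleBand,
    weighting: str = "uniform",
    temperature: float | None = None,
    max_n: int | None = None,
) -> DescriptorSummary:
    """Full descriptor report for a band: EEDL histogram + SIEL statistics.

    SIEL entries are None when the scheme does not mark a substituted
    ligand (e.g. an unsubstituted parent complex analyzed only for
    delocalization).
    """
    eedl = eedl_spectrum(band, max_n=max_n)
    if band.scheme.substituted_index is not None:
        siel_mean, siel_std = siel_ensemble(band, weighting, temperature)
    else:
        siel_mean = siel_std = None
    return DescriptorSummary(
        eedl=eedl,
        siel_mean=siel_mean,
        siel_std=siel_std,
        n_states=len(band),
        weighting=weighting,
        label=band.label,
    )
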