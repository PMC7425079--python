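"""Fragment analysis of one-electron transition density matrices.

The one-electron transition density matrix (1TDM) D couples hole and
excited-electron amplitudes between the ground and an excited state in an
atomic-orbital basis (row = hole AO, column = electron AO).  Partitioning
the AOs into molecular fragments turns D, together with the AO overlap
matrix S, into a small fragment × fragment matrix of charge-transfer
numbers Ω_AB — the weight of the excitation with the hole on fragment A and
the electron on fragment B.  Everything downstream (electron/hole fragment
populations, MLCT/LLCT/MC/LC character, NTO weights) is read off Ω or the
overlap-dressed matrix S^{1/2} D S^{1/2}.

Two partitioning styles are provided:

* ``mulliken`` (default): Ω_ab = ½[(DS)_ab (SD)_ab + D_ab (SDS)_ab],
  summed over AO pairs a∈A, b∈B;
* ``lowdin``: Ω_ab = (S^{1/2} D S^{1/2})_ab², aggregated the same way.

Both reduce to Ω_ab = D_ab² when S = I, and both satisfy the sum rule
Σ_AB Ω_AB = ‖S^{1/2} D S^{1/2}‖²_F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import (
    EmptyTransitionError,
    InvalidOverlapError,
    InvalidPopulationError,
    SchemeError,
    ShapeError,
)
from .fragments import LIGAND, METAL, FragmentScheme, merge_fragments

logger = logging.getLogger(__name__)

#: Mulliken-style partitioning can legitimately produce small negative
#: fragment blocks; entries more negative than this fraction of Ω_total
#: indicate unphysical input and raise.  Smaller negatives are kept exactly
#: in the Ω matrix (so it matches the defining formula) and clamped to zero
#: only when converted to populations.
NEGATIVE_ARTIFACT_FRACTION = 1e-3


@dataclass(frozen=True)
class AOContext:
    """A 1TDM and overlap in the AO basis, plus the AO → fragment mapping.

    ``ao_fragments[a]`` is the fragment index of AO ``a``.  The TDM index
    convention is row = hole AO, column = electron AO; readers of files in
    the opposite convention should transpose on input.
    """

    tdm: np.ndarray
    overlap: np.ndarray
    ao_fragments: np.ndarray

    def __init__(self, tdm, overlap, ao_fragments):
        d = np.asarray(tdm, dtype=float)
        s = np.asarray(overlap, dtype=float)
        frag = np.asarray(ao_fragments, dtype=int)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ShapeError(f"TDM must be square, got {d.shape}")
        if s.shape != d.shape:
            raise ShapeError(f"overlap {s.shape} does not match TDM {d.shape}")
        if frag.shape != (d.shape[0],):
            raise ShapeError(
                f"ao_fragments has {frag.shape} entries for {d.shape[0]} AOs"
            )
        if not np.allclose(s, s.T, atol=1e-8):
            raise InvalidOverlapError("overlap matrix is not symmetric")
        for a in (d, s):
            a.setflags(write=False)
        frag.setflags(write=False)
        object.__setattr__(self, "tdm", d)
        object.__setattr__(self, "overlap", s)
        object.__setattr__(self, "ao_fragments", frag)

    @property
    def n_ao(self) -> int:
        return self.tdm.shape[0]


@dataclass(frozen=True)
class OmegaMatrix:
    """Fragment × fragment charge-transfer numbers.

    ``omega[A, B]`` is the weight with the hole on fragment A and the
    excited electron on fragment B; ``omega_total`` their sum Ω.
    """

    omega: np.ndarray
    scheme: FragmentScheme

    def __init__(self, omega, scheme):
        om = np.asarray(omega, dtype=float)
        n = scheme.n_fragments
        if om.shape != (n, n):
            raise ShapeError(f"omega must be {n}×{n}, got {om.shape}")
        total = om.sum()
        if total <= 0:
            raise EmptyTransitionError("total charge-transfer weight is zero")
        neg = om < 0
        if neg.any():
            worst = float(om[neg].min())
            if -worst > NEGATIVE_ARTIFACT_FRACTION * total:
                raise InvalidPopulationError(
                    f"negative charge-transfer number {worst:.3e} exceeds the "
                    f"numerical-artifact threshold "
                    f"({NEGATIVE_ARTIFACT_FRACTION:.0e}·Ω)"
                )
            logger.warning(
                "keeping %d small negative charge-transfer numbers "
                "(min %.3e; Mulliken-style artifacts, clamped only in "
                "population vectors)",
                int(neg.sum()),
                worst,
            )
        om = om.copy()
        om.setflags(write=False)
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "scheme", scheme)

    @property
    def omega_total(self) -> float:
        return float(self.omega.sum())

    def merged(self, source: str | int, target: str | int) -> "OmegaMatrix":
        """Merge fragment ``source`` into ``target``, summing its Ω blocks."""
        new_scheme, assignment = merge_fragments(self.scheme, source, target)
        k = new_scheme.n_fragments
        # aggregation matrix M[old, new]
        m = np.zeros((self.scheme.n_fragments, k))
        m[np.arange(len(assignment)), assignment] = 1.0
        return OmegaMatrix(m.T @ self.omega @ m, new_scheme)


def _overlap_sqrt(s: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eigh(s)
    if vals.min() <= 1e-10:
        raise InvalidOverlapError(
            f"overlap matrix is not positive-definite (min eigenvalue {vals.min():.3e})"
        )
    return (vecs * np.sqrt(vals)) @ vecs.T


def _aggregate(per_ao: np.ndarray, ao_fragments: np.ndarray, n_frag: int) -> np.ndarray:
    """Sum an AO × AO weight matrix into fragment blocks."""
    om = np.zeros((n_frag, n_frag))
    for a_frag in range(n_frag):
        rows = ao_fragments == a_frag
        for b_frag in range(n_frag):
            cols = ao_fragments == b_frag
            om[a_frag, b_frag] = per_ao[np.ix_(rows, cols)].sum()
    return om


def omega_matrix(
    ctx: AOContext, scheme: FragmentScheme, style: str = "mulliken"
) -> OmegaMatrix:
    """Charge-transfer numbers Ω_AB from a 1TDM and AO overlap.

    ``style`` selects Mulliken-type (default) or Löwdin-type AO
    partitioning; both agree when the overlap is the identity.
    """
    n_frag = scheme.n_fragments
    if ctx.ao_fragments.max() >= n_frag:
        raise SchemeError(
            f"AO map references fragment {ctx.ao_fragments.max()}, "
            f"scheme has {n_frag}"
        )
    d, s = ctx.tdm, ctx.overlap
    if style == "mulliken":
        _overlap_sqrt(s)  # SPD check shared with the lowdin path
        per_ao = 0.5 * ((d @ s) * (s @ d) + d * (s @ d @ s))
    elif style == "lowdin":
        s_half = _overlap_sqrt(s)
        dressed = s_half @ d @ s_half
        per_ao = dressed**2
    else:
        raise ValueError(f"unknown partitioning style {style!r}")
    return OmegaMatrix(_aggregate(per_ao, ctx.ao_fragments, n_frag), scheme)


def _as_populations(sums: np.ndarray) -> np.ndarray:
    """Normalize marginal Ω sums to a valid population vector.

    Tiny negative marginals (Mulliken artifacts) are clamped to zero and the
    vector renormalized so downstream descriptors always see populations.
    """
    if sums.min() < 0:
        sums = np.clip(sums, 0.0, None)
    return sums / sums.sum()


def electron_populations(om: OmegaMatrix) -> np.ndarray:
    """Fragment populations of the excited electron: column sums of Ω / Ω."""
    return _as_populations(np.asarray(om.omega.sum(axis=0), dtype=float))


def hole_populations(om: OmegaMatrix) -> np.ndarray:
    """Fragment populations of the hole: row sums of Ω / Ω."""
    return _as_populations(np.asarray(om.omega.sum(axis=1), dtype=float))


def ct_character(om: OmegaMatrix) -> dict[str, float]:
    """MLCT / LLCT / MC / LC fractions from the Ω block structure.

    MLCT: hole on the metal, electron on a ligand.  LLCT: hole and electron
    on different ligands.  MC: both on the metal.  LC: both on the same
    ligand.  LMCT: hole on a ligand, electron on the metal (usually
    negligible in MLCT-dominated excitations but required for the five
    fractions to partition unity exactly).
    """
    scheme = om.scheme
    mi = scheme.metal_index
    if mi is None:
        raise SchemeError("CT-character decomposition requires a metal fragment")
    w = om.omega / om.omega_total
    lig = list(scheme.ligand_indices)
    mlct = float(w[mi, lig].sum())
    lmct = float(w[lig, mi].sum())
    mc = float(w[mi, mi])
    lc = float(sum(w[i, i] for i in lig))
    llct = float(sum(w[i, j] for i in lig for j in lig if i != j))
    return {"MLCT": mlct, "LLCT": llct, "MC": mc, "LC": lc, "LMCT": lmct}


def nto_weights(ctx: AOContext) -> np.ndarray:
    """Natural-transition-orbital weights λ_k, descending, summing to 1.

    λ_k are the normalized squared singular values of the overlap-dressed
    1TDM S^{1/2} D S^{1/2} — the importance of each hole–electron orbital
    pair in the excitation.
    """
    s_half = _overlap_sqrt(ctx.overlap)
    sigma = scipy.linalg.svd(s_half @ ctx.tdm @ s_half, compute_uv=False)
    total = float((sigma**2).sum())
    if total <= 0:
        raise EmptyTransitionError("transition density matrix is zero")
    return sigma**2 / total
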