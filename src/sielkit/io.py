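"""File formats: population tables, fragment configs, dense matrices.

Population tables are plain CSV/TSV with a mandatory header::

    geometry_id,state_index,multiplicity,energy_eV,osc_strength,e_<frag>,...

one ``e_<fragment>`` column per fragment (ordered as in the fragment
config) and optional ``h_<fragment>`` hole columns.  The reader sniffs
comma vs tab from the header; the writer always emits comma-separated
columns in a fixed order with 12 significant digits, so a write → read
round trip preserves populations.

Fragment configs are YAML/JSON::

    fragments:
      - name: Ru
        role: metal
        atoms: [1]
      - name: bpy1
        role: ligand
        atoms: ["2-20"]        # 1-based, inclusive ranges
        substituted: true
      ...

Atom indices are 1-based and inclusive (the convention of quantum-chemistry
outputs); they are only needed when mapping AO-basis matrices onto
fragments, not for population tables.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemeError, ShapeError, TableParseError
from .fragments import FragmentScheme
from .states import EnsembleBand, ExcitonState
from .tdm import AOContext

META_COLUMNS = ["geometry_id", "state_index", "multiplicity", "energy_eV", "osc_strength"]

#: eV per unit of other common energy units.
ENERGY_UNIT_TO_EV = {
    "ev": 1.0,
    "hartree": 27.211386245988,
    "cm-1": 1.0 / 8065.543937,
}


def convert_energy(value, unit: str):
    """Convert an energy (scalar or array) from ``unit`` to eV."""
    try:
        factor = ENERGY_UNIT_TO_EV[unit.lower()]
    except KeyError:
        raise ValueError(
            f"unknown energy unit {unit!r}; use one of {sorted(ENERGY_UNIT_TO_EV)}"
        ) from None
    return np.asarray(value, dtype=float) * factor


# ---------------------------------------------------------------------------
# fragment configs

def _parse_atoms(spec) -> tuple[int, ...]:
    """Expand a list of 1-based indices and 'a-b' inclusive ranges."""
    atoms: list[int] = []
    for item in spec:
        if isinstance(item, str) and "-" in item:
            lo, hi = item.split("-", 1)
            lo, hi = int(lo), int(hi)
            if lo < 1 or hi < lo:
                raise SchemeError(f"bad atom range {item!r}")
            atoms.extend(range(lo, hi + 1))
        else:
            idx = int(item)
            if idx < 1:
                raise SchemeError(f"atom indices are 1-based, got {idx}")
            atoms.append(idx)
    return tuple(atoms)


class FragmentConfig:
    """Parsed fragment-definition config.

    Holds the :class:`FragmentScheme` plus (optional) per-fragment atom
    assignments used to map AO-basis matrices onto fragments.
    """

    def __init__(self, scheme: FragmentScheme, atoms: dict[str, tuple[int, ...]]):
        self.scheme = scheme
        self.atoms = atoms
        seen: dict[int, str] = {}
        for name, idxs in atoms.items():
            for a in idxs:
                if a in seen:
                    raise SchemeError(
                        f"atom {a} assigned to both {seen[a]!r} and {name!r}"
                    )
                seen[a] = name

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FragmentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        frags = raw["fragments"] if isinstance(raw, dict) else raw
        names, roles, atoms = [], [], {}
        substituted = None
        for i, f in enumerate(frags):
            name = str(f["name"])
            names.append(name)
            roles.append(str(f.get("role", "ligand")))
            if "atoms" in f:
                atoms[name] = _parse_atoms(f["atoms"])
            if f.get("substituted"):
                if substituted is not None:
                    raise SchemeError("more than one fragment marked substituted")
                substituted = i
        return cls(FragmentScheme(names, roles, substituted), atoms)

    def ao_fragments(self, atom_of_ao) -> np.ndarray:
        """Fragment index of each AO, via its (1-based) atom index."""
        if not self.atoms:
            raise SchemeError("fragment config carries no atom assignments")
        atom_to_frag: dict[int, int] = {}
        for name, idxs in self.atoms.items():
            fi = self.scheme.fragment_names.index(name)
            for a in idxs:
                atom_to_frag[a] = fi
        out = []
        for ao, atom in enumerate(atom_of_ao):
            try:
                out.append(atom_to_frag[int(atom)])
            except KeyError:
                raise SchemeError(f"AO {ao} sits on atom {atom}, which no fragment claims") from None
        return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# population tables

def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_population_table(path: str | Path, scheme: FragmentScheme) -> EnsembleBand:
    """Read a population table into a validated band.

    Rows with malformed numbers, negative populations or zero total
    population are rejected with the offending (1-based) data row named.
    """
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"no such file: {path}")
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"geometry_id": str})
    except Exception as exc:
        raise TableParseError(f"cannot parse {path}: {exc}") from exc

    e_cols = [f"e_{name}" for name in scheme.fragment_names]
    h_cols = [f"h_{name}" for name in scheme.fragment_names]
    missing = [c for c in META_COLUMNS[:4] + e_cols if c not in df.columns]
    if missing:
        raise TableParseError(f"missing column(s) {missing} in {path}")
    has_holes = all(c in df.columns for c in h_cols)

    states = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = row._asdict()
        pops = []
        for col in e_cols:
            val = rowd[col]
            try:
                val = float(val)
            except (TypeError, ValueError):
                raise TableParseError(f"malformed number {val!r}", row=i, column=col) from None
            if math.isnan(val):
                raise TableParseError("missing population", row=i, column=col)
            if val < 0:
                raise TableParseError(f"negative population {val}", row=i, column=col)
            pops.append(val)
        if sum(pops) <= 0:
            raise TableParseError("zero total electron population", row=i)
        osc = rowd.get("osc_strength")
        if osc is not None and (isinstance(osc, float) and math.isnan(osc)):
            osc = None
        holes = [rowd[c] for c in h_cols] if has_holes else None
        try:
            states.append(
                ExcitonState(
                    geometry_id=rowd["geometry_id"],
                    state_index=int(rowd["state_index"]),
                    multiplicity=str(rowd["multiplicity"]),
                    energy=float(rowd["energy_eV"]),
                    electron_pops=pops,
                    oscillator_strength=None if osc is None else float(osc),
                    hole_pops=holes,
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableParseError(str(exc), row=i) from exc
    if not states:
        raise TableParseError(f"{path} contains no data rows")
    return EnsembleBand(states=states, scheme=scheme, label=path.stem)


def write_population_table(band: EnsembleBand, path: str | Path) -> None:
    """Write a band in the canonical comma-separated dialect."""
    path = Path(path)
    names = band.scheme.fragment_names
    cols = META_COLUMNS + [f"e_{n}" for n in names]
    has_holes = all(s.hole_pops is not None for s in band.states)
    if has_holes:
        cols += [f"h_{n}" for n in names]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for s in band:
            row = [
                s.geometry_id,
                str(s.state_index),
                s.multiplicity,
                f"{s.energy:.12g}",
                "" if s.oscillator_strength is None else f"{s.oscillator_strength:.12g}",
            ]
            row += [f"{p:.12g}" for p in s.electron_pops]
            if has_holes:
                row += [f"{p:.12g}" for p in s.hole_pops]
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# dense matrices

def read_matrix(path: str | Path) -> np.ndarray:
    """Read a dense whitespace-delimited square matrix."""
    m = np.loadtxt(path, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ShapeError(f"{path}: expected a square matrix, got {m.shape}")
    return m


def read_ao_context(
    tdm_path: str | Path,
    overlap_path: str | Path,
    config: FragmentConfig,
    atom_of_ao=None,
    transpose: bool = False,
) -> AOContext:
    """Assemble an AOContext from matrix files and a fragment config.

    ``atom_of_ao`` gives the 1-based atom of each AO; when omitted, AOs are
    assumed to be numbered 1..n_AO and to coincide with atoms (one basis
    function per atom).  ``transpose`` flips files stored with the opposite
    index convention (row = electron AO).
    """
    d = read_matrix(tdm_path)
    s = read_matrix(overlap_path)
    if transpose:
        d = d.T
    if atom_of_ao is None:
        atom_of_ao = range(1, d.shape[0] + 1)
    return AOContext(tdm=d, overlap=s, ao_fragments=config.ao_fragments(atom_of_ao))
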