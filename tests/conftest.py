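import numpy as np
import pytest

from sielkit import FragmentScheme, SyntheticSpec, generate_ensemble


@pytest.fixture
def ru_scheme():
    """Metal + three bipyridines, first ligand substituted."""
    return FragmentScheme(
        ["Ru", "bpy1", "bpy2", "bpy3"],
        ["metal", "ligand", "ligand", "ligand"],
        substituted_index=1,
    )


@pytest.fixture
def ligand_scheme():
    """Three ligand fragments, no metal (m = n = 3)."""
    return FragmentScheme(
        ["bpy1", "bpy2", "bpy3"], ["ligand"] * 3, substituted_index=0
    )


@pytest.fixture
def small_band(ru_scheme):
    spec = SyntheticSpec(
        n_geometries=10,
        n_states_per_geometry=5,
        n_fragments=4,
        concentration=(0.5, 2.0, 1.0, 1.0),
        seed=42,
    )
    return generate_ensemble(spec, ru_scheme)


def simplex_grid(m: int, step: float = 0.01):
    """All nonnegative integer-step compositions summing to 1 on the m-simplex."""
    k = round(1 / step)
    if m == 3:
        pts = [
            (i / k, j / k, (k - i - j) / k)
            for i in range(k + 1)
            for j in range(k + 1 - i)
        ]
    elif m == 4:
        pts = [
            (i / k, j / k, l / k, (k - i - j - l) / k)
            for i in range(k + 1)
            for j in range(k + 1 - i)
            for l in range(k + 1 - i - j)
        ]
    else:
        raise ValueError("only m = 3 or 4 supported")
    return np.array(pts)
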