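"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from epibind.structio import Atom, StructureModel

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


def make_atom(serial, name, element, coords, chain="A", resi=1,
              resname="ALA", bfactor=0.0, occupancy=1.0):
    return Atom(serial, name, element, tuple(float(c) for c in coords),
                chain, resi, resname, "", bfactor, occupancy)


def point_model(points, element="C", chain="A", name_prefix="C"):
    """One single-atom residue per point; heavy atoms unless element is H."""
    atoms = [make_atom(i + 1, f"{name_prefix}{i + 1}"[:4], element, p,
                       chain=chain, resi=i + 1)
             for i, p in enumerate(points)]
    return StructureModel(atoms)


def two_group_model(points_a, points_b, element="C"):
    """Chain A and chain B single-atom residues at the given points."""
    atoms = [make_atom(i + 1, "X", element, p, chain="A", resi=i + 1)
             for i, p in enumerate(points_a)]
    off = len(atoms)
    atoms += [make_atom(off + i + 1, "X", element, p, chain="B", resi=i + 1)
              for i, p in enumerate(points_b)]
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the code paths they check)
# ---------------------------------------------------------------------------

def brute_force_pairs(coords_a, coords_b, cutoff):
    """All (i, j, dist) with dist strictly < cutoff, O(N^2) loops."""
    out = []
    for i, a in enumerate(coords_a):
        for j, b in enumerate(coords_b):
            d = float(np.sqrt(((np.asarray(a) - np.asarray(b)) ** 2).sum()))
            if d < cutoff:
                out.append((i, j, d))
    return out


def brute_force_hbonds(coords, donors, hydrogens_of, acceptors,
                       da_cutoff=3.5, angle_min=150.0):
    """Triple enumeration over (D, H, A); inclusive distance, >= angle."""
    count = 0
    for d in donors:
        for h in hydrogens_of.get(d, []):
            for a in acceptors:
                if a == d:
                    continue
                dist = np.linalg.norm(coords[d] - coords[a])
                if dist > da_cutoff:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if angle >= angle_min:
                    count += 1
    return count


@pytest.fixture
def tmp_pdb(tmp_path):
    def _write(text, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write
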