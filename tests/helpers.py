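"""Shared builders for hand-made molecular test fixtures."""

import numpy as np

from growlite.chem_io import Atom, BindingSite, Molecule
from growlite.config import vdw_radius


def atom(i, element, pos, h=0, water=False, charge=0):
    return Atom(i, element, np.array(pos, dtype=float), is_water=water,
                vdw_radius=vdw_radius(element), formal_charge=charge,
                attached_hydrogens=h)


def single_atom_site(element="C", pos=(0.0, 0.0, 0.0), frame="site"):
    return BindingSite(Molecule([atom(0, element, pos)]), [], frame)


def hexagon_ring(radius=1.4, z=0.0, name="ring"):
    """Planar six-membered carbon ring with alternating bond orders."""
    coords = [[radius * np.cos(t), radius * np.sin(t), z]
              for t in np.linspace(0.0, 2.0 * np.pi, 6, endpoint=False)]
    return Molecule([atom(i, "C", coords[i], h=1) for i in range(6)],
                    [(i, (i + 1) % 6, 1.0 if i % 2 else 2.0) for i in range(6)],
                    name)
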