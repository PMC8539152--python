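"""Approximate 3D embedding hook.

The contribution data were derived against a database of geometry-optimized
conformations; geometric special groups (H bridges, H...H contacts, ring
angle bins) therefore depend on the stored conformer.  This module offers a
*convenience* substitute — deterministic distance-geometry embedding (ETKDG)
followed by MMFF94 minimization, keeping the lowest-energy conformer of a
seeded ensemble.  It is documented as approximate: contact counts near the
distance thresholds can differ from those of any particular reference
geometry.  Consumers with curated 3D structures should supply them as MOL/SDF
input instead.
"""

from __future__ import annotations

from typing import Union

from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from . import graph as g
from .errors import ParseError
from .graph import Molecule


def embed_3d(source: Union[str, Molecule], seed: int = 2021,
             n_confs: int | None = None, mmff_iters: int = 2000) -> Molecule:
    """Return a molecule with approximate 3D coordinates.

    An ensemble of ``n_confs`` conformers (scaled with the rotatable-bond
    count when not given) is embedded with ETKDGv3 using ``seed`` and
    minimized with MMFF94; the lowest-energy conformer is kept.
    """
    if isinstance(source, str):
        rd = Chem.MolFromSmiles(source)
        if rd is None:
            raise ParseError(f"invalid SMILES: {source!r}")
        rd = Chem.AddHs(rd)
        name = source
    else:
        rd = g._to_rdkit(source, sanitize=True)
        name = source.name
    if n_confs is None:
        n_rot = rdMolDescriptors.CalcNumRotatableBonds(rd)
        n_confs = min(20 + 10 * n_rot, 120)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31)
    params.useRandomCoords = False
    cids = AllChem.EmbedMultipleConfs(rd, numConfs=n_confs, params=params)
    if not cids:
        raise ParseError(f"embedding failed for {name!r}")
    energies = AllChem.MMFFOptimizeMoleculeConfs(rd, maxIters=mmff_iters)
    scored = [(e, cid) for cid, (_, e) in zip(cids, energies) if e is not None]
    best = min(scored)[1] if scored else cids[0]
    conf = Chem.Conformer(rd.GetConformer(int(best)))
    conf.Set3D(True)
    rd.RemoveAllConformers()
    rd.AddConformer(conf, assignId=True)
    if isinstance(source, Molecule):
        # graft coordinates onto the existing (possibly normalized) graph
        out = source.copy()
        import numpy as np
        pos = rd.GetConformer()
        for a in out.atoms:
            p = pos.GetAtomPosition(a.index)
            a.coords = np.array([p.x, p.y, p.z])
        out.has_3d = True
        return out
    return g.from_rdkit(rd, name=name)
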