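"""Generators for simulation inputs and named fixture molecules.

Two kinds of test substrate are produced without any external data:

* sparse synthetic design systems (group-count matrices with known "true"
  contributions, Gaussian noise and planted gross outliers) that exercise
  the solver and the outlier-rejection loop independently of any chemistry,
* small named molecules — the worked examples of the method (diketene, the
  amino-acid prototropic pairs, keto/enol pairs, ionic liquids) plus
  constructed geometries for the distance-threshold special groups.

Synthetic designs deliberately bypass structure perception so that solver
properties are tested in isolation.  All generators are deterministic under
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph as g
from .graph import Atom, Bond, Molecule
from .trainer import DesignSystem


@dataclass
class SyntheticDesignSpec:
    """Parameters of a synthetic group-count training set.

    Defaults emulate the structure of the real problem at desk scale: a few
    dozen sparse group counts per molecule, contributions of a few hundred
    kJ/mol magnitude, residual noise of the order of the published standard
    deviation (about 18 kJ/mol) and, optionally, a small fraction of gross
    outliers at ten times the noise level.
    """

    n_molecules: int = 120
    vocab_size: int = 12
    mean_groups_per_molecule: float = 4.0
    zipf_exponent: float = 1.3
    contribution_range: tuple[float, float] = (-2000.0, 500.0)
    noise_sd: float = 18.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 10.0  # in multiples of noise_sd
    seed: int = 0

    def labels(self) -> list[str]:
        return [f"g{k}" for k in range(self.vocab_size)]


def gen_design(spec: SyntheticDesignSpec) -> tuple[DesignSystem, np.ndarray, np.ndarray]:
    """Generate (design system, true contributions, planted outlier indices).

    Counts are a sparse Poisson/zipf mix: each molecule draws its number of
    distinct groups from a (truncated) Poisson, picks groups with
    zipf-decaying popularity and gives each a small Poisson multiplicity.
    Every vocabulary column is guaranteed at least one occurrence.
    """
    if spec.vocab_size < 1:
        raise ValueError("empty vocabulary")
    if spec.n_molecules < 1:
        raise ValueError("need at least one molecule")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_molecules, spec.vocab_size
    weights = 1.0 / np.arange(1, p + 1) ** spec.zipf_exponent
    weights /= weights.sum()
    X = np.zeros((n, p))
    for i in range(n):
        k = min(p, max(1, rng.poisson(spec.mean_groups_per_molecule)))
        cols = rng.choice(p, size=k, replace=False, p=weights)
        X[i, cols] = 1 + rng.poisson(0.7, size=k)
    for j in np.flatnonzero(~X.any(axis=0)):  # every column occupied
        X[rng.integers(n), j] = 1
    lo, hi = spec.contribution_range
    truth = rng.uniform(lo, hi, size=p)
    y = X @ truth + rng.normal(0.0, spec.noise_sd, size=n)
    n_out = int(round(spec.outlier_fraction * n))
    outliers = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_out)
    y[outliers] += signs * spec.outlier_magnitude * spec.noise_sd
    frame = pd.DataFrame(X, columns=spec.labels())
    return DesignSystem(frame, y), truth, np.sort(outliers)


def training_frame(spec: SyntheticDesignSpec) -> pd.DataFrame:
    """The generated design as a flat training table (CSV schema of the
    ``simulate`` subcommand): group-count columns plus ``hc_exp``."""
    system, truth, outliers = gen_design(spec)
    out = system.X.copy()
    out["hc_exp"] = system.y
    out["is_planted_outlier"] = np.isin(np.arange(len(out)), outliers)
    return out


# -- fixture molecules ----------------------------------------------------

_FIXTURE_SMILES = {
    "diketene": "C1(=C)OC(=O)C1",
    "hydrogen_peroxide": "OO",
    "acetone": "CC(=O)C",
    "acetone_enol": "CC(O)=C",
    "cyclohexanone": "O=C1CCCCC1",
    "cyclohexanone_enol": "OC1=CCCCC1",
    "cyclopentanone": "O=C1CCCC1",
    "cyclopropane": "C1CC1",
    "phenol": "Oc1ccccc1",
    "glycine": "NCC(=O)O",
    "glycine_zwitterion": "[NH3+]CC(=O)[O-]",
    "alanine": "CC(N)C(=O)O",
    "alanine_zwitterion": "CC([NH3+])C(=O)[O-]",
    "sarcosine": "CNCC(=O)O",
    "sarcosine_zwitterion": "C[NH2+]CC(=O)[O-]",
    "n_phenylglycine": "OC(=O)CNc1ccccc1",
    "tetramethylammonium_nitrate": "C[N+](C)(C)C.[O-][N+]([O-])=O",
    "tryptophan_zwitterion": "[NH3+]C(Cc1c[nH]c2ccccc12)C(=O)[O-]",
}


def fixture_molecules() -> dict[str, Molecule]:
    """Named worked-example molecules (topology only), conventions applied."""
    out = {}
    for name, smiles in _FIXTURE_SMILES.items():
        out[name] = g.normalize_conventions(g.parse_smiles(smiles, name))
    out["diketene_3d"] = diketene_3d()
    out["hbond_pair_on"], out["hbond_pair_off"] = hbond_pair()
    return out


def ionic_liquid_benchmark() -> pd.DataFrame:
    """The 28-compound ionic-liquid benchmark (name, SMILES, experimental
    heat of combustion in kJ/mol)."""
    path = Path(resources.files("hcomb") / "data" / "ionic_liquids.tsv")
    return pd.read_csv(path, sep="\t")


def diketene_3d() -> Molecule:
    """Diketene with idealized planar coordinates (square 4-ring, 90 deg
    internal angles) — a constructed geometry fixture, not an optimized
    structure."""
    s = 1.45  # ring edge, Angstrom
    ring = {
        "C3": np.array([0.0, 0.0, 0.0]),   # C bearing =CH2
        "O": np.array([s, 0.0, 0.0]),
        "C1": np.array([s, -s, 0.0]),      # carbonyl C
        "C2": np.array([0.0, -s, 0.0]),    # CH2
    }
    atoms = [
        Atom("C", coords=ring["C3"]),                      # 0 ring C=CH2
        Atom("C", coords=ring["C3"] + [-0.9, 1.05, 0.0]),  # 1 =CH2
        Atom("O", coords=ring["O"]),                       # 2 ring O
        Atom("C", coords=ring["C1"]),                      # 3 carbonyl C
        Atom("O", coords=ring["C1"] + [1.0, -0.7, 0.0]),   # 4 =O
        Atom("C", coords=ring["C2"]),                      # 5 ring CH2
        Atom("H", coords=ring["C3"] + [-1.85, 0.95, 0.0]),
        Atom("H", coords=ring["C3"] + [-0.55, 2.05, 0.0]),
        Atom("H", coords=ring["C2"] + [-0.75, -0.55, 0.75]),
        Atom("H", coords=ring["C2"] + [-0.75, -0.55, -0.75]),
    ]
    bonds = [
        Bond(0, 1, g.DOUBLE), Bond(0, 2, g.SINGLE), Bond(2, 3, g.SINGLE),
        Bond(3, 4, g.DOUBLE), Bond(3, 5, g.SINGLE), Bond(5, 0, g.SINGLE),
        Bond(1, 6, g.SINGLE), Bond(1, 7, g.SINGLE),
        Bond(5, 8, g.SINGLE), Bond(5, 9, g.SINGLE),
    ]
    return Molecule(atoms, bonds, name="diketene_3d", has_3d=True)


def hbond_pair(distance_on: float = 1.6, distance_off: float = 1.9) -> tuple[Molecule, Molecule]:
    """Constructed H-bridge on/off pair: a methanediol-like fragment whose
    hydroxyl H sits at a chosen distance from a non-bonded acceptor O."""

    def build(d: float, name: str) -> Molecule:
        atoms = [
            Atom("C", coords=np.array([0.0, 0.0, 0.0])),      # 0
            Atom("O", coords=np.array([1.4, 0.0, 0.0])),      # 1 O-H donor
            Atom("O", coords=np.array([-0.7, 1.2, 0.0])),     # 2 acceptor (C=O)
            Atom("H", coords=None),                            # 3 donor H
            Atom("H", coords=np.array([0.5, -1.0, 0.0])),     # 4 C-H
        ]
        # place the donor H on the O...acceptor line at distance d from 2
        direction = atoms[2].coords - atoms[1].coords
        direction = direction / np.linalg.norm(direction)
        atoms[3].coords = atoms[2].coords - direction * d
        bonds = [Bond(0, 1, g.SINGLE), Bond(0, 2, g.DOUBLE),
                 Bond(1, 3, g.SINGLE), Bond(0, 4, g.SINGLE)]
        return Molecule(atoms, bonds, name=name, has_3d=True)

    return build(distance_on, "hbond_on"), build(distance_off, "hbond_off")


def hh_pair(distance: float) -> Molecule:
    """Two methane-like CH fragments with one H...H pair at ``distance``."""
    atoms = [
        Atom("C", coords=np.array([0.0, 0.0, 0.0])),
        Atom("H", coords=np.array([1.1, 0.0, 0.0])),
        Atom("H", coords=np.array([-1.1, 0.0, 0.0])),
        Atom("C", coords=np.array([1.1 + distance + 1.1, 0.0, 0.0])),
        Atom("H", coords=np.array([1.1 + distance, 0.0, 0.0])),
        Atom("H", coords=np.array([1.1 + distance + 2.2, 0.0, 0.0])),
    ]
    bonds = [Bond(0, 1), Bond(0, 2), Bond(3, 4), Bond(3, 5), Bond(0, 3)]
    # direct C-C bond keeps the pair in one component but makes H's vicinal;
    # use a 3-atom bridge instead so the contact is a genuine non-bonded one
    atoms.append(Atom("C", coords=np.array([0.0, 3.0, 0.0])))
    bonds[-1] = Bond(0, 6)
    bonds.append(Bond(6, 3))
    return Molecule(atoms, bonds, name=f"hh_{distance}", has_3d=True)
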