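# hcomb

Group-additivity calculation of the standard heat of combustion ΔH°c and
heat of formation ΔH°f of organic molecules, for thermochemists, process
and energetic-materials chemists, and anyone building QSPR baselines.

## The method

A molecule is broken down completely into its *backbone atoms* — atoms bound
to at least two other atoms, hydrogens included. Each backbone atom is
characterized by its element, hybridization and charge plus an encoded
description of its immediate neighbors (e.g. the carbonyl carbon of an acid
is `C sp2 | CO=O`, a phenol oxygen is `O | HC(pi)`). Three-dimensional
effects enter through *special groups*: intramolecular hydrogen bridges,
close H···H contacts, and bond-angle strain classes for small rings
(`Angle60`, `Angle90`, `Angle102`). The heat of combustion is then additive,

    ΔH°c = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ          [kJ/mol]

with `Aᵢ`, `Bⱼ` the occurrence counts and `aᵢ`, `bⱼ` tabulated group
contributions. The package ships the published 390-entry contribution table
(fitted to 5030 experimental compounds); predictions use only *valid*
groups, i.e. contributions supported by at least three independent training
molecules. ΔH°f follows by Hess's law from the combustion enthalpies of the
elements:

    ΔH°f = Σₑ nₑ·cₑ − ΔH°c

The same machinery that consumes the table can re-derive it: a
molecules-by-groups occurrence matrix is normalized into its normal-equation
form and solved with a Gauss–Seidel coordinate sweep, validated by 10-fold
cross-validation, and cleaned by iteratively discarding compounds deviating
by more than three cross-validated standard errors.

## Worked example

```python
from hcomb import load_table, parse_smiles, predict_hc
from hcomb.graph import normalize_conventions
from hcomb.groups import decompose

table = load_table()
mol = normalize_conventions(parse_smiles("C1(=C)OC(=O)C1", "diketene"))
d = decompose(mol, table=table)
for key, n in d.counts.items():
    print(f"{key.render():14s} x{n}  {table.get(key).value:10.2f}")
pred = predict_hc(d, table)
print(f"dHc = {pred.hc:.2f} kJ/mol")
```

prints

```
C sp2 C=CO     x1     -470.12
C sp2 H2=C     x1     -703.30
O C2(2pi)      x1      278.25
C sp2 CO=O     x1     -256.51
C sp3 H2C2     x1     -653.47
Angle90        x4      -24.51
dHc = -1903.19 kJ/mol
```

— diketene (4-methylene-2-oxetanone) decomposes into five ordinary atom
groups plus four 90°-class ring-strain groups for the four-membered ring;
their sum, −1903.2 kJ/mol, is the predicted standard heat of combustion
(experiment: −1913.4 kJ/mol).

The same is available from the shell:

```bash
hcomb predict --smiles "CC(=O)C" --hf       # acetone: dHc = -1791.0 kJ/mol
hcomb decompose --smiles "Oc1ccccc1"        # group table for phenol
hcomb simulate --n-molecules 100 --noise-sd 18 --seed 7 -o train.csv
hcomb fit -i train.csv --seed 7             # refit contributions + stats
```

Scikit-learn users can compose the pieces as estimators:
`GroupDecomposer` (molecules → count matrix) feeds `GaussSeidelRegressor`
or the full `GroupContributionTrainer` (CV + outlier rejection) in an
ordinary `Pipeline`.

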