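"""Regenerate the bundled amino-acid property table from RDKit descriptors.

The packaged table (``src/pepcaps/data/aa_properties.csv``) holds 100 numeric
physicochemical/topological descriptors for the 20 canonical free amino acids,
computed with RDKit from canonical SMILES. Descriptors that are constant
across the 20 residues (zero variance) or non-finite are dropped; the first
100 remaining descriptors in RDKit's registration order are kept.

Run from the repository root:

    python scripts/make_property_table.py
"""

from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

# Canonical SMILES of the 20 free (undigested) L-amino acids.
AA_SMILES = {
    "A": "C[C@@H](N)C(=O)O",
    "C": "N[C@@H](CS)C(=O)O",
    "D": "N[C@@H](CC(=O)O)C(=O)O",
    "E": "N[C@@H](CCC(=O)O)C(=O)O",
    "F": "N[C@@H](Cc1ccccc1)C(=O)O",
    "G": "NCC(=O)O",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)O",
    "I": "CC[C@H](C)[C@H](N)C(=O)O",
    "K": "NCCCC[C@H](N)C(=O)O",
    "L": "CC(C)C[C@H](N)C(=O)O",
    "M": "CSCC[C@H](N)C(=O)O",
    "N": "NC(=O)C[C@H](N)C(=O)O",
    "P": "O=C(O)[C@@H]1CCCN1",
    "Q": "NC(=O)CC[C@H](N)C(=O)O",
    "R": "N=C(N)NCCC[C@H](N)C(=O)O",
    "S": "N[C@@H](CO)C(=O)O",
    "T": "C[C@@H](O)[C@H](N)C(=O)O",
    "V": "CC(C)[C@H](N)C(=O)O",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)O",
}

N_PROPERTIES = 100


def main() -> None:
    rows = {}
    for aa, smi in sorted(AA_SMILES.items()):
        mol = Chem.MolFromSmiles(smi)
        rows[aa] = Descriptors.CalcMolDescriptors(mol)
    table = pd.DataFrame.from_dict(rows, orient="index").astype(float)

    finite = table.columns[np.isfinite(table.to_numpy()).all(axis=0)]
    table = table[finite]
    varying = table.columns[table.std(axis=0, ddof=0) > 1e-12]
    table = table[varying].iloc[:, :N_PROPERTIES]
    assert table.shape == (20, N_PROPERTIES), table.shape

    out = Path(__file__).resolve().parents[1] / "src/pepcaps/data/aa_properties.csv"
    table.index.name = "residue"
    table.to_csv(out, float_format="%.6g")
    print(f"wrote {out}: {table.shape[0]} residues x {table.shape[1]} properties")


if __name__ == "__main__":
    main()
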