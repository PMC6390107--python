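"""CD-loop geometry: distances and hydrogen bonds.

Builds a synthetic serine-pair fixture posed like the loop-stabilising motif
(residue-52 amide deuteron and hydroxyl both donating to the Ser50 side
chain) and measures it. If the RCSB archive is reachable, also measures the
deposited WT (4PVM) and S52P (5NFW) structures, where the Ser50 Cα to
residue-52 N distance widens from 4.2 Å to 4.6 Å.
"""

import numpy as np

from ttrkit import geometry
from ttrkit.structure import Structure

atoms = [  # synthetic stand-in, coordinates posed to the motif geometry
    ("A", 50, "SER", "CA", "C", (4.2, 1.5, 0.0)),
    ("A", 50, "SER", "CB", "C", (1.5, 1.2, 0.8)),
    ("A", 50, "SER", "OG", "O", (0.0, 0.0, 0.0)),
    ("A", 52, "SER", "N", "N", (2.9, 0.0, 0.0)),
    ("A", 52, "SER", "D", "D", (1.9, 0.0, 0.0)),
    ("A", 52, "SER", "CA", "C", (3.5, -1.3, 0.2)),
    ("A", 52, "SER", "CB", "C", (2.6, -2.0, 1.2)),
    ("A", 52, "SER", "OG", "O", (0.2, -2.8, 0.1)),
    ("A", 52, "SER", "HG", "H", (0.13, -1.85, 0.07)),
]
cols = list(zip(*atoms))
fixture = Structure(
    chain_ids=np.array(cols[0], dtype=object), resids=np.array(cols[1]),
    resnames=np.array(cols[2], dtype=object),
    atom_names=np.array(cols[3], dtype=object),
    elements=np.array(cols[4], dtype=object), coords=np.array(cols[5]))

bonds = geometry.find_hbonds(fixture)
print(f"hydrogen bonds in the synthetic serine pair: {len(bonds)}")
for b in bonds:
    print(f"  {b.donor} -{b.hydrogen[2] if b.hydrogen else '?'}-> {b.acceptor}"
          f"  d={b.distance:.2f} Å, angle={b.angle:.0f} deg")
print("Two bonds anchor the loop; a proline at position 52 removes both.")

try:  # optional: measure the deposited structures (needs network)
    for pdb_id, label in [("4PVM", "WT"), ("5NFW", "S52P")]:
        path = geometry.fetch_structure(pdb_id, "scratch", timeout=20)
        d = geometry.atom_distance(path,
                                   geometry.AtomSelector("A", 50, "CA"),
                                   geometry.AtomSelector("A", 52, "N"))
        print(f"{label} ({pdb_id}) chain A: Ser50 CA - res52 N = {d:.1f} Å")
except Exception as err:  # noqa: BLE001
    print(f"(deposited structures not measured: {err})")
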