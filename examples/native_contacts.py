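"""Fraction of native contacts Q on a synthetic unfolding trajectory.

Builds the toy tetramer, unfolds the C/D-strand analogue of chain A over
1000 frames and tracks the monomer fold Q, the monomer-monomer interface Q
and the dimer-dimer interface Q, plus per-strand Q for the perturbed chain.
"""

import numpy as np

from ttrkit import contacts, synth

toy = synth.make_toy_oligomer(n_chains=4, residues_per_chain=96, seed=0)
frames = synth.make_unfolding_trajectory(toy, ["C", "D"], n_frames=1000, seed=1)

units = {
    "fold(A)": contacts.build_contacts(toy, "fold", chain="A"),
    "mm-interface(A,B)": contacts.build_contacts(toy, "interface",
                                                 chain_pair=("A", "B")),
    "dd-interface(AB,CD)": contacts.build_contacts(toy, "interface",
                                                   chain_pair=("AB", "CD")),
}
qs = contacts.q_timeseries(frames, units)
for unit, q in qs.q.items():
    print(f"{unit:>20}: Q start {q[:50].mean():.3f} -> end {q[-50:].mean():.3f}")

strand_q = contacts.q_by_region(frames, units["fold(A)"], toy, toy.regions)
print("\nfinal-block Q by strand (C/D are perturbed):")
print({lab: round(float(v[-100:].mean()), 2) for lab, v in strand_q.q.items()})
print("\nThe perturbed strands lose most of their contacts while distant")
print("strands (A, E, F) stay fully native; interfaces and neighbouring")
print("strands are partially affected where they touch the unfolding region.")
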