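"""PLS functional mode analysis of a synthetic unfolding trajectory.

Regresses the per-frame monomer Q on superposed main-chain coordinates
(20 PLS components, leading 75% of frames for training) and reports the
validation correlation and the residues dominating the maximally correlated
mode — which should be the perturbed C/D-strand analogue.
"""

import numpy as np

from ttrkit import contacts, fma, synth

toy = synth.make_toy_oligomer(4, 96, seed=0)
frames = synth.make_unfolding_trajectory(toy, ["C", "D"], 1000, seed=1)
fold_a = contacts.build_contacts(toy, "fold", chain="A")
q = contacts.q_timeseries(frames, {"A": fold_a}).q["A"]

chain_a = toy.select_chains("A")
mcm = fma.main_chain_mask(chain_a)
idx = np.flatnonzero(toy.chain_ids == "A")
aligned = fma.align_frames(frames[:, idx][:, mcm], chain_a.coords[mcm])

model = fma.fit_fma(aligned, q, n_components=20, train_frac=0.75)
print(f"Pearson r: training {model.r_train:.3f}, validation {model.r_val:.3f}")

amps = fma.mode_rmsf(model, chain_a.resids[mcm])
top = sorted(amps, key=amps.get, reverse=True)[:10]
cd = sorted(set(toy.regions["C"]) | set(toy.regions["D"]))
print("top-10 residues by mode amplitude:", sorted(top))
print(f"C/D-analogue region: residues {cd[0]}..{cd[-1]}")
print("\nA validation r >= 0.97 means the collective mode explains the loss")
print("of native contacts; its amplitude localises on the unfolding strands.")
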