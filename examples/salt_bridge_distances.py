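"""Interdomain salt-bridge distances mapped through an alignment.

For each synthetic structure the two marker residues (the analogue of
the E48–R138 interdomain pair) are located via global alignment to the
reference sequence, their Cβ–Cβ distance is measured, and the per-class
distribution is summarised box-plot style (median, quartiles, 1st/99th
percentiles).
"""

from metamorphscan import (
    SaltBridgePair,
    global_align,
    map_equivalent_positions,
    salt_bridge_distance,
    summarize_distances,
)
from metamorphscan.foldclass import FoldClassLabel
from metamorphscan.synthetic import StructureRecipe, build_two_domain_decoy

# the autoinhibited (ALPHA) state keeps the pair close; open states do not
planted_distances = {FoldClassLabel.ALPHA: 9.6, FoldClassLabel.BETA: 18.0}

for label, planted in planted_distances.items():
    distances = []
    for seed in range(8):
        st, meta = build_two_domain_decoy(
            StructureRecipe(label, marker_pair_distance=planted, seed=seed)
        )
        reference = st.sequence  # identity alignment in this demo
        pair = SaltBridgePair(meta.marker_pos_a, meta.marker_pos_b)
        aln = global_align(reference, st.sequence)
        qa, qb = map_equivalent_positions(aln, pair)
        distances.append(salt_bridge_distance(st, qa, qb))
    s = summarize_distances(distances)
    print(f"{label.value:5s}: planted {planted:5.2f} Å  ->  "
          f"median {s.median:.2f} Å  IQR [{s.q25:.2f}, {s.q75:.2f}]  n={s.n}")

print("\nMedians reproduce the planted Cβ–Cβ distances: a short distance is the")
print("signature of the closed, autoinhibited fold-switching state.")
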