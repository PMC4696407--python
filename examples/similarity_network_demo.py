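"""Build a chemical similarity network and a similarity-aware data split.

Fingerprints a small set of structures, links pairs at Tanimoto >= 0.8,
extracts clusters with their representative compounds, and shows the
training/validation split that keeps all structurally similar compounds in
training.
"""

from p450nnc import (
    build_csn,
    cluster_report,
    clusters,
    fingerprint_from_smiles,
    split_by_similarity,
)

compounds = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "methyl_salicylate": "COC(=O)c1ccccc1O",
    "salicylic_acid": "OC(=O)c1ccccc1O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "theophylline": "Cn1c2c(c(=O)n(C)c1=O)[nH]cn2",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "naproxen": "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "ethanol": "CCO",
}
fps = [fingerprint_from_smiles(name, smi) for name, smi in compounds.items()]

# a lenient threshold so this tiny set forms visible clusters
net = build_csn(fps, threshold=0.3)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges "
      f"(Tanimoto >= {net.graph['threshold']})")
for row in cluster_report(net, clusters(net, min_size=2)):
    print(f"  cluster of {row['size']}: representative={row['representative']}")

train, val = split_by_similarity(fps, ratio=(2, 1), threshold=0.3, seed=0)
print(f"\nsimilarity-aware split: {len(train)} training, {len(val)} validation")
print("validation compounds:", val)
print("Every validation compound is structurally dissimilar (below threshold) to")
print("all other compounds, so validation truly probes unseen chemistry.")
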