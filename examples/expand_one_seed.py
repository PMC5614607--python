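"""Step through the greedy expansion on a 5-gene toy graph.

Edges A-B, A-C, B-D, C-E with z-scores A=1.0, B=2.0, C=-3.0, D=2.5,
E=5.0. From seed A with th=0.05: layer 1 keeps B (adding it raises the
mean by 0.5) and rejects C (-2.0; that path closes, so the high scorer E
behind C is never reached); layer 2 keeps D (+1/3). The final subnetwork
is {A, B, D} with mean z 11/6.
"""

import networkx as nx

from htsnet.core import BioNetwork, GeneScoreTable
from htsnet.detection import detect_subnetworks, expand_seed, filter_redundant

g = nx.Graph([("A", "B"), ("A", "C"), ("B", "D"), ("C", "E")])
net = BioNetwork(kind="interactome", graph=g)
scores = GeneScoreTable(
    entries={"A": 1.0, "B": 2.0, "C": -3.0, "D": 2.5, "E": 5.0})

sn = expand_seed(net, scores, seed="A", th=0.05)
print(f"seed A -> members {sorted(sn.members)}, mean z = {sn.score:.4f}")

print("\nall seeds (size-1 results are dropped):")
for sn in detect_subnetworks(net, scores, th=0.05):
    print(f"  seed {sn.seed}: {sorted(sn.members)}  score {sn.score:.3f}")

kept = filter_redundant(detect_subnetworks(net, scores, th=0.05), rate=0.8)
print(f"\nafter redundancy filtering at 80%: {len(kept)} subnetworks")
for sn in kept:
    print(f"  seed {sn.seed}: {sorted(sn.members)}  score {sn.score:.3f}")
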