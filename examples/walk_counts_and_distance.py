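"""Follow the matrix chain from adjacency to distances on a small network.

Uses the 8-treatment worked example (six two-arm trials).  Powers of the
adjacency matrix A count walks; the indicator of their cumulative sum
shows which treatments are connected; the distance matrix gives the
shortest chain of trials linking each pair.
"""

import numpy as np

from nmaconnect import (
    build_adjacency,
    cumulative_walks,
    distance_matrix,
    indicator,
    indirect_connection,
    paper_network,
    walk_counts,
)

net = paper_network("figure2")
adj = build_adjacency(net)

print("adjacency matrix A (1 = directly compared):")
print(adj.entries)

a2 = walk_counts(adj, 2)
print("\nA^2 counts two-step walks; entry (2,2) =", a2.entries[1, 1],
      "(2-1-2, 2-3-2, 2-5-2)")

print("\nI(C_3): connected within three steps:")
print(indicator(cumulative_walks(adj, 3)))

icm = indirect_connection(adj)
print("\nindirect connection matrix (1 = comparable at all):")
print(icm.entries)

d = distance_matrix(adj)
print("\ndistance matrix (steps needed; 0 off-diagonal = not comparable):")
print(d.entries)
i, j = list(net.labels).index("1"), list(net.labels).index("4")
print(f"\ncomparing treatments 1 and 4 needs {d.entries[i, j]} steps — "
      "two layers of indirectness on top of a head-to-head trial.")
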