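"""Meta-path commuting matrices on a hand-built toy network.

Builds the small drug-protein-disease network in which drug d3 binds
proteins p3 and p5 and both proteins cause disease s2, then counts
drug->protein->disease path instances two ways: by the sparse matrix
product X2 = A_dp . A_sp^T and by exhaustive walk enumeration.
"""

import pathrx as px

a_dp = px.InteractionMatrix.from_edges(
    [("d1", "p1"), ("d2", "p2"), ("d2", "p4"), ("d3", "p3"), ("d3", "p5")],
    row_type="Drug", col_type="Protein")
a_sp = px.InteractionMatrix.from_edges(
    [("s1", "p1"), ("s1", "p2"), ("s2", "p3"), ("s2", "p5")],
    row_type="Disease", col_type="Protein")
a_ds = px.InteractionMatrix.from_edges(
    [("d1", "s1")], row_type="Drug", col_type="Disease")

network = px.build_network(a_dp, a_sp, a_ds)
print("network:", px.summarize(network))

x2 = px.commuting_matrix(network, px.MetaPath.MP2)
print("\nX2 = A_dp . A_sp^T (rows = drugs, columns = diseases):")
print(x2.toarray())

i, j = network.drugs.index("d3"), network.diseases.index("s2")
print(f"\nX2(d3, s2) = {x2.count('d3', 's2')}  "
      f"(enumerated walks: {px.count_path_instances(network, px.MetaPath.MP2, i, j)})")
print("Both proteins p3 and p5 bridge d3 to s2, so two path instances exist;")
print("a larger entry means more molecular intermediaries connect the pair.")
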