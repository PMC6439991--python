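"""Cross-validated evaluation on a simulated network.

Generates a planted-signal synthetic network (treat edges enriched among
drug-disease pairs sharing proteins), then runs 5-fold cross-validation of
the five per-meta-path random forests and their averaging ensemble, using
the no-common-protein reliable-negative filter for training negatives.
"""

import pathrx as px

config = px.SyntheticConfig(seed=1)
network, positives = px.generate_network(config)
print(f"simulated network: {network.n_drugs} drugs, {network.n_proteins} "
      f"proteins, {network.n_diseases} diseases, {len(positives)} treat pairs")

report = px.cross_validate(
    network,
    latent_feature_percent=0.03,  # SVD rank = 3% of min(#drugs, #diseases)
    strategy="reliable",
    seed=1,
    mask_test_edges=False,  # features from the full treat layer (transductive)
)

print("\npooled 5-fold metrics (one row per classifier):")
print(report.to_frame().round(3).to_string())
print("\nAUPR/AUC near 1 mean held-out treat pairs rank far above sampled")
print("negatives; the ensemble row averages the five base classifiers.")
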