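"""Assign breeds to new individuals with calibration and screening.

Held-out genotypes from the training breeds are assigned with high
calibrated confidence; uniform-random genotypes are flagged by the
one-class screen even though the classifier still names a breed.
"""

from breedkit import (
    SimulationConfig,
    SnpPanel,
    predict_new,
    random_genotypes,
    simulate_breeds,
    train,
)
from breedkit.classify import predictions_frame

config = SimulationConfig(n_breeds=3, n_per_breed=25, n_snps=800, fst=0.3, seed=41)
G, breeds, geo, _ = simulate_breeds(config)

# hold out the last 5 individuals of each breed
train_ids = [i for b in breeds.breeds
             for i in breeds.table.loc[breeds.table["breed"] == b, "ID"].iloc[:20]]
test_ids = [i for i in G.individual_ids if i not in set(train_ids)]
bt_train = type(breeds)(breeds.table[breeds.table["ID"].isin(train_ids)]
                        .reset_index(drop=True))

panel = SnpPanel(G.snp_ids[:400])
model, _ = train(G.subset_individuals(train_ids), bt_train, panel,
                 algorithm="rf", seed=41, alpha=2.0)

held_out = predict_new(model, G.subset_individuals(test_ids), geo)
frame = predictions_frame(held_out)
print("held-out individuals (first 5):")
print(frame.head()[["ID", "breed", "P", "z_score", "one_class_pass"]])
print(f"held-out one-class pass rate: {frame['one_class_pass'].mean():.2f}")

noise = predict_new(model, random_genotypes(10, G.snps, seed=42))
noise_frame = predictions_frame(noise)
print(f"random-genotype rejection rate: "
      f"{(~noise_frame['one_class_pass']).mean():.2f}")
# z_score is the calibrated confidence (alpha = 2) of the breed call;
# one_class_pass False marks queries whose genotype likelihood under
# the assigned breed falls below that breed's training threshold —
# random or low-quality genotypes, not members of any training breed.
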