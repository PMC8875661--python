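"""Compare a fitted aqueous logK model with published nanomaterial models.

Fits the aqueous logK pp-LFER on a synthetic cohort and tabulates its
coefficients against the packaged literature models (carbon nanotubes,
graphene, graphene oxide, BP).  The d_* columns are coefficient-wise
differences (fit − literature); similar V coefficients across materials
reflect the shared dominance of dispersion/cavity effects.
"""

from nanosorb.lfer import fit_pplfer, split_train_validation
from nanosorb.pipeline import compare_with_literature
from nanosorb.synthetic import GeneratorConfig, generate_descriptor_table, generate_endpoints

config = GeneratorConfig()
table = generate_descriptor_table(config, seed=0)
dataset = generate_endpoints(table, config, seed=1)
train, _ = split_train_validation(dataset.table, seed=2)
model = fit_pplfer(train, "logK_aqueous")

comparison = compare_with_literature(model)
cols = ["nanomaterial", "n_train", "r2_train", "intercept", "E", "S", "A", "B", "V"]
print(comparison[cols].to_string())
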