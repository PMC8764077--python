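"""Single-factor indices for perceived risk and institutional trust.

Each 3-item block is summarised by a one-factor maximum-likelihood solution
on its covariance matrix; respondents get regression (Thomson) scores which
are then cut into terciles, and the vaccine-doubts score gets its
zero-inflated four-class coding.
"""

from bivintent import SyntheticConfig, generate_survey
from bivintent.dataset import RISK_ITEMS, TRUST_ITEMS
from bivintent.factors import (
    categorize_doubts,
    categorize_terciles,
    compute_scores,
    fit_single_factor,
)

ds = generate_survey(SyntheticConfig(n=448, seed=1))

for name, items in (("risk", RISK_ITEMS), ("trust", TRUST_ITEMS)):
    model = fit_single_factor(ds.table[items])
    print(f"{name}: variance explained "
          f"{100 * model.variance_explained:.1f}%")
    for item, lam in zip(model.item_names, model.loadings):
        print(f"  loading {item}: {lam:.2f}")
    scores = compute_scores(model, ds.table[items])
    coding, cats = categorize_terciles(scores, variable=f"{name}_cat")
    print("  tercile coding:", ", ".join(coding.formatted_labels(3)))
    print("  counts:", cats.value_counts().to_dict())

coding, cats = categorize_doubts(ds.table["vaccine_doubts"])
print("doubts coding:", ", ".join(coding.formatted_labels(3)))
print("counts:", cats.value_counts().to_dict())
# A higher loading means the item is a stronger indicator of the latent
# dimension; the tercile bounds are the row labels the coefficient tables
# print for the categorical covariates.
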