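"""Descriptive layer: stratified table, rank tests, Spearman matrix."""

from bivintent import SyntheticConfig, generate_survey
from bivintent.descriptives import (
    paired_wilcoxon,
    spearman_matrix,
    summaries_to_frame,
    table_one,
)
from bivintent.pipeline import derive_scores

ds = generate_survey(SyntheticConfig(n=448, seed=1))
df, _, _ = derive_scores(ds)

blocks = table_one(
    df, group="doubts_cat",
    continuous=["age", "vaccine_intent", "cta_intent"],
    categorical=["gender", "job"],
)
print(summaries_to_frame(blocks).to_string(index=False))

stat, p = paired_wilcoxon(df.vaccine_intent.to_numpy(), df.cta_intent.to_numpy())
print(f"\nvaccine vs CTA intention (paired signed-rank): p = {p:.2g}")

rho, pvals = spearman_matrix(
    df, ["trust_score", "vaccine_doubts", "risk_score", "conspiracy"]
)
print("\nSpearman correlations:")
print(rho.round(2).to_string())
# Continuous rows show median (q25, q75) per doubts class with a
# Kruskal-Wallis p; categorical rows show N (%) with the chi-squared/Fisher
# switch applied whenever an expected cell count drops below 10.
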