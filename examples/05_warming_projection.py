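"""Project MNC under a warming scenario and test eco-cluster shifts.

Rule-based (Cubist-style) models map environment -> cluster abundance; the
climate columns are perturbed (here +2.2 degC, +6% MAP — a 2050s
high-emission pathway magnitude), abundances and MNC are re-predicted, and
per-cluster shifts are tested with the Mann-Whitney U test.
"""

import pandas as pd

import necromap as nm
from necromap import synthetic as S
from necromap.rules import fit_abundance_mapper
from necromap.sae import SaeConfig, SaeRegressor

env = S.generate_environment(80, seed=1)
table, truth = S.generate_phylotypes(env, 100, seed=2)
truth.mnc_coefficients = S.default_mnc_coefficients(truth.cluster_names())
names = truth.cluster_names()
abund = pd.DataFrame(
    {c: table[truth.members(c)].sum(axis=1) for c in names}).reset_index(drop=True)
sugars = S.generate_amino_sugars(env, abund, truth, seed=3)
mnc = nm.mnc_table(sugars)["total_C"].to_numpy()

rule_models = {c: fit_abundance_mapper(env, abund, c, seed=4) for c in names}
for c, rm in rule_models.items():
    climate = rm.attribute_usage.loc[["MAT", "MAP", "AI"]].max().max()
    print(f"{c}: relative error {rm.relative_error:.2f}, "
          f"max climate attribute usage {climate:.0f}%")

feats = [*names, "NDVI", "silt"]
X = pd.concat([abund, env[["NDVI", "silt"]].reset_index(drop=True)], axis=1)
ce = SaeRegressor(len(feats), SaeConfig(seed=5))
ce.fit(X[feats].to_numpy(dtype=float), mnc)

env_future = S.scenario_perturb(env, delta_mat=2.2, delta_map_frac=0.06)
delta = nm.project_scenario(rule_models, ce, feats, env, env_future)

print("\nper-class summary (mg/g):")
print(delta.class_summary.round(2).to_string(index=False))
print("\ncluster shift tests (Mann-Whitney U, alpha=0.05):")
print(delta.shift_tests.round(4).to_string(index=False))
print("\n-> in this synthetic world warming shrinks the wet-cold cluster "
      "(which carries a +30 weight in the planted MNC law), so projected "
      "MNC declines; the elevation cluster barely responds to climate.")
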